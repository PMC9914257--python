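"""Top-view image pipeline: from RGB frames to a shrinkage series.

Each drying frame is reduced to a single number, the summed pixel area of
the slices, by a six-step pipeline: RGB -> grayscale (channel mean) ->
global threshold (iterative intermeans by default, Otsu optionally) ->
binary mask -> hole filling -> retention of the ``k`` largest particles ->
total foreground area.  Dividing each frame's area by the first frame's
gives the dimensionless shrinkage ``S(t) = A(t) / A(0)``.

Conventions (all configurable where noted):

* slices are *bright* objects on a dark background (``bright_foreground``);
* binarisation keeps pixels *strictly greater* than the threshold;
* particles use 8-connectivity, hole filling uses 4-connectivity for the
  background (the standard complementary pair);
* ties for the k-th largest particle keep the earlier raster-scan label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure

from .errors import (
    DataError,
    DegenerateHistogramWarning,
    EmptyForegroundWarning,
    TieBreakWarning,
)

__all__ = [
    "Particle",
    "ParticleSet",
    "ShrinkageSeries",
    "to_grayscale",
    "cluster_threshold",
    "binarize",
    "fill_holes",
    "filter_top_particles",
    "total_area",
    "shrinkage_series",
    "process_frame",
    "extract_series",
    "read_manifest",
]


@dataclass(frozen=True)
class Particle:
    """One connected component of a binary mask."""

    label: int
    area: int
    coords: np.ndarray  # (area, 2) row/col pixel coordinates


@dataclass(frozen=True)
class ParticleSet:
    """Disjoint connected components retained from a mask."""

    particles: tuple[Particle, ...]

    def __len__(self) -> int:
        return len(self.particles)

    @property
    def areas(self) -> np.ndarray:
        return np.array([p.area for p in self.particles], dtype=np.int64)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        for p in self.particles:
            out[p.coords[:, 0], p.coords[:, 1]] = True
        return out


@dataclass(frozen=True)
class ShrinkageSeries:
    """Time-indexed areas and their ratio to the initial area."""

    times: np.ndarray  # minutes
    areas: np.ndarray  # pixel counts
    shrinkage: np.ndarray  # A(t) / A(0), equals 1 at the first sample

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_min": self.times, "area_px": self.areas, "shrinkage": self.shrinkage}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Average the three colour channels into an 8-bit grayscale image.

    The exact rational mean of the three channel values is rounded
    half-to-even and clipped to [0, 255].
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise DataError(
            f"expected an RGB image with 3 channels, got shape {img.shape}"
        )
    mean = img.astype(np.float64).sum(axis=-1) / 3.0
    return np.clip(np.round(mean), 0, 255).astype(np.uint8)


def _intermeans_threshold(hist: np.ndarray) -> int:
    """Ridler–Calvard fixed point on a 256-bin histogram.

    Iterates T <- floor((mean below-or-at T + mean above T) / 2) from the
    global mean until T no longer changes; the returned integer satisfies
    the fixed-point condition exactly.
    """
    levels = np.arange(256, dtype=np.float64)
    total = hist.sum()
    csum = np.cumsum(hist)
    cmom = np.cumsum(hist * levels)
    t = int(np.floor((hist * levels).sum() / total))
    for _ in range(256):
        n_lo = csum[t]
        n_hi = total - n_lo
        if n_lo == 0 or n_hi == 0:
            break
        m_lo = cmom[t] / n_lo
        m_hi = (cmom[-1] - cmom[t]) / n_hi
        t_new = int(np.floor((m_lo + m_hi) / 2.0))
        if t_new == t:
            break
        t = t_new
    return t


def cluster_threshold(
    img: np.ndarray, method: Literal["intermeans", "otsu"] = "intermeans"
) -> int:
    """Two-cluster histogram threshold of a grayscale image.

    The default is the iterative intermeans (Ridler–Calvard) rule, whose
    fixed point places the threshold halfway between the two class means;
    ``method="otsu"`` selects Otsu's between-class-variance criterion
    instead.  A constant image has no two clusters: its single intensity is
    returned with a :class:`DegenerateHistogramWarning`.
    """
    img = np.asarray(img)
    if img.size == 0:
        raise DataError("cannot threshold an empty image")
    hist = np.bincount(img.reshape(-1).astype(np.int64), minlength=256)[:256]
    nonzero = np.flatnonzero(hist)
    if len(nonzero) == 1:
        warnings.warn(
            f"constant image at intensity {nonzero[0]}; threshold is degenerate",
            DegenerateHistogramWarning,
            stacklevel=2,
        )
        return int(nonzero[0])
    if method == "otsu":
        return int(filters.threshold_otsu(hist=(hist, np.arange(256))))
    if method != "intermeans":
        raise DataError(f"unknown threshold method: {method!r}")
    return _intermeans_threshold(hist)


def binarize(img: np.ndarray, thr: int, bright_foreground: bool = True) -> np.ndarray:
    """Threshold a grayscale image into a boolean foreground mask.

    Foreground is strictly above ``thr`` when ``bright_foreground``,
    otherwise at-or-below ``thr``.
    """
    if not 0 <= thr <= 255:
        raise DataError(f"threshold {thr} outside [0, 255]")
    img = np.asarray(img)
    return img > thr if bright_foreground else img <= thr


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background regions not 4-connected to the image border.

    Foreground pixels are never removed, so the operation is monotone and
    idempotent.
    """
    mask = np.asarray(mask, dtype=bool)
    # default cross-shaped structure = 4-connectivity for the background
    return ndimage.binary_fill_holes(mask)


def filter_top_particles(mask: np.ndarray, k: int = 6) -> ParticleSet:
    """Keep the ``k`` largest 8-connected particles of a mask.

    A tie for rank ``k`` is broken in favour of the particle whose first
    pixel comes earlier in raster-scan order (the smaller label), with a
    :class:`TieBreakWarning`.  An empty mask yields an empty set with an
    :class:`EmptyForegroundWarning`.
    """
    if k < 1:
        raise DataError(f"k must be >= 1, got {k}")
    mask = np.asarray(mask, dtype=bool)
    labels = measure.label(mask, connectivity=2)
    n = labels.max()
    if n == 0:
        warnings.warn("mask has no foreground pixels", EmptyForegroundWarning, stacklevel=2)
        return ParticleSet(())
    areas = np.bincount(labels.reshape(-1))[1:]  # area per label, label order = raster order
    order = np.lexsort((np.arange(1, n + 1), -areas))  # by area desc, then label asc
    kept = order[:k]
    if n > k and areas[order[k - 1]] == areas[order[k]]:
        warnings.warn(
            f"tie at rank {k}: particles with area {areas[order[k]]} compete; "
            "keeping the earlier raster-scan label",
            TieBreakWarning,
            stacklevel=2,
        )
    kept_labels = sorted(int(i) + 1 for i in kept)
    particles = tuple(
        Particle(label=lab, area=int(areas[lab - 1]), coords=np.argwhere(labels == lab))
        for lab in kept_labels
    )
    return ParticleSet(particles)


def total_area(ps: ParticleSet) -> int:
    """Summed pixel count of all retained particles (0 for an empty set)."""
    return int(ps.areas.sum()) if len(ps) else 0


def shrinkage_series(
    areas: Sequence[float], times: Sequence[float]
) -> ShrinkageSeries:
    """Turn a per-frame area series into shrinkage S(t) = A(t)/A(0)."""
    areas = np.asarray(areas, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    if areas.shape != times.shape:
        raise DataError(
            f"areas and times differ in length: {areas.shape} vs {times.shape}"
        )
    if areas.size == 0:
        raise DataError("empty area series")
    if np.any(areas < 0):
        raise DataError("negative area encountered")
    if areas[0] == 0:
        raise DataError("initial area A(0) is zero; shrinkage undefined")
    s = areas / areas[0]
    s[0] = 1.0
    return ShrinkageSeries(times=times, areas=areas, shrinkage=s)


def process_frame(
    frame: np.ndarray,
    *,
    threshold_method: Literal["intermeans", "otsu"] = "intermeans",
    bright_foreground: bool = True,
    top_k: int = 6,
) -> tuple[int, int]:
    """Run the full pipeline on one frame.

    Accepts RGB or already-grayscale frames and returns
    ``(total_area, threshold)``.
    """
    frame = np.asarray(frame)
    gray = to_grayscale(frame) if frame.ndim == 3 else frame
    thr = cluster_threshold(gray, method=threshold_method)
    mask = binarize(gray, thr, bright_foreground=bright_foreground)
    mask = fill_holes(mask)
    ps = filter_top_particles(mask, k=top_k)
    return total_area(ps), thr


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a frame manifest CSV with columns ``time_min, filename``."""
    df = pd.read_csv(path)
    missing = {"time_min", "filename"} - set(df.columns)
    if missing:
        raise DataError(f"manifest {path} lacks columns {sorted(missing)}")
    return df


def extract_series(
    frames_dir: str | Path,
    manifest: str | Path | pd.DataFrame | None = None,
    **pipeline_kwargs,
) -> ShrinkageSeries:
    """Run the pipeline over a directory of frames.

    Frame order and times come from the manifest when given; otherwise
    PNG/TIFF files are taken in lexicographic order with their index
    (in samples) as the time axis.
    """
    frames_dir = Path(frames_dir)
    if manifest is None:
        files = sorted(
            p for p in frames_dir.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff"}
        )
        times = np.arange(len(files), dtype=float)
    else:
        df = manifest if isinstance(manifest, pd.DataFrame) else read_manifest(manifest)
        files = [frames_dir / f for f in df["filename"]]
        times = df["time_min"].to_numpy(dtype=float)
    if not files:
        raise DataError(f"no frames found under {frames_dir}")
    areas = []
    for f in files:
        try:
            frame = iio.imread(f)
        except Exception as exc:  # noqa: BLE001 - surface the frame name
            raise DataError(f"could not read frame {f}: {exc}") from exc
        area, _ = process_frame(frame, **pipeline_kwargs)
        areas.append(area)
    return shrinkage_series(areas, times)
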