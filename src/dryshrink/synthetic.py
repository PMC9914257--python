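"""Synthetic drying experiments with known ground truth.

The generator emulates a bench-top drying run monitored from above: six
bright cylindrical slices on a dark cavity floor, photographed every
30 s for about 41 minutes while their projected area shrinks and their
moisture ratio decays from 1 toward a near-dry endpoint.

The moisture ratio follows a first-order exponential decay
``MR(t) = exp(-k t)``; the default rate empties a slice from 9.87 to
0.176 g/g dry-basis moisture over 41 min (final MR ~ 0.018).  Shrinkage
is tied to MR through a known monotone cubic ``MR = p(S)`` — solved for
S by bisection — so the fitting stage has an exact coefficient ground
truth to recover.  Observed MR adds independent zero-mean Gaussian noise;
rendered frames optionally add Gaussian pixel noise.  Disk shrinkage is
area-proportional (radius scales with sqrt(S)), uniform across the six
disks unless per-disk scales are given.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .drying_model import predict_mr
from .errors import DataError, LayoutError, MonotonicityError

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "default_true_alpha",
    "simulate_series",
    "render_frames",
    "write_fixture",
]

#: Dry-basis moisture content of a fresh slice (g water / g dry matter)
#: and the near-dry stopping value the decay rate is anchored to.
INITIAL_MC = 9.87
FINAL_MC = 0.176
DEFAULT_DURATION_MIN = 41.0
DEFAULT_DECAY_RATE = math.log(INITIAL_MC / FINAL_MC) / DEFAULT_DURATION_MIN


def default_true_alpha() -> np.ndarray:
    """Monotone cubic MR = p(S) used as the default ground-truth link.

    Solves the cubic through the anchor points
    (0.35, 0.012), (0.60, 0.20), (0.80, 0.45), (1.0, 1.0), a convex
    increasing curve of the shape seen in slice-drying experiments, with
    p strictly increasing on [0.35, 1] and p(1) = 1.
    """
    s = np.array([0.35, 0.60, 0.80, 1.0])
    mr = np.array([0.012, 0.20, 0.45, 1.0])
    return np.linalg.solve(np.vander(s, 4, increasing=True), mr)


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions of one synthetic drying run.

    Times are minutes; intensities are 8-bit levels; the canvas is laid
    out as a 3 x 2 grid of disk centres spaced so disks never touch at
    their initial radius.
    """

    duration_min: float = DEFAULT_DURATION_MIN
    sample_period_min: float = 0.5
    decay_rate_per_min: float = DEFAULT_DECAY_RATE
    true_alpha: np.ndarray = field(default_factory=default_true_alpha)
    s_floor: float = 0.35
    noise_sigma: float = 0.02
    canvas_height: int = 260
    canvas_width: int = 360
    disk_centers: tuple[tuple[float, float], ...] = (
        (70, 70), (70, 180), (70, 290), (190, 70), (190, 180), (190, 290),
    )
    initial_radius_px: float = 40.0
    per_disk_scale: tuple[float, ...] | None = None
    foreground: int = 220
    background: int = 30
    pixel_noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(
            self, "true_alpha", np.asarray(self.true_alpha, dtype=np.float64)
        )
        if self.sample_period_min <= 0:
            raise DataError("sample_period_min must be positive")
        if self.duration_min < 0:
            raise DataError("duration_min must be non-negative")
        if not 0 < self.s_floor < 1:
            raise DataError("s_floor must lie in (0, 1)")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_min / self.sample_period_min)) + 1

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.sample_period_min

    def disk_scales(self) -> np.ndarray:
        if self.per_disk_scale is None:
            return np.ones(len(self.disk_centers))
        scales = np.asarray(self.per_disk_scale, dtype=np.float64)
        if scales.shape != (len(self.disk_centers),):
            raise DataError("per_disk_scale must give one factor per disk")
        return scales


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knows about one run."""

    times: np.ndarray
    mr_true: np.ndarray
    mr_noisy: np.ndarray
    s_true: np.ndarray
    areas_true: np.ndarray  # analytic summed disk area, px^2
    true_alpha: np.ndarray


def _check_monotone(alpha: np.ndarray, s_floor: float) -> None:
    grid = np.linspace(s_floor, 1.0, 2001)
    vals = predict_mr(alpha, grid)
    if not np.all(np.diff(vals) > 0):
        raise MonotonicityError(
            f"true polynomial is not strictly increasing on [{s_floor}, 1]"
        )


def _invert_polynomial(
    alpha: np.ndarray, mr: np.ndarray, s_floor: float, tol: float = 1e-10
) -> np.ndarray:
    """Solve p(S) = MR for S on [s_floor, 1] by vectorised bisection."""
    lo = np.full_like(mr, s_floor)
    hi = np.ones_like(mr)
    p_lo = predict_mr(alpha, lo)
    p_hi = predict_mr(alpha, hi)
    if np.any(mr < p_lo - 1e-12) or np.any(mr > p_hi + 1e-12):
        raise DataError(
            "moisture ratio leaves the range of the true polynomial on "
            f"[{s_floor}, 1]; lower s_floor or shorten the run"
        )
    target = np.clip(mr, p_lo, p_hi)
    for _ in range(64):  # 2^-64 < 1e-10 interval width
        mid = 0.5 * (lo + hi)
        below = predict_mr(alpha, mid) < target
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return 0.5 * (lo + hi)


def simulate_series(spec: SimulationSpec) -> GroundTruth:
    """Generate one run's time series with ground truth."""
    _check_monotone(spec.true_alpha, spec.s_floor)
    t = spec.times
    mr_true = np.exp(-spec.decay_rate_per_min * t)
    s_true = _invert_polynomial(spec.true_alpha, mr_true, spec.s_floor)
    rng = np.random.default_rng([spec.seed, 0])
    mr_noisy = mr_true + spec.noise_sigma * rng.standard_normal(t.size)
    r0 = spec.initial_radius_px
    areas_true = math.pi * r0**2 * s_true * spec.disk_scales().sum()
    return GroundTruth(
        times=t,
        mr_true=mr_true,
        mr_noisy=mr_noisy,
        s_true=s_true,
        areas_true=areas_true,
        true_alpha=spec.true_alpha.copy(),
    )


def _check_layout(spec: SimulationSpec) -> None:
    centers = np.asarray(spec.disk_centers, dtype=np.float64)
    r_max = spec.initial_radius_px * math.sqrt(spec.disk_scales().max())
    for i in range(len(centers)):
        cy, cx = centers[i]
        if (
            cy - r_max < 0
            or cx - r_max < 0
            or cy + r_max >= spec.canvas_height
            or cx + r_max >= spec.canvas_width
        ):
            raise LayoutError(f"disk {i} at {tuple(centers[i])} leaves the canvas")
        for j in range(i + 1, len(centers)):
            dist = float(np.hypot(*(centers[i] - centers[j])))
            if dist <= 2 * r_max:
                raise LayoutError(
                    f"disks {i} and {j} would touch (centre distance {dist:.1f} px, "
                    f"max radius {r_max:.1f} px)"
                )


def render_frames(
    truth: GroundTruth, spec: SimulationSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterise the disk scene for every sample.

    Disks are drawn without anti-aliasing (a pixel is foreground iff its
    centre lies within the disk), so a noiseless frame binarises back to
    exactly the rendered pixel count.  Returns ``(frames, rendered_areas)``
    where ``frames`` is a (T, H, W, 3) uint8 stack.
    """
    _check_layout(spec)
    h, w = spec.canvas_height, spec.canvas_width
    yy, xx = np.mgrid[0:h, 0:w]
    centers = np.asarray(spec.disk_centers, dtype=np.float64)
    scales = spec.disk_scales()
    rng = np.random.default_rng([spec.seed, 1])
    frames = np.empty((truth.times.size, h, w, 3), dtype=np.uint8)
    rendered_areas = np.empty(truth.times.size, dtype=np.int64)
    for k, s in enumerate(truth.s_true):
        mask = np.zeros((h, w), dtype=bool)
        for (cy, cx), sc in zip(centers, scales):
            r2 = spec.initial_radius_px**2 * s * sc
            mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r2
        rendered_areas[k] = int(mask.sum())
        plane = np.where(mask, float(spec.foreground), float(spec.background))
        if spec.pixel_noise_sigma > 0:
            plane = plane + spec.pixel_noise_sigma * rng.standard_normal((h, w))
        plane = np.clip(np.round(plane), 0, 255).astype(np.uint8)
        frames[k] = plane[..., None]
    return frames, rendered_areas


def write_fixture(
    truth: GroundTruth,
    frames: np.ndarray,
    out_dir: str | Path,
    spec: SimulationSpec | None = None,
) -> Path:
    """Write PNG frames, a manifest CSV, the ground-truth CSV and a spec echo.

    Returns the manifest path.  Reruns with the same spec and seed produce
    byte-identical CSVs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = [f"frame_{k:04d}.png" for k in range(frames.shape[0])]
    for name, frame in zip(names, frames):
        iio.imwrite(out_dir / name, frame)
    manifest = out_dir / "manifest.csv"
    pd.DataFrame({"time_min": truth.times, "filename": names}).to_csv(
        manifest, index=False
    )
    pd.DataFrame(
        {
            "time_min": truth.times,
            "shrinkage_true": truth.s_true,
            "moisture_ratio_true": truth.mr_true,
            "moisture_ratio": truth.mr_noisy,
            "area_px_true": truth.areas_true,
        }
    ).to_csv(out_dir / "ground_truth.csv", index=False)
    if spec is not None:
        payload = asdict(spec)
        payload["true_alpha"] = [float(c) for c in spec.true_alpha]
        (out_dir / "spec.json").write_text(json.dumps(payload, indent=2) + "\n")
    return manifest
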