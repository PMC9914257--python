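"""Maximum-likelihood-fitness population-evolution (MLFF-PE) estimator.

Fits the linear-in-parameters polynomial MR(S) model by evolving a
population of candidate coefficient vectors with differential-evolution
style operators:

* rand/1 mutation: ``beta = alpha_r1 + F * (alpha_r2 - alpha_r3)`` with
  r1, r2, r3 drawn uniformly, mutually distinct and distinct from the
  target index;
* binomial crossover at rate CR with one guaranteed mutant coordinate
  (index ``q_rand``);
* greedy one-to-one selection: the trial replaces the target only when
  its fitness is strictly smaller.

The fitness J(alpha) is the mean squared residual of the model.  Under
the assumed independent zero-mean Gaussian observation noise, the
log-likelihood of the data is ``const - (D/2) ln J(alpha)`` once the
noise variance is profiled out at its maximising value
``sigma^2 = J(alpha)``, so minimising J is exactly maximum-likelihood
estimation (and coincides with the ordinary least-squares objective,
which serves as an independent check in the test suite).

A single seeded generator drives every random draw.  Per generation and
per individual ``p`` the draw order is: (1) rejection-sampled indices
r1, r2, r3; (2) ``q_rand``; (3) Q crossover uniforms — so runs are
bit-reproducible given the seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .drying_model import ParameterVector, phi
from .errors import (
    ConfigError,
    DataError,
    DegenerateInitWarning,
    PerfectFitWarning,
    UnderdeterminedFitWarning,
)

__all__ = [
    "EvolutionConfig",
    "EvolutionState",
    "FitResult",
    "init_population",
    "mutate",
    "crossover",
    "mlff",
    "sigma2_mle",
    "log_likelihood",
    "select",
    "fit",
    "load_config",
]


@dataclass(frozen=True)
class EvolutionConfig:
    """Settings of the population-evolution estimator.

    ``population_size`` defaults to P = 30.  The scale factor F = 0.5 and
    crossover rate CR = 0.9 are standard differential-evolution practice;
    ``max_generations`` defaults to 500, enough for the population to
    settle onto the least-squares optimum on drying-sized problems
    (D ~ 83, order <= 3).

    The initial population is uniform on ``[init_low, init_high)``.  The
    default [-20, 20) comfortably covers the coefficient magnitudes seen
    in slice-drying fits (order of 1-15).  A deliberately narrow range
    such as [0, 1) is risky: with rand/1 mutation the population's spread
    contracts multiplicatively, and when the least-squares optimum lies
    several units outside the initial hypercube the population routinely
    collapses before reaching it (premature convergence), so the fit
    stalls at a markedly sub-optimal residual.
    """

    population_size: int = 30
    max_generations: int = 500
    scale_factor: float = 0.5
    crossover_rate: float = 0.9
    init_low: float = -20.0
    init_high: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 4:
            raise ConfigError(
                "population_size must be >= 4 (mutation draws three indices "
                f"distinct from the target), got {self.population_size}"
            )
        if self.max_generations < 1:
            raise ConfigError("max_generations must be >= 1")
        if self.scale_factor <= 0:
            raise ConfigError("scale_factor must be positive")
        if not 0.0 <= self.crossover_rate <= 1.0:
            raise ConfigError("crossover_rate must lie in [0, 1]")


@dataclass
class EvolutionState:
    """Population, fitness values and RNG of one evolution run."""

    generation: int
    population: np.ndarray  # (P, Q)
    fitness: np.ndarray  # (P,)
    rng: np.random.Generator

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.fitness))

    @property
    def best_fitness(self) -> float:
        return float(self.fitness[self.best_index])

    @property
    def best_individual(self) -> ParameterVector:
        return ParameterVector(self.population[self.best_index].copy())


@dataclass(frozen=True)
class FitResult:
    """Outcome of a fit: the best individual of the final population."""

    alpha: ParameterVector
    j: float
    sigma2: float
    trace: np.ndarray  # best J per generation, entry 0 = initial population
    config: EvolutionConfig
    order: int

    @property
    def coefficients(self) -> np.ndarray:
        return self.alpha.coefficients


def init_population(cfg: EvolutionConfig, q: int) -> EvolutionState:
    """Draw the initial P x Q population i.i.d. uniform on [init_low, init_high)."""
    if q < 2:
        raise ConfigError(f"parameter dimension must be >= 2, got {q}")
    if cfg.init_low == cfg.init_high:
        warnings.warn(
            "init_low == init_high: the initial population is constant",
            DegenerateInitWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(cfg.seed)
    pop = cfg.init_low + (cfg.init_high - cfg.init_low) * rng.random(
        (cfg.population_size, q)
    )
    return EvolutionState(
        generation=0,
        population=pop,
        fitness=np.full(cfg.population_size, np.nan),
        rng=rng,
    )


def _draw_distinct_indices(rng: np.random.Generator, p: int, pop_size: int) -> tuple[int, int, int]:
    """Rejection-sample r1, r2, r3 uniform on {0..P-1}, distinct and != p."""
    while True:
        r1 = int(rng.integers(pop_size))
        if r1 != p:
            break
    while True:
        r2 = int(rng.integers(pop_size))
        if r2 != p and r2 != r1:
            break
    while True:
        r3 = int(rng.integers(pop_size))
        if r3 != p and r3 != r1 and r3 != r2:
            break
    return r1, r2, r3


def mutate(state: EvolutionState, p: int, f: float) -> np.ndarray:
    """rand/1 differential mutation for target index ``p``.

    Returns ``alpha_r1 + f * (alpha_r2 - alpha_r3)``; mutants are not
    clamped and may leave the initialisation range.
    """
    pop = state.population
    r1, r2, r3 = _draw_distinct_indices(state.rng, p, pop.shape[0])
    return pop[r1] + f * (pop[r2] - pop[r3])


def crossover(
    target: np.ndarray,
    mutant: np.ndarray,
    cr: float,
    q_rand: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Binomial crossover: mutant coordinates where u < CR, always at q_rand."""
    target = np.asarray(target, dtype=np.float64)
    mutant = np.asarray(mutant, dtype=np.float64)
    q = target.size
    if not 0 <= q_rand < q:
        raise ConfigError(f"q_rand {q_rand} outside [0, {q})")
    u = rng.random(q)
    take = u < cr
    take[q_rand] = True
    return np.where(take, mutant, target)


def mlff(
    alpha: ParameterVector | Sequence[float],
    s: Sequence[float],
    mr: Sequence[float],
) -> float:
    """Maximum-likelihood fitness: mean squared residual of the model.

    ``J(alpha) = (1/D) sum_k [MR(k) - phi(k)^T alpha]^2``.
    """
    coeffs = alpha.coefficients if isinstance(alpha, ParameterVector) else np.asarray(
        alpha, dtype=np.float64
    )
    s = np.asarray(s, dtype=np.float64)
    mr = np.asarray(mr, dtype=np.float64)
    if s.size == 0 or s.shape != mr.shape:
        raise DataError("S and MR series must be non-empty and of equal length")
    design = phi(s, coeffs.size - 1)
    resid = mr - design @ coeffs
    return float(np.mean(resid**2))


def sigma2_mle(residuals: Sequence[float]) -> float:
    """Maximum-likelihood noise variance: the mean squared residual.

    Identical in form to :func:`mlff` evaluated at the same coefficients.
    """
    r = np.asarray(residuals, dtype=np.float64)
    if r.size == 0:
        raise DataError("empty residual series")
    return float(np.mean(r**2))


def log_likelihood(j: float, d: int) -> float:
    """Profile log-likelihood up to an additive constant: -(D/2) ln J.

    The dropped constant collects the Gaussian normalisation terms, which
    do not depend on the coefficients.  A perfect fit (J = 0) makes the
    profile likelihood unbounded; +inf is returned with a
    :class:`PerfectFitWarning`.
    """
    if j < 0:
        raise DataError(f"fitness must be non-negative, got {j}")
    if j == 0:
        warnings.warn(
            "zero residual variance: log-likelihood is unbounded",
            PerfectFitWarning,
            stacklevel=2,
        )
        return math.inf
    return -0.5 * d * math.log(j)


def select(
    target: np.ndarray, trial: np.ndarray, j_target: float, j_trial: float
) -> tuple[np.ndarray, float]:
    """Greedy selection: the trial survives only with strictly smaller J."""
    if j_trial < j_target:
        return trial, j_trial
    return target, j_target


def _population_fitness(pop: np.ndarray, design: np.ndarray, mr: np.ndarray) -> np.ndarray:
    resid = mr[:, None] - design @ pop.T  # (D, P)
    return np.mean(resid**2, axis=0)


def fit(
    s: Sequence[float],
    mr: Sequence[float],
    n: int,
    cfg: EvolutionConfig | None = None,
) -> FitResult:
    """Fit an order-``n`` polynomial MR(S) model by population evolution.

    Runs ``max_generations`` generations of mutation, crossover and greedy
    selection over the whole population and reports the argmin-J individual
    of the final population, together with the per-generation best-J trace
    (whose first entry scores the initial population).
    """
    cfg = cfg or EvolutionConfig()
    s = np.asarray(s, dtype=np.float64)
    mr = np.asarray(mr, dtype=np.float64)
    if s.shape != mr.shape or s.size == 0:
        raise DataError("S and MR series must be non-empty and of equal length")
    if not (np.all(np.isfinite(s)) and np.all(np.isfinite(mr))):
        raise DataError("non-finite values in the input series")
    q = n + 1
    if s.size < q:
        warnings.warn(
            f"only D={s.size} observations for Q={q} parameters: "
            "the fit is under-determined",
            UnderdeterminedFitWarning,
            stacklevel=2,
        )

    design = phi(s, n)
    state = init_population(cfg, q)
    state.fitness = _population_fitness(state.population, design, mr)

    p_size, f, cr = cfg.population_size, cfg.scale_factor, cfg.crossover_rate
    trace = np.empty(cfg.max_generations + 1)
    trace[0] = state.best_fitness
    trials = np.empty_like(state.population)
    for gen in range(cfg.max_generations):
        for p in range(p_size):
            mutant = mutate(state, p, f)
            q_rand = int(state.rng.integers(q))
            trials[p] = crossover(state.population[p], mutant, cr, q_rand, state.rng)
        j_trials = _population_fitness(trials, design, mr)
        improved = j_trials < state.fitness
        state.population[improved] = trials[improved]
        state.fitness[improved] = j_trials[improved]
        state.generation = gen + 1
        trace[gen + 1] = state.best_fitness

    best = state.best_individual
    j_best = state.best_fitness
    return FitResult(
        alpha=best, j=j_best, sigma2=j_best, trace=trace, config=cfg, order=n
    )


def load_config(path: str | Path) -> EvolutionConfig:
    """Read a plain-text ``key = value`` config file.

    Recognised keys: population_size, max_generations, scale_factor,
    crossover_rate, init_low, init_high, seed.  Lines starting with ``#``
    and blank lines are ignored; ``order`` is accepted and returned to the
    caller separately via :func:`load_config_with_order`.
    """
    cfg, _ = load_config_with_order(path)
    return cfg


def load_config_with_order(path: str | Path) -> tuple[EvolutionConfig, int | None]:
    int_keys = {"population_size", "max_generations", "seed"}
    float_keys = {"scale_factor", "crossover_rate", "init_low", "init_high"}
    values: dict[str, float | int] = {}
    order: int | None = None
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, val = (part.strip() for part in line.partition("="))
        if key not in int_keys | float_keys | {"order"}:
            raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
        try:
            if key in int_keys:
                values[key] = int(val)
            elif key in float_keys:
                values[key] = float(val)
            else:
                order = int(val)
        except ValueError as exc:
            raise ConfigError(f"{path}:{lineno}: bad value for {key}: {val!r}") from exc
    return EvolutionConfig(**values), order
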