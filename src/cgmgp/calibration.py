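"""Per-genotype estimation of the growth-model parameters.

The 8 genotypic parameters are recovered by model inversion: a
Differential Evolution (DE/rand/1/bin) search over the admissible
parameter box, minimizing the mean normalized root-mean-square error
(NRMSE) between observed and simulated trait trajectories, averaged over
replicates then over the calibration traits.  The best parameter set found
is treated downstream as the genotype's "observed" parameter values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .growth_model import (
    CALIBRATION_TRAITS,
    PARAMETER_BOUNDS,
    PARAMETER_NAMES,
    GenotypeParameters,
    ModelConstants,
    WeatherSeries,
    simulate,
)

__all__ = [
    "nrmse",
    "nmae_series",
    "CalibrationProblem",
    "objective",
    "DESettings",
    "DEResult",
    "differential_evolution",
    "estimate_genotype_parameters",
]

logger = logging.getLogger(__name__)


def nrmse(observed, predicted) -> float:
    """Normalized root-mean-square error: sqrt(mean(((y - yhat)/y)^2)).

    Relative errors are undefined at y = 0; callers drop such points
    before calling.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.size < 1:
        raise ValueError("observed and predicted must be equal-length, non-empty")
    if np.any(observed == 0):
        raise ValueError("zero observation in relative error")
    return float(np.sqrt(np.mean(((observed - predicted) / observed) ** 2)))


def nmae_series(observed, predicted) -> float:
    """Normalized mean absolute error: mean(|y - yhat| / |y|)."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.size < 1:
        raise ValueError("observed and predicted must be equal-length, non-empty")
    if np.any(observed == 0):
        raise ValueError("zero observation in relative error")
    return float(np.mean(np.abs((observed - predicted) / observed)))


@dataclass
class CalibrationProblem:
    """Observed data and settings for calibrating one genotype."""

    phenotypes: pd.DataFrame          # tidy (replicate, day, trait, value) for one genotype
    weather: WeatherSeries
    constants: ModelConstants = field(default_factory=ModelConstants)
    traits: tuple[str, ...] = CALIBRATION_TRAITS
    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(PARAMETER_BOUNDS)
    )

    def __post_init__(self):
        if self.phenotypes.empty:
            raise ValueError("no phenotype observations")
        present = set(self.phenotypes.trait.unique())
        self.traits = tuple(t for t in self.traits if t in present)
        if not self.traits:
            raise ValueError("no calibration traits present in the phenotype table")


def _trait_tables(problem: CalibrationProblem):
    """Pre-index observations: {trait: [(days, values) per replicate]} with
    zero-valued observations dropped (relative errors divide by y)."""
    tables = {}
    for trait in problem.traits:
        sub = problem.phenotypes[problem.phenotypes.trait == trait]
        reps = []
        for _, rep_df in sub.groupby("replicate"):
            rep_df = rep_df[rep_df.value != 0]
            if len(rep_df):
                reps.append((rep_df.day.to_numpy(dtype=int), rep_df.value.to_numpy(dtype=float)))
        if reps:
            tables[trait] = reps
    return tables


def objective(params, problem: CalibrationProblem, _tables=None) -> float:
    """Mean over traits of the replicate-mean NRMSE at ``params``.

    Simulation failures return +inf so the optimizer can discard the
    candidate.
    """
    tables = _tables if _tables is not None else _trait_tables(problem)
    if not isinstance(params, GenotypeParameters):
        params = GenotypeParameters.from_array(params)
    try:
        out = simulate(params, problem.weather, problem.constants)
    except Exception:
        logger.warning("simulation failure during calibration", exc_info=True)
        return float("inf")
    trait_errors = []
    for trait, reps in tables.items():
        series = out.trait_series(trait)
        rep_errors = []
        for days, values in reps:
            if len(series) == 1:  # harvest traits: single point at the end
                pred = np.repeat(series, len(days))
            else:
                pred = series[days - 1]
            rep_errors.append(np.sqrt(np.mean(((values - pred) / values) ** 2)))
        trait_errors.append(np.mean(rep_errors))
    return float(np.mean(trait_errors))


@dataclass(frozen=True)
class DESettings:
    """Differential Evolution hyper-parameters (rand/1/bin)."""

    population: int | None = None  # default 10 * dimension
    f: float = 0.8                 # differential weight
    cr: float = 0.5                # crossover rate (low CR suits the partially
                                   # separable objective; high CR converges
                                   # prematurely on it)
    generations: int = 10000
    seed: int = 0
    tol: float = 0.0               # stop early once best objective <= tol


@dataclass
class DEResult:
    x: np.ndarray
    fun: float
    trace: np.ndarray      # best objective after init and after each generation
    n_evaluations: int


def differential_evolution(func, bounds, settings: DESettings) -> DEResult:
    """DE/rand/1/bin with reflection bound handling and greedy selection.

    Mutation v = a + F (b - c) over distinct population members, binomial
    crossover at rate CR with one forced index, candidates reflected back
    into the search box.  Deterministic given the settings seed.  With
    ``generations=0`` the best member of the random initial population is
    returned.
    """
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi)) and np.all(hi > lo)):
        raise ValueError("bounds must be finite with hi > lo")
    dim = len(bounds)
    rng = np.random.default_rng(settings.seed)
    np_size = settings.population or 10 * dim
    if np_size < 4:
        raise ValueError("population must be >= 4")

    pop = lo + rng.random((np_size, dim)) * (hi - lo)
    fitness = np.array([func(ind) for ind in pop])
    n_eval = np_size
    trace = [float(fitness.min())]

    def reflect(v):
        # reflect into [lo, hi]; loop handles overshoot past both bounds
        for _ in range(100):
            below, above = v < lo, v > hi
            if not (below.any() or above.any()):
                return v
            v = np.where(below, 2 * lo - v, v)
            v = np.where(above, 2 * hi - v, v)
        return np.clip(v, lo, hi)

    for _ in range(settings.generations):
        if trace[-1] <= settings.tol:
            break
        for i in range(np_size):
            choices = rng.choice(np_size - 1, size=3, replace=False)
            a, b, c = [(idx if idx < i else idx + 1) for idx in choices]
            mutant = reflect(pop[a] + settings.f * (pop[b] - pop[c]))
            cross = rng.random(dim) < settings.cr
            cross[rng.integers(dim)] = True
            trial = np.where(cross, mutant, pop[i])
            f_trial = func(trial)
            n_eval += 1
            if f_trial <= fitness[i]:
                pop[i] = trial
                fitness[i] = f_trial
        trace.append(float(fitness.min()))

    best = int(np.argmin(fitness))
    return DEResult(pop[best].copy(), float(fitness[best]), np.array(trace), n_eval)


def estimate_genotype_parameters(
    problem: CalibrationProblem, settings: DESettings | None = None
) -> dict:
    """Calibrate one genotype; returns parameters, objective and fit report.

    The fit report gives one NMAE per calibration trait (pooled over
    replicates and time points) at the selected parameter set.
    """
    settings = settings or DESettings()
    tables = _trait_tables(problem)
    bounds = [problem.bounds[name] for name in PARAMETER_NAMES]
    result = differential_evolution(
        lambda x: objective(x, problem, _tables=tables), bounds, settings
    )
    params = GenotypeParameters.from_array(result.x)
    out = simulate(params, problem.weather, problem.constants)
    per_trait_nmae = {}
    for trait, reps in tables.items():
        series = out.trait_series(trait)
        obs = np.concatenate([v for _, v in reps])
        pred = np.concatenate(
            [np.repeat(series, len(d)) if len(series) == 1 else series[d - 1] for d, _ in reps]
        )
        per_trait_nmae[trait] = nmae_series(obs, pred)
    return {
        "params": params,
        "objective": result.fun,
        "per_trait_nmae": per_trait_nmae,
        "trace": result.trace,
        "n_evaluations": result.n_evaluations,
    }
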