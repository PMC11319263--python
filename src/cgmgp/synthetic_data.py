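"""Synthetic study generator: genotypes, genetic architectures, weather,
and replicated noisy phenotype trials.

The generator emulates a greenhouse phenotyping experiment on a sorghum
diversity panel: a marker matrix with tunable linkage disequilibrium, a
genotype-to-parameter genetic architecture (additive QTL plus optional
epistatic marker pairs), a 45-day weather series with 30 degC days / 23 degC
nights, and four replicated, noisily measured trait trajectories produced
by the growth model.  Everything is deterministic given a seed, so the full
pipeline is testable without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .growth_model import (
    DAILY_TRAITS,
    HARVEST_TRAITS,
    PARAMETER_BOUNDS,
    PARAMETER_NAMES,
    WEEKLY_TRAITS,
    GenotypeParameters,
    ModelConstants,
    SimulationOutput,
    WeatherSeries,
    simulate,
)
from .markers import MarkerMatrix

__all__ = [
    "TrialDesign",
    "ParameterArchitecture",
    "GeneticArchitecture",
    "SyntheticDataset",
    "simulate_genotypes",
    "random_architecture",
    "simulate_parameters",
    "simulate_weather",
    "simulate_trial",
    "generate_dataset",
]


@dataclass(frozen=True)
class TrialDesign:
    """Size and noise structure of a synthetic trial.

    Defaults emulate the structure of the motivating greenhouse study
    (45-day trial, 4 replicates, 30/23 degC day/night, MAF floor 0.05) at a
    desk scale of 300 genotypes x 3000 markers so the full pipeline runs in
    minutes; the original 136 x 31713 scale remains a configuration choice.
    """

    n_genotypes: int = 300
    n_markers: int = 3000
    n_chromosomes: int = 10
    rho: float = 0.9             # first-order haplotype copying probability
    maf_min: float = 0.05        # minimum minor-allele frequency
    replicates: int = 4
    days: int = 45
    day_temp: float = 30.0
    night_temp: float = 23.0
    radiation_mean: float = 10.0  # MJ m^-2 day^-1
    radiation_cv: float = 0.15
    temp_jitter: float = 0.3      # degC sd on daily mean temperature
    noise_cv: float = 0.1         # measurement CV applied to every trait
    seed: int = 0

    def __post_init__(self):
        if self.n_genotypes < 2 or self.n_markers < 1:
            raise ValueError("need n_genotypes >= 2 and n_markers >= 1")
        if not (0.0 <= self.maf_min < 0.5):
            raise ValueError("unattainable MAF: maf_min must lie in [0, 0.5)")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")
        if self.replicates < 1:
            raise ValueError("replicate count must be >= 1")


def simulate_genotypes(design: TrialDesign) -> MarkerMatrix:
    """Generate an n x p marker matrix with LD by first-order haplotype copying.

    Two haplotypes per genotype; within a chromosome, each haplotype copies
    its previous-marker allele with probability ``rho``, otherwise redraws
    from the marker's allele frequency.  Markers violating the MAF floor
    are redrawn (as a last resort, minor alleles are planted by flipping).
    """
    rng = np.random.default_rng(design.seed)
    n, p, rho = design.n_genotypes, design.n_markers, design.rho
    n_hap = 2 * n
    per_chrom = -(-p // design.n_chromosomes)  # ceil
    chrom_starts = set(range(0, p, per_chrom))

    lo = min(0.45, max(design.maf_min, 0.05) + 0.05)
    freqs = rng.uniform(lo, 1.0 - lo, size=p)
    haplo = np.empty((n_hap, p), dtype=np.int8)
    min_minor = int(np.ceil(design.maf_min * n_hap))

    for j in range(p):
        fresh = (rng.random(n_hap) < freqs[j]).astype(np.int8)
        if j in chrom_starts:
            col = fresh
        else:
            copy = rng.random(n_hap) < rho
            col = np.where(copy, haplo[:, j - 1], fresh)
        # enforce the MAF floor without touching copied (LD-bearing) alleles
        for _ in range(20):
            minor = min(col.sum(), n_hap - col.sum())
            if minor >= min_minor:
                break
            redraw = (rng.random(n_hap) < freqs[j]).astype(np.int8)
            if j in chrom_starts:
                col = redraw
            else:
                col = np.where(copy, haplo[:, j - 1], redraw)
        minor = min(col.sum(), n_hap - col.sum())
        if minor < min_minor:  # plant minor alleles deterministically
            major = 1 if col.sum() > n_hap - col.sum() else 0
            idx = rng.permutation(np.flatnonzero(col == major))[: min_minor - minor]
            col = col.copy()
            col[idx] = 1 - major
        haplo[:, j] = col

    codes = haplo[0::2] + haplo[1::2] - 1
    return MarkerMatrix(
        codes,
        tuple(f"G{i:04d}" for i in range(n)),
        tuple(f"M{j:05d}" for j in range(p)),
    )


@dataclass(frozen=True)
class ParameterArchitecture:
    """Genetic architecture of one genotypic parameter."""

    additive: tuple[tuple[int, float], ...]          # (marker index, effect)
    epistatic: tuple[tuple[int, int, float], ...]    # (i, j, interaction effect)
    h2: float                                        # target narrow-sense h2

    def __post_init__(self):
        object.__setattr__(self, "additive", tuple((int(i), float(a)) for i, a in self.additive))
        object.__setattr__(
            self, "epistatic", tuple((int(i), int(j), float(a)) for i, j, a in self.epistatic)
        )
        if not (0.0 <= self.h2 <= 1.0):
            raise ValueError("h2 must lie in [0, 1]")


@dataclass(frozen=True)
class GeneticArchitecture:
    """Per-parameter architectures plus the admissible parameter intervals."""

    parameters: dict[str, ParameterArchitecture]
    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(PARAMETER_BOUNDS)
    )

    def validate(self, p: int) -> None:
        for name, arch in self.parameters.items():
            for i, _ in arch.additive:
                if not (0 <= i < p):
                    raise ValueError(f"{name}: additive QTL index {i} outside [0, {p})")
            for i, j, _ in arch.epistatic:
                if not (0 <= i < p and 0 <= j < p):
                    raise ValueError(f"{name}: epistatic pair ({i},{j}) outside [0, {p})")


def random_architecture(
    p: int,
    seed: int,
    n_additive: int = 30,
    n_epistatic: int = 5,
    epistatic_weight: float = 0.5,
    h2_range: tuple[float, float] = (0.5, 0.9),
) -> GeneticArchitecture:
    """Draw a random architecture for all 8 genotypic parameters.

    Additive QTL are scattered across the genome with N(0,1) effects;
    epistatic terms act on *adjacent* marker pairs (i, i+1) — the LD-local
    interactions a 1-D convolution can in principle detect — with effects
    scaled by ``epistatic_weight``.  Setting ``n_additive=0`` with
    ``n_epistatic > 0`` yields a purely epistatic architecture.
    """
    rng = np.random.default_rng(seed)
    params = {}
    for name in PARAMETER_NAMES:
        additive = tuple(
            (int(i), float(e))
            for i, e in zip(
                rng.choice(p, size=n_additive, replace=False) if n_additive else [],
                rng.normal(0.0, 1.0, size=n_additive),
            )
        )
        epi = []
        if n_epistatic:
            firsts = rng.choice(p - 1, size=n_epistatic, replace=False)
            effects = rng.normal(0.0, epistatic_weight, size=n_epistatic)
            epi = [(int(i), int(i) + 1, float(e)) for i, e in zip(firsts, effects)]
        h2 = float(rng.uniform(*h2_range))
        params[name] = ParameterArchitecture(additive, tuple(epi), h2)
    return GeneticArchitecture(params)


def _genetic_score(X: np.ndarray, arch: ParameterArchitecture) -> np.ndarray:
    g = np.zeros(X.shape[0])
    for i, a in arch.additive:
        g += a * X[:, i]
    for i, j, a in arch.epistatic:
        g += a * (X[:, i] * X[:, j])
    return g


def simulate_parameters(
    markers: MarkerMatrix, arch: GeneticArchitecture, seed: int
) -> pd.DataFrame:
    """Generate "true" genotypic parameter values from marker data.

    For each parameter the genetic score is standardized, i.i.d. noise is
    added so that var(g)/var(g+noise) equals the target h2 exactly in the
    sample (the noise is decorrelated from g and rescaled), and the result
    is min-max mapped into the parameter's admissible interval — so the
    simulator never receives out-of-range inputs.
    """
    arch.validate(markers.p)
    rng = np.random.default_rng(seed)
    X = markers.values.astype(np.float64)
    n = X.shape[0]
    out = {}
    for name in PARAMETER_NAMES:
        pa = arch.parameters[name]
        lo, hi = arch.bounds[name]
        if pa.h2 > 0 and not pa.additive and not pa.epistatic:
            raise ValueError(f"{name}: empty architecture with h2 > 0")
        g = _genetic_score(X, pa)
        if pa.h2 > 0:
            sg = g.std()
            if sg == 0:
                raise ValueError(f"{name}: zero genetic variance with h2 > 0")
            g = (g - g.mean()) / sg
        else:
            g = np.zeros(n)
        if pa.h2 < 1.0:
            z = rng.normal(size=n)
            if pa.h2 > 0:
                # decorrelate from g, rescale to hit the target h2 exactly
                z = z - z.mean() - (z @ g / (g @ g)) * g
                z *= g.std() * np.sqrt((1.0 - pa.h2) / pa.h2) / z.std()
            else:
                z = (z - z.mean()) / z.std()
            score = g + z
        else:
            score = g
        span = score.max() - score.min()
        if span == 0:
            values = np.full(n, (lo + hi) / 2.0)
        else:
            values = lo + (hi - lo) * (score - score.min()) / span
        out[name] = np.clip(values, lo, hi)  # guard float rounding at the edges
    return pd.DataFrame(out, index=list(markers.genotype_ids))


def simulate_weather(
    days: int,
    day_temp: float = 30.0,
    night_temp: float = 23.0,
    radiation_mean: float = 10.0,
    radiation_cv: float = 0.15,
    temp_jitter: float = 0.3,
    seed: int = 0,
) -> WeatherSeries:
    """Greenhouse-style weather: 12 h at day_temp, 12 h at night_temp.

    Daily mean temperature is (day+night)/2 plus Gaussian jitter; radiation
    is lognormal around ``radiation_mean`` with coefficient of variation
    ``radiation_cv``.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    if radiation_mean <= 0:
        raise ValueError("radiation_mean must be positive")
    rng = np.random.default_rng(seed)
    tmean = (day_temp * 12.0 + night_temp * 12.0) / 24.0 + temp_jitter * rng.normal(size=days)
    if radiation_cv > 0:
        sigma2 = np.log1p(radiation_cv**2)
        rad = np.exp(
            np.log(radiation_mean) - sigma2 / 2.0 + np.sqrt(sigma2) * rng.normal(size=days)
        )
    else:
        rad = np.full(days, radiation_mean)
    return WeatherSeries(tmean, rad)


def _measurement_days(trait: str, n_days: int) -> np.ndarray:
    if trait in DAILY_TRAITS:
        return np.arange(1, n_days + 1)
    if trait in WEEKLY_TRAITS:
        return np.arange(7, n_days + 1, 7)
    return np.array([n_days])  # harvest traits


def simulate_trial(
    true_params: pd.DataFrame,
    weather: WeatherSeries,
    design: TrialDesign,
    constants: ModelConstants | None = None,
) -> tuple[pd.DataFrame, dict[str, SimulationOutput]]:
    """Run the growth model per genotype and emit replicated noisy tables.

    Measurement noise is multiplicative lognormal with CV ``design.noise_cv``
    applied independently to every measurement point of every replicate.
    Returns the tidy phenotype table (genotype_id, replicate, day, trait,
    value) and the noiseless simulation outputs keyed by genotype.
    """
    if len(weather) < design.days:
        raise ValueError("weather series shorter than trial duration")
    constants = constants or ModelConstants()
    rng = np.random.default_rng(design.seed + 1)
    cv = design.noise_cv
    sigma = np.sqrt(np.log1p(cv**2)) if cv > 0 else 0.0

    traits = DAILY_TRAITS + WEEKLY_TRAITS + HARVEST_TRAITS
    outputs: dict[str, SimulationOutput] = {}
    rows = []
    for gid in true_params.index:
        params = GenotypeParameters(**true_params.loc[gid].to_dict())
        out = simulate(params, weather, constants)
        outputs[gid] = out
        for trait in traits:
            days = _measurement_days(trait, design.days)
            series = out.trait_series(trait)
            values = series[days - 1] if len(series) > 1 else np.repeat(series, len(days))
            for rep in range(1, design.replicates + 1):
                if sigma > 0:
                    noise = np.exp(sigma * rng.normal(size=len(days)) - sigma**2 / 2.0)
                else:
                    noise = np.ones(len(days))
                for day, v, f in zip(days, values, noise):
                    rows.append((gid, rep, int(day), trait, float(v * f)))
    pheno = pd.DataFrame(rows, columns=["genotype_id", "replicate", "day", "trait", "value"])
    return pheno, outputs


@dataclass
class SyntheticDataset:
    """Everything one synthetic study produces."""

    design: TrialDesign
    markers: MarkerMatrix
    architecture: GeneticArchitecture
    true_params: pd.DataFrame
    weather: WeatherSeries
    phenotypes: pd.DataFrame
    outputs: dict[str, SimulationOutput]
    constants: ModelConstants

    @property
    def observed_trait(self) -> pd.Series:
        """The "observed" integrative trait: noisy replicate mean of
        final-day aboveground fresh weight per genotype (stands in for the
        spatial-model BLUP of the real experiment)."""
        ph = self.phenotypes
        final = ph[(ph.trait == "Biomaerofw") & (ph.day == self.design.days)]
        return final.groupby("genotype_id").value.mean().reindex(list(self.markers.genotype_ids))

    def observed_secondary(self, trait: str) -> pd.Series:
        ph = self.phenotypes
        sel = ph[ph.trait == trait]
        sel = sel[sel.day == sel.day.max()]
        return sel.groupby("genotype_id").value.mean().reindex(list(self.markers.genotype_ids))


def generate_dataset(
    design: TrialDesign | None = None,
    architecture: GeneticArchitecture | None = None,
    constants: ModelConstants | None = None,
    seed: int | None = None,
) -> SyntheticDataset:
    """Generate a full synthetic study (markers -> parameters -> trial)."""
    design = design or TrialDesign()
    if seed is not None:
        design = replace(design, seed=seed)
    constants = constants or ModelConstants()
    markers = simulate_genotypes(design)
    architecture = architecture or random_architecture(design.n_markers, design.seed + 7)
    true_params = simulate_parameters(markers, architecture, design.seed + 13)
    weather = simulate_weather(
        design.days, design.day_temp, design.night_temp, design.radiation_mean,
        design.radiation_cv, design.temp_jitter, design.seed + 29,
    )
    phenotypes, outputs = simulate_trial(true_params, weather, design, constants)
    return SyntheticDataset(
        design, markers, architecture, true_params, weather, phenotypes, outputs, constants
    )
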