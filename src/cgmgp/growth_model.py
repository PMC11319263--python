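"""Sink-driven simulator of sorghum vegetative growth.

The model follows the Ecomeristem school of crop models: the plant is a
collection of axes (main stem + tillers), each axis a sequence of phytomers
(blade + internode) whose initiation, appearance and ligulation are clocked
in thermal time by three genotypic "chrone" parameters.  Organs are
pre-dimensioned at appearance (a potential final size), then grow towards
that potential at a rate set by the thermal-time length of their growth
window.  Daily carbon supply is intercepted radiation converted at
efficiency ``epsib``; when the summed organ demand exceeds supply, growth of
every organ is slowed proportionally.  The supply/demand balance (index of
internal competition, IC) also gates tiller emission through the threshold
parameter ``ict``.

All internal bookkeeping is in grams of dry mass; reported biomass traits
are fresh weight obtained through a constant dry-matter content.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

__all__ = [
    "PARAMETER_BOUNDS",
    "GenotypeParameters",
    "ModelConstants",
    "WeatherSeries",
    "SimulationOutput",
    "PlantState",
    "thermal_time_increment",
    "daily_supply",
    "competition_index",
    "potential_blade",
    "potential_internode",
    "step",
    "simulate",
]

#: Admissible interval for each of the 8 genotypic parameters.  These are
#: both the calibration search bounds and the domain contract of
#: :func:`simulate`.
PARAMETER_BOUNDS: dict[str, tuple[float, float]] = {
    "epsib": (3.0, 8.0),        # light conversion coefficient, g MJ^-1
    "plasto_init": (25.0, 45.0),  # plastochron, degree-days
    "phyllo_init": (25.0, 45.0),  # phyllochron, degree-days
    "ligulo_init": (25.0, 45.0),  # ligulochron, degree-days
    "ict": (0.5, 2.5),          # IC threshold enabling tillering
    "mgr_init": (6.0, 14.0),    # meristem growth rate, mm per leaf rank
    "ll_to_il": (0.1, 0.2),     # internode/leaf length ratio
    "slap": (0.0, 0.1),         # per-rank fractional SLA decrease
}

PARAMETER_NAMES: tuple[str, ...] = tuple(PARAMETER_BOUNDS)


@dataclass(frozen=True)
class GenotypeParameters:
    """The 8 genotypic parameters that characterise a genotype.

    epsib
        Radiation-use efficiency converting intercepted light to dry
        biomass (g MJ^-1).
    plasto_init, phyllo_init, ligulo_init
        Thermal-time intervals (degree-days) between successive phytomer
        initiations, leaf appearances, and leaf ligulations.
    ict
        Supply/demand (IC) threshold that must be exceeded for a tiller to
        emerge.
    mgr_init
        Additive increment of potential blade length per leaf rank (mm).
    ll_to_il
        Ratio of internode length to the length of its subtending leaf.
    slap
        Fractional decrease of specific leaf area between successive
        leaves (per rank).
    """

    epsib: float
    plasto_init: float
    phyllo_init: float
    ligulo_init: float
    ict: float
    mgr_init: float
    ll_to_il: float
    slap: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAMETER_NAMES])

    @classmethod
    def from_array(cls, values) -> "GenotypeParameters":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(PARAMETER_NAMES),):
            raise ValueError(
                f"expected {len(PARAMETER_NAMES)} parameter values, got shape {values.shape}"
            )
        return cls(**dict(zip(PARAMETER_NAMES, values)))

    def out_of_bounds(self) -> list[str]:
        bad = []
        for name, (lo, hi) in PARAMETER_BOUNDS.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                bad.append(name)
        return bad

    def clamped(self) -> "GenotypeParameters":
        clipped = {
            name: float(min(max(getattr(self, name), lo), hi))
            for name, (lo, hi) in PARAMETER_BOUNDS.items()
        }
        return GenotypeParameters(**clipped)


@dataclass(frozen=True)
class ModelConstants:
    """Functional constants of the simulator (genotype-independent).

    Units: lengths mm, areas mm^2, masses g (dry unless noted), ground_area
    m^2, radiation MJ m^-2 day^-1, temperatures degC.
    """

    tbase: float = 11.0               # sorghum base temperature, degC
    k_light: float = 0.5              # canopy extinction coefficient
    ground_area: float = 0.08         # ground area per plant, m^2 (0.4 x 0.2 m)
    first_leaf_length: float = 100.0  # potential length of leaf 1, mm
    width_to_length: float = 0.1      # blade width / blade length
    shape_factor: float = 0.72        # blade area = shape * L * W
    sla_first: float = 30000.0        # SLA of leaf 1, mm^2 per g dry
    dmc: float = 0.15                 # dry matter content, g dry per g fresh
    internode_diameter: float = 8.0   # mm
    internode_density: float = 1.5e-4  # g dry per mm^3
    seed_biomass: float = 0.2         # seed reserve fuelling early growth, g dry
    heterotrophic_days: int = 3       # days over which the reserve is released
    tiller_first_rank: int = 4        # first mainstem rank bearing a tiller site
    tiller_size_factor: float = 0.8   # size reduction of tiller organs
    max_rank: int = 25                # maximum phytomer rank per axis
    ic_max: float = 5.0               # cap on the competition index

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"ModelConstants.{f.name} must be strictly positive")
        if not (0.0 < self.dmc <= 1.0):
            raise ValueError("dmc must lie in (0, 1]")
        if not (0.0 < self.tiller_size_factor <= 1.0):
            raise ValueError("tiller_size_factor must lie in (0, 1]")


@dataclass(frozen=True)
class WeatherSeries:
    """Daily weather driving the simulator."""

    tmean: np.ndarray      # daily mean air temperature, degC
    radiation: np.ndarray  # incident radiation, MJ m^-2 day^-1

    def __post_init__(self):
        tmean = np.asarray(self.tmean, dtype=float)
        radiation = np.asarray(self.radiation, dtype=float)
        object.__setattr__(self, "tmean", tmean)
        object.__setattr__(self, "radiation", radiation)
        if tmean.ndim != 1 or radiation.ndim != 1 or len(tmean) != len(radiation):
            raise ValueError("tmean and radiation must be 1-D series of equal length")
        if np.any(~np.isfinite(tmean)) or np.any(~np.isfinite(radiation)):
            raise ValueError("weather contains non-finite values")
        if np.any(radiation < 0):
            raise ValueError("radiation must be non-negative")

    def __len__(self) -> int:
        return len(self.tmean)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"day": np.arange(1, len(self) + 1), "tmean_C": self.tmean, "rad_MJ_m2": self.radiation}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "WeatherSeries":
        frame = frame.sort_values("day")
        return cls(frame["tmean_C"].to_numpy(), frame["rad_MJ_m2"].to_numpy())


#: Traits used as calibration targets ("starred" traits), with cadence.
CALIBRATION_TRAITS: tuple[str, ...] = (
    "App", "Lig", "Tillernb", "Biomaerofw", "PHT", "Mainstemfw", "Arealfel",
)
DAILY_TRAITS: tuple[str, ...] = ("Biomaerofw", "PLA", "PHT")
WEEKLY_TRAITS: tuple[str, ...] = ("App", "Lig", "Tillernb")
HARVEST_TRAITS: tuple[str, ...] = ("Mainstemfw", "Arealfel")


@dataclass
class SimulationOutput:
    """Daily trait trajectories plus harvest traits of a single plant."""

    days: np.ndarray
    biomaerofw: np.ndarray   # aboveground fresh weight, g
    pla: np.ndarray          # plant leaf area, mm^2
    pht: np.ndarray          # plant height, mm
    app: np.ndarray          # appeared mainstem leaves
    lig: np.ndarray          # ligulated mainstem leaves
    tillernb: np.ndarray     # number of tillers
    ic: np.ndarray           # diagnostic: daily competition index
    mainstem_fresh: np.ndarray
    tiller_fresh: np.ndarray
    mainstemfw: float = 0.0  # harvest: mainstem fresh weight, g
    arealfel: float = 0.0    # harvest: area of last ligulated mainstem leaf, mm^2

    def trait_series(self, trait: str) -> np.ndarray:
        mapping = {
            "Biomaerofw": self.biomaerofw, "PLA": self.pla, "PHT": self.pht,
            "App": self.app, "Lig": self.lig, "Tillernb": self.tillernb,
        }
        if trait in mapping:
            return mapping[trait]
        if trait == "Mainstemfw":
            return np.array([self.mainstemfw])
        if trait == "Arealfel":
            return np.array([self.arealfel])
        raise KeyError(trait)

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for trait in DAILY_TRAITS + WEEKLY_TRAITS:
            for day, value in zip(self.days, self.trait_series(trait)):
                rows.append((int(day), trait, float(value)))
        last = int(self.days[-1])
        rows.append((last, "Mainstemfw", float(self.mainstemfw)))
        rows.append((last, "Arealfel", float(self.arealfel)))
        return pd.DataFrame(rows, columns=["day", "trait", "value"])


def thermal_time_increment(tmean: float, tbase: float) -> float:
    """Daily thermal-time increment (degree-days): max(0, tmean - tbase)."""
    return max(0.0, tmean - tbase)


def daily_supply(epsib: float, radiation: float, pla: float, constants: ModelConstants) -> float:
    """Daily carbon supply (g dry) from light interception.

    Beer-Lambert interception with LAI = plant leaf area / ground area;
    ``epsib`` converts intercepted radiation to dry biomass.
    """
    if pla < 0:
        raise ValueError("pla must be non-negative")
    if radiation <= 0 or pla == 0:
        return 0.0
    lai = pla / (constants.ground_area * 1e6)  # mm^2 -> m^2 leaf per m^2 ground
    interception = 1.0 - math.exp(-constants.k_light * lai)
    return epsib * radiation * constants.ground_area * interception


def competition_index(supply_window, demand_window, ic_max: float = 5.0) -> float:
    """Index of internal competition over a trailing window.

    Ratio of summed supply to summed demand, clamped to [0, ic_max]; the
    no-demand convention returns ic_max (nothing to compete for).
    """
    supply_window = np.asarray(supply_window, dtype=float)
    demand_window = np.asarray(demand_window, dtype=float)
    if supply_window.shape != demand_window.shape:
        raise ValueError("supply and demand windows must have equal length")
    demand = demand_window.sum()
    if demand <= 0:
        return ic_max
    return float(min(max(supply_window.sum() / demand, 0.0), ic_max))


def potential_blade(
    rank: int,
    mgr: float,
    ic_at_predim: float,
    constants: ModelConstants,
    slap: float,
    size_factor: float = 1.0,
) -> tuple[float, float, float]:
    """Pre-dimension a blade: (length mm, area mm^2, dry biomass g).

    Potential length grows additively with rank at rate ``mgr``, modulated
    by the competition index at pre-dimensioning time (capped at 1: a
    non-stressed plant reaches its full potential, surplus carbon does not
    make bigger leaves).  Blade dry mass is area divided by the rank's
    specific leaf area, which declines by ``slap`` per rank.
    """
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if rank > constants.max_rank:
        raise ValueError("rank beyond max_rank: no organ")
    ic_factor = min(1.0, max(0.0, ic_at_predim))
    length = (constants.first_leaf_length + mgr * (rank - 1) * ic_factor) * size_factor
    width = constants.width_to_length * length
    area = constants.shape_factor * length * width
    sla = constants.sla_first * (1.0 - slap) ** (rank - 1)
    return length, area, area / sla


def potential_internode(
    blade_length: float, ll_to_il: float, constants: ModelConstants
) -> tuple[float, float]:
    """Pre-dimension an internode: (length mm, dry biomass g).

    Internode length is a fixed fraction of its leaf's length; mass is the
    cylinder volume times dry tissue density.
    """
    length = ll_to_il * blade_length
    radius = constants.internode_diameter / 2.0
    volume = math.pi * radius**2 * length
    return length, volume * constants.internode_density


_BLADE, _INTERNODE = 0, 1


class _Organ:
    __slots__ = ("axis", "kind", "rank", "pot_dry", "pot_len", "pot_area",
                 "cur_dry", "tt_start", "tt_end")

    def __init__(self, axis, kind, rank, pot_dry, pot_len, pot_area, tt_start, tt_end):
        self.axis = axis
        self.kind = kind
        self.rank = rank
        self.pot_dry = pot_dry
        self.pot_len = pot_len
        self.pot_area = pot_area
        self.cur_dry = 0.0
        self.tt_start = tt_start
        self.tt_end = tt_end

    @property
    def frac(self) -> float:
        return self.cur_dry / self.pot_dry if self.pot_dry > 0 else 1.0


class _Axis:
    __slots__ = ("index", "birth_tt", "next_rank", "appeared", "ligulated",
                 "next_tiller_site")

    def __init__(self, index, birth_tt, first_tiller_site):
        self.index = index
        self.birth_tt = birth_tt
        self.next_rank = 1
        self.appeared = 0
        self.ligulated = 0
        # tiller sites sit on the plastochron clock: site r opens at
        # r * plasto_init + phyllo_init degree-days of axis age
        self.next_tiller_site = first_tiller_site


@dataclass
class PlantState:
    """Mutable state threaded through :func:`step`."""

    params: GenotypeParameters
    constants: ModelConstants
    tt: float = 0.0
    day: int = 0
    reserve: float = field(default=0.0)
    axes: list = field(default_factory=list)
    organs: list = field(default_factory=list)
    pending_ligulation: list = field(default_factory=list)  # (lig_tt, organ)
    supply_hist: list = field(default_factory=list)
    demand_hist: list = field(default_factory=list)
    cum_supply: float = 0.0
    cum_growth: float = 0.0
    pla: float = 0.0
    pht: float = 0.0
    last_ic: float = field(default=0.0)

    def __post_init__(self):
        if not self.axes:
            self.reserve = self.constants.seed_biomass
            self.axes.append(_Axis(0, 0.0, self.constants.tiller_first_rank))
            self.last_ic = self.constants.ic_max

    # -- trait views -------------------------------------------------------
    def axis_dry(self, axis_index: int) -> float:
        return sum(o.cur_dry for o in self.organs if o.axis == axis_index)

    def total_dry(self) -> float:
        return sum(o.cur_dry for o in self.organs) + self.reserve

    def mainstem_fresh(self) -> float:
        # The seed reserve is booked on the main stem so that aboveground
        # fresh weight decomposes exactly into mainstem + tillers.
        return (self.axis_dry(0) + self.reserve) / self.constants.dmc

    def tillers_fresh(self) -> float:
        return sum(
            self.axis_dry(a.index) for a in self.axes if a.index > 0
        ) / self.constants.dmc

    def plant_leaf_area(self) -> float:
        return sum(o.pot_area * o.frac for o in self.organs if o.kind == _BLADE)

    def height(self) -> float:
        mainstem = [o for o in self.organs if o.axis == 0]
        inter = sum(
            o.pot_len * o.frac
            for o in mainstem
            if o.kind == _INTERNODE
        )
        lig_blades = [
            o for o in mainstem
            if o.kind == _BLADE and o.rank <= self.axes[0].ligulated
        ]
        sheath = max((o.pot_len * o.frac for o in lig_blades), default=0.0)
        return inter + sheath

    def arealfel(self) -> float:
        lig = self.axes[0].ligulated
        for o in self.organs:
            if o.axis == 0 and o.kind == _BLADE and o.rank == lig:
                return o.pot_area * o.frac
        return 0.0


def _windowed_ic(state: PlantState, dtt: float) -> float:
    """IC over a trailing window of about one phyllochron of days."""
    c = state.constants
    if dtt > 0:
        window = max(1, round(state.params.phyllo_init / dtt))
    else:
        window = 1
    return competition_index(
        state.supply_hist[-window:] or [0.0],
        state.demand_hist[-window:] or [0.0],
        ic_max=c.ic_max,
    )


def step(state: PlantState, tmean: float, radiation: float) -> PlantState:
    """Advance the plant by one day (mutates and returns ``state``)."""
    if not np.isfinite(tmean) or not np.isfinite(radiation) or radiation < 0:
        raise ValueError("invalid weather: tmean/radiation must be finite, radiation >= 0")
    p, c = state.params, state.constants
    dtt = thermal_time_increment(tmean, c.tbase)
    state.tt += dtt
    state.day += 1

    ic_window = _windowed_ic(state, dtt)

    # -- phenology: ligulations due up to current thermal time ------------
    due = [pl for pl in state.pending_ligulation if pl[0] <= state.tt]
    state.pending_ligulation = [pl for pl in state.pending_ligulation if pl[0] > state.tt]
    for lig_tt, blade in sorted(due, key=lambda x: x[0]):
        axis = state.axes[blade.axis]
        axis.ligulated = max(axis.ligulated, blade.rank)
        il_len, il_dry = potential_internode(blade.pot_len, p.ll_to_il, c)
        state.organs.append(
            _Organ(blade.axis, _INTERNODE, blade.rank, il_dry, il_len, 0.0,
                   lig_tt, lig_tt + 3.0 * p.ligulo_init)
        )

    # -- phenology: leaf appearances per axis ------------------------------
    for axis in list(state.axes):
        while axis.next_rank <= c.max_rank:
            appear_tt = axis.birth_tt + axis.next_rank * p.phyllo_init
            if state.tt < appear_tt:
                break
            rank = axis.next_rank
            size_factor = 1.0 if axis.index == 0 else c.tiller_size_factor
            length, area, dry = potential_blade(
                rank, p.mgr_init, min(1.0, ic_window), c, p.slap, size_factor
            )
            blade = _Organ(axis.index, _BLADE, rank, dry, length, area,
                           appear_tt, appear_tt + p.ligulo_init)
            state.organs.append(blade)
            state.pending_ligulation.append((appear_tt + p.ligulo_init, blade))
            axis.appeared = rank
            axis.next_rank += 1

    # -- tiller emission on the mainstem plastochron clock -----------------
    # site r opens one "plastochron + phyllochron" cycle after phytomer r's
    # initiation; a tiller emerges iff the windowed IC exceeds the genotypic
    # threshold at that moment (a missed window stays empty)
    mainstem = state.axes[0]
    while mainstem.next_tiller_site <= c.max_rank:
        site_tt = mainstem.next_tiller_site * p.plasto_init + p.phyllo_init
        if state.tt < site_tt:
            break
        if ic_window > p.ict:
            state.axes.append(_Axis(len(state.axes), site_tt,
                                    c.tiller_first_rank))
        mainstem.next_tiller_site += 1

    # -- demand ------------------------------------------------------------
    demands = []
    total_demand = 0.0
    for organ in state.organs:
        if organ.cur_dry >= organ.pot_dry or state.tt <= organ.tt_start:
            demands.append(0.0)
            continue
        window_len = organ.tt_end - organ.tt_start
        d = organ.pot_dry * (dtt / window_len) if window_len > 0 else organ.pot_dry
        d = min(d, organ.pot_dry - organ.cur_dry)
        demands.append(d)
        total_demand += d

    # -- supply ------------------------------------------------------------
    photo = daily_supply(p.epsib, radiation, state.pla, c)
    seed_flux = 0.0
    if state.day <= c.heterotrophic_days and state.reserve > 0:
        seed_flux = min(state.reserve, c.seed_biomass / c.heterotrophic_days)
    supply = photo + seed_flux

    # -- growth ------------------------------------------------------------
    if total_demand > 0:
        ic_day = min(max(supply / total_demand, 0.0), c.ic_max)
    else:
        ic_day = c.ic_max
    f = min(1.0, ic_day)
    growth = 0.0
    for organ, d in zip(state.organs, demands):
        if d > 0:
            organ.cur_dry = min(organ.pot_dry, organ.cur_dry + d * f)
            growth += d * f
    seed_used = min(seed_flux, max(0.0, growth - photo))
    state.reserve -= seed_used

    state.supply_hist.append(supply)
    state.demand_hist.append(total_demand)
    state.cum_supply += photo + seed_used
    state.cum_growth += growth
    state.pla = state.plant_leaf_area()
    state.pht = max(state.pht, state.height())  # height never shrinks
    state.last_ic = ic_day
    return state


def simulate(
    params: GenotypeParameters,
    weather: WeatherSeries,
    constants: ModelConstants | None = None,
    strict: bool = False,
) -> SimulationOutput:
    """Run the growth model over a weather series (deterministic).

    Out-of-bounds parameters are clamped to their admissible interval with
    a warning, or rejected when ``strict`` is set.
    """
    constants = constants or ModelConstants()
    if len(weather) < 1:
        raise ValueError("weather series is empty")
    bad = params.out_of_bounds()
    if bad:
        if strict:
            raise ValueError(f"parameters out of bounds: {bad}")
        warnings.warn(f"clamping out-of-bounds parameters: {bad}", stacklevel=2)
        params = params.clamped()

    state = PlantState(params=params, constants=constants)
    n = len(weather)
    out = SimulationOutput(
        days=np.arange(1, n + 1),
        biomaerofw=np.zeros(n), pla=np.zeros(n), pht=np.zeros(n),
        app=np.zeros(n), lig=np.zeros(n), tillernb=np.zeros(n),
        ic=np.zeros(n), mainstem_fresh=np.zeros(n), tiller_fresh=np.zeros(n),
    )
    for d in range(n):
        step(state, weather.tmean[d], weather.radiation[d])
        out.mainstem_fresh[d] = state.mainstem_fresh()
        out.tiller_fresh[d] = state.tillers_fresh()
        out.biomaerofw[d] = out.mainstem_fresh[d] + out.tiller_fresh[d]
        out.pla[d] = state.pla
        out.pht[d] = state.pht
        out.app[d] = state.axes[0].appeared
        out.lig[d] = state.axes[0].ligulated
        out.tillernb[d] = sum(1 for a in state.axes if a.index > 0)
        out.ic[d] = state.last_ic
    out.mainstemfw = float(out.mainstem_fresh[-1])
    out.arealfel = float(state.arealfel())
    return out
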