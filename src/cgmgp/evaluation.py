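"""Two-scenario comparison under shared k-fold cross-validation.

Scenario "direct": regress the integrative trait (final aboveground fresh
weight) on the markers with each engine.  Scenario "cgm-gp": regress the 8
growth-model parameters on the markers, clamp the held-out predictions to
the admissible intervals, run the growth model for each held-out genotype,
and use the simulated trait as the prediction.  The same fold assignment
is consumed by every engine and both scenarios; metrics (NMAE, predictive
ability) are computed on the pooled out-of-fold predictions.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import nmae_series
from .growth_model import (
    PARAMETER_BOUNDS,
    PARAMETER_NAMES,
    GenotypeParameters,
    ModelConstants,
    WeatherSeries,
    simulate,
)
from .gp_models import TargetScaler, build_engine
from .markers import MarkerMatrix

__all__ = [
    "FoldAssignment",
    "ScenarioReport",
    "kfold_split",
    "nmae",
    "predictive_ability",
    "run_direct_scenario",
    "run_cgmgp_scenario",
    "compare",
]

logger = logging.getLogger(__name__)

SECONDARY_TRAITS = ("Mainstemfw", "PHT", "Arealfel")


@dataclass(frozen=True)
class FoldAssignment:
    """Genotype -> fold map shared across engines and scenarios."""

    genotype_ids: tuple[str, ...]
    fold_index: np.ndarray
    k: int
    seed: int

    def folds(self):
        for f in range(self.k):
            test = np.flatnonzero(self.fold_index == f)
            train = np.flatnonzero(self.fold_index != f)
            yield f, train, test

    @property
    def checksum(self) -> str:
        payload = ",".join(f"{g}:{f}" for g, f in zip(self.genotype_ids, self.fold_index))
        return hashlib.md5(payload.encode()).hexdigest()


def kfold_split(genotype_ids, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Random partition into k folds whose sizes differ by at most one."""
    ids = tuple(map(str, genotype_ids))
    n = len(ids)
    if n < k:
        raise ValueError(f"cannot split {n} genotypes into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_index = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k)):
        fold_index[chunk] = f
    return FoldAssignment(ids, fold_index, k, seed)


def nmae(observed, predicted) -> float:
    """Normalized mean absolute error: mean(|(y - yhat)/y|)."""
    return nmae_series(observed, predicted)


def predictive_ability(observed, predicted) -> float:
    """Pearson correlation between observed and predicted values."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.size < 2:
        raise ValueError("need two equal-length series with n >= 2")
    if observed.std() == 0 or predicted.std() == 0:
        raise ValueError("undefined PA: constant input")
    return float(np.corrcoef(observed, predicted)[0, 1])


def _param_nmae(observed: np.ndarray, predicted: np.ndarray):
    """NMAE over nonzero observations (relative error is undefined at 0;
    parameters whose admissible interval starts at 0 can hit it exactly)."""
    keep = observed != 0
    if not keep.any():
        return None
    return nmae(observed[keep], predicted[keep])


def _metrics(observed: np.ndarray, predicted: np.ndarray) -> dict:
    out = {"nmae": nmae(observed, predicted)}
    try:
        out["pa"] = predictive_ability(observed, predicted)
    except ValueError as exc:
        out["pa"] = None
        out["pa_error"] = str(exc)
    return out


def _oof_predict(X: np.ndarray, Y: np.ndarray, folds: FoldAssignment, make_engine):
    """Pooled out-of-fold predictions: each genotype predicted exactly once."""
    oof = np.full(Y.shape, np.nan)
    for f, train, test in folds.folds():
        model = make_engine()
        model.fit(X[train], Y[train])
        oof[test] = np.atleast_2d(model.predict(X[test]).T).T.reshape(len(test), -1)
    assert not np.isnan(oof).any(), "out-of-fold predictions must cover every genotype"
    return oof


def _resolve_engines(engines) -> dict:
    """Accept {name: factory} or {name: settings-dict}; return factories.

    A factory is a zero-argument callable producing a fresh unfitted engine.
    """
    resolved = {}
    for name, cfg in engines.items():
        if callable(cfg):
            resolved[name] = cfg
        else:
            resolved[name] = (lambda n=name, kw=dict(cfg or {}): build_engine(n, **kw))
    return resolved


def run_direct_scenario(markers, trait, folds: FoldAssignment, engines) -> dict:
    """Direct genomic prediction of the integrative trait."""
    X = markers.values.astype(float) if isinstance(markers, MarkerMatrix) else np.asarray(markers, float)
    y = np.asarray(trait, dtype=float)
    if len(y) != X.shape[0]:
        raise ValueError("trait not aligned to marker rows")
    report = {}
    for name, factory in _resolve_engines(engines).items():
        oof = _oof_predict(X, y[:, None], folds, factory)[:, 0]
        entry = _metrics(y, oof)
        entry["per_fold"] = {}
        for f, _, test in folds.folds():
            entry["per_fold"][f] = _metrics(y[test], oof[test])
        entry["predictions"] = oof
        report[name] = entry
    return {"scenario": "direct", "folds_checksum": folds.checksum, "engines": report}


def _clamp_params(P: np.ndarray) -> np.ndarray:
    lo = np.array([PARAMETER_BOUNDS[n][0] for n in PARAMETER_NAMES])
    hi = np.array([PARAMETER_BOUNDS[n][1] for n in PARAMETER_NAMES])
    return np.clip(P, lo, hi)


def run_cgmgp_scenario(
    markers,
    params: pd.DataFrame,
    weather: WeatherSeries,
    folds: FoldAssignment,
    engines,
    constants: ModelConstants | None = None,
    observed_trait=None,
    observed_secondary: dict | None = None,
) -> dict:
    """Predict growth-model parameters from markers, then simulate.

    ``params`` holds the per-genotype "observed" parameter values (DE
    estimates, or the synthetic truth); rows must align with the marker
    matrix.  Engine predictions are clamped to the admissible intervals
    before entering the simulator.
    """
    X = markers.values.astype(float) if isinstance(markers, MarkerMatrix) else np.asarray(markers, float)
    constants = constants or ModelConstants()
    P = params[list(PARAMETER_NAMES)].to_numpy(dtype=float)
    if P.shape[0] != X.shape[0]:
        raise ValueError("parameter table not aligned to marker rows")
    y = None if observed_trait is None else np.asarray(observed_trait, dtype=float)

    param_scaler = TargetScaler.from_bounds([PARAMETER_BOUNDS[n] for n in PARAMETER_NAMES])
    report = {}
    for name, factory in _resolve_engines(engines).items():
        def make():
            engine = factory()
            if hasattr(engine, "scaler") and engine.scaler is None:
                engine.scaler = param_scaler  # parameter bounds are genotype-free
            return engine

        oof_params = _clamp_params(_oof_predict(X, P, folds, make))
        entry = {
            "param_nmae": {
                pname: _param_nmae(P[:, j], oof_params[:, j])
                for j, pname in enumerate(PARAMETER_NAMES)
            },
            "param_predictions": oof_params,
        }
        sim_trait = np.full(X.shape[0], np.nan)
        sim_secondary = {t: np.full(X.shape[0], np.nan) for t in SECONDARY_TRAITS}
        failed = []
        for i in range(X.shape[0]):
            gp = GenotypeParameters.from_array(oof_params[i])
            try:
                out = simulate(gp, weather, constants)
            except Exception:
                failed.append(folds.genotype_ids[i])
                logger.warning("simulation failed for %s", folds.genotype_ids[i], exc_info=True)
                continue
            sim_trait[i] = out.biomaerofw[-1]
            sim_secondary["Mainstemfw"][i] = out.mainstemfw
            sim_secondary["PHT"][i] = out.pht[-1]
            sim_secondary["Arealfel"][i] = out.arealfel
        if failed:
            warnings.warn(f"{len(failed)} genotype simulations failed; excluded from metrics")
        ok = ~np.isnan(sim_trait)
        entry["simulated_trait"] = sim_trait
        entry["failed"] = failed
        if y is not None:
            entry.update(_metrics(y[ok], sim_trait[ok]))
            entry["per_fold"] = {}
            for f, _, test in folds.folds():
                sel = test[ok[test]]
                entry["per_fold"][f] = _metrics(y[sel], sim_trait[sel])
        if observed_secondary:
            entry["secondary"] = {}
            for t, obs in observed_secondary.items():
                obs = np.asarray(obs, dtype=float)
                sim = sim_secondary[t]
                sel = ok & ~np.isnan(obs) & (obs != 0)
                entry["secondary"][t] = _metrics(obs[sel], sim[sel])
        report[name] = entry
    return {"scenario": "cgm-gp", "folds_checksum": folds.checksum, "engines": report}


@dataclass
class ScenarioReport:
    """Merged two-scenario comparison (machine-readable)."""

    direct: dict
    cgmgp: dict
    deltas: dict = field(default_factory=dict)
    folds_checksum: str = ""

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for scenario, part in (("direct", self.direct), ("cgm-gp", self.cgmgp)):
            for engine, entry in part["engines"].items():
                rows.append({
                    "engine": engine, "scenario": scenario,
                    "nmae": entry.get("nmae"), "pa": entry.get("pa"),
                })
        return pd.DataFrame(rows)

    def param_nmae_table(self) -> pd.DataFrame:
        """Per-parameter NMAE, parameters as rows, engines as columns."""
        cols = {
            engine: entry["param_nmae"]
            for engine, entry in self.cgmgp["engines"].items()
        }
        return pd.DataFrame(cols).reindex(list(PARAMETER_NAMES))

    def to_json(self) -> str:
        def clean(obj):
            if isinstance(obj, dict):
                return {str(k): clean(v) for k, v in obj.items()
                        if k not in ("predictions", "param_predictions", "simulated_trait")}
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj
        return json.dumps({
            "folds_checksum": self.folds_checksum,
            "direct": clean(self.direct),
            "cgm_gp": clean(self.cgmgp),
            "deltas": clean(self.deltas),
        }, indent=2)


def compare(direct: dict, cgmgp: dict) -> ScenarioReport:
    """Merge the two scenario parts and compute CGM-GP minus direct deltas."""
    if direct["folds_checksum"] != cgmgp["folds_checksum"]:
        raise ValueError("fold assignment mismatch between scenarios")
    deltas = {}
    for engine in direct["engines"]:
        if engine not in cgmgp["engines"]:
            continue
        d, c = direct["engines"][engine], cgmgp["engines"][engine]
        deltas[engine] = {
            "nmae": (c["nmae"] - d["nmae"])
            if c.get("nmae") is not None and d.get("nmae") is not None else None,
            "pa": (c["pa"] - d["pa"])
            if c.get("pa") is not None and d.get("pa") is not None else None,
        }
    return ScenarioReport(direct, cgmgp, deltas, direct["folds_checksum"])
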