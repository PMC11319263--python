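"""One-call synthetic-study comparison: generate data, run both scenarios.

This is the package's end-to-end entry point: it generates a synthetic
study, takes the per-genotype parameter truth as the "observed" parameter
values (the calibration module can substitute DE estimates), runs the
direct and CGM-GP scenarios with every requested engine under one shared
fold assignment, and returns the merged report.
"""

from __future__ import annotations

from .evaluation import ScenarioReport, compare, kfold_split, run_cgmgp_scenario, run_direct_scenario
from .synthetic_data import GeneticArchitecture, SyntheticDataset, TrialDesign, generate_dataset

__all__ = ["DESK_ENGINE_SETTINGS", "run_synthetic_comparison"]

#: Reduced engine budgets used for desk-scale studies (narrower CNN,
#: shorter Bayes C chain); engine defaults remain the full budgets.
DESK_ENGINE_SETTINGS: dict = {
    "lasso": {},
    "bayesc": {"iterations": 1500, "burn_in": 500, "thin": 5},
    "cnn": {"channels": (8, 16, 16, 32, 32), "epochs": 60, "batch_size": 16,
            "learning_rate": 3e-3, "patience": 20},
}


def _seeded(engine_settings: dict, seed: int) -> dict:
    return {name: {**cfg, "seed": seed} for name, cfg in engine_settings.items()}


def run_synthetic_comparison(
    design: TrialDesign | None = None,
    architecture: GeneticArchitecture | None = None,
    engine_settings: dict | None = None,
    k: int = 5,
    seed: int = 0,
    params: "object" = None,
    dataset: SyntheticDataset | None = None,
    direct_only: bool = False,
) -> tuple[ScenarioReport, SyntheticDataset]:
    """Generate (or reuse) a synthetic study and compare both scenarios.

    ``params`` overrides the "observed" parameter table (e.g. DE
    calibration estimates); by default the synthetic truth is used.
    ``direct_only`` skips the CGM-GP scenario (report deltas are empty).
    """
    data = dataset or generate_dataset(design, architecture, seed=seed)
    engines = _seeded(engine_settings or DESK_ENGINE_SETTINGS, seed)
    folds = kfold_split(data.markers.genotype_ids, k=k, seed=seed)
    trait = data.observed_trait
    observed_secondary = {
        t: data.observed_secondary(t) for t in ("Mainstemfw", "PHT", "Arealfel")
    }
    direct = run_direct_scenario(data.markers, trait, folds, engines)
    if direct_only:
        empty = {"scenario": "cgm-gp", "folds_checksum": direct["folds_checksum"],
                 "engines": {}}
        return ScenarioReport(direct, empty, {}, direct["folds_checksum"]), data
    cgm = run_cgmgp_scenario(
        data.markers,
        params if params is not None else data.true_params,
        data.weather,
        folds,
        engines,
        constants=data.constants,
        observed_trait=trait,
        observed_secondary=observed_secondary,
    )
    return compare(direct, cgm), data
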