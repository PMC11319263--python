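"""Tests of fold handling, metrics, and the two-scenario orchestration."""

import numpy as np
import pandas as pd
import pytest

from cgmgp.evaluation import (
    compare,
    kfold_split,
    nmae,
    predictive_ability,
    run_cgmgp_scenario,
    run_direct_scenario,
)
from cgmgp.gp_models.base import GPModel
from cgmgp.growth_model import PARAMETER_BOUNDS, PARAMETER_NAMES


class TestKfoldSplit:
    def test_near_equal_fold_sizes(self):
        folds = kfold_split([f"G{i}" for i in range(136)], k=5, seed=0)
        sizes = sorted(np.bincount(folds.fold_index).tolist())
        assert sizes == [27, 27, 27, 27, 28]

    def test_exact_division(self):
        folds = kfold_split([f"G{i}" for i in range(10)], k=5, seed=1)
        assert np.bincount(folds.fold_index).tolist() == [2, 2, 2, 2, 2]

    def test_deterministic(self):
        ids = [f"G{i}" for i in range(30)]
        a = kfold_split(ids, seed=3)
        b = kfold_split(ids, seed=3)
        assert np.array_equal(a.fold_index, b.fold_index)
        assert a.checksum == b.checksum

    def test_too_few_genotypes_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(["G0", "G1"], k=5)


class TestMetrics:
    def test_nmae_identity_and_hand_values(self):
        assert nmae([3.0, 4.0], [3.0, 4.0]) == 0.0
        assert nmae([2.0, 4.0], [1.0, 5.0]) == pytest.approx(0.375)
        assert nmae([1.0], [0.0]) == pytest.approx(1.0)

    def test_predictive_ability_affine_invariance(self):
        y = np.array([1.0, 2.0, 3.0, 5.0])
        assert predictive_ability(y, y) == pytest.approx(1.0)
        assert predictive_ability(y, 2.0 + 3.0 * y) == pytest.approx(1.0)
        assert predictive_ability(y, 1.0 - 2.0 * y) == pytest.approx(-1.0)

    def test_predictive_ability_hand_value(self):
        assert predictive_ability([1.0, 2.0, 3.0], [1.0, 3.0, 2.0]) == pytest.approx(0.5)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="undefined PA"):
            predictive_ability([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class _RowLookupOracle(GPModel):
    """Test double: memorizes row -> target pairs seen anywhere (perfect
    out-of-sample predictions for rows it was built with)."""

    def __init__(self, X_full, Y_full):
        self.table = {X_full[i].tobytes(): np.atleast_1d(Y_full[i])
                      for i in range(len(X_full))}

    def _fit(self, X, Y):
        pass

    def _predict(self, X):
        return np.vstack([self.table[X[i].tobytes()] for i in range(len(X))])


class _MeanPredictor(GPModel):
    def _fit(self, X, Y):
        self.mean_ = Y.mean(axis=0)

    def _predict(self, X):
        return np.tile(self.mean_, (len(X), 1))


class _OutOfBoundsEngine(GPModel):
    """Predicts wildly out-of-range parameter values."""

    def _fit(self, X, Y):
        pass

    def _predict(self, X):
        return np.full((len(X), len(PARAMETER_NAMES)), 1e3)


@pytest.fixture(scope="module")
def tiny_noise_free():
    from cgmgp.synthetic_data import TrialDesign, generate_dataset

    return generate_dataset(TrialDesign(n_genotypes=25, n_markers=60,
                                        replicates=2, noise_cv=0.0, seed=21))


class TestDirectScenario:
    def test_oracle_engine_is_perfect(self, tiny_noise_free):
        data = tiny_noise_free
        y = data.observed_trait.to_numpy()
        X = data.markers.values.astype(float)
        folds = kfold_split(data.markers.genotype_ids, k=5, seed=0)
        part = run_direct_scenario(
            data.markers, y, folds, {"oracle": lambda: _RowLookupOracle(X, y)}
        )
        assert part["engines"]["oracle"]["nmae"] == pytest.approx(0.0, abs=1e-12)
        assert part["engines"]["oracle"]["pa"] == pytest.approx(1.0)

    def test_constant_prediction_flags_undefined_pa(self, tiny_noise_free):
        data = tiny_noise_free
        folds = kfold_split(data.markers.genotype_ids, k=5, seed=0)
        part = run_direct_scenario(
            data.markers, data.observed_trait, folds, {"mean": _MeanPredictor}
        )
        entry = part["engines"]["mean"]
        # within each fold the prediction is a constant: PA is undefined
        # there and reported as an error flag rather than a number
        for fold_entry in entry["per_fold"].values():
            assert fold_entry["pa"] is None
            assert "undefined PA" in fold_entry["pa_error"]

    def test_every_genotype_predicted_exactly_once(self, tiny_noise_free):
        data = tiny_noise_free
        y = data.observed_trait.to_numpy()
        folds = kfold_split(data.markers.genotype_ids, k=5, seed=2)
        counts = np.zeros(data.markers.n)
        for _, _, test in folds.folds():
            counts[test] += 1
        assert np.all(counts == 1)
        part = run_direct_scenario(
            data.markers, y, folds,
            {"oracle": lambda: _RowLookupOracle(data.markers.values.astype(float), y)},
        )
        assert np.all(np.isfinite(part["engines"]["oracle"]["predictions"]))


class TestCgmGpScenario:
    def test_true_parameters_reproduce_noise_free_trait(self, tiny_noise_free):
        data = tiny_noise_free
        y = data.observed_trait.to_numpy()
        P = data.true_params.to_numpy()
        X = data.markers.values.astype(float)
        folds = kfold_split(data.markers.genotype_ids, k=5, seed=0)
        part = run_cgmgp_scenario(
            data.markers, data.true_params, data.weather, folds,
            {"oracle": lambda: _RowLookupOracle(X, P)},
            constants=data.constants, observed_trait=y,
        )
        entry = part["engines"]["oracle"]
        assert entry["nmae"] == pytest.approx(0.0, abs=1e-9)
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in entry["param_nmae"].values())

    def test_parameter_nmae_table_has_eight_rows_per_engine(self, tiny_noise_free):
        data = tiny_noise_free
        folds = kfold_split(data.markers.genotype_ids, k=5, seed=0)
        X = data.markers.values.astype(float)
        P = data.true_params.to_numpy()
        direct = run_direct_scenario(
            data.markers, data.observed_trait, folds,
            {"oracle": lambda: _RowLookupOracle(X, data.observed_trait.to_numpy())},
        )
        cgm = run_cgmgp_scenario(
            data.markers, data.true_params, data.weather, folds,
            {"oracle": lambda: _RowLookupOracle(X, P)},
            constants=data.constants, observed_trait=data.observed_trait,
        )
        report = compare(direct, cgm)
        table = report.param_nmae_table()
        assert table.shape == (8, 1)
        assert list(table.index) == list(PARAMETER_NAMES)

    def test_out_of_bounds_predictions_are_clamped(self, tiny_noise_free):
        data = tiny_noise_free
        folds = kfold_split(data.markers.genotype_ids, k=5, seed=0)
        part = run_cgmgp_scenario(
            data.markers, data.true_params, data.weather, folds,
            {"wild": _OutOfBoundsEngine},
            constants=data.constants, observed_trait=data.observed_trait,
        )
        pred = part["engines"]["wild"]["param_predictions"]
        for j, name in enumerate(PARAMETER_NAMES):
            lo, hi = PARAMETER_BOUNDS[name]
            assert pred[:, j].min() >= lo and pred[:, j].max() <= hi


class TestCompare:
    def test_identical_oracle_scenarios_have_zero_deltas(self, tiny_noise_free):
        data = tiny_noise_free
        y = data.observed_trait.to_numpy()
        X = data.markers.values.astype(float)
        P = data.true_params.to_numpy()
        folds = kfold_split(data.markers.genotype_ids, k=5, seed=0)
        direct = run_direct_scenario(
            data.markers, y, folds, {"oracle": lambda: _RowLookupOracle(X, y)}
        )
        cgm = run_cgmgp_scenario(
            data.markers, data.true_params, data.weather, folds,
            {"oracle": lambda: _RowLookupOracle(X, P)},
            constants=data.constants, observed_trait=y,
        )
        report = compare(direct, cgm)
        assert report.deltas["oracle"]["nmae"] == pytest.approx(0.0, abs=1e-9)
        assert report.deltas["oracle"]["pa"] == pytest.approx(0.0, abs=1e-9)

    def test_report_schema(self, tiny_noise_free):
        data = tiny_noise_free
        y = data.observed_trait.to_numpy()
        X = data.markers.values.astype(float)
        P = data.true_params.to_numpy()
        folds = kfold_split(data.markers.genotype_ids, k=5, seed=0)
        direct = run_direct_scenario(
            data.markers, y, folds, {"oracle": lambda: _RowLookupOracle(X, y)}
        )
        cgm = run_cgmgp_scenario(
            data.markers, data.true_params, data.weather, folds,
            {"oracle": lambda: _RowLookupOracle(X, P)},
            constants=data.constants, observed_trait=y,
        )
        report = compare(direct, cgm)
        frame = report.summary_frame()
        assert set(frame.columns) == {"engine", "scenario", "nmae", "pa"}
        assert len(frame) == 2  # one engine x two scenarios
        assert report.to_json()  # serializable

    def test_fold_mismatch_rejected(self, tiny_noise_free):
        data = tiny_noise_free
        y = data.observed_trait.to_numpy()
        X = data.markers.values.astype(float)
        P = data.true_params.to_numpy()
        folds_a = kfold_split(data.markers.genotype_ids, k=5, seed=0)
        folds_b = kfold_split(data.markers.genotype_ids, k=5, seed=99)
        direct = run_direct_scenario(
            data.markers, y, folds_a, {"oracle": lambda: _RowLookupOracle(X, y)}
        )
        cgm = run_cgmgp_scenario(
            data.markers, data.true_params, data.weather, folds_b,
            {"oracle": lambda: _RowLookupOracle(X, P)},
            constants=data.constants, observed_trait=y,
        )
        with pytest.raises(ValueError, match="fold assignment mismatch"):
            compare(direct, cgm)
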