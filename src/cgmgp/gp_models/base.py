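"""Shared fit/predict contract of the whole-genome regression engines."""

from __future__ import annotations

import abc

import numpy as np

from ..markers import as_marker_array

__all__ = ["GPModel", "TargetScaler"]


class GPModel(abc.ABC):
    """A genomic-prediction engine over {-1,0,1} marker matrices.

    All engines accept an n x p marker matrix and an n-vector (or n x m
    matrix) of targets, and return predictions of the same target shape —
    so cross-validation folds and scenarios are engine-agnostic.
    """

    n_features_: int | None = None
    n_targets_: int | None = None
    _squeeze_: bool = False

    @abc.abstractmethod
    def _fit(self, X: np.ndarray, Y: np.ndarray) -> None: ...

    @abc.abstractmethod
    def _predict(self, X: np.ndarray) -> np.ndarray: ...

    def fit(self, X, y) -> "GPModel":
        X = as_marker_array(X)
        Y = np.asarray(y, dtype=float)
        if Y.ndim == 1:
            self._squeeze_ = True
            Y = Y[:, None]
        elif Y.ndim == 2:
            self._squeeze_ = False
        else:
            raise ValueError("targets must be 1-D or 2-D")
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and y have different numbers of genotypes")
        self.n_features_ = X.shape[1]
        self.n_targets_ = Y.shape[1]
        self._fit(X, Y)
        return self

    def predict(self, X) -> np.ndarray:
        if self.n_features_ is None:
            raise RuntimeError("model is not fitted")
        X = as_marker_array(X)
        if X.shape[1] != self.n_features_:
            raise ValueError(
                f"marker count mismatch: model trained with p={self.n_features_}, "
                f"got p={X.shape[1]}"
            )
        pred = self._predict(X)
        if not np.all(np.isfinite(pred)):
            raise FloatingPointError("non-finite predictions")
        return pred[:, 0] if self._squeeze_ else pred


class TargetScaler:
    """Per-target affine map onto [0, 1] and its inverse.

    Needed by the CNN's sigmoid output head; genotype-independent bounds
    (e.g. the admissible parameter intervals) can be supplied instead of
    data-driven min/max.
    """

    def __init__(self, mins, maxs):
        self.mins = np.atleast_1d(np.asarray(mins, dtype=float))
        self.maxs = np.atleast_1d(np.asarray(maxs, dtype=float))
        degenerate = self.maxs - self.mins < 1e-12
        self.mins = np.where(degenerate, self.mins - 0.5, self.mins)
        self.maxs = np.where(degenerate, self.maxs + 0.5, self.maxs)

    @classmethod
    def from_data(cls, Y: np.ndarray) -> "TargetScaler":
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        return cls(Y.min(axis=0), Y.max(axis=0))

    @classmethod
    def from_bounds(cls, bounds) -> "TargetScaler":
        lo, hi = zip(*bounds)
        return cls(np.array(lo), np.array(hi))

    def transform(self, Y: np.ndarray) -> np.ndarray:
        return (np.asarray(Y, dtype=float) - self.mins) / (self.maxs - self.mins)

    def inverse(self, Y01: np.ndarray) -> np.ndarray:
        return np.asarray(Y01, dtype=float) * (self.maxs - self.mins) + self.mins
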