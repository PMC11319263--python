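"""Interchangeable whole-genome regression engines (LASSO, Bayes C, CNN)."""

from __future__ import annotations

import numpy as np

from .base import GPModel, TargetScaler
from .bayesc import BayesCModel, BayesCSettings
from .cnn import CNNModel, CNNSettings, feature_lengths
from .lasso import LassoModel, LassoSettings, lasso_max_lambda

__all__ = [
    "GPModel", "TargetScaler",
    "LassoModel", "LassoSettings", "lasso_max_lambda",
    "BayesCModel", "BayesCSettings",
    "CNNModel", "CNNSettings", "feature_lengths",
    "lasso_fit", "bayesc_fit", "cnn_fit", "predict", "build_engine",
    "ENGINES",
]

ENGINES = {"lasso": (LassoModel, LassoSettings),
           "bayesc": (BayesCModel, BayesCSettings),
           "cnn": (CNNModel, CNNSettings)}


def build_engine(name: str, **settings) -> GPModel:
    """Construct a fresh unfitted engine by name."""
    try:
        model_cls, settings_cls = ENGINES[name]
    except KeyError:
        raise ValueError(f"unknown engine {name!r}; choose from {sorted(ENGINES)}") from None
    scaler = settings.pop("scaler", None)
    cfg = settings_cls(**settings)
    if name == "cnn":
        return model_cls(cfg, scaler=scaler)
    return model_cls(cfg)


def lasso_fit(X, y, settings: LassoSettings | None = None) -> LassoModel:
    return LassoModel(settings).fit(X, y)


def bayesc_fit(X, y, settings: BayesCSettings | None = None) -> BayesCModel:
    return BayesCModel(settings).fit(X, y)


def cnn_fit(X, Y, settings: CNNSettings | None = None,
            scaler: TargetScaler | None = None) -> CNNModel:
    return CNNModel(settings, scaler=scaler).fit(X, Y)


def predict(model: GPModel, X) -> np.ndarray:
    """Engine-agnostic prediction on the original target scale."""
    return model.predict(X)
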