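"""Marker-based narrow-sense heritability.

A VanRaden (method 1) genomic relationship matrix is built from the
{-1,0,1} marker codes, and h2 is estimated by restricted maximum
likelihood for the single-kernel model y = mu + g + e with
g ~ N(0, G sigma_g^2): one eigendecomposition of G reduces the REML
profile to a fast 1-D search over h2 in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .markers import MarkerMatrix, as_marker_array

__all__ = ["GRM", "vanraden_grm", "marker_h2"]


@dataclass(frozen=True)
class GRM:
    """Genomic relationship matrix with the allele frequencies used."""

    matrix: np.ndarray
    allele_freq: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("GRM must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")


def vanraden_grm(X) -> GRM:
    """VanRaden method-1 GRM: G = ZZ' / (2 sum p_j (1-p_j)).

    Z centers the alternate-allele dosage (codes + 1) by twice the
    estimated allele frequencies.  Monomorphic markers make the scaling
    uninformative and are rejected by name.
    """
    ids = X.marker_ids if isinstance(X, MarkerMatrix) else None
    X = as_marker_array(X)
    dosage = X + 1.0
    freq = dosage.mean(axis=0) / 2.0
    mono = np.flatnonzero((freq <= 0.0) | (freq >= 1.0))
    if mono.size:
        names = [ids[i] for i in mono[:5]] if ids else mono[:5].tolist()
        raise ValueError(f"monomorphic marker(s): {names}")
    Z = dosage - 2.0 * freq
    denom = 2.0 * np.sum(freq * (1.0 - freq))
    return GRM(Z @ Z.T / denom, freq)


def _reml_loglik(h2: float, lam: np.ndarray, ystar: np.ndarray, xstar: np.ndarray) -> float:
    """REML log-likelihood (up to a constant) at variance ratio h2."""
    n = len(ystar)
    d = h2 * lam + (1.0 - h2)
    d = np.maximum(d, 1e-12)
    xvx = np.sum(xstar**2 / d)
    beta = np.sum(xstar * ystar / d) / xvx
    r = ystar - xstar * beta
    ss = np.sum(r**2 / d)
    sigma2 = ss / (n - 1)
    return -0.5 * ((n - 1) * np.log(sigma2) + np.sum(np.log(d)) + np.log(xvx) + (n - 1))


def _reml_score(h2: float, lam: np.ndarray, ystar: np.ndarray, xstar: np.ndarray) -> float:
    """Derivative of the REML profile log-likelihood with respect to h2.

    Root-finding on the score is numerically far better conditioned than
    comparing near-equal likelihood values on the flat profile top.
    """
    n = len(ystar)
    d = np.maximum(h2 * lam + (1.0 - h2), 1e-12)
    dd = lam - 1.0
    xvx = np.sum(xstar**2 / d)
    beta = np.sum(xstar * ystar / d) / xvx
    r = ystar - xstar * beta
    ss = np.sum(r**2 / d)
    dss = -np.sum(r**2 * dd / d**2)  # envelope: beta is the GLS minimizer
    dxvx = -np.sum(xstar**2 * dd / d**2)
    return -0.5 * ((n - 1) * dss / ss + np.sum(dd / d) + dxvx / xvx)


def marker_h2(y, grm: GRM) -> dict:
    """REML estimate of h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2).

    Returns a dict with h2, the two variance components, and the REML
    log-likelihood at the maximizer.  The search locates the global
    maximum region on a coarse grid and refines it by root-finding on the
    analytic score, so the estimate is exactly invariant to affine
    rescaling of the phenotype.
    """
    y = np.asarray(y, dtype=float)
    G = grm.matrix
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 observations")
    if y.std() == 0:
        raise ValueError("constant phenotype: heritability undefined")
    lam, U = np.linalg.eigh(G)
    if lam.min() < -1e-6:
        raise ValueError(f"GRM not PSD (min eigenvalue {lam.min():.3g})")
    lam = np.maximum(lam, 0.0)
    # h2 is scale-free: search on standardized y so the optimum is exactly
    # invariant to affine rescaling of the phenotype
    ystar = U.T @ ((y - y.mean()) / y.std())
    xstar = U.T @ np.ones(n)

    grid = np.linspace(0.0, 1.0, 101)
    ll = np.array([_reml_loglik(h, lam, ystar, xstar) for h in grid])
    i = int(np.argmax(ll))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, 100)]
    score = lambda h: _reml_score(h, lam, ystar, xstar)
    if score(lo) <= 0.0 and i == 0:
        h2 = 0.0
    elif score(hi) >= 0.0 and i == 100:
        h2 = 1.0
    elif score(lo) > 0.0 > score(hi):
        h2 = float(brentq(score, lo, hi, xtol=1e-12))
    else:
        h2 = float(grid[i])  # ragged profile: keep the grid maximizer

    # report variance components and log-likelihood on the raw scale
    ystar_raw = U.T @ y
    loglik = _reml_loglik(h2, lam, ystar_raw, xstar)
    d = np.maximum(h2 * lam + (1.0 - h2), 1e-12)
    xvx = np.sum(xstar**2 / d)
    beta = np.sum(xstar * ystar_raw / d) / xvx
    sigma2 = np.sum((ystar_raw - xstar * beta) ** 2 / d) / (n - 1)
    return {
        "h2": h2,
        "sigma_g2": float(h2 * sigma2),
        "sigma_e2": float((1.0 - h2) * sigma2),
        "loglik": float(loglik),
    }
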