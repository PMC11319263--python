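"""Bayes C: spike-and-slab whole-genome regression by Gibbs sampling.

Model: y = mu + sum_k z_k a_k delta_k + e, with inclusion indicators
delta_k ~ Bernoulli(1 - pi), a shared slab variance a_k ~ N(0, sigma_a^2)
across all SNPs, scaled-inverse-chi^2 priors on both variances, and a flat
prior on mu.  Each (delta_k, a_k) pair is updated jointly from its
marginal full conditional; prediction is the posterior-mean genomic value.

The per-SNP sweep is JIT-compiled with numba; the chain is deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .base import GPModel

__all__ = ["BayesCSettings", "BayesCModel"]


@dataclass(frozen=True)
class BayesCSettings:
    pi: float = 0.99          # prior probability that a SNP effect is zero
    iterations: int = 12000
    burn_in: int = 2000
    thin: int = 10
    nu: float = 4.0           # prior degrees of freedom for both variances
    h2_prior: float = 0.5     # prior split of var(y) into genetic/residual
    seed: int = 0
    fixed_sigma_a2: float | None = None  # degenerate prior: variance held fixed
    fixed_sigma_e2: float | None = None
    update_pi: bool = False   # BayesC-pi variant: Beta-Bernoulli update of pi


@njit(cache=True)
def _gibbs(X, y, pi, n_iter, burn, thin, nu_a, s_a, nu_e, s_e,
           sa2_init, se2_init, fix_a, fix_e, update_pi, seed):
    np.random.seed(seed)
    n, p = X.shape
    xtx = np.empty(p)
    for k in range(p):
        acc = 0.0
        for t in range(n):
            acc += X[t, k] * X[t, k]
        xtx[k] = acc
    a = np.zeros(p)
    mu = y.mean()
    e = y - mu
    sa2, se2 = sa2_init, se2_init

    sum_a = np.zeros(p)
    sum_delta = np.zeros(p)
    sum_mu = 0.0
    sum_se2 = 0.0
    sum_se2_sq = 0.0
    sum_sa2 = 0.0
    n_kept = 0

    for it in range(n_iter):
        # intercept (flat prior)
        mu_cond = mu + e.sum() / n
        mu_new = mu_cond + np.random.normal() * np.sqrt(se2 / n)
        e += mu - mu_new
        mu = mu_new

        m_in = 0
        ssq_a = 0.0
        for k in range(p):
            if xtx[k] == 0.0:
                continue
            old = a[k]
            xk = X[:, k]
            rhs = xtx[k] * old
            for t in range(n):
                rhs += xk[t] * e[t]
            if pi >= 1.0:
                include = False
            elif pi <= 0.0:
                include = True
            else:
                log_bf = (-0.5 * np.log(1.0 + sa2 * xtx[k] / se2)
                          + rhs * rhs * sa2 / (2.0 * se2 * (se2 + sa2 * xtx[k])))
                log_odds = log_bf + np.log((1.0 - pi) / pi)
                if log_odds > 35.0:
                    include = True
                elif log_odds < -35.0:
                    include = False
                else:
                    include = np.random.random() < 1.0 / (1.0 + np.exp(-log_odds))
            if include:
                c = xtx[k] + se2 / sa2
                a_new = rhs / c + np.random.normal() * np.sqrt(se2 / c)
                m_in += 1
                ssq_a += a_new * a_new
            else:
                a_new = 0.0
            if a_new != old:
                diff = old - a_new
                for t in range(n):
                    e[t] += xk[t] * diff
            a[k] = a_new

        if not fix_a:
            sa2 = (ssq_a + nu_a * s_a) / np.random.chisquare(nu_a + m_in)
        if not fix_e:
            se2 = (np.dot(e, e) + nu_e * s_e) / np.random.chisquare(nu_e + n)
        if update_pi:
            pi = np.random.beta(p - m_in + 1.0, m_in + 1.0)

        if it >= burn and (it - burn) % thin == 0:
            n_kept += 1
            sum_mu += mu + e.sum() / n  # Rao-Blackwellized intercept E[mu | rest]
            for k in range(p):
                sum_a[k] += a[k]
                if a[k] != 0.0:
                    sum_delta[k] += 1.0
            sum_se2 += se2
            sum_se2_sq += se2 * se2
            sum_sa2 += sa2

    return sum_a / n_kept, sum_delta / n_kept, sum_mu / n_kept, \
        sum_sa2 / n_kept, sum_se2 / n_kept, sum_se2_sq / n_kept, n_kept


class BayesCModel(GPModel):
    """Bayes C engine; multi-target fits run one chain per column."""

    def __init__(self, settings: BayesCSettings | None = None):
        self.settings = settings or BayesCSettings()
        s = self.settings
        if not (0.0 <= s.pi <= 1.0):
            raise ValueError("pi must lie in [0, 1]")
        if s.iterations <= s.burn_in:
            raise ValueError("chain length must exceed burn-in")
        self.effects_: np.ndarray | None = None      # posterior-mean a*delta, (p, m)
        self.inclusion_: np.ndarray | None = None    # posterior inclusion prob, (p, m)
        self.intercepts_: np.ndarray | None = None
        self.posterior_: list[dict] = []

    def _fit(self, X: np.ndarray, Y: np.ndarray) -> None:
        s = self.settings
        X = np.asfortranarray(X)  # the Gibbs sweep walks columns
        effects, incl, mus = [], [], []
        self.posterior_ = []
        col_var = X.var(axis=0)
        mean_col_var = max(col_var.mean(), 1e-12)
        for k in range(Y.shape[1]):
            y = Y[:, k]
            var_y = max(y.var(), 1e-12)
            frac_in = max(1.0 - s.pi, 1.0 / X.shape[1])
            sa2_0 = s.fixed_sigma_a2 if s.fixed_sigma_a2 is not None else \
                s.h2_prior * var_y / (frac_in * X.shape[1] * mean_col_var)
            se2_0 = s.fixed_sigma_e2 if s.fixed_sigma_e2 is not None else \
                max(1.0 - s.h2_prior, 0.05) * var_y
            s_a = sa2_0 * max(s.nu - 2.0, 1e-6) / s.nu
            s_e = se2_0 * max(s.nu - 2.0, 1e-6) / s.nu
            out = _gibbs(
                X, y, float(s.pi), s.iterations, s.burn_in, s.thin,
                float(s.nu), s_a, float(s.nu), s_e, sa2_0, se2_0,
                s.fixed_sigma_a2 is not None, s.fixed_sigma_e2 is not None,
                s.update_pi, (s.seed + 1009 * k) % (2**31 - 1),
            )
            mean_a, mean_delta, mean_mu, mean_sa2, mean_se2, mean_se2_sq, n_kept = out
            effects.append(mean_a)
            incl.append(mean_delta)
            mus.append(mean_mu)
            self.posterior_.append({
                "sigma_a2": float(mean_sa2),
                "sigma_e2": float(mean_se2),
                "sigma_e2_sd": float(np.sqrt(max(mean_se2_sq - mean_se2**2, 0.0))),
                "n_samples": int(n_kept),
            })
        self.effects_ = np.column_stack(effects)
        self.inclusion_ = np.column_stack(incl)
        self.intercepts_ = np.array(mus)

    def _predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.effects_ + self.intercepts_
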