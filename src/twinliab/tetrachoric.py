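"""Tetrachoric correlation for symmetric twin pair tables.

A binary trait under the liability-threshold model arises when a latent
standard-normal liability exceeds a threshold ``tau``.  For a twin pair the
two liabilities are bivariate normal with correlation ``rho``; ``rho``
estimated from the 2x2 (here collapsed, symmetric 3-cell) table of affection
statuses is the tetrachoric correlation.  Because twin ordering within a
pair is arbitrary, a single threshold is shared by both members and the
pair table is the trinomial (concordant unaffected / discordant /
concordant affected).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import owens_t
from scipy.stats import norm

__all__ = [
    "bvn_cdf",
    "bvn_upper_orthant",
    "pair_cell_probabilities",
    "TetrachoricFit",
    "fit_tetrachoric",
]

_BOUNDARY_TOL = 1e-3
_RHO_LIMIT = 0.999
_CHI2_95_DF1 = 3.841458820694124


def bvn_cdf(h, k, rho):
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Vectorized; computed through Owen's T function, which is exact up to
    the accuracy of ``scipy.special.owens_t`` (~1e-14).
    """
    h, k, rho = np.broadcast_arrays(
        np.asarray(h, float), np.asarray(k, float), np.asarray(rho, float)
    )
    if np.any(np.abs(rho) > 1):
        raise ValueError("correlation must lie in [-1, 1]")
    # Perturb exact zeros: the Owen decomposition divides by h and k, and
    # the CDF is continuous, so a 1e-13 shift is harmless.
    h = np.where(h == 0.0, 1e-13, h)
    k = np.where(k == 0.0, 1e-13, k)

    out = np.empty(h.shape, float)
    hi = np.abs(rho) >= 1.0 - 1e-12
    if np.any(hi):
        # Degenerate limits: rho=1 -> comonotone, rho=-1 -> antithetic.
        pos = rho >= 0
        out[hi & pos] = norm.cdf(np.minimum(h, k))[hi & pos]
        neg = hi & ~pos
        out[neg] = np.maximum(norm.cdf(h) + norm.cdf(k) - 1.0, 0.0)[neg]
    lo = ~hi
    if np.any(lo):
        hh, kk, rr = h[lo], k[lo], rho[lo]
        s = np.sqrt(1.0 - rr * rr)
        with np.errstate(over="ignore", divide="ignore"):
            ah = (kk - rr * hh) / (hh * s)
            ak = (hh - rr * kk) / (kk * s)
        beta = np.where(hh * kk < 0, 0.5, 0.0)
        out[lo] = (
            0.5 * (norm.cdf(hh) + norm.cdf(kk))
            - owens_t(hh, ah)
            - owens_t(kk, ak)
            - beta
        )
    res = np.clip(out, 0.0, 1.0)
    return float(res) if res.ndim == 0 else res


def bvn_upper_orthant(h, k, rho):
    """P(X > h, Y > k) for standard bivariate normal with correlation rho.

    By symmetry of the bivariate normal this equals ``bvn_cdf(-h, -k, rho)``,
    which avoids catastrophic cancellation for large thresholds.
    """
    return bvn_cdf(np.negative(h), np.negative(k), rho)


def pair_cell_probabilities(tau, rho):
    """Trinomial cell probabilities (neither, exactly one, both affected)
    for a symmetric pair with shared threshold ``tau`` and liability
    correlation ``rho``."""
    p_both = bvn_upper_orthant(tau, tau, rho)
    p_one = 2.0 * (norm.sf(tau) - p_both)
    p_neither = 1.0 - 2.0 * norm.sf(tau) + p_both
    return p_neither, p_one, p_both


def _table_counts(table):
    """Accept a PairTable-like object or a (n00, n1, n2) triple."""
    if hasattr(table, "n_concordant_unaffected"):
        return (
            float(table.n_concordant_unaffected),
            float(table.n_discordant),
            float(table.n_concordant_affected),
        )
    n00, n1, n2 = table
    return float(n00), float(n1), float(n2)


def _negloglik(tau, rho, counts):
    n0, n1, n2 = counts
    p0, p1, p2 = pair_cell_probabilities(tau, rho)
    p = np.clip(np.array([p0, p1, p2]), 1e-300, 1.0)
    return -(n0 * np.log(p[0]) + n1 * np.log(p[1]) + n2 * np.log(p[2]))


@dataclass
class TetrachoricFit:
    """Maximum-likelihood tetrachoric fit on a symmetric pair table."""

    rho: float
    tau: float
    loglik: float
    ci_low: float | None = None
    ci_high: float | None = None
    boundary_flag: bool = False
    undefined: bool = False
    n_pairs: float = 0.0
    display_na: bool = field(default=False, repr=False)

    def to_dict(self) -> dict:
        return {
            "rho": self.rho,
            "tau": self.tau,
            "loglik": self.loglik,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "boundary_flag": self.boundary_flag,
            "undefined": self.undefined,
            "n_pairs": self.n_pairs,
        }


def _profile_nll(rho, counts, tau_start):
    res = optimize.minimize_scalar(
        lambda t: _negloglik(t, rho, counts),
        bounds=(tau_start - 3.0, tau_start + 3.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return res.fun


def _profile_ci(rho_hat, nll_min, counts, tau_hat):
    """Profile-likelihood 95% CI for rho, bracketed to [-0.999, 0.999]."""

    def deviance(r):
        return 2.0 * (_profile_nll(r, counts, tau_hat) - nll_min) - _CHI2_95_DF1

    lo = -_RHO_LIMIT
    hi = _RHO_LIMIT
    ci_low, ci_high = lo, hi
    if deviance(lo) > 0:
        ci_low = optimize.brentq(deviance, lo, rho_hat, xtol=1e-6)
    if deviance(hi) > 0:
        ci_high = optimize.brentq(deviance, rho_hat, hi, xtol=1e-6)
    return ci_low, ci_high


def fit_tetrachoric(table, ci: bool = True) -> TetrachoricFit:
    """Fit the symmetric trinomial liability model to a twin pair table.

    Parameters
    ----------
    table
        A ``PairTable`` or a ``(n_concordant_unaffected, n_discordant,
        n_concordant_affected)`` triple of counts.
    ci
        Compute a profile-likelihood 95% confidence interval for rho.

    Returns
    -------
    TetrachoricFit
        MLE of (tau, rho) with log-likelihood and optional CI.  With no
        affected individuals the fit is flagged undefined; when the
        likelihood is maximized at |rho| >= 1 - 1e-3 ``boundary_flag``
        is set.
    """
    counts = _table_counts(table)
    n0, n1, n2 = counts
    total = n0 + n1 + n2
    if total < 2:
        raise ValueError("need at least two pairs")
    n_affected = 2 * n2 + n1
    if n_affected == 0:
        return TetrachoricFit(
            rho=np.nan, tau=np.nan, loglik=np.nan, undefined=True, n_pairs=total
        )

    prev = n_affected / (2.0 * total)
    tau0 = norm.isf(min(max(prev, 1e-12), 1 - 1e-12))

    def nll_z(params):
        tau, z = params
        return _negloglik(tau, np.tanh(z), counts)

    best = None
    for rho_start in (0.0, 0.5, 0.9, -0.5):
        res = optimize.minimize(
            nll_z,
            x0=np.array([tau0, np.arctanh(rho_start * (1 - 1e-9))]),
            method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    tau_hat = float(best.x[0])
    rho_hat = float(np.tanh(best.x[1]))
    loglik = -float(best.fun)
    boundary = abs(rho_hat) >= 1.0 - _BOUNDARY_TOL
    if boundary:
        rho_hat = float(np.clip(rho_hat, -1.0, 1.0))

    ci_low = ci_high = None
    if ci:
        rho_for_ci = float(np.clip(rho_hat, -_RHO_LIMIT, _RHO_LIMIT))
        ci_low, ci_high = _profile_ci(rho_for_ci, best.fun, counts, tau_hat)

    return TetrachoricFit(
        rho=rho_hat,
        tau=tau_hat,
        loglik=loglik,
        ci_low=ci_low,
        ci_high=ci_high,
        boundary_flag=boundary,
        n_pairs=total,
        display_na=(n2 == 0),
    )
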