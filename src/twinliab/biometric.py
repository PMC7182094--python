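"""Liability-threshold variance-component models for twin pair tables.

Liability is decomposed into additive genetic (A), shared-environment (C),
dominance (D), and non-shared environment (E) proportions of variance.
MZ co-twins share A (and D) fully and C fully; DZ co-twins share half of A,
a quarter of D, and C fully.  The implied liability correlations

    rho_MZ = a2 + c2 + d2
    rho_DZ = a2/2 + c2 + d2/4

enter a joint trinomial likelihood over the MZ and DZ pair tables with a
single shared threshold.  C and D cannot be separated with twin data alone,
hence the classical model menu ACE / ADE / AE / CE / E compared by AIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import norm

from .tetrachoric import _negloglik, fit_tetrachoric

__all__ = [
    "MODELS",
    "VarianceComponents",
    "BiometricFit",
    "implied_correlations",
    "fit_biometric",
    "select_model",
]

# free variance components per model (e2 always absorbs the remainder)
MODELS: dict[str, tuple[str, ...]] = {
    "ACE": ("a2", "c2"),
    "ADE": ("a2", "d2"),
    "AE": ("a2",),
    "CE": ("c2",),
    "E": (),
}

_CHI2_95_DF1 = 3.841458820694124
_ZERO_SNAP = 1e-6


@dataclass
class VarianceComponents:
    a2: float = 0.0
    c2: float = 0.0
    d2: float = 0.0
    e2: float = 1.0
    model: str = "E"

    def __post_init__(self):
        total = self.a2 + self.c2 + self.d2 + self.e2
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"components must sum to 1, got {total}")

    def as_dict(self) -> dict:
        return {"a2": self.a2, "c2": self.c2, "d2": self.d2, "e2": self.e2}


def implied_correlations(components: VarianceComponents) -> tuple[float, float]:
    """Co-twin liability correlations implied by the variance components."""
    rho_mz = components.a2 + components.c2 + components.d2
    rho_dz = 0.5 * components.a2 + components.c2 + 0.25 * components.d2
    return rho_mz, rho_dz


@dataclass
class BiometricFit:
    components: VarianceComponents
    tau: float
    loglik: float
    aic: float
    ci_low: float | None = None
    ci_high: float | None = None
    degenerate: bool = False
    n_free_params: int = 1
    broad_sense: float | None = field(default=None)
    broad_sense_ci: tuple[float, float] | None = None

    @property
    def model(self) -> str:
        return self.components.model

    @property
    def heritability(self) -> float:
        return self.components.a2

    def to_dict(self) -> dict:
        d = {
            "model": self.model,
            "tau": self.tau,
            "loglik": self.loglik,
            "aic": self.aic,
            "a2_ci_low": self.ci_low,
            "a2_ci_high": self.ci_high,
        }
        d.update(self.components.as_dict())
        if self.broad_sense is not None:
            d["broad_sense"] = self.broad_sense
        return d


def _softmax_components(z: np.ndarray, free: tuple[str, ...]) -> dict:
    """Map unconstrained logits to the unit simplex over (free..., e2)."""
    logits = np.append(z, 0.0)
    w = np.exp(logits - logits.max())
    w /= w.sum()
    comp = dict.fromkeys(("a2", "c2", "d2"), 0.0)
    for name, val in zip(free, w[:-1]):
        comp[name] = float(val)
    comp["e2"] = float(w[-1])
    return comp


def _joint_nll(tau: float, comp: dict, mz_counts, dz_counts) -> float:
    rho_mz = comp["a2"] + comp["c2"] + comp["d2"]
    rho_dz = 0.5 * comp["a2"] + comp["c2"] + 0.25 * comp["d2"]
    return _negloglik(tau, rho_mz, mz_counts) + _negloglik(tau, rho_dz, dz_counts)


def _counts(table):
    if hasattr(table, "counts"):
        return tuple(float(v) for v in table.counts())
    return tuple(float(v) for v in table)


def _falconer_start(mz_counts, dz_counts) -> tuple[float, float]:
    """Starting values: probit threshold from pooled prevalence, Falconer
    heritability from tetrachoric point estimates."""
    n_mz = sum(mz_counts)
    n_dz = sum(dz_counts)
    prev = (2 * mz_counts[2] + mz_counts[1] + 2 * dz_counts[2] + dz_counts[1]) / (
        2.0 * (n_mz + n_dz)
    )
    tau0 = norm.isf(min(max(prev, 1e-10), 1 - 1e-10))
    try:
        r_mz = fit_tetrachoric(mz_counts, ci=False).rho
        r_dz = fit_tetrachoric(dz_counts, ci=False).rho
        a2_0 = float(np.clip(2.0 * (r_mz - r_dz), 0.05, 0.95))
    except Exception:
        a2_0 = 0.5
    return tau0, a2_0


def fit_biometric(mz_table, dz_table, model: str = "AE", ci: bool = True) -> BiometricFit:
    """Fit a variance-component model jointly to MZ and DZ pair tables.

    Maximizes the summed trinomial log-likelihood with a shared threshold.
    Components live on the unit simplex via a softmax transform; estimates
    within 1e-6 of the boundary are reported exactly at 0.  The 95% CI for
    a2 is profile likelihood (chi-square(1) cutoff 3.84), which respects
    the [0, 1] boundary.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(MODELS)}")
    free = MODELS[model]
    mz_counts = _counts(mz_table)
    dz_counts = _counts(dz_table)
    if sum(mz_counts) == 0 or sum(dz_counts) == 0:
        raise ValueError("both pair tables must be nonempty")
    n_affected = 2 * (mz_counts[2] + dz_counts[2]) + mz_counts[1] + dz_counts[1]
    degenerate = n_affected == 0

    tau0, a2_0 = _falconer_start(mz_counts, dz_counts)

    def unpack(x):
        return float(x[0]), _softmax_components(np.asarray(x[1:]), free)

    def nll(x):
        tau, comp = unpack(x)
        return _joint_nll(tau, comp, mz_counts, dz_counts)

    k = len(free)
    starts = []
    if k:
        z0 = np.log(max(a2_0, 0.05) / max(1 - a2_0, 0.05))
        main = np.full(k, z0 if "a2" in free else 0.0)
        if k == 2:
            main[1] = -2.0  # second component starts small
        starts = [np.concatenate(([tau0], main)), np.concatenate(([tau0], np.zeros(k)))]
    else:
        starts = [np.array([tau0])]

    best = None
    for x0 in starts:
        res = optimize.minimize(
            nll, x0, method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 6000},
        )
        if best is None or res.fun < best.fun:
            best = res
    tau_hat, comp_hat = unpack(best.x)
    # snap boundary estimates
    for name in ("a2", "c2", "d2"):
        if 0 < comp_hat[name] < _ZERO_SNAP:
            comp_hat["e2"] += comp_hat[name]
            comp_hat[name] = 0.0
    if comp_hat["e2"] < _ZERO_SNAP:
        # renormalize the dominant component
        comp_hat["e2"] = 0.0
        s = comp_hat["a2"] + comp_hat["c2"] + comp_hat["d2"]
        for name in ("a2", "c2", "d2"):
            comp_hat[name] /= s

    loglik = -float(best.fun)
    n_params = 1 + k
    aic = 2.0 * n_params - 2.0 * loglik

    ci_low = ci_high = None
    if ci and "a2" in free and not degenerate:
        ci_low, ci_high = _profile_ci_a2(
            comp_hat["a2"], best.fun, free, tau_hat, mz_counts, dz_counts
        )

    components = VarianceComponents(model=model, **comp_hat)
    return BiometricFit(
        components=components,
        tau=tau_hat,
        loglik=loglik,
        aic=aic,
        ci_low=ci_low,
        ci_high=ci_high,
        degenerate=degenerate,
        n_free_params=n_params,
    )


def _profile_nll_a2(a2_fixed, free, tau_start, mz_counts, dz_counts):
    """Minimize nll over tau (and the second free component) at fixed a2."""
    others = [f for f in free if f != "a2"]

    if not others:
        def nll(x):
            comp = {"a2": a2_fixed, "c2": 0.0, "d2": 0.0, "e2": 1.0 - a2_fixed}
            return _joint_nll(float(x[0]), comp, mz_counts, dz_counts)

        res = optimize.minimize_scalar(
            lambda t: nll([t]), bounds=(tau_start - 3, tau_start + 3),
            method="bounded", options={"xatol": 1e-9},
        )
        return res.fun

    other = others[0]
    rest = 1.0 - a2_fixed

    def nll(x):
        tau, logit = x
        frac = 1.0 / (1.0 + np.exp(-logit))
        comp = {"a2": a2_fixed, "c2": 0.0, "d2": 0.0}
        comp[other] = rest * frac
        comp["e2"] = rest * (1.0 - frac)
        return _joint_nll(tau, comp, mz_counts, dz_counts)

    best = None
    for l0 in (-3.0, 0.0):
        res = optimize.minimize(
            nll, np.array([tau_start, l0]), method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-9, "maxiter": 3000},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best.fun


def _profile_ci_a2(a2_hat, nll_min, free, tau_hat, mz_counts, dz_counts):
    def deviance(a2):
        return (
            2.0 * (_profile_nll_a2(a2, free, tau_hat, mz_counts, dz_counts) - nll_min)
            - _CHI2_95_DF1
        )

    eps = 1e-6
    lo, hi = eps, 1.0 - eps
    ci_low = 0.0
    ci_high = 1.0
    a2_in = float(np.clip(a2_hat, lo, hi))
    if deviance(lo) > 0:
        ci_low = optimize.brentq(deviance, lo, a2_in, xtol=1e-5)
    if deviance(hi) > 0:
        ci_high = optimize.brentq(deviance, a2_in, hi, xtol=1e-5)
    return ci_low, ci_high


def select_model(fits: list[BiometricFit], broad_sense_window: float = 2.0) -> BiometricFit:
    """Pick the minimum-AIC fit; ties go to the model with fewer parameters.

    When the winner is AE and an ADE fit lies within ``broad_sense_window``
    AIC units, the ADE broad-sense heritability (a2 + d2) is attached to the
    returned fit for reporting alongside the narrow-sense estimate.
    """
    if not fits:
        raise ValueError("no fits to select from")
    ranked = sorted(fits, key=lambda f: (f.aic, f.n_free_params))
    best = ranked[0]
    if best.model == "AE":
        for f in fits:
            if f.model == "ADE" and f.aic - best.aic <= broad_sense_window:
                best.broad_sense = f.components.a2 + f.components.d2
                break
    return best
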