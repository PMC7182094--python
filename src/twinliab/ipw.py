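"""Individual-level liability-threshold fitting with left truncation and
right censoring handled by inverse-probability-of-censoring weighting.

Register cohorts observe disease status only inside an observation window:
persons enter at the later of birth and registry start (left truncation)
and exit at onset, death, or registry end (right censoring).  A person
censored before their would-be onset is recorded unaffected, which drags
naive prevalence — and through it the threshold and the co-twin
correlation — away from the truth.

The correction used here weights each affected individual by the inverse
of the probability of still being under observation at their onset age,
estimated by a product-limit (Kaplan–Meier) curve for the censoring
process on the age scale.  Pairs enter a weighted composite pairwise
likelihood whose cell probabilities are bivariate-probit orthants with
person-specific thresholds ``tau_i = tau0 + beta @ x_i`` (sex and
birth-year-category covariates) and zygosity-structured correlations.
This is an approximation to full likelihood treatments of truncated twin
data, chosen for transparency and testability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import optimize
from scipy.stats import norm

from .biometric import MODELS, BiometricFit, VarianceComponents, _softmax_components
from .tetrachoric import bvn_upper_orthant

__all__ = [
    "CovariateSpec",
    "CensoringModel",
    "build_windows",
    "estimate_censoring",
    "fit_liability_ipw",
]

_DAYS_PER_YEAR = 365.25


@dataclass
class CovariateSpec:
    """Covariates entering the probit threshold linearly."""

    sex: bool = True
    birth_year_bin_width: int | None = 10

    def design(self, df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        cols = []
        names = []
        if self.sex:
            cols.append((df["sex"] == "female").to_numpy(float))
            names.append("female")
        if self.birth_year_bin_width:
            years = df["birth_year"].to_numpy()
            lo = (years.min() // self.birth_year_bin_width) * self.birth_year_bin_width
            bins = ((years - lo) // self.birth_year_bin_width).astype(int)
            uniq, counts = np.unique(bins, return_counts=True)
            reference = uniq[np.argmax(counts)]  # largest bin: identified intercept
            for b in uniq:
                if b == reference:
                    continue
                cols.append((bins == b).astype(float))
                names.append(f"birth_bin_{int(lo + b * self.birth_year_bin_width)}")
        if not cols:
            return np.zeros((len(df), 0)), []
        return np.column_stack(cols), names


@dataclass
class CensoringModel:
    """Product-limit estimate of remaining uncensored on the age scale."""

    times: np.ndarray
    survival: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.survival = np.asarray(self.survival, float)

    def survival_at(self, ages) -> np.ndarray:
        ages = np.asarray(ages, float)
        idx = np.searchsorted(self.times, ages, side="right") - 1
        s = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, len(self.survival) - 1)])
        return s


def _age_years(later, earlier) -> np.ndarray:
    return (
        pd.to_datetime(later).to_numpy() - pd.to_datetime(earlier).to_numpy()
    ).astype("timedelta64[D]").astype(float) / _DAYS_PER_YEAR


def build_windows(
    cohort,
    phenotypes: pd.DataFrame,
    disease: str,
    registry_start_year: int = 1964,
    end_year: int = 2015,
) -> pd.DataFrame:
    """Observation windows on the age scale for one disease.

    entry age = age at the later of birth and registry start; exit age =
    age at the earliest of onset, death, and registry end.  Persons whose
    onset predates entry keep affected status and are flagged
    ``prevalent_at_entry``.  Windows with exit <= entry are dropped
    (``n_dropped`` recorded in ``DataFrame.attrs``).
    """
    df = cohort.individuals.merge(
        phenotypes[["person_id", "affected", "onset_date"]], on="person_id", validate="1:1"
    )
    birth = pd.to_datetime(df["birth_date"])
    start = pd.Timestamp(f"{registry_start_year}-01-01")
    end = pd.Timestamp(f"{end_year}-12-31")

    entry_date = birth.clip(lower=start)
    exit_date = pd.to_datetime(df["death_date"]).fillna(end).clip(upper=end)
    onset = pd.to_datetime(df["onset_date"])
    has_onset = df["affected"] & onset.notna()
    exit_date = exit_date.where(~has_onset, np.minimum(onset, exit_date))

    out = pd.DataFrame(
        {
            "person_id": df["person_id"],
            "pair_id": df["pair_id"],
            "zygosity": df["zygosity"],
            "sex": df["sex"],
            "birth_year": birth.dt.year,
            "entry_age": _age_years(entry_date, birth),
            "exit_age": _age_years(exit_date, birth),
            "affected": df["affected"].to_numpy(),
            "prevalent_at_entry": (has_onset & (onset < entry_date)).to_numpy(),
        }
    )
    # prevalent-at-entry persons: status known, window starts at entry
    ok = (out["exit_age"] > out["entry_age"]) | out["prevalent_at_entry"]
    dropped = int((~ok).sum())
    out = out[ok].reset_index(drop=True)
    out.attrs["n_dropped"] = dropped
    return out


def estimate_censoring(windows: pd.DataFrame) -> CensoringModel:
    """Kaplan–Meier curve for the censoring process on the age scale.

    Exit without disease is the 'event'; onset-terminated windows are
    censored observations of the censoring process; delayed entry is
    respected.
    """
    event = (~windows["affected"].to_numpy()).astype(int)
    if event.sum() == 0:
        tmax = float(windows["exit_age"].max())
        return CensoringModel(np.array([0.0, tmax]), np.array([1.0, 1.0]))
    entry = np.minimum(windows["entry_age"].to_numpy(), windows["exit_age"].to_numpy() - 1e-9)
    km = KaplanMeierFitter()
    km.fit(windows["exit_age"], event_observed=event, entry=entry)
    sf = km.survival_function_
    return CensoringModel(sf.index.to_numpy(float), sf.iloc[:, 0].to_numpy(float))


def _pair_frame(windows: pd.DataFrame) -> pd.DataFrame:
    w = windows.sort_values(["pair_id", "person_id"])
    first = w.groupby("pair_id").nth(0)
    second = w.groupby("pair_id").nth(1)
    merged = first.merge(
        second, on="pair_id", suffixes=("_1", "_2"), validate="1:1"
    )
    return merged[merged["zygosity_1"].isin(("MZ", "DZ"))]


def fit_liability_ipw(
    windows: pd.DataFrame,
    censoring: CensoringModel | None = None,
    model: str = "AE",
    covariates: CovariateSpec | None = None,
    weight_truncation_quantile: float = 0.99,
) -> BiometricFit:
    """Weighted pairwise composite likelihood fit of a variance-component
    model on individual observation windows.

    Each complete pair contributes its bivariate-probit cell probability
    with person-specific thresholds, weighted by the product of member
    weights ``w_i = 1 / S_c(exit_age_i)`` for affected members (1 for
    unaffected members).  Affected weights are truncated at their
    ``weight_truncation_quantile`` to stabilize the variance.  With no
    censoring and no covariates this reduces exactly to the pair-table
    biometric fit.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    free = MODELS[model]
    covariates = covariates if covariates is not None else CovariateSpec(sex=False, birth_year_bin_width=None)

    w = windows.copy()
    if censoring is not None:
        s = censoring.survival_at(w["exit_age"])
        wt = np.where(w["affected"], 1.0 / np.clip(s, 1e-6, None), 1.0)
        aff = w["affected"].to_numpy()
        if aff.any():
            cap = np.quantile(wt[aff], weight_truncation_quantile)
            wt = np.minimum(wt, max(cap, 1.0))
    else:
        wt = np.ones(len(w))
    w["ipw_weight"] = wt

    X, names = covariates.design(w)
    for j, nm in enumerate(names):
        w[f"_x_{j}"] = X[:, j]
    pairs = _pair_frame(w)
    if len(pairs) == 0:
        raise ValueError("no complete pairs with windows")

    xcols1 = [f"_x_{j}_1" for j in range(len(names))]
    xcols2 = [f"_x_{j}_2" for j in range(len(names))]
    X1 = pairs[xcols1].to_numpy(float) if names else np.zeros((len(pairs), 0))
    X2 = pairs[xcols2].to_numpy(float) if names else np.zeros((len(pairs), 0))
    y1 = pairs["affected_1"].to_numpy(bool)
    y2 = pairs["affected_2"].to_numpy(bool)
    is_mz = (pairs["zygosity_1"] == "MZ").to_numpy()
    pw = (pairs["ipw_weight_1"] * pairs["ipw_weight_2"]).to_numpy(float)

    # Group identical likelihood contributions: (zygosity, y1, y2, covariate
    # pattern of both members) -> summed weight.  Keeps each evaluation at a
    # handful of orthant calls regardless of cohort size.
    key = pd.DataFrame(
        np.column_stack([is_mz, y1, y2, X1, X2]),
    )
    grouped = key.assign(_w=pw).groupby(list(key.columns), sort=False)["_w"].sum()
    G = grouped.index.to_frame(index=False).to_numpy(float)
    gw = grouped.to_numpy(float)
    g_mz = G[:, 0].astype(bool)
    g_y1 = G[:, 1].astype(bool)
    g_y2 = G[:, 2].astype(bool)
    p = len(names)
    g_X1 = G[:, 3 : 3 + p]
    g_X2 = G[:, 3 + p : 3 + 2 * p]

    prev = (w["affected"].astype(float) * w["ipw_weight"]).sum() / w["ipw_weight"].sum()
    tau0 = norm.isf(min(max(prev, 1e-10), 1 - 1e-10))
    k_comp = len(free)

    def nll(params):
        tau_base = params[0]
        beta = params[1 : 1 + p]
        comp = _softmax_components(np.asarray(params[1 + p :]), free)
        rho_mz = comp["a2"] + comp["c2"] + comp["d2"]
        rho_dz = 0.5 * comp["a2"] + comp["c2"] + 0.25 * comp["d2"]
        t1 = tau_base + g_X1 @ beta
        t2 = tau_base + g_X2 @ beta
        rho = np.where(g_mz, rho_mz, rho_dz)
        p11 = bvn_upper_orthant(t1, t2, rho)
        s1 = norm.sf(t1)
        s2 = norm.sf(t2)
        pcell = np.where(
            g_y1 & g_y2, p11,
            np.where(
                g_y1 & ~g_y2, s1 - p11,
                np.where(~g_y1 & g_y2, s2 - p11, 1.0 - s1 - s2 + p11),
            ),
        )
        return -np.sum(gw * np.log(np.clip(pcell, 1e-300, None)))

    x0 = np.concatenate(([tau0], np.zeros(p), np.zeros(k_comp)))
    if k_comp:
        x0[-k_comp] = 0.8  # mild pull toward a2 > e2 start
    # bounds keep the threshold and covariate offsets identified when case
    # counts per covariate cell are tiny
    bounds = (
        [(-2.0, 6.0)] + [(-5.0, 5.0)] * p + [(-25.0, 25.0)] * k_comp
    )
    res = optimize.minimize(
        nll, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-9},
    )
    if not res.success:
        res2 = optimize.minimize(
            nll, res.x, method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-9, "maxiter": 8000},
        )
        if res2.fun <= res.fun:
            res = res2
        if not (res.fun < np.inf):
            raise RuntimeError(f"liability fit did not converge: {res.message}")

    tau_hat = float(res.x[0])
    beta_hat = {nm: float(b) for nm, b in zip(names, res.x[1 : 1 + p])}
    comp_hat = _softmax_components(np.asarray(res.x[1 + p :]), free)
    for nm in ("a2", "c2", "d2"):
        if 0 < comp_hat[nm] < 1e-6:
            comp_hat["e2"] += comp_hat[nm]
            comp_hat[nm] = 0.0
    n_params = 1 + p + k_comp
    loglik = -float(res.fun)
    fit = BiometricFit(
        components=VarianceComponents(model=model, **comp_hat),
        tau=tau_hat,
        loglik=loglik,
        aic=2.0 * n_params - 2.0 * loglik,
        n_free_params=n_params,
    )
    fit.beta = beta_hat  # covariate effects on the probit threshold
    return fit
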