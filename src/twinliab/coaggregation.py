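"""Cross-twin familial aggregation and co-aggregation.

Proportional-hazards regression on the age scale, with the co-twin's
diagnosis of an index disease as a time-varying exposure: a twin is
unexposed while the co-twin is undiagnosed and becomes exposed strictly
after the co-twin's diagnosis date.  Left truncation (registry entry) is
handled through delayed entry, ties by the Efron approximation, and
within-pair dependence by a cluster-robust sandwich variance.

The hazard ratio contrasts disease incidence after versus before the
co-twin's diagnosis; run separately for MZ and DZ pairs, the MZ/DZ
difference indexes the genetic contribution to familial (co-)aggregation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceWarning

__all__ = [
    "CoxFit",
    "build_episodes",
    "fit_cox",
    "aggregation_report",
]

OUTCOME_MODES = ("same_disease", "different_disease", "any_disease")
_DAYS_PER_YEAR = 365.25


@dataclass
class CoxFit:
    log_hr: dict
    robust_se: dict
    model_se: dict
    hr: dict
    ci_low: dict
    ci_high: dict
    n_events: int
    n_episodes: int
    flagged: str | None = None

    def summary_row(self, term: str = "exposed") -> dict:
        return {
            "hr": self.hr.get(term),
            "ci_low": self.ci_low.get(term),
            "ci_high": self.ci_high.get(term),
            "n_events": self.n_events,
        }


def _age_at(date, birth):
    return (
        pd.to_datetime(date).to_numpy() - pd.to_datetime(birth).to_numpy()
    ).astype("timedelta64[D]").astype(float) / _DAYS_PER_YEAR


def build_episodes(
    cohort,
    phenotypes: dict[str, pd.DataFrame],
    index_disease: str,
    outcome_mode: str = "same_disease",
    registry_start_year: int = 1964,
    end_year: int = 2015,
) -> pd.DataFrame:
    """Risk episodes with time-varying co-twin exposure.

    Every twin contributes follow-up from the later of birth and the
    disease observation start, until own outcome event, death, or the end
    of follow-up.  The outcome depends on ``outcome_mode``:

    * ``same_disease`` — own diagnosis of the index disease;
    * ``different_disease`` — own diagnosis of any studied disease other
      than the index disease;
    * ``any_disease`` — own diagnosis of any studied disease.

    Exposure is the co-twin's diagnosis of the index disease and begins
    strictly after that date; a same-day own event therefore falls in the
    unexposed state, and zero-length exposed episodes are dropped.
    Persons whose own outcome predates entry contribute nothing
    (``attrs["n_prevalent_skipped"]``).
    """
    if outcome_mode not in OUTCOME_MODES:
        raise ValueError(f"outcome_mode must be one of {OUTCOME_MODES}")
    if index_disease not in phenotypes:
        raise KeyError(f"no phenotype for index disease {index_disease!r}")

    ind = cohort.individuals
    idx_ph = phenotypes[index_disease]

    if outcome_mode == "same_disease":
        outcome = idx_ph.copy()
    else:
        pool = {
            d: ph for d, ph in phenotypes.items()
            if outcome_mode == "any_disease" or d != index_disease
        }
        frames = list(pool.values())
        if not frames:
            # no other studied diseases: nobody can have a qualifying outcome
            outcome = idx_ph[["person_id"]].assign(affected=False, onset_date=pd.NaT)
            frames = [outcome]
        base = frames[0][["person_id"]].copy()
        aff = np.zeros(len(base), bool)
        onset = np.full(len(base), np.datetime64("NaT"), dtype="datetime64[ns]")
        for f in frames:
            aff |= f["affected"].to_numpy()
            onset = np.fmin(onset, f["onset_date"].to_numpy())
        outcome = base.assign(affected=aff, onset_date=pd.to_datetime(onset))

    df = ind.merge(
        outcome.rename(columns={"affected": "out_affected", "onset_date": "out_onset"}),
        on="person_id",
    ).merge(
        idx_ph.rename(columns={"affected": "idx_affected", "onset_date": "idx_onset"}),
        on="person_id",
    )
    co = df[["pair_id", "person_id", "idx_affected", "idx_onset"]].rename(
        columns={
            "person_id": "co_person",
            "idx_affected": "co_affected",
            "idx_onset": "co_onset",
        }
    )
    df = df.merge(co, on="pair_id")
    df = df[df["person_id"] != df["co_person"]]

    birth = df["birth_date"]
    start = pd.Timestamp(f"{registry_start_year}-01-01")
    end = pd.Timestamp(f"{end_year}-12-31")
    entry_age = np.maximum(_age_at(pd.Series(start, index=df.index), birth), 0.0)
    death = pd.to_datetime(df["death_date"]).fillna(end).clip(upper=end)
    event_date = pd.to_datetime(df["out_onset"])
    has_event = df["out_affected"].to_numpy() & event_date.notna().to_numpy()
    exit_date = death.where(~has_event, np.minimum(event_date, death))
    exit_age = _age_at(exit_date, birth)
    event_at_exit = has_event & (event_date.to_numpy() <= death.to_numpy())

    switch_age = np.where(
        df["co_affected"].to_numpy() & pd.to_datetime(df["co_onset"]).notna().to_numpy(),
        _age_at(df["co_onset"], birth),
        np.inf,
    )

    prevalent = exit_age <= entry_age
    n_prevalent = int(prevalent.sum())
    keep = ~prevalent

    rows = {
        "person_id": df["person_id"].to_numpy()[keep],
        "pair_id": df["pair_id"].to_numpy()[keep],
        "zygosity": df["zygosity"].to_numpy()[keep],
        "sex": df["sex"].to_numpy()[keep],
        "birth_year": pd.to_datetime(df["birth_date"]).dt.year.to_numpy()[keep],
        "entry_age": entry_age[keep],
        "exit_age": exit_age[keep],
        "event": event_at_exit[keep],
        "switch_age": switch_age[keep],
    }
    base = pd.DataFrame(rows)

    # split at the exposure switch
    pre = base.copy()
    pre["exposed"] = False
    cut = np.minimum(pre["switch_age"], pre["exit_age"])
    switched = pre["switch_age"] < pre["exit_age"]
    pre.loc[switched, "exit_age"] = pre.loc[switched, "switch_age"]
    pre.loc[switched, "event"] = False
    # exposure begins strictly after the co-twin's diagnosis: a same-day own
    # event stays in the unexposed episode (switch_age >= exit_age there).
    post = base[switched].copy()
    post["exposed"] = True
    # a co-twin diagnosed before this person's registry entry makes them
    # exposed from entry onward, never from before observation began
    post["entry_age"] = np.maximum(post["switch_age"], post["entry_age"])
    post = post[post["exit_age"] > post["entry_age"]]

    episodes = pd.concat([pre, post], ignore_index=True).drop(columns=["switch_age"])
    episodes = episodes[episodes["exit_age"] > episodes["entry_age"]].reset_index(drop=True)
    episodes.attrs["n_prevalent_skipped"] = n_prevalent
    return episodes


def fit_cox(
    episodes: pd.DataFrame,
    covariates: tuple[str, ...] = ("sex", "birth_year_bin"),
    birth_year_bin_width: int = 10,
    compute_model_se: bool = True,
) -> CoxFit:
    """Cox regression on the age scale with delayed entry.

    ``exposed`` is always included; ``sex`` enters as a female indicator
    and ``birth_year_bin`` as categorical 10-year bins.  Cluster-robust
    (pair-level sandwich) standard errors are used for the reported CIs;
    model-based SEs are retained for comparison.
    """
    df = episodes.copy()
    if df["event"].sum() == 0:
        raise ValueError("no events in episode data")
    terms = ["exposed"]
    df["exposed"] = df["exposed"].astype(float)
    if "sex" in covariates:
        df["female"] = (df["sex"] == "female").astype(float)
        if df["female"].nunique() > 1:
            terms.append("female")
    if "birth_year_bin" in covariates:
        lo = (df["birth_year"].min() // birth_year_bin_width) * birth_year_bin_width
        bins = ((df["birth_year"] - lo) // birth_year_bin_width).astype(int)
        for b in sorted(bins.unique())[1:]:
            col = f"bin_{int(lo + b * birth_year_bin_width)}"
            df[col] = (bins == b).astype(float)
            terms.append(col)

    flagged = None
    if not df["exposed"].any():
        flagged = "no_exposed_person_time"

    # guard against constant or separation-prone adjustment columns
    for col in list(terms[1:]):
        sub = df.loc[df["event"], col]
        if df[col].nunique() < 2 or sub.nunique() < 1:
            terms.remove(col)

    def _fit(term_list, step_size):
        fit_df = df[["entry_age", "exit_age", "event", "pair_id"] + term_list]
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            cph.fit(
                fit_df,
                duration_col="exit_age",
                event_col="event",
                entry_col="entry_age",
                cluster_col="pair_id",
                robust=True,
                formula=" + ".join(term_list),
                # rare events with strong exposure effects need a damped
                # Newton step; the full step routinely overshoots into overflow
                fit_options={"step_size": step_size},
            )
        return cph, fit_df

    cph_model = None
    reduced = [t for t in terms if t in ("exposed", "female")]
    for term_list, step in (
        (terms, 0.5), (terms, 0.1),
        (reduced, 0.5), (reduced, 0.1),
        (["exposed"], 0.5), (["exposed"], 0.05),
    ):
        try:
            cph_model, fit_df = _fit(term_list, step)
        except Exception:
            continue
        if term_list is not terms:
            flagged = (flagged or "") + "reduced_covariates"
        terms = term_list
        break
    if cph_model is None:
        raise RuntimeError("proportional-hazards fit failed at all fallbacks")

    model_se = {k: np.nan for k in cph_model.params_.index}
    if compute_model_se:
        for step in (0.5, 0.1, 0.05):
            try:
                cph_naive = CoxPHFitter()
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    warnings.simplefilter("ignore", RuntimeWarning)
                    cph_naive.fit(
                        fit_df.drop(columns="pair_id"),
                        duration_col="exit_age",
                        event_col="event",
                        entry_col="entry_age",
                        formula=" + ".join(terms),
                        fit_options={"step_size": step},
                    )
                model_se = cph_naive.standard_errors_.to_dict()
                break
            except Exception:
                continue
    robust_se = cph_model.standard_errors_.to_dict()

    log_hr = cph_model.params_.to_dict()
    hr = {k: float(np.exp(v)) for k, v in log_hr.items()}
    ci_low = {k: float(np.exp(v - 1.96 * robust_se[k])) for k, v in log_hr.items()}
    ci_high = {k: float(np.exp(v + 1.96 * robust_se[k])) for k, v in log_hr.items()}
    return CoxFit(
        log_hr={k: float(v) for k, v in log_hr.items()},
        robust_se={k: float(v) for k, v in robust_se.items()},
        model_se={k: float(v) for k, v in model_se.items()},
        hr=hr,
        ci_low=ci_low,
        ci_high=ci_high,
        n_events=int(df["event"].sum()),
        n_episodes=len(df),
        flagged=flagged,
    )


def aggregation_report(
    cohort,
    phenotypes: dict[str, pd.DataFrame],
    diseases: list[str] | None = None,
    zygosity_strata: tuple[str, ...] = ("MZ", "DZ"),
    outcome_modes: tuple[str, ...] = OUTCOME_MODES,
    covariates: tuple[str, ...] = ("sex", "birth_year_bin"),
    registry_start_year: int = 1964,
    end_year: int = 2015,
) -> pd.DataFrame:
    """Hazard-ratio grid: index disease x outcome mode x zygosity.

    Strata where the model cannot be estimated (no events, or no exposed
    person-time) are reported with ``estimable = False``.
    """
    diseases = diseases or list(phenotypes)
    rows = []
    for disease in diseases:
        for mode in outcome_modes:
            episodes = build_episodes(
                cohort, phenotypes, disease, mode,
                registry_start_year=registry_start_year, end_year=end_year,
            )
            for zyg in zygosity_strata:
                sub = episodes[episodes["zygosity"] == zyg]
                row = {
                    "disease": disease,
                    "outcome_mode": mode,
                    "zygosity": zyg,
                    "estimable": False,
                    "hr": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "n_events": int(sub["event"].sum()),
                    "n_episodes": len(sub),
                }
                exposed_events = sub.loc[sub["exposed"], "event"].sum()
                if sub["event"].sum() > 0 and sub["exposed"].any() and exposed_events > 0:
                    try:
                        fit = fit_cox(sub, covariates=covariates)
                        row.update(fit.summary_row("exposed"))
                        row["estimable"] = True
                    except Exception:
                        pass
                rows.append(row)
    return pd.DataFrame(rows)
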