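"""Descriptive twin-cohort statistics: prevalence by sex, pair-clustered
sex-difference tests, pair tables, and probandwise concordance."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "PairTable",
    "PrevalenceEstimate",
    "ConcordanceEstimate",
    "prevalence_by_sex",
    "sex_difference_test",
    "build_pair_table",
    "probandwise",
]


@dataclass
class PairTable:
    """Per-zygosity symmetric pair classification by number affected."""

    disease: str
    zygosity: str
    n_concordant_unaffected: int
    n_discordant: int
    n_concordant_affected: int

    @property
    def n_pairs(self) -> int:
        return self.n_concordant_unaffected + self.n_discordant + self.n_concordant_affected

    def counts(self) -> tuple[int, int, int]:
        return (
            self.n_concordant_unaffected,
            self.n_discordant,
            self.n_concordant_affected,
        )


@dataclass
class PrevalenceEstimate:
    disease: str
    stratum: str  # "all", "female", "male"
    n_cases: int
    n_denominator: int
    prevalence_per_100k: float

    @property
    def display(self) -> int:
        """Integer cases per 100 000, as prevalence tables print it."""
        return int(round(self.prevalence_per_100k))


@dataclass
class ConcordanceEstimate:
    rate: float
    ci_low: float
    ci_high: float
    n_probands: int
    undefined: bool = False
    display_na: bool = False


def _merged(cohort, phenotypes: pd.DataFrame) -> pd.DataFrame:
    return cohort.individuals.merge(
        phenotypes[["person_id", "affected", "onset_date"]], on="person_id", validate="1:1"
    )


def prevalence_by_sex(cohort, phenotypes: pd.DataFrame, disease: str) -> list[PrevalenceEstimate]:
    """Observed prevalence per 100 000, overall and per sex."""
    df = _merged(cohort, phenotypes)
    out = []
    for stratum, sub in (
        ("all", df),
        ("female", df[df["sex"] == "female"]),
        ("male", df[df["sex"] == "male"]),
    ):
        denom = len(sub)
        if denom == 0:
            raise ValueError(f"empty denominator for stratum {stratum!r}")
        cases = int(sub["affected"].sum())
        out.append(
            PrevalenceEstimate(disease, stratum, cases, denom, 100_000.0 * cases / denom)
        )
    return out


def sex_difference_test(cohort, phenotypes: pd.DataFrame, disease: str) -> float:
    """Two-sided Wald p-value for a sex difference in disease status.

    Marginal logit model of affected status on sex, with variance clustered
    on twin pair (independence working correlation; robust sandwich
    covariance), i.e. a generalized estimating equation.
    """
    df = _merged(cohort, phenotypes)
    if df["affected"].sum() == 0:
        return float("nan")
    if df["sex"].nunique() < 2:
        raise ValueError("both sexes must be present")
    y = df["affected"].astype(float)
    x = sm.add_constant((df["sex"] == "female").astype(float).rename("female"))
    model = sm.GEE(
        y,
        x,
        groups=df["pair_id"],
        family=sm.families.Binomial(),
        cov_struct=sm.cov_struct.Independence(),
    )
    res = model.fit()
    return float(res.pvalues["female"])


def build_pair_table(cohort, phenotypes: pd.DataFrame, disease: str, zygosity: str) -> PairTable:
    """Classify complete pairs of one zygosity by number affected (0/1/2)."""
    df = _merged(cohort, phenotypes)
    df = df[df["zygosity"] == zygosity]
    n_aff = df.groupby("pair_id")["affected"].sum()
    counts = n_aff.value_counts().reindex([0, 1, 2], fill_value=0)
    return PairTable(
        disease=disease,
        zygosity=zygosity,
        n_concordant_unaffected=int(counts[0]),
        n_discordant=int(counts[1]),
        n_concordant_affected=int(counts[2]),
    )


def probandwise(table: PairTable) -> ConcordanceEstimate:
    """Probandwise concordance: the probability that a twin is affected
    given an affected co-twin, 2C / (2C + D) over concordant-affected (C)
    and discordant (D) pair counts.

    The 95% CI is a Wilson score interval on the proband-level proportion;
    probands within a concordant pair are statistically dependent, so the
    interval is mildly anti-conservative and is reported as descriptive
    only.  With no affected pairs at all the estimate is undefined; with
    discordant but no concordant pairs the rate is 0 and flagged for NA
    display, matching register-study reporting practice.
    """
    c = table.n_concordant_affected
    d = table.n_discordant
    n_probands = 2 * c + d
    if n_probands == 0:
        return ConcordanceEstimate(np.nan, np.nan, np.nan, 0, undefined=True, display_na=True)
    rate = 2.0 * c / n_probands
    lo, hi = proportion_confint(2 * c, n_probands, alpha=0.05, method="wilson")
    return ConcordanceEstimate(
        rate=rate,
        ci_low=float(lo),
        ci_high=float(hi),
        n_probands=n_probands,
        display_na=(c == 0),
    )
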