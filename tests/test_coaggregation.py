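"""Episode construction and cluster-robust proportional-hazards fits."""

import numpy as np
import pandas as pd
import pytest

from twinliab.coaggregation import aggregation_report, build_episodes, fit_cox
from twinliab.simulate import (
    SimulationConfig,
    TraitSpec,
    simulate_cohort,
    truth_phenotypes,
)

from conftest import make_cohort, phenotype_frame


def _two_trait_cohort(seed, n_pairs=4000, rg=0.6, dz_share=0.0, a2=0.6, prev=0.05):
    """Fast truth-phenotype cohort: two correlated traits, no registry loss."""
    traits = [
        TraitSpec("alpha", a2=a2, prevalence=prev, icd10_code="A00"),
        TraitSpec("beta", a2=a2, prevalence=prev, icd10_code="B00"),
    ]
    cfg = SimulationConfig(
        n_pairs=n_pairs,
        mz_fraction=0.5,
        birth_year_range=(1900, 1960),
        traits=traits,
        cross_trait_genetic_correlation=rg,
        dz_additive_correlation=dz_share,
        seed=seed,
        enable_death=False,
        emit_events=False,
    )
    result = simulate_cohort(cfg)
    return result.cohort, truth_phenotypes(result)


class TestBuildEpisodes:
    def _cohort_with_onsets(self, own_onset, co_onset):
        cohort = make_cohort(
            [
                ("e1", "p1", "MZ", "female", "1954-01-01", None),
                ("e2", "p1", "MZ", "female", "1954-01-01", None),
            ]
        )
        onsets = {}
        if own_onset:
            onsets["e1"] = own_onset
        if co_onset:
            onsets["e2"] = co_onset
        phen = phenotype_frame(cohort, set(onsets), onsets)
        return cohort, {"d": phen}

    def test_exposure_switch_splits_follow_up(self):
        # entry at age 10 (registry 1964), co-twin onset 40, own onset 45
        cohort, phen = self._cohort_with_onsets("1999-01-01", "1994-01-01")
        ep = build_episodes(cohort, phen, "d", "same_disease")
        own = ep[ep.person_id == "e1"].sort_values("entry_age")
        assert len(own) == 2
        first, second = own.iloc[0], own.iloc[1]
        assert not first["exposed"] and not first["event"]
        assert first["entry_age"] == pytest.approx(10.0, abs=0.01)
        assert first["exit_age"] == pytest.approx(40.0, abs=0.01)
        assert second["exposed"] and second["event"]
        assert second["entry_age"] == pytest.approx(40.0, abs=0.01)
        assert second["exit_age"] == pytest.approx(45.0, abs=0.01)

    def test_undiagnosed_co_twin_gives_single_episode(self):
        cohort, phen = self._cohort_with_onsets(None, None)
        ep = build_episodes(cohort, phen, "d", "same_disease")
        own = ep[ep.person_id == "e1"]
        assert len(own) == 1
        assert not own.iloc[0]["exposed"] and not own.iloc[0]["event"]
        assert own.iloc[0]["exit_age"] == pytest.approx(61.997, abs=0.01)

    def test_same_day_onsets_counted_unexposed(self):
        cohort, phen = self._cohort_with_onsets("1994-01-01", "1994-01-01")
        ep = build_episodes(cohort, phen, "d", "same_disease")
        own = ep[ep.person_id == "e1"]
        assert len(own) == 1  # zero-length exposed episode dropped
        assert not own.iloc[0]["exposed"]
        assert own.iloc[0]["event"]

    def test_prevalent_before_entry_skipped(self):
        cohort, phen = self._cohort_with_onsets("1960-01-01", None)
        ep = build_episodes(cohort, phen, "d", "same_disease")
        assert (ep.person_id != "e1").all()
        assert ep.attrs["n_prevalent_skipped"] == 1

    def test_person_time_conserved_by_split(self):
        cohort, phen = _two_trait_cohort(seed=21, n_pairs=800)
        ep = build_episodes(cohort, phen, "alpha", "same_disease")
        lengths = (ep["exit_age"] - ep["entry_age"]).groupby(ep["person_id"]).sum()
        n_episodes = ep.groupby("person_id").size()
        split = n_episodes[n_episodes == 2].index
        # for split persons the two episodes abut exactly
        sub = ep[ep.person_id.isin(split)].sort_values(["person_id", "entry_age"])
        starts = sub.groupby("person_id")["entry_age"].agg(["first", "last"])
        ends = sub.groupby("person_id")["exit_age"].agg(["first", "last"])
        assert np.allclose(ends["first"], starts["last"])
        assert (lengths > 0).all()

    def test_event_counts_conserved_across_modes(self):
        cohort, phen = _two_trait_cohort(seed=22, n_pairs=800)
        for mode in ("same_disease", "different_disease", "any_disease"):
            ep = build_episodes(cohort, phen, "alpha", mode)
            per_person = ep.groupby("person_id")["event"].sum()
            assert per_person.max() <= 1


def brute_force_log_hr(episodes, grid=None):
    """Partial-likelihood grid oracle (delayed entry, no ties by design)."""
    entry = episodes["entry_age"].to_numpy()
    exit_ = episodes["exit_age"].to_numpy()
    x = episodes["exposed"].to_numpy(float)
    ev = episodes["event"].to_numpy(bool)
    if grid is None:
        grid = np.arange(-3.0, 3.0, 1e-4)
    ll = np.zeros_like(grid)
    for t, xe in zip(exit_[ev], x[ev]):
        at = (entry < t) & (t <= exit_)
        xa = x[at]
        ll += grid * xe - np.logaddexp.reduce(grid[None, :] * xa[:, None], axis=0)
    return grid[np.argmax(ll)]


class TestFitCox:
    def _toy_episodes(self, seed=8, n=120):
        rng = np.random.default_rng(seed)
        exposed = np.arange(n) % 3 == 0
        t = rng.exponential(np.where(exposed, 0.4, 1.0)) + 0.01
        return pd.DataFrame(
            {
                "person_id": [f"i{k}" for k in range(n)],
                "pair_id": [f"p{k}" for k in range(n)],
                "zygosity": "MZ",
                "sex": "female",
                "birth_year": 1950,
                "entry_age": 0.0,
                "exit_age": t,
                "event": rng.random(n) < 0.8,
                "exposed": exposed,
            }
        )

    def test_matches_grid_oracle(self):
        ep = self._toy_episodes()
        fit = fit_cox(ep, covariates=(), compute_model_se=False)
        oracle = brute_force_log_hr(ep)
        assert fit.log_hr["exposed"] == pytest.approx(oracle, abs=1e-3)

    def test_hr_ci_identity(self):
        ep = self._toy_episodes()
        fit = fit_cox(ep, covariates=())
        lo = np.exp(fit.log_hr["exposed"] - 1.96 * fit.robust_se["exposed"])
        assert fit.ci_low["exposed"] == pytest.approx(lo)
        assert fit.hr["exposed"] == pytest.approx(np.exp(fit.log_hr["exposed"]))

    def test_no_events_raises(self):
        ep = self._toy_episodes()
        ep["event"] = False
        with pytest.raises(ValueError, match="no events"):
            fit_cox(ep)

    def test_robust_se_exceeds_model_se_with_pair_correlation(self):
        cohort, phen = _two_trait_cohort(seed=31, n_pairs=3000, a2=0.8)
        ep = build_episodes(cohort, phen, "alpha", "same_disease")
        mz = ep[ep.zygosity == "MZ"]
        fit = fit_cox(mz, covariates=("sex",))
        assert fit.robust_se["exposed"] >= fit.model_se["exposed"]

    def test_mz_aggregation_exceeds_dz_without_dz_sharing(self):
        hits = 0
        for seed in range(3):
            cohort, phen = _two_trait_cohort(seed=40 + seed)
            ep = build_episodes(cohort, phen, "alpha", "same_disease")
            hr = {}
            for zyg in ("MZ", "DZ"):
                fit = fit_cox(
                    ep[ep.zygosity == zyg], covariates=("sex",), compute_model_se=False
                )
                hr[zyg] = fit.hr["exposed"]
            hits += hr["MZ"] > hr["DZ"]
        assert hits >= 2


class TestAggregationReport:
    def test_single_disease_report_shape(self):
        cohort, phen = _two_trait_cohort(seed=55, n_pairs=1500)
        report = aggregation_report(
            cohort, {"alpha": phen["alpha"]}, covariates=("sex",)
        )
        assert set(report["outcome_mode"]) == {
            "same_disease", "different_disease", "any_disease"
        }
        # with one disease, no different-disease outcomes exist
        diff = report[report.outcome_mode == "different_disease"]
        assert not diff["estimable"].any()
        same = report[report.outcome_mode == "same_disease"].set_index("zygosity")
        any_ = report[report.outcome_mode == "any_disease"].set_index("zygosity")
        for zyg in ("MZ", "DZ"):
            assert same.loc[zyg, "n_events"] == any_.loc[zyg, "n_events"]

    def test_non_estimable_strata_flagged(self):
        cohort, phen = _two_trait_cohort(seed=56, n_pairs=60, prev=0.02)
        report = aggregation_report(cohort, phen, covariates=())
        assert {"disease", "zygosity", "outcome_mode", "hr", "estimable"} <= set(
            report.columns
        )
        assert (~report["estimable"]).any() or report["hr"].notna().all()
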