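"""Cohort I/O, exclusion cascade, and rule-based ascertainment."""

import numpy as np
import pandas as pd
import pytest

from twinliab.cohort import (
    Cohort,
    CohortValidationError,
    DiseaseDefinition,
    ExclusionRules,
    RequiredAtc,
    aggregate_any,
    apply_exclusions,
    ascertain,
    load_disease_definitions,
    read_cohort,
    write_cohort,
)
from twinliab.datasets import EXCLUSION_TALLIES, exclusion_cascade_cohort
from twinliab.simulate import SimulationConfig, simulate_cohort

from conftest import make_cohort


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

class TestReadWrite:
    def test_minimal_cohort_reads(self, tmp_path):
        (tmp_path / "ind.csv").write_text(
            "person_id,pair_id,zygosity,sex,birth_date,death_date\n"
            "x1,p1,MZ,female,1950-01-01,\n"
            "x2,p1,MZ,female,1950-01-01,\n"
        )
        (tmp_path / "ev.csv").write_text("person_id,system,code,date,register\n")
        cohort = read_cohort(tmp_path / "ind.csv", tmp_path / "ev.csv")
        assert cohort.n_pairs == 1
        assert len(cohort.events) == 0

    def test_orphan_event_rejected_with_id(self, tmp_path):
        (tmp_path / "ind.csv").write_text(
            "person_id,pair_id,zygosity,sex,birth_date,death_date\n"
            "x1,p1,MZ,female,1950-01-01,\n"
            "x2,p1,MZ,female,1950-01-01,\n"
        )
        (tmp_path / "ev.csv").write_text(
            "person_id,system,code,date,register\n"
            "ghost,ICD10,E06.3,1990-05-05,patient_register\n"
        )
        with pytest.raises(CohortValidationError, match="ghost"):
            read_cohort(tmp_path / "ind.csv", tmp_path / "ev.csv")

    def test_malformed_date_names_row(self, tmp_path):
        (tmp_path / "ind.csv").write_text(
            "person_id,pair_id,zygosity,sex,birth_date,death_date\n"
            "x1,p1,MZ,female,1950-13-45,\n"
            "x2,p1,MZ,female,1950-01-01,\n"
        )
        (tmp_path / "ev.csv").write_text("person_id,system,code,date,register\n")
        with pytest.raises(ValueError, match="1950-13-45"):
            read_cohort(tmp_path / "ind.csv", tmp_path / "ev.csv")

    def test_round_trip_preserves_simulated_cohort(self, tmp_path):
        result = simulate_cohort(SimulationConfig(n_pairs=150, seed=42))
        write_cohort(result.cohort, tmp_path / "i.csv", tmp_path / "e.csv")
        back = read_cohort(tmp_path / "i.csv", tmp_path / "e.csv")
        a = result.cohort.individuals.sort_values("person_id").reset_index(drop=True)
        b = back.individuals.sort_values("person_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b, check_dtype=False)
        ea = result.cohort.events.sort_values(["person_id", "date", "code"]).reset_index(drop=True)
        eb = back.events.sort_values(["person_id", "date", "code"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(ea, eb, check_dtype=False)


# ---------------------------------------------------------------------------
# Exclusion cascade
# ---------------------------------------------------------------------------

class TestExclusions:
    def test_published_tallies_reproduced(self):
        cohort = exclusion_cascade_cohort()
        assert cohort.n_individuals == EXCLUSION_TALLIES["initial"]
        reduced, report = apply_exclusions(cohort, ExclusionRules())
        tallies = dict(report.steps)
        assert tallies["unknown_zygosity"] == EXCLUSION_TALLIES["unknown_zygosity"]
        assert tallies["dead_before_cutoff"] == EXCLUSION_TALLIES["dead_before_cutoff"]
        assert tallies["co_twin_of_dead"] == EXCLUSION_TALLIES["co_twin_of_dead"]
        assert tallies["ambiguous_birth"] == EXCLUSION_TALLIES["ambiguous_birth"]
        assert report.final_n == EXCLUSION_TALLIES["final"]
        assert report.final_n == report.initial_n - sum(tallies.values())

    def test_clean_cohort_untouched(self, toy_pair_cohort):
        reduced, report = apply_exclusions(toy_pair_cohort)
        assert report.final_n == report.initial_n == 6
        assert all(n == 0 for _, n in report.steps)

    def test_death_removes_both_twins_in_separate_tallies(self):
        cohort = make_cohort(
            [
                ("d1", "p1", "MZ", "male", "1940-01-01", "1975-06-01"),
                ("d2", "p1", "MZ", "male", "1940-01-01", None),
                ("k1", "p2", "DZ", "male", "1950-01-01", None),
                ("k2", "p2", "DZ", "female", "1950-01-01", None),
            ]
        )
        reduced, report = apply_exclusions(cohort)
        tallies = dict(report.steps)
        assert tallies["dead_before_cutoff"] == 1
        assert tallies["co_twin_of_dead"] == 1
        assert reduced.n_individuals == 2

    def test_cascade_idempotent(self):
        cohort = exclusion_cascade_cohort()
        once, report1 = apply_exclusions(cohort)
        twice, report2 = apply_exclusions(once)
        assert report2.final_n == report1.final_n
        assert all(n == 0 for _, n in report2.steps)
        pd.testing.assert_frame_equal(
            once.individuals.reset_index(drop=True),
            twice.individuals.reset_index(drop=True),
        )


# ---------------------------------------------------------------------------
# Ascertainment
# ---------------------------------------------------------------------------

def _definition(min_inclusion=1, required_atc=None):
    return DiseaseDefinition(
        name="toy",
        inclusion_codes={"ICD10": ["E06.3"]},
        exclusion_codes={"ICD10": ["E03.1"]},
        min_inclusion_count=min_inclusion,
        required_atc=required_atc,
    )


def _person(events, death=None):
    cohort = make_cohort(
        [
            ("s1", "p1", "MZ", "female", "1940-01-01", death),
            ("s2", "p1", "MZ", "female", "1940-01-01", None),
        ],
        [("s1", *e) for e in events],
    )
    return cohort


class TestAscertainment:
    def test_single_inclusion_cancelled_by_single_exclusion(self):
        cohort = _person(
            [
                ("ICD10", "E06.3", "1990-01-01", "patient_register"),
                ("ICD10", "E03.1", "1991-01-01", "patient_register"),
            ]
        )
        ph = ascertain(cohort, _definition())
        assert not ph.set_index("person_id").loc["s1", "affected"]

    def test_two_inclusions_survive_single_exclusion(self):
        # person died 1990 so no prescription requirement applies
        cohort = _person(
            [
                ("ICD10", "E06.3", "1980-01-01", "patient_register"),
                ("ICD10", "E06.3", "1985-01-01", "patient_register"),
                ("ICD10", "E03.1", "1986-01-01", "patient_register"),
            ],
            death="1990-06-01",
        )
        req = RequiredAtc(atc_prefix="H03AA", min_dispensations=2)
        ph = ascertain(cohort, _definition(required_atc=req))
        row = ph.set_index("person_id").loc["s1"]
        assert row["affected"]
        assert row["onset_date"] == pd.Timestamp("1980-01-01")

    def test_two_inclusions_killed_by_two_exclusions(self):
        cohort = _person(
            [
                ("ICD10", "E06.3", "1980-01-01", "patient_register"),
                ("ICD10", "E06.3", "1985-01-01", "patient_register"),
                ("ICD10", "E03.1", "1986-01-01", "patient_register"),
                ("ICD10", "E03.1", "1987-01-01", "patient_register"),
            ]
        )
        ph = ascertain(cohort, _definition())
        assert not ph.set_index("person_id").loc["s1", "affected"]

    def test_drug_requirement_blocks_when_alive_with_one_dispensation(self):
        cohort = _person(
            [
                ("ICD10", "E06.3", "1980-01-01", "patient_register"),
                ("ICD10", "E06.3", "1985-01-01", "patient_register"),
                ("ATC", "H03AA01", "2006-03-01", "drug_register"),
            ]
        )
        req = RequiredAtc(atc_prefix="H03AA", min_dispensations=2)
        ph = ascertain(cohort, _definition(required_atc=req))
        assert not ph.set_index("person_id").loc["s1", "affected"]

    def test_drug_requirement_met_with_two_dispensations(self):
        cohort = _person(
            [
                ("ICD10", "E06.3", "1980-01-01", "patient_register"),
                ("ATC", "H03AA01", "2006-03-01", "drug_register"),
                ("ATC", "H03AA01", "2006-09-01", "drug_register"),
            ]
        )
        req = RequiredAtc(atc_prefix="H03AA", min_dispensations=2)
        ph = ascertain(cohort, _definition(required_atc=req))
        row = ph.set_index("person_id").loc["s1"]
        assert row["affected"]
        assert row["onset_date"] == pd.Timestamp("1980-01-01")

    def test_no_events_means_unaffected(self, toy_pair_cohort):
        ph = ascertain(toy_pair_cohort, _definition())
        assert not ph["affected"].any()
        assert ph["onset_date"].isna().all()

    def test_event_order_irrelevant(self):
        events = [
            ("ICD10", "E06.3", "1985-01-01", "patient_register"),
            ("ICD10", "E06.3", "1980-01-01", "patient_register"),
            ("ICD10", "E03.1", "1986-01-01", "patient_register"),
        ]
        ph1 = ascertain(_person(events), _definition())
        ph2 = ascertain(_person(events[::-1]), _definition())
        pd.testing.assert_frame_equal(ph1, ph2)

    def test_prefix_matching_within_system(self):
        cohort = _person(
            [
                ("ICD10", "E06.31", "1990-01-01", "patient_register"),  # prefix hit
                ("ICD9", "E06.3", "1991-01-01", "patient_register"),    # wrong system
            ]
        )
        ph = ascertain(cohort, _definition())
        row = ph.set_index("person_id").loc["s1"]
        assert row["affected"]
        assert row["onset_date"] == pd.Timestamp("1990-01-01")

    def test_diabetes_register_counts_as_inclusion(self):
        defs = load_disease_definitions()
        cohort = _person(
            [("ICD7", "zzz", "1990-01-01", "diabetes_register")]
        )
        ph = ascertain(cohort, defs["type1_diabetes"])
        assert ph.set_index("person_id").loc["s1", "affected"]

    def test_overlapping_inclusion_exclusion_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            DiseaseDefinition(
                name="bad",
                inclusion_codes={"ICD10": ["E06"]},
                exclusion_codes={"ICD10": ["E06"]},
            )


class TestAggregateAny:
    def test_earliest_onset_wins(self, toy_pair_cohort):
        from conftest import phenotype_frame

        ht = phenotype_frame(toy_pair_cohort, {"a1"}, {"a1": "1990-01-01"})
        cd = phenotype_frame(toy_pair_cohort, {"a1"}, {"a1": "1985-01-01"})
        combined = aggregate_any({"ht": ht, "cd": cd})
        row = combined.set_index("person_id").loc["a1"]
        assert row["affected"]
        assert row["onset_date"] == pd.Timestamp("1985-01-01")

    def test_all_unaffected(self, toy_pair_cohort):
        from conftest import phenotype_frame

        ph = phenotype_frame(toy_pair_cohort, set())
        combined = aggregate_any({"x": ph, "y": ph})
        assert not combined["affected"].any()

    def test_union_of_affected_sets(self):
        result = simulate_cohort(SimulationConfig(n_pairs=400, seed=9))
        defs = load_disease_definitions()
        cohort = result.cohort
        phen = {n: ascertain(cohort, d) for n, d in defs.items()}
        combined = aggregate_any(phen)
        union = set()
        for df in phen.values():
            union |= set(df.loc[df["affected"], "person_id"])
        assert int(combined["affected"].sum()) == len(union)
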