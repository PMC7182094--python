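import numpy as np
import pandas as pd
import pytest

from twinliab.cohort import Cohort


def make_cohort(individuals_rows, events_rows=()):
    """Build a validated Cohort from plain tuples.

    individuals: (person_id, pair_id, zygosity, sex, birth, death-or-None)
    events: (person_id, system, code, date, register)
    """
    ind = pd.DataFrame(
        individuals_rows,
        columns=["person_id", "pair_id", "zygosity", "sex", "birth_date", "death_date"],
    )
    ind["birth_date"] = pd.to_datetime(ind["birth_date"])
    ind["death_date"] = pd.to_datetime(ind["death_date"])
    ev = pd.DataFrame(
        list(events_rows), columns=["person_id", "system", "code", "date", "register"]
    )
    ev["date"] = pd.to_datetime(ev["date"])
    return Cohort(ind, ev)


@pytest.fixture
def toy_pair_cohort():
    """Three clean pairs, mixed sex and zygosity, no events."""
    return make_cohort(
        [
            ("a1", "p1", "MZ", "female", "1950-06-01", None),
            ("a2", "p1", "MZ", "female", "1950-06-01", None),
            ("b1", "p2", "DZ", "male", "1960-01-15", None),
            ("b2", "p2", "DZ", "female", "1960-01-15", None),
            ("c1", "p3", "DZ", "male", "1980-03-03", None),
            ("c2", "p3", "DZ", "male", "1980-03-03", None),
        ]
    )


def phenotype_frame(cohort, affected_ids, onsets=None):
    """Phenotype DataFrame aligned to the cohort's individuals."""
    onsets = onsets or {}
    pid = cohort.individuals["person_id"]
    df = pd.DataFrame(
        {
            "person_id": pid,
            "affected": pid.isin(set(affected_ids)).to_numpy(),
            "onset_date": pd.to_datetime(pid.map(onsets)),
        }
    )
    return df


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
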