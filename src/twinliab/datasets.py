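"""Published summary counts from a nationwide twin cohort study of seven
organ-specific autoimmune diseases.

These tables were printed in the study report and serve here as reference
inputs: pair-concordance counts by zygosity, per-sex case counts, cohort
composition, and the inclusion-cascade tallies.  They allow the
liability-threshold machinery to be exercised against real published
numbers without access to the underlying individual-level register data
(which is not publicly deposited).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import Cohort

__all__ = [
    "reference_pair_tables",
    "reference_case_counts",
    "REFERENCE_COHORT",
    "EXCLUSION_TALLIES",
    "exclusion_cascade_cohort",
]

# Cohort composition: totals by sex and zygosity.
REFERENCE_COHORT = {
    "n_total": 110_814,
    "n_female": 58_643,
    "n_male": 52_171,
    "n_mz": 35_990,
    "n_dz": 74_824,
}

# Inclusion-cascade tallies (individuals removed per rule, in order).
EXCLUSION_TALLIES = {
    "initial": 120_286,
    "unknown_zygosity": 3_966,
    "dead_before_cutoff": 3_453,
    "co_twin_of_dead": 2_049,
    "ambiguous_birth": 4,
    "final": 110_814,
}

# Pair classification by zygosity: (concordant unaffected, discordant,
# concordant affected).
_PAIR_TABLES = [
    ("hashimoto_thyroiditis", "MZ", 17_523, 391, 81),
    ("hashimoto_thyroiditis", "DZ", 36_339, 1_016, 57),
    ("atrophic_gastritis", "MZ", 17_803, 183, 9),
    ("atrophic_gastritis", "DZ", 36_968, 437, 7),
    ("celiac_disease", "MZ", 17_855, 93, 47),
    ("celiac_disease", "DZ", 36_981, 401, 30),
    ("graves_disease", "MZ", 17_831, 145, 19),
    ("graves_disease", "DZ", 37_040, 369, 3),
    ("type1_diabetes", "MZ", 17_900, 74, 21),
    ("type1_diabetes", "DZ", 37_170, 236, 6),
    ("vitiligo", "MZ", 17_933, 56, 6),
    ("vitiligo", "DZ", 37_308, 104, 0),
    ("addison_disease", "MZ", 17_986, 4, 5),
    ("addison_disease", "DZ", 37_398, 14, 0),
    ("any_disease", "MZ", 16_957, 831, 207),
    ("any_disease", "DZ", 34_926, 2_335, 151),
]

# Case counts by sex (denominators are the cohort sex totals above).
_CASE_COUNTS = [
    ("hashimoto_thyroiditis", 1_410, 273),
    ("atrophic_gastritis", 398, 254),
    ("celiac_disease", 433, 215),
    ("graves_disease", 463, 95),
    ("type1_diabetes", 179, 185),
    ("vitiligo", 95, 77),
    ("addison_disease", 15, 13),
    ("any_disease", 2_827, 1_055),
]


def reference_pair_tables() -> pd.DataFrame:
    """Published twin-pair concordance counts, one row per disease x zygosity."""
    return pd.DataFrame(
        _PAIR_TABLES,
        columns=[
            "disease",
            "zygosity",
            "n_concordant_unaffected",
            "n_discordant",
            "n_concordant_affected",
        ],
    )


def reference_case_counts() -> pd.DataFrame:
    """Published case counts by sex with cohort denominators."""
    df = pd.DataFrame(_CASE_COUNTS, columns=["disease", "n_cases_female", "n_cases_male"])
    df["n_female"] = REFERENCE_COHORT["n_female"]
    df["n_male"] = REFERENCE_COHORT["n_male"]
    return df


def exclusion_cascade_cohort() -> Cohort:
    """Synthetic individuals table engineered to reproduce the published
    inclusion-cascade tallies exactly.

    Pairs: 1 983 with unknown zygosity; 702 with both members dead before
    1976; 2 049 with exactly one member dead before 1976; 2 with ambiguous
    birth data; the remaining 55 407 pairs clean — 120 286 individuals in,
    110 814 out.  Event stream is empty (the cascade ignores events).
    """
    t = EXCLUSION_TALLIES
    n_unknown_pairs = t["unknown_zygosity"] // 2
    n_one_dead = t["co_twin_of_dead"]
    n_both_dead = (t["dead_before_cutoff"] - n_one_dead) // 2
    n_ambiguous = t["ambiguous_birth"] // 2
    n_total_pairs = t["initial"] // 2
    n_clean = n_total_pairs - n_unknown_pairs - n_one_dead - n_both_dead - n_ambiguous

    blocks = []
    pair_offset = 0

    def add_block(n_pairs, zygosity, death_first, death_second, birth_years):
        nonlocal pair_offset
        pid = np.arange(pair_offset, pair_offset + n_pairs)
        pair_offset += n_pairs
        for member, death in ((0, death_first), (1, death_second)):
            blocks.append(
                pd.DataFrame(
                    {
                        "person_id": [f"P{p:06d}_{member}" for p in pid],
                        "pair_id": [f"T{p:06d}" for p in pid],
                        "zygosity": zygosity,
                        "sex": "female" if member == 0 else "male",
                        "birth_date": pd.Timestamp(f"{birth_years[member]}-06-15"),
                        "death_date": pd.to_datetime(pd.Series([death] * n_pairs)),
                    }
                )
            )

    add_block(n_unknown_pairs, "UN", None, None, (1950, 1950))
    add_block(n_both_dead, "DZ", "1970-03-01", "1972-03-01", (1920, 1920))
    add_block(n_one_dead, "DZ", "1970-03-01", None, (1930, 1930))
    add_block(n_ambiguous, "MZ", None, None, (1950, 1951))
    n_mz_clean = REFERENCE_COHORT["n_mz"] // 2
    add_block(n_mz_clean, "MZ", None, None, (1950, 1950))
    add_block(n_clean - n_mz_clean, "DZ", None, None, (1950, 1950))

    individuals = pd.concat(blocks, ignore_index=True)
    events = pd.DataFrame(
        columns=["person_id", "system", "code", "date", "register"]
    )
    events["date"] = pd.to_datetime(events["date"])
    return Cohort(individuals, events)
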