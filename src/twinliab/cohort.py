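"""Twin cohort data model, tabular I/O, exclusion cascade, and rule-based
disease ascertainment.

The cohort is two tables, mirroring how register extracts arrive:

* ``individuals`` — one row per twin: ``person_id``, ``pair_id``,
  ``zygosity`` (MZ/DZ, anything else = unknown), ``sex`` (female/male),
  ``birth_date``, ``death_date`` (empty if alive).
* ``events`` — one row per register recording: ``person_id``, ``system``
  (ICD7/ICD8/ICD9/ICD10/ATC), ``code``, ``date``, ``register``
  (patient_register / drug_register / diabetes_register).

Disease status is derived from the event stream by a declarative
:class:`DiseaseDefinition`: prefix-matched inclusion codes, exclusion codes
for differential diagnoses of non-autoimmune etiology, and an optional
prescription requirement that applies only to persons alive after the drug
register reached full coverage.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Cohort",
    "DiseaseDefinition",
    "ExclusionRules",
    "ExclusionReport",
    "read_cohort",
    "write_cohort",
    "apply_exclusions",
    "ascertain",
    "aggregate_any",
    "load_disease_definitions",
]

CODE_SYSTEMS = ("ICD7", "ICD8", "ICD9", "ICD10", "ATC")
REGISTERS = ("patient_register", "drug_register", "diabetes_register")
ZYGOSITIES = ("MZ", "DZ")
SEXES = ("female", "male")

PATIENT_REGISTER_RANGE = (pd.Timestamp("1900-01-01"), pd.Timestamp("2015-12-31"))
DRUG_REGISTER_START = pd.Timestamp("2005-07-01")

INDIVIDUAL_COLUMNS = ["person_id", "pair_id", "zygosity", "sex", "birth_date", "death_date"]
EVENT_COLUMNS = ["person_id", "system", "code", "date", "register"]


class CohortValidationError(ValueError):
    pass


@dataclass
class Cohort:
    """A validated twin cohort: individuals plus their register events."""

    individuals: pd.DataFrame
    events: pd.DataFrame

    def __post_init__(self):
        self.individuals = self.individuals.reset_index(drop=True)
        self.events = self.events.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_pairs(self) -> int:
        return self.individuals["pair_id"].nunique()

    def validate(self, strict_pairs: bool = True) -> "Cohort":
        ind, ev = self.individuals, self.events
        if ind["person_id"].duplicated().any():
            dups = ind.loc[ind["person_id"].duplicated(), "person_id"].tolist()
            raise CohortValidationError(f"duplicate person_id(s): {dups[:5]}")
        if strict_pairs:
            sizes = ind.groupby("pair_id").size()
            bad = sizes[sizes != 2]
            if len(bad):
                raise CohortValidationError(
                    f"pairs without exactly two members: {bad.index.tolist()[:5]}"
                )
        known = set(ind["person_id"])
        orphan = ~ev["person_id"].isin(known)
        if orphan.any():
            ids = sorted(ev.loc[orphan, "person_id"].unique().tolist())
            raise CohortValidationError(f"events reference unknown person_id(s): {ids[:10]}")
        bad_sys = ~ev["system"].isin(CODE_SYSTEMS)
        if bad_sys.any():
            raise CohortValidationError(
                f"unknown code system(s): {sorted(ev.loc[bad_sys, 'system'].unique())}"
            )
        bad_reg = ~ev["register"].isin(REGISTERS)
        if bad_reg.any():
            raise CohortValidationError(
                f"unknown register(s): {sorted(ev.loc[bad_reg, 'register'].unique())}"
            )
        pr = ev["register"] == "patient_register"
        lo, hi = PATIENT_REGISTER_RANGE
        out = pr & ((ev["date"] < lo) | (ev["date"] > hi))
        if out.any():
            raise CohortValidationError(
                f"{int(out.sum())} patient-register event(s) dated outside {lo.date()}..{hi.date()}"
            )
        dr = ev["register"] == "drug_register"
        early = dr & (ev["date"] < DRUG_REGISTER_START)
        if early.any():
            raise CohortValidationError(
                f"{int(early.sum())} drug-register event(s) predate {DRUG_REGISTER_START.date()}"
            )
        return self

    def subset(self, person_ids) -> "Cohort":
        keep = self.individuals["person_id"].isin(set(person_ids))
        ind = self.individuals[keep]
        ev = self.events[self.events["person_id"].isin(set(ind["person_id"]))]
        return Cohort(ind.copy(), ev.copy())


def _parse_dates(series: pd.Series, column: str, path) -> pd.Series:
    parsed = pd.to_datetime(series, format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & series.notna() & (series.astype(str).str.strip() != "")
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"{path}: malformed date {series.iloc[row]!r} in column {column!r} (row {row + 2})"
        )
    return parsed


def read_cohort(individuals_path, events_path, sep: str | None = None,
                validate: bool = True, strict_pairs: bool = True) -> Cohort:
    """Read a cohort from delimited text files (CSV or TSV, header row).

    Dates are ISO-8601 (``YYYY-MM-DD``); an empty ``death_date`` means alive.
    Events referring to person ids absent from the individuals file raise a
    validation error listing the offending ids.
    """
    kw = {"dtype": str}
    if sep is None:
        kw.update(sep=None, engine="python")
    else:
        kw.update(sep=sep)
    ind = pd.read_csv(individuals_path, **kw)
    missing = set(INDIVIDUAL_COLUMNS) - set(ind.columns)
    if missing:
        raise ValueError(f"{individuals_path}: missing columns {sorted(missing)}")
    ind["birth_date"] = _parse_dates(ind["birth_date"], "birth_date", individuals_path)
    ind["death_date"] = _parse_dates(
        ind.get("death_date", pd.Series(dtype=str)), "death_date", individuals_path
    )

    try:
        ev = pd.read_csv(events_path, **kw)
    except pd.errors.EmptyDataError:
        ev = pd.DataFrame(columns=EVENT_COLUMNS)
    if len(ev) == 0:
        ev = pd.DataFrame(columns=EVENT_COLUMNS)
        ev["date"] = pd.to_datetime(ev["date"])
    else:
        missing = set(EVENT_COLUMNS) - set(ev.columns)
        if missing:
            raise ValueError(f"{events_path}: missing columns {sorted(missing)}")
        ev["date"] = _parse_dates(ev["date"], "date", events_path)
    cohort = Cohort(ind[INDIVIDUAL_COLUMNS], ev[EVENT_COLUMNS])
    if validate:
        cohort.validate(strict_pairs=strict_pairs)
    return cohort


def write_cohort(cohort: Cohort, individuals_path, events_path, sep: str = ",") -> None:
    ind = cohort.individuals.copy()
    for col in ("birth_date", "death_date"):
        ind[col] = pd.to_datetime(ind[col]).dt.strftime("%Y-%m-%d")
    ind.to_csv(individuals_path, sep=sep, index=False)
    ev = cohort.events.copy()
    ev["date"] = pd.to_datetime(ev["date"]).dt.strftime("%Y-%m-%d")
    ev.to_csv(events_path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Exclusion cascade
# ---------------------------------------------------------------------------

@dataclass
class ExclusionRules:
    """Inclusion cascade for register-based twin cohorts.

    ``survival_cutoff_year``: both members of a pair must be alive, or not
    yet born, on 1 January of this year — deaths before it remove the
    individual and, in a separate tallied step, the surviving co-twin.
    """

    survival_cutoff_year: int = 1976
    birth_year_range: tuple[int, int] = (1886, 2006)


@dataclass
class ExclusionReport:
    initial_n: int
    steps: list[tuple[str, int]] = field(default_factory=list)
    final_n: int = 0

    def as_frame(self) -> pd.DataFrame:
        rows = [{"rule": r, "individuals_removed": n} for r, n in self.steps]
        return pd.DataFrame(rows)


def apply_exclusions(cohort: Cohort, rules: ExclusionRules | None = None):
    """Apply the registry inclusion cascade, removing whole pairs.

    Order of rules (each tally counts individuals removed by that rule):

    1. ``unknown_zygosity`` — pairs with zygosity outside {MZ, DZ}.
    2. ``dead_before_cutoff`` — individuals who died before 1 January of the
       cutoff year.
    3. ``co_twin_of_dead`` — surviving co-twins of rule-2 individuals.
    4. ``ambiguous_birth`` — pairs with missing birth dates, members born in
       different calendar years, or birth year outside the cohort range.

    Returns the reduced cohort (complete pairs only) and a report whose
    tallies sum to ``initial_n - final_n``.  Idempotent.
    """
    rules = rules or ExclusionRules()
    ind = cohort.individuals.copy()
    initial_n = len(ind)
    steps: list[tuple[str, int]] = []

    unknown = ~ind["zygosity"].isin(ZYGOSITIES) | ind["zygosity"].isna()
    bad_pairs = set(ind.loc[unknown, "pair_id"])
    drop = ind["pair_id"].isin(bad_pairs)
    steps.append(("unknown_zygosity", int(drop.sum())))
    ind = ind[~drop]

    cutoff = pd.Timestamp(f"{rules.survival_cutoff_year}-01-01")
    dead = ind["death_date"].notna() & (ind["death_date"] < cutoff)
    dead_pairs = set(ind.loc[dead, "pair_id"])
    steps.append(("dead_before_cutoff", int(dead.sum())))
    cotwin = ~dead & ind["pair_id"].isin(dead_pairs)
    steps.append(("co_twin_of_dead", int(cotwin.sum())))
    ind = ind[~dead & ~cotwin]

    by = ind["birth_date"].dt.year
    lo, hi = rules.birth_year_range
    bad_birth = ind["birth_date"].isna() | (by < lo) | (by > hi)
    year_spread = ind.groupby("pair_id")["birth_date"].transform(
        lambda s: s.dt.year.nunique()
    )
    ambiguous_pairs = set(ind.loc[bad_birth, "pair_id"]) | set(
        ind.loc[year_spread > 1, "pair_id"]
    )
    drop = ind["pair_id"].isin(ambiguous_pairs)
    steps.append(("ambiguous_birth", int(drop.sum())))
    ind = ind[~drop]

    # Safety: enforce complete pairs (no-op for well-formed input).
    sizes = ind.groupby("pair_id")["person_id"].transform("size")
    ind = ind[sizes == 2]

    reduced = Cohort(
        ind.copy(),
        cohort.events[cohort.events["person_id"].isin(set(ind["person_id"]))].copy(),
    )
    report = ExclusionReport(initial_n=initial_n, steps=steps, final_n=len(ind))
    return reduced, report


# ---------------------------------------------------------------------------
# Disease definitions and ascertainment
# ---------------------------------------------------------------------------

@dataclass
class RequiredAtc:
    atc_prefix: str
    min_dispensations: int = 2
    applies_if_alive_after: str = "2005-12-31"


@dataclass
class DiseaseDefinition:
    """Declarative register-based case definition.

    ``inclusion_codes`` and ``exclusion_codes`` map a code system to a list
    of code prefixes (prefix match mirrors the ICD hierarchy).
    ``include_registers`` lists registers whose events count as inclusion
    events regardless of code (used for the diabetes-register cross-match).
    ``required_atc`` adds a prescription requirement for persons alive after
    the stated date.
    """

    name: str
    inclusion_codes: dict[str, list[str]] = field(default_factory=dict)
    exclusion_codes: dict[str, list[str]] = field(default_factory=dict)
    required_atc: RequiredAtc | None = None
    min_inclusion_count: int = 1
    include_registers: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.min_inclusion_count < 1:
            raise ValueError("min_inclusion_count must be >= 1")
        for system in self.inclusion_codes:
            overlap = set(self.inclusion_codes.get(system, [])) & set(
                self.exclusion_codes.get(system, [])
            )
            if overlap:
                raise ValueError(
                    f"{self.name}: inclusion/exclusion overlap in {system}: {sorted(overlap)}"
                )

    @classmethod
    def from_dict(cls, d: dict) -> "DiseaseDefinition":
        req = d.get("required_atc")
        return cls(
            name=d["name"],
            inclusion_codes={k: list(v) for k, v in (d.get("inclusion_codes") or {}).items()},
            exclusion_codes={k: list(v) for k, v in (d.get("exclusion_codes") or {}).items()},
            required_atc=RequiredAtc(**req) if req else None,
            min_inclusion_count=int(d.get("min_inclusion_count", 1)),
            include_registers=list(d.get("include_registers", [])),
        )


def load_disease_definitions(path=None) -> dict[str, DiseaseDefinition]:
    """Load disease definitions from YAML.  Without a path, the package's
    illustrative default set of seven organ-specific autoimmune diseases
    is used (the code lists are editable configuration, not a canonical
    register extract)."""
    if path is None:
        ref = importlib.resources.files("twinliab") / "data" / "diseases.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    defs = [DiseaseDefinition.from_dict(d) for d in raw["diseases"]]
    return {d.name: d for d in defs}


def _prefix_mask(ev: pd.DataFrame, code_map: dict[str, list[str]]) -> pd.Series:
    mask = pd.Series(False, index=ev.index)
    for system, prefixes in code_map.items():
        if not prefixes:
            continue
        mask |= (ev["system"] == system) & ev["code"].str.startswith(tuple(prefixes))
    return mask


def ascertain(cohort: Cohort, definition: DiseaseDefinition) -> pd.DataFrame:
    """Derive per-person phenotype status for one disease.

    A person is affected iff

    * inclusion events >= ``min_inclusion_count``; and
    * not excluded — a single exclusion-code event suffices when there is
      exactly one inclusion event, but with two or more inclusion events two
      or more exclusion events are required; and
    * the prescription requirement, when defined, is met for persons alive
      after its reference date (deceased persons are exempt).

    Onset is the earliest inclusion (or qualifying prescription) event date.

    Returns a DataFrame with columns ``person_id``, ``affected``,
    ``onset_date``, in the order of ``cohort.individuals``.
    """
    ind = cohort.individuals
    ev = cohort.events
    idx = pd.Index(ind["person_id"], name="person_id")

    incl_mask = _prefix_mask(ev, definition.inclusion_codes)
    if definition.include_registers:
        incl_mask |= ev["register"].isin(definition.include_registers)
    incl = ev[incl_mask]
    incl_count = incl.groupby("person_id").size().reindex(idx, fill_value=0)
    incl_first = incl.groupby("person_id")["date"].min().reindex(idx)

    excl = ev[_prefix_mask(ev, definition.exclusion_codes)]
    excl_count = excl.groupby("person_id").size().reindex(idx, fill_value=0)

    has_inclusion = incl_count >= definition.min_inclusion_count
    excluded = np.where(
        incl_count.to_numpy() >= 2,
        excl_count.to_numpy() >= 2,
        excl_count.to_numpy() >= 1,
    )
    affected = has_inclusion.to_numpy() & ~excluded
    onset = incl_first.to_numpy()

    if definition.required_atc is not None:
        req = definition.required_atc
        ref_date = pd.Timestamp(req.applies_if_alive_after)
        death = pd.to_datetime(ind["death_date"]).to_numpy()
        alive_after = pd.isna(death) | (death > np.datetime64(ref_date))
        atc = ev[
            (ev["system"] == "ATC") & ev["code"].str.startswith(req.atc_prefix)
        ]
        atc_count = atc.groupby("person_id").size().reindex(idx, fill_value=0)
        atc_first = atc.groupby("person_id")["date"].min().reindex(idx)
        ok = ~alive_after | (atc_count.to_numpy() >= req.min_dispensations)
        affected = affected & ok
        qualifying = atc_count.to_numpy() >= req.min_dispensations
        onset = np.fmin(
            onset, np.where(qualifying, atc_first.to_numpy(), np.datetime64("NaT"))
        )

    out = pd.DataFrame(
        {
            "person_id": ind["person_id"].to_numpy(),
            "affected": affected,
            "onset_date": pd.to_datetime(onset),
        }
    )
    out.loc[~out["affected"], "onset_date"] = pd.NaT
    return out


def aggregate_any(phenotypes: dict[str, pd.DataFrame], name: str = "any_disease") -> pd.DataFrame:
    """Combine per-disease phenotypes into an 'any disease' aggregate:
    affected iff affected for at least one disease, onset = earliest onset
    among affected diseases."""
    frames = list(phenotypes.values())
    if not frames:
        raise ValueError("no phenotypes to aggregate")
    base = frames[0][["person_id"]].copy()
    affected = np.zeros(len(base), bool)
    onset = np.full(len(base), np.datetime64("NaT"), dtype="datetime64[ns]")
    for df in frames:
        if not (df["person_id"].to_numpy() == base["person_id"].to_numpy()).all():
            raise ValueError("phenotype frames must cover identical persons in order")
        affected |= df["affected"].to_numpy()
        onset = np.fmin(onset, df["onset_date"].to_numpy())
    out = base.copy()
    out["affected"] = affected
    out["onset_date"] = pd.to_datetime(onset)
    out.loc[~out["affected"], "onset_date"] = pd.NaT
    return out
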