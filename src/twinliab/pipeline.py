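"""End-to-end analysis pipeline: cohort in, published-style tables out.

Wires the stages together — exclusion cascade, ascertainment, descriptive
statistics, tetrachoric correlations, variance-component model selection,
IPW liability fits, and co-aggregation — and writes each result both as
CSV/JSON (full precision) and as aligned text (display rounding).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    Cohort,
    ExclusionRules,
    aggregate_any,
    apply_exclusions,
    ascertain,
    load_disease_definitions,
    read_cohort,
)
from .biometric import fit_biometric, select_model
from .coaggregation import aggregation_report
from .descriptive import build_pair_table, prevalence_by_sex, probandwise, sex_difference_test
from .ipw import CovariateSpec, build_windows, estimate_censoring, fit_liability_ipw
from .tetrachoric import fit_tetrachoric

logger = logging.getLogger("twinliab")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    individuals_path: str
    events_path: str
    output_dir: str
    disease_definitions_path: str | None = None
    diseases: list[str] | None = None
    seed: int = 0
    run_descriptive: bool = True
    run_tetrachoric: bool = True
    run_biometric: bool = True
    run_ipw: bool = False
    run_coaggregation: bool = False
    biometric_models: tuple[str, ...] = ("AE", "ACE", "ADE")
    registry_start_year: int = 1964
    registry_end_year: int = 2015
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_table(df: pd.DataFrame, outdir: Path, name: str) -> None:
    df.to_csv(outdir / f"{name}.csv", index=False)
    (outdir / f"{name}.txt").write_text(df.to_string(index=False) + "\n")
    (outdir / f"{name}.json").write_text(df.to_json(orient="records", indent=2))


def run_pipeline(config: RunConfig) -> int:
    """Run the configured stages; returns 0 on success, 1 on stage failure.

    Partial outputs are preserved; a failure marker file records the stage
    and error.  A run manifest (version, seed, config hash) is always
    written.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)

    manifest = {
        "twinliab_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    stage = "load"
    try:
        cohort = read_cohort(config.individuals_path, config.events_path)
        cohort, report = apply_exclusions(cohort, ExclusionRules())
        _write_table(report.as_frame(), outdir, "exclusion_cascade")
        logger.info("cohort: %d individuals after exclusions", cohort.n_individuals)

        definitions = load_disease_definitions(config.disease_definitions_path)
        diseases = config.diseases or list(definitions)
        phenotypes = {d: ascertain(cohort, definitions[d]) for d in diseases}
        phenotypes["any_disease"] = aggregate_any(phenotypes)
        all_outcomes = list(phenotypes)

        # cohort composition (counts by sex and zygosity x any-disease status)
        comp = cohort.individuals.merge(phenotypes["any_disease"], on="person_id")
        composition = (
            comp.assign(autoimmune=np.where(comp["affected"], "affected", "unaffected"))
            .groupby(["autoimmune"])
            .agg(
                n=("person_id", "size"),
                female=("sex", lambda s: int((s == "female").sum())),
                mz=("zygosity", lambda s: int((s == "MZ").sum())),
            )
            .reset_index()
        )
        _write_table(composition, outdir, "cohort_composition")

        if config.run_descriptive:
            stage = "descriptive"
            rows = []
            for d in all_outcomes:
                for est in prevalence_by_sex(cohort, phenotypes[d], d):
                    rows.append(
                        {
                            "disease": d,
                            "stratum": est.stratum,
                            "n_cases": est.n_cases,
                            "n_denominator": est.n_denominator,
                            "prevalence_per_100k": est.prevalence_per_100k,
                            "prevalence_display": est.display,
                        }
                    )
            prev = pd.DataFrame(rows)
            pvals = {
                d: sex_difference_test(cohort, phenotypes[d], d) for d in all_outcomes
            }
            prev["sex_difference_p"] = prev["disease"].map(pvals)
            _write_table(prev, outdir, "prevalence")

        pair_tables = {}
        for d in all_outcomes:
            for z in ("MZ", "DZ"):
                pair_tables[(d, z)] = build_pair_table(cohort, phenotypes[d], d, z)

        if config.run_descriptive or config.run_tetrachoric:
            stage = "concordance"
            rows = []
            for (d, z), pt in pair_tables.items():
                conc = probandwise(pt)
                row = {
                    "disease": d,
                    "zygosity": z,
                    "n_concordant_unaffected": pt.n_concordant_unaffected,
                    "n_discordant": pt.n_discordant,
                    "n_concordant_affected": pt.n_concordant_affected,
                    "probandwise": None if conc.display_na else round(conc.rate, 4),
                    "probandwise_ci_low": None if conc.display_na else round(conc.ci_low, 4),
                    "probandwise_ci_high": None if conc.display_na else round(conc.ci_high, 4),
                }
                if config.run_tetrachoric:
                    fit = fit_tetrachoric(pt)
                    row["tetrachoric"] = None if fit.undefined or fit.display_na else round(fit.rho, 4)
                    row["tetrachoric_ci_low"] = None if fit.undefined or fit.display_na else round(fit.ci_low, 4)
                    row["tetrachoric_ci_high"] = None if fit.undefined or fit.display_na else round(fit.ci_high, 4)
                rows.append(row)
            _write_table(pd.DataFrame(rows), outdir, "concordance")

        if config.run_biometric:
            stage = "biometric"
            rows = []
            for d in all_outcomes:
                mz, dz = pair_tables[(d, "MZ")], pair_tables[(d, "DZ")]
                if mz.n_concordant_affected + mz.n_discordant == 0:
                    continue
                fits = [fit_biometric(mz, dz, m, ci=(m == "AE")) for m in config.biometric_models]
                best = select_model(fits)
                rows.append(
                    {
                        "disease": d,
                        "model": best.model,
                        "a2": round(best.components.a2, 4),
                        "a2_ci_low": None if best.ci_low is None else round(best.ci_low, 4),
                        "a2_ci_high": None if best.ci_high is None else round(best.ci_high, 4),
                        "c2": round(best.components.c2, 4),
                        "d2": round(best.components.d2, 4),
                        "e2": round(best.components.e2, 4),
                        "broad_sense": None if best.broad_sense is None else round(best.broad_sense, 4),
                        "aic": round(best.aic, 2),
                    }
                )
            _write_table(pd.DataFrame(rows), outdir, "heritability")

        if config.run_ipw:
            stage = "ipw"
            rows = []
            for d in all_outcomes:
                windows = build_windows(
                    cohort, phenotypes[d], d,
                    registry_start_year=config.registry_start_year,
                    end_year=config.registry_end_year,
                )
                cens = estimate_censoring(windows)
                for adjusted in (False, True):
                    for weighted in (False, True):
                        spec = CovariateSpec(sex=adjusted, birth_year_bin_width=10 if adjusted else None)
                        try:
                            fit = fit_liability_ipw(
                                windows, censoring=cens if weighted else None,
                                model="AE", covariates=spec,
                            )
                            rows.append(
                                {
                                    "disease": d,
                                    "adjusted": adjusted,
                                    "censoring_weighted": weighted,
                                    "a2": round(fit.components.a2, 4),
                                    "e2": round(fit.components.e2, 4),
                                    "tau": round(fit.tau, 4),
                                }
                            )
                        except Exception as exc:  # degenerate stratum
                            logger.warning("ipw fit failed for %s: %s", d, exc)
            _write_table(pd.DataFrame(rows), outdir, "heritability_ipw_grid")

        if config.run_coaggregation:
            stage = "coaggregation"
            coagg = aggregation_report(
                cohort,
                {d: phenotypes[d] for d in diseases},
                registry_start_year=config.registry_start_year,
                end_year=config.registry_end_year,
            )
            _write_table(coagg, outdir, "coaggregation")

    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc!r}\n")
        logger.exception("pipeline failed at stage %s", stage)
        return 1
    return 0
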