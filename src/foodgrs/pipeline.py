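"""End-to-end pipeline: scores -> group comparison -> whole-GRS screen ->
per-SNP screen -> food-specific GRS -> validation -> stratified effects ->
shared-SNP analysis, with every artifact written to an output directory.

All tabular artifacts are plain CSV, set results are JSON, and a
timestamp-free structured log (``log.json``) records the sample size used
in every fitted model, so a rerun with the same configuration and seed
reproduces every output byte-identically.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import io as fio
from .config import RunConfig
from .errors import FoodGRSError, PipelineError
from .grs_engine import dichotomize, load_panel, score, subset_score
from .interaction_screen import (
    FoodSpecificGRS,
    build_food_grs,
    screen_snps,
    screen_whole_grs,
    shared_snp_analysis,
    stratified_effects,
    validate_food_grs,
)
from .items import FFQ_ITEMS
from .phenotypes import (
    bmi_zscore,
    compare_groups,
    comparisons_to_frame,
    load_lms_reference,
    plant_consumption_index,
    recode_ffq,
    sweet_treat_index,
)
from .synthetic_data import simulate_study

logger = logging.getLogger("foodgrs")


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise package errors as
    PipelineError carrying the stage name and a machine-readable code."""

    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                code = exc_type.__name__ if exc_type else "error"
                raise PipelineError(name, code, str(exc)) from exc
            logger.info("stage %s: done", name)
            return False

    return _Ctx()


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict[str, Any]:
    """Run the full analysis and write the result bundle to ``outdir``.

    Returns a summary dict (flagged foods, per-food selections, shared-SNP
    counts) mirroring what is written to disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_entries: list[dict[str, Any]] = []

    def log_n(stage: str, model: str, n: int) -> None:
        log_entries.append({"stage": stage, "model": model, "n": int(n)})
        logger.info("%s | %s | n=%d", stage, model, n)

    # ---- inputs -----------------------------------------------------------
    with _stage("inputs"):
        panel = load_panel(config.panel_path)
        if config.simulate_n is not None:
            study = simulate_study(n=config.simulate_n, seed=config.seed)
            genotypes, cohort = study.genotypes, study.cohort
            _write_truth(study.truth, outdir / "truth.json")
        else:
            genotypes = fio.read_genotypes(
                config.genotypes_path, panel, config.genotype_format
            )
            cohort = fio.read_cohort_csv(config.cohort_path)
            if config.ffq_path is not None:
                ratings = fio.read_cohort_csv(config.ffq_path)
                weekly = recode_ffq(ratings, config.recode_mapping)
                cohort = cohort.join(weekly, how="left")
            if "bmiz" not in cohort.columns:
                if config.lms_path is None or "bmi" not in cohort.columns:
                    raise PipelineError(
                        "inputs", "missing_outcome",
                        "cohort lacks bmiz; provide bmiz, or bmi + lms_path",
                    )
                ref = load_lms_reference(config.lms_path)
                cohort = cohort.copy()
                cohort["bmiz"] = bmi_zscore(
                    cohort["bmi"], cohort["age"], cohort["sex"], ref
                )

    # ---- dietary indices --------------------------------------------------
    with _stage("indices"):
        cohort = cohort.copy()
        cohort["sweet_treat_index"] = sweet_treat_index(cohort, config.sti_items)
        cohort["plant_consumption_index"] = plant_consumption_index(
            cohort, config.pci_items
        )

    # ---- risk scores ------------------------------------------------------
    with _stage("scores"):
        scores = {
            scheme: score(genotypes, panel, scheme)
            for scheme in config.schemes
        }
        unweighted = scores.get("unweighted") or score(
            genotypes, panel, "unweighted"
        )
        risk_group, cutoff = dichotomize(unweighted)
        score_table = pd.DataFrame(
            {f"grs_{k}": v.values for k, v in scores.items()}
        )
        score_table["n_nonmissing"] = unweighted.n_nonmissing
        score_table["risk_group"] = risk_group
        score_table.to_csv(outdir / "scores.csv")
        cohort["risk_group"] = risk_group.reindex(cohort.index)
        log_n("scores", "all_schemes", len(score_table))

    # ---- descriptive group comparison ------------------------------------
    with _stage("group_comparison"):
        continuous = ["age", "bmiz", "ltpa", "sleep"] + [
            f for f in FFQ_ITEMS if f in cohort.columns
        ] + ["sweet_treat_index", "plant_consumption_index"]
        categorical = ["sex"] + (
            ["eating_habit_group"] if "eating_habit_group" in cohort else []
        )
        comps = compare_groups(
            cohort, cohort["risk_group"],
            continuous=continuous, categorical=categorical,
        )
        comparisons_to_frame(comps).to_csv(
            outdir / "group_comparison.csv", index=False
        )

    # ---- level-1 screen ---------------------------------------------------
    with _stage("whole_grs_screen"):
        foods = [f for f in FFQ_ITEMS if f in cohort.columns] + [
            "sweet_treat_index", "plant_consumption_index",
        ]
        report = screen_whole_grs(
            cohort, scores, foods,
            covariates=config.screening_covariates,
            alpha=config.alpha_grs,
            borderline_band=config.borderline_band,
        )
        report.table.to_csv(outdir / "whole_grs_screen.csv", index=False)
        for _, row in report.table.iterrows():
            log_n("whole_grs_screen", f"{row['food']}|{row['scheme']}",
                  row["n_used"])
        logger.info("flagged foods: %s", report.flagged)

    # ---- level-2 screen + food-specific GRS -------------------------------
    snp_tables: list[pd.DataFrame] = []
    food_grs: list[FoodSpecificGRS] = []
    with _stage("snp_screen"):
        for food in report.flagged:
            sub = report.table[report.table["food"] == food]
            best = sub.loc[sub["p_continuous"].idxmin()]
            direction = 1 if best["b_continuous"] >= 0 else -1
            selection, table = screen_snps(
                cohort, genotypes, panel, food, direction,
                covariates=config.screening_covariates,
                alpha=config.alpha_snp,
            )
            snp_tables.append(table)
            for _, row in table.iterrows():
                log_n("snp_screen", f"{food}|{row['rsid']}", row["n_used"])
            if not selection:
                logger.info(
                    "no SNP selected for %s; food dropped from cascade", food
                )
                continue
            food_grs.append(build_food_grs(panel, selection, food, direction))
        if snp_tables:
            pd.concat(snp_tables, ignore_index=True).to_csv(
                outdir / "snp_screen.csv", index=False
            )
        _write_json(
            outdir / "food_grs.json",
            {
                f.food: {
                    "rsids": f.rsids,
                    "reference_direction": f.reference_direction,
                }
                for f in food_grs
            },
        )

    summary: dict[str, Any] = {
        "flagged_foods": report.flagged,
        "food_grs": {f.food: f.rsids for f in food_grs},
        "cutoff_risk_alleles": cutoff,
    }
    if not food_grs:
        logger.info(
            "screening selected no SNP for any food; pipeline ends after "
            "screening (nothing to validate)"
        )
        _write_json(outdir / "log.json", {"models": log_entries})
        config.to_yaml(outdir / "resolved_config.yaml")
        return summary

    # ---- validation -------------------------------------------------------
    with _stage("validation"):
        rows = []
        for fgrs in food_grs:
            fits = validate_food_grs(
                cohort, genotypes, panel, fgrs,
                models={1: config.validation_model1,
                        2: config.validation_model2},
            )
            for model_id, res in fits.items():
                log_n("validation", f"{fgrs.food}|model{model_id}", res.n_used)
                for term in ("score", fgrs.food, "interaction"):
                    r = res.term(term)
                    rows.append(
                        {
                            "food": fgrs.food,
                            "model": model_id,
                            "term": "food" if term == fgrs.food else term,
                            "b": r["b"], "se": r["se"], "beta": r["beta"],
                            "t": r["t"], "p": r["p"],
                            "ci_low": r["ci_low"], "ci_high": r["ci_high"],
                            "n_used": res.n_used,
                        }
                    )
        validation = pd.DataFrame(rows)
        validation.to_csv(outdir / "validation.csv", index=False)

    # ---- stratified effects ----------------------------------------------
    with _stage("stratified"):
        rows = []
        strat_results = {}
        for fgrs in food_grs:
            se = stratified_effects(
                cohort, genotypes, panel, fgrs,
                covariates=config.validation_model2,
            )
            strat_results[fgrs.food] = se
            for grp in ("low", "high"):
                d = se.per_group[grp]
                log_n("stratified", f"{fgrs.food}|{grp}", d["n"])
                rows.append({"food": fgrs.food, "group": grp, **d,
                             "interaction_b": se.interaction_b,
                             "interaction_p": se.interaction_p})
        strat_table = pd.DataFrame(rows)
        strat_table.to_csv(outdir / "stratified_effects.csv", index=False)
        if config.figures:
            from .plotting import forest_plot

            forest_plot(
                list(strat_results.values()), outdir / "stratified_forest.svg"
            )

    # ---- shared SNPs ------------------------------------------------------
    with _stage("shared_snps"):
        shared = shared_snp_analysis(food_grs)
        _write_json(
            outdir / "shared_snps.json",
            {
                "foods": shared.foods,
                "union": shared.union,
                "intersection": shared.intersection,
                "venn_counts": shared.venn_counts,
            },
        )

    _write_json(outdir / "log.json", {"models": log_entries})
    config.to_yaml(outdir / "resolved_config.yaml")

    summary.update(
        {
            "validated_table": validation,
            "stratified_table": strat_table,
            "shared_union_size": len(shared.union),
            "shared_intersection_size": len(shared.intersection),
        }
    )
    return summary


def _write_json(path: Path, obj: Any) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _write_truth(truth, path: Path) -> None:
    _write_json(
        path,
        {
            "snp_main_effects": dict(truth.snp_main_effects),
            "food_main_effects": dict(truth.food_main_effects),
            "interaction_effects": [
                {"rsid": r, "food": f, "effect": v}
                for (r, f), v in truth.interaction_effects.items()
            ],
            "covariate_effects": dict(truth.covariate_effects),
            "noise_sd": truth.noise_sd,
            "seed": truth.seed,
        },
    )
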