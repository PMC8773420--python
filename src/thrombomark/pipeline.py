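"""End-to-end orchestration: match -> DE -> select -> clogit -> subtype -> annotate.

All randomness flows from the single config seed; rerunning with the same
config reproduces byte-identical report tables (the JSON manifest records
inputs, thresholds, seed, package versions and per-stage record counts, and
deliberately carries no timestamps).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clogit import per_gene_clogit
from .containers import ClinicalCohort, ExpressionMatrix, ValidationError
from .dge import ebayes_moderate, student_t_dge
from .io import (
    read_cohort_csv,
    read_expression_tsv,
    signatures_from_gmt,
    write_report,
)
from .matching import balance_report, fit_propensity, match_nearest_neighbor
from .pathways import (
    annotate_hemostasis,
    load_shipped_pathway_map,
    PathwayMap,
    subtype_dge,
)
from .selection import select_stratified_concordant
from .subtyping import (
    DEFAULT_MARGIN,
    DEFAULT_MIN_SCORE,
    DEFAULT_YOUNG_AGE_CUTOFF,
    SubtypeSignature,
    classify_tcga,
)
from .synthetic import default_cohort_spec, default_expression_spec, simulate_cohort, simulate_expression

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds, file paths and stage toggles for a pipeline run."""

    seed: int = 0
    output_dir: str = "thrombomark_out"
    # Inputs; None means "synthesize with the default study-scale generator".
    cohort_csv: str | None = None
    expression_tsv: str | None = None
    signatures_gmt: str | None = None
    pathway_map_tsv: str | None = None
    # Synthesis scale (used only when inputs are synthesized).
    n_patients: int = 2129
    n_genes: int = 2000
    # Matching.
    caliper: float = 0.2
    covariates: list[str] | None = None  # None -> all cohort covariates + age
    # Main screen.
    p_max: float = 0.05
    q_max: float = 0.10
    fc_min: float = 1.0
    use_ebayes: bool = False
    welch: bool = False
    # Subtyping / exploratory screen.
    run_subtyping: bool = True
    min_score: float = DEFAULT_MIN_SCORE
    margin: float = DEFAULT_MARGIN
    young_age_cutoff: int = DEFAULT_YOUNG_AGE_CUTOFF
    subtype_p_max: float = 0.05
    subtype_fc_min: float = 1.5

    def validate(self) -> None:
        for name in ("p_max", "q_max", "subtype_p_max", "min_score", "margin"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} out of [0, 1]: {v}")
        if self.caliper <= 0:
            raise ValidationError("caliper must be positive")
        if self.fc_min < 0 or self.subtype_fc_min < 0:
            raise ValidationError("fold-change thresholds must be non-negative")
        if self.seed < 0 or self.seed >= 2**31 - 2:
            raise ValidationError("seed must be in [0, 2**31 - 2)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _load_inputs(config: PipelineConfig):
    if config.cohort_csv:
        cohort = read_cohort_csv(config.cohort_csv)
    else:
        cohort = simulate_cohort(default_cohort_spec(seed=config.seed, n_patients=config.n_patients))
    if config.expression_tsv:
        matrix = read_expression_tsv(config.expression_tsv)
    else:
        spec = default_expression_spec(seed=config.seed + 1, n_genes=config.n_genes)
        matrix = simulate_expression(cohort, spec)
    if config.signatures_gmt:
        signatures = signatures_from_gmt(config.signatures_gmt)
    else:
        spec = default_expression_spec(seed=config.seed + 1, n_genes=config.n_genes)
        signatures = {
            s: SubtypeSignature(s, up, down)
            for s, (up, down) in spec.subtype_signatures.items()
        }
    if config.pathway_map_tsv:
        pathway_map = PathwayMap.from_tsv(config.pathway_map_tsv)
    else:
        pathway_map = load_shipped_pathway_map()
    return cohort, matrix, signatures, pathway_map


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order; returns the run manifest (also written)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in dataclasses.asdict(config).items()},
        "stages": {},
    }

    cohort, matrix, signatures, pathway_map = _load_inputs(config)
    manifest["stages"]["inputs"] = {
        "status": "ok",
        "n_patients": len(cohort),
        "n_genes": int(matrix.shape[0]),
        "n_samples": int(matrix.shape[1]),
    }

    # --- matching -----------------------------------------------------------
    eligible = cohort.exclude_thromboprophylaxis()
    covariates = config.covariates or (list(eligible.covariates) + ["age"])
    model = fit_propensity(eligible, covariates)
    match = match_nearest_neighbor(model, ratio=1, caliper=config.caliper)
    balance = balance_report(eligible, match)
    write_report(balance, out / "balance_table.tsv", "matching", {"caliper": config.caliper})
    pd.DataFrame(match.pairs, columns=["case_id", "control_id"]).to_csv(
        out / "matched_pairs.tsv", sep="\t", index=False
    )
    manifest["stages"]["matching"] = {
        "status": "ok",
        "n_excluded_prophylaxis": len(cohort) - len(eligible),
        "n_pairs": len(match.pairs),
        "n_unmatched_cases": len(match.unmatched_cases),
        "mean_abs_dstar_before": float(balance["d_star_before"].abs().mean()),
        "mean_abs_dstar_after": float(balance["d_star_after"].abs().mean()),
    }

    nested = eligible.subset(match.matched_ids())
    nested_matrix = matrix.subset_samples(nested.table["patient_id"])
    labels = nested.table.set_index("patient_id")["vte"].astype(bool)

    # --- per-Lauren-stratum DE and concordance selection ---------------------
    de_by_stratum: dict[str, pd.DataFrame] = {}
    for stratum in ("diffuse", "intestinal"):
        ids = nested.table.loc[nested.table["lauren"] == stratum, "patient_id"]
        de = student_t_dge(
            nested_matrix, labels, stratum_samples=list(ids),
            stratum_label=stratum, welch=config.welch,
        )
        if config.use_ebayes:
            de = ebayes_moderate(de)
        de_by_stratum[stratum] = de
        report = de[["gene_symbol", "fold_change", "p_value", "q_value"]].rename(
            columns={"q_value": "adj_p_value"}
        )
        write_report(
            report, out / f"dge_{stratum}.tsv", "dge",
            {"p_max": config.p_max, "q_max": config.q_max, "fc_min": config.fc_min},
        )

    selected = select_stratified_concordant(
        de_by_stratum["diffuse"], de_by_stratum["intestinal"],
        p_max=config.p_max, q_max=config.q_max, fc_min=config.fc_min,
    )
    write_report(
        selected.table, out / "concordant_genes.tsv", "selection",
        {"p_max": config.p_max, "q_max": config.q_max, "fc_min": config.fc_min},
    )
    manifest["stages"]["dge_selection"] = {
        "status": "ok",
        "n_selected": selected.n_total,
        "n_under": selected.n_under,
        "n_over": selected.n_over,
    }

    # --- conditional logistic regression -------------------------------------
    if selected.n_total:
        fits = per_gene_clogit(nested_matrix, selected, nested, strata="lauren")
        write_report(
            fits[["gene_symbol", "p_value", "odds_ratio", "ci_low", "ci_high"]],
            out / "clogit.tsv", "clogit", {"strata": "lauren"},
        )
        n_sig = int(((fits["ci_low"] > 1) | (fits["ci_high"] < 1)).sum())
    else:
        fits = pd.DataFrame()
        n_sig = 0
    manifest["stages"]["clogit"] = {
        "status": "ok",
        "n_fits": len(fits),
        "n_ci_excluding_1": n_sig,
    }

    # --- molecular subtyping and per-subtype exploratory screen --------------
    if config.run_subtyping:
        assignments = classify_tcga(
            nested_matrix, signatures, nested,
            min_score=config.min_score, margin=config.margin,
            young_age_cutoff=config.young_age_cutoff,
        )
        assignments.to_csv(out / "subtype_assignments.csv", index=False)
        counts = assignments["subtype"].value_counts().to_dict()
        sub_de = subtype_dge(
            nested_matrix, assignments, nested,
            p_max=config.subtype_p_max, fc_min=config.subtype_fc_min,
        )
        annotated_counts = {}
        for subtype, table in sub_de.tables.items():
            annotated = annotate_hemostasis(table, pathway_map)
            write_report(
                annotated, out / f"hemostasis_{subtype}.tsv", "annotate",
                {"p_max": config.subtype_p_max, "fc_min": config.subtype_fc_min},
            )
            annotated_counts[subtype] = {
                "n_de": len(table),
                "n_hemostasis": int(annotated["gene_symbol"].nunique()) if len(annotated) else 0,
            }
        manifest["stages"]["subtyping"] = {
            "status": "ok",
            "counts": {k: int(v) for k, v in sorted(counts.items())},
            "n_imputed": int((assignments["method"] == "clinical_imputation").sum()),
            "subtype_de": annotated_counts,
            "skipped": sub_de.skipped,
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
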