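"""Marker-based molecular subtype classification (EBV / MSI / GS / CIN).

A sample is called a subtype when the genes of that subtype's marker
signature are *relative* outliers in the cohort: up-markers above the Tukey
fence Q3 + 1.5*IQR, down-markers below Q1 - 1.5*IQR, with quartiles taken
per gene across samples (linear interpolation, quantile type 7). The
concordance score of a signature is the fraction of its present marker genes
whose outlier status matches the expected direction. Samples whose top score
is too low or too close to the runner-up are imputed from clinical features
(HER2-positive -> CIN; young diffuse-histology -> GS; further rules
configurable), mirroring practice when no expression controls are available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .containers import TCGA_SUBTYPES, ClinicalCohort, ExpressionMatrix, ValidationError

__all__ = [
    "SubtypeSignature",
    "iqr_outlier_flags",
    "signature_score",
    "classify_tcga",
    "DEFAULT_MIN_SCORE",
    "DEFAULT_MARGIN",
    "DEFAULT_YOUNG_AGE_CUTOFF",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_SCORE = 0.25
DEFAULT_MARGIN = 0.05
DEFAULT_YOUNG_AGE_CUTOFF = 50


@dataclass
class SubtypeSignature:
    """Marker gene lists for one molecular subtype."""

    subtype: str
    up_genes: list[str]
    down_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = set(self.up_genes) & set(self.down_genes)
        if overlap:
            raise ValidationError(
                f"{self.subtype}: genes in both up and down lists: {sorted(overlap)}"
            )
        if not self.up_genes and not self.down_genes:
            raise ValidationError(f"{self.subtype}: empty signature")


def _fences(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    q1 = np.quantile(values, 0.25, axis=1, method="linear")
    q3 = np.quantile(values, 0.75, axis=1, method="linear")
    iqr = q3 - q1
    return q1 - 1.5 * iqr, q3 + 1.5 * iqr


def iqr_outlier_flags(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-(gene, sample) outlier flag: "high", "low" or "none".

    Strict inequalities: a constant gene has zero IQR and collapsed fences,
    so nothing is flagged.
    """
    if matrix.shape[1] < 5:
        raise ValidationError("need >= 5 samples for meaningful quartiles")
    v = matrix.values.to_numpy()
    low_fence, high_fence = _fences(v)
    flags = np.where(
        v > high_fence[:, None], "high", np.where(v < low_fence[:, None], "low", "none")
    )
    return pd.DataFrame(flags, index=matrix.genes, columns=matrix.samples)


def signature_score(flags: pd.DataFrame, signature: SubtypeSignature, sample) -> float:
    """Fraction of present signature genes whose flag matches the direction.

    Returns NaN when none of the signature's genes are present (the sample
    must then be imputed clinically).
    """
    up = [g for g in signature.up_genes if g in flags.index]
    down = [g for g in signature.down_genes if g in flags.index]
    dropped = len(signature.up_genes) + len(signature.down_genes) - len(up) - len(down)
    if dropped:
        logger.info("%s signature: %d genes absent from matrix", signature.subtype, dropped)
    n = len(up) + len(down)
    if n == 0:
        return float("nan")
    hits = int((flags.loc[up, sample] == "high").sum()) if up else 0
    hits += int((flags.loc[down, sample] == "low").sum()) if down else 0
    return hits / n


ImputationRule = tuple[Callable[[pd.Series], bool], str]


def _default_imputation_rules(young_age_cutoff: int) -> list[ImputationRule]:
    return [
        (lambda r: bool(r.get("her2_positive", 0)), "CIN"),
        (
            lambda r: r["lauren"] == "diffuse" and r["age"] < young_age_cutoff,
            "GS",
        ),
    ]


def classify_tcga(
    matrix: ExpressionMatrix,
    signatures: dict[str, SubtypeSignature],
    cohort: ClinicalCohort,
    min_score: float = DEFAULT_MIN_SCORE,
    margin: float = DEFAULT_MARGIN,
    young_age_cutoff: int = DEFAULT_YOUNG_AGE_CUTOFF,
    extra_rules: list[ImputationRule] | None = None,
) -> pd.DataFrame:
    """Assign exactly one subtype per sample.

    The expression rule assigns the argmax-score subtype when the top score
    is >= ``min_score`` and beats the runner-up by >= ``margin`` (ties go to
    imputation, never to an arbitrary subtype order). Otherwise clinical
    imputation rules are applied in order; a sample failing every rule falls
    back to histology (diffuse -> GS, intestinal -> CIN) and is flagged
    low-confidence.

    Returns a frame: sample_id, subtype, method (expression_rule /
    clinical_imputation), score, low_confidence.
    """
    missing = set(TCGA_SUBTYPES) - set(signatures)
    if missing:
        raise ValidationError(f"signatures missing for subtypes: {sorted(missing)}")
    flags = iqr_outlier_flags(matrix)
    t = cohort.table.set_index("patient_id")
    samples = [s for s in matrix.samples if s in t.index]
    if len(samples) != matrix.shape[1]:
        raise ValidationError("matrix contains samples absent from the cohort")

    score_mat = pd.DataFrame(
        {
            sub: [signature_score(flags, signatures[sub], s) for s in samples]
            for sub in TCGA_SUBTYPES
        },
        index=samples,
    )

    rules = _default_imputation_rules(young_age_cutoff) + list(extra_rules or [])
    rows = []
    n_imputed = 0
    for s in samples:
        scores = score_mat.loc[s]
        if scores.isna().all():
            top, runner, best = float("nan"), float("nan"), None
        else:
            ranked = scores.sort_values(ascending=False)
            top, runner = float(ranked.iloc[0]), float(ranked.iloc[1])
            best = str(ranked.index[0])
        decisive = (
            best is not None
            and np.isfinite(top)
            and top >= min_score
            and (top - runner) >= margin
        )
        if decisive:
            rows.append((s, best, "expression_rule", top, False))
            continue
        n_imputed += 1
        clinical = t.loc[s]
        for rule, subtype in rules:
            if rule(clinical):
                rows.append((s, subtype, "clinical_imputation", top, False))
                break
        else:
            fallback = "GS" if clinical["lauren"] == "diffuse" else "CIN"
            rows.append((s, fallback, "clinical_imputation", top, True))
    if n_imputed:
        logger.info("%d samples required clinical imputation", n_imputed)
    return pd.DataFrame(
        rows, columns=["sample_id", "subtype", "method", "score", "low_confidence"]
    )
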