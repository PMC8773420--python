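"""Synthetic cohorts and expression matrices with the structure the analysis assumes.

The generator emulates a national advanced-gastric-cancer registry cohort
(~2129 patients, ~10% venous thromboembolism) with the published baseline
covariate prevalences, and a normalized log2 microarray-style expression
matrix with (a) thrombosis-associated genes planted at the fold-change
magnitudes reported for this disease (|FC| 1.1-1.4), (b) Lauren-subtype
structure, and (c) per-molecular-subtype marker-gene blocks expressed at
outlier levels. VTE status is assigned by a logistic model on the covariates
so that propensity-score matching is consequential and testable.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .containers import (
    TCGA_SUBTYPES,
    ClinicalCohort,
    ExpressionMatrix,
    ValidationError,
)

__all__ = [
    "CohortSpec",
    "ExpressionSpec",
    "simulate_cohort",
    "simulate_expression",
    "default_cohort_spec",
    "default_expression_spec",
]

# Pooled covariate prevalences of the source registry's baseline table
# (case and control counts combined over 2129 patients).
DEFAULT_COVARIATE_FREQS: dict[str, float] = {
    "sex_male": 0.709,
    "her2_positive": 0.180,
    "ecog_0": 0.220,
    "metastatic_sites_gt2": 0.281,
    "poorly_differentiated": 0.409,
    "anthracycline": 0.211,
    "cisplatin": 0.205,
    "docetaxel": 0.115,
    "oxaliplatin": 0.387,
    "trastuzumab": 0.155,
    "signet_ring_cells": 0.299,
    "charlson_ge2": 0.155,
    "prior_vascular_disease": 0.08,
}

# Per-covariate log-odds effects on VTE. Signs mirror the direction of the
# pre-matching imbalances in the published baseline table (cases carried more
# cisplatin, trastuzumab, HER2+, >2 metastatic sites and signet-ring tumors,
# and slightly fewer males and oxaliplatin/docetaxel regimens).
DEFAULT_CONFOUNDING: dict[str, float] = {
    "her2_positive": 0.30,
    "metastatic_sites_gt2": 0.40,
    "cisplatin": 0.45,
    "trastuzumab": 0.35,
    "signet_ring_cells": 0.35,
    "sex_male": -0.10,
    "oxaliplatin": -0.30,
    "docetaxel": -0.15,
}

# P(intestinal Lauren histology); the analyzed sample split 51/97 intestinal.
DEFAULT_INTESTINAL_FRACTION = 51 / 97

# Molecular-subtype mix conditioned on histology: genomically-stable tumors
# are enriched among diffuse histology, chromosomally-instable among
# intestinal; marginals approximate the analyzed sample (20/15/25/37 of 97).
SUBTYPE_PROBS = {
    "diffuse": {"EBV": 0.20, "MSI": 0.15, "GS": 0.45, "CIN": 0.20},
    "intestinal": {"EBV": 0.21, "MSI": 0.16, "GS": 0.10, "CIN": 0.53},
}

DEFAULT_PROPHYLAXIS_RATE = 0.06


@dataclass
class CohortSpec:
    """Parameters of the simulated registry cohort."""

    n_patients: int = 2129
    vte_rate: float = 211 / 2129
    covariate_freqs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_FREQS)
    )
    age_range: tuple[int, int] = (20, 89)
    lauren_mix: float = DEFAULT_INTESTINAL_FRACTION
    confounding_strength: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONFOUNDING)
    )
    prophylaxis_rate: float = DEFAULT_PROPHYLAXIS_RATE
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 4:
            raise ValidationError("n_patients must be >= 4")
        probs = [self.vte_rate, self.lauren_mix, self.prophylaxis_rate]
        probs += list(self.covariate_freqs.values())
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"probability out of [0, 1]: {p}")
        if self.age_range[0] > self.age_range[1]:
            raise ValidationError("age_range must be (low, high) with low <= high")
        unknown = set(self.confounding_strength) - set(self.covariate_freqs)
        if unknown:
            raise ValidationError(f"confounding on unknown covariates: {sorted(unknown)}")


def _solve_intercept(eta0: np.ndarray, target_rate: float) -> float:
    """Intercept alpha with mean(expit(alpha + eta0)) == target_rate."""
    if target_rate <= 0.0 or target_rate >= 1.0:
        raise ValidationError("vte_rate must be strictly inside (0, 1)")

    def f(alpha: float) -> float:
        return float(np.mean(expit(alpha + eta0))) - target_rate

    return brentq(f, -40.0, 40.0)


def simulate_cohort(spec: CohortSpec) -> ClinicalCohort:
    """Draw a cohort; VTE follows a logistic model on the binary covariates.

    The logistic intercept is solved numerically so the expected VTE
    prevalence equals ``spec.vte_rate`` for the covariates actually drawn.
    Patients on thromboprophylaxis are flagged (the matching stage excludes
    them). A latent molecular subtype per patient is recorded in
    ``true_subtype``; the expression generator uses it to plant marker blocks.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    table = pd.DataFrame({"patient_id": [f"P{i:05d}" for i in range(n)]})
    table["age"] = rng.integers(spec.age_range[0], spec.age_range[1] + 1, size=n)
    for name, freq in spec.covariate_freqs.items():
        table[name] = (rng.random(n) < freq).astype(int)
    table["lauren"] = np.where(
        rng.random(n) < spec.lauren_mix, "intestinal", "diffuse"
    )
    table["thromboprophylaxis"] = rng.random(n) < spec.prophylaxis_rate

    eta0 = np.zeros(n)
    for name, gamma in spec.confounding_strength.items():
        eta0 += gamma * table[name].to_numpy()
    alpha = _solve_intercept(eta0, spec.vte_rate)
    table["vte"] = rng.random(n) < expit(alpha + eta0)

    subtype = np.empty(n, dtype=object)
    for lauren, probs in SUBTYPE_PROBS.items():
        idx = np.flatnonzero(table["lauren"].to_numpy() == lauren)
        subtype[idx] = rng.choice(
            list(probs), size=len(idx), p=list(probs.values())
        )
    table["true_subtype"] = subtype

    covs = tuple(spec.covariate_freqs)
    return ClinicalCohort(table, covariates=covs)


@dataclass
class ExpressionSpec:
    """Parameters of the simulated log2 expression matrix.

    ``planted_genes`` holds ``(gene, signed_fold_change, stratum)`` triples
    with stratum in {"intestinal", "diffuse", "both"}; the signed fold-change
    convention reports a ratio r >= 1 as +r and 1/r as -r, so |FC| >= 1.
    ``subtype_signatures`` maps each molecular subtype to (up, down) marker
    lists; samples of that subtype express up-genes ``signature_shift`` log2
    units above baseline and down-genes the same amount below.
    """

    n_genes: int = 2000
    baseline_mean: float = 7.0
    baseline_sd: float = 0.5
    planted_genes: list[tuple[str, float, str]] = field(default_factory=list)
    subtype_signatures: dict[str, tuple[list[str], list[str]]] = field(
        default_factory=dict
    )
    signature_shift: float = 1.5
    genes: list[str] | None = None
    ambiguous_samples: list[str] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be positive")
        if self.baseline_sd <= 0:
            raise ValidationError("baseline_sd must be positive")
        for gene, fc, stratum in self.planted_genes:
            if abs(fc) < 1.0:
                raise ValidationError(
                    f"planted fold change for {gene} violates |FC| >= 1: {fc}"
                )
            if stratum not in ("intestinal", "diffuse", "both"):
                raise ValidationError(f"unknown stratum for {gene}: {stratum}")
        for subtype, (up, down) in self.subtype_signatures.items():
            if set(up) & set(down):
                raise ValidationError(
                    f"{subtype} signature has genes in both up and down lists"
                )

    def gene_universe(self) -> list[str]:
        """Explicit gene list, or one built from planted/signature genes plus filler."""
        if self.genes is not None:
            universe = list(self.genes)
        else:
            universe = []
            seen = set()
            for gene, _, _ in self.planted_genes:
                if gene not in seen:
                    universe.append(gene)
                    seen.add(gene)
            for up, down in self.subtype_signatures.values():
                for gene in list(up) + list(down):
                    if gene not in seen:
                        universe.append(gene)
                        seen.add(gene)
            filler = self.n_genes - len(universe)
            i = 0
            while filler > 0:
                name = f"G{i:05d}"
                i += 1
                if name in seen:
                    continue
                universe.append(name)
                seen.add(name)
                filler -= 1
        planted = {g for g, _, _ in self.planted_genes}
        missing = planted - set(universe)
        if missing:
            raise ValidationError(f"planted genes not in universe: {sorted(missing)}")
        return universe


def simulate_expression(cohort: ClinicalCohort, spec: ExpressionSpec) -> ExpressionMatrix:
    """Baseline i.i.d. Normal log2 intensities plus planted shifts.

    Planted thrombosis genes differ between VTE and non-VTE samples by
    ``log2 |FC|`` (signed) within the affected Lauren stratum; each sample's
    latent-subtype marker genes are shifted by ``signature_shift`` in the
    signed direction. Everything else is Normal(baseline_mean, baseline_sd).
    """
    if len(cohort) == 0:
        raise ValidationError("cohort is empty")
    spec.validate()
    universe = spec.gene_universe()
    rng = np.random.default_rng(spec.seed)

    samples = cohort.table["patient_id"].to_numpy()
    vte = cohort.table["vte"].to_numpy(dtype=bool)
    lauren = cohort.table["lauren"].to_numpy()

    values = rng.normal(spec.baseline_mean, spec.baseline_sd, (len(universe), len(samples)))
    gene_idx = {g: i for i, g in enumerate(universe)}

    for gene, fc, stratum in spec.planted_genes:
        delta = np.sign(fc) * np.log2(abs(fc))
        in_stratum = np.ones(len(samples), bool) if stratum == "both" else lauren == stratum
        values[gene_idx[gene], vte & in_stratum] += delta

    if spec.subtype_signatures:
        if "true_subtype" not in cohort.table.columns:
            raise ValidationError(
                "subtype signatures requested but cohort lacks true_subtype"
            )
        true_subtype = cohort.table["true_subtype"].to_numpy()
        ambiguous = np.isin(samples, spec.ambiguous_samples)
        for subtype, (up, down) in spec.subtype_signatures.items():
            cols = (true_subtype == subtype) & ~ambiguous
            for gene in up:
                if gene in gene_idx:
                    values[gene_idx[gene], cols] += spec.signature_shift
            for gene in down:
                if gene in gene_idx:
                    values[gene_idx[gene], cols] -= spec.signature_shift

    return ExpressionMatrix(pd.DataFrame(values, index=universe, columns=samples))


def _load_reported_de(stratum: str) -> pd.DataFrame:
    fname = f"reported_de_{stratum}.tsv"
    ref = importlib.resources.files("thrombomark.data").joinpath(fname)
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def default_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """Study-scale cohort spec (n=2129, ~9.9% VTE, published prevalences)."""
    return CohortSpec(seed=seed, **overrides)


def default_expression_spec(seed: int = 0, n_genes: int = 2000) -> ExpressionSpec:
    """Expression spec planting the 15 reported thrombosis genes.

    Each reported gene is planted at its published per-stratum signed fold
    change (one entry per Lauren stratum), and each molecular subtype gets a
    synthetic 40-up / 40-down marker signature expressed 3 baseline-SDs
    beyond baseline, mimicking fence-clearing marker blocks.
    """
    planted: list[tuple[str, float, str]] = []
    for stratum in ("diffuse", "intestinal"):
        reported = _load_reported_de(stratum)
        planted += [
            (row.gene_symbol, float(row.fold_change), stratum)
            for row in reported.itertuples()
        ]
    signatures = {
        s: (
            [f"{s}_UP_{i:02d}" for i in range(40)],
            [f"{s}_DN_{i:02d}" for i in range(40)],
        )
        for s in TCGA_SUBTYPES
    }
    baseline_sd = 0.5
    return ExpressionSpec(
        n_genes=n_genes,
        baseline_sd=baseline_sd,
        planted_genes=planted,
        subtype_signatures=signatures,
        signature_shift=3 * baseline_sd,
        seed=seed,
    )
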