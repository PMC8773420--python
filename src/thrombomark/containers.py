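"""Core in-memory containers shared across the pipeline.

The pipeline operates on two primary objects: a clinical covariate table
(one row per patient, with the thrombosis outcome and Lauren histology) and
a normalized log2 expression matrix (genes x samples). Both are thin,
validated wrappers around :class:`pandas.DataFrame`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ClinicalCohort", "ExpressionMatrix", "ValidationError"]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


#: Columns every cohort table must carry besides the binary covariates.
REQUIRED_COHORT_COLUMNS = ("patient_id", "age", "vte", "lauren", "thromboprophylaxis")

LAUREN_SUBTYPES = ("intestinal", "diffuse")
TCGA_SUBTYPES = ("EBV", "MSI", "GS", "CIN")


@dataclass
class ClinicalCohort:
    """Per-patient covariates, VTE status and Lauren histology.

    ``table`` holds one row per patient. ``vte`` and ``thromboprophylaxis``
    are boolean, ``lauren`` is ``"intestinal"`` or ``"diffuse"``, and any
    additional integer/float columns are treated as covariates.
    """

    table: pd.DataFrame
    covariates: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"cohort table missing columns: {missing}")
        if self.table["patient_id"].duplicated().any():
            dupes = self.table.loc[self.table["patient_id"].duplicated(), "patient_id"]
            raise ValidationError(f"duplicate patient ids: {sorted(set(dupes))}")
        bad = set(self.table["lauren"]) - set(LAUREN_SUBTYPES)
        if bad:
            raise ValidationError(f"unknown Lauren subtype labels: {sorted(bad)}")
        if not self.covariates:
            extra = [
                c
                for c in self.table.columns
                if c not in REQUIRED_COHORT_COLUMNS + ("true_subtype",)
            ]
            self.covariates = tuple(extra)
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_cases(self) -> int:
        return int(self.table["vte"].sum())

    @property
    def n_controls(self) -> int:
        return int((~self.table["vte"].astype(bool)).sum())

    def exclude_thromboprophylaxis(self) -> "ClinicalCohort":
        """Drop patients on primary thromboprophylaxis (study exclusion rule)."""
        keep = ~self.table["thromboprophylaxis"].astype(bool)
        return ClinicalCohort(self.table.loc[keep].reset_index(drop=True), self.covariates)

    def subset(self, patient_ids) -> "ClinicalCohort":
        idx = self.table["patient_id"].isin(set(patient_ids))
        return ClinicalCohort(self.table.loc[idx].reset_index(drop=True), self.covariates)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ClinicalCohort":
        return cls(pd.read_csv(path))


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of normalized log2 intensities.

    ``values`` is indexed by gene symbol (rows) and sample/patient id
    (columns). Symbols and sample ids must be unique.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = sorted(set(self.values.index[self.values.index.duplicated()]))
            raise ValidationError(f"duplicate gene symbols: {dupes}")
        if self.values.columns.duplicated().any():
            dupes = sorted(set(self.values.columns[self.values.columns.duplicated()]))
            raise ValidationError(f"duplicate sample ids: {dupes}")
        if not np.issubdtype(np.asarray(self.values).dtype, np.number):
            raise ValidationError("expression matrix contains non-numeric values")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        present = [s for s in sample_ids if s in self.values.columns]
        return ExpressionMatrix(self.values.loc[:, present])

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "gene_symbol"
        out.to_csv(path, sep="\t")
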