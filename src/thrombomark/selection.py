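"""Cross-stratum concordance selection.

A gene is retained only if it passes the per-stratum screen (raw p < 0.05,
|fold change| > 1, BH q < 0.10 by default, all strict) in BOTH Lauren
strata AND changes in the same direction in both. Retained genes are
labelled ``under`` (negative fold change, lower expression in VTE) or
``over``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ValidationError

__all__ = ["ConcordantGeneSet", "passes_screen", "select_stratified_concordant"]


@dataclass
class ConcordantGeneSet:
    """Genes concordantly differentially expressed in both strata."""

    table: pd.DataFrame  # gene_symbol, fc_<stratumA>, fc_<stratumB>, direction

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene_symbol"])

    @property
    def n_total(self) -> int:
        return len(self.table)

    @property
    def n_under(self) -> int:
        return int((self.table["direction"] == "under").sum())

    @property
    def n_over(self) -> int:
        return int((self.table["direction"] == "over").sum())


def passes_screen(
    de: pd.DataFrame,
    p_max: float = 0.05,
    q_max: float = 0.10,
    fc_min: float = 1.0,
) -> pd.DataFrame:
    """Rows passing the per-stratum thresholds (all strict inequalities)."""
    required = {"gene_symbol", "fold_change", "p_value", "q_value"}
    missing = required - set(de.columns)
    if missing:
        raise ValidationError(f"DE table missing columns: {sorted(missing)}")
    mask = (
        (de["p_value"] < p_max)
        & (de["q_value"] < q_max)
        & (de["fold_change"].abs() > fc_min)
    )
    return de.loc[mask]


def select_stratified_concordant(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    p_max: float = 0.05,
    q_max: float = 0.10,
    fc_min: float = 1.0,
) -> ConcordantGeneSet:
    """Intersect the two per-stratum passing sets, keeping concordant signs.

    Genes absent from one stratum's table (e.g. excluded there as degenerate)
    are treated as non-passing in that stratum. The result is invariant to
    the order of the two strata and to gene ordering.
    """
    pass_a = passes_screen(de_a, p_max, q_max, fc_min)
    pass_b = passes_screen(de_b, p_max, q_max, fc_min)

    label_a = str(pass_a["stratum"].iloc[0]) if len(pass_a) and "stratum" in pass_a else "a"
    label_b = str(pass_b["stratum"].iloc[0]) if len(pass_b) and "stratum" in pass_b else "b"
    if label_a == label_b:
        label_a, label_b = f"{label_a}_1", f"{label_b}_2"

    merged = pass_a[["gene_symbol", "fold_change"]].merge(
        pass_b[["gene_symbol", "fold_change"]],
        on="gene_symbol",
        suffixes=("_a", "_b"),
    )
    concordant = merged[
        np.sign(merged["fold_change_a"]) == np.sign(merged["fold_change_b"])
    ].copy()
    concordant["direction"] = np.where(
        concordant["fold_change_a"] < 0, "under", "over"
    )
    # Canonical stratum order so the result does not depend on argument order.
    if label_a <= label_b:
        cols = {"fold_change_a": f"fc_{label_a}", "fold_change_b": f"fc_{label_b}"}
    else:
        cols = {"fold_change_b": f"fc_{label_b}", "fold_change_a": f"fc_{label_a}"}
    concordant = concordant.rename(columns=cols)
    ordered = ["gene_symbol", *sorted(c for c in concordant.columns if c.startswith("fc_")), "direction"]
    concordant = concordant[ordered].sort_values("gene_symbol").reset_index(drop=True)
    return ConcordantGeneSet(concordant)
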