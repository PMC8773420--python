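"""Per-molecular-subtype exploratory DE screen and hemostasis-pathway annotation.

Within each molecular subtype, VTE cases are compared with controls using the
same Student t machinery as the main screen, but at the looser exploratory
thresholds (raw p < 0.05, no multiplicity adjustment, |fold change| > 1.5).
Hits are annotated against a static local gene -> Reactome-hemostasis-pathway
table; the shipped fixture holds the published mapping for this disease and a
larger user-supplied table can be substituted (a live pathway web service is
deliberately not queried, for reproducibility).
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass

import pandas as pd

from .containers import ClinicalCohort, ExpressionMatrix, ValidationError
from .dge import signed_fold_change, student_t_dge

__all__ = [
    "PathwayMap",
    "SubtypeDEResults",
    "subtype_dge",
    "annotate_hemostasis",
    "fold_change_from_log_means",
    "load_shipped_pathway_map",
]

logger = logging.getLogger(__name__)


@dataclass
class PathwayMap:
    """Gene symbol -> list of pathway names."""

    entries: dict[str, list[str]]
    provenance: str = "user-supplied"

    @classmethod
    def from_tsv(cls, path, provenance: str | None = None) -> "PathwayMap":
        df = pd.read_csv(path, sep="\t", comment="#")
        required = {"gene_symbol", "pathway"}
        if not required <= set(df.columns):
            raise ValidationError(f"pathway table needs columns {sorted(required)}")
        entries: dict[str, list[str]] = {}
        for row in df.itertuples():
            entries.setdefault(row.gene_symbol, [])
            if row.pathway not in entries[row.gene_symbol]:
                entries[row.gene_symbol].append(row.pathway)
        return cls(entries, provenance or str(path))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_symbol": g, "pathway": p}
            for g, paths in self.entries.items()
            for p in paths
        ]
        return pd.DataFrame(rows, columns=["gene_symbol", "pathway"])


def load_shipped_pathway_map() -> PathwayMap:
    """The hemostasis mapping shipped with the package."""
    ref = importlib.resources.files("thrombomark.data").joinpath("hemostasis_pathways.tsv")
    with importlib.resources.as_file(ref) as path:
        return PathwayMap.from_tsv(path, provenance="shipped hemostasis fixture")


@dataclass
class SubtypeDEResults:
    """Filtered per-subtype DE tables plus the subtypes skipped and why."""

    tables: dict[str, pd.DataFrame]
    skipped: dict[str, str]


def subtype_dge(
    matrix: ExpressionMatrix,
    assignments: pd.DataFrame,
    cohort: ClinicalCohort,
    p_max: float = 0.05,
    fc_min: float = 1.5,
) -> SubtypeDEResults:
    """Exploratory DE screen within each molecular subtype.

    Filters at raw p < ``p_max`` and |FC| > ``fc_min`` with no multiplicity
    adjustment (by design: an exploratory, per-subtype screen). Subtypes with
    fewer than 2 cases or 2 controls are skipped with a logged warning and
    reported in ``skipped``.
    """
    t = cohort.table.set_index("patient_id")
    labels = t["vte"].astype(bool)
    tables: dict[str, pd.DataFrame] = {}
    skipped: dict[str, str] = {}
    for subtype, group in assignments.groupby("subtype"):
        samples = [s for s in group["sample_id"] if s in set(matrix.samples)]
        n_case = int(labels.reindex(samples).sum())
        n_ctrl = len(samples) - n_case
        if n_case < 2 or n_ctrl < 2:
            reason = f"only {n_case} cases / {n_ctrl} controls"
            logger.warning("skipping subtype %s: %s", subtype, reason)
            skipped[subtype] = reason
            continue
        de = student_t_dge(matrix, labels, stratum_samples=samples, stratum_label=str(subtype))
        mask = (de["p_value"] < p_max) & (de["fold_change"].abs() > fc_min)
        tables[str(subtype)] = de.loc[mask].reset_index(drop=True)
    return SubtypeDEResults(tables=tables, skipped=skipped)


def _split_symbols(symbol: str) -> list[str]:
    return [s.strip() for s in str(symbol).split(";") if s.strip()]


def annotate_hemostasis(de: pd.DataFrame, pathway_map: PathwayMap) -> pd.DataFrame:
    """Inner-join DE hits with the hemostasis map.

    Multi-symbol entries (e.g. probes covering several immunoglobulin genes,
    separated by ';') are split so each constituent gene is matched and
    reported on its own row. An empty intersection yields an empty frame.
    """
    rows = []
    for rec in de.to_dict("records"):
        for sym in _split_symbols(rec.get("gene_symbol", "")):
            for pathway in pathway_map.entries.get(sym, []):
                out = dict(rec)
                out["gene_symbol"] = sym
                out["pathway"] = pathway
                rows.append(out)
    if not rows:
        logger.info("no DE genes matched the hemostasis map (0 annotated)")
        cols = list(de.columns) + ["pathway"]
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)


def fold_change_from_log_means(t_avg_log2: float, n_avg_log2: float) -> float:
    """Signed fold change from per-group mean log2 expression levels."""
    return signed_fold_change(float(t_avg_log2) - float(n_avg_log2))


def plot_subtype_heatmap(matrix: ExpressionMatrix, genes, samples, path) -> None:
    """Descriptive clustered heat map of selected genes x samples (optional).

    Hierarchical clustering with average linkage on Euclidean distances, both
    axes. Requires matplotlib; purely descriptive output.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import leaves_list, linkage

    sub = matrix.values.loc[[g for g in genes if g in matrix.genes], list(samples)]
    if sub.empty:
        raise ValidationError("no genes to plot")
    gene_order = leaves_list(linkage(sub.to_numpy(), method="average", metric="euclidean"))
    samp_order = leaves_list(linkage(sub.to_numpy().T, method="average", metric="euclidean"))
    ordered = sub.iloc[gene_order, samp_order]

    fig, ax = plt.subplots(figsize=(max(6, 0.2 * len(samples)), max(4, 0.2 * len(sub))))
    im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="RdYlGn_r")
    ax.set_yticks(range(len(ordered.index)), ordered.index, fontsize=6)
    ax.set_xticks(range(len(ordered.columns)), ordered.columns, fontsize=6, rotation=90)
    fig.colorbar(im, ax=ax, label="log2 expression")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
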