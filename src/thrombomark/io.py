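"""Readers and writers for the pipeline's text formats.

Expression matrices travel as TSV (rows = genes, first column = gene symbol,
header row = sample ids), cohorts as CSV, marker signatures and pathway maps
as GMT-like text, and reports as TSV with a header comment naming the
producing stage and its thresholds.
"""

from __future__ import annotations

import pandas as pd

from .containers import ClinicalCohort, ExpressionMatrix, ValidationError
from .pathways import PathwayMap
from .subtyping import SubtypeSignature

__all__ = [
    "read_expression_tsv",
    "read_cohort_csv",
    "read_gmt",
    "write_gmt",
    "signatures_from_gmt",
    "pathway_map_from_gmt",
    "write_report",
]


def read_expression_tsv(path) -> ExpressionMatrix:
    """Parse a genes x samples TSV with location-bearing error messages."""
    # pandas silently renames duplicate header fields, so check them first.
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                header = line.rstrip("\n").split("\t")[1:]
                dupes = sorted({s for i, s in enumerate(header) if s in header[:i]})
                if dupes:
                    raise ValidationError(f"{path}: duplicate sample ids: {dupes}")
                break
    try:
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, comment="#")
    except pd.errors.ParserError as exc:
        raise ValidationError(f"{path}: ragged or malformed TSV: {exc}") from exc
    df.index.name = None
    if df.index.duplicated().any():
        for i, (sym, dup) in enumerate(zip(df.index, df.index.duplicated()), start=2):
            if dup:
                raise ValidationError(
                    f"{path}: duplicate gene symbol {sym!r} at data row {i}"
                )
    if df.columns.duplicated().any():
        dupes = sorted(set(df.columns[df.columns.duplicated()]))
        raise ValidationError(f"{path}: duplicate sample ids: {dupes}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna()
    if bad.any().any() or numeric.isna().any().any():
        mask = numeric.isna()
        gene = mask.any(axis=1).idxmax()
        sample = mask.loc[gene].idxmax()
        raise ValidationError(
            f"{path}: non-numeric or missing value at gene {gene!r}, sample {sample!r}"
        )
    return ExpressionMatrix(numeric)


def read_cohort_csv(path) -> ClinicalCohort:
    """Parse a one-row-per-patient covariate table."""
    return ClinicalCohort(pd.read_csv(path, comment="#"))


def read_gmt(path) -> dict[str, tuple[str, list[str]]]:
    """Parse GMT: name <TAB> description <TAB> member genes. Empty file -> {}."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT set needs name, description and >= 1 member"
                )
            name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if not members:
                raise ValidationError(f"{path}:{lineno}: set {name!r} has no members")
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = (desc, members)
    return sets


def write_gmt(sets: dict[str, tuple[str, list[str]]], path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


def signatures_from_gmt(path) -> dict[str, SubtypeSignature]:
    """Resolve the ``<SUBTYPE>_up`` / ``<SUBTYPE>_down`` naming convention."""
    raw = read_gmt(path)
    up: dict[str, list[str]] = {}
    down: dict[str, list[str]] = {}
    for name, (_, members) in raw.items():
        lower = name.lower()
        if lower.endswith("_up"):
            up[name[: -len("_up")]] = members
        elif lower.endswith("_down") or lower.endswith("_dn"):
            base = name.rsplit("_", 1)[0]
            down[base] = members
        else:
            raise ValidationError(
                f"GMT set {name!r} lacks the _up/_down suffix convention"
            )
    signatures = {}
    for subtype in sorted(set(up) | set(down)):
        signatures[subtype] = SubtypeSignature(
            subtype=subtype,
            up_genes=up.get(subtype, []),
            down_genes=down.get(subtype, []),
        )
    return signatures


def pathway_map_from_gmt(path) -> PathwayMap:
    """Interpret each GMT set as a pathway and its members as genes."""
    raw = read_gmt(path)
    entries: dict[str, list[str]] = {}
    for pathway, (_, members) in raw.items():
        for gene in members:
            entries.setdefault(gene, [])
            if pathway not in entries[gene]:
                entries[gene].append(pathway)
    return PathwayMap(entries, provenance=str(path))


def write_report(df: pd.DataFrame, path, stage: str, thresholds: dict | None = None) -> None:
    """Write a TSV report with a comment header naming stage and thresholds."""
    meta = f"# stage={stage}"
    if thresholds:
        meta += " " + " ".join(f"{k}={v}" for k, v in sorted(thresholds.items()))
    with open(path, "w") as fh:
        fh.write(meta + "\n")
        df.to_csv(fh, sep="\t", index=False)
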