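"""Readers and writers for the pipeline's plain-text formats.

Expression travels as TSV (gene rows, sample columns) or GCT 1.2; clinical
tables as TSV with documented columns; annotation gene sets as GMT;
interactions as two-column TSV; networks as SIF plus a companion statistics
TSV.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .evaluation import AnnotationCollection
from .rules import ImplicationNetwork

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_clinical_table",
    "write_clinical_table",
    "read_gmt",
    "write_gmt",
    "read_interactions",
    "write_interactions",
    "write_network_sif",
    "read_annotation_collection",
]

PathLike = Union[str, Path]

CLINICAL_COLUMNS = ("sample_id", "smoker", "surv_months", "event", "stage", "age", "gender")
_STAGE_TOKENS = {"I", "II", "III", "Unknown"}


def _check_unique_ids(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    for i in ids:
        seen[i] = seen.get(i, 0) + 1
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise ValueError(f"duplicate {what} IDs: {dups[:10]}")


def read_expression_matrix(path: PathLike, format: str = "tsv") -> pd.DataFrame:
    """Read a genes x samples expression matrix from TSV or GCT 1.2."""
    path = Path(path)
    if format not in ("tsv", "gct"):
        raise ValueError(f"unknown expression format {format!r}")
    lines = path.read_text().splitlines()
    if format == "gct":
        if len(lines) < 3 or not lines[0].startswith("#1.2"):
            raise ValueError(f"{path}: not a GCT 1.2 file")
        try:
            n_rows, n_cols = (int(x) for x in lines[1].split("\t")[:2])
        except ValueError as exc:
            raise ValueError(f"{path}: line 2: bad GCT dimension line") from exc
        body = lines[2:]
        header = body[0].split("\t")
        samples = header[2:]
        data_lines = body[1:]
        if len(data_lines) != n_rows or len(samples) != n_cols:
            raise ValueError(
                f"{path}: declared dimensions {n_rows}x{n_cols} do not match body "
                f"({len(data_lines)} rows, {len(samples)} columns)"
            )
        offset, id_cols = 3, 2
    else:
        header = lines[0].split("\t")
        samples = header[1:]
        data_lines = lines[1:]
        offset, id_cols = 2, 1
    _check_unique_ids(samples, "sample")
    genes: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(data_lines, start=offset):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != id_cols + len(samples):
            raise ValueError(
                f"{path}: line {lineno}: expected {id_cols + len(samples)} fields, "
                f"got {len(parts)}"
            )
        genes.append(parts[0])
        try:
            rows.append([float(x) for x in parts[id_cols:]])
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: non-numeric value ({exc})") from exc
    _check_unique_ids(genes, "gene")
    return pd.DataFrame(rows, index=genes, columns=samples)


def write_expression_matrix(
    expr: pd.DataFrame, path: PathLike, format: str = "tsv"
) -> None:
    path = Path(path)
    if format == "tsv":
        with path.open("w") as fh:
            fh.write("gene_id\t" + "\t".join(map(str, expr.columns)) + "\n")
            for gene, row in zip(expr.index, expr.to_numpy()):
                fh.write(str(gene) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    elif format == "gct":
        with path.open("w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{expr.shape[0]}\t{expr.shape[1]}\n")
            fh.write("NAME\tDescription\t" + "\t".join(map(str, expr.columns)) + "\n")
            for gene, row in zip(expr.index, expr.to_numpy()):
                fh.write(
                    f"{gene}\tna\t" + "\t".join(repr(float(v)) for v in row) + "\n"
                )
    else:
        raise ValueError(f"unknown expression format {format!r}")


def read_clinical_table(
    path: PathLike,
    expression_samples: Optional[Sequence[str]] = None,
    required: Sequence[str] = ("sample_id", "smoker", "surv_months", "event"),
) -> pd.DataFrame:
    """Read a clinical TSV; validates columns, stage tokens and sample overlap.

    Unknown smoking status may be encoded as an empty field or ``NA``; it is
    preserved as missing and downstream stages exclude those samples with a
    logged count.  Samples absent from the expression matrix are dropped
    with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, na_values=["NA", ""])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required clinical column(s): {missing}")
    if "stage" in df.columns:
        bad = set(df["stage"].dropna().astype(str)) - _STAGE_TOKENS
        if bad:
            raise ValueError(
                f"{path}: stage tokens outside {sorted(_STAGE_TOKENS)}: {sorted(bad)}"
            )
    df = df.set_index("sample_id", drop=False)
    _check_unique_ids(list(df.index), "sample")
    if expression_samples is not None:
        known = set(expression_samples)
        extra = [s for s in df.index if s not in known]
        if extra:
            warnings.warn(
                f"{len(extra)} clinical sample(s) absent from expression matrix; excluded"
            )
            df = df.loc[[s for s in df.index if s in known]]
    for col in ("smoker", "event", "gender", "cancer"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise").astype("Int64")
    for col in ("surv_months", "age"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    return df


def write_clinical_table(clinical: pd.DataFrame, path: PathLike) -> None:
    out = clinical.reset_index(drop=True) if "sample_id" in clinical.columns else clinical.reset_index()
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_gmt(path: PathLike) -> dict[str, frozenset]:
    """GMT: one set per line -- name, description, tab-separated gene IDs."""
    sets: dict[str, frozenset] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: line {lineno}: GMT lines need name, description, >=1 gene")
        name = parts[0]
        if name in sets:
            raise ValueError(f"{path}: line {lineno}: duplicate set name {name!r}")
        sets[name] = frozenset(g for g in parts[2:] if g)
    return sets


def write_gmt(gene_sets: Mapping[str, Iterable[str]], path: PathLike) -> None:
    with Path(path).open("w") as fh:
        for name in sorted(gene_sets):
            genes = sorted(gene_sets[name])
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_interactions(path: PathLike) -> set[frozenset]:
    pairs: set[frozenset] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}: line {lineno}: interaction lines need two gene IDs")
        if parts[0] == parts[1]:
            raise ValueError(f"{path}: line {lineno}: self-interaction {parts[0]!r}")
        pairs.add(frozenset(parts[:2]))
    return pairs


def write_interactions(pairs: Iterable[frozenset], path: PathLike) -> None:
    with Path(path).open("w") as fh:
        for pair in sorted(tuple(sorted(p)) for p in pairs):
            fh.write("\t".join(pair) + "\n")


def read_annotation_collection(
    gmt_paths: Sequence[PathLike] = (),
    interaction_paths: Sequence[PathLike] = (),
) -> AnnotationCollection:
    """Merge any number of GMT and interaction files into one collection."""
    gene_sets: dict[str, frozenset] = {}
    for p in gmt_paths:
        for name, members in read_gmt(p).items():
            if name in gene_sets and gene_sets[name] != members:
                raise ValueError(f"conflicting definitions for gene set {name!r}")
            gene_sets[name] = members
    interactions: set[frozenset] = set()
    for p in interaction_paths:
        interactions |= read_interactions(p)
    return AnnotationCollection(gene_sets=gene_sets, interactions=interactions)


def write_network_sif(network: ImplicationNetwork, sif_path: PathLike, stats_path: Optional[PathLike] = None) -> None:
    """Write a network as SIF (geneA <tab> rule <tab> geneB) plus a stats TSV."""
    with Path(sif_path).open("w") as fh:
        for (a, b), stats in sorted(network.edges.items()):
            fh.write(f"{a}\t{stats.rule_type}\t{b}\n")
    if stats_path is not None:
        network.to_frame().to_csv(stats_path, sep="\t", index=False, float_format="%.6g")
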