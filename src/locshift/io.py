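"""Readers and writers: cell tables, profiles, rankings, curves, CDT heatmaps.

All writers use a fixed ``%.6g`` float format so identical inputs produce
byte-identical files.  The heatmap export targets the CDT dialect read by
Java TreeView (with a plain TSV mirror written alongside), since clustered
gene-by-feature heat maps are the standard way to inspect profile, change
and z-score matrices in this kind of screen analysis.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .detect import ChangeMatrix, ZScoreResult, ranking_frame
from .evaluate import EvaluationCurve, curve_frame
from .profiles import CELL_TABLE_COLUMNS, CELL_TYPES, FEATURES, ProfileMatrix

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"
_MAX_REJECT_FRACTION = 0.10


def _fmt(x: float) -> str:
    return FLOAT_FMT % x


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read a single-cell feature TSV into the canonical cell table.

    Malformed rows (bad numbers, non-positive size, unknown cell type) are
    rejected with line-numbered warnings; more than 10% rejected rows is an
    error.  Cell types are accepted case-insensitively.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in CELL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    df = df[list(CELL_TABLE_COLUMNS)]
    n_in = len(df)
    if n_in == 0:
        return df.assign(cell_size=pd.Series(dtype=float),
                         **{f: pd.Series(dtype=float) for f in FEATURES})

    numeric = df[["cell_size", *FEATURES]].apply(pd.to_numeric, errors="coerce")
    ctype = df["cell_type"].astype(str).str.strip().str.lower()
    bad = (
        numeric.isna().any(axis=1)
        | ~np.isfinite(numeric).all(axis=1)
        | (numeric["cell_size"] <= 0)
        | ~ctype.isin(CELL_TYPES)
        | df[["gene_id", "screen_id", "cell_id"]].isna().any(axis=1)
    )
    if bad.any():
        for idx in df.index[bad][:10]:
            logger.warning("%s: rejecting malformed row at line %d", path, idx + 2)
        if int(bad.sum()) > 10:
            logger.warning("%s: ... %d malformed rows in total", path, int(bad.sum()))
        if bad.sum() / n_in > _MAX_REJECT_FRACTION:
            raise ValueError(
                f"{path}: {int(bad.sum())}/{n_in} rows malformed (> {_MAX_REJECT_FRACTION:.0%})"
            )
    out = df.loc[~bad, ["gene_id", "screen_id", "cell_id"]].copy()
    out["cell_type"] = ctype[~bad]
    out[["cell_size", *FEATURES]] = numeric.loc[~bad]
    return out.reset_index(drop=True)


def write_cell_table(cells: pd.DataFrame, path: str | Path) -> None:
    """Write a cell table in the canonical TSV schema."""
    cells[list(CELL_TABLE_COLUMNS)].to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_profiles(matrix: ProfileMatrix, path: str | Path) -> None:
    """Write a profile matrix as TSV with a one-line metadata header comment."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            f"# screen_id={matrix.screen_id}\taggregator={matrix.aggregator}"
            f"\trescaled={int(matrix.rescaled)}\n"
        )
        fh.write("gene_id\t" + "\t".join(matrix.feature_labels) + "\n")
        for gene, row in zip(matrix.gene_ids, matrix.values):
            fh.write(gene + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def read_profiles(path: str | Path) -> ProfileMatrix:
    """Read a profile matrix written by :func:`write_profiles`."""
    path = Path(path)
    meta = {"screen_id": "", "aggregator": "mean", "rescaled": "1"}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for kv in first[1:].strip().split("\t"):
                key, _, val = kv.partition("=")
                meta[key.strip()] = val
            header_line = fh.readline()
        else:
            header_line = first
        labels = header_line.rstrip("\n").split("\t")[1:]
        genes, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            genes.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    return ProfileMatrix(
        screen_id=meta["screen_id"],
        gene_ids=genes,
        values=np.array(rows) if rows else np.empty((0, len(labels))),
        feature_labels=labels,
        aggregator=meta["aggregator"],
        rescaled=bool(int(meta["rescaled"])),
    )


def write_ranking(
    results: list[ZScoreResult], feature_labels: Sequence[str], path: str | Path
) -> None:
    """Ranking TSV: gene_id, rank, rms, then the 60 M_{label} columns."""
    frame = ranking_frame(results, list(feature_labels)).sort_values("rank")
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_ranking(path: str | Path) -> pd.DataFrame:
    """Read a ranking TSV (detect or baseline output) sorted by rank."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "rank", "rms"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return df.sort_values("rank", ignore_index=True)


def write_naive_ranking(ranking: pd.DataFrame, path: str | Path) -> None:
    """Baseline ranking TSV: gene_id, rank, rms."""
    ranking[["gene_id", "rank", "rms"]].to_csv(path, sep="\t", index=False,
                                               float_format=FLOAT_FMT)


def write_curve(curve: EvaluationCurve, path: str | Path) -> None:
    curve_frame(curve).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def _as_matrix(matrix) -> tuple[list[str], list[str], np.ndarray]:
    if isinstance(matrix, (ProfileMatrix, ChangeMatrix)):
        return list(matrix.gene_ids), list(matrix.feature_labels), matrix.values
    gene_ids, labels, values = matrix
    return list(gene_ids), list(labels), np.asarray(values, dtype=float)


def export_cdt(matrix, path: str | Path, threshold: float | None = None) -> None:
    """Export a gene-by-feature matrix as a Java TreeView CDT file.

    ``matrix`` may be a ProfileMatrix, a ChangeMatrix, or a ``(gene_ids,
    feature_labels, values)`` triple.  With ``threshold`` set, entries with
    ``|value| <= threshold`` are written as 0 — the thresholded views used to
    compare raw change values (cut-off 12.0) against modified z-scores
    (cut-off 2.0).  A plain TSV mirror is written next to the CDT.
    """
    gene_ids, labels, values = _as_matrix(matrix)
    if values.size == 0:
        raise ValueError("refusing to export an empty matrix")
    if threshold is not None:
        values = np.where(np.abs(values) <= threshold, 0.0, values)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("GID\tNAME\tGWEIGHT\t" + "\t".join(labels) + "\n")
        fh.write("EWEIGHT\t\t\t" + "\t".join("1" for _ in labels) + "\n")
        for i, (gene, row) in enumerate(zip(gene_ids, values)):
            fh.write(f"GENE{i}X\t{gene}\t1\t" + "\t".join(_fmt(v) for v in row) + "\n")
    mirror = path.with_suffix(path.suffix + ".tsv") if path.suffix != ".tsv" else path
    pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=labels).to_csv(
        mirror, sep="\t", float_format=FLOAT_FMT
    )


def read_cdt(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    """Parse a CDT file written by :func:`export_cdt` back into memory."""
    with open(path) as fh:
        labels = fh.readline().rstrip("\n").split("\t")[3:]
        fh.readline()  # EWEIGHT row
        genes, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            genes.append(parts[1])
            rows.append([float(v) for v in parts[3:]])
    return genes, labels, np.array(rows)
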