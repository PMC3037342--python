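"""Reading expression matrices and writing bicluster reports.

Matrices travel as delimiter-separated text: a header line of condition
identifiers, then one row per gene starting with its identifier.  Results
are written per bicluster with the standard report columns — gene and
condition counts, volume, average correlation rho(B), its standard
deviation, fitness, MSR and gene variance — followed by a summary row of
column means.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import measures
from .model import Bicluster, ExpressionMatrix
from .search import SearchConfig

__all__ = [
    "MatrixFormatError",
    "ResultRecord",
    "read_matrix",
    "write_matrix",
    "write_truth",
    "read_truth",
    "records_from_biclusters",
    "write_results",
]


class MatrixFormatError(ValueError):
    """The input file does not parse as a valid expression matrix."""


def read_matrix(
    path: str | Path,
    delimiter: str = "\t",
    missing_token: str = "NA",
    missing_policy: str = "reject",
) -> ExpressionMatrix:
    """Load a gene-by-condition matrix from delimited text.

    ``missing_policy='reject'`` aborts on the first missing cell (naming
    it); ``'mean_impute'`` replaces each missing cell with the gene's mean
    over its present values.  Imputation is an explicit opt-in because the
    usual expression inputs are already preprocessed upstream.
    """
    if missing_policy not in ("reject", "mean_impute"):
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    try:
        df = pd.read_csv(
            path,
            sep=delimiter,
            index_col=0,
            na_values=[missing_token],
            keep_default_na=False,
            float_precision="round_trip",
        )
    except pd.errors.ParserError as exc:
        raise MatrixFormatError(f"cannot parse {path}: {exc}") from exc
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise MatrixFormatError(f"duplicate gene id {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise MatrixFormatError(f"duplicate condition id {dup!r}")
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise MatrixFormatError(f"non-numeric cell in {path}: {exc}") from exc
    if df.isna().any().any():
        if missing_policy == "reject":
            gene, cond = _first_missing(df)
            raise MatrixFormatError(
                f"missing value at gene {gene!r}, condition {cond!r} "
                "(use mean_impute to fill from row means)"
            )
        all_missing = df.isna().all(axis=1)
        if all_missing.any():
            gene = df.index[all_missing][0]
            raise MatrixFormatError(f"gene {gene!r} has no present values to impute from")
        row_means = df.mean(axis=1)
        df = df.apply(lambda row: row.fillna(row_means[row.name]), axis=1)
    return ExpressionMatrix(
        df.to_numpy(dtype=float),
        tuple(str(g) for g in df.index),
        tuple(str(c) for c in df.columns),
    )


def _first_missing(df: pd.DataFrame) -> tuple[str, str]:
    rows, cols = np.nonzero(df.isna().to_numpy())
    return str(df.index[rows[0]]), str(df.columns[cols[0]])


def write_matrix(matrix: ExpressionMatrix, path: str | Path, delimiter: str = "\t") -> None:
    """Write a matrix in the same format :func:`read_matrix` reads.

    Floats carry 17 significant digits, so a read-back reproduces the
    matrix bit for bit.
    """
    df = pd.DataFrame(
        matrix.values, index=list(matrix.gene_ids), columns=list(matrix.condition_ids)
    )
    df.to_csv(path, sep=delimiter, index_label="gene", float_format="%.17g")


def write_truth(
    truth: Sequence[Bicluster], matrix: ExpressionMatrix, path: str | Path
) -> None:
    """Ground-truth sidecar: one implant per line as id lists."""
    with open(path, "w") as fh:
        fh.write("implant\tgene_ids\tcondition_ids\n")
        for i, b in enumerate(truth, start=1):
            fh.write(
                f"implant{i}\t"
                + ";".join(b.gene_labels(matrix))
                + "\t"
                + ";".join(b.condition_labels(matrix))
                + "\n"
            )


def read_truth(path: str | Path, matrix: ExpressionMatrix) -> list[Bicluster]:
    """Read a ground-truth sidecar back into biclusters."""
    gene_pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    cond_pos = {c: j for j, c in enumerate(matrix.condition_ids)}
    out = []
    with open(path) as fh:
        next(fh)  # header
        for line in fh:
            _, genes, conds = line.rstrip("\n").split("\t")
            out.append(
                Bicluster(
                    tuple(gene_pos[g] for g in genes.split(";") if g),
                    tuple(cond_pos[c] for c in conds.split(";") if c),
                )
            )
    return out


@dataclass(frozen=True)
class ResultRecord:
    """One report row: identity, membership and quality measures."""

    bicluster_id: str
    gene_ids: tuple[str, ...]
    condition_ids: tuple[str, ...]
    n_genes: int
    n_conditions: int
    volume: int
    avg_corr: float
    corr_sd: float
    fitness: float
    msr: float
    gene_variance: float


_NUMERIC_COLUMNS = (
    "n_genes",
    "n_conditions",
    "volume",
    "avg_corr",
    "corr_sd",
    "fitness",
    "msr",
    "gene_variance",
)


def records_from_biclusters(
    biclusters: Sequence[Bicluster],
    matrix: ExpressionMatrix,
    config: SearchConfig | None = None,
    id_prefix: str = "bi",
) -> list[ResultRecord]:
    """Score each bicluster and assemble report records."""
    m1 = config.m1 if config else 1.0
    m2 = config.m2 if config else 1.0
    records = []
    for i, b in enumerate(biclusters, start=1):
        sc = measures.score(b, matrix, m1, m2)
        records.append(
            ResultRecord(
                bicluster_id=f"{id_prefix}{i}",
                gene_ids=b.gene_labels(matrix),
                condition_ids=b.condition_labels(matrix),
                n_genes=b.n_genes,
                n_conditions=b.n_conditions,
                volume=b.volume,
                avg_corr=sc.avg_corr,
                corr_sd=sc.corr_sd,
                fitness=sc.fitness,
                msr=sc.msr,
                gene_variance=sc.gene_variance,
            )
        )
    return records


def _summary(records: Sequence[ResultRecord]) -> dict[str, float | None]:
    out: dict[str, float | None] = {}
    for col in _NUMERIC_COLUMNS:
        vals = [getattr(r, col) for r in records]
        vals = [v for v in vals if not (isinstance(v, float) and math.isnan(v))]
        out[col] = float(np.mean(vals)) if vals else None
    return out


def _fmt(v: float | int | None) -> str:
    if v is None:
        return ""
    if isinstance(v, int):
        return str(v)
    return format(v, ".10g")


def write_results(
    records: Sequence[ResultRecord], path: str | Path, format: str = "tsv"
) -> None:
    """Write per-bicluster records plus a mean-summary row (TSV or JSON)."""
    if format == "tsv":
        cols = ("bicluster_id",) + _NUMERIC_COLUMNS + ("gene_ids", "condition_ids")
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for r in records:
                row = [r.bicluster_id]
                row += [_fmt(getattr(r, c)) for c in _NUMERIC_COLUMNS]
                row += [";".join(r.gene_ids), ";".join(r.condition_ids)]
                fh.write("\t".join(row) + "\n")
            summ = _summary(records)
            fh.write(
                "\t".join(
                    ["average"] + [_fmt(summ[c]) for c in _NUMERIC_COLUMNS] + ["", ""]
                )
                + "\n"
            )
    elif format == "json":
        payload = {
            "biclusters": [
                {**asdict(r), "gene_ids": list(r.gene_ids), "condition_ids": list(r.condition_ids)}
                for r in records
            ],
            "summary": _summary(records),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, allow_nan=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown results format {format!r}")
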