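"""Domain types: expression matrices, biclusters and their bit-string encoding.

A bicluster of an ``N x L`` expression matrix is a subset of gene (row)
indices together with a subset of condition (column) indices.  For the
evolutionary search, biclusters are encoded as binary strings of length
``N + L``: the first ``N`` bits select genes, the remaining ``L`` bits select
conditions.  Encoding and decoding are exact inverses, and the Hamming
distance between encodings serves as the diversity metric of the search.

Indices are 0-based internally; user-facing labels (``g1``, ``c1``, ...) are
1-based, matching the conventional presentation in the biclustering
literature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "Bicluster",
    "InvalidBiclusterError",
    "DimensionMismatchError",
    "encode",
    "decode",
    "hamming",
    "bits_from_str",
    "bits_to_str",
]


class InvalidBiclusterError(ValueError):
    """A bicluster's index sets do not fit the matrix it is used with."""


class DimensionMismatchError(ValueError):
    """Operands (vectors, bit strings) have incompatible lengths."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """A real-valued gene-by-condition matrix with row and column identifiers.

    Parameters
    ----------
    values
        ``(N, L)`` array of expression levels (arbitrary units).  Every entry
        must be finite; missing-value handling happens at load time (see
        :func:`corrbic.io.read_matrix`).
    gene_ids, condition_ids
        Unique identifiers for the ``N`` rows and ``L`` columns.
    """

    values: np.ndarray
    gene_ids: tuple[str, ...]
    condition_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("expression values must form a 2-D matrix")
        n, l = values.shape
        if n < 2 or l < 2:
            raise ValueError(f"matrix must be at least 2x2, got {n}x{l}")
        if not np.all(np.isfinite(values)):
            raise ValueError("matrix contains non-finite entries")
        gene_ids = tuple(str(g) for g in self.gene_ids)
        condition_ids = tuple(str(c) for c in self.condition_ids)
        if len(gene_ids) != n:
            raise ValueError("number of gene ids does not match row count")
        if len(condition_ids) != l:
            raise ValueError("number of condition ids does not match column count")
        if len(set(gene_ids)) != n:
            raise ValueError("duplicate gene ids")
        if len(set(condition_ids)) != l:
            raise ValueError("duplicate condition ids")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "condition_ids", condition_ids)

    @classmethod
    def from_array(
        cls,
        values: np.ndarray,
        gene_ids: Sequence[str] | None = None,
        condition_ids: Sequence[str] | None = None,
    ) -> "ExpressionMatrix":
        """Wrap a plain array, autogenerating ``g1.. / c1..`` labels."""
        values = np.asarray(values, dtype=float)
        n, l = values.shape
        if gene_ids is None:
            gene_ids = [f"g{i + 1}" for i in range(n)]
        if condition_ids is None:
            condition_ids = [f"c{j + 1}" for j in range(l)]
        return cls(values, tuple(gene_ids), tuple(condition_ids))

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    def submatrix(self, bicluster: "Bicluster") -> np.ndarray:
        """Extract the sub-array selected by a bicluster (genes x conditions)."""
        if bicluster.n_genes and bicluster.genes[-1] >= self.n_genes:
            raise InvalidBiclusterError("gene index out of range for this matrix")
        if bicluster.n_conditions and bicluster.conditions[-1] >= self.n_conditions:
            raise InvalidBiclusterError("condition index out of range for this matrix")
        return self.values[np.ix_(bicluster.genes, bicluster.conditions)]


@dataclass(frozen=True)
class Bicluster:
    """A subset of gene indices and condition indices (0-based, sorted).

    Empty index sets are representable — crossover during the search can
    produce them — but carry worst-possible fitness rather than raising (see
    :func:`corrbic.measures.fitness`).
    """

    genes: tuple[int, ...]
    conditions: tuple[int, ...]

    def __post_init__(self) -> None:
        genes = tuple(sorted({int(g) for g in self.genes}))
        conditions = tuple(sorted({int(c) for c in self.conditions}))
        if genes and genes[0] < 0:
            raise InvalidBiclusterError("negative gene index")
        if conditions and conditions[0] < 0:
            raise InvalidBiclusterError("negative condition index")
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "conditions", conditions)

    @classmethod
    def from_sets(cls, genes: Iterable[int], conditions: Iterable[int]) -> "Bicluster":
        return cls(tuple(genes), tuple(conditions))

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def volume(self) -> int:
        """Number of cells, ``nG * nC``."""
        return self.n_genes * self.n_conditions

    def gene_labels(self, matrix: ExpressionMatrix) -> tuple[str, ...]:
        return tuple(matrix.gene_ids[g] for g in self.genes)

    def condition_labels(self, matrix: ExpressionMatrix) -> tuple[str, ...]:
        return tuple(matrix.condition_ids[c] for c in self.conditions)


def encode(bicluster: Bicluster, n_genes: int, n_conditions: int) -> np.ndarray:
    """Encode a bicluster as a 0/1 array of length ``N + L``.

    Bit ``i`` (0-based, ``i < N``) is 1 iff gene ``i`` is selected; bit
    ``N + j`` is 1 iff condition ``j`` is selected.
    """
    if bicluster.n_genes and bicluster.genes[-1] >= n_genes:
        raise InvalidBiclusterError(
            f"gene index {bicluster.genes[-1]} out of range for N={n_genes}"
        )
    if bicluster.n_conditions and bicluster.conditions[-1] >= n_conditions:
        raise InvalidBiclusterError(
            f"condition index {bicluster.conditions[-1]} out of range for L={n_conditions}"
        )
    bits = np.zeros(n_genes + n_conditions, dtype=np.uint8)
    bits[list(bicluster.genes)] = 1
    bits[[n_genes + c for c in bicluster.conditions]] = 1
    return bits


def decode(bits: np.ndarray, n_genes: int, n_conditions: int) -> Bicluster:
    """Inverse of :func:`encode`."""
    bits = np.asarray(bits)
    if bits.shape != (n_genes + n_conditions,):
        raise DimensionMismatchError(
            f"expected bit string of length {n_genes + n_conditions}, got {bits.shape}"
        )
    genes = tuple(int(i) for i in np.flatnonzero(bits[:n_genes]))
    conditions = tuple(int(j) for j in np.flatnonzero(bits[n_genes:]))
    return Bicluster(genes, conditions)


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    """Number of positions where two bit strings differ."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise DimensionMismatchError(f"bit strings of lengths {a.size} and {b.size}")
    return int(np.count_nonzero(a != b))


def bits_from_str(s: str) -> np.ndarray:
    """Parse a textual bit string; a ``|`` gene/condition separator is ignored."""
    s = s.replace("|", "")
    if set(s) - {"0", "1"}:
        raise ValueError(f"not a bit string: {s!r}")
    return np.frombuffer(s.encode(), dtype=np.uint8) - ord("0")


def bits_to_str(bits: np.ndarray, n_genes: int | None = None) -> str:
    """Render bits as text, optionally with a cosmetic ``|`` after the gene block."""
    s = "".join("1" if b else "0" for b in np.asarray(bits))
    if n_genes is not None:
        s = s[:n_genes] + "|" + s[n_genes:]
    return s
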