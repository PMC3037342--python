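"""Bicluster quality measures.

The central measure is the average pairwise Pearson correlation of the
bicluster's genes, computed over the bicluster's selected conditions only.
Two genes related by ``g_Y = alpha * g_X + beta`` with ``alpha > 0`` — a
shifting-and-scaling pattern — have correlation exactly 1, so a bicluster of
such genes scores an average correlation of 1 regardless of the spread of
the scaling factors.  The composite fitness

    f(B) = (1 - rho(B)) + sigma_rho + M1 / nG + M2 / nC

is minimised by the search: ``rho(B)`` is the average correlation,
``sigma_rho`` the population standard deviation of the pairwise
coefficients (guarding against a high mean hiding a few uncorrelated
genes), and ``M1``, ``M2`` are volume penalties — larger values favour
biclusters with more genes and conditions.

The mean squared residue (MSR) and the per-gene row variance are computed
for reporting only: MSR is blind to the difference between shifting
patterns (which it scores 0) and scaling patterns with a wide factor
spread (which it penalises even though they are perfectly correlated),
which is exactly the gap the correlation fitness closes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import Bicluster, DimensionMismatchError, ExpressionMatrix

__all__ = [
    "UndefinedMeasureError",
    "BiclusterScore",
    "pearson",
    "pairwise_correlations",
    "avg_correlation",
    "corr_sd",
    "fitness",
    "msr",
    "gene_variance",
    "score",
]


class UndefinedMeasureError(ValueError):
    """The measure is undefined for this bicluster (too few genes/conditions)."""


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient between two equal-length vectors.

    Computed with population (divide-by-n) moments; as a scale-free ratio
    the value is identical under sample (n-1) moments.  A vector that is
    constant has zero standard deviation; its correlation with anything is
    defined as 0 (uncorrelated), keeping the measure total.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise DimensionMismatchError(
            f"expected equal-length vectors, got {x.shape} and {y.shape}"
        )
    if x.size < 2:
        raise DimensionMismatchError("need at least 2 observations")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = math.sqrt(float(dx @ dx) / x.size)
    sy = math.sqrt(float(dy @ dy) / y.size)
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = float(dx @ dy) / (x.size * sx * sy)
    return max(-1.0, min(1.0, r))


def pairwise_correlations(bicluster: Bicluster, matrix: ExpressionMatrix) -> np.ndarray:
    """All ``C(nG, 2)`` pairwise gene correlations within the bicluster.

    Restricted to the bicluster's selected conditions.  Pairs involving a
    constant gene contribute 0.
    """
    if bicluster.n_genes < 2 or bicluster.n_conditions < 2:
        raise UndefinedMeasureError(
            "pairwise correlations need at least 2 genes and 2 conditions"
        )
    sub = matrix.submatrix(bicluster)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(sub)
    corr = np.nan_to_num(corr, nan=0.0)  # constant genes -> uncorrelated
    iu = np.triu_indices(bicluster.n_genes, k=1)
    return np.clip(corr[iu], -1.0, 1.0)


def avg_correlation(bicluster: Bicluster, matrix: ExpressionMatrix) -> float:
    """Average correlation rho(B): mean of all pairwise gene correlations."""
    return float(pairwise_correlations(bicluster, matrix).mean())


def corr_sd(bicluster: Bicluster, matrix: ExpressionMatrix) -> float:
    """Population standard deviation of the pairwise gene correlations.

    Zero for a 2-gene bicluster (a single coefficient has no spread).
    """
    return float(pairwise_correlations(bicluster, matrix).std())


def fitness(
    bicluster: Bicluster,
    matrix: ExpressionMatrix,
    m1: float = 1.0,
    m2: float = 1.0,
) -> float:
    """Composite fitness ``(1 - rho(B)) + sigma_rho + M1/nG + M2/nC``.

    Lower is better.  Total over all representable biclusters: degenerate
    ones (fewer than 2 genes or 2 conditions) map to ``+inf`` so the
    evolutionary loop never has to special-case them.
    """
    try:
        coeffs = pairwise_correlations(bicluster, matrix)
    except UndefinedMeasureError:
        return math.inf
    rho = float(coeffs.mean())
    sd = float(coeffs.std())
    return (1.0 - rho) + sd + m1 / bicluster.n_genes + m2 / bicluster.n_conditions


def msr(bicluster: Bicluster, matrix: ExpressionMatrix) -> float:
    """Mean squared residue of the bicluster's submatrix.

    Mean over cells of ``(a_ij - a_iJ - a_Ij + a_IJ)^2`` where ``a_iJ``,
    ``a_Ij`` and ``a_IJ`` are the row, column and overall means.  Zero for
    constant and for pure shifting submatrices; strictly positive for
    scaling patterns with spread-out factors.
    """
    if bicluster.n_genes < 1 or bicluster.n_conditions < 1:
        raise UndefinedMeasureError("MSR needs a non-empty bicluster")
    sub = matrix.submatrix(bicluster)
    residues = sub - sub.mean(axis=1, keepdims=True) - sub.mean(axis=0, keepdims=True) + sub.mean()
    return float(np.mean(residues**2))


def gene_variance(bicluster: Bicluster, matrix: ExpressionMatrix) -> float:
    """Mean squared deviation of each cell from its gene's row mean.

    Indicates the magnitude of expression change within the bicluster:
    large for scaling patterns with big factors, zero for flat genes.
    """
    if bicluster.n_genes < 1 or bicluster.n_conditions < 2:
        raise UndefinedMeasureError("gene variance needs >=1 gene and >=2 conditions")
    sub = matrix.submatrix(bicluster)
    return float(np.mean((sub - sub.mean(axis=1, keepdims=True)) ** 2))


@dataclass(frozen=True)
class BiclusterScore:
    """Bundle of the quality measures of one bicluster.

    ``avg_corr``/``corr_sd``/``msr``/``gene_variance`` are NaN where
    undefined (degenerate biclusters); ``fitness`` is then ``+inf``.
    """

    avg_corr: float
    corr_sd: float
    fitness: float
    msr: float
    gene_variance: float
    volume: int


def score(
    bicluster: Bicluster,
    matrix: ExpressionMatrix,
    m1: float = 1.0,
    m2: float = 1.0,
) -> BiclusterScore:
    """Compute all measures in one pass (single correlation evaluation)."""
    try:
        coeffs = pairwise_correlations(bicluster, matrix)
    except UndefinedMeasureError:
        coeffs = None
    if coeffs is None:
        avg = sd = math.nan
        fit = math.inf
    else:
        avg = float(coeffs.mean())
        sd = float(coeffs.std())
        fit = (1.0 - avg) + sd + m1 / bicluster.n_genes + m2 / bicluster.n_conditions
    try:
        m = msr(bicluster, matrix)
    except UndefinedMeasureError:
        m = math.nan
    try:
        gv = gene_variance(bicluster, matrix)
    except UndefinedMeasureError:
        gv = math.nan
    return BiclusterScore(avg, sd, fit, m, gv, bicluster.volume)
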