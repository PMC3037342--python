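"""Synthetic expression matrices with implanted shifting-and-scaling biclusters.

The generator builds an ``N x L`` background of Gaussian noise and overwrites
disjoint blocks with implanted patterns: each implanted gene is
``g_i = alpha_i * p + beta_i + eps`` for a shared base profile ``p``, a
per-gene scaling factor ``alpha_i > 0``, a shift ``beta_i`` and optional
Gaussian noise ``eps``.  With zero noise every pair of implanted genes is
perfectly positively correlated, whatever the spread of the factors — the
pattern class the correlation fitness is designed to recover and the mean
squared residue is not.

Ground-truth positions are returned alongside the matrix so recovery can be
quantified with :func:`jaccard_recovery`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Bicluster, ExpressionMatrix

__all__ = ["ImplantSpec", "make_matrix", "jaccard_recovery"]


@dataclass(frozen=True)
class ImplantSpec:
    """Shape and distribution of one implanted bicluster.

    ``alpha_range`` must be strictly positive so the implanted genes are
    positively correlated by construction; ``noise_sd = 0`` yields exact
    patterns (every pairwise correlation is 1).  The base profile ``p`` is
    drawn from ``background_distribution`` (mean, sd).
    """

    n_genes: int
    n_conditions: int
    alpha_range: tuple[float, float] = (0.5, 2.0)
    beta_range: tuple[float, float] = (-2.0, 2.0)
    noise_sd: float = 0.0
    background_distribution: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.n_genes < 2 or self.n_conditions < 2:
            raise ValueError("an implant needs at least 2 genes and 2 conditions")
        if self.alpha_range[0] <= 0 or self.alpha_range[1] < self.alpha_range[0]:
            raise ValueError("alpha_range must be a strictly positive interval")
        if self.beta_range[1] < self.beta_range[0]:
            raise ValueError("beta_range must be a valid interval")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def make_matrix(
    n_genes: int,
    n_conditions: int,
    implants: list[ImplantSpec],
    rng: np.random.Generator | int | None = None,
    background: tuple[float, float] = (0.0, 1.0),
) -> tuple[ExpressionMatrix, list[Bicluster]]:
    """Generate a matrix with implanted biclusters and return ground truth.

    Implants occupy disjoint, randomly placed row and column blocks so the
    truth is unambiguous.  Deterministic given the generator state.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if sum(s.n_genes for s in implants) > n_genes:
        raise ValueError("implants require more genes than the matrix has")
    if sum(s.n_conditions for s in implants) > n_conditions:
        raise ValueError("implants require more conditions than the matrix has")
    mean, sd = background
    values = rng.normal(mean, sd, size=(n_genes, n_conditions))
    row_pool = rng.permutation(n_genes)
    col_pool = rng.permutation(n_conditions)
    truth: list[Bicluster] = []
    r = c = 0
    for spec in implants:
        rows = np.sort(row_pool[r : r + spec.n_genes])
        cols = np.sort(col_pool[c : c + spec.n_conditions])
        r += spec.n_genes
        c += spec.n_conditions
        b_mean, b_sd = spec.background_distribution
        profile = rng.normal(b_mean, b_sd, size=spec.n_conditions)
        alphas = rng.uniform(*spec.alpha_range, size=spec.n_genes)
        betas = rng.uniform(*spec.beta_range, size=spec.n_genes)
        block = alphas[:, None] * profile[None, :] + betas[:, None]
        if spec.noise_sd > 0:
            block = block + rng.normal(0.0, spec.noise_sd, size=block.shape)
        values[np.ix_(rows, cols)] = block
        truth.append(Bicluster(tuple(int(i) for i in rows), tuple(int(j) for j in cols)))
    return ExpressionMatrix.from_array(values), truth


def jaccard_recovery(found: Bicluster, truth: Bicluster) -> float:
    """Jaccard overlap of the two biclusters' cell sets (gene x condition).

    1 for identical biclusters, 0 for disjoint ones.  Cell counts factor
    over the index sets, so no explicit cell enumeration is needed.
    """
    genes_inter = len(set(found.genes) & set(truth.genes))
    conds_inter = len(set(found.conditions) & set(truth.conditions))
    inter = genes_inter * conds_inter
    union = found.volume + truth.volume - inter
    if union == 0:
        return 1.0 if found.volume == truth.volume == 0 else 0.0
    return inter / union
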