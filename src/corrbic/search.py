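"""Scatter Search engine for correlation-based biclustering.

Scatter Search evolves a small *reference set* of ``S`` solutions, half
chosen for quality (lowest fitness) and half for diversity (largest
Hamming distance to the quality half).  One search consists of:

1.  *Diversification generation*: a structured bit-flipping rule produces a
    population of diverse binary solutions from random seeds.
2.  *Improvement*: each bicluster is repaired by removing genes that are
    not positively correlated with the genes already retained, so only
    shifting-and-scaling (positively correlated) patterns survive.
3.  *Combination*: every unordered pair of reference-set members is
    combined with uniform crossover, giving ``S * (S - 1) / 2`` children.
4.  *Updating*: the reference set keeps the ``S`` best of the union of
    itself and the improved children; when an update changes nothing the
    set is *stable* and is rebuilt (quality half kept, diversity half
    drawn afresh from the population) to re-inject diversity.

The outer driver repeats the whole search ``numBi`` times with fresh
random substreams and returns the best bicluster of each repetition.

All randomness flows through a single :class:`numpy.random.Generator`, so
runs are reproducible from one integer seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import measures
from .measures import BiclusterScore
from .model import Bicluster, DimensionMismatchError, ExpressionMatrix, decode, encode

__all__ = [
    "SearchConfig",
    "ReferenceSet",
    "SearchTrace",
    "ShortageError",
    "diversify",
    "admissible_flip_periods",
    "generate_population",
    "improve",
    "combine",
    "combine_all",
    "select_best",
    "select_scattered",
    "scatter_search_once",
    "run",
]

logger = logging.getLogger(__name__)


class ShortageError(RuntimeError):
    """Not enough distinct candidates to fill a selection."""


@dataclass
class SearchConfig:
    """Tunable parameters of the search.

    Defaults follow the standard setting for expression data: 20 outer
    iterations, a reference set of 10, an initial population of 200 and 100
    biclusters per run.  ``m1``/``m2`` weight the volume penalties of the
    fitness function: 1 yields small, tightly correlated biclusters, 10
    trades correlation for volume.
    """

    num_biclusters: int = 100
    num_iterations: int = 20
    refset_size: int = 10
    population_size: int = 200
    m1: float = 1.0
    m2: float = 1.0
    rng_seed: int | None = None
    h_max_divisor: int = 5
    improve_mode: str = "contract"

    def __post_init__(self) -> None:
        if self.refset_size < 2 or self.refset_size % 2:
            raise ValueError("refset_size must be an even integer >= 2")
        if self.population_size <= self.refset_size:
            raise ValueError("population_size must exceed refset_size")
        if self.num_iterations < 0 or self.num_biclusters < 1:
            raise ValueError("iteration counts must be non-negative / positive")
        if self.improve_mode not in ("contract", "literal"):
            raise ValueError("improve_mode must be 'contract' or 'literal'")
        if self.m1 < 0 or self.m2 < 0:
            raise ValueError("penalty weights must be non-negative")


@dataclass(frozen=True)
class _Solution:
    """Internal search unit: encoded bits, hash key, decoded view, score."""

    bits: np.ndarray
    key: bytes
    bicluster: Bicluster
    score: BiclusterScore


@dataclass
class ReferenceSet:
    """Ordered reference set; the first S/2 members are the quality half."""

    members: list[_Solution]

    @property
    def quality_half(self) -> list[_Solution]:
        return self.members[: len(self.members) // 2]

    @property
    def diversity_half(self) -> list[_Solution]:
        return self.members[len(self.members) // 2 :]

    def keys(self) -> frozenset[bytes]:
        return frozenset(s.key for s in self.members)

    def best(self) -> _Solution:
        return min(self.members, key=lambda s: s.score.fitness)


@dataclass
class SearchTrace:
    """Optional instrumentation collected by :func:`scatter_search_once`.

    ``inner_best_fitness`` holds, per rebuild phase, the best reference-set
    fitness after each inner update; ``stable_reached`` records whether the
    inner loop reached stability; ``disjoint_ok`` whether population and
    reference set were disjoint after each (re)build.
    """

    inner_best_fitness: list[list[float]] = field(default_factory=list)
    stable_reached: list[bool] = field(default_factory=list)
    disjoint_ok: list[bool] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Diversification generation
# ---------------------------------------------------------------------------

def diversify(seed: np.ndarray, h: int) -> np.ndarray:
    """Flip every ``h``-th bit of ``seed`` starting at the first position.

    Positions ``1 + k*h`` (1-based, i.e. 0-based ``0, h, 2h, ...``) are
    complemented while they fall inside the string; all other bits are
    copied.  ``h = 1`` therefore yields the bitwise complement.
    """
    seed = np.asarray(seed, dtype=np.uint8)
    n = seed.size
    if not 1 <= h < max(n, 2):
        raise ValueError(f"flip period h={h} out of range for length {n}")
    out = seed.copy()
    idx = np.arange(0, n, h)
    out[idx] = 1 - out[idx]
    return out


def admissible_flip_periods(n_bits: int, divisor: int = 5) -> list[int]:
    """Flip periods ``h`` with ``1 <= h < n/divisor``; ``[1]`` if none fit."""
    hs = [h for h in range(1, n_bits) if h * divisor < n_bits]
    return hs or [1]


def generate_population(
    matrix: ExpressionMatrix,
    size: int,
    config: SearchConfig,
    rng: np.random.Generator,
) -> list[Bicluster]:
    """Generate ``size`` distinct biclusters by diversification generation."""
    bits = _generate_population_bits(
        matrix.n_genes + matrix.n_conditions, size, config.h_max_divisor, rng
    )
    n, l = matrix.n_genes, matrix.n_conditions
    return [decode(b, n, l) for b in bits]


def _generate_population_bits(
    n_bits: int, size: int, divisor: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Distinct bit strings: random seed -> all flip periods -> re-seed."""
    hs = admissible_flip_periods(n_bits, divisor)
    out: list[np.ndarray] = []
    seen: set[bytes] = set()
    seed = rng.integers(0, 2, size=n_bits, dtype=np.uint8)
    while len(out) < size:
        produced = False
        last = seed
        for h in hs:
            cand = diversify(seed, h)
            last = cand
            key = cand.tobytes()
            if key not in seen:
                seen.add(key)
                out.append(cand)
                produced = True
                if len(out) == size:
                    return out
        # Re-seed from the last emitted solution; if the cycle stalled
        # (every derivative already known), draw a fresh random seed.
        seed = last if produced else rng.integers(0, 2, size=n_bits, dtype=np.uint8)
    return out


# ---------------------------------------------------------------------------
# Improvement method
# ---------------------------------------------------------------------------

def improve(
    bicluster: Bicluster,
    matrix: ExpressionMatrix,
    mode: str = "contract",
) -> Bicluster:
    """Strip genes that are not positively correlated with the kept genes.

    The first gene of the bicluster anchors the result.  In ``contract``
    mode a gene is retained iff its correlation with *every* already-kept
    gene is strictly positive, which guarantees the output contract that
    all retained pairs are non-negatively correlated.  ``literal`` mode
    follows the classic sweep formulation (a rejected-set ``R`` accumulated
    over an ``i < j`` double loop), kept for traceability; it can rarely
    retain a pair whose correlation is negative against an earlier gene.
    Conditions are never modified.
    """
    if bicluster.n_genes < 2 or bicluster.n_conditions < 2:
        return bicluster
    sub = matrix.submatrix(bicluster)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(sub)
    corr = np.nan_to_num(corr, nan=0.0)
    n = bicluster.n_genes
    if mode == "contract":
        kept = [0]
        for j in range(1, n):
            if all(corr[j, k] > 0.0 for k in kept):
                kept.append(j)
    elif mode == "literal":
        kept_set = {0}
        rejected: set[int] = set()
        for i in range(n):
            for j in range(i + 1, n):
                if corr[i, j] > 0.0:
                    if j not in rejected:
                        kept_set.add(j)
                else:
                    rejected.add(j)
        kept = sorted(kept_set)
    else:
        raise ValueError(f"unknown improve mode {mode!r}")
    if len(kept) == n:
        return bicluster
    return Bicluster(
        tuple(bicluster.genes[k] for k in kept), bicluster.conditions
    )


# ---------------------------------------------------------------------------
# Combination
# ---------------------------------------------------------------------------

def combine(
    parent_a: np.ndarray, parent_b: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Uniform crossover: child takes parent_a where a random mask is 1."""
    parent_a = np.asarray(parent_a, dtype=np.uint8)
    parent_b = np.asarray(parent_b, dtype=np.uint8)
    if parent_a.shape != parent_b.shape:
        raise DimensionMismatchError("parents have different lengths")
    mask = rng.integers(0, 2, size=parent_a.size, dtype=np.uint8)
    return np.where(mask == 1, parent_a, parent_b).astype(np.uint8)


def combine_all(
    parents: Sequence[np.ndarray], rng: np.random.Generator
) -> list[np.ndarray]:
    """Combine every unordered pair: exactly ``S*(S-1)/2`` children."""
    children = []
    for i in range(len(parents)):
        for j in range(i + 1, len(parents)):
            children.append(combine(parents[i], parents[j], rng))
    return children


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def select_best(
    candidates: Sequence[Bicluster],
    k: int,
    matrix: ExpressionMatrix,
    config: SearchConfig,
) -> list[Bicluster]:
    """The ``k`` distinct candidates with lowest fitness (stable ties)."""
    n, l = matrix.n_genes, matrix.n_conditions
    seen: set[bytes] = set()
    distinct: list[Bicluster] = []
    for b in candidates:
        key = encode(b, n, l).tobytes()
        if key not in seen:
            seen.add(key)
            distinct.append(b)
    if len(distinct) < k:
        raise ShortageError(f"only {len(distinct)} distinct candidates for k={k}")
    order = sorted(
        range(len(distinct)),
        key=lambda i: (measures.fitness(distinct[i], matrix, config.m1, config.m2), i),
    )
    return [distinct[i] for i in order[:k]]


def select_scattered(
    pool: Sequence[np.ndarray],
    anchors: Sequence[np.ndarray],
    k: int,
) -> list[int]:
    """Greedy max-min Hamming selection; returns indices into ``pool``.

    Repeatedly picks the pool member whose minimum distance to the anchors
    and the already-selected members is largest; ties break toward the
    earliest pool position.
    """
    if k > len(pool):
        raise ShortageError(f"pool of {len(pool)} cannot supply k={k}")
    if k == 0:
        return []
    P = np.stack([np.asarray(p, dtype=np.uint8) for p in pool])
    if anchors:
        A = np.stack([np.asarray(a, dtype=np.uint8) for a in anchors])
        min_dist = (P[:, None, :] != A[None, :, :]).sum(axis=2).min(axis=1)
    else:
        min_dist = np.full(len(pool), np.iinfo(np.int64).max, dtype=np.int64)
    chosen: list[int] = []
    taken = np.zeros(len(pool), dtype=bool)
    for _ in range(k):
        masked = np.where(taken, -1, min_dist)
        i = int(np.argmax(masked))  # argmax returns the first maximum
        chosen.append(i)
        taken[i] = True
        d = (P != P[i]).sum(axis=1)
        min_dist = np.minimum(min_dist, d)
    return chosen


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------

class _Engine:
    """One Scatter Search run over a fixed matrix/config/random stream."""

    MAX_INNER_UPDATES = 10_000  # safety net; stability is provably finite

    def __init__(
        self,
        matrix: ExpressionMatrix,
        config: SearchConfig,
        rng: np.random.Generator,
        trace: SearchTrace | None = None,
    ) -> None:
        self.matrix = matrix
        self.config = config
        self.rng = rng
        self.trace = trace
        self.n_bits = matrix.n_genes + matrix.n_conditions
        self._cache: dict[bytes, _Solution] = {}  # raw bits -> improved solution

    # -- solution pipeline --------------------------------------------------

    def _pipeline(self, raw_bits: np.ndarray) -> _Solution:
        """decode -> improve -> re-encode -> score, memoised on raw bits."""
        raw_key = raw_bits.tobytes()
        sol = self._cache.get(raw_key)
        if sol is not None:
            return sol
        bic = decode(raw_bits, self.matrix.n_genes, self.matrix.n_conditions)
        bic = improve(bic, self.matrix, self.config.improve_mode)
        bits = encode(bic, self.matrix.n_genes, self.matrix.n_conditions)
        sc = measures.score(bic, self.matrix, self.config.m1, self.config.m2)
        sol = _Solution(bits, bits.tobytes(), bic, sc)
        self._cache[raw_key] = sol
        return sol

    def _fresh_population(self, exclude: frozenset[bytes]) -> list[_Solution]:
        """Generate, improve and deduplicate a population of solutions."""
        pop: list[_Solution] = []
        seen = set(exclude)
        attempts = 0
        while len(pop) < self.config.population_size and attempts < 50:
            bits_list = _generate_population_bits(
                self.n_bits,
                self.config.population_size,
                self.config.h_max_divisor,
                self.rng,
            )
            for bits in bits_list:
                sol = self._pipeline(bits)
                if sol.key not in seen:
                    seen.add(sol.key)
                    pop.append(sol)
                    if len(pop) == self.config.population_size:
                        break
            attempts += 1
        return pop

    # -- reference set ------------------------------------------------------

    @staticmethod
    def _k_best(solutions: Sequence[_Solution], k: int) -> list[_Solution]:
        order = sorted(range(len(solutions)), key=lambda i: (solutions[i].score.fitness, i))
        return [solutions[i] for i in order[:k]]

    def _build_refset(self, pop: list[_Solution]) -> tuple[ReferenceSet, list[_Solution]]:
        """Quality half from the population, diversity half by max-min distance."""
        half = self.config.refset_size // 2
        r1 = self._k_best(pop, half)
        r1_keys = {s.key for s in r1}
        remainder = [s for s in pop if s.key not in r1_keys]
        if len(remainder) < half:
            remainder += self._fresh_population(
                frozenset(r1_keys | {s.key for s in remainder})
            )
        idx = select_scattered(
            [s.bits for s in remainder], [s.bits for s in r1], half
        )
        r2 = [remainder[i] for i in idx]
        refset = ReferenceSet(r1 + r2)
        pop = [s for s in remainder if s.key not in refset.keys()]
        if self.trace is not None:
            self.trace.disjoint_ok.append(
                not (refset.keys() & {s.key for s in pop})
            )
        return refset, pop

    def _update_until_stable(self, refset: ReferenceSet) -> ReferenceSet:
        """Combine/improve/keep-best until the reference set stops changing."""
        fitness_log: list[float] = []
        stable = False
        for _ in range(self.MAX_INNER_UPDATES):
            before = refset.keys()
            children_bits = combine_all([s.bits for s in refset.members], self.rng)
            children = [self._pipeline(b) for b in children_bits]
            candidates = list(refset.members) + children
            seen: set[bytes] = set()
            distinct = []
            for s in candidates:
                if s.key not in seen:
                    seen.add(s.key)
                    distinct.append(s)
            refset = ReferenceSet(self._k_best(distinct, self.config.refset_size))
            fitness_log.append(refset.best().score.fitness)
            if refset.keys() == before:
                stable = True
                break
        if self.trace is not None:
            self.trace.inner_best_fitness.append(fitness_log)
            self.trace.stable_reached.append(stable)
        return refset

    def _rebuild_refset(
        self, refset: ReferenceSet, pop: list[_Solution]
    ) -> tuple[ReferenceSet, list[_Solution]]:
        """Keep the quality half, redraw the diversity half from the population."""
        half = self.config.refset_size // 2
        r1 = self._k_best(refset.members, half)
        r1_keys = {s.key for s in r1}
        pool = [s for s in pop if s.key not in r1_keys]
        if len(pool) < half:
            pool += self._fresh_population(
                frozenset(r1_keys | {s.key for s in pool})
            )
        idx = select_scattered([s.bits for s in pool], [s.bits for s in r1], half)
        r2 = [pool[i] for i in idx]
        new_refset = ReferenceSet(r1 + r2)
        pop = [s for s in pool if s.key not in new_refset.keys()]
        if self.trace is not None:
            self.trace.disjoint_ok.append(
                not (new_refset.keys() & {s.key for s in pop})
            )
        return new_refset, pop

    # -- main loop -----------------------------------------------------------

    def search_once(self) -> Bicluster:
        pop = self._fresh_population(frozenset())
        refset, pop = self._build_refset(pop)
        for i in range(self.config.num_iterations):
            refset = self._update_until_stable(refset)
            refset, pop = self._rebuild_refset(refset, pop)
            logger.debug(
                "iteration %d: best fitness %.6g, population %d",
                i + 1,
                refset.best().score.fitness,
                len(pop),
            )
        return refset.best().bicluster


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def scatter_search_once(
    matrix: ExpressionMatrix,
    config: SearchConfig,
    rng: np.random.Generator | int | None = None,
    trace: SearchTrace | None = None,
) -> Bicluster:
    """Run one full Scatter Search and return its best bicluster.

    Deterministic given the generator state.  With ``num_iterations = 0``
    the best member of the initially built reference set is returned.
    """
    if rng is None:
        rng = config.rng_seed
    engine = _Engine(matrix, config, _as_rng(rng), trace)
    return engine.search_once()


def run(
    matrix: ExpressionMatrix,
    config: SearchConfig,
    rng: np.random.Generator | int | None = None,
) -> list[Bicluster]:
    """Repeat the search ``num_biclusters`` times with fresh substreams.

    Each repetition starts from a new population drawn from its own child
    stream of ``rng``, so the result list is reproducible from one seed.
    """
    if rng is None:
        rng = config.rng_seed
    parent = _as_rng(rng)
    results: list[Bicluster] = []
    for i, sub in enumerate(parent.spawn(config.num_biclusters)):
        best = scatter_search_once(matrix, config, sub)
        fit = measures.fitness(best, matrix, config.m1, config.m2)
        logger.info(
            "bicluster %d/%d: %d genes x %d conditions, fitness %.6g",
            i + 1,
            config.num_biclusters,
            best.n_genes,
            best.n_conditions,
            fit,
        )
        results.append(best)
    return results
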