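"""Diversification, improvement, combination, selection and the full search."""

import numpy as np
import pytest

import corrbic as cb
from corrbic.model import bits_from_str, bits_to_str
from corrbic.search import ShortageError, admissible_flip_periods


class FixedMaskRng:
    """Stands in for a Generator when a crossover mask must be forced."""

    def __init__(self, mask):
        self.mask = np.asarray(mask, dtype=np.uint8)

    def integers(self, low, high, size=None, dtype=None):
        assert size == self.mask.size
        return self.mask


def perfect_pattern_matrix(rng, n_genes=6, n_conditions=5, negate=()):
    """Genes that are positive (or, for listed rows, negative) affine maps of one profile."""
    profile = rng.normal(size=n_conditions)
    rows = []
    for i in range(n_genes):
        a = rng.uniform(0.5, 3.0) * (-1 if i in negate else 1)
        rows.append(a * profile + rng.normal(0, 2))
    return cb.ExpressionMatrix.from_array(np.array(rows))


class TestDiversify:
    @pytest.mark.parametrize(
        "h,expected",
        [
            (1, "1111111111"),
            (2, "1010101010"),
            (3, "1001001001"),
        ],
    )
    def test_flip_rule_on_zero_seed(self, h, expected):
        out = cb.diversify(np.zeros(10, dtype=np.uint8), h)
        assert bits_to_str(out) == expected

    def test_non_flipped_bits_copied(self):
        seed = bits_from_str("0110010111")
        out = cb.diversify(seed, 3)
        flipped = {0, 3, 6, 9}
        for i in range(10):
            if i in flipped:
                assert out[i] == 1 - seed[i]
            else:
                assert out[i] == seed[i]

    def test_out_of_range_h_rejected(self):
        with pytest.raises(ValueError):
            cb.diversify(np.zeros(10, dtype=np.uint8), 0)

    def test_admissible_periods_respect_strict_bound(self):
        assert admissible_flip_periods(70) == list(range(1, 14))  # h < 70/5 = 14
        assert admissible_flip_periods(10) == [1]
        assert admissible_flip_periods(4) == [1]  # fallback for tiny strings


class TestGeneratePopulation:
    def test_size_and_distinctness(self, small_matrix):
        cfg = cb.SearchConfig(population_size=30, refset_size=4)
        pop = cb.generate_population(small_matrix, 30, cfg, np.random.default_rng(0))
        assert len(pop) == 30
        keys = {cb.encode(b, 6, 5).tobytes() for b in pop}
        assert len(keys) == 30

    def test_deterministic_given_seed(self, small_matrix):
        cfg = cb.SearchConfig(population_size=20, refset_size=4)
        a = cb.generate_population(small_matrix, 20, cfg, np.random.default_rng(7))
        b = cb.generate_population(small_matrix, 20, cfg, np.random.default_rng(7))
        assert a == b


class TestImprove:
    def test_removes_the_negatively_correlated_gene(self, rng):
        # three mutually positively correlated genes plus one anti-correlated
        m = perfect_pattern_matrix(rng, n_genes=4, negate={3})
        b = cb.Bicluster((0, 1, 2, 3), tuple(range(5)))
        out = cb.improve(b, m)
        assert out.genes == (0, 1, 2)
        assert cb.avg_correlation(out, m) == pytest.approx(1.0, abs=1e-9)

    def test_all_positive_returned_unchanged(self, rng):
        m = perfect_pattern_matrix(rng, n_genes=5)
        b = cb.Bicluster(tuple(range(5)), tuple(range(5)))
        assert cb.improve(b, m) == b

    def test_anti_correlated_pair_keeps_first_gene(self):
        m = cb.ExpressionMatrix.from_array(np.array([[1.0, 2, 3], [3.0, 2, 1]]))
        out = cb.improve(cb.Bicluster((0, 1), (0, 1, 2)), m)
        assert out.genes == (0,)

    def test_conditions_never_change(self, rng):
        m = cb.ExpressionMatrix.from_array(rng.normal(size=(8, 6)))
        b = cb.Bicluster(tuple(range(8)), (0, 2, 5))
        assert cb.improve(b, m).conditions == (0, 2, 5)

    def test_literal_mode_on_the_four_gene_case(self, rng):
        m = perfect_pattern_matrix(rng, n_genes=4, negate={3})
        b = cb.Bicluster((0, 1, 2, 3), tuple(range(5)))
        out = cb.improve(b, m, mode="literal")
        assert out.genes == (0, 1, 2)

    def test_retained_pairs_all_non_negative(self, rng):
        # output contract, checked over random biclusters
        m = cb.ExpressionMatrix.from_array(rng.normal(size=(12, 8)))
        for _ in range(25):
            genes = tuple(rng.choice(12, size=rng.integers(2, 10), replace=False))
            conds = tuple(rng.choice(8, size=rng.integers(2, 7), replace=False))
            out = cb.improve(cb.Bicluster(genes, conds), m)
            if out.n_genes >= 2:
                coeffs = cb.measures.pairwise_correlations(out, m)
                assert (coeffs >= 0).all()


class TestCombine:
    def test_mask_selects_between_parents(self):
        a = bits_from_str("0000")
        b = bits_from_str("1111")
        child = cb.combine(a, b, FixedMaskRng(bits_from_str("1010")))
        assert bits_to_str(child) == "0101"

    def test_all_ones_mask_copies_first_parent(self):
        a = bits_from_str("0110")
        b = bits_from_str("1001")
        assert bits_to_str(cb.combine(a, b, FixedMaskRng([1, 1, 1, 1]))) == "0110"
        assert bits_to_str(cb.combine(a, b, FixedMaskRng([0, 0, 0, 0]))) == "1001"

    def test_length_mismatch_rejected(self):
        with pytest.raises(cb.DimensionMismatchError):
            cb.combine(bits_from_str("00"), bits_from_str("000"), np.random.default_rng(0))

    @pytest.mark.parametrize("s,expected", [(2, 1), (5, 10), (10, 45)])
    def test_combine_all_child_count(self, s, expected):
        parents = [np.zeros(8, dtype=np.uint8) for _ in range(s)]
        rng = np.random.default_rng(3)
        assert len(cb.combine_all(parents, rng)) == expected
        # count is a structural property, independent of the rng state
        assert len(cb.combine_all(parents, rng)) == expected


class TestSelection:
    def test_select_best_orders_by_fitness(self, rng):
        m = perfect_pattern_matrix(rng, n_genes=6, n_conditions=6, negate={5})
        good = cb.Bicluster((0, 1, 2, 3), tuple(range(6)))   # perfect pattern
        medium = cb.Bicluster((0, 1), (0, 1, 2))             # perfect but tiny
        bad = cb.Bicluster((0, 5), tuple(range(6)))          # anti-correlated pair
        cfg = cb.SearchConfig(refset_size=2, population_size=10)
        out = cb.select_best([bad, medium, good], 2, m, cfg)
        assert out == [good, medium]

    def test_select_best_collapses_duplicates(self, rng, small_matrix):
        b = cb.Bicluster((0, 1), (0, 1))
        cfg = cb.SearchConfig(refset_size=2, population_size=10)
        with pytest.raises(ShortageError):
            cb.select_best([b, b, b], 2, small_matrix, cfg)

    def test_select_scattered_max_min_distance(self):
        anchors = [bits_from_str("0000")]
        pool = [bits_from_str(s) for s in ("1111", "0001", "1110")]
        assert cb.select_scattered(pool, anchors, 1) == [0]
        # second pick: "0001" and "1110" tie at min-distance 1; input order wins
        assert cb.select_scattered(pool, anchors, 2) == [0, 1]

    def test_select_scattered_shortage(self):
        with pytest.raises(ShortageError):
            cb.select_scattered([bits_from_str("01")], [], 2)


def desk_case(seed):
    rng = np.random.default_rng(seed)
    matrix, truth = cb.make_matrix(30, 12, [cb.ImplantSpec(6, 5)], rng=rng)
    return matrix, truth[0], rng


class TestScatterSearch:
    CFG = dict(num_iterations=4, refset_size=6, population_size=40)

    def test_deterministic_given_equal_seeds(self):
        matrix, _, _ = desk_case(0)
        cfg = cb.SearchConfig(**self.CFG)
        a = cb.scatter_search_once(matrix, cfg, np.random.default_rng(5))
        b = cb.scatter_search_once(matrix, cfg, np.random.default_rng(5))
        assert a == b

    def test_zero_iterations_returns_initial_refset_best(self):
        matrix, _, _ = desk_case(1)
        cfg = cb.SearchConfig(num_iterations=0, refset_size=6, population_size=40)
        best = cb.scatter_search_once(matrix, cfg, np.random.default_rng(2))
        assert isinstance(best, cb.Bicluster)
        assert np.isfinite(cb.fitness(best, matrix))

    def test_search_invariants_hold(self):
        """Monotone best fitness, guaranteed stability, refset/population disjointness."""
        matrix, _, rng = desk_case(2)
        trace = cb.SearchTrace()
        cb.scatter_search_once(matrix, cb.SearchConfig(**self.CFG), rng, trace=trace)
        assert trace.stable_reached and all(trace.stable_reached)
        assert trace.disjoint_ok and all(trace.disjoint_ok)
        for phase in trace.inner_best_fitness:
            assert all(b <= a + 1e-12 for a, b in zip(phase, phase[1:]))

    def test_run_returns_requested_count_deterministically(self):
        matrix, _, _ = desk_case(3)
        cfg = cb.SearchConfig(num_biclusters=3, **self.CFG)
        a = cb.run(matrix, cfg, np.random.default_rng(9))
        b = cb.run(matrix, cfg, np.random.default_rng(9))
        assert len(a) == 3 and a == b

    def test_best_bicluster_is_highly_correlated(self):
        matrix, _, rng = desk_case(4)
        best = cb.scatter_search_once(matrix, cb.SearchConfig(**self.CFG), rng)
        assert cb.avg_correlation(best, matrix) >= 0.95

    def test_restart_protocol_recovers_implants(self):
        """Best-of-restarts (lowest fitness) recovers the implanted gene set."""
        hits = 0
        for seed in range(3):
            rng = np.random.default_rng(seed)
            matrix, truth = cb.make_matrix(50, 20, [cb.ImplantSpec(8, 6)], rng=rng)
            results = cb.run(matrix, cb.SearchConfig(num_biclusters=20), rng)
            best = min(results, key=lambda b: cb.fitness(b, matrix))
            found, true = set(best.genes), set(truth[0].genes)
            if len(found & true) / len(found | true) > 0.5:
                hits += 1
        assert hits >= 2
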