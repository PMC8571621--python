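import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import landfuse as lf
from landfuse.errors import GridAlignmentError
from landfuse.infovolume import InfoVolumeResult


def grid_of(values, nodata=-9999.0):
    return lf.Grid(np.asarray(values, dtype=np.float64), nodata=nodata)


def entropy2(counts):
    n = sum(counts)
    return -sum((k / n) * math.log2(k / n) for k in counts if k)


class TestQuantize:
    def test_endpoints_and_midpoint(self):
        grid = grid_of([[0.0, 5.0, 10.0]])
        q = lf.quantize_surface(grid, 4)
        np.testing.assert_array_equal(q.values, [[0, 5000, 10000]])

    def test_constant_surface_all_zero(self):
        q = lf.quantize_surface(grid_of([[3.0, 3.0, 3.0]]))
        np.testing.assert_array_equal(q.values, 0)

    def test_round_half_up_not_bankers(self):
        # 0.0005 normalizes to 0.00005 -> 0.5 at 4 decimals -> symbol 1
        q = lf.quantize_surface(grid_of([[0.0, 0.0005, 10.0]]), 4)
        assert q.values[0, 1] == 1

    def test_nodata_keeps_sentinel(self):
        q = lf.quantize_surface(grid_of([[0.0, -9999.0, 1.0]]))
        assert q.values[0, 1] == -1
        assert not q.valid_mask[0, 1]

    def test_nonpositive_decimals_rejected(self):
        with pytest.raises(ValueError):
            lf.quantize_surface(grid_of([[0.0, 1.0]]), 0)


class TestHuffman:
    def test_three_symbol_example(self):
        book = lf.huffman_codebook({10: 2, 20: 1, 30: 1})
        assert book.code_length == {10: 1, 20: 2, 30: 2}

    def test_equal_counts_balanced_tree(self):
        book = lf.huffman_codebook({s: 5 for s in range(4)})
        assert set(book.code_length.values()) == {2}

    def test_single_symbol_convention(self):
        assert lf.huffman_codebook({7: 100}).code_length == {7: 1}

    def test_zero_count_symbols_get_no_code(self):
        book = lf.huffman_codebook({1: 3, 2: 0, 3: 2})
        assert 2 not in book.code_length

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            lf.huffman_codebook({})

    @given(
        counts=st.lists(st.integers(1, 500), min_size=2, max_size=40)
    )
    @settings(max_examples=100, deadline=None)
    def test_kraft_equality_and_entropy_bound(self, counts):
        book = lf.huffman_codebook(dict(enumerate(counts)))
        assert book.kraft_sum() == pytest.approx(1.0, abs=1e-12)
        h2 = entropy2(counts)
        assert h2 - 1e-9 <= book.mean_code_length < h2 + 1.0

    def test_beats_random_prefix_codes(self):
        """Optimality against shuffled full-binary-tree adversaries."""
        rng = np.random.default_rng(31)
        for _ in range(50):
            n_sym = int(rng.integers(2, 12))
            counts = {s: int(rng.integers(1, 100)) for s in range(n_sym)}
            book = lf.huffman_codebook(counts)
            total = sum(counts.values())
            for _ in range(5):
                depths = _random_tree_depths(list(counts), rng)
                adversary = (
                    sum(counts[s] * d for s, d in depths.items()) / total
                )
                assert book.mean_code_length <= adversary + 1e-12


def _random_tree_depths(symbols, rng):
    """Code lengths of a random full binary tree over the symbols."""
    if len(symbols) == 1:
        return {symbols[0]: 0}
    perm = list(symbols)
    rng.shuffle(perm)
    k = int(rng.integers(1, len(perm)))
    left = _random_tree_depths(perm[:k], rng)
    right = _random_tree_depths(perm[k:], rng)
    return {s: d + 1 for s, d in {**left, **right}.items()}


class TestInfoVolume:
    def test_total_bits_from_codebook_example(self):
        # 4 cells quantizing to counts {2, 1, 1} -> 2*1 + 1*2 + 1*2 = 6 bits
        grid = grid_of([[0.0, 0.0, 0.5, 1.0]])
        result = lf.info_volume(grid)
        assert result.total_bits == 6
        assert result.mean_bits_per_cell == 1.5

    def test_constant_surface_one_bit_per_cell(self):
        result = lf.info_volume(grid_of(np.full((5, 4), 2.5)))
        assert result.total_bits == 20

    def test_uniform_four_symbols_two_bits_per_cell(self):
        grid = grid_of([[0.0, 0.25, 0.5, 1.0]] * 3)
        assert lf.info_volume(grid).total_bits == 24

    def test_entropy_bound_on_mean_bits(self):
        rng = np.random.default_rng(33)
        grid = grid_of(rng.choice([0.0, 1.0, 2.0, 5.0, 9.0], size=(20, 20)))
        result = lf.info_volume(grid)
        counts = list(result.codebook.counts.values())
        h2 = entropy2(counts)
        assert h2 - 1e-9 <= result.mean_bits_per_cell < h2 + 1.0

    @pytest.mark.parametrize("scale,shift", [(2.0, 0.0), (8.0, 3.0), (0.25, -1.0)])
    def test_affine_rescaling_invariance(self, scale, shift):
        rng = np.random.default_rng(34)
        vals = rng.normal(size=(15, 15))
        base = lf.info_volume(grid_of(vals))
        rescaled = lf.info_volume(grid_of(vals * scale + shift))
        assert rescaled.total_bits == base.total_bits


class TestDegreeOfChanges:
    def test_identical_surfaces_zero(self):
        a = grid_of([[0.0, 1.0, 2.0]])
        doc = lf.degree_of_changes(a, a)
        np.testing.assert_allclose(doc.values, 0.0)

    def test_constant_baseline_returns_normalized_other(self):
        a = grid_of([[0.0, 2.0, 4.0]])
        b = grid_of([[7.0, 7.0, 7.0]])
        doc = lf.degree_of_changes(a, b)
        np.testing.assert_allclose(doc.values, [[0.0, 0.5, 1.0]])

    def test_opposed_two_cell_surfaces(self):
        doc = lf.degree_of_changes(grid_of([[0.0, 1.0]]), grid_of([[1.0, 0.0]]))
        np.testing.assert_allclose(doc.values, [[1.0, 1.0]])

    def test_bounded_and_symmetric(self):
        rng = np.random.default_rng(35)
        a, b = grid_of(rng.normal(size=(9, 9))), grid_of(rng.normal(size=(9, 9)))
        d1, d2 = lf.degree_of_changes(a, b), lf.degree_of_changes(b, a)
        assert (d1.values >= 0.0).all() and (d1.values <= 1.0).all()
        np.testing.assert_allclose(d1.values, d2.values)

    def test_shape_mismatch(self):
        with pytest.raises(GridAlignmentError):
            lf.degree_of_changes(grid_of([[0.0]]), grid_of([[0.0, 1.0]]))


class TestSurfaceCorrelation:
    def test_identity_and_antisymmetry(self):
        rng = np.random.default_rng(36)
        vals = rng.normal(size=(8, 8))
        a = grid_of(vals)
        assert lf.surface_correlation(a, a) == pytest.approx(1.0)
        assert lf.surface_correlation(a, grid_of(-vals)) == pytest.approx(-1.0)

    def test_textbook_four_point_value(self):
        a = grid_of([[1.0, 2.0, 3.0, 4.0]])
        b = grid_of([[1.0, 2.0, 3.0, 5.0]])
        assert lf.surface_correlation(a, b) == pytest.approx(0.982708, abs=1e-6)

    def test_zero_variance_flagged_none(self):
        a = grid_of([[1.0, 2.0, 3.0]])
        assert lf.surface_correlation(a, grid_of([[5.0, 5.0, 5.0]])) is None

    def test_too_few_shared_cells_flagged(self):
        a = grid_of([[1.0, -9999.0]])
        b = grid_of([[2.0, 3.0]])
        assert lf.surface_correlation(a, b) is None


def _iv_from_bits(bits):
    grid = grid_of(bits)
    valid = grid.valid_mask
    total = int(grid.values[valid].sum())
    book = lf.huffman_codebook({0: 1})
    return InfoVolumeResult(grid, total, total / valid.sum(), book)


class TestCompareInfoVolume:
    def test_identity(self):
        x = _iv_from_bits([[1.0, 2.0, 2.0]])
        cmp_ = lf.compare_info_volume(x, x)
        assert cmp_.ra == 0.0
        assert cmp_.rv is None
        np.testing.assert_allclose(cmp_.div.masked_values(), 0.0)

    def test_strict_dominance(self):
        x = _iv_from_bits([[3.0, 4.0]])
        y = _iv_from_bits([[1.0, 2.0]])
        cmp_ = lf.compare_info_volume(x, y)
        assert cmp_.ra == 1.0
        assert cmp_.rv == 1.0
        assert cmp_.totals_ratio == pytest.approx(7 / 3)

    def test_mixed_differences(self):
        x = _iv_from_bits([[3.0, 1.0, 3.0, 2.0]])
        y = _iv_from_bits([[1.0, 2.0, 2.0, 2.0]])
        cmp_ = lf.compare_info_volume(x, y)  # DIV = +2, -1, +1, 0
        assert cmp_.ra == 0.5
        assert cmp_.rv == pytest.approx(3 / 4)
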