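"""SCN and alternative normalizations, filtering, correlation, binning, blur."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scn3c import normalize as nz
from scn3c.biases import DistanceExpectation

from conftest import make_frag_table


def cm(values, index=None, scope="all"):
    values = np.asarray(values, dtype=float)
    if index is None:
        index = np.arange(values.shape[0])
    return nz.ContactMatrix(values, index, scope=scope)


def random_symmetric(n, rng, lo=0.5, hi=1.0):
    a = rng.uniform(lo, hi, (n, n))
    return (a + a.T) / 2


def scn_oracle(values, tol=1e-12, max_iter=10_000):
    """Independent brute-force sweep loop, run to machine-level balance."""
    v = values.astype(float).copy()
    for _ in range(max_iter):
        v = v / np.linalg.norm(v, axis=0)[None, :]
        v = v / np.linalg.norm(v, axis=1)[:, None]
        cols = np.linalg.norm(v, axis=0)
        rows = np.linalg.norm(v, axis=1)
        if max(np.abs(cols - 1).max(), np.abs(rows - 1).max()) < tol:
            return (v + v.T) / 2
    raise AssertionError("oracle failed to converge")


class TestLowNormFilter:
    def test_norm_arithmetic_removes_exactly_the_middle(self):
        # rows engineered to have Euclidean norms 50, 29, 31
        v = np.diag([50.0, 29.0, 31.0])
        out = nz.filter_low_norm(cm(v), threshold=30)
        assert list(out.index) == [0, 2]
        assert out.metadata["low_norm_removed"] == 1

    def test_zero_row_removed_at_any_positive_threshold(self):
        v = np.array([[1.0, 1, 0], [1, 1, 0], [0, 0, 0]])
        out = nz.filter_low_norm(cm(v), threshold=0.5)
        assert 2 not in out.index

    def test_threshold_zero_is_identity(self):
        rng = np.random.default_rng(0)
        v = random_symmetric(6, rng)
        out = nz.filter_low_norm(cm(v), threshold=0)
        np.testing.assert_array_equal(out.values, v)

    def test_all_removed_is_fatal(self):
        with pytest.raises(nz.DegenerateMatrixError):
            nz.filter_low_norm(cm(np.ones((3, 3))), threshold=1e6)


class TestSCN:
    def test_all_ones_two_by_two(self):
        out, sweeps = nz.scn(cm(np.ones((2, 2))))
        np.testing.assert_allclose(out.values, np.full((2, 2), 1 / np.sqrt(2)))
        assert sweeps == 1

    def test_identity_is_fixed_point(self):
        out, sweeps = nz.scn(cm(np.eye(4)))
        np.testing.assert_array_equal(out.values, np.eye(4))
        assert sweeps == 0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            v = random_symmetric(5, rng, 0.2, 2.0)
            out, _ = nz.scn(cm(v), tol=1e-9, max_iter=500)
            np.testing.assert_allclose(out.values, scn_oracle(v), atol=1e-6)

    def test_output_is_balanced_and_symmetric(self):
        rng = np.random.default_rng(1)
        out, _ = nz.scn(cm(random_symmetric(20, rng)), tol=1e-6, max_iter=200)
        assert out.check_symmetric()
        assert np.abs(np.linalg.norm(out.values, axis=0) - 1).max() < 1e-5
        assert np.abs(np.linalg.norm(out.values, axis=1) - 1).max() < 1e-5

    def test_fixed_point_of_one_further_sweep(self):
        rng = np.random.default_rng(7)
        out, _ = nz.scn(cm(random_symmetric(10, rng)), tol=1e-8, max_iter=500)
        again, sweeps = nz.scn(out, tol=1e-6)
        assert sweeps == 0
        np.testing.assert_allclose(again.values, out.values, atol=1e-9)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(min_value=1e-6, max_value=1e6), st.integers(0, 2**31 - 1))
    def test_scale_invariance(self, scale, seed):
        """SCN output does not depend on a global rescaling of the counts."""
        rng = np.random.default_rng(seed)
        v = random_symmetric(6, rng)
        a, _ = nz.scn(cm(v), tol=1e-8, max_iter=500)
        b, _ = nz.scn(cm(v * scale), tol=1e-8, max_iter=500)
        np.testing.assert_allclose(a.values, b.values, atol=1e-7)

    def test_zero_pattern_preserved(self):
        v = np.array(
            [[2.0, 1, 0, 1], [1, 2, 1, 0], [0, 1, 2, 1], [1, 0, 1, 2]]
        )
        out, _ = nz.scn(cm(v), tol=1e-8, max_iter=500)
        np.testing.assert_array_equal(out.values == 0, v == 0)

    def test_zero_row_is_fatal_with_index(self):
        v = np.ones((3, 3))
        v[1, :] = 0
        v[:, 1] = 0
        with pytest.raises(nz.DegenerateMatrixError, match="index 1"):
            nz.scn(cm(v))

    def test_bipartite_block_structure_raises_convergence_error(self):
        """A two-block checkerboard (the 2-chromosome inter pattern) has no
        L2-balanced symmetric limit; the failure is reported, not silent."""
        rng = np.random.default_rng(3)
        b = rng.uniform(0.5, 1.0, (4, 6))
        v = np.zeros((10, 10))
        v[:4, 4:] = b
        v[4:, :4] = b.T
        with pytest.raises(nz.ConvergenceError):
            nz.scn(cm(v), max_iter=50)


class TestSinglePassAlternatives:
    def test_norm_product_all_ones(self):
        out = nz.norm_product(cm(np.ones((2, 2))))
        np.testing.assert_allclose(out.values, np.full((2, 2), 0.5))
        # marginal norms are not one: this is the argument for SCN
        assert np.linalg.norm(out.values, axis=1)[0] == pytest.approx(1 / np.sqrt(2))

    def test_norm_product_close_to_scn_on_well_conditioned_input(self):
        rng = np.random.default_rng(5)
        v = random_symmetric(30, rng, 0.8, 1.2)
        a, _ = nz.scn(cm(v), tol=1e-8, max_iter=500)
        b = nz.norm_product(cm(v))
        ratio = a.values / b.values
        assert ratio.std() / ratio.mean() < 0.05

    def test_marginal_sum_all_ones(self):
        out = nz.marginal_sum(cm(np.ones((2, 2))))
        np.testing.assert_allclose(out.values, np.full((2, 2), 0.25))

    def test_marginal_sum_constant_on_doubly_stochastic(self):
        v = np.array([[0.5, 0.5], [0.5, 0.5]])
        out = nz.marginal_sum(cm(v))
        np.testing.assert_allclose(out.values, v / 1.0)

    def test_marginal_sum_has_lower_contrast_than_scn(self):
        """On a structured map the sum-based normalization compresses the
        dynamic range relative to SCN."""
        rng = np.random.default_rng(11)
        v = random_symmetric(40, rng, 0.2, 1.0)
        hot = rng.choice(40, 8, replace=False)
        v[np.ix_(hot, hot)] *= 6.0
        v = (v + v.T) / 2
        a, _ = nz.scn(cm(v), tol=1e-8, max_iter=500)
        b = nz.marginal_sum(cm(v))
        off = ~np.eye(40, dtype=bool)

        def contrast(x):
            return x[off].std() / x[off].mean()

        assert contrast(b.values) < contrast(a.values)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.floats(min_value=1e-4, max_value=1e4), st.integers(0, 2**31 - 1))
    def test_single_pass_scale_invariance(self, scale, seed):
        """Rescaling the counts rescales the single-pass outputs globally:
        the normalized map is unchanged up to one constant (all rankings
        and ratios are preserved)."""
        rng = np.random.default_rng(seed)
        v = random_symmetric(5, rng)
        for op in (nz.norm_product, nz.marginal_sum):
            a = op(cm(v)).values
            b = op(cm(v * scale)).values
            np.testing.assert_allclose(a / a.sum(), b / b.sum(), atol=1e-12)


class TestDistanceNormalize:
    def _setup(self):
        frags = make_frag_table({"chr1": [1000] * 30})
        mids = ((frags.df["start"] + frags.df["end"]) // 2).to_numpy()
        dg = np.abs(mids[:, None] - mids[None, :]).astype(float)
        exp = DistanceExpectation(
            bin_edges=np.array([1.0, 1e5]),
            n_possible=np.array([1]),
            n_reads=np.array([1]),
            coeffs=np.array([-1.0, 6.0]),  # E(D) = 1e6 / D
            domain=(1.0, 1e5),
        )
        return frags, mids, dg, exp

    def test_counts_equal_to_expectation_become_ones(self):
        frags, mids, dg, exp = self._setup()
        values = np.where(dg > 0, 1e6 / np.maximum(dg, 1.0), 0.0)
        out = nz.distance_normalize(cm(values, frags.df["fragment_id"].to_numpy(), "intra"), exp, frags)
        off = ~np.eye(30, dtype=bool)
        np.testing.assert_allclose(out.values[off], 1.0)

    def test_linearity(self):
        frags, mids, dg, exp = self._setup()
        rng = np.random.default_rng(0)
        values = random_symmetric(30, rng)
        a = nz.distance_normalize(cm(values, frags.df["fragment_id"].to_numpy(), "intra"), exp, frags)
        b = nz.distance_normalize(cm(2 * values, frags.df["fragment_id"].to_numpy(), "intra"), exp, frags)
        np.testing.assert_allclose(b.values, 2 * a.values)

    def test_planted_enrichment_preserved(self):
        """A distance-independent enrichment between two loci survives
        distance normalization with its ratio intact."""
        frags, mids, dg, exp = self._setup()
        values = np.where(dg > 0, 1e6 / np.maximum(dg, 1.0), 0.0)
        values[3, 20] *= 5.0
        values[20, 3] *= 5.0
        out = nz.distance_normalize(cm(values, frags.df["fragment_id"].to_numpy(), "intra"), exp, frags)
        assert out.values[3, 20] == pytest.approx(5.0)

    def test_inter_scope_rejected(self):
        frags, mids, dg, exp = self._setup()
        with pytest.raises(ValueError):
            nz.distance_normalize(cm(np.ones((30, 30)), frags.df["fragment_id"].to_numpy(), "inter"), exp, frags)


class TestCorrelationMap:
    def test_identical_rows_correlate_to_one(self):
        v = np.array([[1.0, 2, 3, 1], [1, 2, 3, 1], [3, 1, 0, 2], [0, 1, 2, 0]])
        out = nz.correlation_map(cm(v))
        assert out.values[0, 1] == pytest.approx(1.0)
        assert np.diag(out.values) == pytest.approx(1.0)

    def test_matches_direct_pearson_formula(self):
        rng = np.random.default_rng(9)
        v = rng.uniform(0, 5, (4, 4))
        out = nz.correlation_map(cm(v))
        for i in range(4):
            for j in range(4):
                x, y = v[i], v[j]
                num = ((x - x.mean()) * (y - y.mean())).sum()
                den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
                if i == j:
                    assert out.values[i, j] == 1.0
                else:
                    assert out.values[i, j] == pytest.approx(num / den)

    def test_values_bounded(self):
        rng = np.random.default_rng(2)
        out = nz.correlation_map(cm(rng.uniform(0, 1, (10, 10))))
        assert (np.abs(out.values) <= 1 + 1e-12).all()

    def test_zero_variance_row_flagged(self):
        rng = np.random.default_rng(5)
        v = rng.uniform(1, 2, (4, 4))
        v[0, :] = 1.0
        v[:, 0] = 1.0
        out = nz.correlation_map(cm(v))
        assert out.metadata["zero_variance_rows"] >= 1
        assert np.isnan(out.values[0, 1])


class TestBinMatrix:
    def test_bin_size_one_is_identity(self):
        rng = np.random.default_rng(0)
        v = random_symmetric(6, rng)
        out = nz.bin_matrix(cm(v), 1)
        np.testing.assert_array_equal(out.values, v)

    def test_four_ones_binned_pairwise(self):
        out = nz.bin_matrix(cm(np.ones((4, 4))), 2)
        np.testing.assert_array_equal(out.values, np.full((2, 2), 4.0))

    def test_partial_final_bin_and_mass_conservation(self):
        rng = np.random.default_rng(4)
        v = random_symmetric(7, rng)
        for b in (2, 3, 5, 7, 10):
            out = nz.bin_matrix(cm(v), b)
            assert out.values.sum() == pytest.approx(v.sum())

    def test_chromosomes_never_share_a_bin(self):
        chroms = np.array(["c1"] * 3 + ["c2"] * 3)
        v = np.ones((6, 6))
        out = nz.bin_matrix(cm(v), 2, chroms=chroms)
        assert out.n == 4  # two bins per chromosome


class TestBlur:
    def test_single_pass_scales_constant_interior_by_kernel_sum(self):
        v = np.full((9, 9), 2.0)
        out = nz.blur(v, reps=1)
        assert out[4, 4] == pytest.approx(0.45 * 2.0)

    def test_impulse_spreads_to_three_by_three(self):
        v = np.zeros((7, 7))
        v[3, 3] = 1.0
        out = nz.blur(v, reps=1)
        np.testing.assert_allclose(out[2:5, 2:5], np.full((3, 3), 0.05))
        assert out.sum() == pytest.approx(0.45)

    def test_ten_passes_attenuate_interior_geometrically(self):
        v = np.ones((41, 41))
        out = nz.blur(v, reps=10)
        assert out[20, 20] == pytest.approx(0.45**10, rel=0.05)
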