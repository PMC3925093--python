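"""Distance-correlation and mutual-information estimators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcgrn import (
    ContingencyTable,
    ExpressionMatrix,
    InvalidInputError,
    auto_bins,
    dc_dependence_matrix,
    dcor,
    dcov,
    discretize_equal_width,
    double_center,
    dvar,
    joint_counts,
    mi_dependence_matrix,
    mi_miller_madow,
    mi_plugin,
    pairwise_distance_matrix,
)


def dcov_sq_triple_sum(x, y):
    """Independent oracle: dCov^2 = S1 + S2 - 2*S3 with explicit sums."""
    x = np.atleast_2d(np.asarray(x, float).T).T
    y = np.atleast_2d(np.asarray(y, float).T).T
    n = x.shape[0]
    a = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=2)
    b = np.linalg.norm(y[:, None, :] - y[None, :, :], axis=2)
    s1 = (a * b).sum() / n**2
    s2 = a.mean() * b.mean()
    s3 = float(a.sum(axis=1) @ b.sum(axis=1)) / n**3
    return s1 + s2 - 2 * s3


class TestDistanceGeometry:
    @pytest.mark.parametrize(
        "rows, expected",
        [
            ([[0.0], [3.0]], [[0, 3], [3, 0]]),
            ([[1.0], [1.0], [1.0]], np.zeros((3, 3))),
            ([[0.0, 0.0], [3.0, 4.0]], [[0, 5], [5, 0]]),
        ],
    )
    def test_euclidean_entries(self, rows, expected):
        np.testing.assert_allclose(pairwise_distance_matrix(rows), expected)

    def test_single_row_rejected(self):
        with pytest.raises(InvalidInputError):
            pairwise_distance_matrix([[1.0]])

    def test_double_center_two_points(self):
        d = 2.5
        out = double_center([[0, d], [d, 0]])
        np.testing.assert_allclose(out, [[-d / 2, d / 2], [d / 2, -d / 2]])

    def test_double_center_zero_sums(self):
        out = double_center([[0, 1, 2], [1, 0, 1], [2, 1, 0]])
        np.testing.assert_allclose(out.sum(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(out.sum(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(out, out.T)

    def test_double_center_nonsquare_rejected(self):
        with pytest.raises(InvalidInputError):
            double_center(np.zeros((2, 3)))


class TestDistanceCorrelation:
    def test_n2_closed_form(self):
        # n = 2: V_n^2 = d*e/4 with d = |x1-x0|, e = |y1-y0|
        assert dcov([0, 1], [0, 1]) == pytest.approx(0.5, abs=1e-12)
        assert dvar([0, 1]) == pytest.approx(0.5, abs=1e-12)

    def test_constant_block_gives_zero(self, rng):
        y = rng.normal(size=12)
        assert dcov(np.full(12, 3.0), y) == 0.0
        assert dvar(np.full(12, 3.0)) == 0.0
        assert dcor(y, np.full(12, 3.0)) == 0.0

    def test_self_dependence_is_one(self):
        assert dcor([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_any_nondegenerate_pair_at_n2_is_one(self, rng):
        for _ in range(10):
            x = rng.normal(size=2)
            y = rng.normal(size=2)
            assert dcor(x, y) == pytest.approx(1.0, abs=1e-12)

    def test_row_count_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            dcov([1, 2, 3], [1, 2])
        with pytest.raises(InvalidInputError):
            dcor([1, 2, 3], [1, 2])

    def test_triple_sum_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 31))
            p = int(rng.integers(1, 4))
            q = int(rng.integers(1, 4))
            x = rng.normal(size=(n, p))
            y = rng.normal(size=(n, q))
            expected = math.sqrt(max(dcov_sq_triple_sum(x, y), 0.0))
            assert dcov(x, y) == pytest.approx(expected, abs=1e-10)

    def test_dcor_composition_matches_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = x**2
        expected = math.sqrt(
            dcov_sq_triple_sum(x, y)
            / math.sqrt(dcov_sq_triple_sum(x, x) * dcov_sq_triple_sum(y, y))
        )
        assert dcor(x, y) == pytest.approx(expected, abs=1e-10)

    def test_dvar_equals_self_dcov(self, rng):
        x = rng.normal(size=(15, 2))
        assert dvar(x) == dcov(x, x)

    @given(
        a=st.floats(min_value=0.1, max_value=10),
        b=st.floats(min_value=0.1, max_value=10),
        c=st.floats(min_value=-5, max_value=5),
        d=st.floats(min_value=-5, max_value=5),
        flip=st.sampled_from([1.0, -1.0]),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_affine_invariance(self, a, b, c, d, flip):
        rng = np.random.default_rng(7)
        x = rng.normal(size=20)
        y = x**2 + rng.normal(size=20)
        assert dcor(flip * a * x + c, b * y + d) == pytest.approx(
            dcor(x, y), abs=1e-9
        )

    def test_bounds_and_symmetry(self, rng):
        for _ in range(20):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            r = dcor(x, y)
            assert 0.0 <= r <= 1.0
            assert dcov(x, y) == pytest.approx(dcov(y, x), abs=1e-12)

    def test_independence_consistency(self, rng):
        """Median dcor of independent pairs shrinks as n grows."""
        meds = {}
        for n in (25, 400):
            vals = [
                dcor(rng.normal(size=n), rng.normal(size=n)) for _ in range(20)
            ]
            meds[n] = np.median(vals)
        assert meds[400] < meds[25]


class TestDcDependenceMatrix:
    def test_identical_columns(self):
        e = ExpressionMatrix(
            np.column_stack([[1.0, 2, 3], [1.0, 2, 3]]), ["a", "b"]
        )
        m = dc_dependence_matrix(e)
        assert m.values[0, 1] == pytest.approx(1.0)
        assert m.values[0, 0] == 0.0

    def test_symmetric_zero_diagonal(self, small_expression):
        m = dc_dependence_matrix(small_expression)
        np.testing.assert_allclose(m.values, m.values.T)
        np.testing.assert_allclose(np.diag(m.values), 0)
        assert np.all(m.values <= 1.0) and np.all(m.values >= 0.0)

    def test_constant_gene_row_zero(self, rng):
        vals = rng.normal(size=(10, 3))
        vals[:, 1] = 2.0
        m = dc_dependence_matrix(ExpressionMatrix(vals, ["a", "b", "c"]))
        np.testing.assert_allclose(m.values[1, :], 0)
        np.testing.assert_allclose(m.values[:, 1], 0)

    def test_matches_pairwise_dcor(self, small_expression):
        m = dc_dependence_matrix(small_expression)
        v = small_expression.values
        for i in range(4):
            for j in range(i + 1, 4):
                assert m.values[i, j] == pytest.approx(
                    dcor(v[:, i], v[:, j]), abs=1e-12
                )


class TestDiscretization:
    @pytest.mark.parametrize(
        "values, bins, expected",
        [
            ([0, 1, 2, 3], 2, [0, 0, 1, 1]),
            ([5, 5, 5], 4, [0, 0, 0]),
            ([0, 0.4, 0.6, 1.0], 2, [0, 0, 1, 1]),
        ],
    )
    def test_equal_width(self, values, bins, expected):
        np.testing.assert_array_equal(
            discretize_equal_width(values, bins), expected
        )

    def test_max_lands_in_last_bin(self, rng):
        v = rng.normal(size=50)
        idx = discretize_equal_width(v, 7)
        assert idx[np.argmax(v)] == 6
        assert idx.min() >= 0 and idx.max() <= 6

    def test_bad_bin_count(self):
        with pytest.raises(InvalidInputError):
            discretize_equal_width([1.0, 2.0], 0)

    def test_joint_counts_examples(self):
        t = joint_counts([0, 1], [0, 1])
        np.testing.assert_array_equal(t.counts, [[1, 0], [0, 1]])
        assert t.n == 2
        t2 = joint_counts([0, 0], [0, 1])
        np.testing.assert_array_equal(t2.counts, [[1, 1]])

    def test_joint_counts_conserves_total(self, rng):
        bx = rng.integers(0, 4, size=33)
        by = rng.integers(0, 3, size=33)
        assert joint_counts(bx, by).counts.sum() == 33

    def test_joint_counts_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            joint_counts([0, 1], [0])


class TestMutualInformation:
    def test_independent_uniform_table_is_zero(self):
        assert mi_plugin(ContingencyTable(np.array([[1, 1], [1, 1]]), 4)) == 0.0

    def test_diagonal_table_is_ln2(self):
        t = ContingencyTable(np.array([[2, 0], [0, 2]]), 4)
        assert mi_plugin(t) == pytest.approx(math.log(2), abs=1e-12)

    def test_worked_table(self):
        # cell probabilities [[1/2, 0], [1/4, 1/4]]
        t = ContingencyTable(np.array([[2, 0], [1, 1]]), 4)
        expected = (
            0.5 * math.log(0.5 / (0.5 * 0.75))
            + 0.25 * math.log(0.25 / (0.5 * 0.75))
            + 0.25 * math.log(0.25 / (0.5 * 0.25))
        )
        assert expected == pytest.approx(0.2158, abs=5e-5)
        assert mi_plugin(t) == pytest.approx(expected, abs=1e-12)

    def test_miller_madow_correction(self):
        t = ContingencyTable(np.array([[2, 0], [0, 2]]), 4)
        assert mi_miller_madow(t) == pytest.approx(
            math.log(2) + 1 / 8, abs=1e-12
        )
        t1 = ContingencyTable(np.array([[5]]), 5)
        assert mi_miller_madow(t1) == 0.0

    def test_miller_madow_correction_shrinks_with_n(self):
        small = ContingencyTable(np.array([[2, 1], [1, 2]]), 6)
        big = ContingencyTable(np.array([[20, 10], [10, 20]]), 60)
        assert (mi_miller_madow(small) - mi_plugin(small)) == pytest.approx(
            10 * (mi_miller_madow(big) - mi_plugin(big))
        )

    def test_plugin_nonnegative_random_tables(self, rng):
        for _ in range(30):
            counts = rng.integers(0, 6, size=(3, 4))
            counts[0, 0] += 1  # keep non-empty
            t = ContingencyTable(counts, int(counts.sum()))
            assert mi_plugin(t) >= 0.0


class TestMiDependenceMatrix:
    def test_identical_columns_give_ln2_with_two_bins(self, rng):
        col = np.concatenate([rng.uniform(0, 0.4, 5), rng.uniform(0.6, 1.0, 5)])
        e = ExpressionMatrix(np.column_stack([col, col]), ["a", "b"])
        m = mi_dependence_matrix(e, estimator="plugin", n_bins=2)
        assert m.values[0, 1] == pytest.approx(math.log(2), abs=1e-12)

    def test_symmetric_zero_diagonal_nonnegative(self, small_expression):
        for est in ("plugin", "miller_madow"):
            m = mi_dependence_matrix(small_expression, estimator=est)
            np.testing.assert_allclose(m.values, m.values.T)
            np.testing.assert_allclose(np.diag(m.values), 0)
            assert np.all(m.values >= 0)

    def test_auto_bins_rule(self):
        assert auto_bins(50) == 8
        assert auto_bins(49) == 7

    def test_unknown_estimator_rejected(self, small_expression):
        with pytest.raises(InvalidInputError):
            mi_dependence_matrix(small_expression, estimator="kernel")
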