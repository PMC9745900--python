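"""Association statistics against independent formula oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import pearson_p_oracle, welch_oracle

from mmscreen.stats import (
    class_aggregate_test,
    cluster_cell_lines,
    correlation_table,
    pearson_with_p,
    sign_consistency,
    welch_test,
)


class TestWelch:
    def test_identical_groups(self):
        res = welch_test([10, 20, 30], [10, 20, 30])
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_textbook_case(self):
        res = welch_test([2.1, 2.2, 2.3], [1.0, 1.1, 1.2])
        t, df, p = welch_oracle([2.1, 2.2, 2.3], [1.0, 1.1, 1.2])
        assert res.t == pytest.approx(13.47, abs=0.01)
        assert res.t == pytest.approx(t, abs=1e-10)
        assert res.df == pytest.approx(df, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)

    def test_matches_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            a = rng.normal(10, 3, rng.integers(3, 12))
            b = rng.normal(12, 5, rng.integers(3, 12))
            res = welch_test(a, b)
            t, df, p = welch_oracle(a, b)
            assert res.t == pytest.approx(t, abs=1e-10)
            assert res.df == pytest.approx(df, abs=1e-10)
            assert res.p == pytest.approx(p, abs=1e-10)

    def test_swapping_groups_flips_sign_only(self):
        a, b = [5.0, 6.0, 9.0], [1.0, 2.0, 2.5]
        fwd, rev = welch_test(a, b), welch_test(b, a)
        assert fwd.t == pytest.approx(-rev.t)
        assert fwd.p == pytest.approx(rev.p)

    @settings(max_examples=40, deadline=None)
    @given(
        shift=st.floats(-100.0, 100.0),
        scale=st.floats(0.01, 50.0),
    )
    def test_location_scale_invariance_of_p(self, shift, scale):
        a = np.array([3.0, 5.0, 9.0, 4.0])
        b = np.array([1.0, 2.0, 2.0, 4.0, 3.0])
        base = welch_test(a, b)
        moved = welch_test(a * scale + shift, b * scale + shift)
        assert moved.p == pytest.approx(base.p, abs=1e-9)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_test([1.0], [2.0, 3.0])

    def test_two_constant_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_test([5.0, 5.0], [7.0, 7.0])


class TestClassAggregate:
    def _matrix(self):
        rng = np.random.default_rng(1)
        mat = pd.DataFrame(
            rng.uniform(0, 60, size=(4, 6)),
            index=["mek1", "mek2", "mek3", "other"],
            columns=[f"c{i}" for i in range(6)],
        )
        return mat

    def test_single_drug_class_equals_plain_test(self):
        mat = self._matrix()
        g_a, g_b = ["c0", "c1", "c2"], ["c3", "c4", "c5"]
        pooled = class_aggregate_test(mat, ["mek1"], g_a, g_b)
        direct = welch_test(mat.loc["mek1", g_a], mat.loc["mek1", g_b])
        assert pooled.t == pytest.approx(direct.t)
        assert pooled.p == pytest.approx(direct.p)

    def test_pooling_counts_every_drug_cell_observation(self):
        mat = self._matrix()
        res = class_aggregate_test(mat, ["mek1", "mek2", "mek3"],
                                   ["c0", "c1"], ["c2", "c3", "c4", "c5"])
        assert res.n_a == 6  # 3 drugs x 2 cell lines
        assert res.n_b == 12

    def test_overlapping_groups_rejected(self):
        mat = self._matrix()
        with pytest.raises(ValueError, match="both groups"):
            class_aggregate_test(mat, ["mek1"], ["c0"], ["c0", "c1"])

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            class_aggregate_test(self._matrix(), [], ["c0"], ["c1"])


class TestPearson:
    def test_perfect_linear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = pearson_with_p(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        res = pearson_with_p(x, -x)
        assert res.r == pytest.approx(-1.0)

    def test_known_p_at_r_07_n9(self):
        """r=0.7 with 9 samples sits just under the 0.05 line (p ~ 0.036)."""
        rng = np.random.default_rng(5)
        # construct vectors with exactly r = 0.7
        x = rng.normal(size=9)
        z = rng.normal(size=9)
        x = (x - x.mean()) / x.std()
        z = z - z.mean()
        z -= x * (x @ z) / (x @ x)
        z /= np.sqrt(z @ z / 9)
        r_target = 0.7
        y = r_target * x + np.sqrt(1 - r_target**2) * z
        res = pearson_with_p(x, y)
        assert res.r == pytest.approx(0.7, abs=1e-10)
        assert res.p == pytest.approx(0.0358, abs=2e-3)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            x = rng.normal(size=rng.integers(4, 15))
            y = rng.normal(size=x.size) + 0.5 * x
            res = pearson_with_p(x, y)
            r, p = pearson_p_oracle(x, y)
            assert res.r == pytest.approx(r, abs=1e-10)
            assert res.p == pytest.approx(p, abs=1e-10)

    def test_affine_invariance(self):
        x = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        y = np.array([2.0, 3.0, 1.0, 9.0, 4.0])
        base = pearson_with_p(x, y)
        moved = pearson_with_p(3 * x - 7, y)
        assert moved.r == pytest.approx(base.r, abs=1e-12)
        flipped = pearson_with_p(-2 * x, y)
        assert flipped.r == pytest.approx(-base.r, abs=1e-12)
        assert flipped.p == pytest.approx(base.p, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_p([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_correlation_table_shape_and_bh(dss_matrix_small):
    rng = np.random.default_rng(3)
    prot = pd.DataFrame(
        rng.normal(size=(3, 8)),
        index=["p1", "p2", "p3"], columns=dss_matrix_small.columns,
    )
    table = correlation_table(prot, dss_matrix_small, adjust=True)
    assert len(table) == 3 * 6
    assert ((table["q_bh"] >= table["p"] - 1e-12)).all()
    assert table["q_bh"].max() <= 1.0


class TestClustering:
    def test_identical_columns_merge_first(self, dss_matrix_small):
        mat = dss_matrix_small.copy()
        mat["cl1"] = mat["cl0"]
        order, z = cluster_cell_lines(mat)
        first = {int(z[0, 0]), int(z[0, 1])}
        assert first == {0, 1}
        assert z[0, 2] == pytest.approx(0.0)

    def test_close_pair_merges_first(self):
        mat = pd.DataFrame(
            [[0.0, 1.0, 10.0]], index=["d"], columns=["a", "b", "c"]
        )
        _, z = cluster_cell_lines(mat)
        assert {int(z[0, 0]), int(z[0, 1])} == {0, 1}

    def test_column_permutation_leaves_topology_invariant(self,
                                                          dss_matrix_small):
        from scipy.cluster.hierarchy import cophenet
        from scipy.spatial.distance import squareform

        _, z1 = cluster_cell_lines(dss_matrix_small)
        cols = list(dss_matrix_small.columns)[::-1]
        _, z2 = cluster_cell_lines(dss_matrix_small[cols])
        d1 = pd.DataFrame(squareform(cophenet(z1)),
                          index=dss_matrix_small.columns,
                          columns=dss_matrix_small.columns)
        d2 = pd.DataFrame(squareform(cophenet(z2)), index=cols, columns=cols)
        d2 = d2.loc[d1.index, d1.columns]
        assert np.allclose(d1.to_numpy(), d2.to_numpy())

    def test_single_column_rejected(self):
        with pytest.raises(ValueError):
            cluster_cell_lines(pd.DataFrame({"a": [1.0, 2.0]}))


class TestSignConsistency:
    def _frames(self):
        rng = np.random.default_rng(4)
        r = pd.DataFrame(rng.uniform(-1, 1, size=(3, 4)),
                         index=list("abc"), columns=list("wxyz"))
        return r

    def test_equal_matrices_fully_consistent(self):
        r = self._frames()
        assert sign_consistency(r, r) == 1.0

    def test_negated_matrix_fully_inconsistent(self):
        r = self._frames()
        assert sign_consistency(-r, r) == 0.0

    def test_half_matched(self):
        r = pd.DataFrame([[1.0, 1.0, -1.0, -1.0]], columns=list("wxyz"))
        b = pd.DataFrame([[1.0, -1.0, -1.0, 1.0]], columns=list("wxyz"))
        assert sign_consistency(b, r) == 0.5

    def test_zeros_excluded(self):
        r = pd.DataFrame([[0.5, -0.5]], columns=["a", "b"])
        b = pd.DataFrame([[0.0, -1.0]], columns=["a", "b"])
        assert sign_consistency(b, r) == 1.0

    def test_all_zero_rejected(self):
        r = pd.DataFrame([[0.5]], columns=["a"])
        b = pd.DataFrame([[0.0]], columns=["a"])
        with pytest.raises(ValueError):
            sign_consistency(b, r)
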