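import numpy as np
import pytest
from scipy import stats

from kinomeprofiler.differential import (
    cluster_peptides,
    contrast,
    export_heatmap,
    export_violin,
    export_volcano,
    fraction_changed,
)

from conftest import make_matrix


def _two_group_matrix(a_rows, b_rows):
    values = np.vstack([a_rows, b_rows])
    groups = ["A"] * len(a_rows) + ["B"] * len(b_rows)
    return make_matrix(values, groups)


class TestContrast:
    def test_hand_computed_pooled_case(self):
        """groupA=(0,2), groupB=(1,3): lfc=-1, t=-1/sqrt(2), p from t(2)."""
        m = _two_group_matrix([[0.0], [2.0]], [[1.0], [3.0]])
        res = contrast(m, "A", "B")
        assert res.lfc[0] == pytest.approx(-1.0)
        assert res.t[0] == pytest.approx(-1 / np.sqrt(2), abs=1e-12)
        assert res.p[0] == pytest.approx(2 * stats.t.sf(1 / np.sqrt(2), df=2), abs=1e-12)
        assert res.p[0] == pytest.approx(0.5528, abs=1e-4)

    def test_identical_groups_null(self):
        rows = np.array([[1.0, 2.0], [3.0, 4.0]])
        m = _two_group_matrix(rows, rows)
        res = contrast(m, "A", "B")
        np.testing.assert_allclose(res.lfc, 0.0)
        np.testing.assert_allclose(res.p, 1.0)

    def test_group_swap_symmetry(self):
        rng = np.random.default_rng(5)
        m = _two_group_matrix(rng.normal(0, 1, (3, 8)), rng.normal(0.5, 1, (4, 8)))
        ab = contrast(m, "A", "B")
        ba = contrast(m, "B", "A")
        np.testing.assert_allclose(ab.lfc, -ba.lfc, atol=1e-12)
        np.testing.assert_allclose(ab.t, -ba.t, atol=1e-12)
        np.testing.assert_allclose(ab.p, ba.p, atol=1e-12)

    def test_degenerate_zero_variance_unequal_means(self):
        m = _two_group_matrix([[1.0], [1.0]], [[2.0], [2.0]])
        res = contrast(m, "A", "B")
        assert res.degenerate[0]
        assert 0 < res.p[0] < 1e-300

    def test_rejects_singleton_group(self):
        m = make_matrix([[1.0], [2.0], [3.0]], ["A", "B", "B"])
        with pytest.raises(ValueError, match=">= 2 samples"):
            contrast(m, "A", "B")

    def test_agrees_with_t_cdf_oracle_on_random_inputs(self):
        """Pooled t and p recomputed from first principles on 100 random draws."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            na, nb = rng.integers(2, 7, size=2)
            a = rng.normal(0, 1, size=(na, 1))
            b = rng.normal(rng.normal(), 1, size=(nb, 1))
            res = contrast(make_matrix(np.vstack([a, b]), ["A"] * na + ["B"] * nb), "A", "B")
            sp = np.sqrt(
                ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
            )
            t_oracle = (a.mean() - b.mean()) / (sp * np.sqrt(1 / na + 1 / nb))
            p_oracle = 2 * stats.t.sf(abs(t_oracle), df=na + nb - 2)
            assert res.t[0] == pytest.approx(t_oracle, abs=1e-10)
            assert res.p[0] == pytest.approx(p_oracle, abs=1e-10)

    def test_null_rejection_rate_calibrated(self):
        """Global null: rejection rate at alpha=0.05 inside the exact binomial 99% CI."""
        rng = np.random.default_rng(2026)
        n_tests = 3000
        m = _two_group_matrix(
            rng.normal(8, 1, size=(5, n_tests)), rng.normal(8, 1, size=(8, n_tests))
        )
        res = contrast(m, "A", "B")
        rejections = int(res.significant.sum())
        lo, hi = stats.binom.interval(0.99, n_tests, 0.05)
        assert lo <= rejections <= hi


class TestFractionChanged:
    def test_counts_and_partition(self):
        m = _two_group_matrix([[1, 0, 2, 0.5], [1, 0, 2, 0.5]], [[0, 1, 0, 0.5], [0, 1, 0, 0.5]])
        res = contrast(m, "A", "B")  # lfc = (1, -1, 2, 0)
        up = fraction_changed(res, "up")
        down = fraction_changed(res, "down")
        assert up == 0.5 and down == 0.25
        assert up + down + np.mean(res.lfc == 0) == pytest.approx(1.0)

    def test_all_up(self):
        m = _two_group_matrix([[2, 3], [2, 3]], [[1, 1], [1, 1]])
        res = contrast(m, "A", "B")
        assert fraction_changed(res, "up") == 1.0
        assert fraction_changed(res, "down") == 0.0


class TestClusterPeptides:
    def test_hand_executed_upgma_three_leaves(self):
        """d(1,2)=1, d(1,3)=d(2,3)=10: first merge {1,2} at 1, then {1,2}-{3}
        at the average of (10, 10) = 10."""
        # peptide profiles over 2 samples placed so the euclidean distances
        # are exactly (1, 10, 10)
        profiles = np.array(
            [[-0.5, 0.0], [0.5, 0.0], [0.0, np.sqrt(100.0 - 0.25)]]
        )
        m = make_matrix(profiles.T, ["g", "g"])  # samples x peptides
        _, link = cluster_peptides(m)
        assert set(link[0, :2]) == {0, 1}
        assert link[0, 2] == pytest.approx(1.0, abs=1e-12)
        assert link[1, 2] == pytest.approx(10.0, abs=1e-9)

    def test_duplicate_rows_merge_at_zero(self):
        values = np.array([[1.0, 1.0, 5.0], [2.0, 2.0, 6.0]])  # peptides in columns
        m = make_matrix(values, ["g", "g"])
        order, link = cluster_peptides(m)
        assert link[0, 2] == 0.0
        merged = set(link[0, :2])
        assert merged == {0, 1}

    def test_leaf_order_is_permutation(self):
        rng = np.random.default_rng(9)
        m = make_matrix(rng.normal(size=(4, 20)), ["g"] * 4)
        order, _ = cluster_peptides(m)
        assert sorted(order) == sorted(m.peptides)

    def test_rejects_single_peptide(self):
        m = make_matrix([[1.0], [2.0]], ["g", "g"])
        with pytest.raises(ValueError, match=">= 2 peptides"):
            cluster_peptides(m)


class TestExports:
    def test_volcano_columns_and_arithmetic(self, tmp_path):
        rng = np.random.default_rng(1)
        m = _two_group_matrix(rng.normal(0, 1, (3, 10)), rng.normal(1, 1, (3, 10)))
        res = contrast(m, "A", "B")
        df = export_volcano(res, tmp_path / "v.tsv")
        assert len(df) == 10
        np.testing.assert_allclose(df["neg_log10_p"], -np.log10(res.p), atol=1e-12)
        assert (df["significant"] == (res.p < res.alpha)).all()

    def test_violin_long_format(self, tmp_path):
        m = make_matrix([[1.0, 2.0], [3.0, 4.0]], ["A", "B"])
        df = export_violin(m, tmp_path / "violin.tsv")
        assert len(df) == 4
        assert set(df.columns) == {"sample", "peptide", "log2_signal", "group"}

    def test_heatmap_reorders_both_axes(self, tmp_path):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.normal(size=(4, 6)), ["A", "A", "B", "B"])
        df = export_heatmap(m, tmp_path / "h.tsv")
        assert sorted(df.index) == sorted(m.samples)
        assert sorted(df.columns) == sorted(m.peptides)
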