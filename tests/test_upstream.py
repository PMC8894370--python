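import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kinomeprofiler.differential import contrast
from kinomeprofiler.upstream import (
    KinaseSubstrateMap,
    KinaseResult,
    export_coral,
    kinase_statistic,
    rank_kinases,
    read_substrate_map,
    significance_score,
    specificity_score,
    write_substrate_map,
)

from conftest import make_matrix

B = 200  # permutations used throughout these tests; score cap is log10(B+1)


def _matrix_with_effect(n_peptides=30, effect_cols=(), effect=1.0, seed=0, na=5, nb=8):
    rng = np.random.default_rng(seed)
    values = rng.normal(8.0, 0.35, size=(na + nb, n_peptides))
    for c in effect_cols:
        values[:na, c] += effect  # group A elevated
    return make_matrix(values, ["A"] * na + ["B"] * nb)


def _map_for(matrix, sets):
    return KinaseSubstrateMap(
        {k: {matrix.peptides[c]: w for c, w in subs.items()} for k, subs in sets.items()}
    )


class TestKinaseStatistic:
    def test_unweighted_and_weighted_means(self):
        m = _matrix_with_effect(5)
        res = contrast(m, "A", "B")
        res.lfc = np.array([0.2, 0.4, 0.0, 0.0, 0.0])
        smap = _map_for(m, {"K": {0: 10, 1: 5, 2: 1}})
        assert kinase_statistic(res, smap, "K") == pytest.approx((0.2 + 0.4 + 0.0) / 3)
        assert kinase_statistic(res, smap, "K", weighted=True) == pytest.approx(
            (10 * 0.2 + 5 * 0.4 + 1 * 0.0) / 16
        )

    def test_weighted_mean_worked_example(self):
        m = _matrix_with_effect(3)
        res = contrast(m, "A", "B")
        res.lfc = np.array([0.2, 0.4, 0.9])
        smap = _map_for(m, {"K": {0: 10, 1: 5}})
        with pytest.raises(ValueError, match="min_set_size"):
            kinase_statistic(res, smap, "K")  # only 2 substrates
        assert kinase_statistic(res, smap, "K", weighted=True, min_set_size=2) == (
            pytest.approx((10 * 0.2 + 5 * 0.4) / 15)
        )

    def test_matches_brute_force_oracle_on_random_maps(self):
        """Weighted and unweighted statistics vs a literal loop over substrates."""
        rng = np.random.default_rng(77)
        m = _matrix_with_effect(40, seed=1)
        res = contrast(m, "A", "B")
        for _ in range(100):
            size = int(rng.integers(3, 15))
            cols = rng.choice(40, size=size, replace=False)
            weights = rng.integers(1, 11, size=size)
            smap = _map_for(m, {"K": dict(zip(cols.tolist(), weights.tolist()))})
            brute = sum(res.lfc[c] for c in cols) / size
            brute_w = sum(w * res.lfc[c] for c, w in zip(cols, weights)) / weights.sum()
            assert kinase_statistic(res, smap, "K") == pytest.approx(brute, abs=1e-12)
            assert kinase_statistic(res, smap, "K", weighted=True) == pytest.approx(
                brute_w, abs=1e-12
            )

    def test_negative_lfcs_give_negative_statistic(self):
        m = _matrix_with_effect(10, effect_cols=range(10), effect=-1.0, seed=3)
        res = contrast(m, "A", "B")
        smap = _map_for(m, {"K": {0: 5, 1: 5, 2: 5}})
        assert kinase_statistic(res, smap, "K") < 0

    def test_weight_zero_substrates_dropped_at_load(self):
        m = _matrix_with_effect(5)
        smap = _map_for(m, {"K": {0: 0, 1: 5, 2: 5, 3: 5}})
        assert len(smap.substrates_of["K"]) == 3


class TestPermutationScores:
    def test_null_statistic_scores_near_zero(self):
        m = _matrix_with_effect(30, seed=5)  # no effect anywhere
        smap = _map_for(m, {"K": {i: 5 for i in range(8)}})
        sig = significance_score(m, smap, "K", "A", "B", b_labels=B, seed=9)
        assert 0 <= sig < 1.0  # p well away from the floor

    def test_planted_effect_hits_score_cap(self):
        m = _matrix_with_effect(142, effect_cols=range(8), effect=2.0, seed=6)
        smap = _map_for(m, {"K": {i: 10 for i in range(8)}})
        sig = significance_score(m, smap, "K", "A", "B", b_labels=B, seed=9)
        assert sig == pytest.approx(np.log10(B + 1), abs=1e-9)

    def test_significance_invariant_to_group_order(self):
        m = _matrix_with_effect(30, effect_cols=range(5), seed=8)
        smap = _map_for(m, {"K": {i: 5 for i in range(5)}})
        s1 = significance_score(m, smap, "K", "A", "B", b_labels=B, seed=4)
        s2 = significance_score(m, smap, "K", "B", "A", b_labels=B, seed=4)
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_specificity_planted_extremes(self):
        """A 3-peptide set holding the 3 largest lfcs out of 142 maxes the score."""
        m = _matrix_with_effect(142, effect_cols=(0, 1, 2), effect=3.0, seed=10)
        res = contrast(m, "A", "B")
        smap = _map_for(m, {"K": {0: 10, 1: 10, 2: 10}})
        spec = specificity_score(res, smap, "K", b_peptides=B, seed=2)
        assert spec == pytest.approx(np.log10(B + 1), abs=1e-9)

    def test_specificity_near_zero_for_near_global_set(self):
        """A set that is almost the whole array cannot be specific."""
        m = _matrix_with_effect(20, effect_cols=range(20), effect=1.0, seed=11)
        res = contrast(m, "A", "B")
        smap = _map_for(m, {"K": {i: 5 for i in range(19)}})
        spec = specificity_score(res, smap, "K", b_peptides=B, seed=2)
        assert spec < 0.5

    def test_specificity_rejects_full_array_set(self):
        m = _matrix_with_effect(5)
        res = contrast(m, "A", "B")
        smap = _map_for(m, {"K": {i: 5 for i in range(5)}})
        with pytest.raises(ValueError, match="smaller than"):
            specificity_score(res, smap, "K", b_peptides=B, seed=0)

    def test_pvalue_floor_bound(self):
        """Scores never exceed log10(B+1); p never below 1/(B+1)."""
        m = _matrix_with_effect(50, effect_cols=range(4), effect=5.0, seed=12)
        res = contrast(m, "A", "B")
        smap = _map_for(m, {"K": {i: 10 for i in range(4)}})
        spec = specificity_score(res, smap, "K", b_peptides=B, seed=1)
        sig = significance_score(m, smap, "K", "A", "B", b_labels=B, seed=1)
        cap = np.log10(B + 1)
        assert 0 <= spec <= cap + 1e-12 and 0 <= sig <= cap + 1e-12

    def test_independent_streams(self):
        """Label-permutation draws do not depend on whether peptide draws ran."""
        m = _matrix_with_effect(30, effect_cols=range(5), seed=13)
        res = contrast(m, "A", "B")
        smap = _map_for(m, {"K": {i: 5 for i in range(5)}})
        s1 = significance_score(m, smap, "K", "A", "B", b_labels=B, seed=21)
        specificity_score(res, smap, "K", b_peptides=B, seed=21)
        s2 = significance_score(m, smap, "K", "A", "B", b_labels=B, seed=21)
        assert s1 == s2

    def test_null_significance_pvalues_uniform(self):
        """Under a global null the permutation p-values are approximately uniform."""
        rng = np.random.default_rng(31)
        pvals = []
        for rep in range(25):
            values = rng.normal(8.0, 0.35, size=(13, 60))
            m = make_matrix(values, ["A"] * 5 + ["B"] * 8)
            sets = {
                f"K{j}": {int(c): 5 for c in rng.choice(60, size=6, replace=False)}
                for j in range(8)
            }
            smap = _map_for(m, sets)
            for j in range(8):
                s = significance_score(m, smap, f"K{j}", "A", "B", b_labels=100, seed=rep)
                pvals.append(10 ** (-s))
        assert len(pvals) == 200
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestRankKinases:
    def test_threshold_filtering_and_ranks(self):
        m = _matrix_with_effect(60, effect_cols=range(6), effect=2.0, seed=14)
        smap = _map_for(
            m,
            {
                "HIT": {i: 10 for i in range(6)},
                "NULL1": {i: 5 for i in range(20, 26)},
                "NULL2": {i: 5 for i in range(30, 36)},
            },
        )
        full, reported = rank_kinases(m, smap, "A", "B", b_labels=B, b_peptides=B, seed=7)
        assert [r.rank for r in full] == [1, 2, 3]
        assert full[0].kinase == "HIT"
        assert all(r.score > 1.5 for r in reported)
        assert {r.kinase for r in reported} <= {r.kinase for r in full}
        for r in full:
            assert r.score == pytest.approx(r.significance_score + r.specificity_score)

    def test_bit_reproducible_with_fixed_seed(self):
        m = _matrix_with_effect(40, effect_cols=range(5), seed=15)
        smap = _map_for(m, {"K1": {i: 5 for i in range(5)}, "K2": {i: 5 for i in range(10, 18)}})
        r1, _ = rank_kinases(m, smap, "A", "B", b_labels=100, b_peptides=100, seed=3)
        r2, _ = rank_kinases(m, smap, "A", "B", b_labels=100, b_peptides=100, seed=3)
        assert [(a.kinase, a.statistic, a.score) for a in r1] == [
            (a.kinase, a.statistic, a.score) for a in r2
        ]

    def test_small_fingerprints_skipped(self):
        m = _matrix_with_effect(20, seed=16)
        smap = _map_for(m, {"TINY": {0: 5}, "OK": {i: 5 for i in range(4)}})
        full, _ = rank_kinases(m, smap, "A", "B", b_labels=50, b_peptides=50, seed=0)
        assert [r.kinase for r in full] == ["OK"]

    def test_empty_map_raises(self):
        m = _matrix_with_effect(10)
        with pytest.raises(ValueError, match="empty"):
            rank_kinases(m, KinaseSubstrateMap({}), "A", "B")


class TestIO:
    def test_substrate_map_roundtrip(self, tmp_path):
        smap = KinaseSubstrateMap(
            {"K1": {"A_1_10": 5, "B_2_12": 10}, "K2": {"C_3_14": 7}}
        )
        path = tmp_path / "map.tsv"
        write_substrate_map(smap, path)
        back = read_substrate_map(path)
        assert back.substrates_of == smap.substrates_of

    def test_map_rejects_bad_weight_and_bad_id(self):
        with pytest.raises(ValueError, match="0..10"):
            KinaseSubstrateMap({"K": {"A_1_10": 11}})
        with pytest.raises(Exception, match="peptide ID"):
            KinaseSubstrateMap({"K": {"NOPE": 5}})

    def test_coral_export_shape_and_roundtrip(self, tmp_path):
        results = [
            KinaseResult(kinase=f"K{i}", n_peptides=5, statistic=(-1) ** i * 0.3,
                         significance_score=1.0, specificity_score=0.5, rank=i + 1)
            for i in range(16)
        ]
        path = tmp_path / "coral.tsv"
        export_coral(results, path)
        assert len(path.read_text().splitlines()) == 17
        back = pd.read_csv(path, sep="\t")
        np.testing.assert_allclose(back["statistic"], [r.statistic for r in results], atol=1e-9)
        assert (back["score"] >= 0).all()
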