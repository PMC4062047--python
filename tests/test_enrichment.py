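"""Expression frequencies, the preranked GSEA engine, and overlap tests."""

import numpy as np
import pandas as pd
import pytest

from pdxspace import (
    RankedList,
    expression_frequency,
    frequency_difference,
    gsea_preranked,
    overlap_enrichment,
    rank_by_ttest,
)


def ranked(genes, metric):
    return RankedList(genes=np.asarray(genes), metric=np.asarray(metric, dtype=float))


def es_oracle(metric, hits):
    """Direct textbook running-sum ES (weight 1), independent code path."""
    metric, hits = np.asarray(metric, float), np.asarray(hits, bool)
    nh = hits.sum()
    denom_hit = np.abs(metric[hits]).sum()
    best, run = 0.0, 0.0
    for m, h in zip(metric, hits):
        run += abs(m) / denom_hit if h else -1.0 / (len(metric) - nh)
        if abs(run) > abs(best):
            best = run
    return best


class TestFrequencies:
    def test_fraction_of_expressed_samples(self):
        C = pd.DataFrame(
            [[1, 1, 1, 0, 0]], index=["g1"], columns=[f"s{i}" for i in range(5)]
        )
        freq = expression_frequency(C, pd.Series("grp", index=C.columns))
        assert freq.loc["g1", "grp"] == pytest.approx(0.6)

    def test_extremes_and_integrality(self, random_calls):
        groups = pd.Series(
            ["a"] * 12 + ["b"] * 8, index=random_calls.columns
        )
        freq = expression_frequency(random_calls, groups)
        sizes = freq.attrs["group_sizes"]
        for grp in ("a", "b"):
            counts = freq[grp] * sizes[grp]
            np.testing.assert_allclose(counts, np.round(counts), atol=1e-9)
        all_on = random_calls.copy()
        all_on.iloc[0] = 1
        all_off = all_on.copy()
        all_off.iloc[0] = 0
        assert expression_frequency(all_on, groups).loc[all_on.index[0]].eq(1.0).all()
        assert expression_frequency(all_off, groups).loc[all_on.index[0]].eq(0.0).all()

    def test_unassigned_sample_rejected(self, random_calls):
        groups = pd.Series(["a"] * 19, index=random_calls.columns[:19])
        with pytest.raises(ValueError, match="without a group"):
            expression_frequency(random_calls, groups)

    def test_difference_ranks_descending_with_bounds(self, random_calls):
        groups = pd.Series(["t"] * 10 + ["x"] * 10, index=random_calls.columns)
        freq = expression_frequency(random_calls, groups)
        rl = frequency_difference(freq, "t", "x")
        assert (np.diff(rl.metric) <= 1e-12).all()
        assert rl.metric.max() <= 1.0 and rl.metric.min() >= -1.0
        direct = freq.loc[rl.genes[0], "t"] - freq.loc[rl.genes[0], "x"]
        assert rl.metric[0] == pytest.approx(direct)

    def test_difference_worked_values(self):
        freq = pd.DataFrame({"tumor": [0.9, 0.5], "pdx": [0.2, 0.5]}, index=["g1", "g2"])
        rl = frequency_difference(freq, "tumor", "pdx")
        assert dict(zip(rl.genes, rl.metric)) == pytest.approx({"g1": 0.7, "g2": 0.0})

    def test_unknown_group(self):
        freq = pd.DataFrame({"a": [0.1]}, index=["g1"])
        with pytest.raises(KeyError, match="unknown group"):
            frequency_difference(freq, "a", "zzz")

    def test_ties_ordered_by_gene_id(self):
        freq = pd.DataFrame({"a": [0.5, 0.5, 0.9], "b": [0.5, 0.5, 0.1]},
                            index=["zz", "aa", "mm"])
        rl = frequency_difference(freq, "a", "b")
        assert rl.genes.tolist() == ["mm", "aa", "zz"]


class TestGSEAPreranked:
    def test_hand_worked_es_plus_one(self):
        rl = ranked(["g1", "g2", "g3", "g4", "g5"], [3, 2, 1, -1, -2])
        res = gsea_preranked(rl, {"S": {"g1", "g2"}}, min_size=2, n_perm=100, seed=0)
        assert res.table.loc["S", "es"] == pytest.approx(1.0)
        assert res.leading_edge["S"] == ["g1", "g2"]
        assert res.table.loc["S", "direction"] == "up"

    def test_mirrored_configuration_gives_minus_one(self):
        rl = ranked(["g5", "g4", "g3", "g2", "g1"], [2, 1, -1, -2, -3])
        res = gsea_preranked(rl, {"S": {"g1", "g2"}}, min_size=2, n_perm=100, seed=0)
        assert res.table.loc["S", "es"] == pytest.approx(-1.0)
        assert res.table.loc["S", "direction"] == "down"

    @pytest.mark.parametrize("seed", range(3))
    def test_es_matches_bruteforce_running_sum(self, seed):
        rng = np.random.default_rng(seed)
        genes = np.array([f"g{i:03d}" for i in range(80)])
        rl = RankedList.from_series(pd.Series(rng.normal(size=80), index=genes))
        members = set(rng.choice(genes, 17, replace=False))
        res = gsea_preranked(rl, {"S": members}, n_perm=100, seed=0)
        hits = np.isin(rl.genes, list(members))
        assert res.table.loc["S", "es"] == pytest.approx(es_oracle(rl.metric, hits))
        assert -1.0 <= res.table.loc["S", "es"] <= 1.0

    def test_small_sets_filtered_out(self):
        genes = [f"g{i}" for i in range(100)]
        rl = ranked(genes, np.linspace(2, -2, 100))
        sets = {"tiny": set(genes[:10]), "ok": set(genes[:20])}
        res = gsea_preranked(rl, sets, min_size=15, n_perm=100, seed=0)
        assert list(res.table.index) == ["ok"]
        with pytest.raises(ValueError, match="no gene set"):
            gsea_preranked(rl, {"tiny": set(genes[:10])}, min_size=15, n_perm=100, seed=0)

    def test_nes_sign_matches_es_and_fdr_bounds(self):
        rng = np.random.default_rng(3)
        genes = np.array([f"g{i:03d}" for i in range(200)])
        rl = RankedList.from_series(pd.Series(rng.normal(size=200), index=genes))
        sets = {f"S{j}": set(rng.choice(genes, 25, replace=False)) for j in range(10)}
        res = gsea_preranked(rl, sets, n_perm=200, seed=4)
        t = res.table
        assert (np.sign(t["nes"]) == np.sign(t["es"])).all()
        assert t["fdr"].between(0, 1).all()
        assert t["pval"].between(0, 1).all()

    def test_bit_reproducible_given_seed(self):
        rng = np.random.default_rng(6)
        genes = np.array([f"g{i:03d}" for i in range(150)])
        rl = RankedList.from_series(pd.Series(rng.normal(size=150), index=genes))
        sets = {f"S{j}": set(rng.choice(genes, 20, replace=False)) for j in range(5)}
        a = gsea_preranked(rl, sets, n_perm=200, seed=9)
        b = gsea_preranked(rl, sets, n_perm=200, seed=9)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_rejects_tiny_permutation_count(self):
        rl = ranked(["a", "b"], [1, -1])
        with pytest.raises(ValueError, match="n_perm"):
            gsea_preranked(rl, {"S": {"a"}}, min_size=1, n_perm=10, seed=0)


class TestOverlapEnrichment:
    def test_exact_hypergeometric_example(self):
        universe = {f"u{i}" for i in range(10)}
        pathway = {f"u{i}" for i in range(4)}
        signature = {f"u{i}" for i in range(5)}
        # overlap 4 of 4 drawn from 5/10 successes: C(5,4)/C(10,4) = 5/210
        assert overlap_enrichment(pathway, signature, universe) == pytest.approx(5 / 210)

    def test_zero_overlap_has_p_one(self):
        universe = {"a", "b", "c", "d"}
        assert overlap_enrichment({"a"}, {"b"}, universe) == pytest.approx(1.0)

    def test_signature_equals_universe_forces_overlap(self):
        universe = {"a", "b", "c"}
        assert overlap_enrichment({"a", "b"}, universe, universe) == pytest.approx(1.0)

    def test_subset_violations(self):
        with pytest.raises(ValueError, match="pathway"):
            overlap_enrichment({"zz"}, {"a"}, {"a", "b"})
        with pytest.raises(ValueError, match="signature"):
            overlap_enrichment({"a"}, {"zz"}, {"a", "b"})


class TestRankByTTest:
    def test_identical_groups_score_zero(self):
        X = pd.DataFrame(
            [[1.0, 2.0, 1.0, 2.0]], index=["g1"], columns=["a1", "a2", "b1", "b2"]
        )
        rl = rank_by_ttest(X, ["a1", "a2"], ["b1", "b2"])
        assert rl.metric[0] == pytest.approx(0.0)

    def test_constant_difference_with_floored_variance_ranks_first(self):
        X = pd.DataFrame(
            {
                "a1": [1.0, 0.3], "a2": [1.0, 0.1], "a3": [1.0, 0.6],
                "b1": [0.0, 0.2], "b2": [0.0, 0.4], "b3": [0.0, 0.3],
            },
            index=["flat", "noisy"],
        )
        rl = rank_by_ttest(X, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        assert rl.genes[0] == "flat"
        assert rl.metric[0] > 1e3  # variance floor keeps it finite but large

    def test_swapping_groups_negates_metric(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(
            rng.normal(size=(10, 6)),
            index=[f"g{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(6)],
        )
        ab = rank_by_ttest(X, X.columns[:3], X.columns[3:]).to_series()
        ba = rank_by_ttest(X, X.columns[3:], X.columns[:3]).to_series()
        np.testing.assert_allclose(ab.sort_index(), -ba.sort_index(), atol=1e-12)

    def test_group_too_small(self):
        X = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=["a", "b", "c"])
        with pytest.raises(ValueError, match=">= 2 samples"):
            rank_by_ttest(X, ["a"], ["b", "c"])
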