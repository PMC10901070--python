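import itertools

import numpy as np
import pandas as pd
import pytest

from opsccrna.expression import de_test
from opsccrna.gsea import RankedList, enrichment_score, gsea_significance, rank_genes
from opsccrna.io_core import GeneSetCollection
from opsccrna.synthetic import SimulationConfig, gen_counts, gen_gene_sets

# ---------------------------------------------------------------------------
# independent oracles


def running_sum_oracle(stats, hit_mask, weight_p):
    """Direct O(N) running-sum ES: no position arithmetic shared with the
    implementation under test. The ES is the extremum of largest magnitude,
    the positive one on an exact tie."""
    stats = np.asarray(stats, float)
    hit_mask = np.asarray(hit_mask, bool)
    n, k = len(stats), hit_mask.sum()
    w = np.abs(stats[hit_mask]) ** weight_p
    tot = w.sum()
    run = 0.0
    top = 0.0
    bottom = 0.0
    wi = 0
    for i in range(n):
        if hit_mask[i]:
            run += w[wi] / tot
            wi += 1
        else:
            run -= 1.0 / (n - k)
        top = max(top, run)
        bottom = min(bottom, run)
    return top if top >= -bottom - 1e-12 else bottom


def exhaustive_p_oracle(stats, k, es_obs):
    """Nominal p by full enumeration of all k-subsets of hit positions,
    using the same-sign tail with a +1 pseudo-count."""
    n = len(stats)
    null = []
    for pos in itertools.combinations(range(n), k):
        mask = np.zeros(n, bool)
        mask[list(pos)] = True
        null.append(running_sum_oracle(stats, mask, 1.0))
    null = np.array(null)
    if es_obs > 0:
        pos_null = null[null >= 0]
        return (1.0 + np.sum(pos_null >= es_obs - 1e-12)) / (1.0 + len(pos_null))
    neg = null[null < 0]
    return (1.0 + np.sum(neg <= es_obs + 1e-12)) / (1.0 + len(neg))


# ---------------------------------------------------------------------------


class TestRankGenes:
    def test_descending_order(self):
        df = pd.DataFrame({"stat": [2.0, -1.0, 3.0], "log2FC": [1, 1, 1]}, index=["A", "B", "C"])
        assert rank_genes(df, "stat").genes == ["C", "A", "B"]

    def test_tie_broken_lexicographically(self):
        df = pd.DataFrame({"stat": [1.0, 1.0], "log2FC": [0, 0]}, index=["B", "A"])
        assert rank_genes(df, "stat").genes == ["A", "B"]

    def test_lfc_and_stat_modes_can_disagree(self):
        # gene X: big LFC, big SE (small stat); gene Y: modest LFC, tiny SE
        df = pd.DataFrame(
            {"stat": [1.0, 5.0, 0.5], "log2FC": [4.0, 2.0, 0.1]}, index=["X", "Y", "Z"]
        )
        assert rank_genes(df, "lfc").genes == ["X", "Y", "Z"]
        assert rank_genes(df, "stat").genes == ["Y", "X", "Z"]

    def test_duplicate_gene_rejected(self):
        with pytest.raises(ValueError):
            RankedList(["A", "A"], np.array([1.0, 2.0]))


class TestEnrichmentScore:
    def test_hand_example_top_two(self):
        ranked = RankedList(["g1", "g2", "g3", "g4", "g5"], np.array([3, 2, 1, -1, -2], float))
        es, running, le = enrichment_score(ranked, {"g1", "g2"})
        assert es == pytest.approx(1.0)
        np.testing.assert_allclose(running, [0.6, 1.0, 2 / 3, 1 / 3, 0.0], atol=1e-12)
        assert le == ["g1", "g2"]

    def test_whole_list_set_rejected(self):
        ranked = RankedList(["a", "b", "c", "d", "e"], np.arange(5, 0, -1).astype(float))
        with pytest.raises(ValueError):
            enrichment_score(ranked, {"a", "b", "c", "d", "e"})

    def test_empty_intersection_rejected(self):
        ranked = RankedList(["a", "b"], np.array([1.0, 0.5]))
        with pytest.raises(ValueError):
            enrichment_score(ranked, {"zz"})

    def test_p0_matches_ks_oracle_on_random_lists(self):
        """With weight 0 the ES is the classic KS statistic; check against
        the brute-force running-sum oracle on 100 random 20-gene lists."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            stats = rng.normal(size=20)
            order = np.argsort(-stats)
            genes = [f"g{i}" for i in order]
            ranked = RankedList(genes, stats[order])
            members = set(rng.choice(genes, size=6, replace=False))
            es, _, _ = enrichment_score(ranked, members, weight_p=0.0)
            mask = np.array([g in members for g in genes])
            assert es == pytest.approx(running_sum_oracle(ranked.stats, mask, 0.0), abs=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(7)
        stats = np.sort(rng.normal(size=30))[::-1]
        genes = [f"g{i}" for i in range(30)]
        ranked = RankedList(genes, stats)
        members = set(genes[::4])
        es1, _, _ = enrichment_score(ranked, members)
        ranked2 = RankedList(genes, stats * 17.3)
        es2, _, _ = enrichment_score(ranked2, members)
        assert es1 == pytest.approx(es2, rel=1e-12)

    def test_reversal_negates_es_at_p0(self):
        rng = np.random.default_rng(9)
        stats = np.sort(rng.normal(size=24))[::-1]
        genes = [f"g{i}" for i in range(24)]
        members = set(rng.choice(genes, 5, replace=False))
        es_fwd, _, _ = enrichment_score(RankedList(genes, stats), members, weight_p=0.0)
        es_rev, _, _ = enrichment_score(
            RankedList(genes[::-1], stats[::-1]), members, weight_p=0.0
        )
        assert es_fwd == pytest.approx(-es_rev, abs=1e-12)


class TestSignificance:
    def test_exhaustive_matches_bruteforce_enumeration(self):
        """On a 12-gene list with a 4-gene set the exhaustive permutation p
        equals full-subset enumeration through an independent ES oracle."""
        rng = np.random.default_rng(11)
        stats = np.sort(rng.normal(size=12))[::-1]
        genes = [f"g{i}" for i in range(12)]
        members = list(rng.choice(genes, 4, replace=False))
        ranked = RankedList(genes, stats)
        res = gsea_significance(
            ranked,
            GeneSetCollection({"S": members}),
            exhaustive=True,
            min_size=2,
        )
        es, _, _ = enrichment_score(ranked, set(members))
        p_oracle = exhaustive_p_oracle(stats, 4, es)
        assert res.table.loc["S", "pval"] == pytest.approx(p_oracle, abs=1e-12)

    def test_planted_set_recovered_with_largest_nes(self):
        """The planted 50-gene top set gets the largest NES and FDR < 0.05."""
        cfg = SimulationConfig(
            n_genes=1000, n_samples_per_group=(20, 20), planted_set_size=50, planted_lfc=2.0, seed=7
        )
        cm, truth = gen_counts(cfg)
        ranked = rank_genes(de_test(cm, "group"), "stat")
        sets = gen_gene_sets(cfg, truth)
        res = gsea_significance(ranked, sets, nperm=1000, seed=7)
        assert res.table["NES"].idxmax() == "PLANTED_SET"
        assert res.table.loc["PLANTED_SET", "FDR"] < 0.05

    def test_shuffled_statistic_kills_significance(self):
        """With the ranking shuffled, the planted set's nominal p exceeds
        0.05 in at least 90% of repeats."""
        cfg = SimulationConfig(
            n_genes=1000, n_samples_per_group=(20, 20), planted_set_size=50, planted_lfc=2.0, seed=7
        )
        cm, truth = gen_counts(cfg)
        ranked = rank_genes(de_test(cm, "group"), "stat")
        sets = GeneSetCollection({"PLANTED_SET": truth.planted_genes})
        rng = np.random.default_rng(8)
        n_null = 0
        reps = 50
        for _ in range(reps):
            # reassign the statistics to genes at random, then re-rank
            stats = ranked.stats[rng.permutation(len(ranked))]
            order = np.argsort(-stats)
            shuffled = RankedList([ranked.genes[i] for i in order], stats[order])
            res = gsea_significance(shuffled, sets, nperm=200, seed=int(rng.integers(2**31)))
            n_null += res.table.loc["PLANTED_SET", "pval"] > 0.05
        assert n_null >= 0.9 * reps

    def test_duplicate_set_names_get_identical_scores(self):
        rng = np.random.default_rng(13)
        stats = np.sort(rng.normal(size=60))[::-1]
        genes = [f"g{i}" for i in range(60)]
        members = list(rng.choice(genes, 8, replace=False))
        sets = GeneSetCollection({"S1": members, "S2": list(members)})
        res = gsea_significance(RankedList(genes, stats), sets, nperm=200, seed=3)
        assert res.table.loc["S1", "ES"] == res.table.loc["S2", "ES"]
        assert res.table.loc["S1", "NES"] == res.table.loc["S2", "NES"]

    def test_reproducible_for_fixed_seed_and_p_in_unit_interval(self):
        rng = np.random.default_rng(17)
        stats = np.sort(rng.normal(size=80))[::-1]
        genes = [f"g{i}" for i in range(80)]
        sets = GeneSetCollection(
            {f"S{k}": list(rng.choice(genes, 10, replace=False)) for k in range(4)}
        )
        r1 = gsea_significance(RankedList(genes, stats), sets, nperm=300, seed=5)
        r2 = gsea_significance(RankedList(genes, stats), sets, nperm=300, seed=5)
        pd.testing.assert_frame_equal(r1.table, r2.table)
        assert ((r1.table["pval"] > 0) & (r1.table["pval"] <= 1)).all()
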