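from itertools import combinations
from math import comb

import numpy as np
import pytest
from scipy import stats as sps

import enrichrank as er
from enrichrank.permutation import permutation_labelings


def _de_from_pvals(pvals, sig_threshold=0.05):
    """DEResult whose adjusted p-values are given verbatim."""
    p = np.asarray(pvals, dtype=float)
    return er.DEResult(
        gene_ids=[f"g{i}" for i in range(p.size)],
        log2fc=np.zeros(p.size),
        stat=np.zeros(p.size),
        pval=p,
        adj_pval=p,
        adjust="none",
    )


def hypergeom_tail_oracle(N, K, n, k):
    """P(X >= k) by exhaustive pmf enumeration."""
    return sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1)) / comb(N, n)


class TestORA:
    def test_derived_example_matches_enumeration(self):
        """N=20, K=5, n=5, k=3: the upper tail is 1126/15504."""
        p = [0.01] * 5 + [0.5] * 15  # first 5 genes significant
        de = _de_from_pvals(p)
        gsc = er.GeneSetCollection(
            sets={"S": ["g0", "g1", "g2", "g5", "g6"]}  # k=3 of n=5 significant
        )
        ranking = er.ora(de, gsc, alpha=0.05)
        assert ranking.pvals[0] == pytest.approx(1126 / 15504, rel=1e-12)
        assert hypergeom_tail_oracle(20, 5, 5, 3) == pytest.approx(1126 / 15504)
        assert ranking.scores[0] == 3

    def test_no_significant_members_gives_p_one(self):
        de = _de_from_pvals([0.01] * 3 + [0.5] * 17)
        gsc = er.GeneSetCollection(sets={"S": [f"g{i}" for i in range(10, 16)]})
        assert er.ora(de, gsc).pvals[0] == 1.0  # tail includes k=0

    def test_set_equal_to_universe_gives_p_one(self):
        de = _de_from_pvals([0.01] * 4 + [0.5] * 6)
        gsc = er.GeneSetCollection(sets={"S": [f"g{i}" for i in range(10)]})
        assert er.ora(de, gsc).pvals[0] == 1.0

    def test_zero_significant_genes_warns_not_errors(self, caplog):
        de = _de_from_pvals([0.5] * 10)
        gsc = er.GeneSetCollection(sets={"S": [f"g{i}" for i in range(6)]})
        with caplog.at_level("WARNING"):
            ranking = er.ora(de, gsc)
        assert (ranking.pvals == 1.0).all()
        assert "no significant genes" in caplog.text

    def test_unmeasured_sets_dropped(self):
        de = _de_from_pvals([0.01] * 10)
        gsc = er.GeneSetCollection(
            sets={"S": [f"g{i}" for i in range(6)], "absent": ["x1", "x2", "x3", "x4", "x5"]}
        )
        assert er.ora(de, gsc).set_ids == ["S"]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle_random_cases(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(8, 31))
        K = int(rng.integers(1, N + 1))
        n = int(rng.integers(1, N + 1))
        p = [0.01] * K + [0.5] * (N - K)
        de = _de_from_pvals(p)
        members = [f"g{i}" for i in rng.choice(N, size=n, replace=False)]
        gsc = er.GeneSetCollection(sets={"S": members})
        k = sum(1 for m in members if int(m[1:]) < K)
        got = er.ora(de, gsc, min_size=1).pvals[0]
        assert got == pytest.approx(hypergeom_tail_oracle(N, K, n, k), rel=1e-10)


class TestEnrichmentScore:
    def test_members_at_top_give_es_one(self):
        stats = np.arange(10, 0, -1, dtype=float)
        mask = np.array([True] * 3 + [False] * 7)
        assert er.gsea_enrichment_score(stats, mask, weight_exp=0) == pytest.approx(1.0)

    def test_four_step_running_sum_by_hand(self):
        """N=4, members at positions 1 and 3 (w=0): partial sums are
        1/2, 0, 1/2, 0 so the signed extreme is +1/2."""
        stats = np.array([4.0, 3.0, 2.0, 1.0])
        mask = np.array([True, False, True, False])
        assert er.gsea_enrichment_score(stats, mask, weight_exp=0) == pytest.approx(0.5)

    def test_bottom_concentration_is_symmetric(self):
        stats = np.arange(8, 0, -1, dtype=float)
        top = np.array([True] * 3 + [False] * 5)
        bottom = top[::-1]
        es_top = er.gsea_enrichment_score(stats, top, weight_exp=0)
        es_bottom = er.gsea_enrichment_score(stats, bottom, weight_exp=0)
        assert abs(es_bottom) == pytest.approx(abs(es_top))
        assert es_bottom < 0 < es_top

    def test_weighted_form_uses_stat_magnitudes(self):
        stats = np.array([10.0, 1.0, 1.0, 1.0])
        mask = np.array([True, False, False, True])
        es = er.gsea_enrichment_score(stats, mask, weight_exp=1)
        # first hit already contributes 10/11 of the hit mass
        assert es == pytest.approx(10 / 11)

    def test_empty_or_full_membership_rejected(self):
        stats = np.ones(4)
        with pytest.raises(ValueError):
            er.gsea_enrichment_score(stats, np.zeros(4, dtype=bool))
        with pytest.raises(ValueError):
            er.gsea_enrichment_score(stats, np.ones(4, dtype=bool))

    @pytest.mark.parametrize("n,n_hit,seed", [(6, 2, 0), (10, 4, 1), (12, 5, 2)])
    def test_unweighted_es_equals_classic_ks_statistic(self, n, n_hit, seed):
        """weight_exp=0 on tie-free input: |ES| equals the two-sample KS
        distance between member and non-member rank CDFs, computed directly."""
        rng = np.random.default_rng(seed)
        stats = np.sort(rng.normal(size=n))[::-1]
        members = np.zeros(n, dtype=bool)
        members[rng.choice(n, size=n_hit, replace=False)] = True
        es = er.gsea_enrichment_score(stats, members, weight_exp=0)
        hit_pos = np.flatnonzero(members)
        miss_pos = np.flatnonzero(~members)
        d = max(
            abs((hit_pos <= i).mean() - (miss_pos <= i).mean()) for i in range(n)
        )
        assert abs(es) == pytest.approx(d)


def _brute_force_safe(data, gsc, global_stat):
    """Independent oracle: enumerate every 3+3 relabeling, recompute |t| with
    scipy, aggregate the global statistic, count."""
    n1 = int(data.groups.sum())
    results = {}
    labelings = [
        np.isin(np.arange(data.n_samples), case)
        for case in combinations(range(data.n_samples), n1)
    ]
    gene_order = sorted(range(data.n_genes), key=lambda i: data.gene_ids[i])
    values = data.values[gene_order]
    gene_ids = [data.gene_ids[i] for i in gene_order]

    def local(mask):
        t = sps.ttest_ind(values[:, mask], values[:, ~mask], axis=1, equal_var=True).statistic
        return np.abs(t)

    def global_of(local_stats, member_idx):
        if global_stat == "wilcoxon":
            return sps.rankdata(local_stats)[member_idx].sum()
        if global_stat == "sum_sq":
            return (local_stats[member_idx] ** 2).sum()
        order = np.argsort(-local_stats, kind="stable")
        mask = np.zeros(len(local_stats), dtype=bool)
        mask[member_idx] = True
        return er.gsea_enrichment_score(local_stats[order], mask[order], weight_exp=0)

    observed_mask = data.groups == 1
    for sid, members in gsc.sets.items():
        member_idx = [gene_ids.index(g) for g in members if g in gene_ids]
        obs = global_of(local(observed_mask), member_idx)
        perm = np.array([global_of(local(m), member_idx) for m in labelings])
        b = int((perm >= obs).sum())
        results[sid] = (b + 1) / (len(labelings) + 1)
    return results


@pytest.fixture(scope="module")
def small_study():
    rng = np.random.default_rng(21)
    values = rng.normal(8, 1, size=(12, 6))
    values[:4, 3:] += 2.0
    data = er.ExpressionDataset(
        values=values,
        gene_ids=[f"g{i:02d}" for i in range(12)],
        sample_ids=[f"s{j}" for j in range(6)],
        groups=np.array([0, 0, 0, 1, 1, 1]),
    )
    gsc = er.GeneSetCollection(
        sets={
            "shifted": [f"g{i:02d}" for i in range(4)],
            "null1": [f"g{i:02d}" for i in range(4, 8)],
            "null2": [f"g{i:02d}" for i in range(8, 12)],
        }
    )
    return data, gsc


class TestSafeRun:
    @pytest.mark.parametrize("global_stat", ["wilcoxon", "ks", "sum_sq"])
    def test_exhaustive_pvalues_equal_counting_oracle(self, small_study, global_stat):
        data, gsc = small_study
        ranking = er.safe_run(
            data,
            gsc,
            global_stat=global_stat,
            cfg=er.PermutationConfig(exhaustive=True),
            weight_exp=0.0,
            min_size=1,
        )
        oracle = _brute_force_safe(data, gsc, global_stat)
        for sid, p in zip(ranking.set_ids, ranking.pvals):
            assert p == pytest.approx(oracle[sid], abs=1e-12), (global_stat, sid)

    def test_dispatch_contract(self, small_study):
        data, gsc = small_study
        cfg = er.PermutationConfig(n_perm=30, seed=1)
        assert er.gsea(data, gsc, cfg=cfg, min_size=1).method_name == "gsea"
        assert er.safe(data, gsc, cfg=cfg, min_size=1).method_name == "safe"
        assert er.samgs(data, gsc, cfg=cfg, min_size=1).method_name == "samgs"

    def test_wilcoxon_statistic_maximal_for_top_members(self, small_study):
        """When the member genes carry the k largest |t| among N genes, the
        rank sum equals sum_{i=N-k+1..N} i."""
        data, gsc = small_study
        ranking = er.safe_run(
            data, gsc, global_stat="wilcoxon",
            cfg=er.PermutationConfig(n_perm=10, seed=0), min_size=1,
        )
        de = er.de_statistics(data)
        top4 = set(np.array(de.gene_ids)[np.argsort(-np.abs(de.stat))[:4]])
        if top4 == set(gsc["shifted"]):
            i = ranking.set_ids.index("shifted")
            assert ranking.scores[i] == pytest.approx(9 + 10 + 11 + 12)

    def test_seed_makes_ranking_bit_reproducible(self, small_study):
        data, gsc = small_study
        kw = dict(global_stat="wilcoxon", min_size=1)
        r1 = er.safe_run(data, gsc, cfg=er.PermutationConfig(n_perm=200, seed=7), **kw)
        r2 = er.safe_run(data, gsc, cfg=er.PermutationConfig(n_perm=200, seed=7), **kw)
        assert r1.set_ids == r2.set_ids
        np.testing.assert_array_equal(r1.pvals, r2.pvals)
        np.testing.assert_array_equal(r1.scores, r2.scores)

    def test_spiked_set_ranked_first_by_all_methods(self, sim_small):
        data, gsc, _, truth = sim_small
        spiked = truth.loc[truth.spiked == 1, "set_id"].item()
        cfg = er.PermutationConfig(n_perm=200, seed=3)
        de = er.de_statistics(data)
        assert er.ora(de, gsc, use_adjusted=False).set_ids[0] == spiked
        for fn in (er.gsea, er.safe, er.samgs):
            assert fn(data, gsc, cfg=cfg).set_ids[0] == spiked

    def test_null_pvalues_are_calibrated(self):
        """On exchangeable data the empirical CDF of set p-values at alpha
        stays within 3 binomial SE of alpha."""
        rng = np.random.default_rng(13)
        n_sets, size = 60, 10
        values = rng.normal(size=(n_sets * size, 12))
        data = er.ExpressionDataset(
            values=values,
            gene_ids=[f"g{i:04d}" for i in range(values.shape[0])],
            sample_ids=[f"s{j}" for j in range(12)],
            groups=np.array([0] * 6 + [1] * 6),
        )
        gsc = er.GeneSetCollection(
            sets={
                f"S{s:02d}": [f"g{i:04d}" for i in range(s * size, (s + 1) * size)]
                for s in range(n_sets)
            }
        )
        ranking = er.safe_run(
            data, gsc, global_stat="wilcoxon",
            cfg=er.PermutationConfig(n_perm=400, seed=2),
        )
        alpha = 0.05
        frac = (ranking.pvals < alpha).mean()
        tol = 3 * np.sqrt(alpha * (1 - alpha) / n_sets)
        assert abs(frac - alpha) <= tol
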