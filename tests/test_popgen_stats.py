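import numpy as np
import pytest

from primpop.popgen_stats import (
    DistanceMatrix,
    amova,
    compare_groupings,
    gene_diversity,
    pairwise_fst,
    pca_genotypes,
    resample_fst_matrices,
    squared_distance_matrix,
)
from primpop.snp_data import MISSING, PopulationMap, SnpDataError

from conftest import make_matrix


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def wc_theta_oracle(geno, pops):
    """Weir & Cockerham (1984) theta for two populations, written directly
    from the published per-locus component formulas with explicit loops."""
    labels = sorted(set(pops))
    assert len(labels) == 2
    r = 2
    sum_a = sum_abc = 0.0
    for j in range(len(geno[0])):
        n = []  # typed individuals per pop
        p = []  # alt freq
        h = []  # observed het fraction
        for lab in labels:
            rows = [i for i, q in enumerate(pops) if q == lab and geno[i][j] != MISSING]
            if not rows:
                n.append(0)
                p.append(0.0)
                h.append(0.0)
                continue
            n.append(len(rows))
            p.append(sum(geno[i][j] for i in rows) / (2 * len(rows)))
            h.append(sum(geno[i][j] == 1 for i in rows) / len(rows))
        if min(n) == 0 or (n[0] + n[1]) <= 2:
            continue
        nbar = (n[0] + n[1]) / 2
        nc = (r * nbar - (n[0] ** 2 + n[1] ** 2) / (r * nbar)) / (r - 1)
        pbar = (n[0] * p[0] + n[1] * p[1]) / (r * nbar)
        s2 = (n[0] * (p[0] - pbar) ** 2 + n[1] * (p[1] - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n[0] * h[0] + n[1] * h[1]) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
        sum_a += a
        sum_abc += a + b + c
    return sum_a / sum_abc


def amova_oracle(d2, pop_of, grp_of_pop):
    """Direct sums-of-squares decomposition with explicit loops, then the
    Excoffier variance-component equations."""
    n = d2.shape[0]
    pops = sorted(set(pop_of))
    groups = sorted(set(grp_of_pop.values()))

    def ssd(indices):
        tot = 0.0
        for a in range(len(indices)):
            for b in range(a + 1, len(indices)):
                tot += d2[indices[a], indices[b]]
        return tot / len(indices)

    ssd_t = ssd(list(range(n)))
    ssd_wp = sum(ssd([i for i in range(n) if pop_of[i] == p]) for p in pops)
    ssd_wg = sum(
        ssd([i for i in range(n) if grp_of_pop[pop_of[i]] == gk]) for gk in groups
    )
    ssd_ag = ssd_t - ssd_wg
    ssd_ap = ssd_wg - ssd_wp
    df_ag, df_ap, df_wp = len(groups) - 1, len(pops) - len(groups), n - len(pops)
    sizes = {p: sum(1 for q in pop_of if q == p) for p in pops}
    gsizes = {gk: sum(sizes[p] for p in pops if grp_of_pop[p] == gk) for gk in groups}
    s1 = sum(sum(sizes[p] ** 2 for p in pops if grp_of_pop[p] == gk) / gsizes[gk] for gk in groups)
    n1 = (n - s1) / df_ap
    n2 = (s1 - sum(sizes[p] ** 2 for p in pops) / n) / df_ag
    n3 = (n - sum(gsizes[gk] ** 2 for gk in groups) / n) / df_ag
    sc = ssd_wp / df_wp
    sb = (ssd_ap / df_ap - sc) / n1
    sa = (ssd_ag / df_ag - sc - n2 * sb) / n3
    return sa, sb, sc


# ---------------------------------------------------------------------------
# Gene diversity
# ---------------------------------------------------------------------------

class TestGeneDiversity:
    def test_fixed_population_has_zero_diversity(self):
        g, pm = make_matrix(np.zeros((4, 5)), ["A"] * 4)
        out = gene_diversity(g, pm)
        assert out["mean_H"].iloc[0] == 0.0

    def test_unbiased_formula_two_copies_each(self):
        # genotypes {0, 2}: n = 4 copies, p = 0.5 -> H = 2*0.25*(4/3) = 2/3
        g, pm = make_matrix([[0], [2]], ["A", "A"])
        out = gene_diversity(g, pm)
        assert out["mean_H"].iloc[0] == pytest.approx(2.0 / 3.0)

    def test_duplicating_individuals_changes_only_the_correction(self):
        g1, pm1 = make_matrix([[0], [2]], ["A", "A"])
        g2, pm2 = make_matrix([[0], [2], [0], [2]], ["A"] * 4)
        h1 = gene_diversity(g1, pm1)["mean_H"].iloc[0]
        h2 = gene_diversity(g2, pm2)["mean_H"].iloc[0]
        # p is unchanged; only n/(n-1) moves: (8/7) vs (4/3)
        assert h2 == pytest.approx(h1 * (8 / 7) / (4 / 3))


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

class TestPairwiseFst:
    def test_complete_fixation_gives_one(self):
        geno = [[0] * 4] * 5 + [[2] * 4] * 5
        g, pm = make_matrix(geno, ["A"] * 5 + ["B"] * 5)
        assert pairwise_fst(g, pm).values[0, 1] == pytest.approx(1.0)

    def test_identical_populations_give_nonpositive_theta(self, rng):
        block = rng.integers(0, 3, size=(6, 40))
        geno = np.vstack([block, block])
        g, pm = make_matrix(geno, ["A"] * 6 + ["B"] * 6)
        assert pairwise_fst(g, pm).values[0, 1] <= 0.0

    def test_matches_handwritten_component_oracle(self, rng):
        geno = rng.integers(0, 3, size=(8, 3))
        geno[2, 1] = MISSING
        pops = ["A"] * 4 + ["B"] * 4
        g, pm = make_matrix(geno, pops)
        expected = wc_theta_oracle(geno.tolist(), pops)
        assert pairwise_fst(g, pm).values[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_no_shared_loci_is_an_error(self):
        M = MISSING
        geno = [[1, M], [0, M], [M, 1], [M, 0]]
        g, pm = make_matrix(geno, ["A", "A", "B", "B"])
        with pytest.raises(SnpDataError, match="share no typed loci"):
            pairwise_fst(g, pm)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

class TestAmova:
    def grouping(self):
        return {"P1": "X", "P2": "X", "P3": "Y"}

    def test_matches_brute_force_partition(self, rng):
        geno = rng.integers(0, 3, size=(12, 20))
        pops = ["P1"] * 4 + ["P2"] * 4 + ["P3"] * 4
        g, pm = make_matrix(geno, pops, self.grouping())
        res = amova(g, pm)
        d2 = squared_distance_matrix(g)
        sa, sb, sc = amova_oracle(d2, pops, self.grouping())
        assert res.sigma_among_groups == pytest.approx(sa, rel=1e-9)
        assert res.sigma_among_pops_within == pytest.approx(sb, rel=1e-9)
        assert res.sigma_within_pops == pytest.approx(sc, rel=1e-9)
        assert res.phi_st == pytest.approx((sa + sb) / (sa + sb + sc), rel=1e-9)
        assert sum(res.percent) == pytest.approx(100.0)

    def test_identical_individuals_degenerate(self):
        g, pm = make_matrix(np.ones((12, 5)), ["P1"] * 4 + ["P2"] * 4 + ["P3"] * 4,
                            self.grouping())
        res = amova(g, pm)
        assert res.degenerate
        assert res.percent == (0.0, 0.0, 0.0)

    def test_pure_between_group_divergence(self):
        """Two groups of two populations, every individual identical within its
        group and group frequencies differing by 1: sigma_b = 0, Phi_CT = Phi_ST."""
        geno = np.vstack([np.zeros((10, 30)), np.full((10, 30), 2)])
        pops = ["P1"] * 5 + ["P2"] * 5 + ["P3"] * 5 + ["P4"] * 5
        g, pm = make_matrix(geno, pops, {"P1": "X", "P2": "X", "P3": "Y", "P4": "Y"})
        res = amova(g, pm)
        assert abs(res.sigma_among_pops_within) < 1e-9
        assert res.phi_ct == pytest.approx(res.phi_st, abs=1e-9)
        assert res.phi_ct == pytest.approx(1.0)

    def test_permutation_p_small_for_real_structure(self, rng):
        geno = np.vstack([rng.integers(0, 2, (8, 50)), rng.integers(1, 3, (8, 50))])
        pops = ["P1"] * 4 + ["P2"] * 4 + ["P3"] * 4 + ["P4"] * 4
        g, pm = make_matrix(geno, pops, {"P1": "X", "P2": "X", "P3": "Y", "P4": "Y"})
        res = amova(g, pm, n_perm=99, seed=5)
        assert res.p_values["phi_ST"] <= 0.05
        assert all(0 < p <= 1 for p in res.p_values.values())

    def test_null_p_values_not_extreme(self, rng):
        """Unstructured data: permutation p for Phi_CT should not be tiny."""
        geno = rng.integers(0, 3, size=(16, 40))
        pops = ["P1"] * 4 + ["P2"] * 4 + ["P3"] * 4 + ["P4"] * 4
        g, pm = make_matrix(geno, pops, {"P1": "X", "P2": "X", "P3": "Y", "P4": "Y"})
        res = amova(g, pm, n_perm=99, seed=7)
        assert res.p_values["phi_CT"] > 0.05


class TestCompareGroupings:
    def test_true_split_beats_random_split(self, rng):
        base = rng.integers(0, 2, size=(6, 80))
        geno = np.vstack([base + rng.integers(0, 2, (6, 80)),
                          base + 1])
        pops = (["P1"] * 3 + ["P2"] * 3) + (["P3"] * 3 + ["P4"] * 3)
        g, pm = make_matrix(geno, pops)
        true_split = {"P1": "X", "P2": "X", "P3": "Y", "P4": "Y"}
        random_split = {"P1": "X", "P3": "X", "P2": "Y", "P4": "Y"}
        table, best = compare_groupings(g, pm, {"true": true_split, "random": random_split})
        assert best == "true"

    def test_duplicate_strategy_scores_identically(self, toy_matrix):
        g, pm = toy_matrix
        s = {"A": "X", "B": "Y"}
        table, _ = compare_groupings(g, pm, {"s1": s, "s2": dict(s)})
        assert table["pct_among_groups"].iloc[0] == table["pct_among_groups"].iloc[1]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

class TestPca:
    def test_two_clusters_rank_one(self):
        geno = np.vstack([np.zeros((5, 30)), np.full((5, 30), 2)])
        g, _ = make_matrix(geno, ["A"] * 5 + ["B"] * 5)
        scores, pct = pca_genotypes(g)
        assert pct[0] == pytest.approx(100.0)
        assert np.sign(scores[:5, 0]).std() == 0  # cluster 1 on one side
        assert scores[:5, 0].mean() * scores[5:, 0].mean() < 0

    def test_percentages_sum_to_100_and_decrease(self, rng):
        geno = rng.integers(0, 3, size=(10, 25))
        g, _ = make_matrix(geno, ["A"] * 10)
        _, pct = pca_genotypes(g)
        assert pct.sum() == pytest.approx(100.0)
        assert (np.diff(pct) <= 1e-9).all()

    def test_matches_eigendecomposition_oracle(self, rng):
        geno = rng.integers(0, 3, size=(5, 4)).astype(float)
        g, _ = make_matrix(geno, ["A"] * 5)
        scores, pct = pca_genotypes(g)
        x = geno - geno.mean(axis=0)
        cov = x.T @ x
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        expected_scores = x @ v
        for k in range(min(4, scores.shape[1])):
            assert np.allclose(np.abs(scores[:, k]), np.abs(expected_scores[:, k]), atol=1e-9)
        assert np.allclose(pct[: w.size], 100 * w / w.sum(), atol=1e-9)

    def test_missing_data_mean_imputed(self):
        geno = np.array([[0, 2], [2, 0], [MISSING, 1]], dtype=np.int16)
        g, _ = make_matrix(geno, ["A"] * 3)
        scores, _ = pca_genotypes(g)  # must not raise; imputed row is central
        assert np.isfinite(scores).all()


# ---------------------------------------------------------------------------
# F_ST resampling
# ---------------------------------------------------------------------------

class TestResampleFst:
    def test_full_sample_equals_full_matrix(self, toy_matrix):
        g, pm = toy_matrix
        full = pairwise_fst(g, pm)
        reps = resample_fst_matrices(g, pm, g.n_loci, 3, seed=0)
        for rep in reps:
            assert np.allclose(rep.values, full.values)

    def test_zero_reps_empty(self, toy_matrix):
        g, pm = toy_matrix
        assert resample_fst_matrices(g, pm, 2, 0, seed=0) == []

    def test_too_many_loci_errors(self, toy_matrix):
        g, pm = toy_matrix
        with pytest.raises(ValueError):
            resample_fst_matrices(g, pm, g.n_loci + 1, 1, seed=0)

    def test_subsample_mean_near_full_value(self, rng):
        geno = np.vstack([rng.integers(0, 2, (8, 200)), rng.integers(1, 3, (8, 200))])
        g, pm = make_matrix(geno, ["A"] * 8 + ["B"] * 8)
        full = pairwise_fst(g, pm).values[0, 1]
        reps = resample_fst_matrices(g, pm, 180, 100, seed=1)
        mean = np.mean([r.values[0, 1] for r in reps])
        assert mean == pytest.approx(full, abs=0.02)

    def test_deterministic_under_seed(self, toy_matrix):
        g, pm = toy_matrix
        a = resample_fst_matrices(g, pm, 2, 4, seed=9)
        b = resample_fst_matrices(g, pm, 2, 4, seed=9)
        for x, y in zip(a, b):
            assert np.array_equal(x.values, y.values)
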