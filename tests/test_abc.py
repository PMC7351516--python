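import numpy as np
import pandas as pd
import pytest

from primpop.abc import (
    ReferenceTable,
    SummaryVector,
    adjust_parameters,
    build_reference_table,
    hpd_interval,
    model_check,
    reject,
    scenario_posterior,
    summarize,
    summary_names,
    to_years,
)
from primpop.coalescent import Divergence, Population, Prior, PriorSet, Scenario
from primpop.snp_data import MISSING

from conftest import make_matrix


def grouped_matrix(geno, pops, grouping):
    g, pm = make_matrix(geno, pops, grouping)
    return g, pm


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

class TestSummarize:
    def test_identical_groups_have_no_differentiation(self, rng):
        block = rng.integers(0, 3, size=(8, 60))
        geno = np.vstack([block, block])
        g, pm = grouped_matrix(geno, ["A"] * 8 + ["B"] * 8, {"A": "GA", "B": "GB"})
        sv = summarize(g, pm)
        s = sv.to_series()
        assert s["fst_GA_GB"] <= 0.0
        assert s["nei_GA_GB"] == pytest.approx(0.0, abs=1e-9)

    def test_f3_negative_for_admixed_target(self, rng):
        """Target frequencies are the 50:50 mixture of two diverged sources."""
        L = 400
        xa = rng.uniform(0.02, 0.4, L)
        xb = rng.uniform(0.6, 0.98, L)
        xt = (xa + xb) / 2
        n = 30

        def draw(freqs):
            return rng.binomial(2, freqs[None, :].repeat(n, axis=0))

        geno = np.vstack([draw(xt), draw(xa), draw(xb)])
        pops = ["T"] * n + ["A"] * n + ["B"] * n
        g, pm = grouped_matrix(geno, pops, {"T": "T", "A": "A", "B": "B"})
        sv = summarize(g, pm).to_series()
        assert sv["f3_T_A_B"] < 0
        assert sv["f3_A_B_T"] > 0  # a true source is no mixture of the others

    def test_matches_direct_recomputation(self, rng):
        """Every entry of a small 3-group table agrees with loop-based recomputation."""
        geno = rng.integers(0, 3, size=(9, 12))
        geno[1, 3] = MISSING
        pops = ["P1"] * 3 + ["P2"] * 3 + ["P3"] * 3
        grouping = {"P1": "A", "P2": "B", "P3": "C"}
        g, pm = grouped_matrix(geno, pops, grouping)
        sv = summarize(g, pm).to_series()

        def freqs(rows, j):
            vals = [geno[i, j] for i in rows if geno[i, j] != MISSING]
            return (sum(vals) / (2 * len(vals)), len(vals)) if vals else (np.nan, 0)

        rows_of = {"A": [0, 1, 2], "B": [3, 4, 5], "C": [6, 7, 8]}
        # proportion of monomorphic loci in group A
        mono = 0
        for j in range(12):
            p, m = freqs(rows_of["A"], j)
            mono += p in (0.0, 1.0)
        assert sv["pmono_A"] == pytest.approx(mono / 12)
        # mean gene diversity in group B
        hs = []
        for j in range(12):
            p, m = freqs(rows_of["B"], j)
            if m > 0:
                hs.append(2 * p * (1 - p) * (2 * m) / (2 * m - 1))
        assert sv["meanH_B"] == pytest.approx(np.mean(hs))
        # f3(C; A, B)
        f3 = []
        for j in range(12):
            pc, _ = freqs(rows_of["C"], j)
            pa, _ = freqs(rows_of["A"], j)
            pb, _ = freqs(rows_of["B"], j)
            if not any(np.isnan([pa, pb, pc])):
                f3.append((pc - pa) * (pc - pb))
        assert sv["f3_C_A_B"] == pytest.approx(np.mean(f3))
        # Nei standard distance A-B from per-locus gene identities
        jx = jy = jxy = 0.0
        for j in range(12):
            pa, _ = freqs(rows_of["A"], j)
            pb, _ = freqs(rows_of["B"], j)
            jx += pa**2 + (1 - pa) ** 2
            jy += pb**2 + (1 - pb) ** 2
            jxy += pa * pb + (1 - pa) * (1 - pb)
        assert sv["nei_A_B"] == pytest.approx(-np.log(jxy / np.sqrt(jx * jy)))

    def test_summary_order_is_canonical(self):
        names = summary_names(["A", "B", "C"])
        assert names[:3] == ["pmono_A", "meanH_A", "varH_A"]
        assert "fst_A_B" in names and "f3_C_A_B" in names
        assert len(names) == 9 + 6 + 3


# ---------------------------------------------------------------------------
# Reference table and rejection
# ---------------------------------------------------------------------------

def toy_table(rng, n_rows=500, n_scen=2, n_dim=4):
    sid = np.tile(np.arange(n_scen), n_rows // n_scen)
    summ = rng.normal(size=(n_rows, n_dim)) + sid[:, None] * 0.5
    params = pd.DataFrame({"theta": rng.uniform(0, 10, n_rows)})
    return ReferenceTable(sid, [f"s{k}" for k in range(n_scen)], params, summ,
                          [f"S{k}" for k in range(n_dim)])


class TestBuildReferenceTable:
    def test_row_bookkeeping(self):
        scens = [
            Scenario("a", [Population("A", 4, 500.0), Population("B", 4, 500.0)],
                     [Divergence("B", "A", "t")]),
            Scenario("b", [Population("A", 4, 500.0), Population("B", 4, 500.0)],
                     [Divergence("B", "A", "t")]),
        ]
        pris = [PriorSet({"t": Prior("t", "uniform", 100, 1000)})] * 2
        tbl = build_reference_table(scens, pris, 10, 25, seed=3)
        assert tbl.n_rows == 20
        assert np.bincount(tbl.scenario_ids).tolist() == [10, 10]
        assert tbl.summaries.shape[1] == len(tbl.summary_labels)
        _, scale = tbl.standardization()
        assert (scale[scale > 0] > 0).all()

    def test_round_trip_through_csv(self, tmp_path, rng):
        tbl = toy_table(rng)
        tbl.write(tmp_path / "t.csv", tmp_path / "t.json")
        tbl2 = ReferenceTable.read(tmp_path / "t.csv", tmp_path / "t.json")
        assert np.allclose(tbl2.summaries, tbl.summaries)
        assert tbl2.scenario_names == tbl.scenario_names
        assert np.array_equal(tbl2.scenario_ids, tbl.scenario_ids)


class TestReject:
    def test_tolerance_one_retains_all(self, rng):
        tbl = toy_table(rng)
        ret = reject(tbl.summaries[0], tbl, 1.0)
        assert ret.n_retained == tbl.n_rows

    def test_exact_row_has_zero_distance(self, rng):
        tbl = toy_table(rng)
        ret = reject(tbl.summaries[17], tbl, 0.01)
        assert 17 in ret.indices
        assert ret.distances[0] == pytest.approx(0.0)

    def test_planted_near_duplicates_are_retained(self, rng):
        tbl = toy_table(rng, n_rows=1000)
        obs = rng.normal(size=4) * 0.1 + 30.0  # far from the bulk
        planted = np.arange(0, 1000, 100)
        tbl.summaries[planted] = obs + rng.normal(size=(10, 4)) * 1e-3
        tbl.__post_init__()  # reset caches
        ret = reject(obs, tbl, 0.01)
        assert set(ret.indices) == set(planted)

    def test_invariant_to_monotone_rescaling_of_one_summary(self, rng):
        tbl = toy_table(rng)
        obs = rng.normal(size=4)
        ret1 = reject(obs, tbl, 0.05)
        tbl2 = ReferenceTable(tbl.scenario_ids, tbl.scenario_names, tbl.parameters,
                              tbl.summaries.copy(), tbl.summary_labels)
        tbl2.summaries[:, 2] = tbl2.summaries[:, 2] * 37.0 - 4.0
        obs2 = obs.copy()
        obs2[2] = obs2[2] * 37.0 - 4.0
        ret2 = reject(obs2, tbl2, 0.05)
        assert np.array_equal(ret1.indices, ret2.indices)


# ---------------------------------------------------------------------------
# Scenario choice
# ---------------------------------------------------------------------------

class TestScenarioPosterior:
    def test_single_scenario_retained_probability_one(self, rng):
        tbl = toy_table(rng, n_rows=400, n_scen=2)
        # push scenario 1 far away so only scenario 0 is retained
        tbl.summaries[tbl.scenario_ids == 1] += 100.0
        tbl.__post_init__()
        obs = tbl.summaries[tbl.scenario_ids == 0][0]
        ret = reject(obs, tbl, 0.02)
        choice = scenario_posterior(tbl, ret, obs, n_bootstrap=0)
        assert choice.probabilities[0] == pytest.approx(1.0)
        assert choice.flags

    def test_symmetric_scenarios_near_half(self, rng):
        sid = np.tile(np.arange(2), 2000)
        summ = rng.normal(size=(4000, 3))  # identical distributions
        tbl = ReferenceTable(sid, ["a", "b"], pd.DataFrame({"x": np.zeros(4000)}),
                             summ, ["S0", "S1", "S2"])
        obs = np.zeros(3)
        ret = reject(obs, tbl, 0.1)
        choice = scenario_posterior(tbl, ret, obs, n_bootstrap=0)
        assert abs(choice.probabilities[0] - 0.5) < 0.15

    def test_probabilities_sum_to_one_with_ci(self, rng):
        tbl = toy_table(rng, n_rows=600)
        obs = tbl.summaries.mean(axis=0)
        ret = reject(obs, tbl, 0.2)
        choice = scenario_posterior(tbl, ret, obs, n_bootstrap=50, seed=3)
        assert choice.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
        assert (choice.ci_low <= choice.ci_high).all()


# ---------------------------------------------------------------------------
# Parameter adjustment
# ---------------------------------------------------------------------------

class TestAdjustParameters:
    def test_linear_model_recovery(self, rng):
        """theta = 2*S + noise: the adjusted posterior concentrates on the
        generative value with bias < 5% of the prior range."""
        n = 5000
        s = rng.normal(size=(n, 1))
        theta = 2.0 * s[:, 0] + rng.normal(0, 0.05, n)
        tbl = ReferenceTable(np.zeros(n, dtype=int), ["s0"],
                             pd.DataFrame({"theta": theta}), s, ["S0"])
        pri = PriorSet({"theta": Prior("theta", "uniform", -10, 10)})
        obs = np.array([0.7])
        ret = reject(obs, tbl, 0.05)
        post = adjust_parameters(tbl, ret, obs, pri)
        mean = post.summary.set_index("parameter").loc["theta", "mean"]
        assert abs(mean - 1.4) < 0.05 * 20
        lo, hi = post.hpd("theta")
        assert lo <= 1.4 <= hi
        assert -10 <= lo <= hi <= 10

    def test_uncorrelated_summaries_leave_sample_roughly_unchanged(self, rng):
        n = 2000
        s = rng.normal(size=(n, 2))
        theta = rng.uniform(4, 6, n)  # independent of summaries
        tbl = ReferenceTable(np.zeros(n, dtype=int), ["s0"],
                             pd.DataFrame({"theta": theta}), s, ["S0", "S1"])
        pri = PriorSet({"theta": Prior("theta", "uniform", 0, 10)})
        obs = s.mean(axis=0)
        ret = reject(obs, tbl, 0.2)
        post = adjust_parameters(tbl, ret, obs, pri)
        raw = theta[ret.indices]
        adj = post.samples["theta"].to_numpy()
        assert np.mean(adj) == pytest.approx(np.mean(raw), abs=0.1)

    def test_small_retained_set_rejected(self, rng):
        tbl = toy_table(rng, n_rows=100)
        ret = reject(tbl.summaries[0], tbl, 0.01)
        with pytest.raises(ValueError, match="too small"):
            adjust_parameters(tbl, ret, tbl.summaries[0],
                              PriorSet({"theta": Prior("theta", "uniform", 0, 10)}))


class TestHpd:
    def test_shortest_interval_matches_brute_force(self, rng):
        x = rng.exponential(size=200)
        lo, hi = hpd_interval(x, 0.9)
        xs = np.sort(x)
        k = int(np.ceil(0.9 * 200))
        widths = [(xs[i + k - 1] - xs[i], xs[i], xs[i + k - 1]) for i in range(200 - k + 1)]
        w, blo, bhi = min(widths)
        assert (lo, hi) == pytest.approx((blo, bhi))

    def test_mass_contained(self, rng):
        x = rng.normal(size=1000)
        lo, hi = hpd_interval(x, 0.95)
        assert ((x >= lo) & (x <= hi)).mean() >= 0.95


# ---------------------------------------------------------------------------
# Model check & time conversion
# ---------------------------------------------------------------------------

class TestModelCheck:
    def test_reproducible_and_well_calibrated_for_self_fit(self):
        scen = Scenario("pair", [Population("A", 6, "N"), Population("B", 6, "N")],
                        [Divergence("B", "A", "t")])
        pri = PriorSet({"t": Prior("t", "uniform", 500, 5000),
                        "N": Prior("N", "loguniform", 500, 5000)})
        tbl = build_reference_table([scen], [pri], 400, 40, seed=11)
        gobs, pmobs = None, None
        from primpop.coalescent import simulate_dataset

        gobs, pmobs = simulate_dataset(scen, {"t": 2000.0, "N": 1500.0}, 40, seed=99)
        obs = summarize(gobs, pmobs, by="population")
        ret = reject(obs, tbl, 0.25)
        post = adjust_parameters(tbl, ret, obs, pri, scenario_id=0)
        chk1 = model_check(scen, post, obs, n_ppc=100, seed=5, n_loci=40)
        chk2 = model_check(scen, post, obs, n_ppc=100, seed=5, n_loci=40)
        assert chk1["p_value"].tolist() == chk2["p_value"].tolist()
        # data generated by the fitted scenario: few summaries flagged
        assert chk1["flagged"].mean() <= 0.25


def test_to_years_generation_time():
    assert to_years(470_000, 1.0) == 470_000  # 0.47 Ma at one-year generations
    assert to_years(100, 3.0) == 300
    with pytest.raises(ValueError):
        to_years(-1, 1)
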