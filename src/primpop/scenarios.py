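"""The three-step demographic scenario batteries and the end-to-end pipeline.

Step 1 compares 13 three-lineage histories (L1-L3): the three rooted
bifurcating topologies with unsampled ancestors, a trichotomy, six
origin-from-within chains and three origin-from-within fans.  Scenario 13 is
the fan in which both L1 and L2 bud off from L3.

Step 2 fixes the backbone inferred for the six groups (G3 ancestral; G6 and
G1 from G3; G2 an admixture pulse between G3 and G6) and compares the two
orderings of the G4/G5 divergence from G3.

Step 3 compares, per group, four single-population size-change histories:
old expansion, recent expansion, expansion-shrinkage, and
expansion-shrinkage-expansion, with disjoint time-prior windows separating
"old" from "recent".
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import yaml

from .coalescent import (
    Admixture,
    Divergence,
    Population,
    Prior,
    PriorSet,
    Scenario,
    SizeChange,
)

# Default prior windows (generations / diploid sizes)
SIZE_LOW, SIZE_HIGH = 1e2, 1e6
TIME_LOW, TIME_HIGH = 1e3, 1e6
RECENT_LOW, RECENT_HIGH = 1e1, 5e4     # post-dates the last glaciation window
OLD_LOW, OLD_HIGH = 5e4, 1e6


def _size_priors(pops: list[str]) -> dict[str, Prior]:
    return {f"N_{p}": Prior(f"N_{p}", "loguniform", SIZE_LOW, SIZE_HIGH) for p in pops}


def _t(name: str, low: float = TIME_LOW, high: float = TIME_HIGH) -> Prior:
    return Prior(name, "uniform", low, high)


# ---------------------------------------------------------------------------
# Step 1: 13 three-lineage topologies
# ---------------------------------------------------------------------------

#: which main lineage each of the six groups belongs to
LINEAGE_OF_GROUP = {"G1": "L3", "G2": "L3", "G3": "L3", "G4": "L1", "G5": "L1", "G6": "L2"}


def step1_battery(samples: dict[str, int] | None = None) -> tuple[list[Scenario], list[PriorSet]]:
    """13 scenarios over the three main lineages L1, L2, L3.

    Default sampling is 5 diploids per population (L1: 2 populations, L2: 4,
    L3: 6).
    """
    L = ["L1", "L2", "L3"]
    n_samp = samples or {"L1": 10, "L2": 20, "L3": 30}  # noqa: default design

    def pops(extra: list[str] = ()) -> list[Population]:
        ps = [Population(name, n_samp[name], f"N_{name}") for name in L]
        ps += [Population(name, 0, f"N_{name}") for name in extra]
        return ps

    scenarios: list[Scenario] = []
    priorsets: list[PriorSet] = []

    def mk_priors(extra_sizes: list[str], times: list[str], constraints):
        pri = _size_priors(L + list(extra_sizes))
        for t in times:
            pri[t] = _t(t)
        return PriorSet(pri, constraints)

    # 1-3: rooted bifurcating topologies with an unsampled ancestor of the cherry
    for first, second, out in (("L1", "L2", "L3"), ("L1", "L3", "L2"), ("L2", "L3", "L1")):
        anc = "ANC"
        sc = Scenario(
            f"bifurcating_({first},{second})_{out}",
            pops([anc]),
            [
                Divergence(first, anc, "t_a"),
                Divergence(second, anc, "t_a"),
                Divergence(out, anc, "t_b"),
            ],
        )
        scenarios.append(sc)
        priorsets.append(mk_priors([anc], ["t_a", "t_b"], [("t_b", "t_a")]))
    # 4: trichotomy
    scenarios.append(
        Scenario(
            "trichotomy",
            pops(["ANC"]),
            [Divergence("L1", "ANC", "t_a"), Divergence("L2", "ANC", "t_a"), Divergence("L3", "ANC", "t_a")],
        )
    )
    priorsets.append(mk_priors(["ANC"], ["t_a"], []))
    # 5-10: origin-from-within chains root -> mid -> tip
    chains = [
        ("L1", "L2", "L3"), ("L1", "L3", "L2"),
        ("L2", "L1", "L3"), ("L2", "L3", "L1"),
        ("L3", "L1", "L2"), ("L3", "L2", "L1"),
    ]
    for root, mid, tip in chains:
        sc = Scenario(
            f"chain_{tip}<-{mid}<-{root}",
            pops(),
            [Divergence(tip, mid, "t_a"), Divergence(mid, root, "t_b")],
        )
        scenarios.append(sc)
        priorsets.append(mk_priors([], ["t_a", "t_b"], [("t_b", "t_a")]))
    # 11-13: origin-from-within fans (both non-roots bud off the root)
    for root, (u, v) in (("L1", ("L2", "L3")), ("L2", ("L1", "L3")), ("L3", ("L1", "L2"))):
        sc = Scenario(
            f"fan_{u}+{v}<-{root}",
            pops(),
            [Divergence(u, root, "t_a"), Divergence(v, root, "t_b")],
        )
        scenarios.append(sc)
        priorsets.append(mk_priors([], ["t_a", "t_b"], [("t_b", "t_a")]))
    assert len(scenarios) == 13
    return scenarios, priorsets


# ---------------------------------------------------------------------------
# Step 2: divergence order of G4 and G5
# ---------------------------------------------------------------------------

GROUPS = ["G1", "G2", "G3", "G4", "G5", "G6"]
#: diploid individuals per group in the ABC sampling design (5 per population;
#: G3 spans 4 populations, G6 spans 4, the other groups 1 each)
STEP2_SAMPLES = {"G1": 5, "G2": 5, "G3": 20, "G4": 5, "G5": 5, "G6": 20}


def _step2_backbone(samples: dict[str, int] | None = None) -> list[Population]:
    samples = samples or STEP2_SAMPLES
    return [Population(g, samples[g], f"N_{g}") for g in GROUPS]


def step2_battery(samples: dict[str, int] | None = None,
                  root_size_changes: bool = True) -> tuple[list[Scenario], list[PriorSet]]:
    """Two six-group scenarios differing in the order of the G4/G5 divergence.

    Shared structure: G3 is the root; G6 and G1 diverge from G3; G2 is formed
    by an admixture pulse between G3 and G6; G3 carries a recent bottleneck
    and an ancestral expansion (size-change events shared by both scenarios,
    so the backbone can absorb the root population's history and the scenario
    choice reflects the ordering, not shared misfit).  Scenario (a): G4 from
    G3, then G5 from G4 more recently.  Scenario (b): the alternative
    ordering.
    """
    shared = [
        Divergence("G1", "G3", "t_G1"),
        Admixture("G2", "G3", "G6", "r_G2", "t_G2"),
        Divergence("G6", "G3", "t_G6"),
    ]
    if root_size_changes:
        shared += [
            SizeChange("G3", "t_G3_bot", "N_G3_big"),
            SizeChange("G3", "t_G3_exp", "N_G3_anc"),
        ]
    a = Scenario(
        "G4_from_G3_then_G5_from_G4",
        _step2_backbone(samples),
        shared + [Divergence("G5", "G4", "t_G5"), Divergence("G4", "G3", "t_G4")],
    )
    b = Scenario(
        "G5_from_G3_then_G4_from_G5",
        _step2_backbone(samples),
        shared + [Divergence("G4", "G5", "t_G4"), Divergence("G5", "G3", "t_G5")],
    )
    pri = _size_priors(GROUPS)
    for t in ("t_G1", "t_G2", "t_G4", "t_G5", "t_G6"):
        pri[t] = _t(t)
    pri["r_G2"] = Prior("r_G2", "uniform", 0.001, 0.999)
    shared_c = [("t_G6", "t_G2")]
    if root_size_changes:
        pri["t_G3_bot"] = Prior("t_G3_bot", "uniform", RECENT_LOW, RECENT_HIGH)
        pri["t_G3_exp"] = Prior("t_G3_exp", "uniform", OLD_LOW, 2e6)
        pri["N_G3_big"] = Prior("N_G3_big", "loguniform", SIZE_LOW, SIZE_HIGH)
        pri["N_G3_anc"] = Prior("N_G3_anc", "loguniform", SIZE_LOW, SIZE_HIGH)
        shared_c += [
            # the ancestral expansion pre-dates every divergence from G3
            ("t_G3_exp", "t_G6"), ("t_G3_exp", "t_G1"),
            ("t_G3_exp", "t_G4"), ("t_G3_exp", "t_G5"),
            ("N_G3_big", "N_G3"), ("N_G3_big", "N_G3_anc"),
        ]
    pri_a = PriorSet(dict(pri), shared_c + [("t_G4", "t_G5")])
    pri_b = PriorSet(dict(pri), shared_c + [("t_G5", "t_G4")])
    return [a, b], [pri_a, pri_b]


# ---------------------------------------------------------------------------
# Step 3: size-change histories per group
# ---------------------------------------------------------------------------

def step3_battery(group: str, n_sample: int = 5) -> tuple[list[Scenario], list[PriorSet]]:
    """Four single-population size-change scenarios for one group."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    p = group

    def pop() -> list[Population]:
        return [Population(p, n_sample, "N_cur")]

    base_sizes = {
        "N_cur": Prior("N_cur", "loguniform", SIZE_LOW, SIZE_HIGH),
        "N_anc": Prior("N_anc", "loguniform", SIZE_LOW, SIZE_HIGH),
    }
    # (i) old expansion: ancestral size smaller, change in the old window
    s_old = Scenario(f"{p}_old_expansion", pop(), [SizeChange(p, "t_exp", "N_anc")])
    pri_old = PriorSet(
        dict(base_sizes, t_exp=Prior("t_exp", "uniform", OLD_LOW, OLD_HIGH)),
        [("N_cur", "N_anc")],
    )
    # (ii) recent expansion
    s_rec = Scenario(f"{p}_recent_expansion", pop(), [SizeChange(p, "t_exp", "N_anc")])
    pri_rec = PriorSet(
        dict(base_sizes, t_exp=Prior("t_exp", "uniform", RECENT_LOW, RECENT_HIGH)),
        [("N_cur", "N_anc")],
    )
    # (iii) expansion followed by shrinkage (forward time): backward, the size
    # rises at t_shr to the pre-shrinkage maximum, then falls at t_exp
    s_es = Scenario(
        f"{p}_expansion_shrinkage",
        pop(),
        [SizeChange(p, "t_shr", "N_big"), SizeChange(p, "t_exp", "N_anc")],
    )
    pri_es = PriorSet(
        dict(
            base_sizes,
            N_big=Prior("N_big", "loguniform", SIZE_LOW, SIZE_HIGH),
            t_shr=Prior("t_shr", "uniform", RECENT_LOW, RECENT_HIGH),
            t_exp=Prior("t_exp", "uniform", OLD_LOW, OLD_HIGH),
        ),
        [("t_exp", "t_shr"), ("N_big", "N_cur"), ("N_big", "N_anc")],
    )
    # (iv) expansion, shrinkage, then a new expansion
    s_ese = Scenario(
        f"{p}_expansion_shrinkage_expansion",
        pop(),
        [
            SizeChange(p, "t_exp2", "N_small"),
            SizeChange(p, "t_shr", "N_big"),
            SizeChange(p, "t_exp1", "N_anc"),
        ],
    )
    pri_ese = PriorSet(
        dict(
            base_sizes,
            N_big=Prior("N_big", "loguniform", SIZE_LOW, SIZE_HIGH),
            N_small=Prior("N_small", "loguniform", SIZE_LOW, SIZE_HIGH),
            t_exp2=Prior("t_exp2", "uniform", RECENT_LOW, RECENT_HIGH),
            t_shr=Prior("t_shr", "uniform", RECENT_LOW, RECENT_HIGH),
            t_exp1=Prior("t_exp1", "uniform", OLD_LOW, OLD_HIGH),
        ),
        [
            ("t_shr", "t_exp2"),
            ("t_exp1", "t_shr"),
            ("N_cur", "N_small"),
            ("N_big", "N_small"),
            ("N_big", "N_anc"),
        ],
    )
    return [s_old, s_rec, s_es, s_ese], [pri_old, pri_rec, pri_es, pri_ese]


# ---------------------------------------------------------------------------
# Battery config round-trip
# ---------------------------------------------------------------------------

def battery_to_yaml(scenarios: list[Scenario], priors: list[PriorSet], path) -> None:
    doc = {
        "scenarios": [s.to_dict() for s in scenarios],
        "priors": [p.to_dict() for p in priors],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def battery_from_yaml(path) -> tuple[list[Scenario], list[PriorSet]]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    scenarios = [Scenario.from_dict(d) for d in doc["scenarios"]]
    priors = [PriorSet.from_dict(d) for d in doc["priors"]]
    return scenarios, priors


# ---------------------------------------------------------------------------
# Step-1/2 individual subsetting
# ---------------------------------------------------------------------------

def least_missing_individuals(g, pm, per_population: int = 5) -> list[str]:
    """Per population, the ``per_population`` individuals with least missing
    data; ties broken by individual id."""
    from .snp_data import MISSING

    miss = (g.genotypes == MISSING).sum(axis=1)
    chosen: list[str] = []
    for pop in pm.populations:
        members = [
            (int(miss[i]), g.individual_ids[i])
            for i in range(g.n_individuals)
            if pm.individual_to_population[g.individual_ids[i]] == pop
        ]
        members.sort()
        chosen += [ind for _, ind in members[:per_population]]
    return chosen


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Problem sizes for the end-to-end run (scaled-down defaults)."""

    min_group_presence: float = 0.8
    maf: float = 0.01
    n_perm_amova: int = 999
    n_perm_protest: int = 999
    barrier_n_loci: int = 1000
    barrier_n_reps: int = 25
    n_barriers: int = 10
    abc_table_size: int = 2000       # rows per scenario
    abc_n_loci: int = 300            # loci per simulated dataset
    abc_tolerance: float = 0.01
    n_bootstrap: int = 100       # bootstrap resamples for scenario-choice CIs
    run_step1: bool = True
    run_step3: bool = True
    generation_time: float = 1.0


def run_pipeline(g, pm, geo, config: PipelineConfig | None = None, seed: int = 0,
                 grouping_strategies: dict[str, dict[str, str]] | None = None) -> dict:
    """Filtering -> structure statistics -> spatial analyses -> three-step ABC.

    Every stochastic stage is seeded from ``seed``.  Returns a JSON-serializable
    report dictionary.
    """
    from . import abc as abc_mod
    from . import popgen_stats as ps
    from . import spatial as sp
    from .snp_data import filter_loci

    cfg = config or PipelineConfig()
    rng = np.random.default_rng(seed)
    report: dict = {"seed": seed}

    def stage_seed() -> int:
        return int(rng.integers(0, 2**31 - 1))

    # --- filtering ---------------------------------------------------------
    n_before = g.n_loci
    g = filter_loci(g, pm, cfg.min_group_presence, cfg.maf)
    report["filter"] = {"n_loci_before": n_before, "n_loci_after": g.n_loci,
                        "missing_fraction": g.missing_fraction()}

    # --- structure statistics ----------------------------------------------
    fst = ps.pairwise_fst(g, pm)
    off = fst.offdiagonal()
    report["fst"] = {"mean": float(off.mean()), "min": float(off.min()),
                     "max": float(off.max()), "global_theta": ps.global_fst(g, pm)}
    amova_res = ps.amova(g, pm, n_perm=cfg.n_perm_amova, seed=stage_seed())
    report["amova"] = json.loads(amova_res.to_series().to_json())
    report["amova"]["phi_ST"] = amova_res.phi_st
    if grouping_strategies:
        table, best = ps.compare_groupings(g, pm, grouping_strategies)
        report["grouping_comparison"] = {
            "table": table.to_dict(orient="records"), "best": best,
        }
    scores, pct = ps.pca_genotypes(g)
    report["pca"] = {"pct_variance_pc1": float(pct[0]), "pct_variance_pc2": float(pct[1]),
                     "pct_variance_pc3": float(pct[2]) if pct.size > 2 else None}

    # --- spatial structure --------------------------------------------------
    coords = geo.coordinates(pm.populations)
    gen12 = ps.population_mean_scores(scores, g, pm, axes=(0, 1))
    pro12 = sp.protest(gen12, coords, n_perm=cfg.n_perm_protest, seed=stage_seed())
    gen13 = ps.population_mean_scores(scores, g, pm, axes=(0, 2))
    pro13 = sp.protest(gen13, coords, n_perm=cfg.n_perm_protest, seed=stage_seed())
    report["procrustes"] = {
        "t0_pc12": pro12.t0, "p_pc12": pro12.p_value,
        "t0_pc13": pro13.t0, "p_pc13": pro13.p_value,
    }
    tri = sp.delaunay_graph(coords, pm.populations)
    mats = ps.resample_fst_matrices(g, pm, min(cfg.barrier_n_loci, g.n_loci),
                                    cfg.barrier_n_reps, stage_seed())
    barriers = sp.barrier_support(tri, mats, k=cfg.n_barriers)
    report["barriers"] = [
        {"priority": b.priority, "support": b.support,
         "edges": [list(e) for e in b.crossed_edges]}
        for b in barriers.barriers
    ]

    # --- ABC ----------------------------------------------------------------
    sub_ids = least_missing_individuals(g, pm, per_population=5)
    g_sub = g.subset_individuals(sub_ids)
    if pm.grouping is not None:
        # re-apply the presence/MAF filters on the subset so the observed loci
        # share the simulated datasets' ascertainment panel
        g_sub = filter_loci(g_sub, pm, cfg.min_group_presence, cfg.maf)

    def group_pm(groups: dict[str, str]):
        return pm.with_grouping(groups)

    def run_step(scens, priors, observed_sv, label):
        tbl = abc_mod.build_reference_table(
            scens, priors, cfg.abc_table_size, cfg.abc_n_loci, stage_seed(), maf=cfg.maf
        )
        # floor the retained count so the regression stages stay identifiable
        # when the table is small
        tol = min(1.0, max(cfg.abc_tolerance, 200 / tbl.n_rows))
        ret = abc_mod.reject(observed_sv, tbl, tol)
        choice = abc_mod.scenario_posterior(tbl, ret, observed_sv,
                                            n_bootstrap=cfg.n_bootstrap,
                                            seed=stage_seed())
        report[label] = {
            "posteriors": {n: float(p) for n, p in zip(choice.scenario_names, choice.probabilities)},
            "best": choice.best,
            "ci_low": None if choice.ci_low is None else [float(v) for v in choice.ci_low],
            "ci_high": None if choice.ci_high is None else [float(v) for v in choice.ci_high],
        }
        return tbl, ret, choice

    if pm.grouping is None:
        report["abc"] = "skipped: no grouping attached to the population map"
        return report

    grp_pm = pm
    groups = grp_pm.groups
    samples = {gname: sum(1 for i in sub_ids
                          if grp_pm.grouping[grp_pm.individual_to_population[i]] == gname)
               for gname in groups}

    # step 1: three-lineage topology choice
    if cfg.run_step1 and set(groups) == set(GROUPS):
        lineage_grouping = {p: LINEAGE_OF_GROUP[grp_pm.grouping[p]] for p in grp_pm.populations}
        lin_pm = grp_pm.with_grouping(lineage_grouping)
        lin_samples = {ln: 0 for ln in ("L1", "L2", "L3")}
        for gname, n_g in samples.items():
            lin_samples[LINEAGE_OF_GROUP[gname]] += n_g
        obs1 = abc_mod.summarize(g_sub, lin_pm, by="group")
        scens1, pris1 = step1_battery(lin_samples)
        run_step(scens1, pris1, obs1, "abc_step1")

    # step 2: divergence order of the six groups
    obs2 = abc_mod.summarize(g_sub, grp_pm, by="group")
    scens2, pris2 = step2_battery(samples)
    tbl2, ret2, choice2 = run_step(scens2, pris2, obs2, "abc_step2")
    best_sid = int(np.argmax(choice2.probabilities))
    post = abc_mod.adjust_parameters(tbl2, ret2, obs2, pris2[best_sid], scenario_id=best_sid)
    times = {}
    for t in ("t_G1", "t_G2", "t_G4", "t_G5", "t_G6"):
        if t in post.parameters:
            lo, hi = post.hpd(t)
            times[t] = {
                "median_generations": float(post.summary.set_index("parameter").loc[t, "median"]),
                "median_Ma": abc_mod.to_years(
                    float(post.summary.set_index("parameter").loc[t, "median"]),
                    cfg.generation_time,
                ) / 1e6,
                "hpd_low": lo, "hpd_high": hi,
            }
    report["abc_step2"]["divergence_times"] = times

    if cfg.run_step3:
        report["abc_step3"] = {}
        single_fn = lambda gg, _pm: abc_mod.SummaryVector(*_single_group_summary(gg))  # noqa: E731
        for gname in groups:
            if gname not in GROUPS:
                continue
            # step 3 uses all individuals of single-population groups, the
            # 5-per-population subset for multi-population groups
            multi = sum(1 for p in grp_pm.populations if grp_pm.grouping[p] == gname) > 1
            pool = sub_ids if multi else g.individual_ids
            members = [i for i in pool
                       if grp_pm.grouping[grp_pm.individual_to_population[i]] == gname]
            g_grp = g.subset_individuals(members)
            single = single_fn(g_grp, None)
            scens3, pris3 = step3_battery(gname, n_sample=len(members))
            tbl3 = abc_mod.build_reference_table(
                scens3, pris3, max(cfg.abc_table_size // 2, 200), cfg.abc_n_loci,
                stage_seed(), maf=cfg.maf, summary_fn=single_fn,
            )
            tol3 = min(1.0, max(cfg.abc_tolerance, 200 / tbl3.n_rows))
            ret3 = abc_mod.reject(single, tbl3, tol3)
            choice3 = abc_mod.scenario_posterior(tbl3, ret3, single, n_bootstrap=0,
                                                 seed=stage_seed())
            report["abc_step3"][gname] = {
                "posteriors": {n: float(p) for n, p in zip(choice3.scenario_names,
                                                           choice3.probabilities)},
                "best": choice3.best,
            }
    return report


def _single_group_summary(g) -> tuple[list[str], np.ndarray]:
    """Within-population summaries for a single-group ABC step (step 3)."""
    from .popgen_stats import _counts_by_unit
    from .snp_data import PopulationMap

    pm1 = PopulationMap({i: "X" for i in g.individual_ids})
    alt, n, het = _counts_by_unit(g, pm1.population_of(g), 1)
    n_copies = 2.0 * n[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n[0] > 0, alt[0] / np.maximum(n_copies, 1), np.nan)
        h = np.where(n_copies >= 2, 2 * p * (1 - p) * n_copies / np.maximum(n_copies - 1, 1e-12), np.nan)
    typed = n[0] > 0
    mono = float(((alt[0] <= 0) | (alt[0] >= n_copies))[typed].mean()) if typed.any() else 1.0
    good = np.isfinite(h)
    mean_h = float(h[good].mean()) if good.any() else 0.0
    var_h = float(h[good].var()) if good.any() else 0.0
    # folded allele-frequency spectrum moments add size-change information
    minor = np.fmin(p, 1 - p)
    m1 = float(np.nanmean(minor)) if np.isfinite(minor).any() else 0.0
    m2 = float(np.nanvar(minor)) if np.isfinite(minor).any() else 0.0
    return (["pmono", "meanH", "varH", "maf_mean", "maf_var"],
            np.array([mono, mean_h, var_h, m1, m2]))


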