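"""Structured-coalescent simulator of unlinked single-SNP loci.

Demographic histories are event lists over a set of populations: stepwise
size changes, divergences (child lineages merge into the parent, backward in
time), and admixture pulses (each lineage of the target moves to one of two
donors).  Each locus carries exactly one mutation, placed on a branch with
probability proportional to its length, so every simulated locus is a
polymorphic biallelic SNP.  Times are in generations; population sizes are
diploid effective sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
from numba import njit

from .snp_data import GenotypeMatrix, PopulationMap

ParamValue = Union[float, int, str]


class ScenarioError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Scenario description
# ---------------------------------------------------------------------------

@dataclass
class Population:
    name: str
    n_sample: int = 0          # diploid individuals sampled at time 0
    size: ParamValue = 1e4     # diploid N_e at time 0, or a prior parameter name


@dataclass
class SizeChange:
    population: str
    time: ParamValue
    new_size: ParamValue

    kind = "size_change"


@dataclass
class Divergence:
    child: str
    parent: str
    time: ParamValue

    kind = "divergence"


@dataclass
class Admixture:
    target: str
    donor_a: str
    donor_b: str
    rate: ParamValue           # probability a lineage moves to donor_a
    time: ParamValue

    kind = "admixture"


Event = Union[SizeChange, Divergence, Admixture]


@dataclass
class Scenario:
    """A demographic history with (possibly symbolic) parameters."""

    name: str
    populations: list[Population]
    events: list[Event] = field(default_factory=list)

    def population_names(self) -> list[str]:
        return [p.name for p in self.populations]

    def parameter_names(self) -> list[str]:
        """Prior parameter names referenced anywhere in the scenario."""
        names: dict[str, None] = {}

        def visit(v):
            if isinstance(v, str):
                names.setdefault(v, None)

        for p in self.populations:
            visit(p.size)
        for e in self.events:
            if isinstance(e, SizeChange):
                visit(e.time), visit(e.new_size)
            elif isinstance(e, Divergence):
                visit(e.time)
            else:
                visit(e.time), visit(e.rate)
        return list(names)

    def validate(self, params: dict[str, float] | None = None) -> None:
        """Check structural invariants; with ``params``, numeric ones too."""
        names = self.population_names()
        if len(set(names)) != len(names):
            raise ScenarioError("duplicate population names")
        active = set(names)
        for e in self.events:
            if isinstance(e, Divergence):
                if e.child not in active:
                    raise ScenarioError(f"divergence child {e.child!r} not active at its event")
                if e.parent not in active or e.parent == e.child:
                    raise ScenarioError(f"invalid divergence parent {e.parent!r}")
                active.discard(e.child)
            elif isinstance(e, Admixture):
                if e.target not in active:
                    raise ScenarioError(f"admixture target {e.target!r} not active")
                if {e.donor_a, e.donor_b} - active or e.target in (e.donor_a, e.donor_b):
                    raise ScenarioError("admixture donors must be distinct active populations")
                active.discard(e.target)
            elif isinstance(e, SizeChange):
                if e.population not in active:
                    raise ScenarioError(f"size change on inactive population {e.population!r}")
            else:  # pragma: no cover
                raise ScenarioError(f"unknown event {e!r}")
        sampled_roots = active
        if len(sampled_roots) != 1:
            raise ScenarioError(
                f"lineages must reach a single root population; {sorted(active)} remain"
            )
        if params is not None:
            comp = self.resolve(params)
            if (comp.ev_time <= 0).any():
                raise ScenarioError("event times must be strictly positive")
            admix = comp.ev_type == 2
            if ((comp.ev_r[admix] <= 0) | (comp.ev_r[admix] >= 1)).any():
                raise ScenarioError("admixture rate must lie in (0, 1)")
            if (comp.sizes0 <= 0).any() or (comp.ev_r[comp.ev_type == 0] <= 0).any():
                raise ScenarioError("population sizes must be positive")

    # -- numeric compilation -------------------------------------------------

    def resolve(self, params: dict[str, float]) -> "CompiledScenario":
        def val(v: ParamValue) -> float:
            if isinstance(v, str):
                try:
                    return float(params[v])
                except KeyError:
                    raise ScenarioError(f"missing parameter {v!r}") from None
            return float(v)

        pop_index = {p.name: i for i, p in enumerate(self.populations)}
        sample_sizes = np.array([p.n_sample for p in self.populations], dtype=np.int64)
        sizes0 = np.array([val(p.size) for p in self.populations])
        rows = []
        for order, e in enumerate(self.events):
            if isinstance(e, SizeChange):
                rows.append((val(e.time), order, 0, pop_index[e.population], -1, -1, val(e.new_size)))
            elif isinstance(e, Divergence):
                rows.append((val(e.time), order, 1, pop_index[e.child], pop_index[e.parent], -1, 0.0))
            else:
                rows.append(
                    (val(e.time), order, 2, pop_index[e.target], pop_index[e.donor_a],
                     pop_index[e.donor_b], val(e.rate))
                )
        rows.sort(key=lambda r: (r[0], r[1]))
        ev_time = np.array([r[0] for r in rows])
        ev_type = np.array([r[2] for r in rows], dtype=np.int64)
        ev_a = np.array([r[3] for r in rows], dtype=np.int64)
        ev_b = np.array([r[4] for r in rows], dtype=np.int64)
        ev_c = np.array([r[5] for r in rows], dtype=np.int64)
        ev_r = np.array([r[6] for r in rows])
        return CompiledScenario(
            self, sample_sizes, sizes0, ev_time, ev_type, ev_a, ev_b, ev_c, ev_r
        )

    # -- declarative config --------------------------------------------------

    def to_dict(self) -> dict:
        evs = []
        for e in self.events:
            d = {"kind": e.kind}
            d.update({k: v for k, v in e.__dict__.items()})
            evs.append(d)
        return {
            "name": self.name,
            "populations": [
                {"name": p.name, "n_sample": p.n_sample, "size": p.size}
                for p in self.populations
            ],
            "events": evs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        pops = [Population(**p) for p in d["populations"]]
        events: list[Event] = []
        for e in d["events"]:
            e = dict(e)
            kind = e.pop("kind")
            if kind == "size_change":
                events.append(SizeChange(**e))
            elif kind == "divergence":
                events.append(Divergence(**e))
            elif kind == "admixture":
                events.append(Admixture(**e))
            else:
                raise ScenarioError(f"unknown event kind {kind!r}")
        return cls(d["name"], pops, events)


@dataclass
class CompiledScenario:
    scenario: Scenario
    sample_sizes: np.ndarray   # diploid individuals per population
    sizes0: np.ndarray         # diploid N_e per population at time 0
    ev_time: np.ndarray
    ev_type: np.ndarray        # 0 size change, 1 divergence, 2 admixture
    ev_a: np.ndarray
    ev_b: np.ndarray
    ev_c: np.ndarray
    ev_r: np.ndarray

    @property
    def sample_pops(self) -> np.ndarray:
        """Population index per sampled haploid copy (2 per diploid)."""
        return np.repeat(np.arange(len(self.sample_sizes)), 2 * self.sample_sizes).astype(np.int64)

    def root_final_size(self) -> float:
        """Diploid size of the root population in the deepest epoch."""
        active = set(range(len(self.sizes0)))
        sizes = self.sizes0.copy()
        for k in range(len(self.ev_time)):
            if self.ev_type[k] == 0:
                sizes[self.ev_a[k]] = self.ev_r[k]
            else:  # divergence or admixture retires the child/target
                active.discard(int(self.ev_a[k]))
        root = next(iter(active)) if len(active) == 1 else max(active)
        return float(sizes[root])


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

@dataclass
class Prior:
    name: str
    dist: str                  # "uniform" | "loguniform"
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.dist not in ("uniform", "loguniform"):
            raise ScenarioError(f"unknown distribution {self.dist!r}")
        if not (np.isfinite(self.low) and np.isfinite(self.high) and self.low <= self.high):
            raise ScenarioError("prior bounds must be finite with low <= high")
        if self.dist == "loguniform" and self.low <= 0:
            raise ScenarioError("log-uniform bounds must be positive")

    def sample(self, rng: np.random.Generator, size=None):
        if self.dist == "uniform":
            return rng.uniform(self.low, self.high, size=size)
        return np.exp(rng.uniform(np.log(self.low), np.log(self.high), size=size))


@dataclass
class PriorSet:
    """Named priors plus pairwise order constraints (larger > smaller)."""

    priors: dict[str, Prior]
    constraints: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, b in self.constraints:
            if a not in self.priors or b not in self.priors:
                raise ScenarioError(f"constraint references unknown parameter ({a}, {b})")
        # reject cyclic constraint graphs (a > b > ... > a is unsatisfiable)
        edges = {a: set() for a, _ in self.constraints}
        for a, b in self.constraints:
            edges[a].add(b)
        seen: set[str] = set()

        def walk(node: str, stack: set[str]) -> None:
            if node in stack:
                raise ScenarioError("cyclic order constraints")
            if node in seen:
                return
            seen.add(node)
            for nxt in edges.get(node, ()):
                walk(nxt, stack | {node})

        for a in list(edges):
            walk(a, set())

    def names(self) -> list[str]:
        return list(self.priors)

    def to_dict(self) -> dict:
        return {
            "priors": [
                {"name": p.name, "dist": p.dist, "low": p.low, "high": p.high}
                for p in self.priors.values()
            ],
            "constraints": [list(c) for c in self.constraints],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSet":
        priors = {p["name"]: Prior(**p) for p in d["priors"]}
        return cls(priors, [tuple(c) for c in d.get("constraints", [])])


def draw_parameters(priors: PriorSet, seed: int | np.random.Generator) -> dict[str, float]:
    """Independent prior draws, rejected until all order constraints hold."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _ in range(100_000):
        params = {name: float(p.sample(rng)) for name, p in priors.priors.items()}
        if all(params[a] > params[b] for a, b in priors.constraints):
            return params
    raise ScenarioError("10^5 consecutive rejections: constraints look infeasible")


# ---------------------------------------------------------------------------
# Numba kernels
# ---------------------------------------------------------------------------

@njit(cache=False)
def _sim_tree_core(sample_pops, sizes, ev_time, ev_type, ev_a, ev_b, ev_c, ev_r,
                   parent, ntime, members, mcount):
    """Simulate one genealogy in place.  RNG state must be seeded by caller.

    ``members[p, :mcount[p]]`` holds the active lineage node ids of population
    p, so coalescent pair picks are O(1) and demographic events touch only the
    affected population's lineages.
    """
    n = sample_pops.shape[0]
    P = sizes.shape[0]
    for p in range(P):
        mcount[p] = 0
    for i in range(n):
        p = sample_pops[i]
        members[p, mcount[p]] = i
        mcount[p] += 1
        ntime[i] = 0.0
    n_active = n
    t = 0.0
    ev_i = 0
    next_node = n
    n_ev = ev_time.shape[0]
    while n_active > 1:
        total = 0.0
        for p in range(P):
            kp = mcount[p]
            if kp > 1:
                total += kp * (kp - 1) / 2.0 / (2.0 * sizes[p])
        if total > 0.0:
            w = np.random.exponential(1.0 / total)
        else:
            w = 1e300
        if ev_i < n_ev and t + w >= ev_time[ev_i]:
            t = ev_time[ev_i]
            et = ev_type[ev_i]
            a = ev_a[ev_i]
            if et == 0:
                sizes[a] = ev_r[ev_i]
            elif et == 1:
                b = ev_b[ev_i]
                for i in range(mcount[a]):
                    members[b, mcount[b]] = members[a, i]
                    mcount[b] += 1
                mcount[a] = 0
            else:
                b = ev_b[ev_i]
                c = ev_c[ev_i]
                r = ev_r[ev_i]
                for i in range(mcount[a]):
                    node = members[a, i]
                    if np.random.random() < r:
                        members[b, mcount[b]] = node
                        mcount[b] += 1
                    else:
                        members[c, mcount[c]] = node
                        mcount[c] += 1
                mcount[a] = 0
            ev_i += 1
            continue
        t += w
        u = np.random.random() * total
        acc = 0.0
        cp = -1
        for p in range(P):
            kp = mcount[p]
            if kp > 1:
                acc += kp * (kp - 1) / 2.0 / (2.0 * sizes[p])
                if u <= acc:
                    cp = p
                    break
        if cp == -1:
            for p in range(P - 1, -1, -1):
                if mcount[p] > 1:
                    cp = p
                    break
        k = mcount[cp]
        i1 = np.random.randint(0, k)
        i2 = np.random.randint(0, k - 1)
        if i2 >= i1:
            i2 += 1
        node1 = members[cp, i1]
        node2 = members[cp, i2]
        parent[node1] = next_node
        parent[node2] = next_node
        ntime[next_node] = t
        members[cp, i1] = next_node
        members[cp, i2] = members[cp, k - 1]
        mcount[cp] = k - 1
        n_active -= 1
        next_node += 1
    parent[2 * n - 2] = -1


@njit(cache=False)
def _place_mutation(parent, ntime, n):
    """Pick a branch with probability proportional to length; return its node."""
    totlen = 0.0
    for node in range(2 * n - 2):
        totlen += ntime[parent[node]] - ntime[node]
    u = np.random.random() * totlen
    acc = 0.0
    for node in range(2 * n - 2):
        acc += ntime[parent[node]] - ntime[node]
        if u <= acc:
            return node
    return 2 * n - 3


@njit(cache=False)
def _mark_derived(parent, mut, n, out_row):
    for leaf in range(n):
        node = leaf
        while node != -1:
            if node == mut:
                out_row[leaf] = 1
                break
            node = parent[node]


@njit(cache=False)
def _total_length(parent, ntime, n):
    tot = 0.0
    for node in range(2 * n - 2):
        tot += ntime[parent[node]] - ntime[node]
    return tot


@njit(cache=False)
def _pilot_lengths(sample_pops, sizes0, ev_time, ev_type, ev_a, ev_b, ev_c, ev_r,
                   n_pilot, seed):
    np.random.seed(seed)
    n = sample_pops.shape[0]
    P = sizes0.shape[0]
    out = np.empty(n_pilot)
    parent = np.empty(2 * n - 1, dtype=np.int64)
    ntime = np.empty(2 * n - 1, dtype=np.float64)
    members = np.empty((P, 2 * n), dtype=np.int64)
    mcount = np.empty(P, dtype=np.int64)
    sizes = np.empty(P, dtype=np.float64)
    for k in range(n_pilot):
        for p in range(P):
            sizes[p] = sizes0[p]
        _sim_tree_core(sample_pops, sizes, ev_time, ev_type, ev_a, ev_b, ev_c, ev_r,
                       parent, ntime, members, mcount)
        out[k] = _total_length(parent, ntime, n)
    return out


@njit(cache=False)
def _simulate_snp_batch(sample_pops, sizes0, ev_time, ev_type, ev_a, ev_b, ev_c, ev_r,
                        n_loci, seed, length_cap):
    """Simulate n_loci independent single-SNP loci; returns derived-allele
    indicators of shape (n_loci, n_copies).

    With ``length_cap > 0``, genealogies are accepted with probability
    min(1, L / length_cap), i.e. (up to a negligible truncated tail)
    proportionally to their total length L -- the distribution of the
    genealogy at a site ascertained to be a SNP in the low-mutation limit.
    With ``length_cap <= 0`` every genealogy is kept (plain fixed-one-mutation
    placement).
    """
    np.random.seed(seed)
    n = sample_pops.shape[0]
    P = sizes0.shape[0]
    derived = np.zeros((n_loci, n), dtype=np.uint8)
    parent = np.empty(2 * n - 1, dtype=np.int64)
    ntime = np.empty(2 * n - 1, dtype=np.float64)
    members = np.empty((P, 2 * n), dtype=np.int64)
    mcount = np.empty(P, dtype=np.int64)
    sizes = np.empty(P, dtype=np.float64)
    for locus in range(n_loci):
        while True:
            for p in range(P):
                sizes[p] = sizes0[p]
            _sim_tree_core(sample_pops, sizes, ev_time, ev_type, ev_a, ev_b, ev_c, ev_r,
                           parent, ntime, members, mcount)
            if length_cap <= 0.0:
                break
            tot = _total_length(parent, ntime, n)
            if tot >= length_cap or np.random.random() * length_cap < tot:
                break
        mut = _place_mutation(parent, ntime, n)
        _mark_derived(parent, mut, n, derived[locus])
    return derived


@njit(cache=False)
def _simulate_one_tree(sample_pops, sizes0, ev_time, ev_type, ev_a, ev_b, ev_c, ev_r, seed):
    np.random.seed(seed)
    n = sample_pops.shape[0]
    P = sizes0.shape[0]
    parent = np.empty(2 * n - 1, dtype=np.int64)
    ntime = np.empty(2 * n - 1, dtype=np.float64)
    members = np.empty((P, 2 * n), dtype=np.int64)
    mcount = np.empty(P, dtype=np.int64)
    sizes = sizes0.copy()
    _sim_tree_core(sample_pops, sizes, ev_time, ev_type, ev_a, ev_b, ev_c, ev_r,
                   parent, ntime, members, mcount)
    return parent, ntime


@njit(cache=False)
def _drop_snp_seeded(parent, ntime, n, seed):
    np.random.seed(seed)
    out = np.zeros(n, dtype=np.uint8)
    mut = _place_mutation(parent, ntime, n)
    _mark_derived(parent, mut, n, out)
    return out


# ---------------------------------------------------------------------------
# Public simulation API
# ---------------------------------------------------------------------------

@dataclass
class GenealogyTree:
    """Coalescent genealogy: leaves 0..n-1, internal nodes n..2n-2 (root last)."""

    parent: np.ndarray
    node_time: np.ndarray      # generations
    leaf_population: np.ndarray
    populations: list[str]

    @property
    def n_leaves(self) -> int:
        return (self.parent.shape[0] + 1) // 2

    @property
    def tmrca(self) -> float:
        return float(self.node_time[-1])

    @property
    def total_branch_length(self) -> float:
        n = self.n_leaves
        nodes = np.arange(2 * n - 2)
        return float((self.node_time[self.parent[nodes]] - self.node_time[nodes]).sum())

    def n_coalescences(self) -> int:
        return self.n_leaves - 1


def _seed_for(seed: int) -> int:
    """Map arbitrary ints into numba's legal seed range."""
    return int(np.uint32(seed))


def simulate_genealogy(
    scenario: Scenario, params: dict[str, float] | None, seed: int
) -> GenealogyTree:
    """Simulate the coalescent genealogy of one locus under ``scenario``."""
    params = params or {}
    scenario.validate(params)
    comp = scenario.resolve(params)
    if 2 * comp.sample_sizes.sum() < 2:
        raise ScenarioError("need at least 2 sampled haploid copies")
    parent, ntime = _simulate_one_tree(
        comp.sample_pops, comp.sizes0, comp.ev_time, comp.ev_type,
        comp.ev_a, comp.ev_b, comp.ev_c, comp.ev_r, _seed_for(seed),
    )
    return GenealogyTree(parent, ntime, comp.sample_pops, scenario.population_names())


def drop_snp(tree: GenealogyTree, seed: int) -> np.ndarray:
    """Place one mutation on the genealogy; returns derived-allele indicator
    per sampled haploid copy.  The locus is polymorphic by construction."""
    return _drop_snp_seeded(tree.parent, tree.node_time, tree.n_leaves, _seed_for(seed))


#: Tail margin (in units of 4 * root N) of the length-bias acceptance cap;
#: the weighted probability mass beyond the cap is ~exp(-12) of the tail.
_LENGTH_CAP_MARGIN = 12.0


def _length_cap(comp: CompiledScenario, seed: int, n_pilot: int = 16) -> float:
    pilot = _pilot_lengths(
        comp.sample_pops, comp.sizes0, comp.ev_time, comp.ev_type,
        comp.ev_a, comp.ev_b, comp.ev_c, comp.ev_r, n_pilot, _seed_for(seed),
    )
    return float(pilot.max() + _LENGTH_CAP_MARGIN * 4.0 * comp.root_final_size())


def simulate_snp_copies(
    scenario: Scenario, params, n_loci: int, seed: int, length_bias: bool = True
) -> np.ndarray:
    """(n_loci, n_copies) derived-allele indicators for haploid copies.

    ``length_bias=True`` (default) samples each locus genealogy proportionally
    to its total branch length before placing the single mutation, matching
    the distribution of an ascertained segregating site; this makes the
    derived-allele spectrum for a constant-size panmictic sample exactly
    proportional to 1/i.
    """
    if n_loci < 1:
        raise ScenarioError("n_loci must be >= 1")
    params = params or {}
    scenario.validate(params)
    comp = scenario.resolve(params)
    cap = _length_cap(comp, seed ^ 0x5F5F) if length_bias else -1.0
    return _simulate_snp_batch(
        comp.sample_pops, comp.sizes0, comp.ev_time, comp.ev_type,
        comp.ev_a, comp.ev_b, comp.ev_c, comp.ev_r, n_loci, _seed_for(seed), cap,
    )


def simulate_dataset(
    scenario: Scenario,
    params: dict[str, float] | None,
    n_loci: int,
    seed: int,
    maf: float | None = None,
    population_split: dict[str, list[tuple[str, int]]] | None = None,
    length_bias: bool = True,
) -> tuple[GenotypeMatrix, PopulationMap]:
    """Simulate a diploid SNP dataset under ``scenario``.

    Haploid copies are paired consecutively within each population (copies are
    exchangeable, so this is a uniform random pairing).  ``maf`` optionally
    applies the pooled minor-allele-frequency ascertainment filter.
    ``population_split`` maps a simulated population to a list of
    (subpopulation, n_individuals) used to relabel individuals; lineages
    within a simulated population are panmictic.
    """
    derived = simulate_snp_copies(scenario, params, n_loci, seed, length_bias=length_bias)
    geno = (derived[:, 0::2] + derived[:, 1::2]).T.astype(np.int16)  # (n_ind, n_loci)
    comp = scenario.resolve(params or {})
    pop_names = scenario.population_names()
    ind_pops: list[str] = []
    for p, ns in zip(pop_names, comp.sample_sizes):
        if population_split and p in population_split:
            split = population_split[p]
            if sum(c for _, c in split) != ns:
                raise ScenarioError(f"population_split for {p!r} does not sum to its sample size")
            for sub, c in split:
                ind_pops.extend([sub] * c)
        else:
            ind_pops.extend([p] * int(ns))
    ids = []
    counter: dict[str, int] = {}
    for p in ind_pops:
        counter[p] = counter.get(p, 0) + 1
        ids.append(f"{p}_{counter[p]:03d}")
    locus_ids = [f"L{j + 1:06d}" for j in range(n_loci)]
    g = GenotypeMatrix(geno, ids, locus_ids)
    if maf is not None:
        freq = g.allele_frequencies()
        minor = np.fmin(freq, 1 - freq)
        g = g.subset_loci(minor >= maf)
    pm = PopulationMap(dict(zip(ids, ind_pops)))
    return g, pm
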