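"""Genetic-geographic concordance and maximum-difference barriers.

Procrustes superimposition quantifies the similarity t0 in [0, 1] between the
population-mean genetic PC configuration and the geographic map; PROTEST is
its permutation test.  Monmonier's maximum-difference algorithm traces
genetic barriers along Voronoi edges of the population tessellation, crossing
at each step the Delaunay (population-pair) edge of largest genetic distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, Voronoi

from .popgen_stats import DistanceMatrix


class SpatialError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Procrustes / PROTEST
# ---------------------------------------------------------------------------

@dataclass
class ProcrustesResult:
    rotation: np.ndarray          # 2x2 orthogonal
    scale: float
    translation: np.ndarray       # applied to the centered, fitted configuration
    t0: float
    p_value: float | None = None


def _center_norm(x: np.ndarray):
    x = np.asarray(x, dtype=float)
    c = x.mean(axis=0)
    y = x - c
    ss = np.sqrt((y**2).sum())
    if ss == 0:
        raise SpatialError("degenerate configuration: all points identical")
    return y / ss, c, ss


def procrustes_t0(
    genetic: np.ndarray, geo: np.ndarray, allow_reflection: bool = False
) -> ProcrustesResult:
    """Procrustes similarity between two n x 2 configurations.

    Both configurations are centered and scaled to unit sum of squares; the
    optimal rotation comes from the SVD of the cross-product matrix.  With
    ``allow_reflection=False`` (default) the fit is restricted to proper
    rotations.  t0 = sqrt(1 - D) with D the residual sum of squares.
    """
    genetic = np.asarray(genetic, float)
    geo = np.asarray(geo, float)
    if genetic.shape != geo.shape or genetic.ndim != 2:
        raise SpatialError("configurations must have identical n x d shape")
    if genetic.shape[0] < 3:
        raise SpatialError("need at least 3 points")
    x, cx, ssx = _center_norm(genetic)   # configuration to be rotated
    y, cy, ssy = _center_norm(geo)       # target
    u, s, vt = np.linalg.svd(x.T @ y)
    if not allow_reflection and np.linalg.det(u @ vt) < 0:
        u = u.copy()
        u[:, -1] *= -1.0
        s = s.copy()
        s[-1] *= -1.0
    rotation = u @ vt
    trace = s.sum()
    scale = trace  # optimal scaling of the unit-normalized x onto y
    d_resid = max(0.0, 1.0 - trace**2)
    t0 = float(np.sqrt(max(0.0, 1.0 - d_resid)))
    return ProcrustesResult(rotation=rotation, scale=float(scale), translation=cy, t0=t0)


def protest(
    genetic: np.ndarray,
    geo: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
    allow_reflection: bool = False,
) -> ProcrustesResult:
    """Permutation test of the Procrustes similarity.

    Rows of the genetic configuration are permuted; ties count as >=, and the
    p-value carries the +1 correction: p = (#{t0_perm >= t0_obs} + 1)/(n_perm + 1).
    """
    if n_perm < 1:
        raise SpatialError("n_perm must be >= 1")
    res = procrustes_t0(genetic, geo, allow_reflection=allow_reflection)
    rng = np.random.default_rng(seed)
    genetic = np.asarray(genetic, float)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(genetic.shape[0])
        t0p = procrustes_t0(genetic[perm], geo, allow_reflection=allow_reflection).t0
        if t0p >= res.t0 - 1e-12:
            count += 1
    res.p_value = (count + 1) / (n_perm + 1)
    return res


# ---------------------------------------------------------------------------
# Delaunay / Voronoi tessellation
# ---------------------------------------------------------------------------

#: Sentinel for the unbounded side of a hull-crossing Voronoi edge.
OPEN_END = -1


@dataclass
class Triangulation:
    """Population tessellation: Delaunay edges paired with dual Voronoi edges.

    Each Delaunay edge (a population pair) is crossed by exactly one Voronoi
    ridge; ridges with an OPEN_END vertex reach the convex-hull boundary.
    """

    labels: list[str]
    points: np.ndarray
    edges: list[tuple[int, int]]                 # Delaunay edges (i < j population indices)
    voronoi_ends: list[tuple[int, int]]          # dual Voronoi vertex pair per edge
    voronoi_vertices: np.ndarray
    vertex_ridges: dict[int, list[int]] = field(default_factory=dict)

    @property
    def hull_edges(self) -> list[int]:
        return [k for k, (v1, v2) in enumerate(self.voronoi_ends) if OPEN_END in (v1, v2)]

    def edge_labels(self, k: int) -> tuple[str, str]:
        i, j = self.edges[k]
        return self.labels[i], self.labels[j]


def delaunay_graph(points: np.ndarray, labels: list[str] | None = None) -> Triangulation:
    """Delaunay/Voronoi dual graph of population coordinates.

    Raises on fewer than 3 points, duplicate points, or collinear input.
    """
    points = np.asarray(points, float)
    n = points.shape[0]
    if n < 3:
        raise SpatialError("need >= 3 populations")
    if labels is None:
        labels = [str(i) for i in range(n)]
    uniq = np.unique(points, axis=0)
    if uniq.shape[0] != n:
        raise SpatialError("duplicate coordinates")
    try:
        vor = Voronoi(points)
        dela = Delaunay(points)
    except Exception as e:
        raise SpatialError(f"degenerate (collinear?) configuration: {e}") from e
    ridge_of: dict[tuple[int, int], tuple[int, int]] = {}
    for (p1, p2), verts in zip(vor.ridge_points, vor.ridge_vertices):
        key = (int(min(p1, p2)), int(max(p1, p2)))
        ridge_of[key] = (int(verts[0]), int(verts[1]))
    del_edges: set[tuple[int, int]] = set()
    for simplex in dela.simplices:
        for a in range(3):
            i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
            del_edges.add((min(i, j), max(i, j)))
    edges: list[tuple[int, int]] = []
    ends: list[tuple[int, int]] = []
    for key in sorted(del_edges):
        if key in ridge_of:
            ends.append(ridge_of[key])
        else:
            # co-circular degeneracy: the dual Voronoi edge has zero length;
            # both ends sit on the shared circumcenter vertex
            ri = set(vor.regions[vor.point_region[key[0]]])
            rj = set(vor.regions[vor.point_region[key[1]]])
            common = sorted(v for v in ri & rj if v != -1)
            if not common:
                raise SpatialError(f"no dual Voronoi vertex for edge {key}")
            ends.append((common[0], common[0]))
        edges.append(key)
    vertex_ridges: dict[int, list[int]] = {}
    for k, (v1, v2) in enumerate(ends):
        for v in (v1, v2):
            if v != OPEN_END:
                vertex_ridges.setdefault(v, []).append(k)
    return Triangulation(list(labels), points, edges, ends, vor.vertices, vertex_ridges)


# ---------------------------------------------------------------------------
# Monmonier barriers
# ---------------------------------------------------------------------------

@dataclass
class Barrier:
    priority: int
    crossed_edges: list[tuple[str, str]]   # population pairs, in crossing order
    support: float | None = None


@dataclass
class BarrierResult:
    barriers: list[Barrier]
    labels: list[str]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "priority": [b.priority for b in self.barriers],
                "edges": ["; ".join(f"{a}-{b_}" for a, b_ in b.crossed_edges) for b in self.barriers],
                "support": [b.support for b in self.barriers],
            }
        )


def _edge_distance(tri: Triangulation, d: DistanceMatrix, k: int) -> float:
    i, j = tri.edges[k]
    li, lj = tri.labels[i], tri.labels[j]
    di = d.labels.index(li)
    dj = d.labels.index(lj)
    return float(d.values[di, dj])


def _tie_key(tri: Triangulation, k: int):
    return tri.edge_labels(k)


def monmonier_barriers(tri: Triangulation, d: DistanceMatrix, k: int = 1) -> BarrierResult:
    """Trace up to ``k`` maximum-difference barriers.

    Barrier i seeds at the not-yet-crossed Delaunay edge of maximal distance
    and grows from both ends of the seed's Voronoi edge (alternating ends);
    each step crosses the eligible adjacent Delaunay edge of maximal distance.
    A branch stops on reaching the convex hull or a Voronoi vertex already on
    any barrier.  Crossed edges become ineligible for later barriers.  Ties
    break lexicographically on the population-pair labels.
    """
    if k < 1:
        raise SpatialError("k must be >= 1")
    if set(tri.labels) - set(d.labels):
        raise SpatialError("distance matrix labels do not cover triangulation points")
    dist = np.array([_edge_distance(tri, d, e) for e in range(len(tri.edges))])
    used_edges = np.zeros(len(tri.edges), dtype=bool)
    visited_vertices: set[int] = set()
    barriers: list[Barrier] = []
    for priority in range(1, k + 1):
        candidates = np.flatnonzero(~used_edges)
        if candidates.size == 0:
            break
        seed = min(candidates, key=lambda e: (-dist[e], _tie_key(tri, e)))
        used_edges[seed] = True
        crossed = [seed]
        v1, v2 = tri.voronoi_ends[seed]
        seed_vertices = [v for v in (v1, v2)]
        # active growth ends (Voronoi vertices); OPEN_END terminates immediately
        ends = []
        for v in seed_vertices:
            if v == OPEN_END or v in visited_vertices:
                continue
            ends.append(v)
            visited_vertices.add(v)
        # grow alternately from both ends
        turn = 0
        order_front: list[int] = []   # edges crossed growing from end 0 (prepended)
        order_back: list[int] = [seed]
        while ends:
            turn_idx = turn % len(ends)
            v = ends[turn_idx]
            elig = [
                e for e in tri.vertex_ridges.get(v, [])
                if not used_edges[e]
                and (
                    (w := tri.voronoi_ends[e][1] if tri.voronoi_ends[e][0] == v else tri.voronoi_ends[e][0])
                    == OPEN_END
                    or w not in visited_vertices
                )
            ]
            if not elig:
                ends.pop(turn_idx)
                continue
            nxt = min(elig, key=lambda e: (-dist[e], _tie_key(tri, e)))
            used_edges[nxt] = True
            w = tri.voronoi_ends[nxt][1] if tri.voronoi_ends[nxt][0] == v else tri.voronoi_ends[nxt][0]
            if turn_idx == 0 and len(ends) > 1:
                order_front.append(nxt)
            else:
                order_back.append(nxt)
            if w == OPEN_END or w in visited_vertices:
                ends.pop(turn_idx)
            else:
                visited_vertices.add(w)
                ends[turn_idx] = w
            turn += 1
        crossed = list(reversed(order_front)) + order_back
        barriers.append(Barrier(priority, [tri.edge_labels(e) for e in crossed]))
    return BarrierResult(barriers, list(tri.labels))


def barrier_support(
    tri: Triangulation, matrices: list[DistanceMatrix], k: int = 10
) -> BarrierResult:
    """Barriers on the mean matrix, with bootstrap support per barrier.

    Support of barrier b = fraction of matrices whose own k-barrier solution
    crosses every Delaunay edge of b.
    """
    if not matrices:
        raise SpatialError("need at least one distance matrix")
    labels = matrices[0].labels
    for m in matrices[1:]:
        if m.labels != labels:
            raise SpatialError("inconsistent labels across distance matrices")
    mean = DistanceMatrix(labels, np.mean([m.values for m in matrices], axis=0))
    ref = monmonier_barriers(tri, mean, k)
    replicate_edge_sets = []
    for m in matrices:
        sol = monmonier_barriers(tri, m, k)
        crossed = set()
        for b in sol.barriers:
            crossed.update(frozenset(e) for e in b.crossed_edges)
        replicate_edge_sets.append(crossed)
    for b in ref.barriers:
        need = {frozenset(e) for e in b.crossed_edges}
        b.support = float(np.mean([need <= rep for rep in replicate_edge_sets]))
    return ref
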