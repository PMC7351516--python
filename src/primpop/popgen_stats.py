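"""Diversity, differentiation, hierarchical AMOVA, genotype PCA.

F_ST is the Weir & Cockerham (1984) theta estimator with multi-locus
ratio-of-sums combining.  AMOVA follows the squared-Euclidean-distance
sums-of-squares partition of Excoffier et al. (1992) on individual genotype
vectors, with missing data handled by pairwise-complete rescaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .snp_data import MISSING, GenotypeMatrix, PopulationMap, SnpDataError


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance (here: F_ST) matrix over populations."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("matrix not symmetric")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(c) for c in df.columns], df.to_numpy(float))

    def offdiagonal(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), 1)
        return self.values[iu]


@dataclass
class AmovaResult:
    """Three-level AMOVA variance components and Phi statistics."""

    sigma_among_groups: float
    sigma_among_pops_within: float
    sigma_within_pops: float
    phi_ct: float
    phi_sc: float
    phi_st: float
    percent: tuple[float, float, float]  # per level, sums to 100
    p_values: dict[str, float] | None = None
    degenerate: bool = False
    flags: list[str] | None = None

    @property
    def total(self) -> float:
        return self.sigma_among_groups + self.sigma_among_pops_within + self.sigma_within_pops

    def to_series(self) -> pd.Series:
        d = {
            "sigma_among_groups": self.sigma_among_groups,
            "sigma_among_pops_within_groups": self.sigma_among_pops_within,
            "sigma_within_pops": self.sigma_within_pops,
            "phi_CT": self.phi_ct,
            "phi_SC": self.phi_sc,
            "phi_ST": self.phi_st,
            "pct_among_groups": self.percent[0],
            "pct_among_pops_within_groups": self.percent[1],
            "pct_within_pops": self.percent[2],
        }
        if self.p_values:
            d.update({f"p_{k}": v for k, v in self.p_values.items()})
        return pd.Series(d)

    def write(self, path) -> None:
        """Key-value TSV of components, Phi statistics and p-values."""
        self.to_series().to_csv(path, sep="\t", header=False)


# ---------------------------------------------------------------------------
# Gene diversity
# ---------------------------------------------------------------------------

def _counts_by_unit(g: GenotypeMatrix, unit_idx: np.ndarray, n_units: int):
    """Per unit x locus: alt-allele copies, typed individuals, het individuals."""
    geno = g.genotypes
    typed = geno != MISSING
    alt = np.where(typed, geno, 0)
    het = (geno == 1)
    alt_u = np.zeros((n_units, g.n_loci))
    n_u = np.zeros((n_units, g.n_loci))
    het_u = np.zeros((n_units, g.n_loci))
    for u in range(n_units):
        rows = unit_idx == u
        alt_u[u] = alt[rows].sum(axis=0)
        n_u[u] = typed[rows].sum(axis=0)
        het_u[u] = het[rows].sum(axis=0)
    return alt_u, n_u, het_u


def expected_heterozygosity(alt: np.ndarray, n_ind: np.ndarray) -> np.ndarray:
    """Unbiased per-locus gene diversity H = 2p(1-p) * n/(n-1), n allele copies.

    Entries with fewer than 2 typed copies are NaN.
    """
    n = 2.0 * n_ind
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / n
        h = 2.0 * p * (1.0 - p) * n / (n - 1.0)
    return np.where(n >= 2, h, np.nan)


def gene_diversity(g: GenotypeMatrix, pm: PopulationMap) -> pd.DataFrame:
    """Per-population mean and variance over loci of expected heterozygosity."""
    pop_idx = pm.population_of(g)
    alt, n, _ = _counts_by_unit(g, pop_idx, len(pm.populations))
    if (n.sum(axis=1) == 0).any():
        empty = [pm.populations[i] for i in np.flatnonzero(n.sum(axis=1) == 0)]
        raise SnpDataError(f"population(s) with no typed genotypes: {empty}")
    h = expected_heterozygosity(alt, n)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(h, axis=1)
        var = np.nanvar(h, axis=1)
    return pd.DataFrame({"population": pm.populations, "mean_H": mean, "var_H": var})


# ---------------------------------------------------------------------------
# Weir & Cockerham F_ST
# ---------------------------------------------------------------------------

def _wc_components(alt: np.ndarray, n_ind: np.ndarray, het: np.ndarray):
    """Per-locus W&C (1984) a, b, c variance components for r populations.

    Inputs are (r, L) arrays of alt copies, typed individuals, heterozygote
    counts.  Loci where any population has 0 typed individuals, or with mean
    sample size <= 1, are masked (returned components are 0 there).
    """
    r = alt.shape[0]
    valid = (n_ind > 0).all(axis=0)
    n = np.where(n_ind > 0, n_ind, np.nan)
    nbar = np.nanmean(n, axis=0)
    valid &= nbar > 1
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / (2.0 * n)
        hbar = het.sum(axis=0) / (r * nbar)
        pbar = (n * p).sum(axis=0) / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        nc = (r * nbar - (n**2).sum(axis=0) / (r * nbar)) / (r - 1.0)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0
    a = np.where(valid, a, 0.0)
    b = np.where(valid, b, 0.0)
    c = np.where(valid, c, 0.0)
    return a, b, c, valid


def wc_theta(alt: np.ndarray, n_ind: np.ndarray, het: np.ndarray) -> float:
    """Multi-locus W&C theta as ratio of summed components."""
    a, b, c, _ = _wc_components(alt, n_ind, het)
    denom = (a + b + c).sum()
    if denom == 0:
        return 0.0
    return float(a.sum() / denom)


def pairwise_fst(g: GenotypeMatrix, pm: PopulationMap) -> DistanceMatrix:
    """Pairwise multi-locus Weir & Cockerham theta between all populations."""
    pops = pm.populations
    if len(pops) < 2:
        raise SnpDataError("need at least two populations")
    pop_idx = pm.population_of(g)
    alt, n, het = _counts_by_unit(g, pop_idx, len(pops))
    k = len(pops)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            shared = (n[i] > 0) & (n[j] > 0)
            if not shared.any():
                raise SnpDataError(f"populations {pops[i]!r} and {pops[j]!r} share no typed loci")
            theta = wc_theta(alt[[i, j]], n[[i, j]], het[[i, j]])
            out[i, j] = out[j, i] = theta
    return DistanceMatrix(list(pops), out)


def global_fst(g: GenotypeMatrix, pm: PopulationMap) -> float:
    """Multi-population W&C theta over all populations at once."""
    pop_idx = pm.population_of(g)
    alt, n, het = _counts_by_unit(g, pop_idx, len(pm.populations))
    return wc_theta(alt, n, het)


def resample_fst_matrices(
    g: GenotypeMatrix,
    pm: PopulationMap,
    n_loci: int,
    n_reps: int,
    seed: int,
) -> list[DistanceMatrix]:
    """Locus-resampled pairwise F_ST matrices (sampling without replacement)."""
    if n_loci > g.n_loci:
        raise ValueError(f"n_loci={n_loci} exceeds available loci ({g.n_loci})")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_reps):
        keep = np.sort(rng.choice(g.n_loci, size=n_loci, replace=False))
        out.append(pairwise_fst(g.subset_loci(keep), pm))
    return out


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

def squared_distance_matrix(g: GenotypeMatrix) -> np.ndarray:
    """Pairwise squared Euclidean distances between individual genotype rows.

    Computed over pairwise-complete loci and rescaled by n_loci / n_shared so
    individuals with different missingness patterns are comparable.
    """
    geno = g.genotypes.astype(float)
    mask = (g.genotypes != MISSING).astype(float)
    gz = np.where(mask > 0, geno, 0.0)
    shared = mask @ mask.T
    sq = gz**2
    ss = (sq @ mask.T) + (mask @ sq.T) - 2.0 * (gz @ gz.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = g.n_loci * ss / shared
    d2 = np.where(shared > 0, d2, np.nan)
    np.fill_diagonal(d2, 0.0)
    if np.isnan(d2).any():
        raise SnpDataError("individual pair with no shared typed loci")
    return d2


def _ssd_partition(d2: np.ndarray, pop_idx: np.ndarray, grp_of_pop: np.ndarray):
    """SSD total / among-group / among-pop-within / within-pop from d2/2 sums."""
    n = d2.shape[0]
    ssd_total = d2.sum() / 2.0 / n  # sum_{i<j} d2 / n  (d2 symmetric)
    pops = np.unique(pop_idx)
    ssd_wp = 0.0
    for p in pops:
        idx = np.flatnonzero(pop_idx == p)
        if idx.size:
            ssd_wp += d2[np.ix_(idx, idx)].sum() / 2.0 / idx.size
    grp_idx = grp_of_pop[pop_idx]
    ssd_wg = 0.0
    for gk in np.unique(grp_idx):
        idx = np.flatnonzero(grp_idx == gk)
        ssd_wg += d2[np.ix_(idx, idx)].sum() / 2.0 / idx.size
    ssd_ap = ssd_wg - ssd_wp
    ssd_ag = ssd_total - ssd_wg
    return ssd_total, ssd_ag, ssd_ap, ssd_wp


def _amova_components(d2, pop_idx, grp_of_pop):
    """Variance components (sigma_a, sigma_b, sigma_c) of the 3-level design."""
    n = d2.shape[0]
    pops = np.unique(pop_idx)
    n_pops = pops.size
    grp_idx = grp_of_pop[pop_idx]
    groups = np.unique(grp_of_pop[pop_idx])
    n_groups = groups.size
    _, ssd_ag, ssd_ap, ssd_wp = _ssd_partition(d2, pop_idx, grp_of_pop)
    df_ag = n_groups - 1
    df_ap = n_pops - n_groups
    df_wp = n - n_pops
    if df_wp <= 0 or df_ag <= 0:
        raise SnpDataError("degenerate AMOVA design")
    ms_wp = ssd_wp / df_wp
    sizes = np.array([(pop_idx == p).sum() for p in pops], dtype=float)
    gsizes = {gk: (grp_idx == gk).sum() for gk in groups}
    # Excoffier n-coefficients
    sum_sq_by_group = {gk: 0.0 for gk in groups}
    for p, sz in zip(pops, sizes):
        sum_sq_by_group[grp_of_pop[p]] += sz**2
    s1 = sum(sum_sq_by_group[gk] / gsizes[gk] for gk in groups)
    n1 = (n - s1) / df_ap if df_ap > 0 else np.nan
    n2 = (s1 - (sizes**2).sum() / n) / df_ag
    n3 = (n - sum(gsizes[gk] ** 2 for gk in groups) / n) / df_ag
    sigma_c = ms_wp
    if df_ap > 0:
        ms_ap = ssd_ap / df_ap
        sigma_b = (ms_ap - sigma_c) / n1
    else:
        sigma_b = 0.0
    ms_ag = ssd_ag / df_ag
    sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3
    return sigma_a, sigma_b, sigma_c, df_ap


def _phi_stats(sigma_a, sigma_b, sigma_c):
    total = sigma_a + sigma_b + sigma_c
    if total <= 0:
        return 0.0, 0.0, 0.0
    phi_ct = sigma_a / total
    phi_sc = sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) > 0 else 0.0
    phi_st = (sigma_a + sigma_b) / total
    return phi_ct, phi_sc, phi_st


def amova(
    g: GenotypeMatrix,
    pm: PopulationMap,
    grouping: dict[str, str] | None = None,
    n_perm: int = 0,
    seed: int = 0,
) -> AmovaResult:
    """Three-level AMOVA (groups / populations within groups / within populations).

    Permutation tests: Phi_CT permutes whole populations among groups, Phi_SC
    permutes individuals among populations within groups, Phi_ST permutes
    individuals among all populations.  p = (#{perm >= obs} + 1) / (n_perm + 1).
    """
    pmx = pm if grouping is None else pm.with_grouping(grouping)
    if pmx.grouping is None:
        raise SnpDataError("AMOVA needs a grouping")
    if len(pmx.groups) < 2:
        raise SnpDataError("need >= 2 groups")
    pop_idx = pmx.population_of(g)
    group_names = pmx.groups
    glookup = {name: i for i, name in enumerate(group_names)}
    grp_of_pop = np.array([glookup[pmx.grouping[p]] for p in pmx.populations])
    d2 = squared_distance_matrix(g)
    sigma_a, sigma_b, sigma_c, df_ap = _amova_components(d2, pop_idx, grp_of_pop)
    flags = []
    if df_ap <= 0:
        flags.append("phi_SC undefined: every group has a single population")
    total = sigma_a + sigma_b + sigma_c
    degenerate = total <= 0
    if degenerate:
        percent = (0.0, 0.0, 0.0)
        phi = (0.0, 0.0, 0.0)
        flags.append("zero total variance")
    else:
        percent = tuple(100.0 * s / total for s in (sigma_a, sigma_b, sigma_c))
        phi = _phi_stats(sigma_a, sigma_b, sigma_c)
    p_values = None
    if n_perm > 0 and not degenerate:
        rng = np.random.default_rng(seed)
        obs_ct, obs_sc, obs_st = phi
        n_pops = len(pmx.populations)
        count_ct = count_sc = count_st = 0
        for _ in range(n_perm):
            # Phi_CT: permute populations among groups
            perm_g = grp_of_pop[rng.permutation(n_pops)]
            s = _amova_components(d2, pop_idx, perm_g)
            count_ct += _phi_stats(*s[:3])[0] >= obs_ct
            # Phi_SC: permute individuals among pops within groups
            perm_pop = pop_idx.copy()
            for gk in range(len(group_names)):
                rows = np.flatnonzero(grp_of_pop[pop_idx] == gk)
                perm_pop[rows] = pop_idx[rows][rng.permutation(rows.size)]
            s = _amova_components(d2, perm_pop, grp_of_pop)
            count_sc += _phi_stats(*s[:3])[1] >= obs_sc
            # Phi_ST: permute individuals among all populations
            perm_all = pop_idx[rng.permutation(len(pop_idx))]
            s = _amova_components(d2, perm_all, grp_of_pop)
            count_st += _phi_stats(*s[:3])[2] >= obs_st
        p_values = {
            "phi_CT": (count_ct + 1) / (n_perm + 1),
            "phi_SC": (count_sc + 1) / (n_perm + 1),
            "phi_ST": (count_st + 1) / (n_perm + 1),
        }
    return AmovaResult(
        sigma_a, sigma_b, sigma_c, *phi, percent=percent, p_values=p_values,
        degenerate=degenerate, flags=flags or None,
    )


def compare_groupings(
    g: GenotypeMatrix,
    pm: PopulationMap,
    strategies: dict[str, dict[str, str]],
) -> tuple[pd.DataFrame, str]:
    """Percent among-group variance per grouping strategy; best = argmax.

    Ties are broken in favour of the strategy with fewer groups.  Strategies
    whose AMOVA fails are skipped with a NaN row.
    """
    if len(strategies) < 2 and len(strategies) != 1:
        raise ValueError("need at least one strategy")
    rows = []
    for name, grouping in strategies.items():
        n_groups = len(set(grouping.values()))
        try:
            res = amova(g, pm, grouping=grouping, n_perm=0)
            rows.append((name, n_groups, res.percent[0], res.phi_ct))
        except SnpDataError:
            rows.append((name, n_groups, np.nan, np.nan))
    df = pd.DataFrame(rows, columns=["strategy", "n_groups", "pct_among_groups", "phi_CT"])
    ok = df.dropna(subset=["pct_among_groups"])
    if ok.empty:
        raise SnpDataError("no strategy produced a valid AMOVA")
    best = ok.sort_values(["pct_among_groups", "n_groups"], ascending=[False, True]).iloc[0]
    return df, str(best["strategy"])


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_genotypes(g: GenotypeMatrix, n_axes: int | None = None):
    """PCA of the genotype matrix.

    Missing entries are replaced by the locus mean; columns are centered but
    not variance-scaled.  Returns (scores, percent_variance) where percent
    variance is eigenvalue / trace * 100 over all axes.
    """
    if g.n_individuals < 2 or g.n_loci < 2:
        raise SnpDataError("PCA needs >= 2 individuals and >= 2 loci")
    geno = g.genotypes.astype(float)
    typed = g.genotypes != MISSING
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(typed, geno, 0).sum(axis=0) / np.maximum(typed.sum(axis=0), 1)
    x = np.where(typed, geno, mean[None, :]) - mean[None, :]
    if not x.any():
        raise SnpDataError("zero-variance genotype matrix")
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    ev = s**2
    pct = 100.0 * ev / ev.sum()
    scores = u * s
    if n_axes is not None:
        scores = scores[:, :n_axes]
    return scores, pct


def population_mean_scores(
    scores: np.ndarray, g: GenotypeMatrix, pm: PopulationMap, axes: tuple[int, int] = (0, 1)
) -> np.ndarray:
    """Mean PC scores per population on the requested axes (population order)."""
    pop_idx = pm.population_of(g)
    out = np.zeros((len(pm.populations), len(axes)))
    for i in range(len(pm.populations)):
        rows = pop_idx == i
        if not rows.any():
            raise SnpDataError(f"population {pm.populations[i]!r} has no individuals")
        out[i] = scores[rows][:, list(axes)].mean(axis=0)
    return out
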