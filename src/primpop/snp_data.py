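"""Data model and I/O for diploid biallelic SNP genotypes.

Genotypes are stored as alternate-allele counts (0, 1, 2) with a missing
sentinel.  The on-disk formats are VCF (read via cyvcf2) and a plain TSV
genotype table; population membership, group assignments and population
coordinates are plain TSVs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing diploid genotype, both in memory and in the table format.
MISSING: int = -9

_VALID_CODES = frozenset({0, 1, 2, MISSING})


class SnpDataError(ValueError):
    """Malformed genotype input (non-biallelic site, duplicate ids, bad codes)."""


@dataclass
class GenotypeMatrix:
    """Individuals x loci matrix of alternate-allele counts.

    Parameters
    ----------
    genotypes
        ``(n_individuals, n_loci)`` integer array with entries in
        ``{0, 1, 2, MISSING}``.
    individual_ids, locus_ids
        Unique string identifiers for rows and columns.
    """

    genotypes: np.ndarray
    individual_ids: list[str]
    locus_ids: list[str]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int16)
        if self.genotypes.ndim != 2:
            raise SnpDataError("genotypes must be a 2-D array")
        n, m = self.genotypes.shape
        if m < 1:
            raise SnpDataError("need at least one locus")
        if len(self.individual_ids) != n or len(self.locus_ids) != m:
            raise SnpDataError("id lists do not match matrix shape")
        if len(set(self.individual_ids)) != n:
            raise SnpDataError("duplicated individual id")
        if len(set(self.locus_ids)) != m:
            raise SnpDataError("duplicated locus id")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise SnpDataError(f"invalid genotype codes: {np.unique(self.genotypes[bad])}")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def typed_mask(self) -> np.ndarray:
        """Boolean mask of non-missing genotypes."""
        return self.genotypes != MISSING

    def missing_fraction(self) -> float:
        return float((self.genotypes == MISSING).mean())

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.individual_ids.index(i) for i in ids]
        return GenotypeMatrix(self.genotypes[idx], list(ids), list(self.locus_ids))

    def subset_loci(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Subset by boolean mask or integer index array over loci."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            self.genotypes[:, keep],
            list(self.individual_ids),
            [self.locus_ids[j] for j in keep],
        )

    def allele_frequencies(self) -> np.ndarray:
        """Pooled alternate-allele frequency per locus, ignoring missing."""
        typed = self.typed_mask
        alt = np.where(typed, self.genotypes, 0).sum(axis=0)
        n_copies = 2 * typed.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_copies > 0, alt / np.maximum(n_copies, 1), np.nan)


@dataclass
class PopulationMap:
    """Individual -> population assignment plus an optional population -> group map.

    The population order is preserved as given (or first-appearance order) and
    used as the canonical label order in distance matrices and AMOVA output.
    """

    individual_to_population: dict[str, str]
    grouping: dict[str, str] | None = None
    populations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.populations:
            seen: dict[str, None] = {}
            for p in self.individual_to_population.values():
                seen.setdefault(p, None)
            self.populations = list(seen)
        missing = set(self.individual_to_population.values()) - set(self.populations)
        if missing:
            raise SnpDataError(f"populations absent from ordering: {sorted(missing)}")
        if self.grouping is not None:
            unassigned = set(self.populations) - set(self.grouping)
            if unassigned:
                raise SnpDataError(f"populations without group: {sorted(unassigned)}")

    @property
    def groups(self) -> list[str]:
        """Group labels in sorted order (stable across population orderings)."""
        if self.grouping is None:
            raise SnpDataError("no grouping attached")
        return sorted({self.grouping[p] for p in self.populations})

    def with_grouping(self, grouping: Mapping[str, str]) -> "PopulationMap":
        return PopulationMap(dict(self.individual_to_population), dict(grouping), list(self.populations))

    def population_of(self, g: GenotypeMatrix) -> np.ndarray:
        """Population index (into ``self.populations``) per row of ``g``."""
        lookup = {p: i for i, p in enumerate(self.populations)}
        try:
            return np.array([lookup[self.individual_to_population[i]] for i in g.individual_ids])
        except KeyError as e:  # pragma: no cover - defensive
            raise SnpDataError(f"individual not in population map: {e}") from e

    def group_of(self, g: GenotypeMatrix) -> np.ndarray:
        """Group index (into ``self.groups``) per row of ``g``."""
        groups = self.groups
        lookup = {name: i for i, name in enumerate(groups)}
        return np.array(
            [lookup[self.grouping[self.individual_to_population[i]]] for i in g.individual_ids]
        )


@dataclass
class GeoTable:
    """Population coordinates in decimal degrees (planar use downstream)."""

    table: pd.DataFrame  # columns: population, longitude, latitude[, elevation]

    def __post_init__(self) -> None:
        required = {"population", "longitude", "latitude"}
        if not required.issubset(self.table.columns):
            raise SnpDataError(f"coordinate table needs columns {sorted(required)}")
        if self.table["population"].duplicated().any():
            raise SnpDataError("duplicate population in coordinate table")
        coords = self.table[["longitude", "latitude"]].to_numpy(float)
        if not np.isfinite(coords).all():
            raise SnpDataError("non-finite coordinates")

    @property
    def populations(self) -> list[str]:
        return list(self.table["population"])

    def coordinates(self, populations: Sequence[str] | None = None) -> np.ndarray:
        """(n, 2) array of (longitude, latitude) in the requested order."""
        df = self.table.set_index("population")
        pops = list(populations) if populations is not None else self.populations
        return df.loc[pops, ["longitude", "latitude"]].to_numpy(float)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_genotypes(path: str | os.PathLike, format: str = "table") -> GenotypeMatrix:
    """Read a genotype matrix from ``path``.

    ``format="vcf"`` accepts biallelic SNP records with a GT field; half
    missing calls (``./1``) are coded MISSING.  ``format="table"`` reads the
    TSV dialect written by :func:`write_genotypes`.
    """
    if format == "vcf":
        return _read_vcf(os.fspath(path))
    if format == "table":
        return _read_table(os.fspath(path))
    raise ValueError(f"unknown format: {format!r}")


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise SnpDataError("duplicated individual id in VCF header")
    codes: list[np.ndarray] = []
    locus_ids: list[str] = []
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            name = var.ID or f"{var.CHROM}:{var.POS}"
            raise SnpDataError(f"non-biallelic-SNP site {name} (ALT={','.join(var.ALT)})")
        gts = var.genotype.array()  # (n, 3): allele1, allele2, phased
        a1, a2 = gts[:, 0], gts[:, 1]
        col = np.where((a1 < 0) | (a2 < 0), MISSING, a1 + a2)
        codes.append(col.astype(np.int16))
        locus_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
    if not codes:
        raise SnpDataError("empty VCF")
    return GenotypeMatrix(np.column_stack(codes), samples, locus_ids)


def _read_table(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    locus_ids = list(df.columns[1:])
    ids = list(df.iloc[:, 0])
    if len(set(ids)) != len(ids):
        raise SnpDataError("duplicated individual id in genotype table")
    return GenotypeMatrix(df.iloc[:, 1:].to_numpy(np.int16), ids, locus_ids)


def write_genotypes(g: GenotypeMatrix, path: str | os.PathLike, format: str = "table") -> None:
    """Write ``g`` to ``path`` in the table or a minimal VCF dialect."""
    path = os.fspath(path)
    if format == "table":
        df = pd.DataFrame(g.genotypes, columns=g.locus_ids)
        df.insert(0, "individual", g.individual_ids)
        df.to_csv(path, sep="\t", index=False)
    elif format == "vcf":
        _write_vcf(g, path)
    else:
        raise ValueError(f"unknown format: {format!r}")


def _write_vcf(g: GenotypeMatrix, path: str) -> None:
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.individual_ids) + "\n")
        for j, locus in enumerate(g.locus_ids):
            calls = "\t".join(gt_str[int(c)] for c in g.genotypes[:, j])
            fh.write(f"1\t{j + 1}\t{locus}\tA\tT\t.\t.\t.\tGT\t{calls}\n")


def read_population_map(path: str | os.PathLike, grouping_path: str | os.PathLike | None = None) -> PopulationMap:
    """Read individual->population TSV and (optionally) a population->group TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    ind2pop = dict(zip(df["individual"], df["population"]))
    grouping = None
    if grouping_path is not None:
        gdf = pd.read_csv(grouping_path, sep="\t", dtype=str)
        grouping = dict(zip(gdf["population"], gdf["group"]))
    return PopulationMap(ind2pop, grouping)


def write_population_map(pm: PopulationMap, path: str | os.PathLike, grouping_path: str | os.PathLike | None = None) -> None:
    pd.DataFrame(
        {"individual": list(pm.individual_to_population),
         "population": list(pm.individual_to_population.values())}
    ).to_csv(path, sep="\t", index=False)
    if grouping_path is not None and pm.grouping is not None:
        pd.DataFrame(
            {"population": pm.populations,
             "group": [pm.grouping[p] for p in pm.populations]}
        ).to_csv(grouping_path, sep="\t", index=False)


def read_geo_table(path: str | os.PathLike) -> GeoTable:
    return GeoTable(pd.read_csv(path, sep="\t", dtype={"population": str}))


def write_geo_table(geo: GeoTable, path: str | os.PathLike) -> None:
    geo.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Filtering and missingness
# ---------------------------------------------------------------------------

def filter_loci(
    g: GenotypeMatrix,
    pm: PopulationMap,
    min_group_presence: float = 0.8,
    maf: float = 0.01,
) -> GenotypeMatrix:
    """Apply the study's locus filters.

    A locus is retained when it is (i) typed in at least ``min_group_presence``
    of the individuals of *every* group, (ii) polymorphic in the pooled
    sample, and (iii) has pooled minor allele frequency >= ``maf`` (missing
    genotypes ignored).  Locus order is preserved.
    """
    if not (0 <= min_group_presence <= 1 and 0 <= maf <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    if pm.grouping is not None:
        group_idx = pm.group_of(g)
        n_units = len(pm.groups)
    else:
        group_idx = pm.population_of(g)
        n_units = len(pm.populations)
    typed = g.typed_mask
    keep = np.ones(g.n_loci, dtype=bool)
    for u in range(n_units):
        rows = group_idx == u
        n_u = int(rows.sum())
        if n_u == 0:
            unit = (pm.groups if pm.grouping is not None else pm.populations)[u]
            raise SnpDataError(f"group {unit!r} has no individuals")
        keep &= typed[rows].sum(axis=0) >= min_group_presence * n_u
    freq = g.allele_frequencies()
    with np.errstate(invalid="ignore"):
        minor = np.fmin(freq, 1.0 - freq)
        keep &= np.nan_to_num(minor, nan=-1.0) > 0  # polymorphic pooled
        keep &= np.nan_to_num(minor, nan=-1.0) >= maf
    return g.subset_loci(keep)


def inject_missingness(g: GenotypeMatrix, rate: float, seed: int) -> GenotypeMatrix:
    """Set each genotype to MISSING independently with probability ``rate``."""
    if not (0 <= rate < 1):
        raise ValueError("rate must lie in [0, 1)")
    if rate == 0:
        return GenotypeMatrix(g.genotypes.copy(), list(g.individual_ids), list(g.locus_ids))
    rng = np.random.default_rng(seed)
    mask = rng.random(g.genotypes.shape) < rate
    geno = np.where(mask, MISSING, g.genotypes).astype(np.int16)
    return GenotypeMatrix(geno, list(g.individual_ids), list(g.locus_ids))
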