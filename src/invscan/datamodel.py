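"""Core domain types for inversion scanning on a fragmented linkage map.

Genotypes are stored as alternate-allele counts (0/1/2) with -1 for missing;
heterozygosity only needs the value 1, so phase is ignored throughout.
Map coordinates are centimorgans (cM) on integer-labelled linkage groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic SNP anchored to the linkage map via its contig."""

    snp_id: str
    contig: str
    lg: int
    cm: float
    alleles: tuple[str, str]

    def __post_init__(self) -> None:
        if len(self.alleles) != 2:
            raise ValueError(f"{self.snp_id}: exactly 2 alleles required")
        if self.cm < 0:
            raise ValueError(f"{self.snp_id}: cM position must be non-negative")


@dataclass
class GenotypeTable:
    """Individuals x SNPs matrix of alternate-allele counts.

    Parameters
    ----------
    samples : list of str
        Ordered individual ids (rows).
    snps : list of SnpRecord
        Ordered SNP records (columns).
    genotypes : ndarray of int8, shape (n_samples, n_snps)
        Values in {0, 1, 2} or MISSING (-1).
    """

    samples: list[str]
    snps: list[SnpRecord]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        bad = ~np.isin(self.genotypes, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotypes must be in {0, 1, 2} or -1 (missing)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_frame(self) -> pd.DataFrame:
        """Per-SNP map coordinates as a DataFrame (snp_id, contig, lg, cm)."""
        return pd.DataFrame(
            {
                "snp_id": [s.snp_id for s in self.snps],
                "contig": [s.contig for s in self.snps],
                "lg": [s.lg for s in self.snps],
                "cm": [s.cm for s in self.snps],
            }
        )

    def take_snps(self, index: np.ndarray) -> "GenotypeTable":
        """Column subset by integer indices or boolean mask (order preserved)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeTable(
            samples=list(self.samples),
            snps=[self.snps[i] for i in index],
            genotypes=self.genotypes[:, index],
        )

    def take_samples(self, ids: list[str]) -> "GenotypeTable":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[s] for s in ids]
        return GenotypeTable(
            samples=list(ids),
            snps=list(self.snps),
            genotypes=self.genotypes[idx, :],
        )

    def het_counts(self, snp_mask: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Per-individual (k, n): heterozygous and genotyped SNP counts."""
        g = self.genotypes if snp_mask is None else self.genotypes[:, np.asarray(snp_mask)]
        called = g != MISSING
        return (g == 1).sum(axis=1), called.sum(axis=1)


ECOTYPES = ("crab", "wave", "barnacle", "brackish", "other")
GROUPS = ("northern_saxatilis", "iberian_saxatilis", "arcana", "compressa")


def validate_meta(meta: pd.DataFrame, table: GenotypeTable | None = None) -> pd.DataFrame:
    """Validate a sample metadata table (individual, location, ecotype, group)."""
    required = {"individual", "location", "ecotype", "group"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    bad_eco = set(meta["ecotype"]) - set(ECOTYPES)
    if bad_eco:
        raise ValueError(f"unknown ecotypes: {sorted(bad_eco)}")
    bad_grp = set(meta["group"]) - set(GROUPS)
    if bad_grp:
        raise ValueError(f"unknown groups: {sorted(bad_grp)}")
    if meta["individual"].duplicated().any():
        dups = meta.loc[meta["individual"].duplicated(), "individual"].tolist()
        raise ValueError(f"duplicated individuals in metadata: {dups}")
    if table is not None:
        absent = set(table.samples) - set(meta["individual"])
        if absent:
            raise ValueError(f"samples without metadata: {sorted(absent)}")
    return meta


@dataclass
class MapTable:
    """Contig -> linkage-map placement after marker filtering.

    `frame` has one row per contig: contig, lg, cm_mean, n_markers; `positions`
    keeps the retained marker positions per contig.
    """

    frame: pd.DataFrame
    positions: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for contig, pos in self.positions.items():
            row = self.frame.loc[self.frame["contig"] == contig]
            if len(row) and pos:
                assert abs(row["cm_mean"].iloc[0] - float(np.mean(pos))) < 1e-9

    def lookup(self, contig: str) -> tuple[int, float] | None:
        row = self.frame.loc[self.frame["contig"] == contig]
        if row.empty:
            return None
        return int(row["lg"].iloc[0]), float(row["cm_mean"].iloc[0])

    @property
    def contigs(self) -> set[str]:
        return set(self.frame["contig"])


@dataclass(frozen=True)
class InversionRegion:
    """A named putative inversion (LGC) as a cM interval on one linkage group."""

    name: str
    lg: int
    start_cm: float
    end_cm: float
    complex_flag: bool = False  # three arrangements expected (overlapping inversions)

    def __post_init__(self) -> None:
        if not self.start_cm < self.end_cm:
            raise ValueError(f"{self.name}: start_cm must be < end_cm")

    def contains(self, cm: np.ndarray) -> np.ndarray:
        cm = np.asarray(cm, dtype=float)
        return (cm >= self.start_cm) & (cm <= self.end_cm)
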