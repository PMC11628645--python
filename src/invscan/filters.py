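"""SNP, map-marker and boundary filters, plus 1-cM window assignment.

These are the bookkeeping steps between a raw call set and the detection
methods: site-quality filtering of already-called SNPs, trimming of
inconsistent linkage-map markers, transfer of published inversion boundaries
onto the filtered map, and partition of mapped SNPs into non-overlapping
1-cM windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import GenotypeTable, InversionRegion, MapTable

SNP_FILTER_COLUMNS = ("snp_id", "qual", "maf", "n_alleles", "mean_depth")


def filter_snps(
    table: GenotypeTable,
    site_stats: pd.DataFrame,
    map_table: MapTable | None = None,
    min_qual: float = 30.0,
    min_maf: float = 0.05,
    depth_range: tuple[float, float] = (5.0, 35.0),
) -> GenotypeTable:
    """Apply the site-quality filter to an already-called SNP set.

    Retains biallelic SNPs with mapping quality >= 30, minor allele frequency
    >= 0.05, mean allele depth within [5, 35] (bounds inclusive; the depth
    rule is read as "extreme depth removed") and, when `map_table` is given,
    a contig present on the linkage map.

    `site_stats` must carry one row per SNP with columns
    snp_id, qual, maf, n_alleles, mean_depth.
    """
    missing = set(SNP_FILTER_COLUMNS) - set(site_stats.columns)
    if missing:
        raise ValueError(f"site_stats missing column(s): {sorted(missing)}")
    stats = site_stats.set_index("snp_id")
    ids = [s.snp_id for s in table.snps]
    absent = set(ids) - set(stats.index)
    if absent:
        raise ValueError(f"site_stats missing rows for SNPs: {sorted(absent)[:5]} ...")
    st = stats.loc[ids]
    keep = (
        (st["n_alleles"].to_numpy() == 2)
        & (st["qual"].to_numpy() >= min_qual)
        & (st["maf"].to_numpy() >= min_maf)
        & (st["mean_depth"].to_numpy() >= depth_range[0])
        & (st["mean_depth"].to_numpy() <= depth_range[1])
    )
    if map_table is not None:
        mapped = map_table.contigs
        keep &= np.array([s.contig in mapped for s in table.snps])
    return table.take_snps(keep)


def filter_map_markers(raw_map: pd.DataFrame, max_dev_cm: float = 2.0) -> MapTable:
    """Trim inconsistent markers and average contig positions.

    Per contig: markers mapping to a linkage group other than the contig's
    modal LG are dropped; then markers deviating more than `max_dev_cm` from
    the contig's average position are trimmed greedily (drop the most deviant
    marker, recompute the mean, repeat) until all survivors are within the
    tolerance. Contigs losing every marker are dropped.
    """
    if raw_map.empty:
        raise ValueError("empty marker table")
    rows = []
    positions: dict[str, list[float]] = {}
    for contig, grp in raw_map.groupby("contig", sort=True):
        lg_counts = grp["lg"].value_counts()
        top = lg_counts.max()
        modal_lg = int(min(lg_counts[lg_counts == top].index))
        cms = sorted(grp.loc[grp["lg"] == modal_lg, "cm"].astype(float))
        while len(cms) > 1:
            mean = float(np.mean(cms))
            dev = [abs(c - mean) for c in cms]
            worst = max(dev)
            if worst <= max_dev_cm:
                break
            # ties on deviation: drop the larger-cM marker (deterministic)
            drop_idx = max(i for i, d in enumerate(dev) if d == worst)
            cms.pop(drop_idx)
        if not cms:
            continue
        rows.append(
            {"contig": contig, "lg": modal_lg, "cm_mean": float(np.mean(cms)), "n_markers": len(cms)}
        )
        positions[contig] = cms
    if not rows:
        raise ValueError("no contigs survived marker filtering")
    return MapTable(frame=pd.DataFrame(rows), positions=positions)


#: cM windows fixed by hand where automatic transfer would overlap neighbours
BOUNDARY_OVERRIDES: dict[str, tuple[float, float]] = {
    "LGC14.3": (12.0, 34.66),
    "LGC12.3": (46.0, 50.09),
}


def transfer_boundaries(
    published: pd.DataFrame,
    map_table: MapTable,
    complex_names: set[str] | None = None,
    overrides: dict[str, tuple[float, float]] | None = None,
) -> list[InversionRegion]:
    """Transfer published inversion boundaries onto the new map.

    `published` has one row per anchor contig: (name, side in {left, right},
    contig). For each inversion the widest interval is adopted: start = the
    minimum cM over left-anchor contigs, end = the maximum over right-anchor
    contigs. Anchors on unmapped contigs are skipped with a warning; an
    inversion with no mappable anchor raises. `overrides` (default: the
    LGC14.3 / LGC12.3 hand-set windows) replace the anchored interval.
    """
    if overrides is None:
        overrides = BOUNDARY_OVERRIDES
    complex_names = complex_names or set()
    regions: list[InversionRegion] = []
    for name, grp in published.groupby("name", sort=True):
        lgs: list[int] = []
        left: list[float] = []
        right: list[float] = []
        for row in grp.itertuples(index=False):
            hit = map_table.lookup(row.contig)
            if hit is None:
                warnings.warn(f"{name}: anchor contig {row.contig} absent from map; skipped")
                continue
            lg, cm = hit
            lgs.append(lg)
            (left if row.side == "left" else right).append(cm)
        if name in overrides:
            start, end = overrides[str(name)]
            if not lgs:
                raise ValueError(f"{name}: no anchor contig found on the map")
            regions.append(
                InversionRegion(str(name), lgs[0], start, end, str(name) in complex_names)
            )
            continue
        if not left or not right:
            raise ValueError(f"{name}: no mappable anchors on one or both sides")
        regions.append(
            InversionRegion(
                str(name), lgs[0], min(left), max(right), str(name) in complex_names
            )
        )
    return regions


@dataclass
class WindowAssignment:
    """SNP indices per 1-cM window, per linkage group.

    Window w on LG g holds SNPs with cm in [w*width, (w+1)*width), half-open,
    so every mapped SNP falls in exactly one window. `empty` lists windows
    inside the LG span with no markers ("no markers" flag).
    """

    width_cm: float
    windows: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    empty: list[tuple[int, int]] = field(default_factory=list)

    def lg_windows(self, lg: int) -> list[int]:
        return sorted(w for (g, w) in self.windows if g == lg)


def window_assign(table: GenotypeTable, width_cm: float = 1.0) -> WindowAssignment:
    """Partition mapped SNPs into non-overlapping windows of `width_cm`."""
    snp = table.snp_frame()
    out = WindowAssignment(width_cm=width_cm)
    snp["win"] = np.floor(snp["cm"].to_numpy() / width_cm).astype(int)
    for (lg, w), grp in snp.groupby(["lg", "win"]):
        out.windows[(int(lg), int(w))] = grp.index.to_numpy()
    for lg in sorted(snp["lg"].unique()):
        present = out.lg_windows(int(lg))
        for w in range(min(present), max(present) + 1):
            if (int(lg), w) not in out.windows:
                out.empty.append((int(lg), w))
    return out
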