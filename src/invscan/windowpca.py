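"""Window-based PCA along the linkage map, region PCA and outgroup projection.

PCA of SNP genotypes inside each 1-cM window separates karyotypes: a simple
inversion forms three clusters on PC1, two overlapping inversions (three
arrangements) form six clusters on PC1 x PC2. Because the sign of a
principal component is arbitrary, PC1 scores of successive windows are
re-oriented by flipping any window whose scores correlate negatively with
the preceding (already-oriented) window, giving a sign-consistent profile
along the map.

Genotypes are centred and scaled per SNP; missing genotypes are imputed to
the SNP mean (so an all-missing individual scores ~0 on every component).
Region PCAs store their centring/scaling vectors and loadings so outgroup
individuals can be projected onto the fitted axes without refitting —
projection keeps the ingroup axes from being dominated by interspecific
divergence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datamodel import MISSING, GenotypeTable, InversionRegion

__all__ = [
    "WindowPCAProfile",
    "pca_window",
    "orient_chain",
    "RegionPCA",
    "pca_region",
    "pca_colinear",
    "project",
]


class MonomorphicWindowError(ValueError):
    """Raised when a window has no polymorphic SNP after imputation."""


def _prepare(genotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Mean-impute missing, drop monomorphic SNPs, centre and scale.

    Returns (standardized matrix, column means, column scales, kept-column mask).
    """
    g = np.asarray(genotypes, dtype=float)
    g[g == MISSING] = np.nan
    means = np.nanmean(g, axis=0)
    means = np.where(np.isnan(means), 0.0, means)  # all-missing SNP -> constant
    inds = np.where(np.isnan(g), means, g)
    sd = inds.std(axis=0)
    keep = sd > 0
    z = (inds[:, keep] - means[keep]) / sd[keep]
    return z, means, sd, keep


@dataclass
class WindowPCAProfile:
    """Oriented PC1 profile of one 1-cM window."""

    lg: int
    window: int
    pc1_scores: np.ndarray
    pct_var_pc1: float
    mean_het: float
    flipped: bool = False
    orientation_flagged: bool = False  # zero-variance correlation with neighbour


def pca_window(
    genotypes: np.ndarray, lg: int = 0, window: int = 0
) -> tuple[WindowPCAProfile, np.ndarray]:
    """PCA of the SNPs inside one window; returns (PC1 profile, PC2 scores)."""
    g = np.asarray(genotypes)
    if g.shape[1] < 2 or g.shape[0] < 3:
        raise ValueError("window PCA needs >=2 SNPs and >=3 individuals")
    z, _, _, keep = _prepare(g)
    if keep.sum() == 0:
        raise MonomorphicWindowError(f"window {window} on LG {lg} is monomorphic")
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    scores = u * s
    var = s**2 / np.sum(s**2)
    het = (g == 1).sum() / max(1, (g != MISSING).sum())
    prof = WindowPCAProfile(
        lg=lg,
        window=window,
        pc1_scores=scores[:, 0],
        pct_var_pc1=float(100 * var[0]),
        mean_het=float(het),
    )
    pc2 = scores[:, 1] if scores.shape[1] > 1 else np.zeros(g.shape[0])
    return prof, pc2


def orient_chain(profiles: list[WindowPCAProfile]) -> list[WindowPCAProfile]:
    """Sign-align PC1 across consecutive windows (first window unchanged).

    A window negatively correlated (Pearson, over shared individuals) with
    its already-oriented predecessor is negated. Zero-variance pairs leave
    the sign unchanged and set `orientation_flagged`. Idempotent.
    """
    if not profiles:
        return profiles
    out = [profiles[0]]
    for prof in profiles[1:]:
        prev = out[-1].pc1_scores
        cur = prof.pc1_scores
        ok = np.isfinite(prev) & np.isfinite(cur)
        flagged = False
        flip = False
        if ok.sum() >= 2 and prev[ok].std() > 0 and cur[ok].std() > 0:
            r = np.corrcoef(prev[ok], cur[ok])[0, 1]
            flip = r < 0
        else:
            flagged = True
        out.append(
            WindowPCAProfile(
                lg=prof.lg,
                window=prof.window,
                pc1_scores=-cur if flip else cur.copy(),
                pct_var_pc1=prof.pct_var_pc1,
                mean_het=prof.mean_het,
                flipped=bool(prof.flipped ^ flip),
                orientation_flagged=flagged,
            )
        )
    return out


@dataclass
class RegionPCA:
    """Fitted PCA of one map region, with everything needed for projection."""

    name: str
    samples: list[str]
    scores: np.ndarray  # (n, 2): PC1, PC2
    pct_var: tuple[float, float]
    snp_index: np.ndarray  # columns of the source table used (post-monomorphic-drop)
    means: np.ndarray
    scales: np.ndarray
    loadings: np.ndarray  # (n_snps_kept, 2)


def _fit_region(table: GenotypeTable, cols: np.ndarray, name: str) -> RegionPCA:
    g = table.genotypes[:, cols]
    z, means, sd, keep = _prepare(g)
    if keep.sum() < 2:
        raise ValueError(f"{name}: fewer than 2 polymorphic SNPs")
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = (u * s)[:, :2]
    var = s**2 / np.sum(s**2)
    return RegionPCA(
        name=name,
        samples=list(table.samples),
        scores=scores,
        pct_var=(float(100 * var[0]), float(100 * var[1]) if var.size > 1 else 0.0),
        snp_index=cols[keep],
        means=means[keep],
        scales=sd[keep],
        loadings=vt[:2, :].T,
    )


def pca_region(
    table: GenotypeTable,
    region: InversionRegion,
    exclude: list[tuple[float, float]] | None = None,
) -> RegionPCA:
    """PCA of all SNPs within a region, minus optional excluded cM sub-intervals.

    Exclusion handles inversions whose mapped coordinates overlap a
    neighbouring inversion: those shared SNPs are left out of genotyping.
    """
    snp = table.snp_frame()
    mask = (snp["lg"].to_numpy() == region.lg) & region.contains(snp["cm"].to_numpy())
    for lo, hi in exclude or []:
        cm = snp["cm"].to_numpy()
        mask &= ~((cm >= lo) & (cm <= hi))
    cols = np.flatnonzero(mask)
    if cols.size < 2:
        raise ValueError(f"{region.name}: fewer than 2 SNPs after exclusions")
    return _fit_region(table, cols, region.name)


def pca_colinear(
    table: GenotypeTable,
    lg: int,
    regions: list[InversionRegion],
    buffer_cm: float = 2.0,
) -> RegionPCA:
    """Control PCA of the colinear genome of one linkage group.

    Uses all SNPs outside every inversion plus a `buffer_cm` margin (the
    boundary positions are imprecise); left and right colinear segments are
    merged. Raises when the LG is mostly covered by inversions and nothing
    informative remains.
    """
    snp = table.snp_frame()
    cm = snp["cm"].to_numpy()
    mask = snp["lg"].to_numpy() == lg
    for reg in regions:
        if reg.lg != lg:
            continue
        mask &= ~((cm >= reg.start_cm - buffer_cm) & (cm <= reg.end_cm + buffer_cm))
    cols = np.flatnonzero(mask)
    if cols.size < 2:
        raise ValueError(
            f"LG{lg}: mostly covered by inversions (+{buffer_cm} cM buffer); "
            "no colinear control possible"
        )
    return _fit_region(table, cols, f"LG{lg}_colinear")


def project(rp: RegionPCA, genotypes: np.ndarray) -> np.ndarray:
    """Project additional individuals onto a fitted region PCA.

    `genotypes` is (n_out, n_snps_of_source_table); the stored SNP columns,
    ingroup means (for imputation and centring), scales and loadings are
    applied; the PCA is not refitted. Returns (n_out, 2) scores.
    """
    g = np.asarray(genotypes, dtype=float)
    if g.shape[1] <= rp.snp_index.max():
        raise ValueError("outgroup genotypes do not cover the region's SNP columns")
    sub = g[:, rp.snp_index]
    sub[sub == MISSING] = np.nan
    if np.all(np.isnan(sub)):
        warnings.warn(f"{rp.name}: projecting individuals with no overlapping genotypes")
    sub = np.where(np.isnan(sub), rp.means, sub)
    z = (sub - rp.means) / rp.scales
    return z @ rp.loadings
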