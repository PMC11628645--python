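"""Karyotype genotyping from region-PCA scores.

Scores are clustered with K-means (100 random starts, keeping the start with
the highest between-group sum of squares); K is chosen by mean silhouette
(K in {2,3} on PC1 for simple inversions, K in {2..9} on PC1 x PC2 for
complex three-arrangement regions). Clusters are converted to arrangement
genotypes: the homokaryotype cluster holding the most crab individuals is
the reference 'RR'; for complex regions the homokaryotype furthest from RR
on PC1 is 'A1A1' and the remaining vertex 'A2A2', with heterokaryotype
clusters labelled by their two nearest vertices. For K=2 the second cluster
is called 'RA' rather than 'AA' when its mean region heterozygosity clearly
exceeds the RR cluster's (heterokaryotypes carry two diverged haplotypes).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

__all__ = [
    "kmeans_best",
    "choose_k",
    "KaryotypeCallSet",
    "label_clusters",
    "arrangement_counts",
    "frequency_table",
    "site_polymorphism",
    "ancestral_call",
]

HET_LABELS = {"RA", "RA1", "RA2", "A1A2"}
HOMO_LABELS = {"RR", "AA", "A1A1", "A2A2"}


def _as_2d(scores: np.ndarray) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    return scores.reshape(-1, 1) if scores.ndim == 1 else scores


def kmeans_best(
    scores: np.ndarray, k: int, n_starts: int = 100, seed: int = 0
) -> tuple[np.ndarray, float, float]:
    """K-means with `n_starts` random starts, keeping the best partition.

    The retained start maximises the between-group sum of squares; since the
    total sum of squares is fixed this is the start minimising the K-means
    within-group objective. Returns (assignment, between_ss, within_ss);
    deterministic for a given seed.
    """
    x = _as_2d(scores)
    if k > x.shape[0]:
        raise ValueError(f"K={k} exceeds {x.shape[0]} individuals")
    km = KMeans(n_clusters=k, init="random", n_init=n_starts, random_state=seed)
    labels = km.fit_predict(x)
    total_ss = float(((x - x.mean(axis=0)) ** 2).sum())
    within_ss = float(km.inertia_)
    return labels, total_ss - within_ss, within_ss


def choose_k(
    scores: np.ndarray,
    simple: bool = True,
    n_starts: int = 100,
    seed: int = 0,
) -> tuple[int, dict[int, float]]:
    """Silhouette-based choice of the cluster count.

    Simple inversions: K in {2, 3} on PC1 only. Complex regions: K in
    {2..9} on (PC1, PC2). K values whose best partition contains a
    singleton cluster (silhouette undefined in spirit) are skipped. Returns
    (best K, mean silhouette per tested K); ties go to the smaller K.
    """
    x = _as_2d(scores)
    if simple:
        x = x[:, :1]
        k_range = range(2, 4)
    else:
        x = x[:, :2]
        k_range = range(2, 10)
    sils: dict[int, float] = {}
    for k in k_range:
        if k >= x.shape[0]:
            continue
        labels, _, _ = kmeans_best(x, k, n_starts=n_starts, seed=seed)
        counts = np.bincount(labels, minlength=k)
        if (counts < 2).any():
            continue
        sils[k] = float(silhouette_score(x, labels, metric="euclidean"))
    if not sils:
        raise ValueError("no K in range yields a valid silhouette")
    best = max(sorted(sils), key=lambda k: sils[k])
    return best, sils


@dataclass
class KaryotypeCallSet:
    """Arrangement-genotype calls for one inversion region."""

    region: str
    k: int
    samples: list[str]
    cluster: np.ndarray  # raw K-means cluster ids
    labels: list[str]  # per-individual karyotype label or "unassigned"
    silhouettes: dict[int, float]
    flags: list[str] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": self.region,
                "individual": self.samples,
                "cluster": self.cluster,
                "label": self.labels,
            }
        )


def _cluster_means(scores: np.ndarray, labels: np.ndarray) -> dict[int, np.ndarray]:
    return {c: scores[labels == c].mean(axis=0) for c in np.unique(labels)}


def label_clusters(
    assignment: np.ndarray,
    scores: np.ndarray,
    meta: pd.DataFrame,
    samples: list[str],
    region: str = "",
    complex_region: bool = False,
    region_het: np.ndarray | None = None,
    k2_het_ratio: float = 0.5,
    overrides: dict[str, str] | None = None,
) -> KaryotypeCallSet:
    """Convert a cluster assignment into arrangement-genotype labels.

    `region_het` (per-individual mean heterozygosity over the region's SNPs)
    is required for K=2 calls, where it decides RR/AA versus RR/RA: the
    second cluster is heterokaryotypic when its mean heterozygosity exceeds
    the RR cluster's by more than `k2_het_ratio` (relative). `overrides`
    maps individual id -> label and is applied last, with a warning.
    """
    x = _as_2d(scores)
    labels = np.asarray(assignment)
    k = len(np.unique(labels))
    eco = meta.set_index("individual").loc[samples, "ecotype"].to_numpy()
    means = _cluster_means(x, labels)
    flags: list[str] = []

    def crab_count(c: int) -> int:
        return int(((labels == c) & (eco == "crab")).sum())

    def pick_rr(cands: list[int]) -> int:
        best = sorted(cands, key=lambda c: (-crab_count(c), means[c][0]))
        if all(crab_count(c) == 0 for c in cands):
            flags.append("no-crab-in-homokaryotypes:lower-PC1-rule")
            warnings.warn(f"{region}: no crab samples in any homokaryotype cluster; "
                          "RR assigned to the lowest-mean-PC1 cluster")
        return best[0]

    name_of: dict[int, str] = {}
    if not complex_region or k <= 3:
        order = sorted(means, key=lambda c: means[c][0])  # by mean PC1
        if k == 1:
            name_of[order[0]] = "RR"
            flags.append("single-cluster")
        elif k == 2:
            rr = pick_rr(order)
            other = order[1] if rr == order[0] else order[0]
            if region_het is None:
                name_of[rr], name_of[other] = "RR", "AA"
                flags.append("k2-no-heterozygosity:AA-assumed")
            else:
                h_rr = float(np.nanmean(region_het[labels == rr]))
                h_other = float(np.nanmean(region_het[labels == other]))
                is_het = h_other > h_rr * (1.0 + k2_het_ratio)
                name_of[rr] = "RR"
                name_of[other] = "RA" if is_het else "AA"
        else:  # k == 3: extremes are homokaryotypes, middle is heterokaryotype
            rr = pick_rr([order[0], order[-1]])
            aa = order[-1] if rr == order[0] else order[0]
            name_of[rr], name_of[order[1]], name_of[aa] = "RR", "RA", "AA"
    else:
        # complex region: the 3 mutually most distant clusters are the
        # homokaryotype vertices; others labelled by their 2 nearest vertices
        clusters = sorted(means)
        best_triple, best_d = None, -np.inf
        for triple in itertools.combinations(clusters, 3):
            d = sum(
                np.linalg.norm(means[a] - means[b])
                for a, b in itertools.combinations(triple, 2)
            )
            if d > best_d:
                best_d, best_triple = d, triple
        vertices = list(best_triple)
        rr = pick_rr(vertices)
        others = [c for c in vertices if c != rr]
        # furthest from RR on PC1 is A1A1
        others.sort(key=lambda c: -abs(means[c][0] - means[rr][0]))
        a1, a2 = others
        name_of[rr], name_of[a1], name_of[a2] = "RR", "A1A1", "A2A2"
        arr_of = {rr: "R", a1: "A1", a2: "A2"}
        pair_name = {
            frozenset(["R", "A1"]): "RA1",
            frozenset(["R", "A2"]): "RA2",
            frozenset(["A1", "A2"]): "A1A2",
        }
        for c in clusters:
            if c in name_of:
                continue
            near = sorted(vertices, key=lambda v: np.linalg.norm(means[c] - means[v]))[:2]
            name_of[c] = pair_name[frozenset(arr_of[v] for v in near)]

    out = [name_of.get(int(c), "unassigned") for c in labels]
    if overrides:
        for ind, lab in overrides.items():
            if ind in samples:
                warnings.warn(f"{region}: manual override {ind} -> {lab}")
                out[samples.index(ind)] = lab
                flags.append(f"override:{ind}")
    return KaryotypeCallSet(
        region=region, k=k, samples=list(samples), cluster=labels,
        labels=out, silhouettes={}, flags=flags,
    )


#: arrangement allele content of each karyotype label
_ALLELES = {
    "RR": ("R", "R"), "RA": ("R", "A"), "AA": ("A", "A"),
    "A1A1": ("A1", "A1"), "A2A2": ("A2", "A2"),
    "RA1": ("R", "A1"), "RA2": ("R", "A2"), "A1A2": ("A1", "A2"),
}


def arrangement_counts(label: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    for a in _ALLELES[label]:
        counts[a] = counts.get(a, 0) + 1
    return counts


def frequency_table(calls: KaryotypeCallSet, meta: pd.DataFrame, by: str = "location") -> pd.DataFrame:
    """Arrangement frequencies per stratum (location, ecotype or group)."""
    m = meta.set_index("individual")
    rows: dict[tuple[str, str], int] = {}
    n_ind: dict[str, int] = {}
    for ind, lab in zip(calls.samples, calls.labels):
        if lab == "unassigned":
            continue
        stratum = str(m.loc[ind, by])
        n_ind[stratum] = n_ind.get(stratum, 0) + 1
        for arr, c in arrangement_counts(lab).items():
            rows[(stratum, arr)] = rows.get((stratum, arr), 0) + c
    recs = []
    for (stratum, arr), count in sorted(rows.items()):
        recs.append(
            {
                "region": calls.region,
                by: stratum,
                "arrangement": arr,
                "count": count,
                "n_individuals": n_ind[stratum],
                "freq": count / (2 * n_ind[stratum]),
            }
        )
    return pd.DataFrame(recs)


def site_polymorphism(calls: KaryotypeCallSet, meta: pd.DataFrame) -> pd.DataFrame:
    """Per sampling site: is the inversion polymorphic there?

    Polymorphic iff any individual is heterokaryotypic or more than one
    arrangement homokaryotype is present.
    """
    m = meta.set_index("individual")
    rows = []
    df = pd.DataFrame({"individual": calls.samples, "label": calls.labels})
    df["location"] = [str(m.loc[i, "location"]) for i in calls.samples]
    for loc, grp in df[df["label"] != "unassigned"].groupby("location"):
        labs = set(grp["label"])
        poly = bool(labs & HET_LABELS) or len(labs & HOMO_LABELS) > 1
        rows.append({"region": calls.region, "location": loc, "polymorphic": poly})
    return pd.DataFrame(rows)


def ancestral_call(
    outgroup_scores: np.ndarray, calls: KaryotypeCallSet, scores: np.ndarray
) -> str:
    """Infer the ancestral arrangement from projected outgroup individuals.

    Each outgroup individual is assigned to the nearest cluster centroid (in
    the ingroup score space). If all outgroup fall in one homokaryotype
    cluster, the corresponding arrangement is ancestral; if they span
    clusters or land nearest a heterokaryotype centroid, the call is "P"
    (polymorphic/indeterminate); with no outgroup, "unknown".
    """
    og = _as_2d(outgroup_scores)
    if og.shape[0] == 0:
        return "unknown"
    x = _as_2d(scores)[:, : og.shape[1]]
    labels = np.asarray(calls.labels)
    centroids = {
        lab: x[labels == lab].mean(axis=0) for lab in set(labels) if lab != "unassigned"
    }
    hits = []
    for row in og:
        lab = min(centroids, key=lambda c: np.linalg.norm(row - centroids[c]))
        hits.append(lab)
    uniq = set(hits)
    if len(uniq) == 1:
        lab = hits[0]
        if lab in HOMO_LABELS:
            return _ALLELES[lab][0]
        return "P"
    return "P"
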