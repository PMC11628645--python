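"""Heterozygosity-split detection of inversions.

Per individual and linkage group, the proportion of heterozygous SNPs per
contig is modelled with a beta-binomial distribution (mean ``H_Ind`` = mu,
intraclass-correlation dispersion rho). A hierarchical split function scans
all 1-cM candidate boundaries for a two-segment model (two means, shared
dispersion), keeps the boundary maximising the likelihood, accepts it when
the likelihood-ratio test chi2 = -2(LL0 - LL1) is significant at p < 0.01
(chi-square, 1 df), and recurses into each accepted segment for at most
three levels — so a linkage group yields between 1 and 8 segments.

At the group level, significant split positions are tested for spatial
clustering: the observed variance of split counts over 3-cM sliding windows
(each the sum of three consecutive 1-cM windows) is compared with 10,000
multinomial redistributions of the splits over marker-bearing 1-cM windows,
and the empirical p-values are Benjamini–Hochberg corrected across all
(linkage group x genetic group) tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BetaBinFit",
    "fit_betabin",
    "betabin_loglik",
    "SplitScan",
    "best_split",
    "SegmentationResult",
    "hierarchical_split",
    "het_observations",
    "segment_all",
    "ClusterTestResult",
    "split_cluster_test",
    "bh_adjust",
]

_MU_LO, _MU_HI = 1e-6, 1.0 - 1e-6
_RHO_LO, _RHO_HI = 1e-6, 0.995


@dataclass(frozen=True)
class BetaBinFit:
    """Beta-binomial MLE: mean heterozygosity mu, dispersion rho, log-likelihood."""

    mu: float
    rho: float
    loglik: float


def _log_binom(k: np.ndarray, n: np.ndarray) -> float:
    return float(
        np.sum(special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1))
    )


def betabin_loglik(k: np.ndarray, n: np.ndarray, mu: float, rho: float) -> float:
    """Full beta-binomial log-likelihood at (mu, rho) for observations (k, n)."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    nu = (1.0 - rho) / rho
    a, b = mu * nu, (1.0 - mu) * nu
    ll = np.sum(
        special.betaln(k + a, n - k + b) - special.betaln(a, b)
    ) + _log_binom(k, n)
    return float(ll)


def _nll_and_grad(
    x: np.ndarray, k: np.ndarray, n: np.ndarray, seg: np.ndarray, n_seg: int
) -> tuple[float, np.ndarray]:
    """Negative log-likelihood (without binomial constant) and gradient.

    x = [mu_1 .. mu_S, rho]; `seg` assigns each observation to a segment;
    rho (hence nu) is shared across segments.
    """
    mus, rho = x[:-1], x[-1]
    nu = (1.0 - rho) / rho
    mu_i = mus[seg]
    a_i = mu_i * nu
    b_i = (1.0 - mu_i) * nu
    ll_terms = (
        special.gammaln(k + a_i)
        - special.gammaln(a_i)
        + special.gammaln(n - k + b_i)
        - special.gammaln(b_i)
        - special.gammaln(n + nu)
        + special.gammaln(nu)
    )
    ga_i = special.digamma(k + a_i) - special.digamma(a_i)
    gb_i = special.digamma(n - k + b_i) - special.digamma(b_i)
    gn = np.sum(special.digamma(nu) - special.digamma(n + nu))
    grad = np.empty(n_seg + 1)
    dl_dnu = gn
    for s in range(n_seg):
        m = seg == s
        ga, gb = ga_i[m].sum(), gb_i[m].sum()
        grad[s] = nu * (ga - gb)
        dl_dnu += mus[s] * ga + (1.0 - mus[s]) * gb
    grad[-1] = dl_dnu * (-1.0 / rho**2)  # d(nu)/d(rho)
    return -float(ll_terms.sum()), -grad


def _fit_segments(
    k: np.ndarray,
    n: np.ndarray,
    seg: np.ndarray,
    n_seg: int,
    x0: np.ndarray | None = None,
) -> tuple[np.ndarray, float, float]:
    """Maximise the shared-dispersion beta-binomial likelihood; returns (mus, rho, loglik)."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if x0 is None:
        x0 = np.empty(n_seg + 1)
        for s in range(n_seg):
            m = seg == s
            tot = n[m].sum()
            x0[s] = np.clip(k[m].sum() / tot if tot > 0 else 0.5, 0.01, 0.99)
        x0[-1] = 0.05
    bounds = [(_MU_LO, _MU_HI)] * n_seg + [(_RHO_LO, _RHO_HI)]
    res = optimize.minimize(
        _nll_and_grad,
        np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds]),
        args=(k, n, seg, n_seg),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
    )
    loglik = -res.fun + _log_binom(k, n)
    return res.x[:-1], float(res.x[-1]), float(loglik)


def fit_betabin(k: np.ndarray, n: np.ndarray) -> BetaBinFit:
    """MLE of the single-mean beta-binomial model for per-contig (k, n) counts."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if k.size == 0 or not (n > 0).any():
        raise ValueError("need at least one observation with n > 0")
    if ((k < 0) | (k > n)).any():
        raise ValueError("require 0 <= k <= n")
    keep = n > 0
    mus, rho, ll = _fit_segments(k[keep], n[keep], np.zeros(keep.sum(), dtype=int), 1)
    return BetaBinFit(mu=float(mus[0]), rho=rho, loglik=ll)


@dataclass
class SplitScan:
    """Result of the exhaustive one-split scan of a segment."""

    split_cm: float | None
    lrt: float
    p: float
    significant: bool
    null_fit: BetaBinFit
    candidates: pd.DataFrame  # cm, loglik, lrt, p per candidate boundary


def _candidate_grid(cm: np.ndarray, width_cm: float = 1.0) -> np.ndarray:
    """1-cM window boundaries with at least one contig strictly on each side."""
    lo = int(np.floor(cm.min() / width_cm)) + 1
    hi = int(np.floor(cm.max() / width_cm))
    cands = []
    for c in range(lo, hi + 1):
        b = c * width_cm
        if (cm < b).any() and (cm >= b).any():
            cands.append(b)
    return np.asarray(cands, dtype=float)


def best_split(
    cm: np.ndarray,
    k: np.ndarray,
    n: np.ndarray,
    alpha: float = 0.01,
    width_cm: float = 1.0,
) -> SplitScan | None:
    """Exhaustive scan over 1-cM candidate boundaries for the best two-segment model.

    Observations are per-contig (cm, k, n), cm-sorted. The no-split model
    (mu, rho) is compared with each candidate's (mu_left, mu_right, shared
    rho) model; the candidate maximising the likelihood is returned with
    chi2 = -2(LL0 - LL1) and its 1-df p-value. Returns None when no valid
    candidate exists. Ties in likelihood go to the smallest cM position.
    """
    cm = np.asarray(cm, dtype=float)
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    keep = n > 0
    cm, k, n = cm[keep], k[keep], n[keep]
    if cm.size < 2:
        return None
    order = np.argsort(cm, kind="stable")
    cm, k, n = cm[order], k[order], n[order]
    cands = _candidate_grid(cm, width_cm)
    if cands.size == 0:
        return None
    mus0, rho0, ll0 = _fit_segments(k, n, np.zeros(cm.size, dtype=int), 1)
    null_fit = BetaBinFit(mu=float(mus0[0]), rho=rho0, loglik=ll0)
    x0 = np.array([mus0[0], mus0[0], rho0])
    rows = []
    best_i, best_ll = -1, -np.inf
    for i, b in enumerate(cands):
        seg = (cm >= b).astype(int)
        # warm start at the null optimum: guarantees LL1 >= LL0
        _, _, ll1 = _fit_segments(k, n, seg, 2, x0=x0.copy())
        lrt = max(0.0, 2.0 * (ll1 - ll0))
        rows.append({"cm": b, "loglik": ll1, "lrt": lrt, "p": stats.chi2.sf(lrt, df=1)})
        if ll1 > best_ll + 1e-12:
            best_ll, best_i = ll1, i
    cand_df = pd.DataFrame(rows)
    best = cand_df.iloc[best_i]
    return SplitScan(
        split_cm=float(best["cm"]),
        lrt=float(best["lrt"]),
        p=float(best["p"]),
        significant=bool(best["p"] < alpha),
        null_fit=null_fit,
        candidates=cand_df,
    )


@dataclass
class SegmentationResult:
    """Per individual x linkage group: accepted splits and segment H_Ind means."""

    individual: str
    lg: int
    splits: list[float]
    segments: list[tuple[float, float, float]]  # (start_cm, end_cm, H_Ind)

    @property
    def n_segments(self) -> int:
        return len(self.segments)


def hierarchical_split(
    cm: np.ndarray,
    k: np.ndarray,
    n: np.ndarray,
    lg_start: float = 0.0,
    lg_end: float | None = None,
    alpha: float = 0.01,
    max_levels: int = 3,
    individual: str = "",
    lg: int = 0,
) -> SegmentationResult:
    """Three-level recursive segmentation of one individual's linkage group.

    Each accepted split partitions its segment in two; recursion stops per
    segment on non-significance or after `max_levels` levels, bounding the
    result at 2**max_levels segments (8 for the default three levels).
    """
    cm = np.asarray(cm, dtype=float)
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    keep = n > 0
    cm, k, n = cm[keep], k[keep], n[keep]
    if cm.size == 0:
        raise ValueError("no observations with n > 0")
    if lg_end is None:
        lg_end = float(np.ceil(cm.max()))

    splits: list[float] = []

    def recurse(lo: float, hi: float, level: int) -> None:
        if level >= max_levels:
            return
        m = (cm >= lo) & (cm < hi) if hi < lg_end else (cm >= lo) & (cm <= hi)
        if m.sum() < 2:
            return
        scan = best_split(cm[m], k[m], n[m], alpha=alpha)
        if scan is None or not scan.significant:
            return
        b = scan.split_cm
        splits.append(b)
        recurse(lo, b, level + 1)
        recurse(b, hi, level + 1)

    recurse(lg_start, lg_end, 0)
    splits.sort()
    bounds = [lg_start, *splits, lg_end]
    segments = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        m = (cm >= lo) & (cm < hi) if hi < lg_end else (cm >= lo) & (cm <= hi)
        h = fit_betabin(k[m], n[m]).mu if m.any() else float("nan")
        segments.append((lo, hi, h))
    return SegmentationResult(individual=individual, lg=lg, splits=splits, segments=segments)


def het_observations(table, meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per (individual, lg, contig): heterozygous count k and genotyped count n.

    Contigs are the observation unit: they are the natural block on a
    fragmented linkage map and carry the overdispersion that rho models.
    """
    snp = table.snp_frame()
    het = table.genotypes == 1
    called = table.genotypes != -1
    rows = []
    for (lg, contig), grp in snp.groupby(["lg", "contig"], sort=True):
        idx = grp.index.to_numpy()
        cm = float(grp["cm"].iloc[0])
        kk = het[:, idx].sum(axis=1)
        nn = called[:, idx].sum(axis=1)
        for i, ind in enumerate(table.samples):
            rows.append(
                {"individual": ind, "lg": int(lg), "contig": contig, "cm": cm,
                 "k": int(kk[i]), "n": int(nn[i])}
            )
    obs = pd.DataFrame(rows).sort_values(["individual", "lg", "cm"], kind="stable")
    if meta is not None:
        obs = obs.merge(meta[["individual", "group"]], on="individual", how="left")
    return obs.reset_index(drop=True)


def segment_all(obs: pd.DataFrame, alpha: float = 0.01) -> list[SegmentationResult]:
    """Run hierarchical_split for every (individual, lg) in an observation table."""
    out = []
    for (ind, lg), grp in obs.groupby(["individual", "lg"], sort=True):
        out.append(
            hierarchical_split(
                grp["cm"].to_numpy(), grp["k"].to_numpy(), grp["n"].to_numpy(),
                individual=str(ind), lg=int(lg), alpha=alpha,
            )
        )
    return out


@dataclass
class ClusterTestResult:
    """Permutation test for clustering of split positions on one linkage group."""

    lg: int
    group: str
    observed_variance: float
    perm_variances: np.ndarray
    p_emp: float
    p_adj: float | None = None
    degenerate: bool = False


def _sliding3_variance(counts: np.ndarray) -> np.ndarray:
    """Variance over 3-window sliding sums; counts shape (..., n_windows)."""
    c = np.cumsum(counts, axis=-1)
    pad = np.zeros(counts.shape[:-1] + (1,))
    c = np.concatenate([pad, c], axis=-1)
    s3 = c[..., 3:] - c[..., :-3]
    return s3.var(axis=-1)


def split_cluster_test(
    split_cms: np.ndarray,
    eligible_windows: np.ndarray,
    reps: int = 10_000,
    seed: int | np.random.Generator = 0,
    lg: int = 0,
    group: str = "",
) -> ClusterTestResult:
    """Test whether splits cluster spatially along a linkage group.

    ``split_cms``: all individuals' significant split positions (cM);
    ``eligible_windows``: indices of 1-cM windows with at least one marker.
    The statistic is the variance of 3-cM sliding-window split counts; the
    null redistributes the total split count multinomially (uniform) over
    eligible windows. Empirical p uses the +1 correction. A split at
    boundary position c is counted in the window to its left (c - 1).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eligible = np.asarray(sorted(set(int(w) for w in eligible_windows)))
    if eligible.size < 3:
        raise ValueError("need at least 3 eligible windows")
    split_cms = np.asarray(split_cms, dtype=float)
    if split_cms.size == 0:
        return ClusterTestResult(
            lg=lg, group=group, observed_variance=0.0,
            perm_variances=np.zeros(0), p_emp=1.0, degenerate=True,
        )
    w0, w1 = int(eligible.min()), int(eligible.max())
    span = w1 - w0 + 1
    # split at an integer boundary c separates windows c-1 and c; count it left
    win_of_split = np.where(
        split_cms == np.floor(split_cms), split_cms - 1, np.floor(split_cms)
    ).astype(int)
    obs_counts = np.zeros(span)
    for w in win_of_split:
        obs_counts[np.clip(w, w0, w1) - w0] += 1
    obs_var = float(_sliding3_variance(obs_counts))
    total = int(split_cms.size)
    probs = np.full(eligible.size, 1.0 / eligible.size)
    perm = rng.multinomial(total, probs, size=reps)
    grid = np.zeros((reps, span))
    grid[:, eligible - w0] = perm
    perm_var = _sliding3_variance(grid)
    p_emp = (1.0 + np.sum(perm_var >= obs_var - 1e-12)) / (reps + 1.0)
    return ClusterTestResult(
        lg=lg, group=group, observed_variance=obs_var,
        perm_variances=perm_var, p_emp=float(p_emp),
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
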