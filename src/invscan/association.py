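"""Inversion–ecotype association via a ladder of binomial logistic models.

For each inversion the response is the per-individual count of 'A'
arrangement alleles out of two (complex regions sum A1 and A2 into 'A').
Three nested binomial GLMs (logit link) are fitted to samples from
locations where both contrast groups were collected:

* Null:  A-count ~ location
* Eco:   A-count ~ ecotype + location
* Int:   A-count ~ ecotype * location

Model choice follows a hierarchical AIC ladder: an ecotype effect is
accepted when AIC_Null - AIC_Eco > 2; Eco then beats Int only when
AIC_Int - AIC_Eco > 2, otherwise Int wins (ties within 2 AIC report the
simpler model flagged "ambiguous"). Without an ecotype effect, Null and Int
are compared the same way. The winning model gets a pseudo-R²
(1 - residual deviance / null deviance) and a chi-square p-value from the
deviance drop of its focal term; p-values are Benjamini–Hochberg corrected
across regions within each contrast.

With a single shared location (the crab vs L. arcana case) the location
term is dropped: Null simplifies to an intercept and Int is not fitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from patsy import dmatrix
from scipy import stats

from .hetsplit import bh_adjust
from .karyotype import KaryotypeCallSet, arrangement_counts

__all__ = [
    "ContrastSpec",
    "AssociationResult",
    "arrangement_response",
    "decide_best",
    "fit_ladder",
    "run_contrasts",
    "DEFAULT_CONTRASTS",
]


@dataclass(frozen=True)
class ContrastSpec:
    """Two-group contrast, restricted to locations where both were sampled."""

    name: str
    group_a: str
    group_b: str
    column: str = "ecotype"  # or "group" for species contrasts


DEFAULT_CONTRASTS = (
    ContrastSpec("crab-wave", "crab", "wave"),
    ContrastSpec("wave-barnacle", "wave", "barnacle"),
    ContrastSpec("arcana-crab", "arcana", "crab", column="mixed"),
    ContrastSpec("arcana-wave", "arcana", "wave", column="mixed"),
)


def arrangement_response(calls: KaryotypeCallSet) -> pd.DataFrame:
    """Per-individual (successes, trials=2) count of 'A' arrangement alleles.

    A1 and A2 count toward 'A'. Unassigned individuals are dropped (their
    number is recorded in the returned frame's attrs)."""
    rows = []
    dropped = 0
    for ind, lab in zip(calls.samples, calls.labels):
        if lab == "unassigned":
            dropped += 1
            continue
        a = sum(c for arr, c in arrangement_counts(lab).items() if arr.startswith("A"))
        rows.append({"individual": ind, "successes": a, "trials": 2})
    out = pd.DataFrame(rows)
    out.attrs["n_dropped"] = dropped
    return out


def decide_best(aic_null: float, aic_eco: float, aic_int: float | None) -> tuple[str, bool]:
    """The AIC ladder as a pure function of the three AICs.

    Returns (best model name, ambiguous flag). `aic_int` is None when the
    interaction model was not fitted (single shared location)."""
    d_eco = aic_null - aic_eco
    if d_eco > 2:
        if aic_int is None:
            return "Eco", False
        d_int = aic_int - aic_eco
        if d_int > 2:
            return "Eco", False
        if d_int < -2:
            return "Int", False
        return "Eco", True  # simpler of Eco/Int, within the 2-AIC band
    if aic_int is None:
        return ("Null", 0 < d_eco <= 2)
    d = aic_null - aic_int
    if d > 2:
        return "Int", False
    return "Null", (0 < d <= 2) or (0 < d_eco <= 2)


@dataclass
class AssociationResult:
    region: str
    contrast: str
    aic_null: float
    aic_eco: float
    aic_int: float | None
    best: str
    pseudo_r2: float
    p_raw: float  # focal term of the best model (interaction when Int wins)
    p_eco: float = float("nan")  # ecotype main-effect p, always 1-df Null vs Eco
    p_adj: float | None = None
    ambiguous: bool = False
    separation_adjusted: bool = False
    n_individuals: int = 0


def _fit_glm(endog: np.ndarray, design: str, data: pd.DataFrame):
    x = dmatrix(design, data, return_type="dataframe")
    model = sm.GLM(endog, x, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit()


def _has_separation(data: pd.DataFrame, factor: str) -> bool:
    """A stratum fixed for one arrangement (all successes or all failures)."""
    for _, grp in data.groupby(factor, observed=True):
        s, t = grp["successes"].sum(), grp["trials"].sum()
        if t > 0 and (s == 0 or s == t):
            return True
    return False


def fit_ladder(
    response: pd.DataFrame,
    meta: pd.DataFrame,
    contrast: ContrastSpec,
    region: str = "",
) -> AssociationResult | None:
    """Fit the Null/Eco/Int ladder for one inversion and contrast.

    `response` columns: individual, successes, trials. Returns None when no
    location has both contrast groups. Strata fixed for one arrangement are
    stabilised with a small Haldane-style continuity adjustment (0.25 allele
    pulled toward the centre per individual in the degenerate stratum) and
    flagged `separation_adjusted`.
    """
    data = _contrast_data(response, meta, contrast)
    if data is None:
        return None
    data = data.copy()
    n_loc = data["location"].nunique()
    single_loc = n_loc == 1

    data["cell"] = data["grp"].astype(str) + ":" + data["location"].astype(str)
    adjusted = _has_separation(data, "cell")
    succ = data["successes"].to_numpy(dtype=float)
    fail = data["trials"].to_numpy(dtype=float) - succ
    if adjusted:
        for _, idx in data.groupby("cell", observed=True).groups.items():
            ii = np.asarray(idx)
            s, t = succ[ii].sum(), (succ[ii] + fail[ii]).sum()
            if s == 0:
                succ[ii] += 0.25
                fail[ii] -= 0.25
            elif s == t:
                succ[ii] -= 0.25
                fail[ii] += 0.25
    endog = np.column_stack([succ, fail])

    if single_loc:
        fit_null = _fit_glm(endog, "1", data)
        fit_eco = _fit_glm(endog, "C(grp)", data)
        fit_int = None
    else:
        fit_null = _fit_glm(endog, "C(location)", data)
        fit_eco = _fit_glm(endog, "C(grp) + C(location)", data)
        fit_int = _fit_glm(endog, "C(grp) * C(location)", data)

    aic_int = float(fit_int.aic) if fit_int is not None else None
    best, ambiguous = decide_best(float(fit_null.aic), float(fit_eco.aic), aic_int)
    fits = {"Null": fit_null, "Eco": fit_eco, "Int": fit_int}
    best_fit = fits[best]
    null_dev = float(fit_null.deviance)
    pseudo_r2 = 0.0 if best == "Null" or null_dev <= 0 else 1.0 - float(best_fit.deviance) / null_dev
    pseudo_r2 = float(np.clip(pseudo_r2, 0.0, 1.0))

    p_eco = float(stats.chi2.sf(max(null_dev - float(fit_eco.deviance), 0.0), df=1))
    if best == "Int":
        drop = float(fit_eco.deviance) - float(fit_int.deviance)
        df = max(1, n_loc - 1)
        p_raw = float(stats.chi2.sf(max(drop, 0.0), df=df))
    else:  # focal term: ecotype (Eco vs Null), also reported when Null wins
        p_raw = p_eco

    return AssociationResult(
        region=region,
        contrast=contrast.name,
        aic_null=float(fit_null.aic),
        aic_eco=float(fit_eco.aic),
        aic_int=aic_int,
        best=best,
        pseudo_r2=pseudo_r2,
        p_raw=p_raw,
        p_eco=p_eco,
        ambiguous=ambiguous,
        separation_adjusted=adjusted,
        n_individuals=len(data),
    )


def _contrast_data(
    response: pd.DataFrame, meta: pd.DataFrame, contrast: ContrastSpec
) -> pd.DataFrame | None:
    """Merge response with metadata, restrict to shared locations, code the groups."""
    m = meta.copy()
    if contrast.column == "mixed":
        # species vs ecotype contrast: arcana individuals vs one saxatilis ecotype
        m["grp"] = np.where(
            m["group"] == "arcana",
            "arcana",
            np.where(m["group"].str.endswith("saxatilis"), m["ecotype"], "other"),
        )
    else:
        m["grp"] = m[contrast.column]
    m = m[m["grp"].isin([contrast.group_a, contrast.group_b])]
    data = response.merge(m[["individual", "location", "grp"]], on="individual")
    by_loc = data.groupby("location")["grp"].nunique()
    shared = by_loc[by_loc == 2].index
    if len(shared) == 0:
        warnings.warn(f"{contrast.name}: no location with both groups; contrast skipped")
        return None
    return data[data["location"].isin(shared)].reset_index(drop=True)


def run_contrasts(
    calls_by_region: dict[str, KaryotypeCallSet],
    meta: pd.DataFrame,
    contrasts: tuple[ContrastSpec, ...] = DEFAULT_CONTRASTS,
) -> pd.DataFrame:
    """Fit every (region x contrast); BH-adjust p within each contrast family."""
    results: list[AssociationResult] = []
    for contrast in contrasts:
        family: list[AssociationResult] = []
        for region, calls in calls_by_region.items():
            res = fit_ladder(arrangement_response(calls), meta, contrast, region=region)
            if res is not None:
                family.append(res)
        if family:
            adj = bh_adjust([r.p_raw for r in family])
            for r, pa in zip(family, adj):
                r.p_adj = float(pa)
        results.extend(family)
    return pd.DataFrame([vars(r) for r in results])
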