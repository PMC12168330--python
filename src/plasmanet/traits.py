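"""Associations of modules and proteins with clinical traits.

Covers the clinical composite construction (global cognition as the mean of
memory and executive z-scores), semi-quantitative neuropathology burden
sums over sampled regions or a medial-temporal-lobe region of interest,
module–trait correlation tables (Spearman or bicor), per-protein
differential correlation volcano tables, cross-platform validation of
assay-based against immunoassay-based analytes, and the plasma-sampling
interval confound check for autopsy analyses.
"""

from __future__ import annotations

import warnings
from functools import lru_cache
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from plasmanet.correlation import bicor, correlation_p_from_t
from plasmanet.simulate import MTL_REGIONS, OTHER_REGIONS, PROTEINOPATHIES

__all__ = [
    "cognitive_composite",
    "neuropath_composites",
    "subregion_contributions",
    "module_trait_correlations",
    "protein_trait_differential_correlation",
    "cross_platform_check",
    "interval_confound_check",
]

_KNOWN_REGIONS = set(MTL_REGIONS) | set(OTHER_REGIONS)


def cognitive_composite(memory_z, executive_z):
    """Global cognition: mean of available domain z-scores.

    Accepts scalars or aligned Series; a missing domain falls back to the
    other, and the composite is missing only when both are.
    """
    mem = pd.Series(memory_z, dtype=float) if not np.isscalar(memory_z) else pd.Series([memory_z], dtype=float)
    exe = pd.Series(executive_z, dtype=float) if not np.isscalar(executive_z) else pd.Series([executive_z], dtype=float)
    out = pd.concat([mem, exe], axis=1).mean(axis=1, skipna=True)
    if np.isscalar(memory_z) and np.isscalar(executive_z):
        return float(out.iloc[0]) if pd.notna(out.iloc[0]) else np.nan
    return out


def neuropath_composites(ratings: pd.DataFrame, roi=None) -> pd.DataFrame:
    """Per-sample burden sums per proteinopathy over a region set.

    ``ratings`` is long format with columns sample_id, region, proteinopathy,
    rating (integers 0-3).  ``roi`` restricts to a region subset (e.g.
    ``MTL_REGIONS``); None sums over all sampled regions.
    """
    req = {"sample_id", "region", "proteinopathy", "rating"}
    if not req <= set(ratings.columns):
        raise ValueError(f"ratings table needs columns {sorted(req)}")
    unknown = set(ratings["region"]) - _KNOWN_REGIONS
    if unknown:
        raise ValueError(f"unknown region name(s): {sorted(unknown)}")
    r = ratings["rating"]
    if (~r.isin([0, 1, 2, 3])).any():
        raise ValueError("ratings must be integers in 0..3")
    sub = ratings if roi is None else ratings[ratings["region"].isin(set(roi))]
    out = sub.pivot_table(index="sample_id", columns="proteinopathy",
                          values="rating", aggfunc="sum", fill_value=0)
    return out.reindex(columns=[p for p in PROTEINOPATHIES if p in out.columns])


def subregion_contributions(ratings: pd.DataFrame, proteinopathy: str, roi=MTL_REGIONS) -> pd.Series:
    """Percent of the cohort-level ROI burden contributed by each subregion."""
    sub = ratings[(ratings["proteinopathy"] == proteinopathy)
                  & (ratings["region"].isin(set(roi)))]
    per_region = sub.groupby("region")["rating"].sum()
    total = per_region.sum()
    if total == 0:
        return per_region.astype(float) * 0.0
    return 100.0 * per_region / total


@lru_cache(maxsize=8)
def _perm_matrix(n: int) -> np.ndarray:
    """All n! permutations of range(n), one per row (n <= 9)."""
    return np.array(list(permutations(range(n))), dtype=np.intp)


def _spearman(x, y, n_exact: int = 10):
    """Spearman rho with midranks; exact permutation p below ``n_exact``.

    The permutation null is evaluated in one matrix product over the cached
    table of all n! orderings, so small-n cells stay cheap.
    """
    n = len(x)
    rho = stats.spearmanr(x, y).statistic
    if n < n_exact:
        rx = stats.rankdata(x) - (n + 1) / 2.0
        ry = stats.rankdata(y) - (n + 1) / 2.0
        denom = np.sqrt((rx**2).sum() * (ry**2).sum())
        if denom == 0:
            return rho, np.nan
        perm_rhos = (ry[_perm_matrix(n)] @ rx) / denom
        p = float(np.mean(np.abs(perm_rhos) >= abs(rho) - 1e-12))
        return rho, p
    return rho, stats.spearmanr(x, y).pvalue


def _corr_cell(x, y, method: str):
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 5:
        return np.nan, np.nan, n
    xs, ys = x[ok], y[ok]
    if np.std(xs) == 0 or np.std(ys) == 0:
        warnings.warn("zero-variance variable in correlation; untested")
        return np.nan, np.nan, n
    if method == "spearman":
        r, p = _spearman(xs, ys)
    elif method == "bicor":
        r = bicor(xs, ys)
        p = float(correlation_p_from_t(r, n))
    else:
        raise ValueError("method must be 'spearman' or 'bicor'")
    return float(r), float(p), n


def module_trait_correlations(
    eigenproteins: pd.DataFrame,
    traits: pd.DataFrame,
    groups: pd.Series | None = None,
    method: str = "spearman",
) -> pd.DataFrame:
    """Correlation of each eigenprotein with each trait, pooled and per group.

    Returns a long table (module, trait, group, n, r, p); group "all" is the
    pooled estimate.  Cells with fewer than five complete pairs are untested
    (NaN).
    """
    rows = []
    subsets = {"all": eigenproteins.index}
    if groups is not None:
        groups = groups.loc[eigenproteins.index]
        for g in pd.unique(groups.dropna()):
            subsets[str(g)] = eigenproteins.index[groups == g]
    for gname, idx in subsets.items():
        for mod in eigenproteins.columns:
            for trait in traits.columns:
                x = eigenproteins.loc[idx, mod].to_numpy(dtype=float)
                y = traits.reindex(idx)[trait].to_numpy(dtype=float)
                r, p, n = _corr_cell(x, y, method)
                rows.append({"module": mod, "trait": trait, "group": gname,
                             "n": n, "r": r, "p": p})
    return pd.DataFrame(rows)


def protein_trait_differential_correlation(
    matrix: pd.DataFrame,
    trait: pd.Series,
    subgroup_index=None,
    labels: pd.Series | None = None,
    alpha: float = 0.05,
    method: str = "spearman",
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-protein trait correlations within a subgroup, plus module summary.

    Returns the per-protein volcano table (rho, p, n per tested protein) and,
    when module labels are given, a per-module table with the fraction of
    members reaching nominal significance and the members' mean coefficient.
    """
    idx = matrix.index if subgroup_index is None else subgroup_index
    sub = matrix.loc[idx]
    t = trait.reindex(idx).to_numpy(dtype=float)
    if np.isfinite(t).sum() < 5:
        raise ValueError("subgroup needs at least 5 samples with the trait")
    rows = []
    for p_id in sub.columns:
        x = sub[p_id].to_numpy(dtype=float)
        r, p, n = _corr_cell(x, t, method)
        rows.append({"protein": p_id, "rho": r, "p": p, "n": n})
    volcano = pd.DataFrame(rows).set_index("protein").dropna(subset=["rho"])
    summary = None
    if labels is not None:
        lab = labels.reindex(volcano.index)
        srows = []
        for m in sorted(x for x in lab.dropna().unique() if x > 0):
            members = volcano[lab == m]
            srows.append({
                "module": int(m),
                "n_members": len(members),
                "frac_significant": float((members["p"] < alpha).mean()) if len(members) else np.nan,
                "mean_rho": float(members["rho"].mean()) if len(members) else np.nan,
            })
        summary = pd.DataFrame(srows).set_index("module")
    return volcano, summary


def cross_platform_check(olink_values: pd.Series, immunoassay_values: pd.Series) -> dict:
    """Agreement between an assay-based analyte and its immunoassay counterpart."""
    x = olink_values.to_numpy(dtype=float)
    y = immunoassay_values.reindex(olink_values.index).to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 5:
        return {"n": int(ok.sum()), "pearson_r": np.nan, "spearman_rho": np.nan,
                "pearson_p": np.nan, "spearman_p": np.nan}
    pr = stats.pearsonr(x[ok], y[ok])
    sr = stats.spearmanr(x[ok], y[ok])
    return {"n": int(ok.sum()), "pearson_r": float(pr.statistic), "pearson_p": float(pr.pvalue),
            "spearman_rho": float(sr.statistic), "spearman_p": float(sr.pvalue)}


def interval_confound_check(
    eigenproteins: pd.DataFrame,
    interval_years: pd.Series,
    group: pd.Series,
) -> tuple[pd.DataFrame, dict]:
    """Sampling-to-death interval against eigenproteins and autopsy groups.

    Returns one bicor row per module plus a two-sided t test of the interval
    between the two autopsy groups.
    """
    interval = interval_years.reindex(eigenproteins.index)
    ok = interval.notna()
    if ok.sum() < 5:
        raise ValueError("need at least 5 samples with an interval")
    rows = []
    for mod in eigenproteins.columns:
        x = eigenproteins.loc[ok, mod].to_numpy(dtype=float)
        y = interval[ok].to_numpy(dtype=float)
        r, p, n = _corr_cell(x, y, "bicor")
        rows.append({"module": mod, "n": n, "bicor": r, "p": p})
    table = pd.DataFrame(rows).set_index("module")
    g = group.reindex(eigenproteins.index)[ok]
    levels = pd.unique(g.dropna())
    ttest = {"p": np.nan, "t": np.nan}
    if len(levels) == 2:
        a = interval[ok][g == levels[0]]
        b = interval[ok][g == levels[1]]
        res = stats.ttest_ind(a, b)
        t_stat = float(res.statistic)
        ttest = {"t": 0.0 if np.isnan(t_stat) and a.var() == 0 and b.var() == 0 else t_stat,
                 "p": 1.0 if np.isnan(res.pvalue) and float(a.mean()) == float(b.mean()) else float(res.pvalue)}
    return table, ttest
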