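"""Per-protein and module-level differential abundance.

One-way fixed-effects ANOVA across clinical groups with Tukey–Kramer
honestly-significant-difference post-hoc tests (studentized-range
distribution, valid for unequal group sizes), pairwise log2 fold changes as
differences of group means, module-level summaries, and stratification of
fold changes by absolute-abundance tier.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "anova_tukey",
    "eigenprotein_group_tests",
    "module_da_summary",
    "tier_stratified_analysis",
    "assign_abundance_tiers",
]

#: log10 pg/L boundaries of the absolute-abundance tiers; the boundary
#: values themselves belong to the intermediate tier.
TIER_LOW_MAX = 6.0
TIER_HIGH_MIN = 9.5


def studentized_range_sf(q, k: int, df: float) -> np.ndarray:
    """Survival function of the studentized range, vectorized over q.

    P(Q > q) for the range of k standard-normal means divided by an
    independent scale estimate on ``df`` degrees of freedom, computed by
    Gauss–Legendre quadrature of the classical double integral

        P(Q <= q) = ∫ f(u) · k ∫ φ(z) [Φ(z) − Φ(z − q·u)]^{k−1} dz du,

    where u is the scale factor (chi_df / sqrt(df)).  Agrees with the
    reference distribution implementation to ~1e-6 over the p-value range
    that matters, at a tiny fraction of the cost for large batches.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    # outer nodes over the scale factor u ~ chi_df / sqrt(df)
    lo = stats.chi.ppf(1e-10, df) / np.sqrt(df)
    hi = stats.chi.ppf(1.0 - 1e-10, df) / np.sqrt(df)
    xu, wu = np.polynomial.legendre.leggauss(64)
    u = 0.5 * (hi - lo) * xu + 0.5 * (hi + lo)
    wu = wu * 0.5 * (hi - lo)
    log_fu = (
        (df / 2.0) * np.log(df) - (df / 2.0 - 1.0) * np.log(2.0)
        - gammaln(df / 2.0) + (df - 1.0) * np.log(u) - df * u**2 / 2.0
    )
    fu = np.exp(log_fu)
    # inner nodes over z
    xz, wz = np.polynomial.legendre.leggauss(128)
    zlo, zhi = -9.0, 9.0
    z = 0.5 * (zhi - zlo) * xz + 0.5 * (zhi + zlo)
    wz = wz * 0.5 * (zhi - zlo)
    phi_z = stats.norm.pdf(z)
    Phi_z = stats.norm.cdf(z)
    # diff[zi, ui, qi] = Φ(z) − Φ(z − q·u)
    qu = u[:, None] * q[None, :]                       # (nu, nq)
    diff = Phi_z[:, None, None] - stats.norm.cdf(z[:, None, None] - qu[None, :, :])
    inner = np.einsum("z,zuq->uq", wz * phi_z, np.clip(diff, 0.0, None) ** (k - 1))
    cdf = np.einsum("u,uq->q", wu * fu, k * inner)
    return np.clip(1.0 - cdf, 0.0, 1.0)


def anova_tukey(
    matrix: pd.DataFrame,
    groups: pd.Series,
    module_labels: pd.Series | None = None,
) -> pd.DataFrame:
    """One-way ANOVA with Tukey–Kramer pairwise post-hoc tests per protein.

    Proteins require at least two groups with two or more non-missing values
    each; those failing the requirement are reported with ``tested=False``
    rather than dropped.  Pairwise log2 fold changes are differences of group
    means (first group minus second).

    Returns a table with columns ``F``, ``p``, ``tested``, per-group means
    ``mean_<g>``, and per-pair ``log2fc_<a>_vs_<b>`` / ``tukey_p_<a>_vs_<b>``.
    """
    groups = groups.loc[matrix.index]
    labels = [g for g in pd.unique(groups) if pd.notna(g)]
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    X = matrix.to_numpy(dtype=float)
    n_prot = X.shape[1]
    masks = {g: (groups == g).to_numpy() for g in labels}

    counts = {g: np.isfinite(X[m]).sum(axis=0) for g, m in masks.items()}
    sums = {g: np.nansum(np.where(np.isfinite(X[m]), X[m], 0.0), axis=0)
            for g, m in masks.items()}
    means = {g: np.where(counts[g] > 0, sums[g] / np.maximum(counts[g], 1), np.nan)
             for g in labels}

    testable = {g: counts[g] >= 2 for g in labels}
    n_testable = np.sum(list(testable.values()), axis=0)
    tested = n_testable >= 2

    # Within-group sum of squares over testable groups only.
    ssw = np.zeros(n_prot)
    ssb = np.zeros(n_prot)
    n_tot = np.zeros(n_prot)
    grand = np.zeros(n_prot)
    for g in labels:
        use = testable[g]
        n_tot += np.where(use, counts[g], 0)
        grand += np.where(use, sums[g], 0.0)
    grand = np.where(n_tot > 0, grand / np.maximum(n_tot, 1), np.nan)
    for g in labels:
        use = testable[g]
        dev = X[masks[g]] - means[g][None, :]
        ssw += np.where(use, np.nansum(np.where(np.isfinite(dev), dev**2, 0.0), axis=0), 0.0)
        ssb += np.where(use, counts[g] * (means[g] - grand) ** 2, 0.0)

    df_b = n_testable - 1
    df_w = n_tot - n_testable
    with np.errstate(invalid="ignore", divide="ignore"):
        msb = ssb / np.maximum(df_b, 1)
        msw = ssw / np.maximum(df_w, 1)
        F = np.where(msw > 0, msb / msw, np.where(msb > 0, np.inf, 0.0))
    p = np.where(tested & (df_w > 0), stats.f.sf(F, np.maximum(df_b, 1), np.maximum(df_w, 1)), np.nan)
    p = np.where(tested & np.isclose(F, 0.0), 1.0, p)

    out = pd.DataFrame(index=matrix.columns)
    out["F"] = np.where(tested, F, np.nan)
    out["p"] = p
    out["tested"] = tested
    for g in labels:
        out[f"mean_{g}"] = means[g]

    k = n_testable.astype(float)
    for a, b in combinations(labels, 2):
        diff = means[a] - means[b]
        pair_ok = tested & testable[a] & testable[b] & (df_w > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            se = np.sqrt(msw / 2.0 * (1.0 / np.maximum(counts[a], 1)
                                      + 1.0 / np.maximum(counts[b], 1)))
            q = np.abs(diff) / se
        tukey_p = np.full(n_prot, np.nan)
        idx = np.flatnonzero(pair_ok)
        if idx.size:
            finite_q = np.isfinite(q[idx]) & (q[idx] > 0)
            sub = idx[finite_q]
            if sub.size > 32:
                # quadrature path: per unique (k, df) batch
                for kk, dd in set(zip(k[sub], df_w[sub])):
                    batch = sub[(k[sub] == kk) & (df_w[sub] == dd)]
                    tukey_p[batch] = studentized_range_sf(q[batch], int(kk), float(dd))
            else:
                tukey_p[sub] = stats.studentized_range.sf(q[sub], k[sub], df_w[sub])
            degen = idx[~finite_q]
            tukey_p[degen] = np.where(np.isclose(diff[degen], 0.0), 1.0, 0.0)
        out[f"log2fc_{a}_vs_{b}"] = np.where(pair_ok, diff, np.nan)
        out[f"tukey_p_{a}_vs_{b}"] = np.minimum(tukey_p, 1.0)
    if module_labels is not None:
        out["module"] = module_labels.reindex(out.index)
    return out


def eigenprotein_group_tests(eigenproteins: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Group tests on module eigenproteins.

    Three or more groups use the same ANOVA + Tukey machinery as proteins;
    exactly two groups use a two-sided Welch-free (pooled) t test, reported
    in ``p`` and the single pairwise column.
    """
    groups = groups.loc[eigenproteins.index]
    labels = [g for g in pd.unique(groups) if pd.notna(g)]
    if len(labels) > 2:
        return anova_tukey(eigenproteins, groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    a, b = labels
    out = pd.DataFrame(index=eigenproteins.columns)
    xa = eigenproteins[groups == a]
    xb = eigenproteins[groups == b]
    res = stats.ttest_ind(xa, xb, nan_policy="omit")
    out["t"] = res.statistic
    out["p"] = res.pvalue
    out["tested"] = True
    out[f"mean_{a}"] = xa.mean().to_numpy()
    out[f"mean_{b}"] = xb.mean().to_numpy()
    out[f"log2fc_{a}_vs_{b}"] = (xa.mean() - xb.mean()).to_numpy()
    out[f"tukey_p_{a}_vs_{b}"] = res.pvalue
    return out


def module_da_summary(
    diff: pd.DataFrame,
    labels: pd.Series,
    pair: tuple[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-module fraction of differentially abundant members and mean log2FC."""
    a, b = pair
    pcol, fcol = f"tukey_p_{a}_vs_{b}", f"log2fc_{a}_vs_{b}"
    if pcol not in diff.columns:
        pcol, fcol = f"tukey_p_{b}_vs_{a}", f"log2fc_{b}_vs_{a}"
        sign = -1.0
        if pcol not in diff.columns:
            raise KeyError(f"no Tukey column for pair {pair}")
    else:
        sign = 1.0
    labels = labels.reindex(diff.index)
    rows = []
    for m in sorted(x for x in labels.dropna().unique() if x > 0):
        members = diff[labels == m]
        sig = members[pcol] < alpha
        rows.append({
            "module": int(m),
            "n_members": len(members),
            "frac_da": float(sig.mean()) if len(members) else np.nan,
            "mean_log2fc": float(sign * members[fcol].mean()),
            "n_da": int(sig.sum()),
        })
    return pd.DataFrame(rows).set_index("module")


def assign_abundance_tiers(abundance_log10_pg_per_l: pd.Series) -> pd.Series:
    """Tier proteins by absolute plasma abundance.

    high > 9.5 log10 pg/L; intermediate in [6.0, 9.5]; low < 6.0.  Proteins
    without an annotation are NaN.
    """
    a = abundance_log10_pg_per_l
    tier = pd.Series(pd.NA, index=a.index, dtype="object")
    tier[a < TIER_LOW_MAX] = "low"
    tier[(a >= TIER_LOW_MAX) & (a <= TIER_HIGH_MIN)] = "intermediate"
    tier[a > TIER_HIGH_MIN] = "high"
    return tier


def tier_stratified_analysis(
    diff: pd.DataFrame,
    tiers: pd.Series,
    pair: tuple[str, str],
    alpha: float = 0.05,
) -> dict:
    """Stratify a pairwise contrast by absolute-abundance tier.

    Runs a one-way ANOVA of signed per-protein log2 fold changes across
    tiers and a chi-square test of independence (no continuity correction)
    on the tier x (upregulated vs not) contingency table; reports per-tier
    mean fold change and percent differentially upregulated.
    """
    a, b = pair
    fcol, pcol = f"log2fc_{a}_vs_{b}", f"tukey_p_{a}_vs_{b}"
    sign = 1.0
    if fcol not in diff.columns:
        fcol, pcol = f"log2fc_{b}_vs_{a}", f"tukey_p_{b}_vs_{a}"
        sign = -1.0
        if fcol not in diff.columns:
            raise KeyError(f"no fold-change column for pair {pair}")
    tiers = tiers.reindex(diff.index)
    sub = diff[[fcol, pcol]].copy()
    sub[fcol] = sign * sub[fcol]
    sub["tier"] = tiers
    sub = sub.dropna(subset=[fcol, "tier"])
    tier_groups = []
    tier_names = []
    for t in ("low", "intermediate", "high"):
        vals = sub.loc[sub["tier"] == t, fcol].to_numpy()
        if len(vals) < 2:
            warnings.warn(f"tier {t!r} has <2 proteins; excluded")
            continue
        tier_groups.append(vals)
        tier_names.append(t)
    if len(tier_groups) < 2:
        raise ValueError("need at least 2 populated tiers")
    F, p_anova = stats.f_oneway(*tier_groups)

    up = (sub[pcol] < alpha) & (sub[fcol] > 0)
    table = np.array([
        [int(up[sub["tier"] == t].sum()), int((~up[sub["tier"] == t]).sum())]
        for t in tier_names
    ])
    chi2, p_chi2, _, _ = stats.chi2_contingency(table, correction=False)
    per_tier = pd.DataFrame({
        "tier": tier_names,
        "n": [len(g) for g in tier_groups],
        "mean_log2fc": [float(np.mean(g)) for g in tier_groups],
        "pct_da_up": [100.0 * table[i, 0] / table[i].sum() for i in range(len(tier_names))],
    }).set_index("tier")
    return {
        "F": float(F),
        "p_anova": float(p_anova),
        "chi2": float(chi2),
        "p_chi2": float(p_chi2),
        "per_tier": per_tier,
    }
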