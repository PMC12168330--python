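"""Gene-set enrichment statistics.

Overrepresentation is assessed with one-tailed Fisher exact
(hypergeometric) tests on the 2x2 table of hit-list membership against
gene-set membership within a background universe; the p-value is reported
as a signed z score (positive for enrichment beyond expectation, negative
for depletion) via the standard-normal quantile transform.  Multiple
testing uses Benjamini–Hochberg step-up q-values.

Symbol matching is case-insensitive exact match; no alias expansion.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["fisher_enrichment", "bh_fdr", "module_overrepresentation"]

_P_FLOOR = 1e-300
_P_CEIL = 1.0 - 1e-16


def _norm_symbols(items) -> set[str]:
    return {str(s).strip().upper() for s in items if str(s).strip()}


def fisher_enrichment(hit_list, gene_set, universe) -> dict:
    """One row of an enrichment table for a (hit list, gene set) pair.

    Returns overlap count, expected overlap, one-tailed Fisher p (greater),
    and the signed z score.  ``hit_list`` must lie within ``universe``;
    ``gene_set`` is intersected with it.
    """
    hits = _norm_symbols(hit_list)
    gset = _norm_symbols(gene_set)
    uni = _norm_symbols(universe)
    if not hits or not gset or not uni:
        raise ValueError("hit list, gene set, and universe must be non-empty")
    if not hits <= uni:
        raise ValueError("hit list must be a subset of the universe")
    gset &= uni
    if not gset:
        raise ValueError("gene set has no members in the universe")

    N, K, n = len(uni), len(gset), len(hits)
    k = len(hits & gset)
    expected = n * K / N
    # one-tailed enrichment p: P(X >= k)
    p_greater = float(stats.hypergeom.sf(k - 1, N, K, n))
    # The z transform uses the mid-p (half the point mass), which removes
    # the discreteness bias of the exact tail: at the expected overlap z is
    # near zero, and z is a smooth, strictly decreasing function of the
    # evidence on either side.  The reported p stays the exact tail.
    half_point = 0.5 * float(stats.hypergeom.pmf(k, N, K, n))
    if k >= expected:
        p_mid = min(max(p_greater - half_point, _P_FLOOR), _P_CEIL)
        z = float(stats.norm.isf(p_mid))
    else:
        p_less = float(stats.hypergeom.cdf(k, N, K, n))
        p_mid = min(max(p_less - half_point, _P_FLOOR), _P_CEIL)
        z = -float(stats.norm.isf(p_mid))
    return {
        "overlap": k,
        "expected": expected,
        "set_size": K,
        "list_size": n,
        "universe_size": N,
        "p": p_greater,
        "z": z,
    }


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values.

    NaN p-values propagate as NaN and are excluded from the ranking.
    """
    p = np.asarray(pvals, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    ps = p[ok]
    m = ps.size
    if m == 0:
        return q
    order = np.argsort(ps, kind="stable")
    ranked = ps[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


def module_overrepresentation(
    protein_trait_corrs: pd.DataFrame,
    labels: pd.Series,
    direction: str = "negative",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Module-wise overrepresentation of trait-associated proteins.

    The hit list is the set of proteins with nominal correlation p below
    ``alpha`` in the requested direction (sign of the coefficient); each
    module is tested against the universe of all tested proteins with a
    one-tailed Fisher exact test, and q-values are BH-corrected across
    modules.

    ``protein_trait_corrs`` needs columns ``rho`` and ``p`` indexed by
    protein.
    """
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    tested = protein_trait_corrs.dropna(subset=["rho", "p"])
    sign_ok = tested["rho"] > 0 if direction == "positive" else tested["rho"] < 0
    hits = set(tested.index[(tested["p"] < alpha) & sign_ok])
    universe = set(tested.index)
    labels = labels.reindex(tested.index)
    rows = []
    mods = sorted(m for m in labels.dropna().unique() if m > 0)
    if not hits:
        warnings.warn("no trait-associated proteins at the nominal threshold")
        for m in mods:
            members = set(labels.index[labels == m])
            rows.append({"module": int(m), "overlap": 0, "expected": 0.0,
                         "set_size": len(members), "list_size": 0,
                         "universe_size": len(universe), "p": 1.0, "z": 0.0})
        out = pd.DataFrame(rows).set_index("module")
        out["q"] = 1.0
        return out
    for m in mods:
        members = set(labels.index[labels == m])
        res = fisher_enrichment(hits, members, universe)
        res["module"] = int(m)
        rows.append(res)
    out = pd.DataFrame(rows).set_index("module")
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out
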