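"""Biweight midcorrelation (bicor).

bicor is a robust alternative to Pearson correlation that downweights
observations far from the median, using Tukey's biweight.  For a vector x
with median m_x and MAD_x = median(|x - m_x|):

    u_i = (x_i - m_x) / (9 * MAD_x)
    w_i = (1 - u_i^2)^2  if |u_i| < 1 else 0

and the correlation is the normalized inner product of the weighted,
median-centered vectors a_i = (x_i - m_x) * w_i.  A vector with MAD = 0
(more than half its values tied) carries no robust scale information; for
such a vector the computation falls back to Pearson-style mean centering
with unit weights, matching the conventional implementation.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["bicor", "bicor_matrix", "bicor_pairs", "correlation_p_from_t"]


def _biweight_terms(x: np.ndarray) -> np.ndarray:
    """Weighted median-centered values for one complete vector."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0.0:
        # Pearson fallback: unit weights, mean centering.
        return x - x.mean()
    u = (x - med) / (9.0 * mad)
    with np.errstate(over="ignore"):
        w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
    return (x - med) * w


def bicor(x, y, min_obs: int = 3) -> float:
    """Biweight midcorrelation of two vectors over pairwise-complete entries.

    Parameters
    ----------
    x, y
        1-d numeric arrays of equal length; NaN marks missing.
    min_obs
        Minimum number of jointly observed entries (default 3).

    Returns
    -------
    float in [-1, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("bicor expects two 1-d vectors of equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < min_obs:
        raise ValueError(
            f"bicor needs at least {min_obs} pairwise-complete observations, got {int(ok.sum())}"
        )
    a = _biweight_terms(x[ok])
    b = _biweight_terms(y[ok])
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0.0:
        # weights collapsed (near-degenerate MAD): Pearson fallback
        a = x[ok] - x[ok].mean()
        b = y[ok] - y[ok].mean()
        denom = np.sqrt((a**2).sum() * (b**2).sum())
        if denom == 0.0:
            return 0.0
    return float(np.clip((a * b).sum() / denom, -1.0, 1.0))


def _transform_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise biweight transform with NaN support.

    Column statistics (median, MAD) are computed on each column's observed
    values; missing entries contribute zero and are renormalized per pair in
    the matrix products downstream.  Returns (A, M): weighted centered values
    with NaN -> 0, and the observation mask.
    """
    X = np.asarray(X, dtype=float)
    mask = np.isfinite(X)
    A = np.zeros_like(X)
    for j in range(X.shape[1]):
        col = X[mask[:, j], j]
        if col.size == 0:
            continue
        a = _biweight_terms(col)
        A[mask[:, j], j] = a
    return A, mask.astype(float)


def bicor_matrix(X: np.ndarray, min_obs: int = 3) -> np.ndarray:
    """All pairwise biweight midcorrelations between columns of X.

    Missing entries are handled pairwise-complete at the product stage:
    numerator and both denominators are restricted to jointly observed rows.
    Pairs with fewer than ``min_obs`` joint observations are NaN.
    """
    A, M = _transform_columns(X)
    A2 = A**2
    num = A.T @ A
    # Denominator of column i within pair (i, j): sum of a_i^2 over rows
    # observed in both i and j.  a_i is already 0 where i is missing.
    d_left = A2.T @ M     # d_left[i, j] = sum_k a_ik^2 * m_jk
    d_right = d_left.T
    with np.errstate(invalid="ignore", divide="ignore"):
        C = num / np.sqrt(d_left * d_right)
    n_joint = M.T @ M
    C[n_joint < min_obs] = np.nan
    C = np.clip(C, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return C


def bicor_pairs(X: np.ndarray, Y: np.ndarray, min_obs: int = 3) -> np.ndarray:
    """Cross biweight midcorrelations: columns of X against columns of Y."""
    A, Mx = _transform_columns(X)
    B, My = _transform_columns(Y)
    num = A.T @ B
    d_left = (A**2).T @ My
    d_right = Mx.T @ (B**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = num / np.sqrt(d_left * d_right)
    n_joint = Mx.T @ My
    C[n_joint < min_obs] = np.nan
    return np.clip(C, -1.0, 1.0)


def correlation_p_from_t(r, n):
    """Two-sided p-value for a correlation via the t approximation on n-2 df."""
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2.0) / np.clip(1.0 - r**2, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(t), np.maximum(n - 2.0, 1.0))
    return np.where(np.isfinite(r) & (n > 2), np.minimum(p, 1.0), np.nan)
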