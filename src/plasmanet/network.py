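"""Signed weighted co-expression network construction.

The pipeline mirrors the standard weighted-correlation-network workflow for
proteomics: a robust correlation matrix (biweight midcorrelation), signed
soft-threshold adjacency a_ij = ((1 + c_ij)/2)^power, topological overlap
similarity, average-linkage clustering with dynamic hybrid tree cutting,
module eigenproteins (first principal component of each module), merging of
modules with near-identical eigenproteins, and iterative kME-consistency
reassignment of module membership.  Module ids are stable integers ordered
by size (module 1 is the largest); 0 marks unassigned proteins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from plasmanet.correlation import bicor_matrix, bicor_pairs
from plasmanet.treecut import dynamic_hybrid_cut

__all__ = [
    "NetworkParams",
    "NetworkModel",
    "signed_adjacency",
    "tom_similarity",
    "cut_modules",
    "module_eigenprotein",
    "merge_close_modules",
    "kme_table",
    "enforce_kme_consistency",
    "build_network",
]


@dataclass
class NetworkParams:
    """Tuning parameters of the co-expression network.

    Defaults are the analysis settings this package standardizes on for
    plasma NPX data: soft threshold 7.5 on a signed network, maximal
    split sensitivity, modules of at least 10 proteins, eigenprotein
    merge distance 0.07, and the mean-denominator topological overlap.
    """

    power: float = 7.5
    deep_split: int = 4
    min_module_size: int = 10
    merge_cut_height: float = 0.07
    tom_denom: str = "mean"
    correlation: str = "bicor"
    signed: bool = True
    pam_stage: bool = True
    pam_respects_dendro: bool = True
    min_kme: float = 0.30
    max_kme_iter: int = 30

    def __post_init__(self):
        if self.power <= 0:
            raise ValueError("power must be positive")
        if not (0.0 <= self.merge_cut_height < 1.0):
            raise ValueError("merge_cut_height must be in [0, 1)")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if self.tom_denom not in ("mean", "min"):
            raise ValueError("tom_denom must be 'mean' or 'min'")
        if self.correlation not in ("bicor", "pearson"):
            raise ValueError("correlation must be 'bicor' or 'pearson'")


@dataclass
class NetworkModel:
    """Fitted network: dendrogram, labels, eigenproteins, and kME table."""

    params: NetworkParams
    linkage: np.ndarray
    module_labels: pd.Series            # protein -> module id, 0 = unassigned
    eigenproteins: pd.DataFrame         # samples x modules ("M1", "M2", ...)
    kme: pd.DataFrame                   # proteins x modules
    variance_explained: pd.Series       # per module
    converged: bool = True
    notes: list = field(default_factory=list)

    @property
    def n_modules(self) -> int:
        return int((self.module_labels.unique() > 0).sum())


def _correlation_matrix(values: np.ndarray, method: str) -> np.ndarray:
    if method == "bicor":
        return bicor_matrix(values)
    C = pd.DataFrame(values).corr(min_periods=3).to_numpy()
    np.fill_diagonal(C, 1.0)
    return C


def signed_adjacency(C: np.ndarray, power: float) -> np.ndarray:
    """Soft-threshold adjacency of a signed network: ((1 + c)/2)^power."""
    C = np.asarray(C, dtype=float)
    if C.shape[0] != C.shape[1] or not np.allclose(C, C.T, atol=1e-10, equal_nan=True):
        raise ValueError("correlation matrix must be symmetric")
    if np.nanmax(np.abs(C)) > 1 + 1e-9:
        raise ValueError("correlation entries must lie in [-1, 1]")
    A = ((1.0 + np.clip(C, -1.0, 1.0)) / 2.0) ** power
    np.fill_diagonal(A, 1.0)
    return A


def tom_similarity(A: np.ndarray, denom: str = "mean") -> np.ndarray:
    """Topological overlap similarity of an adjacency matrix.

    TOM_ij = (l_ij + a_ij) / (D_ij + 1 - a_ij) with l_ij the shared-neighbor
    weight sum and D_ij the mean (or min) of the two node connectivities.
    """
    A = np.asarray(A, dtype=float)
    if A.min() < -1e-12 or A.max() > 1 + 1e-9:
        raise ValueError("adjacency entries must lie in [0, 1]")
    if not np.allclose(np.diag(A), 1.0):
        raise ValueError("adjacency must have unit diagonal")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    k = A.sum(axis=0) - 1.0
    L = A @ A - 2.0 * A            # removes the u=i and u=j terms (diag = 1)
    if denom == "mean":
        D = (k[:, None] + k[None, :]) / 2.0
    elif denom == "min":
        D = np.minimum(k[:, None], k[None, :])
    else:
        raise ValueError("denom must be 'mean' or 'min'")
    tom = (L + A) / (D + 1.0 - A)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def cut_modules(dissimilarity: np.ndarray, params: NetworkParams) -> tuple[np.ndarray, np.ndarray]:
    """Initial module labels from dynamic hybrid cutting of the TOM dendrogram."""
    return dynamic_hybrid_cut(
        dissimilarity,
        deep_split=params.deep_split,
        min_module_size=params.min_module_size,
        pam_stage=params.pam_stage,
        pam_respects_dendro=params.pam_respects_dendro,
    )


def module_eigenprotein(
    matrix: pd.DataFrame, members: list[str]
) -> tuple[pd.Series, float]:
    """First principal component of a module's member proteins.

    Member columns are standardized; missing cells are imputed with the
    protein median for this computation only.  The score is scaled to unit
    variance and signed so that its mean correlation with members is
    positive.  Zero-variance members are dropped with a warning.
    """
    if len(members) < 2:
        raise ValueError("a module needs at least 2 members")
    sub = matrix[list(members)].to_numpy(dtype=float)
    if sub.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    med = np.nanmedian(sub, axis=0)
    filled = np.where(np.isfinite(sub), sub, med[None, :])
    sd = filled.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance member(s)")
        if keep.sum() < 2:
            raise ValueError("fewer than 2 members with variance")
        filled, sd = filled[:, keep], sd[keep]
    Zs = (filled - filled.mean(axis=0)) / sd
    U, s, _ = np.linalg.svd(Zs, full_matrices=False)
    score = U[:, 0]
    var_explained = float(s[0] ** 2 / (s**2).sum())
    score = score / score.std(ddof=1)
    mean_cor = np.mean([np.corrcoef(Zs[:, j], score)[0, 1] for j in range(Zs.shape[1])])
    if mean_cor < 0:
        score = -score
    return pd.Series(score, index=matrix.index), var_explained


def _eigenproteins(matrix: pd.DataFrame, labels: pd.Series) -> tuple[pd.DataFrame, pd.Series]:
    mes, ve = {}, {}
    for m in sorted(labels.unique()):
        if m <= 0:
            continue
        members = labels.index[labels == m].tolist()
        score, v = module_eigenprotein(matrix, members)
        mes[f"M{m}"] = score
        ve[f"M{m}"] = v
    return pd.DataFrame(mes, index=matrix.index), pd.Series(ve, dtype=float)


def merge_close_modules(
    matrix: pd.DataFrame, labels: pd.Series, merge_cut_height: float
) -> pd.Series:
    """Iteratively merge module pairs with eigenprotein dissimilarity below cut.

    Dissimilarity is 1 - Pearson correlation of eigenproteins; after each
    merge the eigenproteins are recomputed, so merging cascades correctly.
    """
    labels = labels.copy()
    while True:
        mods = sorted(m for m in labels.unique() if m > 0)
        if len(mods) < 2:
            return labels
        mes, _ = _eigenproteins(matrix, labels)
        corr = np.corrcoef(mes.to_numpy().T)
        np.fill_diagonal(corr, -np.inf)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if 1.0 - corr[i, j] >= merge_cut_height:
            return labels
        a, b = mods[i], mods[j]
        labels[labels == max(a, b)] = min(a, b)


def kme_table(matrix: pd.DataFrame, eigenproteins: pd.DataFrame) -> pd.DataFrame:
    """kME: biweight midcorrelation of every protein with every eigenprotein."""
    K = bicor_pairs(matrix.to_numpy(dtype=float), eigenproteins.to_numpy(dtype=float))
    return pd.DataFrame(K, index=matrix.columns, columns=eigenproteins.columns)


def enforce_kme_consistency(
    matrix: pd.DataFrame,
    labels: pd.Series,
    min_kme: float = 0.30,
    max_iter: int = 30,
    min_module_size: int = 10,
) -> tuple[pd.Series, bool]:
    """Iteratively reassign proteins until the kME table is self-consistent.

    Each pass recomputes eigenproteins and kME, then (a) moves every protein
    whose maximal kME belongs to a module other than its label into that
    module (including recruiting unassigned proteins whose best kME clears
    ``min_kme``), (b) unassigns proteins whose own-module kME falls below
    ``min_kme``, and (c) dissolves modules that drop below
    ``min_module_size``.  Returns the labels and a convergence flag.
    """
    labels = labels.copy()
    for _ in range(max_iter):
        mods = sorted(m for m in labels.unique() if m > 0)
        if not mods:
            return labels, True
        mes, _ = _eigenproteins(matrix, labels)
        kme = kme_table(matrix, mes)
        mod_ids = np.array([int(c[1:]) for c in kme.columns])
        arr = kme.to_numpy()
        best_col = np.nanargmax(arr, axis=1)
        best_val = arr[np.arange(arr.shape[0]), best_col]
        new = labels.copy()
        for i, p in enumerate(kme.index):
            lab = labels[p]
            target = int(mod_ids[best_col[i]])
            if lab > 0:
                own = kme.at[p, f"M{lab}"]
                if target != lab and best_val[i] > own:
                    new[p] = target
                if np.isnan(own) or own < min_kme:
                    if best_val[i] >= min_kme:
                        new[p] = target
                    else:
                        new[p] = 0
            else:
                if best_val[i] >= min_kme:
                    new[p] = target
        counts = new[new > 0].value_counts()
        for m in counts.index[counts < min_module_size]:
            new[new == m] = 0
        if new.equals(labels):
            return labels, True
        labels = new
    warnings.warn("kME reassignment did not reach a fixed point; returning last state")
    return labels, False


def _relabel_by_size(labels: pd.Series) -> pd.Series:
    counts = labels[labels > 0].value_counts()
    order = sorted(counts.index, key=lambda m: (-counts[m], m))
    mapping = {old: i + 1 for i, old in enumerate(order)}
    mapping[0] = 0
    return labels.map(mapping)


def build_network(matrix: pd.DataFrame, params: NetworkParams | None = None) -> NetworkModel:
    """Full network pipeline: correlation -> adjacency -> TOM -> modules -> kME."""
    params = params or NetworkParams()
    notes: list[str] = []
    sd = matrix.std(axis=0, ddof=1)
    keep = sd[sd > 0].index
    if len(keep) < matrix.shape[1]:
        notes.append(f"dropped {matrix.shape[1] - len(keep)} zero-variance proteins")
        matrix = matrix[keep]
    values = matrix.to_numpy(dtype=float)
    C = _correlation_matrix(values, params.correlation)
    C = np.nan_to_num(C, nan=0.0)
    if not params.signed:
        C = np.abs(C)
        A = (C ** params.power)
        np.fill_diagonal(A, 1.0)
    else:
        A = signed_adjacency(C, params.power)
    tom = tom_similarity(A, params.tom_denom)
    labels_arr, Z = cut_modules(1.0 - tom, params)
    labels = pd.Series(labels_arr, index=matrix.columns)
    if (labels > 0).any():
        labels = merge_close_modules(matrix, labels, params.merge_cut_height)
        labels, converged = enforce_kme_consistency(
            matrix, labels, params.min_kme, params.max_kme_iter, params.min_module_size
        )
        # reassignment can re-create near-duplicate modules; merge once more
        labels = merge_close_modules(matrix, labels, params.merge_cut_height)
    else:
        converged = True
    labels = _relabel_by_size(labels)
    if (labels > 0).any():
        mes, ve = _eigenproteins(matrix, labels)
        kme = kme_table(matrix, mes)
    else:
        mes = pd.DataFrame(index=matrix.index)
        ve = pd.Series(dtype=float)
        kme = pd.DataFrame(index=matrix.columns)
    return NetworkModel(
        params=params,
        linkage=Z,
        module_labels=labels,
        eigenproteins=mes,
        kme=kme,
        variance_explained=ve,
        converged=converged,
        notes=notes,
    )
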