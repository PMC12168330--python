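"""Quality control and covariate adjustment of the protein matrix.

The QC chain runs in a fixed order: LOD masking, protein-level filtering
(QC-warned assays, duplicate UniProt accessions, high missingness),
connectivity-based sample outlier removal, then bootstrap age/sex
adjustment with case-status protection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from plasmanet.correlation import bicor_matrix

__all__ = [
    "QCReport",
    "apply_lod_mask",
    "filter_proteins",
    "sample_connectivity",
    "remove_outlier_samples",
    "bootstrap_covariate_adjust",
]


@dataclass
class QCReport:
    """Accounting of what each QC stage removed."""

    n_input_proteins: int = 0
    n_qc_warning: int = 0
    n_duplicate_removed: int = 0
    n_high_missing: int = 0
    n_retained_proteins: int = 0
    n_input_samples: int = 0
    n_outlier_samples: int = 0
    n_retained_samples: int = 0
    removed_samples: dict = field(default_factory=dict)  # sample id -> connectivity Z
    connectivity_z: pd.Series | None = None

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "connectivity_z"}
        d["removed_samples"] = {k: float(v) for k, v in self.removed_samples.items()}
        return d


def apply_lod_mask(matrix: pd.DataFrame, qc: pd.DataFrame) -> pd.DataFrame:
    """Mask cells below the limit of detection.

    The LOD of an assay is its median log2 buffer signal plus three buffer
    standard deviations; cells strictly below it are coded missing (values
    equal to the limit are retained).
    """
    missing_rows = [p for p in matrix.columns if p not in qc.index]
    if missing_rows:
        raise KeyError(f"no QC row for protein(s): {missing_rows[:5]}")
    sub = qc.loc[matrix.columns]
    if (sub["buffer_sd"] < 0).any():
        raise ValueError("buffer_sd must be non-negative")
    lod = (sub["buffer_median"] + 3.0 * sub["buffer_sd"]).to_numpy()
    vals = matrix.to_numpy(dtype=float)
    masked = np.where(vals < lod[None, :], np.nan, vals)
    return pd.DataFrame(masked, index=matrix.index, columns=matrix.columns)


def filter_proteins(
    matrix: pd.DataFrame,
    qc: pd.DataFrame,
    missing_threshold: float = 0.5,
) -> tuple[pd.DataFrame, QCReport]:
    """Drop QC-warned assays, duplicate UniProt assays, and high-missing proteins.

    Among assays sharing a UniProt accession exactly one is kept: the assay
    with the lowest missing fraction, ties broken by highest variance, then
    lexicographically smallest assay id.  Proteins with missing fraction
    strictly greater than ``missing_threshold`` are then removed.
    """
    report = QCReport(n_input_proteins=matrix.shape[1],
                      n_input_samples=matrix.shape[0],
                      n_retained_samples=matrix.shape[0])
    sub = qc.loc[matrix.columns]

    warned = sub.index[sub["qc_warning"].astype(bool)]
    report.n_qc_warning = len(warned)
    kept = matrix.drop(columns=list(warned))
    sub = sub.drop(index=list(warned))

    miss_frac = kept.isna().mean(axis=0)
    variance = kept.var(axis=0, ddof=1)
    order = pd.DataFrame({
        "uniprot": sub["uniprot_id"],
        "miss": miss_frac,
        "neg_var": -variance.fillna(0.0),
        "assay": kept.columns,
    })
    winners = (
        order.sort_values(["miss", "neg_var", "assay"])
        .groupby("uniprot", sort=False)
        .head(1)["assay"]
    )
    dup_removed = [a for a in kept.columns if a not in set(winners)]
    report.n_duplicate_removed = len(dup_removed)
    kept = kept.drop(columns=dup_removed)

    miss_frac = kept.isna().mean(axis=0)
    high = miss_frac.index[miss_frac > missing_threshold]
    report.n_high_missing = len(high)
    kept = kept.drop(columns=list(high))

    if kept.shape[1] == 0:
        raise ValueError("no proteins retained after filtering")
    report.n_retained_proteins = kept.shape[1]
    return kept, report


def sample_connectivity(matrix: pd.DataFrame, method: str = "bicor") -> pd.Series:
    """Standardized per-sample connectivity Z.

    Connectivity of sample i is the sum of its correlations (bicor by
    default, Pearson optionally) with every other sample across
    pairwise-complete proteins; Z standardizes across samples.  When all
    connectivities are equal the Z scores are degenerate and returned as
    zeros with a warning.
    """
    if matrix.shape[0] < 3 or matrix.shape[1] < 2:
        raise ValueError("need at least 3 samples and 2 proteins")
    vals = matrix.to_numpy(dtype=float).T  # proteins x samples; samples as variables
    obs = np.isfinite(vals).astype(float)
    joint = obs.T @ obs
    np.fill_diagonal(joint, np.inf)
    if (joint.min(axis=1) < 2).any():
        bad = matrix.index[joint.min(axis=1) < 2].tolist()
        raise ValueError(f"sample(s) with <2 pairwise-complete proteins: {bad[:5]}")
    if method == "bicor":
        C = bicor_matrix(vals, min_obs=2)
    elif method == "pearson":
        C = pd.DataFrame(vals).corr(min_periods=2).to_numpy()
    else:
        raise ValueError(f"unknown connectivity method {method!r}")
    np.fill_diagonal(C, 0.0)
    k = np.nansum(C, axis=1)
    sd = k.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        warnings.warn("degenerate connectivity (zero spread); returning all-zero Z")
        z = np.zeros_like(k)
    else:
        z = (k - k.mean()) / sd
    return pd.Series(z, index=matrix.index, name="connectivity_z")


def remove_outlier_samples(
    matrix: pd.DataFrame,
    z_cutoff: float = 3.0,
    method: str = "bicor",
) -> tuple[pd.DataFrame, QCReport]:
    """Remove low-connectivity outlier samples in a single pass.

    Samples whose connectivity Z falls below ``-z_cutoff`` are removed.
    The rule is one-sided: decorrelated samples can only lose connectivity.
    """
    if z_cutoff <= 0:
        raise ValueError("z_cutoff must be positive")
    z = sample_connectivity(matrix, method=method)
    flag = z < -z_cutoff
    if flag.all():
        raise ValueError("all samples flagged as outliers; check the matrix")
    report = QCReport(
        n_input_proteins=matrix.shape[1],
        n_retained_proteins=matrix.shape[1],
        n_input_samples=matrix.shape[0],
        n_outlier_samples=int(flag.sum()),
        n_retained_samples=int((~flag).sum()),
        removed_samples=dict(z[flag]),
        connectivity_z=z,
    )
    return matrix.loc[~flag], report


def _ols_betas(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Least-squares coefficients for every response column of Y."""
    XtX = X.T @ X
    return np.linalg.solve(XtX, X.T @ Y)


def bootstrap_covariate_adjust(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "sex"),
    n_boot: int = 1000,
    seed: int = 0,
    group_col: str = "group",
    resample: bool = True,
    max_retries: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Regress out covariates with case-status protection.

    For each bootstrap replicate the samples are resampled with replacement
    within each case-status group, and each protein is regressed on the
    covariates plus group indicator dummies (on its non-missing cells).  The
    element-wise median of the covariate coefficients over replicates is
    multiplied by the raw covariate values and subtracted from the observed
    matrix; group terms are estimated but never subtracted, protecting
    case-related variance.  Missing cells stay missing.

    With ``resample=False`` and ``n_boot=1`` this reduces to a single
    ordinary least-squares fit on the full sample.

    Returns
    -------
    (adjusted_matrix, coefficients)
        ``coefficients`` has one row per protein and one column per covariate
        (the median bootstrap estimate).
    """
    meta = meta.loc[matrix.index]
    for c in covariates:
        if meta[c].nunique(dropna=True) < 2:
            raise ValueError(f"covariate {c!r} is constant")
    groups = meta[group_col].astype("category")
    if (groups.value_counts() < 2).any():
        raise ValueError("each group needs at least 2 samples")

    dummies = pd.get_dummies(groups, drop_first=True, dtype=float)
    design_cols = ["_intercept", *covariates, *dummies.columns.astype(str)]
    base = np.column_stack([
        np.ones(len(meta)),
        meta[list(covariates)].to_numpy(dtype=float),
        dummies.to_numpy(),
    ])
    Y = matrix.to_numpy(dtype=float)
    n, p = Y.shape
    obs = np.isfinite(Y)
    group_codes = groups.cat.codes.to_numpy()
    idx_by_group = [np.flatnonzero(group_codes == g) for g in range(len(groups.cat.categories))]

    rng = np.random.default_rng(seed)
    n_cov = len(covariates)
    betas = np.empty((n_boot, n_cov, p))

    # Proteins sharing a missingness pattern are fitted jointly.
    pattern_ids, pattern_index = np.unique(obs, axis=1, return_inverse=True)

    for b in range(n_boot):
        for attempt in range(max_retries + 1):
            if resample:
                rows = np.concatenate([rng.choice(g, size=len(g), replace=True)
                                       for g in idx_by_group])
            else:
                rows = np.arange(n)
            Xb = base[rows]
            ok = True
            for k in range(pattern_ids.shape[1]):
                cols = np.flatnonzero(pattern_index == k)
                keep = pattern_ids[rows, k]
                Xk = Xb[keep]
                if Xk.shape[0] <= Xb.shape[1] or np.linalg.matrix_rank(Xk) < Xb.shape[1]:
                    ok = False
                    break
            if ok:
                break
        else:
            raise RuntimeError("could not draw a non-singular bootstrap design "
                               f"within {max_retries} retries")
        for k in range(pattern_ids.shape[1]):
            cols = np.flatnonzero(pattern_index == k)
            keep = pattern_ids[rows, k]
            bk = _ols_betas(Xb[keep], Y[rows][np.ix_(keep, cols)])
            betas[b, :, cols] = bk[1:1 + n_cov, :].T

    med = np.median(betas, axis=0)  # n_cov x p
    cov_vals = meta[list(covariates)].to_numpy(dtype=float)  # n x n_cov
    adjusted = Y - cov_vals @ med
    adjusted[~obs] = np.nan
    coef = pd.DataFrame(med.T, index=matrix.columns, columns=list(covariates))
    out = pd.DataFrame(adjusted, index=matrix.index, columns=matrix.columns)
    return out, coef
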