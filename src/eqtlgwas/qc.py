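"""Genotype and expression quality control, normalization, covariates.

Implements the standard post-imputation variant filters (MAF, missingness,
exact Hardy–Weinberg test, imputation-quality score), the mean-FPKM expression
floor, the rank-based inverse-normal transform, ancestry principal components,
and SVD-based hidden expression factors used in place of PEER.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, ndtri
from scipy.stats import rankdata

log = logging.getLogger(__name__)

__all__ = [
    "QcThresholds",
    "compute_maf",
    "hwe_exact_test",
    "variant_qc",
    "filter_genes_by_expression",
    "inverse_normal_transform",
    "ancestry_pcs",
    "hidden_factors",
    "mean_impute",
]


@dataclass(frozen=True)
class QcThresholds:
    """Variant / gene inclusion cut-offs.

    Defaults: MAF >= 1%, missing rate < 5%, HWE exact p > 1e-5, imputation
    quality >= 0.3, mean FPKM >= 0.1.
    """

    maf_min: float = 0.01
    missing_max: float = 0.05
    hwe_p_min: float = 1e-5
    quality_min: float = 0.3
    fpkm_mean_min: float = 0.1


def compute_maf(dosages: np.ndarray | pd.Series) -> float:
    """Folded allele frequency min(f, 1-f) with f = mean(dosage)/2 over
    non-missing entries."""
    x = np.asarray(dosages, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("all dosages missing")
    f = float(np.mean(x)) / 2.0
    return min(f, 1.0 - f)


def hwe_exact_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact conditional Hardy–Weinberg test.

    Conditions on the minor-allele count and sums, over all admissible
    heterozygote counts of matching parity, the probabilities no larger than
    the observed configuration's (two-sided minimum-likelihood rule).
    """
    if min(n_hom_major, n_het, n_hom_minor) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_major + n_het + n_hom_minor
    if n < 1:
        raise ValueError("need at least one genotype")
    n_minor = 2 * n_hom_minor + n_het
    n_minor = min(n_minor, 2 * n - n_minor)  # fold to the minor allele
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    # log P(het = h | allele counts) up to a shared constant
    logp = (
        hets * np.log(2)
        - gammaln(hets + 1)
        - gammaln((n_minor - hets) // 2 + 1)
        - gammaln(n - (n_minor + hets) // 2 + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    p_obs = p[hets == n_het][0]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def variant_qc(
    dosages: pd.DataFrame,
    variants: pd.DataFrame,
    thresholds: QcThresholds = QcThresholds(),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Filter variants on MAF, missingness, HWE and quality score, in that
    order; the report records the first failing criterion per variant."""
    mat = dosages.to_numpy(dtype=float)
    n = mat.shape[0]
    miss_frac = np.isnan(mat).mean(axis=0)
    records = []
    for j, vid in enumerate(dosages.columns):
        col = mat[:, j]
        ok = ~np.isnan(col)
        maf = np.nan if not ok.any() else min(col[ok].mean() / 2, 1 - col[ok].mean() / 2)
        # HWE needs hard genotype classes; round dosages to nearest genotype
        g = np.rint(col[ok]).astype(int)
        counts = np.bincount(np.clip(g, 0, 2), minlength=3)
        hwe_p = hwe_exact_test(int(counts[0]), int(counts[1]), int(counts[2])) if ok.any() else np.nan
        qual = float(variants["quality_score"].iloc[j])
        reason = ""
        if np.isnan(maf) or maf < thresholds.maf_min:
            reason = "maf"
        elif miss_frac[j] >= thresholds.missing_max:
            reason = "missingness"
        elif hwe_p <= thresholds.hwe_p_min:
            reason = "hwe"
        elif qual < thresholds.quality_min:
            reason = "quality"
        records.append(
            {
                "variant_id": vid,
                "maf": maf,
                "missing_fraction": miss_frac[j],
                "hwe_p": hwe_p,
                "quality_score": qual,
                "pass": reason == "",
                "first_fail_reason": reason,
            }
        )
    report = pd.DataFrame(records)
    keep = report["pass"].to_numpy()
    if not keep.any():
        log.warning("variant_qc removed every variant (n=%d)", len(report))
    kept_ids = report.loc[keep, "variant_id"]
    return (
        dosages.loc[:, kept_ids],
        variants[variants["id"].isin(kept_ids)].reset_index(drop=True),
        report,
    )


def filter_genes_by_expression(expr: pd.DataFrame, fpkm_mean_min: float = 0.1) -> pd.DataFrame:
    """Drop genes whose across-sample mean FPKM is strictly below the floor
    (boundary genes are kept)."""
    keep = expr.mean(axis=1) >= fpkm_mean_min
    if not keep.any():
        warnings.warn("expression filter removed every gene", stacklevel=2)
    return expr.loc[keep]


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse-normal transform.

    Average ranks for ties; transformed value Phi^-1((rank - 0.5)/n).  A
    constant vector maps to all zeros (with a warning) since every rank ties
    at the median.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("expects a single gene vector")
    ok = ~np.isnan(x)
    if ok.sum() < 2:
        raise ValueError("need at least two non-missing values")
    out = np.full_like(x, np.nan)
    v = x[ok]
    if np.all(v == v[0]):
        warnings.warn("constant vector; inverse-normal transform is all zeros", stacklevel=2)
        out[ok] = 0.0
        return out
    ranks = rankdata(v, method="average")
    out[ok] = ndtri((ranks - 0.5) / v.size)
    return out


def transform_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Apply the inverse-normal transform to every gene row."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mat = np.vstack([inverse_normal_transform(row) for row in expr.to_numpy()])
    return pd.DataFrame(mat, index=expr.index, columns=expr.columns)


def mean_impute(mat: np.ndarray) -> np.ndarray:
    """Replace missing entries by their column mean (zero if all missing)."""
    out = np.array(mat, dtype=float)
    mask = np.isnan(out)
    if mask.any():
        with np.errstate(invalid="ignore"):
            col_mean = np.nanmean(out, axis=0)
        col_mean = np.nan_to_num(col_mean)
        out[mask] = np.take(col_mean, np.nonzero(mask)[1])
    return out


def ancestry_pcs(dosages: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Top-k sample-score principal components of the column-standardized
    (mean-imputed) dosage matrix, ordered by decreasing variance explained."""
    if k == 0:
        return pd.DataFrame(index=dosages.index)
    x = mean_impute(dosages.to_numpy(dtype=float))
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x = x / sd
    rank = min(x.shape)
    if k > rank:
        raise ValueError(f"k={k} exceeds admissible rank {rank}")
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :k] * s[:k]
    return pd.DataFrame(
        scores, index=dosages.index, columns=[f"PC{i + 1}" for i in range(k)]
    )


def hidden_factors(
    expr_transformed: pd.DataFrame,
    known_covariates: pd.DataFrame | None,
    k: int = 15,
) -> pd.DataFrame:
    """Hidden expression confounder covariates.

    Gene-wise residualization on the known covariates followed by the top-k
    left singular directions (sample scores) of the residual matrix — a
    deterministic surrogate for PEER's variational factor model, with the
    same default factor count.
    """
    y = expr_transformed.to_numpy(dtype=float).T  # samples x genes
    n, g = y.shape
    if k >= min(g, n):
        raise ValueError(f"k={k} must be < min(n_genes, n_samples)={min(g, n)}")
    if k == 0:
        return pd.DataFrame(index=expr_transformed.columns)
    design = np.ones((n, 1))
    if known_covariates is not None and known_covariates.shape[1] > 0:
        design = np.hstack([design, known_covariates.to_numpy(dtype=float)])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    u, s, _ = np.linalg.svd(resid, full_matrices=False)
    scores = u[:, :k] * s[:k]
    return pd.DataFrame(
        scores,
        index=expr_transformed.columns,
        columns=[f"factor{i + 1}" for i in range(k)],
    )
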