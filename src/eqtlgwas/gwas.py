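"""Case-control association, genomic inflation, locus grouping, trend power.

Per-variant logistic regression under the additive model is fit by iteratively
reweighted least squares (Newton scoring) with Wald tests on the dosage term.
Analytic power for the Cochran–Armitage trend test follows the genotype-
relative-risk parameterization used by GWAS power calculators: additive-on-risk
penetrances f_het = r·f0, f_hom = (2r − 1)·f0 with the baseline solved from
the population prevalence under Hardy–Weinberg genotype frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

log = logging.getLogger(__name__)

__all__ = [
    "PowerSpec",
    "logistic_assoc",
    "gwas_scan",
    "genomic_lambda",
    "select_suggestive",
    "define_loci",
    "trend_test_power",
]

CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.45494...
MAX_ABS_LOG_OR = 10.0


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of the analytic trend-test power calculation."""

    n_cases: int
    n_controls: int
    maf: float
    grr: float
    alpha: float = 1e-5
    prevalence: float = 0.01
    model: str = "additive"

    def __post_init__(self) -> None:
        if not (0 < self.maf <= 0.5):
            raise ValueError("maf must be in (0, 0.5]")
        if self.grr <= 0:
            raise ValueError("grr must be > 0")
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must be in (0, 1)")
        if self.model != "additive":
            raise ValueError("only the additive model is supported")


class DegenerateFitError(ValueError):
    """Raised when the logistic model cannot be fit (constant dosage or a
    single outcome class)."""


def _irls(y: np.ndarray, X: np.ndarray, tol: float = 1e-8, maxiter: int = 100):
    """Newton scoring for logistic regression; returns (beta, cov, converged)."""
    n, p = X.shape
    beta = np.zeros(p)
    ll_old = -np.inf
    converged = False
    for _ in range(maxiter):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1 - mu)
        w = np.maximum(w, 1e-12)
        XtW = X.T * w
        try:
            delta = np.linalg.solve(XtW @ X, X.T @ (y - mu))
        except np.linalg.LinAlgError:
            break
        beta = beta + delta
        eta = X @ beta
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
    eta = X @ beta
    mu = expit(eta)
    w = np.maximum(mu * (1 - mu), 1e-12)
    try:
        cov = np.linalg.inv((X.T * w) @ X)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        converged = False
    return beta, cov, converged


def logistic_assoc(
    status: np.ndarray,
    dosage: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
    effect_allele: str = "",
    other_allele: str = "",
    variant_id: str = "",
) -> dict:
    """Additive-model logistic regression of case status on dosage.

    Convergence requires a log-likelihood change below 1e-8 within 100
    iterations; a non-converged fit or |log OR| > 10 (quasi-separation) sets
    ``converged`` False so the variant can be excluded downstream.
    """
    y = np.asarray(status, dtype=float)
    x = np.asarray(dosage, dtype=float)
    if y.min() == y.max():
        raise DegenerateFitError("only one outcome class present")
    if np.std(x) == 0:
        raise DegenerateFitError("constant dosage")
    cols = [np.ones_like(x), x]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.append(cov)
    X = np.column_stack(cols)
    beta, cov_mat, converged = _irls(y, X)
    log_or = float(beta[1])
    se = float(np.sqrt(cov_mat[1, 1]))
    if abs(log_or) > MAX_ABS_LOG_OR:
        converged = False
    z = log_or / se if se > 0 else np.nan
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
    return {
        "variant_id": variant_id,
        "effect_allele": effect_allele,
        "other_allele": other_allele,
        "log_or": log_or,
        "se": se,
        "z": z,
        "p": p,
        "n_cases": int(y.sum()),
        "n_controls": int((1 - y).sum()),
        "converged": bool(converged),
    }


def gwas_scan(
    phenotypes: pd.DataFrame,
    dosages: pd.DataFrame,
    variants: pd.DataFrame,
    covariate_cols: tuple[str, ...] = ("age", "sex"),
    pcs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-variant logistic association for one cohort.

    Covariates are the named phenotype columns plus any supplied ancestry PC
    scores.  Variants that fail to fit are reported with converged=False and
    NaN statistics (logged), mirroring the exclusion policy downstream.
    """
    y = phenotypes["case_status"].to_numpy(dtype=float)
    cov = phenotypes[list(covariate_cols)].to_numpy(dtype=float)
    if pcs is not None and pcs.shape[1] > 0:
        cov = np.hstack([cov, pcs.loc[phenotypes.index].to_numpy(dtype=float)])
    meta = variants.set_index("id")
    rows = []
    n_failed = 0
    for vid in dosages.columns:
        x = dosages[vid].to_numpy(dtype=float)
        if np.isnan(x).any():
            x = np.where(np.isnan(x), np.nanmean(x), x)
        ea = str(meta.loc[vid, "alt"]) if vid in meta.index else ""
        oa = str(meta.loc[vid, "ref"]) if vid in meta.index else ""
        try:
            rec = logistic_assoc(y, x, cov, ea, oa, vid)
        except DegenerateFitError:
            rec = {
                "variant_id": vid, "effect_allele": ea, "other_allele": oa,
                "log_or": np.nan, "se": np.nan, "z": np.nan, "p": np.nan,
                "n_cases": int(y.sum()), "n_controls": int(len(y) - y.sum()),
                "converged": False,
            }
            n_failed += 1
        rows.append(rec)
    if n_failed:
        log.info("gwas_scan: %d variant(s) failed to fit", n_failed)
    out = pd.DataFrame(rows)
    out["beta"] = out["log_or"]  # alias used by the meta-analysis stage
    return out


def genomic_lambda(p) -> float:
    """Genomic inflation factor: median 1-df chi-square quantile of the
    p-values divided by the null chi-square median (~0.4549)."""
    p = np.asarray(p, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no p-values")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    chi = stats.chi2.isf(p, 1)
    return float(np.median(chi) / CHI2_1DF_MEDIAN)


def select_suggestive(
    meta_table: pd.DataFrame,
    per_cohort: list[pd.DataFrame],
    p_meta_max: float = 1e-5,
    p_cohort_max: float = 0.05,
    require_concordance: bool = True,
) -> pd.DataFrame:
    """Variants at suggestive meta significance with nominal support in every
    cohort (and, by default, a concordant effect direction)."""
    keep = meta_table[meta_table["p"] < p_meta_max].copy()
    signs = None
    for i, tab in enumerate(per_cohort):
        t = tab.set_index("variant_id")
        keep[f"p_cohort_{i + 1}"] = keep["variant_id"].map(t["p"])
        s = keep["variant_id"].map(np.sign(t["beta"]))
        signs = s if signs is None else signs.where(signs == s, other=0.0)
        keep = keep[keep[f"p_cohort_{i + 1}"] < p_cohort_max]
        signs = signs.loc[keep.index]
    if require_concordance and signs is not None:
        keep = keep[(signs != 0) & signs.notna()]
    return keep.reset_index(drop=True)


def define_loci(variants: pd.DataFrame, gap: int = 500_000) -> pd.DataFrame:
    """Greedy p-ascending clumping: each variant within ``gap`` of an existing
    index joins that locus, otherwise founds a new one.  Input order never
    matters (sorting is internal)."""
    df = variants.sort_values(["p", "chrom", "pos"], kind="mergesort").reset_index(drop=True)
    loci: list[dict] = []
    assign = []
    for _, row in df.iterrows():
        found = None
        for locus in loci:
            if row["chrom"] == locus["chrom"] and abs(row["pos"] - locus["index_pos"]) <= gap:
                found = locus
                break
        if found is None:
            found = {
                "locus_id": f"locus{len(loci) + 1}",
                "chrom": row["chrom"],
                "index_pos": int(row["pos"]),
                "index_variant": row["variant_id"],
                "min_p": float(row["p"]),
            }
            loci.append(found)
        assign.append(found["locus_id"])
    df["locus_id"] = assign
    return df


def trend_test_power(spec: PowerSpec) -> float:
    """Analytic power of the Cochran–Armitage trend test (scores 0, 1, 2).

    The noncentrality is the squared expected score difference between cases
    and controls over its null (pooled) variance; power is the upper tail of
    the noncentral 1-df chi-square beyond the central critical value at alpha.
    """
    p = spec.maf
    g = np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])
    r = spec.grr
    rr = np.array([1.0, r, 2 * r - 1])
    if np.any(rr < 0):
        raise ValueError("additive model needs grr >= 0.5")
    f0 = spec.prevalence / float(g @ rr)
    f = f0 * rr
    if np.any(f > 1) or np.any(f < 0):
        raise ValueError("implied penetrances outside [0, 1]; grr too large for prevalence/maf")
    k = float(g @ f)
    p_case = g * f / k
    p_ctrl = g * (1 - f) / (1 - k)
    x = np.array([0.0, 1.0, 2.0])
    n_r, n_s = spec.n_cases, spec.n_controls
    n = n_r + n_s
    pooled = (n_r * p_case + n_s * p_ctrl) / n
    var_pooled = float(pooled @ x**2 - (pooled @ x) ** 2)
    delta = float(p_case @ x - p_ctrl @ x)
    var_null = var_pooled * (1.0 / n_r + 1.0 / n_s)
    ncp = delta**2 / var_null
    crit = stats.chi2.isf(spec.alpha, 1)
    if spec.grr == 1.0:
        return float(spec.alpha)
    return float(stats.ncx2.sf(crit, 1, ncp))
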