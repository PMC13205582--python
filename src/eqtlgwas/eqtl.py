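"""Per-cohort cis-eQTL mapping.

Enumerates variant–gene pairs within a window of each gene's TSS (default
±1 Mb, boundary-inclusive) and fits covariate-adjusted ordinary least squares
of transformed expression on alternative-allele dosage.  ``map_cohort`` uses
the Frisch–Waugh–Lovell residualization fast path — regress the covariates out
of both expression and dosage once, then simple regression with the residual
degrees of freedom corrected for the covariate count — which is algebraically
identical to the full multiple regression.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .qc import mean_impute

log = logging.getLogger(__name__)

DEFAULT_CIS_WINDOW = 1_000_000
P_FLOOR = np.nextafter(0, 1)

__all__ = ["cis_pairs", "fit_association", "map_cohort", "bh_adjust"]


def cis_pairs(
    variants: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = DEFAULT_CIS_WINDOW,
) -> pd.DataFrame:
    """All same-chromosome (variant, gene) pairs with |pos - tss| <= window.

    ``tss_distance`` is signed pos - tss, with the sign flipped for minus-
    strand genes so that positive always means downstream of transcription.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    out = []
    for chrom, vsub in variants.groupby("chrom", sort=False):
        gsub = genes[genes["chrom"] == chrom]
        if gsub.empty:
            continue
        pos = vsub["pos"].to_numpy()
        order = np.argsort(pos)
        pos_sorted = pos[order]
        ids_sorted = vsub["id"].to_numpy()[order]
        for _, gene in gsub.iterrows():
            tss = int(gene["tss"])
            lo = np.searchsorted(pos_sorted, tss - window, side="left")
            hi = np.searchsorted(pos_sorted, tss + window, side="right")
            if hi <= lo:
                continue
            d = pos_sorted[lo:hi] - tss
            if gene["strand"] == "-":
                d = -d
            out.append(
                pd.DataFrame(
                    {
                        "variant_id": ids_sorted[lo:hi],
                        "gene_id": gene["gene_id"],
                        "tss_distance": d,
                    }
                )
            )
    if not out:
        return pd.DataFrame(columns=["variant_id", "gene_id", "tss_distance"])
    return pd.concat(out, ignore_index=True)


def fit_association(
    y: np.ndarray,
    x: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
) -> dict:
    """OLS of y on [1, x, covariates]; beta / se / t / p for the x term.

    Degenerate inputs (zero-variance x or y, or a perfect fit) yield a
    flagged record: the p-value is floored at the smallest positive float
    rather than reported as zero.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.size
    cov = None
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        # drop collinear covariate columns
        q, r = np.linalg.qr(np.hstack([np.ones((n, 1)), cov]))
        keep = np.abs(np.diag(r))[1:] > 1e-10 * max(1.0, np.abs(r[0, 0]))
        if not keep.all():
            log.warning("dropping %d collinear covariate column(s)", (~keep).sum())
            cov = cov[:, keep]
    p_cov = 0 if cov is None else cov.shape[1]
    if n <= p_cov + 2:
        raise ValueError(f"n={n} too small for {p_cov} covariates")
    if np.std(x) == 0 or np.std(y) == 0:
        return {
            "beta": np.nan, "se": np.nan, "statistic": np.nan, "p": np.nan,
            "n": n, "df": n - p_cov - 2, "flag": "zero_variance",
        }
    design = np.ones((n, 1)) if cov is None else np.hstack([np.ones((n, 1)), cov])
    bx, *_ = np.linalg.lstsq(design, x, rcond=None)
    by, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ bx
    ry = y - design @ by
    sxx = float(rx @ rx)
    sxy = float(rx @ ry)
    syy = float(ry @ ry)
    df = n - p_cov - 2
    beta = sxy / sxx
    rss = max(syy - beta * sxy, 0.0)
    flag = ""
    if rss <= 1e-12 * max(syy, 1.0):
        se = np.sqrt(max(rss, 1e-300) / df / sxx)
        t = beta / se if se > 0 else np.inf
        p = P_FLOOR
        flag = "degenerate"
    else:
        se = np.sqrt(rss / df / sxx)
        t = beta / se
        p = float(2 * stats.t.sf(abs(t), df))
        p = max(p, P_FLOOR)
    return {"beta": beta, "se": se, "statistic": t, "p": p, "n": n, "df": df, "flag": flag}


def map_cohort(
    expr: pd.DataFrame,
    dosages: pd.DataFrame,
    covariates: pd.DataFrame | None,
    pairs: pd.DataFrame,
    per_gene_covariates: dict[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """One association row per cis pair for a single cohort.

    Expression must already be inverse-normal transformed; dosage columns are
    mean-imputed.  Pairs whose variant or gene was removed upstream are
    skipped (count logged).  Genes with per-gene covariates fall back to the
    direct per-pair fit; all others use the residualization fast path.
    """
    samples = expr.columns
    dos = dosages.loc[samples]
    n = len(samples)
    cov_mat = None
    if covariates is not None and covariates.shape[1] > 0:
        cov_mat = covariates.loc[samples].to_numpy(dtype=float)
    p_cov = 0 if cov_mat is None else cov_mat.shape[1]
    df = n - p_cov - 2
    if df < 1:
        raise ValueError("not enough samples for the covariate count")

    have = pairs["variant_id"].isin(dos.columns) & pairs["gene_id"].isin(expr.index)
    skipped = int((~have).sum())
    if skipped:
        log.info("map_cohort: skipping %d pairs referencing filtered ids", skipped)
    pairs = pairs.loc[have]

    design = np.ones((n, 1)) if cov_mat is None else np.hstack([np.ones((n, 1)), cov_mat])
    x_all = mean_impute(dos.to_numpy(dtype=float))
    bx, *_ = np.linalg.lstsq(design, x_all, rcond=None)
    rx_all = x_all - design @ bx
    y_all = expr.to_numpy(dtype=float)
    by, *_ = np.linalg.lstsq(design, y_all.T, rcond=None)
    ry_all = y_all.T - design @ by  # samples x genes

    col_of = {v: j for j, v in enumerate(dos.columns)}
    row_of = {g: i for i, g in enumerate(expr.index)}

    records = []
    for gene_id, sub in pairs.groupby("gene_id", sort=False):
        gi = row_of[gene_id]
        vidx = np.array([col_of[v] for v in sub["variant_id"]])
        if per_gene_covariates and gene_id in per_gene_covariates:
            extra = per_gene_covariates[gene_id].loc[samples].to_numpy(dtype=float)
            full_cov = extra if cov_mat is None else np.hstack([cov_mat, extra])
            for k, j in enumerate(vidx):
                r = fit_association(y_all[gi], x_all[:, j], full_cov)
                records.append((sub["variant_id"].iloc[k], gene_id,
                                int(sub["tss_distance"].iloc[k]), r))
            continue
        ry = ry_all[:, gi]
        rx = rx_all[:, vidx]
        sxx = np.einsum("ij,ij->j", rx, rx)
        sxy = rx.T @ ry
        syy = float(ry @ ry)
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = sxy / sxx
            rss = np.maximum(syy - beta * sxy, 0.0)
            se = np.sqrt(rss / df / sxx)
            tstat = beta / se
        for k, j in enumerate(vidx):
            if sxx[k] <= 1e-12 * n or syy <= 1e-12 * n:
                r = {"beta": np.nan, "se": np.nan, "statistic": np.nan, "p": np.nan,
                     "n": n, "df": df, "flag": "zero_variance"}
            elif rss[k] <= 1e-12 * max(syy, 1.0):
                r = {"beta": beta[k], "se": se[k], "statistic": tstat[k],
                     "p": P_FLOOR, "n": n, "df": df, "flag": "degenerate"}
            else:
                p = max(float(2 * stats.t.sf(abs(tstat[k]), df)), P_FLOOR)
                r = {"beta": beta[k], "se": se[k], "statistic": tstat[k],
                     "p": p, "n": n, "df": df, "flag": ""}
            records.append((sub["variant_id"].iloc[k], gene_id,
                            int(sub["tss_distance"].iloc[k]), r))

    out = pd.DataFrame(
        [
            {
                "variant_id": v, "gene_id": g, "tss_distance": d,
                "beta": r["beta"], "se": r["se"], "statistic": r["statistic"],
                "p": r["p"], "n": r["n"], "df": r["df"], "flag": r["flag"],
            }
            for v, g, d, r in records
        ],
        columns=["variant_id", "gene_id", "tss_distance", "beta", "se",
                 "statistic", "p", "n", "df", "flag"],
    )
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
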