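"""Fixed-effects inverse-variance meta-analysis and heterogeneity triage.

Shared by the eQTL and GWAS stages.  Pools per-study effects with weights
1/se², reports Cochran's Q, I² = max(0, (Q - df)/Q)·100 and its chi-square
p-value, and flags substantial heterogeneity at I² >= 75% with P_Het < 0.05.
Also converts printed OR / 95% CI summaries back to the log scale so that
stage-level results can be combined.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "MetaStat",
    "ivw_meta",
    "ci_to_log_scale",
    "combine_or_stages",
    "heterogeneity_triage",
    "meta_analyze_table",
    "harmonize_alleles",
]

I2_TRIAGE_MIN = 75.0
P_HET_TRIAGE_MAX = 0.05


@dataclass(frozen=True)
class MetaStat:
    beta_meta: float
    se_meta: float
    z: float
    p: float
    q: float
    df: int
    p_het: float
    i2: float
    k: int
    het_flag: bool


def ivw_meta(stats_list) -> MetaStat:
    """Fixed-effects inverse-variance pooling of (beta, se) tuples.

    For a single study the input passes through with Q = 0, P_Het = 1, I² = 0.
    The pooled p-value uses the normal approximation of z.
    """
    betas = np.array([b for b, _ in stats_list], dtype=float)
    ses = np.array([s for _, s in stats_list], dtype=float)
    if betas.size == 0:
        raise ValueError("need at least one study")
    bad = np.flatnonzero(~(ses > 0))
    if bad.size:
        raise ValueError(f"non-positive standard error at index {bad[0]}")
    w = 1.0 / ses**2
    beta_meta = float(np.sum(w * betas) / np.sum(w))
    se_meta = float(np.sum(w) ** -0.5)
    z = beta_meta / se_meta
    p = float(2 * stats.norm.sf(abs(z)))
    k = betas.size
    df = k - 1
    q = float(np.sum(w * (betas - beta_meta) ** 2))
    if df == 0:
        p_het, i2 = 1.0, 0.0
    else:
        p_het = float(stats.chi2.sf(q, df))
        i2 = 0.0 if q <= 0 else max(0.0, (q - df) / q) * 100.0
    het_flag = (i2 >= I2_TRIAGE_MIN) and (p_het < P_HET_TRIAGE_MAX)
    return MetaStat(beta_meta, se_meta, z, p, q, df, p_het, i2, k, het_flag)


def ci_to_log_scale(
    or_value: float, ci_low: float, ci_high: float, level: float = 0.95
) -> tuple[float, float]:
    """Recover (log_or, se) from a printed OR with its Wald CI."""
    if not (0 < ci_low <= or_value <= ci_high):
        raise ValueError("require 0 < ci_low <= or <= ci_high")
    if ci_low == ci_high:
        raise ValueError("degenerate CI (zero width)")
    z = stats.norm.ppf(0.5 * (1 + level))
    return math.log(or_value), (math.log(ci_high) - math.log(ci_low)) / (2 * z)


def combine_or_stages(stages, level: float = 0.95) -> tuple[float, tuple[float, float], float]:
    """Pool per-stage (OR, ci_low, ci_high) summaries on the log scale.

    Returns the pooled OR, its Wald CI at ``level`` and the two-sided p.
    Order-invariant; needs at least two stages.
    """
    if len(stages) < 2:
        raise ValueError("need at least two stages")
    pooled = ivw_meta([ci_to_log_scale(o, lo, hi, level) for o, lo, hi in stages])
    z = stats.norm.ppf(0.5 * (1 + level))
    ci = (
        math.exp(pooled.beta_meta - z * pooled.se_meta),
        math.exp(pooled.beta_meta + z * pooled.se_meta),
    )
    return math.exp(pooled.beta_meta), ci, pooled.p


def heterogeneity_triage(
    meta_table: pd.DataFrame,
    i2_min: float = I2_TRIAGE_MIN,
    p_het_max: float = P_HET_TRIAGE_MAX,
) -> tuple[pd.DataFrame, float]:
    """Flag rows with substantial heterogeneity and report the proportion."""
    if meta_table.empty:
        raise ValueError("meta table is empty")
    flags = (meta_table["i2"] >= i2_min) & (meta_table["p_het"] < p_het_max)
    out = meta_table.copy()
    out["het_flag"] = flags.to_numpy()
    return out[out["het_flag"]], float(flags.mean())


_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def harmonize_alleles(reference: pd.DataFrame, other: pd.DataFrame) -> pd.DataFrame:
    """Align a second cohort's summary statistics to a reference cohort.

    If effect/other alleles are swapped relative to the reference, the beta
    sign is flipped; strand-ambiguous (A/T, C/G) variants whose alleles do not
    match either orientation are dropped with a warning.  Both tables need
    variant_id, effect_allele, other_allele and beta columns.
    """
    ref = reference.set_index("variant_id")
    rows = []
    dropped = 0
    for _, r in other.iterrows():
        vid = r["variant_id"]
        if vid not in ref.index:
            rows.append(r)
            continue
        ea, oa = ref.loc[vid, "effect_allele"], ref.loc[vid, "other_allele"]
        if (r["effect_allele"], r["other_allele"]) == (ea, oa):
            rows.append(r)
        elif (ea, oa) in _AMBIGUOUS:
            # a swap of A/T or C/G alleles is indistinguishable from a strand
            # difference: drop rather than guess the orientation
            dropped += 1
        elif (r["effect_allele"], r["other_allele"]) == (oa, ea):
            r = r.copy()
            r["beta"] = -r["beta"]
            r["effect_allele"], r["other_allele"] = ea, oa
            rows.append(r)
        else:
            dropped += 1
    if dropped:
        log.warning("harmonize_alleles: dropped %d mismatched variant(s)", dropped)
    return pd.DataFrame(rows).reset_index(drop=True)


def meta_analyze_table(
    tables: list[pd.DataFrame],
    keys: list[str],
    require_all: bool = False,
) -> pd.DataFrame:
    """Vectorized IVW meta-analysis across per-cohort summary tables.

    ``keys`` names the join columns (e.g. ["variant_id"] for GWAS,
    ["variant_id", "gene_id"] for eQTL).  Rows present in a single cohort are
    pooled as k = 1 and labelled single_cohort unless ``require_all``.
    """
    if not tables:
        raise ValueError("no tables to pool")
    frames = []
    for i, t in enumerate(tables):
        f = t[keys + ["beta", "se"]].copy()
        f = f[np.isfinite(f["beta"]) & (f["se"] > 0)]
        f["study"] = i
        frames.append(f)
    long = pd.concat(frames, ignore_index=True)
    long["w"] = 1.0 / long["se"] ** 2
    long["wb"] = long["w"] * long["beta"]
    g = long.groupby(keys, sort=False)
    agg = g.agg(sw=("w", "sum"), swb=("wb", "sum"), k=("w", "size"))
    agg["beta_meta"] = agg["swb"] / agg["sw"]
    agg["se_meta"] = agg["sw"] ** -0.5

    merged = long.merge(agg[["beta_meta"]], left_on=keys, right_index=True)
    merged["qterm"] = merged["w"] * (merged["beta"] - merged["beta_meta"]) ** 2
    q = merged.groupby(keys, sort=False)["qterm"].sum()
    agg["q"] = q
    agg["df"] = agg["k"] - 1
    agg["z"] = agg["beta_meta"] / agg["se_meta"]
    agg["p"] = 2 * stats.norm.sf(np.abs(agg["z"]))
    agg["p_het"] = np.where(agg["df"] > 0, stats.chi2.sf(agg["q"], np.maximum(agg["df"], 1)), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        i2 = np.where(agg["q"] > 0, np.maximum(0.0, (agg["q"] - agg["df"]) / agg["q"]) * 100.0, 0.0)
    agg["i2"] = i2
    agg["het_flag"] = (agg["i2"] >= I2_TRIAGE_MIN) & (agg["p_het"] < P_HET_TRIAGE_MAX)
    agg["label"] = np.where(agg["k"] < len(tables), "single_cohort", "")
    out = agg.reset_index().drop(columns=["sw", "swb"])
    if require_all:
        out = out[out["k"] == len(tables)].reset_index(drop=True)
    return out
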