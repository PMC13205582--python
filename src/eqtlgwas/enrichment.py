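"""Regulatory enrichment of eQTLs against matched non-eQTL nulls.

Lead (most significant) eQTLs per gene are compared with an equal-size set of
non-significant variants sampled from the same MAF × |TSS distance| stratum,
then tested for annotation overlap with Fisher's exact test.  Odds ratios and
Woolf confidence intervals use a Haldane–Anscombe 0.5 correction only when a
2×2 cell is zero; the exact p never does.  Also provides the generic gene-set
over-representation (hypergeometric) test used for eGene pathway analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .eqtl import bh_adjust

log = logging.getLogger(__name__)

__all__ = [
    "MatchSpec",
    "lead_variants",
    "sample_matched_controls",
    "annotate_overlap",
    "fisher_enrichment",
    "adjust_categories",
    "geneset_enrichment",
]

DEFAULT_DISTANCE_EDGES = (0.0, 1e3, 1e4, 1e5, 1e6)


@dataclass
class MatchSpec:
    """Stratified-sampling specification for the matched non-eQTL null.

    MAF bins default to deciles of the pooled lead + pool MAF distribution;
    |TSS distance| bins default to log-decades up to 1 Mb.  On bin exhaustion
    the sampler borrows from the nearest bin by Manhattan distance on bin
    indices (ties resolved toward the lower MAF bin).
    """

    maf_bins: np.ndarray | None = None
    distance_bins: np.ndarray = field(
        default_factory=lambda: np.asarray(DEFAULT_DISTANCE_EDGES)
    )
    seed: int = 0


def lead_variants(assoc: pd.DataFrame) -> pd.DataFrame:
    """The most significant pair per gene.

    Ties on FDR break by raw p, then by larger |beta|, then by variant id.
    """
    df = assoc.copy()
    df["_abs_beta"] = -df["beta_meta" if "beta_meta" in df else "beta"].abs()
    df = df.sort_values(
        ["gene_id", "fdr", "p", "_abs_beta", "variant_id"],
        kind="mergesort",
    )
    out = df.groupby("gene_id", sort=False).head(1).drop(columns="_abs_beta")
    return out.reset_index(drop=True)


def _bin_index(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(edges, values, side="right") - 1
    return np.clip(idx, 0, len(edges) - 2)


def sample_matched_controls(
    leads: pd.DataFrame,
    pool: pd.DataFrame,
    spec: MatchSpec | None = None,
) -> pd.DataFrame:
    """One MAF / TSS-distance matched non-eQTL control per lead variant.

    ``leads`` and ``pool`` need variant_id, maf and tss_distance columns; the
    pool must already be restricted to non-significant pairs (FDR >= 0.05).
    Sampling is without replacement, reproducible given ``spec.seed``; every
    borrow from a neighbouring stratum is logged.
    """
    if spec is None:
        spec = MatchSpec()
    if pool.empty or len(pool) < len(leads):
        raise ValueError(f"control pool ({len(pool)}) smaller than lead set ({len(leads)})")
    lead_maf = leads["maf"].to_numpy(dtype=float)
    pool_maf = pool["maf"].to_numpy(dtype=float)
    if spec.maf_bins is None:
        pooled = np.concatenate([lead_maf, pool_maf])
        edges = np.unique(np.quantile(pooled, np.linspace(0, 1, 11)))
        if len(edges) < 2:
            edges = np.array([pooled.min(), pooled.max() + 1e-9])
    else:
        edges = np.asarray(spec.maf_bins, dtype=float)
    dedges = np.asarray(spec.distance_bins, dtype=float)

    lead_d = np.abs(leads["tss_distance"].to_numpy(dtype=float))
    pool_d = np.abs(pool["tss_distance"].to_numpy(dtype=float))
    li = np.stack([_bin_index(lead_maf, edges), _bin_index(lead_d, dedges)], axis=1)
    pi = np.stack([_bin_index(pool_maf, edges), _bin_index(pool_d, dedges)], axis=1)

    rng = np.random.default_rng(spec.seed)
    cells: dict[tuple[int, int], list[int]] = {}
    for row, key in enumerate(map(tuple, pi)):
        cells.setdefault(key, []).append(row)
    for key in cells:
        rng.shuffle(cells[key])

    chosen: list[int] = []
    n_borrow = 0
    for key in map(tuple, li):
        if cells.get(key):
            chosen.append(cells[key].pop())
            continue
        # borrow from the nearest non-empty cell (Manhattan distance on bin
        # indices; ties toward the lower MAF bin)
        candidates = [
            (abs(k[0] - key[0]) + abs(k[1] - key[1]), k[0], k[1])
            for k, v in cells.items()
            if v
        ]
        if not candidates:
            raise ValueError("control pool exhausted")
        _, k0, k1 = min(candidates)
        n_borrow += 1
        chosen.append(cells[(k0, k1)].pop())
    if n_borrow:
        log.info("sample_matched_controls: %d draw(s) borrowed from neighbouring bins", n_borrow)
    return pool.iloc[chosen].reset_index(drop=True)


def annotate_overlap(variants: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    """Whether each variant (1-based pos) falls in any BED interval
    (0-based, half-open): overlap iff pos - 1 in [start, end)."""
    bad = intervals[intervals["start"] >= intervals["end"]]
    if len(bad):
        raise ValueError(f"malformed interval at line {bad.index[0] + 1} (start >= end)")
    out = np.zeros(len(variants), dtype=bool)
    chroms = variants["chrom"].to_numpy()
    pos0 = variants["pos"].to_numpy() - 1
    for chrom in pd.unique(chroms):
        isub = intervals[intervals["chrom"] == chrom].sort_values("start")
        if isub.empty:
            continue
        # merge so searchsorted containment is exact
        m_starts: list[int] = []
        m_ends: list[int] = []
        for s, e in zip(isub["start"].to_numpy(), isub["end"].to_numpy()):
            if m_ends and s <= m_ends[-1]:
                m_ends[-1] = max(m_ends[-1], e)
            else:
                m_starts.append(s)
                m_ends.append(e)
        starts = np.asarray(m_starts)
        ends = np.asarray(m_ends)
        sel = chroms == chrom
        p = pos0[sel]
        j = np.searchsorted(starts, p, side="right") - 1
        out[sel] = (j >= 0) & (p < ends[np.maximum(j, 0)])
    return out


def _or_ci(a: float, b: float, c: float, d: float, level: float = 0.95):
    """OR with a Woolf log-scale CI; Haldane 0.5 added to every cell iff any
    cell is zero."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_value = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 * (1 + level))
    log_or = np.log(or_value)
    return or_value, np.exp(log_or - z * se), np.exp(log_or + z * se)


def fisher_enrichment(
    query_overlap: np.ndarray,
    control_overlap: np.ndarray,
    category: str = "",
) -> dict:
    """Fisher's exact test on the 2×2 overlap table of query vs control.

    a/b = query overlapping / not, c/d = control overlapping / not.  The
    two-sided exact p sums hypergeometric probabilities no larger than the
    observed table's (scipy's convention).
    """
    q = np.asarray(query_overlap, dtype=bool)
    c_ = np.asarray(control_overlap, dtype=bool)
    if q.size == 0 or c_.size == 0:
        raise ValueError("query and control sets must be nonempty")
    a = int(q.sum())
    b = int(q.size - a)
    c = int(c_.sum())
    d = int(c_.size - c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    or_value, lo, hi = _or_ci(a, b, c, d)
    return {
        "category": category,
        "a": a, "b": b, "c": c, "d": d,
        "or_value": float(or_value),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "p": float(p),
    }


_BH_FAMILIES = {"functional_categories", "histone_marks"}
_BONF_FAMILIES = {"tf", "rbp"}


def adjust_categories(records: pd.DataFrame, family: str) -> pd.DataFrame:
    """Multiplicity adjustment per annotation family: BH for functional
    categories and histone marks, Bonferroni for TF / RBP binding sites."""
    out = records.copy()
    if family in _BH_FAMILIES:
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
        out["adjust_method"] = "BH"
    elif family in _BONF_FAMILIES:
        out["p_adj"] = np.minimum(1.0, len(out) * out["p"].to_numpy())
        out["adjust_method"] = "bonferroni"
    else:
        raise ValueError(f"unknown annotation family {family!r}")
    return out


def geneset_enrichment(query_genes: set, gene_set: set, background: set) -> dict:
    """Over-representation of a gene set within a query (upper hypergeometric
    tail), with the odds ratio from the induced 2×2 table."""
    query = set(query_genes)
    if not query:
        raise ValueError("empty query gene set")
    if not query <= set(background):
        raise ValueError("query must be a subset of the background")
    bg = set(background)
    in_set = gene_set & bg
    if not in_set:
        raise ValueError("gene set does not intersect the background")
    n_bg = len(bg)
    n_set = len(in_set)
    n_query = len(query)
    overlap = len(query & in_set)
    p = float(stats.hypergeom.sf(overlap - 1, n_bg, n_set, n_query))
    a = overlap
    b = n_query - overlap
    c = n_set - overlap
    d = n_bg - n_set - b
    or_value, lo, hi = _or_ci(a, b, c, d)
    return {
        "overlap": overlap, "n_query": n_query, "n_set": n_set, "n_background": n_bg,
        "a": a, "b": b, "c": c, "d": d,
        "or_value": float(or_value), "ci_low": float(lo), "ci_high": float(hi),
        "p": p,
    }
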