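"""Lead selection, matched-control sampling, interval overlap, Fisher
enrichment with Haldane correction, and gene-set over-representation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eqtlgwas import enrichment as enr

from conftest import make_variant_frame


def assoc_frame(rows):
    return pd.DataFrame(rows, columns=["variant_id", "gene_id", "beta", "p", "fdr", "maf", "tss_distance"])


def test_lead_variants_tie_breaks_on_abs_beta():
    tab = assoc_frame(
        [
            ("vA", "g1", 0.5, 1e-5, 1e-4, 0.2, 100),
            ("vB", "g1", -0.3, 1e-5, 1e-4, 0.2, 200),
            ("vC", "g2", 0.1, 0.5, 0.8, 0.3, 300),
        ]
    )
    leads = enr.lead_variants(tab)
    got = leads.set_index("gene_id")["variant_id"]
    assert got["g1"] == "vA"  # FDR and p tie; larger |beta| wins
    assert got["g2"] == "vC"  # single-pair gene


def test_lead_variants_matches_brute_force(rng):
    rows = []
    for g in range(50):
        for j in range(rng.integers(1, 6)):
            p = float(rng.random())
            rows.append((f"v{g}_{j}", f"g{g}", float(rng.normal()), p, p, 0.2, 100))
    tab = assoc_frame(rows)
    leads = enr.lead_variants(tab).set_index("gene_id")["variant_id"]
    for g, sub in tab.groupby("gene_id"):
        best_key = None
        best_vid = None
        for _, r in sub.iterrows():  # explicit scan with the stated tie-breaks
            key = (r["fdr"], r["p"], -abs(r["beta"]), r["variant_id"])
            if best_key is None or key < best_key:
                best_key, best_vid = key, r["variant_id"]
        assert leads[g] == best_vid


def test_matched_controls_properties(rng):
    leads = pd.DataFrame(
        {
            "variant_id": [f"L{i}" for i in range(40)],
            "maf": rng.uniform(0.05, 0.5, size=40),
            "tss_distance": rng.integers(-900_000, 900_000, size=40),
        }
    )
    pool = pd.DataFrame(
        {
            "variant_id": [f"P{i}" for i in range(2000)],
            "maf": rng.uniform(0.05, 0.5, size=2000),
            "tss_distance": rng.integers(-900_000, 900_000, size=2000),
            "fdr": rng.uniform(0.05, 1.0, size=2000),
        }
    )
    spec = enr.MatchSpec(seed=7)
    ctrl = enr.sample_matched_controls(leads, pool, spec)
    assert len(ctrl) == len(leads)
    assert ctrl["variant_id"].is_unique
    assert (ctrl["fdr"] >= 0.05).all()
    # ample pool: per-cell counts match exactly
    edges = np.unique(
        np.quantile(np.concatenate([leads["maf"], pool["maf"]]), np.linspace(0, 1, 11))
    )
    dedges = np.asarray(enr.DEFAULT_DISTANCE_EDGES)
    li = np.stack(
        [enr._bin_index(leads["maf"].to_numpy(), edges),
         enr._bin_index(np.abs(leads["tss_distance"].to_numpy(dtype=float)), dedges)],
        axis=1,
    )
    ci = np.stack(
        [enr._bin_index(ctrl["maf"].to_numpy(), edges),
         enr._bin_index(np.abs(ctrl["tss_distance"].to_numpy(dtype=float)), dedges)],
        axis=1,
    )
    lead_cells = pd.Series(map(tuple, li)).value_counts()
    ctrl_cells = pd.Series(map(tuple, ci)).value_counts()
    assert lead_cells.equals(ctrl_cells)
    # reproducibility
    ctrl2 = enr.sample_matched_controls(leads, pool, enr.MatchSpec(seed=7))
    pd.testing.assert_frame_equal(ctrl, ctrl2)


def test_matched_controls_maf_distribution_close(rng):
    leads = pd.DataFrame(
        {
            "variant_id": [f"L{i}" for i in range(60)],
            "maf": rng.beta(2, 5, size=60) * 0.5,
            "tss_distance": rng.integers(-500_000, 500_000, size=60),
        }
    )
    pool = pd.DataFrame(
        {
            "variant_id": [f"P{i}" for i in range(5000)],
            "maf": rng.uniform(0.01, 0.5, size=5000),
            "tss_distance": rng.integers(-900_000, 900_000, size=5000),
        }
    )
    stats_ds = []
    for seed in range(100):
        ctrl = enr.sample_matched_controls(leads, pool, enr.MatchSpec(seed=seed))
        stats_ds.append(stats.ks_2samp(leads["maf"], ctrl["maf"]).statistic)
    edges = np.quantile(np.concatenate([leads["maf"], pool["maf"]]), np.linspace(0, 1, 11))
    max_bin_width = np.diff(edges).max()
    # KS distance bounded by the coarseness of the matching grid
    assert np.mean(stats_ds) <= max_bin_width + 0.1


def test_matched_controls_pool_too_small_errors():
    leads = pd.DataFrame({"variant_id": ["a", "b"], "maf": [0.1, 0.2], "tss_distance": [0, 0]})
    pool = pd.DataFrame({"variant_id": ["x"], "maf": [0.1], "tss_distance": [0]})
    with pytest.raises(ValueError):
        enr.sample_matched_controls(leads, pool)


def test_matched_controls_forced_matching_is_deterministic():
    leads = pd.DataFrame(
        {"variant_id": ["a", "b"], "maf": [0.05, 0.45], "tss_distance": [500, 500_000]}
    )
    pool = pd.DataFrame(
        {"variant_id": ["x", "y"], "maf": [0.06, 0.44], "tss_distance": [600, 400_000]}
    )
    spec = enr.MatchSpec(maf_bins=np.array([0.0, 0.25, 0.5]))
    out1 = enr.sample_matched_controls(leads, pool, spec)
    out2 = enr.sample_matched_controls(
        leads, pool, enr.MatchSpec(maf_bins=np.array([0.0, 0.25, 0.5]), seed=99)
    )
    pd.testing.assert_frame_equal(out1, out2)  # one eligible control per cell


def test_annotate_overlap_coordinate_convention():
    variants = make_variant_frame([100, 100, 50])
    bed = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [99, 100], "end": [100, 200]})
    hit = enr.annotate_overlap(variants.iloc[[0]], bed.iloc[[0]])
    assert hit[0]
    hit = enr.annotate_overlap(variants.iloc[[0]], bed.iloc[[1]])
    assert not hit[0]
    # empty track
    empty = pd.DataFrame(columns=["chrom", "start", "end"])
    assert not enr.annotate_overlap(variants, empty).any()
    with pytest.raises(ValueError, match="line"):
        enr.annotate_overlap(
            variants, pd.DataFrame({"chrom": ["chr1"], "start": [10], "end": [10]})
        )


def test_annotate_overlap_matches_brute_force(rng):
    variants = make_variant_frame(rng.integers(1, 10_000, size=200))
    starts = rng.integers(0, 9_900, size=40)
    bed = pd.DataFrame(
        {"chrom": "chr1", "start": starts, "end": starts + rng.integers(1, 200, size=40)}
    )
    got = enr.annotate_overlap(variants, bed)
    brute = np.array(
        [
            any(s <= p - 1 < e for s, e in zip(bed["start"], bed["end"]))
            for p in variants["pos"]
        ]
    )
    np.testing.assert_array_equal(got, brute)


def fisher_two_sided_oracle(a, b, c, d):
    """Independent enumeration: sum hypergeometric probabilities <= observed."""
    n1, n0 = a + b, c + d
    k = a + c

    def prob(x):
        return (
            math.comb(n1, x) * math.comb(n0, k - x) / math.comb(n1 + n0, k)
        )

    p_obs = prob(a)
    return sum(
        prob(x)
        for x in range(max(0, k - n0), min(k, n1) + 1)
        if prob(x) <= p_obs * (1 + 1e-9)
    )


def test_fisher_enrichment_matches_enumeration_oracle():
    q = np.r_[np.ones(10), np.zeros(90)].astype(bool)
    c = np.r_[np.ones(5), np.zeros(95)].astype(bool)
    rec = enr.fisher_enrichment(q, c, "cat")
    assert rec["or_value"] == pytest.approx(10 * 95 / (90 * 5), abs=1e-3)  # 2.111
    assert rec["p"] == pytest.approx(fisher_two_sided_oracle(10, 90, 5, 95), rel=1e-9)


def test_fisher_enrichment_no_association_or_one():
    q = np.r_[np.ones(10), np.zeros(90)].astype(bool)
    c = np.r_[np.ones(20), np.zeros(180)].astype(bool)
    rec = enr.fisher_enrichment(q, c)
    assert rec["or_value"] == pytest.approx(1.0)


def test_fisher_enrichment_haldane_zero_cell():
    q = np.zeros(10, dtype=bool)
    c = np.r_[np.ones(5), np.zeros(5)].astype(bool)
    rec = enr.fisher_enrichment(q, c)
    assert rec["or_value"] == pytest.approx((0.5 * 5.5) / (10.5 * 5.5), abs=1e-4)  # 0.0476
    assert np.isfinite(rec["ci_low"]) and np.isfinite(rec["ci_high"])


def test_fisher_enrichment_swap_symmetry(rng):
    q = rng.random(80) < 0.3
    c = rng.random(120) < 0.2
    r1 = enr.fisher_enrichment(q, c)
    r2 = enr.fisher_enrichment(c, q)
    assert r1["p"] == pytest.approx(r2["p"], rel=1e-9)
    assert r1["or_value"] == pytest.approx(1 / r2["or_value"], rel=1e-9)


def test_adjust_categories_policies():
    rec = pd.DataFrame({"category": list("abc"), "p": [0.01, 0.2, 0.5]})
    bonf = enr.adjust_categories(rec, "tf")
    np.testing.assert_allclose(bonf["p_adj"], [0.03, 0.6, 1.0])
    bh = enr.adjust_categories(rec, "histone_marks")
    from eqtlgwas.eqtl import bh_adjust

    np.testing.assert_allclose(bh["p_adj"], bh_adjust(rec["p"].to_numpy()))
    single = enr.adjust_categories(rec.iloc[:1], "rbp")
    assert single["p_adj"].iloc[0] == pytest.approx(0.01)
    with pytest.raises(ValueError):
        enr.adjust_categories(rec, "unknown_family")


def test_geneset_enrichment_hand_combinatorics():
    background = {f"g{i}" for i in range(10)}
    gene_set = {f"g{i}" for i in range(5)}
    query = {"g0", "g1", "g2", "g3"}
    rec = enr.geneset_enrichment(query, gene_set, background)
    assert rec["p"] == pytest.approx(5 / 210, rel=1e-9)
    assert rec["overlap"] == 4


def test_geneset_enrichment_disjoint_and_errors():
    background = {f"g{i}" for i in range(10)}
    rec = enr.geneset_enrichment({"g8", "g9"}, {"g0", "g1"}, background)
    assert rec["p"] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        enr.geneset_enrichment(set(), {"g0"}, background)
    with pytest.raises(ValueError):
        enr.geneset_enrichment({"gX"}, {"g0"}, background)


def test_geneset_enrichment_null_uniform(rng):
    background = [f"g{i}" for i in range(200)]
    gene_set = set(rng.choice(background, size=40, replace=False))
    ps = []
    for _ in range(1000):
        query = set(rng.choice(background, size=20, replace=False))
        ps.append(enr.geneset_enrichment(query, gene_set, set(background))["p"])
    # discrete p-values are stochastically >= uniform; check no excess of small p
    assert np.mean(np.asarray(ps) < 0.05) <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / 1000)
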