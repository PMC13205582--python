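"""Generator checks: Hardy–Weinberg proportions, LD structure, effect
injection, case-fraction calibration, annotation enrichment, fixture I/O."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtri

from eqtlgwas import simulate
from eqtlgwas.eqtl import fit_association
from eqtlgwas.simulate import SimConfig


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(ld_rho=1.0)
    with pytest.raises(ValueError):
        SimConfig(maf_range=(0.0, 0.5))
    with pytest.raises(ValueError):
        SimConfig(maf_range=(0.1, 0.6))
    with pytest.raises(ValueError):
        SimConfig(case_fraction=1.5)


def test_empirical_maf_matches_target_fair_coin():
    # single MAF 0.5, independent variants: symmetric fair draws
    cfg = SimConfig(
        n_samples_per_cohort={"c": 10_000}, n_variants=20, maf_range=(0.5, 0.5),
        ld_rho=0.0, n_causal_pairs=0, seed=3,
    )
    _, dos = simulate.simulate_genotypes(cfg, "c")
    freq = dos.to_numpy().mean(axis=0) / 2
    se = np.sqrt(0.5 * 0.5 / (2 * 10_000))
    # per-variant at 4 SEs (20 variants tested jointly); the mean at 3 SEs
    assert np.all(np.abs(freq - 0.5) < 4 * se)
    assert abs(freq.mean() - 0.5) < 3 * se / np.sqrt(20)


def test_hardy_weinberg_heterozygosity():
    cfg = SimConfig(
        n_samples_per_cohort={"c": 8_000}, n_variants=40, maf_range=(0.1, 0.4),
        ld_rho=0.0, n_causal_pairs=0, seed=4,
    )
    variants, dos = simulate.simulate_genotypes(cfg, "c")
    mat = dos.to_numpy()
    for j, p in enumerate(variants["maf"]):
        exp_het = 2 * p * (1 - p)
        obs_het = np.mean(mat[:, j] == 1)
        se = np.sqrt(exp_het * (1 - exp_het) / mat.shape[0])
        assert abs(obs_het - exp_het) < 3 * se + 1e-12


def test_high_ld_limit_gives_high_adjacent_correlation():
    cfg = SimConfig(
        n_samples_per_cohort={"c": 2_000}, n_variants=20, maf_range=(0.3, 0.3),
        ld_block_size=20, ld_rho=0.999, n_causal_pairs=0, seed=5,
    )
    _, dos = simulate.simulate_genotypes(cfg, "c")
    mat = dos.to_numpy()
    r = np.corrcoef(mat[:, 3], mat[:, 4])[0, 1]
    assert r >= 0.9


def test_adjacent_r2_matches_copula_oracle(rng):
    # independent large-sample oracle: 1e6 haplotype pairs from the same
    # bivariate-normal threshold model
    rho, maf = 0.5, 0.2
    t = ndtri(maf)
    z1 = rng.standard_normal(1_000_000)
    z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(1_000_000)
    h = np.stack([z1 < t, z2 < t], axis=1).astype(float)
    g = h[:500_000] + h[500_000:]
    oracle_r2 = np.corrcoef(g[:, 0], g[:, 1])[0, 1] ** 2

    cfg = SimConfig(
        n_samples_per_cohort={"c": 5_000}, n_variants=100, maf_range=(maf, maf),
        ld_block_size=10, ld_rho=rho, n_causal_pairs=0, seed=6,
    )
    _, dos = simulate.simulate_genotypes(cfg, "c")
    mat = dos.to_numpy()
    r2 = []
    for j in range(mat.shape[1] - 1):
        if (j + 1) % 10:  # adjacent pair within a block
            r2.append(np.corrcoef(mat[:, j], mat[:, j + 1])[0, 1] ** 2)
    assert abs(np.mean(r2) - oracle_r2) < 0.03


def test_variant_table_shared_across_cohorts(small_config):
    va, _ = simulate.simulate_genotypes(small_config, "cohortA")
    vb, _ = simulate.simulate_genotypes(small_config, "cohortB")
    pd.testing.assert_frame_equal(va, vb)


def test_null_expression_uncorrelated_with_dosage():
    cfg = SimConfig(
        n_samples_per_cohort={"c": 200}, n_variants=100, n_genes=50,
        n_causal_pairs=0, n_hidden_factors=0, seed=7,
    )
    genes = simulate.simulate_genes(cfg)
    variants, dos = simulate.simulate_genotypes(cfg, "c")
    truth = simulate.make_truth(cfg, variants, genes)
    expr = simulate.simulate_expression(dos, genes, truth, cfg, "c")
    lat = np.log(expr.to_numpy())
    cors = [
        np.corrcoef(lat[i], dos.iloc[:, i].to_numpy())[0, 1]
        for i in range(min(50, len(genes)))
    ]
    assert abs(np.mean(cors)) < 3 / np.sqrt(200 * len(cors)) * 3


def test_injected_beta_recovered_by_ols():
    cfg = SimConfig(
        n_samples_per_cohort={"c": 300}, n_variants=200, n_genes=20,
        n_causal_pairs=1, beta_causal=0.25, n_hidden_factors=0, noise_sd=1.0,
        low_expr_fraction=0.0, seed=8,
    )
    genes = simulate.simulate_genes(cfg)
    variants, dos = simulate.simulate_genotypes(cfg, "c")
    truth = simulate.make_truth(cfg, variants, genes)
    expr = simulate.simulate_expression(dos, genes, truth, cfg, "c")
    pair = truth.causal_pairs.iloc[0]
    from eqtlgwas.qc import inverse_normal_transform

    y = inverse_normal_transform(expr.loc[pair["gene_id"]].to_numpy())
    x = dos[pair["variant_id"]].to_numpy()
    r = fit_association(y, x)
    assert abs(r["beta"] - 0.25) < 3 * r["se"]


def test_noiseless_expression_is_affine_in_dosage():
    cfg = SimConfig(
        n_samples_per_cohort={"c": 100}, n_variants=200, n_genes=10,
        n_causal_pairs=1, beta_causal=1.0, n_hidden_factors=0, noise_sd=1e-12,
        low_expr_fraction=0.0, seed=9,
    )
    genes = simulate.simulate_genes(cfg)
    variants, dos = simulate.simulate_genotypes(cfg, "c")
    truth = simulate.make_truth(cfg, variants, genes)
    # suppress covariate terms by zeroing the scaled non-genetic part via tiny noise_sd
    expr = simulate.simulate_expression(dos, genes, truth, cfg, "c")
    pair = truth.causal_pairs.iloc[0]
    y = np.log(expr.loc[pair["gene_id"]].to_numpy())
    x = dos[pair["variant_id"]].to_numpy()
    if np.std(x) > 0:
        assert abs(np.corrcoef(y, x)[0, 1]) > 0.999999


def test_case_fraction_calibration_null_model():
    cfg = SimConfig(
        n_samples_per_cohort={"c": 4_000}, n_variants=50, n_causal_pairs=0,
        n_risk_variants=0, case_fraction=0.5, seed=10,
    )
    genes = simulate.simulate_genes(cfg)
    variants, dos = simulate.simulate_genotypes(cfg, "c")
    truth = simulate.make_truth(cfg, variants, genes)
    pheno = simulate.simulate_case_control(dos, truth, cfg, "c")
    frac = pheno["case_status"].mean()
    assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / 4_000)


def test_case_control_recovers_planted_log_or():
    # logistic MLE consistency at large n
    from eqtlgwas.gwas import logistic_assoc

    cfg = SimConfig(
        n_samples_per_cohort={"c": 20_000}, n_variants=50, maf_range=(0.2, 0.2),
        n_causal_pairs=0, n_risk_variants=1, risk_or=1.2, seed=12,
    )
    genes = simulate.simulate_genes(cfg)
    variants, dos = simulate.simulate_genotypes(cfg, "c")
    truth = simulate.make_truth(cfg, variants, genes)
    pheno = simulate.simulate_case_control(dos, truth, cfg, "c")
    vid = truth.risk_variants["variant_id"].iloc[0]
    rec = logistic_assoc(
        pheno["case_status"].to_numpy(),
        dos[vid].to_numpy(),
        pheno[["age", "sex"]].to_numpy(dtype=float),
    )
    assert abs(rec["log_or"] - np.log(1.2)) < 3 * rec["se"]


def test_unachievable_case_fraction_errors():
    with pytest.raises(ValueError, match="unachievable"):
        simulate._solve_intercept(np.full(10, 1e6), 0.5)


def test_annotation_no_enrichment_setting():
    cfg = SimConfig(
        n_samples_per_cohort={"c": 10}, n_variants=2_000, n_genes=100,
        n_causal_pairs=80, beta_causal=0.2, annotation_enrichment=1.0,
        annotation_coverage=0.3, seed=13,
    )
    genes = simulate.simulate_genes(cfg)
    variants = simulate.simulate_variants(cfg)
    truth = simulate.make_truth(cfg, variants, genes)
    rng = simulate.substream(cfg.seed, "annotations")
    causal = variants["id"].isin(truth.causal_pairs["variant_id"]).to_numpy()
    covered = rng.random(len(variants)) < 0.3  # same draw as the generator
    frac_causal = covered[causal].mean()
    frac_other = covered[~causal].mean()
    assert abs(frac_causal - frac_other) < 0.12  # equal in expectation


def test_full_coverage_track_overlaps_everything():
    from eqtlgwas.enrichment import annotate_overlap

    cfg = SimConfig(n_variants=100, annotation_coverage=1.0, annotation_enrichment=1.0, seed=14)
    genes = simulate.simulate_genes(cfg)
    variants = simulate.simulate_variants(cfg)
    truth = simulate.make_truth(cfg, variants, genes)
    bed, _ = simulate.simulate_annotations(variants, truth, cfg, half_width=10**8)
    assert annotate_overlap(variants, bed).all()


def test_fixture_round_trip_and_determinism(tmp_path, small_config):
    out1 = tmp_path / "a"
    out2 = tmp_path / "b"
    art = simulate.write_fixture_set(out1, small_config)
    simulate.write_fixture_set(out2, small_config)
    for name in ["cohortA.vcf", "genes.tsv", "annotations.bed", "categories.tsv"]:
        assert (out1 / name).read_bytes() == (out2 / name).read_bytes()
    back = simulate.read_fixture_set(out1)
    dos0 = art["cohortA"]["dosages"].to_numpy()
    dos1 = back["cohortA"]["dosages"].to_numpy()
    assert np.allclose(dos0, dos1, atol=5e-7, equal_nan=True)
    pd.testing.assert_frame_equal(
        art["variants"], back["variants"], atol=5e-5, check_dtype=False
    )


def test_empty_variant_set_yields_header_only_vcf(tmp_path):
    variants = pd.DataFrame(columns=["id", "chrom", "pos", "ref", "alt", "maf", "quality_score"])
    dosages = pd.DataFrame(index=["s1", "s2"])
    path = tmp_path / "empty.vcf"
    simulate.write_vcf_dosages(path, variants, dosages)
    v, d = simulate.read_vcf_dosages(path)
    assert len(v) == 0 and d.shape == (2, 0)
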