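import numpy as np
import pandas as pd
import pytest

from eqtlgwas import simulate


@pytest.fixture(scope="session")
def small_config():
    return simulate.SimConfig(
        n_samples_per_cohort={"cohortA": 120, "cohortB": 120},
        n_variants=300,
        n_genes=30,
        n_causal_pairs=5,
        beta_causal=0.8,
        n_hidden_factors=2,
        n_risk_variants=2,
        risk_or=1.5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    """Variants, genes, truth and per-cohort data for a small two-cohort study."""
    cfg = small_config
    genes = simulate.simulate_genes(cfg)
    variants = simulate.simulate_variants(cfg)
    truth = simulate.make_truth(cfg, variants, genes)
    data = {}
    for cohort in cfg.cohorts:
        _, dos = simulate.simulate_genotypes(cfg, cohort)
        data[cohort] = {
            "dosages": dos,
            "expression": simulate.simulate_expression(dos, genes, truth, cfg, cohort),
            "phenotypes": simulate.simulate_case_control(dos, truth, cfg, cohort),
        }
    return {"config": cfg, "genes": genes, "variants": variants, "truth": truth, "data": data}


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


def make_variant_frame(positions, chrom="chr1", maf=0.25):
    n = len(positions)
    return pd.DataFrame(
        {
            "id": [f"v{i}" for i in range(n)],
            "chrom": chrom,
            "pos": np.asarray(positions, dtype=np.int64),
            "ref": "A",
            "alt": "G",
            "maf": maf,
            "quality_score": 1.0,
        }
    )
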