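"""Synthetic multi-cohort genotype / expression / phenotype generator.

Produces the inputs the analysis stages expect — LD-blocked dosage matrices in
Hardy–Weinberg proportions, FPKM-scale expression with additive cis effects and
hidden batch factors, liability-style case-control phenotypes, and annotation
tracks enriched at causal variants — together with a ground-truth table for
recovery testing.

Genotypes come from a Gaussian copula: each haplotype is a latent AR(1) vector
(block-diagonal, lag-one correlation ``ld_rho``) thresholded at the
allele-frequency quantile, and the dosage is the sum of two independent
haplotypes.  With ``ld_rho = 0`` this reduces to independent binomial draws,
i.e. exact Hardy–Weinberg proportions.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

CIS_WINDOW = 1_000_000

__all__ = [
    "SimConfig",
    "TruthTable",
    "make_truth",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_case_control",
    "simulate_annotations",
    "write_fixture_set",
    "read_fixture_set",
    "read_vcf_dosages",
]


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic named RNG substream derived from a single master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(zlib.crc32(name.encode()),))
    )


@dataclass
class SimConfig:
    """Parameters of one simulated study (shared variants, per-cohort samples).

    ``beta_causal`` may be a scalar (same cis effect in every cohort) or a
    mapping cohort_id -> effect, in transformed-expression SD units per
    alternative allele.  ``het_fraction`` of causal pairs get an opposite-sign
    effect in the second cohort to exercise heterogeneity triage.
    """

    n_samples_per_cohort: dict[str, int] = field(
        default_factory=lambda: {"cohortA": 150, "cohortB": 150}
    )
    n_variants: int = 500
    n_genes: int = 50
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    ld_rho: float = 0.5
    n_causal_pairs: int = 10
    beta_causal: float | dict[str, float] = 0.25
    het_fraction: float = 0.0
    n_hidden_factors: int = 2
    factor_sd: float = 1.0
    noise_sd: float = 1.0
    n_risk_variants: int = 0
    risk_or: float = 1.2
    risk_overlap_causal: float = 0.0  # fraction of risk variants drawn from causal eQTL variants
    case_fraction: float = 0.5
    chrom_length: int = 10_000_000
    missing_rate: float = 0.0
    low_expr_fraction: float = 0.1
    annotation_coverage: float = 0.1
    annotation_enrichment: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError(f"ld_rho must be in [0, 1), got {self.ld_rho}")
        for name in ("n_variants", "n_genes", "ld_block_size", "chrom_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_causal_pairs", "n_hidden_factors", "n_risk_variants"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 < self.case_fraction < 1.0):
            raise ValueError("case_fraction must be in (0, 1)")
        if self.risk_or <= 0:
            raise ValueError("risk_or must be > 0")
        if any(n <= 0 for n in self.n_samples_per_cohort.values()):
            raise ValueError("sample sizes must be positive")

    @property
    def cohorts(self) -> list[str]:
        return list(self.n_samples_per_cohort)

    def beta_for(self, cohort_id: str) -> float:
        if isinstance(self.beta_causal, dict):
            return float(self.beta_causal[cohort_id])
        return float(self.beta_causal)


@dataclass
class TruthTable:
    """Simulator ground truth used by recovery tests.

    ``causal_pairs`` has one ``beta_<cohort>`` column per cohort;
    ``risk_variants`` carries per-allele log odds ratios;
    ``hidden_factor_loadings`` is genes x factors.
    """

    causal_pairs: pd.DataFrame
    risk_variants: pd.DataFrame
    hidden_factor_loadings: pd.DataFrame


# ---------------------------------------------------------------------------
# variant metadata and gene models (cohort-independent)
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def simulate_variants(config: SimConfig) -> pd.DataFrame:
    """Variant metadata shared by all cohorts of one configuration."""
    rng = substream(config.seed, "variants")
    m = config.n_variants
    pos = np.sort(rng.choice(config.chrom_length, size=m, replace=False)) + 1
    lo, hi = config.maf_range
    maf = lo + (hi - lo) * rng.random(m) if hi > lo else np.full(m, lo)
    ref_idx = rng.integers(0, 4, size=m)
    alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
    return pd.DataFrame(
        {
            "id": [f"var{i + 1}" for i in range(m)],
            "chrom": "chr1",
            "pos": pos.astype(np.int64),
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
            "maf": maf,
            "quality_score": 0.5 + 0.5 * rng.random(m),
        }
    )


def simulate_genes(config: SimConfig) -> pd.DataFrame:
    """Gene models with strand-aware TSS (start for +, end for -)."""
    rng = substream(config.seed, "genes")
    g = config.n_genes
    length = rng.integers(5_000, 100_000, size=g)
    start = rng.integers(1, max(2, config.chrom_length - int(length.max())), size=g)
    strand = np.where(rng.random(g) < 0.5, "+", "-")
    end = start + length
    tss = np.where(strand == "+", start, end)
    df = pd.DataFrame(
        {
            "gene_id": [f"gene{i + 1}" for i in range(g)],
            "chrom": "chr1",
            "strand": strand,
            "start": start.astype(np.int64),
            "end": end.astype(np.int64),
            "tss": tss.astype(np.int64),
        }
    )
    return df


def make_truth(config: SimConfig, variants: pd.DataFrame, genes: pd.DataFrame) -> TruthTable:
    """Draw causal SNP-gene pairs (inside the cis window), risk variants, loadings."""
    rng = substream(config.seed, "truth")
    cohorts = config.cohorts

    rows = []
    if config.n_causal_pairs > 0:
        gene_order = rng.permutation(len(genes))
        pos = variants["pos"].to_numpy()
        for gi in gene_order:
            if len(rows) >= config.n_causal_pairs:
                break
            tss = int(genes["tss"].iloc[gi])
            in_cis = np.flatnonzero(np.abs(pos - tss) <= CIS_WINDOW)
            if in_cis.size == 0:
                continue
            vi = int(rng.choice(in_cis))
            row = {
                "variant_id": variants["id"].iloc[vi],
                "gene_id": genes["gene_id"].iloc[gi],
            }
            flip = rng.random() < config.het_fraction
            for j, c in enumerate(cohorts):
                b = config.beta_for(c)
                if flip and j > 0:
                    b = -b
                row[f"beta_{c}"] = b
            rows.append(row)
        if len(rows) < config.n_causal_pairs:
            raise ValueError(
                f"could only place {len(rows)} of {config.n_causal_pairs} causal pairs "
                "inside cis windows; increase n_genes or n_variants"
            )
    causal = pd.DataFrame(rows, columns=["variant_id", "gene_id"] + [f"beta_{c}" for c in cohorts])

    if config.n_risk_variants > 0:
        n_shared = min(
            int(round(config.risk_overlap_causal * config.n_risk_variants)), len(causal)
        )
        shared = (
            rng.choice(causal["variant_id"].to_numpy(), size=n_shared, replace=False)
            if n_shared
            else np.array([], dtype=object)
        )
        rest_pool = variants.loc[~variants["id"].isin(shared), "id"].to_numpy()
        rest = rng.choice(rest_pool, size=config.n_risk_variants - n_shared, replace=False)
        vids = np.concatenate([shared, rest])
        risk = pd.DataFrame({"variant_id": vids, "log_or": np.log(config.risk_or)})
    else:
        risk = pd.DataFrame(columns=["variant_id", "log_or"])

    loadings = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(config.n_genes, config.n_hidden_factors)),
        index=[f"gene{i + 1}" for i in range(config.n_genes)],
        columns=[f"factor{j + 1}" for j in range(config.n_hidden_factors)],
    )
    return TruthTable(causal_pairs=causal, risk_variants=risk, hidden_factor_loadings=loadings)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _ar1_latent(rng: np.random.Generator, n: int, m: int, block: int, rho: float) -> np.ndarray:
    """n x m latent Gaussians, block-diagonal lag-one correlation rho."""
    z = rng.standard_normal((n, m))
    if rho > 0:
        c = np.sqrt(1.0 - rho * rho)
        for j in range(1, m):
            if j % block:  # same block as j-1
                z[:, j] = rho * z[:, j - 1] + c * z[:, j]
    return z


def simulate_genotypes(config: SimConfig, cohort_id: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dosages for one cohort on the shared variant panel.

    Returns ``(variants, dosages)`` where dosages is a samples x variants
    DataFrame in [0, 2] (NaN where missing).  The variant table depends only on
    the configuration, so every cohort sees identical variants; the haplotype
    draws use a cohort-specific substream.
    """
    if cohort_id not in config.n_samples_per_cohort:
        raise KeyError(f"unknown cohort {cohort_id!r}")
    variants = simulate_variants(config)
    n = config.n_samples_per_cohort[cohort_id]
    m = config.n_variants
    rng = substream(config.seed, f"haplotypes:{cohort_id}")
    thresh = ndtri(variants["maf"].to_numpy())  # latent < thresh -> minor allele
    h1 = _ar1_latent(rng, n, m, config.ld_block_size, config.ld_rho) < thresh
    h2 = _ar1_latent(rng, n, m, config.ld_block_size, config.ld_rho) < thresh
    dose = (h1.astype(np.float64) + h2) if m else np.zeros((n, 0))
    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        dose = np.where(mask, np.nan, dose)
    dosages = pd.DataFrame(
        dose,
        index=[f"{cohort_id}_s{i + 1}" for i in range(n)],
        columns=variants["id"].to_numpy(),
    )
    return variants, dosages


# ---------------------------------------------------------------------------
# covariates / expression / phenotypes
# ---------------------------------------------------------------------------

# fixed covariate effects on the liability and expression scales
_AGE_BETA = 0.3
_SEX_BETA = 0.2


def simulate_known_covariates(config: SimConfig, cohort_id: str) -> pd.DataFrame:
    """Age (standardized) and sex per sample; shared by the expression and
    case-control generators via the substream name."""
    n = config.n_samples_per_cohort[cohort_id]
    rng = substream(config.seed, f"covariates:{cohort_id}")
    return pd.DataFrame(
        {
            "age": rng.standard_normal(n),
            "sex": rng.integers(0, 2, size=n).astype(float),
        },
        index=[f"{cohort_id}_s{i + 1}" for i in range(n)],
    )


def simulate_expression(
    dosages: pd.DataFrame,
    genes: pd.DataFrame,
    truth: TruthTable,
    config: SimConfig,
    cohort_id: str | None = None,
) -> pd.DataFrame:
    """Genes x samples FPKM-like expression with additive cis effects.

    Latent value per gene/sample = baseline + beta * dosage + hidden-factor
    term + known-covariate term + Gaussian noise.  The non-genetic part
    (covariates + factors + noise) is scaled per gene to total standard
    deviation ``noise_sd``, so ``beta`` is an effect per allele in units of
    the gene's non-genetic expression SD — the scale on which the rank-based
    inverse-normal transform downstream preserves it.  Values are emitted
    positive through a per-gene exponential scale, with ``low_expr_fraction``
    of genes pushed below the 0.1 FPKM floor so the expression filter has
    something to remove.
    """
    if cohort_id is None:
        cohort_id = str(dosages.index[0]).rsplit("_s", 1)[0]
    beta_col = f"beta_{cohort_id}"
    for _, pair in truth.causal_pairs.iterrows():
        if pair["variant_id"] not in dosages.columns:
            raise KeyError(f"causal variant {pair['variant_id']} absent from dosages")
        if pair["gene_id"] not in set(genes["gene_id"]):
            raise KeyError(f"causal gene {pair['gene_id']} absent from gene models")

    n = len(dosages)
    g = len(genes)
    rng = substream(config.seed, f"expression:{cohort_id}")
    covs = simulate_known_covariates(config, cohort_id)

    nongenetic = rng.normal(0.0, config.noise_sd, size=(g, n))
    var_ng = np.full(g, config.noise_sd**2)
    nongenetic += np.outer(np.full(g, 1.0), _AGE_BETA * covs["age"].to_numpy())
    nongenetic += np.outer(np.full(g, 1.0), _SEX_BETA * covs["sex"].to_numpy())
    var_ng += _AGE_BETA**2 + _SEX_BETA**2 * 0.25
    if config.n_hidden_factors > 0:
        factors = rng.standard_normal((config.n_hidden_factors, n)) * config.factor_sd
        loadings = truth.hidden_factor_loadings.to_numpy()[:g]
        nongenetic += loadings @ factors
        var_ng += (loadings**2).sum(axis=1) * config.factor_sd**2
    # rescale so the non-genetic sample variance is noise_sd**2 for every gene:
    # beta then survives the rank-based transform without attenuation
    nongenetic *= (config.noise_sd / np.sqrt(var_ng))[:, None]
    latent = nongenetic + rng.normal(0.0, 1.0, size=(g, 1))  # per-gene baseline

    gene_index = {gid: i for i, gid in enumerate(genes["gene_id"])}
    for _, pair in truth.causal_pairs.iterrows():
        gi = gene_index[pair["gene_id"]]
        x = dosages[pair["variant_id"]].to_numpy(dtype=float)
        x = np.nan_to_num(x, nan=float(np.nanmean(x)))
        latent[gi] += float(pair[beta_col]) * x

    # positive FPKM-like scale; monotone per gene, so rank-based downstream
    # normalization recovers the latent ordering exactly
    scale = np.exp(rng.normal(1.0, 1.0, size=g))
    n_low = int(round(config.low_expr_fraction * g))
    if n_low:
        low_idx = rng.choice(g, size=n_low, replace=False)
        scale[low_idx] = 1e-4
    fpkm = scale[:, None] * np.exp(0.5 * latent)
    return pd.DataFrame(fpkm, index=genes["gene_id"].to_numpy(), columns=dosages.index)


def _solve_intercept(eta: np.ndarray, target: float, tol: float = 1e-6) -> float:
    """Bisection on alpha so that mean(expit(alpha + eta)) == target."""
    lo, hi = -40.0, 40.0
    f = lambda a: float(np.mean(expit(a + eta))) - target
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(f"case_fraction {target} unachievable for the given effects")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_case_control(
    dosages: pd.DataFrame,
    truth: TruthTable,
    config: SimConfig,
    cohort_id: str | None = None,
) -> pd.DataFrame:
    """Case-control phenotypes under an additive log-odds model.

    The intercept is calibrated by bisection (tolerance 1e-6 on the
    sample-average probability) so the expected case fraction matches
    ``config.case_fraction``; statuses are then independent Bernoulli draws.
    """
    if cohort_id is None:
        cohort_id = str(dosages.index[0]).rsplit("_s", 1)[0]
    missing = set(truth.risk_variants["variant_id"]) - set(dosages.columns)
    if missing:
        raise KeyError(f"risk variants absent from dosages: {sorted(missing)}")

    covs = simulate_known_covariates(config, cohort_id)
    eta = _AGE_BETA * covs["age"].to_numpy() + _SEX_BETA * covs["sex"].to_numpy()
    for _, rv in truth.risk_variants.iterrows():
        x = dosages[rv["variant_id"]].to_numpy(dtype=float)
        x = np.nan_to_num(x, nan=float(np.nanmean(x)))
        eta = eta + float(rv["log_or"]) * x
    alpha = _solve_intercept(eta, config.case_fraction)
    prob = expit(alpha + eta)
    rng = substream(config.seed, f"phenotype:{cohort_id}")
    status = (rng.random(len(prob)) < prob).astype(int)
    # guarantee both classes, flipping the most marginal sample if needed
    if status.min() == status.max():
        j = int(np.argmin(prob)) if status[0] == 1 else int(np.argmax(prob))
        status[j] = 1 - status[j]
    return pd.DataFrame(
        {
            "case_status": status,
            "age": covs["age"].to_numpy(),
            "sex": covs["sex"].to_numpy().astype(int),
            "cohort_id": cohort_id,
        },
        index=dosages.index,
    )


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

_CATEGORIES = np.array(["intronic", "utr", "intergenic"])


def simulate_annotations(
    variants: pd.DataFrame,
    truth: TruthTable,
    config: SimConfig,
    half_width: int = 50,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Interval track plus per-variant functional-category labels.

    Causal variants fall inside the track with probability
    ``min(1, enrichment * coverage)`` versus ``coverage`` for the rest, and are
    preferentially labelled non-intergenic.  Returns a BED-style DataFrame
    (chrom, start, end; 0-based half-open) and a (variant_id, category) table.
    """
    rng = substream(config.seed, "annotations")
    causal = variants["id"].isin(truth.causal_pairs["variant_id"]).to_numpy()
    p0 = config.annotation_coverage
    p1 = min(1.0, config.annotation_enrichment * p0)
    covered = rng.random(len(variants)) < np.where(causal, p1, p0)

    pos = variants["pos"].to_numpy()
    starts = np.maximum(pos[covered] - 1 - half_width, 0)
    ends = pos[covered] - 1 + half_width + 1
    bed = pd.DataFrame({"chrom": "chr1", "start": starts, "end": ends}).sort_values(
        ["start", "end"], ignore_index=True
    )
    # merge overlapping windows
    merged: list[list] = []
    for _, row in bed.iterrows():
        if merged and row["start"] <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], row["end"])
        else:
            merged.append(["chr1", int(row["start"]), int(row["end"])])
    bed = pd.DataFrame(merged, columns=["chrom", "start", "end"])

    p_cat_causal = np.array([0.55, 0.35, 0.10])
    p_cat_null = np.array([0.25, 0.15, 0.60])
    cats = np.where(
        causal,
        rng.choice(_CATEGORIES, size=len(variants), p=p_cat_causal),
        rng.choice(_CATEGORIES, size=len(variants), p=p_cat_null),
    )
    labels = pd.DataFrame({"variant_id": variants["id"], "category": cats})
    return bed, labels


# ---------------------------------------------------------------------------
# fixture I/O (VCF 4.2 with DS, TSV tables, BED)
# ---------------------------------------------------------------------------

def write_vcf_dosages(path, variants: pd.DataFrame, dosages: pd.DataFrame) -> None:
    """VCF 4.2 with dosages in a per-sample DS FORMAT field ('.' if missing)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write("##contig=<ID=chr1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(dosages.index) + "\n")
        mat = dosages.to_numpy().T  # variants x samples
        for i in range(len(variants)):
            v = variants.iloc[i]
            vals = "\t".join(
                "." if np.isnan(d) else f"{d:.6f}" for d in mat[i]
            )
            fh.write(
                f"{v['chrom']}\t{v['pos']}\t{v['id']}\t{v['ref']}\t{v['alt']}"
                f"\t.\t.\tMAF={v['maf']:.6f};INFO={v['quality_score']:.4f}\tDS\t{vals}\n"
            )


def read_vcf_dosages(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inverse of :func:`write_vcf_dosages`."""
    rows, doses, samples = [], [], None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            f = line.split("\t")
            info = dict(kv.split("=", 1) for kv in f[7].split(";") if "=" in kv)
            rows.append(
                {
                    "id": f[2],
                    "chrom": f[0],
                    "pos": int(f[1]),
                    "ref": f[3],
                    "alt": f[4],
                    "maf": float(info.get("MAF", "nan")),
                    "quality_score": float(info.get("INFO", "nan")),
                }
            )
            doses.append([np.nan if x == "." else float(x) for x in f[9:]])
    variants = pd.DataFrame(
        rows, columns=["id", "chrom", "pos", "ref", "alt", "maf", "quality_score"]
    )
    if samples is None:
        raise ValueError(f"{path}: missing #CHROM header line")
    dmat = np.array(doses, dtype=float).reshape(len(variants), len(samples))
    dosages = pd.DataFrame(dmat.T, index=samples, columns=variants["id"].to_numpy())
    return variants, dosages


def write_fixture_set(outdir, config: SimConfig) -> dict[str, object]:
    """Generate and write the full fixture bundle for every cohort.

    Emits per-cohort VCF / expression / phenotype / covariate TSVs, shared
    gene-model, annotation (BED + categories) and truth tables, and a manifest
    echoing the seed and parameters.  Deterministic byte-for-byte given the
    configuration.  Returns the in-memory artifacts.
    """
    import os

    import yaml

    os.makedirs(outdir, exist_ok=True)
    genes = simulate_genes(config)
    variants = simulate_variants(config)
    truth = make_truth(config, variants, genes)
    artifacts: dict[str, object] = {"variants": variants, "genes": genes, "truth": truth}

    genes.to_csv(os.path.join(outdir, "genes.tsv"), sep="\t", index=False)
    for cohort in config.cohorts:
        _, dos = simulate_genotypes(config, cohort)
        expr = simulate_expression(dos, genes, truth, config, cohort)
        pheno = simulate_case_control(dos, truth, config, cohort)
        covs = simulate_known_covariates(config, cohort)
        write_vcf_dosages(os.path.join(outdir, f"{cohort}.vcf"), variants, dos)
        expr.round(6).to_csv(os.path.join(outdir, f"{cohort}.expression.tsv"), sep="\t")
        pheno.to_csv(
            os.path.join(outdir, f"{cohort}.phenotypes.tsv"),
            sep="\t",
            index_label="sample_id",
            float_format="%.6f",
        )
        covs.to_csv(
            os.path.join(outdir, f"{cohort}.covariates.tsv"),
            sep="\t",
            index_label="sample_id",
            float_format="%.6f",
        )
        artifacts[cohort] = {"dosages": dos, "expression": expr, "phenotypes": pheno}

    bed, labels = simulate_annotations(variants, truth, config)
    bed.to_csv(os.path.join(outdir, "annotations.bed"), sep="\t", index=False, header=False)
    labels.to_csv(os.path.join(outdir, "categories.tsv"), sep="\t", index=False)
    truth.causal_pairs.to_csv(os.path.join(outdir, "truth_causal_pairs.tsv"), sep="\t", index=False)
    truth.risk_variants.to_csv(
        os.path.join(outdir, "truth_risk_variants.tsv"), sep="\t", index=False
    )
    artifacts["bed"], artifacts["categories"] = bed, labels

    manifest = {"seed": config.seed, "config": {
        k: (v if not isinstance(v, tuple) else list(v)) for k, v in vars(config).items()
    }}
    with open(os.path.join(outdir, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return artifacts


def read_fixture_set(outdir) -> dict[str, object]:
    """Read back a bundle written by :func:`write_fixture_set`."""
    import os

    import yaml

    with open(os.path.join(outdir, "manifest.yaml")) as fh:
        manifest = yaml.safe_load(fh)
    cfg = manifest["config"]
    cohorts = list(cfg["n_samples_per_cohort"])
    out: dict[str, object] = {
        "genes": pd.read_csv(os.path.join(outdir, "genes.tsv"), sep="\t"),
        "manifest": manifest,
    }
    for cohort in cohorts:
        variants, dos = read_vcf_dosages(os.path.join(outdir, f"{cohort}.vcf"))
        out["variants"] = variants
        out[cohort] = {
            "dosages": dos,
            "expression": pd.read_csv(
                os.path.join(outdir, f"{cohort}.expression.tsv"), sep="\t", index_col=0
            ),
            "phenotypes": pd.read_csv(
                os.path.join(outdir, f"{cohort}.phenotypes.tsv"), sep="\t", index_col=0
            ),
        }
    out["bed"] = pd.read_csv(
        os.path.join(outdir, "annotations.bed"),
        sep="\t",
        names=["chrom", "start", "end"],
    )
    out["categories"] = pd.read_csv(os.path.join(outdir, "categories.tsv"), sep="\t")
    return out
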