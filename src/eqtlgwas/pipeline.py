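"""GWAS–eQTL intersection, report bundle, and the end-to-end pipeline.

The integration step retains variant–gene pairs with suggestive GWAS meta
significance (P_meta < 1e-5), nominal association in every cohort (p < 0.05,
concordant direction by default) and eQTL significance (FDR < 0.05), then
annotates each candidate with its locus and the sign relation between the
GWAS effect allele and the expression effect.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import enrichment as enr
from . import eqtl, gwas, meta, qc, simulate

log = logging.getLogger(__name__)

__all__ = ["IntegrationThresholds", "RunConfig", "integrate", "report", "run_pipeline"]


@dataclass(frozen=True)
class IntegrationThresholds:
    p_meta_max: float = 1e-5
    p_cohort_max: float = 0.05
    eqtl_fdr_max: float = 0.05
    require_concordance: bool = True
    locus_gap: int = 500_000


@dataclass
class RunConfig:
    """Pipeline configuration: either a simulation block or input paths."""

    outdir: str = "results"
    seed: int = 0
    sim: dict = field(default_factory=dict)
    thresholds: IntegrationThresholds = field(default_factory=IntegrationThresholds)
    qc_thresholds: qc.QcThresholds = field(default_factory=qc.QcThresholds)
    cis_window: int = eqtl.DEFAULT_CIS_WINDOW
    n_ancestry_pcs: int = 3
    n_hidden_factors: int = 5
    input_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        if not os.path.exists(path):
            raise FileNotFoundError(f"config file not found: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thr = IntegrationThresholds(**raw.pop("thresholds", {}))
        qthr = qc.QcThresholds(**raw.pop("qc_thresholds", {}))
        return cls(thresholds=thr, qc_thresholds=qthr, **raw)


def _direction_note(gwas_log_or: float, eqtl_beta: float) -> str:
    risk = "risk" if gwas_log_or > 0 else "protective"
    expr = "increases" if eqtl_beta > 0 else "decreases"
    return f"{risk}_allele_{expr}_expression"


def integrate(
    gwas_meta: pd.DataFrame,
    gwas_cohorts: list[pd.DataFrame],
    eqtl_meta_fdr: pd.DataFrame,
    thresholds: IntegrationThresholds = IntegrationThresholds(),
    variants: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Candidate variant–gene pairs supported by both data types.

    Joins on variant id; a GWAS variant with no tested cis pair is dropped.
    Returns one row per surviving pair; summary counts are logged.
    """
    sugg = gwas.select_suggestive(
        gwas_meta,
        gwas_cohorts,
        p_meta_max=thresholds.p_meta_max,
        p_cohort_max=thresholds.p_cohort_max,
        require_concordance=thresholds.require_concordance,
    )
    sig_eqtl = eqtl_meta_fdr[eqtl_meta_fdr["fdr"] < thresholds.eqtl_fdr_max]
    gwas_side = pd.DataFrame(
        {
            "variant_id": sugg["variant_id"],
            "p_meta_gwas": sugg["p"],
            "gwas_beta_meta": sugg["beta_meta"],
            "p_cohort_1": sugg.get("p_cohort_1", np.nan),
            "p_cohort_2": sugg.get("p_cohort_2", np.nan),
        }
    )
    eqtl_side = pd.DataFrame(
        {
            "variant_id": sig_eqtl["variant_id"],
            "gene_id": sig_eqtl["gene_id"],
            "eqtl_fdr": sig_eqtl["fdr"],
            "eqtl_beta_meta": sig_eqtl["beta_meta"],
            "eqtl_i2": sig_eqtl["i2"],
            "het_flag": sig_eqtl["het_flag"],
        }
    )
    joined = gwas_side.merge(eqtl_side, on="variant_id", how="inner")
    if joined.empty:
        log.warning("integration produced no candidates")
        return pd.DataFrame(
            columns=[
                "variant_id", "gene_id", "p_meta_gwas", "p_cohort_1", "p_cohort_2",
                "eqtl_fdr", "eqtl_beta_meta", "eqtl_i2", "het_flag", "locus_id",
                "direction_note",
            ]
        )
    if variants is not None:
        loc = gwas.define_loci(
            sugg.merge(variants[["id", "chrom", "pos"]], left_on="variant_id", right_on="id"),
            gap=thresholds.locus_gap,
        ).set_index("variant_id")["locus_id"]
        joined["locus_id"] = joined["variant_id"].map(loc)
    else:
        joined["locus_id"] = ""
    records = pd.DataFrame(
        {
            "variant_id": joined["variant_id"],
            "gene_id": joined["gene_id"],
            "p_meta_gwas": joined["p_meta_gwas"],
            "p_cohort_1": joined["p_cohort_1"],
            "p_cohort_2": joined["p_cohort_2"],
            "eqtl_fdr": joined["eqtl_fdr"],
            "eqtl_beta_meta": joined["eqtl_beta_meta"],
            "eqtl_i2": joined["eqtl_i2"],
            "het_flag": joined["het_flag"],
            "locus_id": joined["locus_id"],
            "direction_note": [
                _direction_note(b, e)
                for b, e in zip(joined["gwas_beta_meta"], joined["eqtl_beta_meta"])
            ],
        }
    )
    log.info(
        "integrate: %d candidate pairs, %d variants, %d genes, %d loci",
        len(records),
        records["variant_id"].nunique(),
        records["gene_id"].nunique(),
        records["locus_id"].nunique(),
    )
    return records.reset_index(drop=True)


def report(
    outdir: str,
    gwas_meta: pd.DataFrame | None = None,
    eqtl_leads: pd.DataFrame | None = None,
    variants: pd.DataFrame | None = None,
    manifest: dict | None = None,
) -> dict:
    """Report bundle: Manhattan / QQ tables, lead-eQTL TSS-distance histogram,
    and a run manifest.  Purely tabular; plotting is left to the caller."""
    os.makedirs(outdir, exist_ok=True)
    out: dict = {}
    if gwas_meta is not None and variants is not None:
        man = gwas_meta.merge(
            variants[["id", "chrom", "pos"]], left_on="variant_id", right_on="id"
        )[["chrom", "pos", "p"]].sort_values(["chrom", "pos"])
        man.to_csv(os.path.join(outdir, "manhattan.tsv"), sep="\t", index=False)
        p = np.sort(gwas_meta["p"].to_numpy())
        p = p[np.isfinite(p) & (p > 0)]
        qq = pd.DataFrame(
            {
                "expected_neglog10p": -np.log10((np.arange(len(p)) + 0.5) / len(p)),
                "observed_neglog10p": -np.log10(p),
            }
        )
        lam = gwas.genomic_lambda(p)
        qq.to_csv(os.path.join(outdir, "qq.tsv"), sep="\t", index=False)
        out["lambda"] = lam
        out["manhattan"], out["qq"] = man, qq
    if eqtl_leads is not None:
        edges = [0, 1e3, 1e4, 1e5, 1e6, np.inf]
        d = np.abs(eqtl_leads["tss_distance"].to_numpy(dtype=float))
        counts, _ = np.histogram(d, bins=edges)
        hist = pd.DataFrame(
            {
                "distance_bin": ["0-1kb", "1-10kb", "10-100kb", "100kb-1Mb", ">1Mb"],
                "n_lead_eqtls": counts,
            }
        )
        hist.to_csv(os.path.join(outdir, "tss_distance_hist.tsv"), sep="\t", index=False)
        out["tss_hist"] = hist
    manifest = dict(manifest or {})
    if "lambda" in out:
        manifest["lambda"] = out["lambda"]
    with open(os.path.join(outdir, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    out["manifest"] = manifest
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Simulate (or load) cohorts, run QC, eQTL and GWAS stages, meta-analyze,
    test enrichment, intersect and report.  Returns the stage artifacts."""
    os.makedirs(config.outdir, exist_ok=True)
    counts: dict = {"seed": config.seed}

    if config.input_dir is not None:
        bundle = simulate.read_fixture_set(config.input_dir)
        genes = bundle["genes"]
        variants = bundle["variants"]
        cohorts = [k for k in bundle if isinstance(bundle.get(k), dict) and "dosages" in bundle[k]]
        data = {c: bundle[c] for c in cohorts}
        bed, labels = bundle["bed"], bundle["categories"]
        truth = None
    else:
        sim_cfg = simulate.SimConfig(seed=config.seed, **config.sim)
        genes = simulate.simulate_genes(sim_cfg)
        variants = simulate.simulate_variants(sim_cfg)
        truth = simulate.make_truth(sim_cfg, variants, genes)
        data = {}
        for cohort in sim_cfg.cohorts:
            _, dos = simulate.simulate_genotypes(sim_cfg, cohort)
            data[cohort] = {
                "dosages": dos,
                "expression": simulate.simulate_expression(dos, genes, truth, sim_cfg, cohort),
                "phenotypes": simulate.simulate_case_control(dos, truth, sim_cfg, cohort),
            }
        bed, labels = simulate.simulate_annotations(variants, truth, sim_cfg)

    eqtl_tabs, gwas_tabs = [], []
    for cohort, d in data.items():
        dos_qc, var_qc, qc_report = qc.variant_qc(d["dosages"], variants, config.qc_thresholds)
        qc_report.to_csv(
            os.path.join(config.outdir, f"{cohort}.variant_qc.tsv"), sep="\t", index=False
        )
        expr = qc.filter_genes_by_expression(
            d["expression"], config.qc_thresholds.fpkm_mean_min
        )
        expr_t = qc.transform_expression(expr)
        pcs = qc.ancestry_pcs(dos_qc, k=min(config.n_ancestry_pcs, min(dos_qc.shape) - 1))
        known = d["phenotypes"][["age", "sex"]].astype(float)
        kf = min(config.n_hidden_factors, min(expr_t.shape) - 1)
        factors = qc.hidden_factors(expr_t, known, k=max(kf, 0))
        covs = pd.concat([known, pcs, factors], axis=1)

        pairs = eqtl.cis_pairs(var_qc, genes, window=config.cis_window)
        assoc = eqtl.map_cohort(expr_t, dos_qc, covs, pairs)
        assoc.to_csv(os.path.join(config.outdir, f"{cohort}.eqtl.tsv"), sep="\t", index=False)
        eqtl_tabs.append(assoc)

        gtab = gwas.gwas_scan(d["phenotypes"], dos_qc, var_qc, pcs=pcs)
        gtab = gtab[gtab["converged"]]
        gtab.to_csv(os.path.join(config.outdir, f"{cohort}.gwas.tsv"), sep="\t", index=False)
        gwas_tabs.append(gtab)
        counts[f"{cohort}_variants_post_qc"] = int(var_qc.shape[0])

    eqtl_meta = meta.meta_analyze_table(eqtl_tabs, keys=["variant_id", "gene_id"])
    eqtl_meta["fdr"] = eqtl.bh_adjust(eqtl_meta["p"].to_numpy())
    pair_info = pd.concat(eqtl_tabs)[["variant_id", "gene_id", "tss_distance"]].drop_duplicates()
    eqtl_meta = eqtl_meta.merge(pair_info, on=["variant_id", "gene_id"], how="left")
    eqtl_meta.to_csv(os.path.join(config.outdir, "eqtl_meta.tsv"), sep="\t", index=False)
    counts["eqtl_pairs_tested"] = int(len(eqtl_meta))
    counts["eqtl_pairs_fdr05"] = int((eqtl_meta["fdr"] < 0.05).sum())
    counts["egenes"] = int(eqtl_meta.loc[eqtl_meta["fdr"] < 0.05, "gene_id"].nunique())

    # enrichment of lead eQTLs vs matched non-eQTLs
    maf_map = variants.set_index("id")["maf"]
    eqtl_meta["maf"] = eqtl_meta["variant_id"].map(maf_map)
    sig = eqtl_meta[eqtl_meta["fdr"] < 0.05]
    enrich_records = None
    leads = None
    if not sig.empty:
        leads = enr.lead_variants(sig)
        pool = eqtl_meta[eqtl_meta["fdr"] >= 0.05]
        if len(pool) >= len(leads):
            controls = enr.sample_matched_controls(
                leads, pool, enr.MatchSpec(seed=config.seed)
            )
            vind = variants.set_index("id")
            lead_v = vind.loc[leads["variant_id"]].reset_index()
            ctrl_v = vind.loc[controls["variant_id"]].reset_index()
            rec = enr.fisher_enrichment(
                enr.annotate_overlap(lead_v, bed),
                enr.annotate_overlap(ctrl_v, bed),
                category="interval_track",
            )
            recs = [rec]
            cat_map = labels.set_index("variant_id")["category"]
            for cat in sorted(labels["category"].unique()):
                recs.append(
                    enr.fisher_enrichment(
                        (cat_map.loc[leads["variant_id"]] == cat).to_numpy(),
                        (cat_map.loc[controls["variant_id"]] == cat).to_numpy(),
                        category=cat,
                    )
                )
            enrich_records = enr.adjust_categories(
                pd.DataFrame(recs), family="functional_categories"
            )
            enrich_records.to_csv(
                os.path.join(config.outdir, "enrichment.tsv"), sep="\t", index=False
            )

    gwas_meta_tab = meta.meta_analyze_table(gwas_tabs, keys=["variant_id"])
    gwas_meta_tab.to_csv(os.path.join(config.outdir, "gwas_meta.tsv"), sep="\t", index=False)
    counts["gwas_lambda"] = gwas.genomic_lambda(
        gwas_meta_tab.loc[gwas_meta_tab["p"] > 0, "p"].to_numpy()
    )

    candidates = integrate(
        gwas_meta_tab, gwas_tabs, eqtl_meta, config.thresholds, variants=variants
    )
    candidates.to_csv(os.path.join(config.outdir, "candidates.tsv"), sep="\t", index=False)
    counts["candidate_pairs"] = int(len(candidates))
    counts["candidate_variants"] = int(candidates["variant_id"].nunique())
    counts["candidate_genes"] = int(candidates["gene_id"].nunique())

    bundle_out = report(
        config.outdir,
        gwas_meta=gwas_meta_tab,
        eqtl_leads=leads,
        variants=variants,
        manifest=counts,
    )
    return {
        "genes": genes,
        "variants": variants,
        "truth": truth,
        "eqtl_cohorts": eqtl_tabs,
        "eqtl_meta": eqtl_meta,
        "gwas_cohorts": gwas_tabs,
        "gwas_meta": gwas_meta_tab,
        "enrichment": enrich_records,
        "candidates": candidates,
        "report": bundle_out,
        "counts": counts,
    }
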