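"""End-to-end orchestration of the analysis stages.

Order of execution: genotype QC -> methylation preprocessing (detection
filter, probe exclusions, batch centering, cell-type PCs) -> EWAS ->
targeted-panel fine-mapping -> expression preprocessing and eQTM ->
co-expression modules and eigengene correlation -> signature overlap and
enrichment.  Each stage writes TSV outputs; the run is summarised in a
machine-readable manifest (config, seeds, thresholds, output hashes)
and a short human-readable report.

Inputs come either from files or from the built-in synthetic cohort;
thresholds default to the conventional values (epigenome-wide p < 9e-8,
FDR 0.05, detection p 0.01 in >= 25% of samples, counts >= 10 in >= 90%
of samples, B = 1000 permutations).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import coexpression as coex
from . import enrichment as enr
from . import expression as expr
from . import genotype as geno
from . import methylation as meth
from .ewas import (
    GENOMEWIDE_P,
    PRIMARY_COVARIATES,
    SENSITIVITY_COVARIATES,
    CovariateSet,
    run_ewas,
)
from .region import direction_consistency, run_region_models
from .synthetic import FOCAL_CPG, FOCAL_GENE, FOCAL_SNP, SimConfig, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "build_covariates", "run_all"]


@dataclass
class PipelineConfig:
    """Everything a run needs: inputs (or synthetic mode) and thresholds."""

    synthetic: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    input_dir: str | None = None  # bundle directory for non-synthetic mode
    covariate_preset: str = "primary"  # or "sensitivity"
    genomewide_p: float = GENOMEWIDE_P
    fdr: float = 0.05
    detp_thresh: float = 0.01
    detp_frac: float = 0.25
    min_count: int = 10
    min_count_frac: float = 0.90
    callrate_min: float = 0.98
    maf_min: float = 0.01
    hwe_p_min: float = 1e-6
    ld_window: int = 200
    ld_step: int = 100
    ld_r2: float = 0.2
    mds_k: int = 4
    celltype_var_target: float = 0.70
    module_min_size: int = 30
    cut_height: float = 0.99
    overlap_B: int = 1000
    seed: int = 0

    def to_yaml(self, path: str) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        sim = d.pop("sim", None)
        cfg = cls(**d)
        if sim is not None:
            if isinstance(sim.get("module_sizes"), list):
                sim["module_sizes"] = tuple(sim["module_sizes"])
            cfg.sim = SimConfig(**sim)
        return cfg


def build_covariates(bundle, config: PipelineConfig | None = None) -> CovariateSet:
    """Assemble the modelling covariates for the methylation cohort.

    Runs genotype QC + IBS-MDS for the ancestry axes and the cell-type
    PCA, then joins them onto the phenotype table.  Returns a
    CovariateSet restricted to the preset columns plus the exposure.
    """
    cfg = config or PipelineConfig(sim=bundle.config)
    gmat, _ = geno.filter_variants(bundle.genotypes, cfg.callrate_min,
                                   cfg.maf_min, cfg.hwe_p_min)
    kept = geno.ld_prune(gmat, cfg.ld_window, cfg.ld_step, cfg.ld_r2)
    mds = geno.ibs_mds(gmat.subset_variants(kept), k=cfg.mds_k)
    ct_pcs, _ = meth.celltype_pcs(bundle.cell_props, cfg.celltype_var_target)

    table = bundle.phenotypes.join(mds.as_frame("PC")).join(ct_pcs)
    preset = PRIMARY_COVARIATES if cfg.covariate_preset == "primary" else SENSITIVITY_COVARIATES
    cols = [c for c in preset if c in table.columns] + ["BET"]
    missing_pcs = [c for c in preset if c not in table.columns]
    if missing_pcs:
        logger.warning("covariate preset columns unavailable: %s", missing_pcs)
    return CovariateSet(table[cols].copy(), exposure="BET")


def _hash_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig, outdir: str):
    """Execute every stage in order and write outputs under ``outdir``.

    Returns a report dict with the per-stage headline results.  A stage
    failure raises with the stage name; outputs of completed stages stay
    on disk.
    """
    os.makedirs(outdir, exist_ok=True)
    p = lambda name: os.path.join(outdir, name)  # noqa: E731
    report: dict = {"stages": {}}
    t_all = time.time()

    def stage(name):
        logger.info("=== stage: %s ===", name)
        return time.time()

    # --- inputs -----------------------------------------------------------
    t0 = stage("inputs")
    if config.synthetic:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        bundle = simulate_cohort(sim)
    else:
        if not config.input_dir:
            raise ValueError("non-synthetic mode requires config.input_dir")
        bundle = _load_bundle(config.input_dir, config)
    report["stages"]["inputs"] = {"seconds": round(time.time() - t0, 2),
                                  "n_samples": len(bundle.phenotypes),
                                  "n_cpgs": int(len(bundle.beta.cpgs))}

    # --- genotype QC + covariates ----------------------------------------
    t0 = stage("genotype_qc")
    try:
        covars = build_covariates(bundle, config)
    except Exception as exc:
        raise RuntimeError(f"stage genotype_qc failed: {exc}") from exc
    covars.data.to_csv(p("covariates.tsv"), sep="\t", index_label="sample")
    report["stages"]["genotype_qc"] = {"seconds": round(time.time() - t0, 2),
                                       "covariates": list(covars.data.columns)}

    # --- methylation preprocessing ---------------------------------------
    t0 = stage("methylation_preprocess")
    beta = meth.detection_filter(bundle.beta, bundle.detp,
                                 config.detp_thresh, config.detp_frac)
    beta = meth.apply_blacklist(beta, blacklist=[], drop_sex_chroms=True)
    beta = meth.batch_center(beta, bundle.phenotypes["slide"])
    beta.to_bed(p("kept_cpgs.bed"))
    report["stages"]["methylation_preprocess"] = {
        "seconds": round(time.time() - t0, 2),
        "n_cpgs_kept": int(len(beta.cpgs)),
    }

    # --- EWAS -------------------------------------------------------------
    t0 = stage("ewas")
    ewas_table = run_ewas(beta, covars, genomewide_p=config.genomewide_p)
    ewas_table.to_csv(p("ewas.tsv"), sep="\t", index_label="cpg")
    top = ewas_table.head(5)
    report["stages"]["ewas"] = {
        "seconds": round(time.time() - t0, 2),
        "n_genomewide": int(ewas_table["genomewide"].sum()),
        "n_fdr": int((ewas_table["q"] < config.fdr).sum()),
        "top_hits": {
            cpg: {"p": float(row["p"]), "q": float(row["q"]),
                  "estimate": round(float(row["estimate"]), 6),
                  "mean_diff": round(float(row["mean_diff"]), 6)}
            for cpg, row in top.iterrows()
        },
    }

    # --- fine-mapping panel ----------------------------------------------
    t0 = stage("region_models")
    plate_cov = CovariateSet(
        covars.data.join(bundle.phenotypes[["plate"]]),
        exposure="BET", categorical=("plate",),
    )
    snp_dose = bundle.genotypes.dosage_of(FOCAL_SNP)
    region_table = run_region_models(bundle.region_beta, plate_cov, snp_dose, config.fdr)
    region_table.drop(columns=[c for c in region_table.columns if c == "error"],
                      errors="ignore").to_csv(p("region_models.tsv"), sep="\t")
    nominal = region_table[region_table["exposure_p"] < 0.05]
    if len(nominal):
        same = int((np.sign(nominal["exposure_estimate"])
                    == np.sign(nominal["exposure_estimate"]).mode()[0]).sum())
        consistency = direction_consistency(same, len(nominal))
    else:
        consistency = {"point": None, "tail": None}
    report["stages"]["region_models"] = {
        "seconds": round(time.time() - t0, 2),
        "n_panel": int(len(region_table)),
        "n_exposure_fdr": int((region_table.get("exposure_q", pd.Series(dtype=float)) < config.fdr).sum()),
        "n_snp_fdr": int((region_table.get("snp_q", pd.Series(dtype=float)) < config.fdr).sum()),
        "direction_consistency": consistency,
    }

    # --- expression & eQTM -------------------------------------------------
    t0 = stage("expression")
    counts = expr.filter_counts(bundle.counts, config.min_count, config.min_count_frac)
    log_expr = expr.normalize_transform(counts)
    log_expr.to_csv(p("expression_log2.tsv"), sep="\t", index_label="gene")
    universe = counts.index.tolist()
    meth_vec = bundle.expr_phenotypes["focal_cpg_beta"]
    eqtm_res = None
    if FOCAL_GENE in log_expr.index:
        eqtm_res = expr.eqtm(
            meth_vec, log_expr.loc[FOCAL_GENE],
            covariates=bundle.expr_phenotypes[["delivery_cs", "labor", "parity",
                                               "hypertension", "diabetes"]],
        )
        labels, med = expr.median_split(meth_vec)
        group_means = log_expr.loc[FOCAL_GENE].groupby(labels).mean()
        report["stages"]["expression"] = {
            "seconds": round(time.time() - t0, 2),
            "n_genes_kept": int(len(universe)),
            "eqtm": {k: (float(v) if np.isscalar(v) else v) for k, v in eqtm_res.items()},
            "median_split": {"median": med, **group_means.round(4).to_dict()},
        }
    else:
        report["stages"]["expression"] = {
            "seconds": round(time.time() - t0, 2),
            "n_genes_kept": int(len(universe)),
            "eqtm": "focal gene removed by the count filter",
        }

    # --- co-expression -----------------------------------------------------
    t0 = stage("coexpression")
    power, power_diag = coex.choose_soft_power(log_expr)
    power_diag.to_csv(p("soft_power.tsv"), sep="\t")
    adj = coex.adjacency(log_expr, power)
    net = coex.CoexpressionNetwork(
        genes=log_expr.index.tolist(), power=power, kind="unsigned",
        tom_matrix=coex.tom(adj), connectivity=adj.sum(axis=0) - 1,
    )
    modules = coex.detect_modules(net, config.module_min_size, config.cut_height)
    modules = coex.assign_eigengenes(log_expr, modules)
    modules.labels.rename("module").to_csv(p("modules.tsv"), sep="\t", index_label="gene")
    if not modules.eigengenes.empty:
        modules.eigengenes.to_csv(p("eigengenes.tsv"), sep="\t", index_label="sample")
    focal_module = modules.labels.get(FOCAL_GENE, coex.UNASSIGNED)
    if focal_module != coex.UNASSIGNED:
        eig = modules.eigengenes[focal_module]
        mcorr = coex.module_trait_correlation(eig, meth_vec).to_dict()
        module_genes = modules.members(focal_module)
    else:
        # fall back to the largest detected module
        named = modules.sizes.drop(coex.UNASSIGNED, errors="ignore")
        focal_module = named.index[0] if len(named) else coex.UNASSIGNED
        mcorr = (coex.module_trait_correlation(
            modules.eigengenes[focal_module], meth_vec).to_dict()
            if focal_module != coex.UNASSIGNED else {})
        module_genes = (modules.members(focal_module)
                        if focal_module != coex.UNASSIGNED else [])
    report["stages"]["coexpression"] = {
        "seconds": round(time.time() - t0, 2),
        "power": power,
        "module_sizes": modules.sizes.to_dict(),
        "focal_module": focal_module,
        "eigengene_meth_corr": mcorr,
    }

    # --- overlap & enrichment ----------------------------------------------
    t0 = stage("overlap_enrichment")
    signature = enr.restrict_to_universe(bundle.signature, universe)
    overlap = enr.overlap_permutation_test(
        module_genes, signature, universe, B=config.overlap_B, seed=config.seed,
    )
    overlap.as_series().to_csv(p("overlap_test.tsv"), sep="\t", header=False)
    # direction concordance: gene-vs-focal-gene expression correlation sign
    # against the external signature's reported sign
    overlap_genes = [g for g in signature if g in module_genes]
    conc = None
    if overlap_genes and FOCAL_GENE in log_expr.index:
        focal_profile = log_expr.loc[FOCAL_GENE]
        signs = pd.Series(
            {g: np.corrcoef(log_expr.loc[g], focal_profile)[0, 1] for g in overlap_genes}
        )
        conc = enr.concordance_summary(signs, bundle.signature_effects)
    enrich_table = enr.hypergeom_enrichment(module_genes, bundle.gene_sets,
                                            universe, config.fdr)
    enrich_table.to_csv(p("enrichment.tsv"), sep="\t")
    report["stages"]["overlap_enrichment"] = {
        "seconds": round(time.time() - t0, 2),
        "overlap": {k: v for k, v in overlap.as_series().items()},
        "concordance": conc,
        "n_sets_significant": int(enrich_table["significant"].sum()) if len(enrich_table) else 0,
    }

    # --- manifest & summary -------------------------------------------------
    report["total_seconds"] = round(time.time() - t_all, 2)
    manifest = {
        "config": _jsonable(dataclasses.asdict(config)),
        "seed": config.seed,
        "thresholds": {
            "genomewide_p": config.genomewide_p, "fdr": config.fdr,
            "detp": [config.detp_thresh, config.detp_frac],
            "count_filter": [config.min_count, config.min_count_frac],
            "overlap_B": config.overlap_B,
        },
        "outputs": {},
    }
    for name in sorted(os.listdir(outdir)):
        fp = os.path.join(outdir, name)
        if os.path.isfile(fp) and name not in ("manifest.json", "summary.txt"):
            manifest["outputs"][name] = _hash_file(fp)
    with open(p("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    _write_summary(report, p("summary.txt"))
    report["manifest"] = manifest
    return report, bundle


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _write_summary(report: dict, path: str) -> None:
    lines = ["analysis summary", "================", ""]
    for name, info in report["stages"].items():
        lines.append(f"[{name}] ({info.get('seconds', '?')} s)")
        for k, v in info.items():
            if k == "seconds":
                continue
            lines.append(f"  {k}: {v}")
        lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def _load_bundle(input_dir: str, config: PipelineConfig):
    """Load a bundle previously written by ``CohortBundle.write``."""
    from .synthetic import CohortBundle

    p = lambda name: os.path.join(input_dir, name)  # noqa: E731
    required = ["phenotypes.tsv", "beta.tsv", "beta_annot.tsv"]
    for name in required:
        if not os.path.exists(p(name)):
            raise FileNotFoundError(f"missing required input file: {name}")
    pheno = pd.read_csv(p("phenotypes.tsv"), sep="\t", index_col="sample")
    beta = meth.BetaMatrix.from_tsv(p("beta.tsv"), p("beta_annot.tsv"))
    region_beta = meth.BetaMatrix.from_tsv(p("region_beta.tsv"), p("region_beta_annot.tsv"))
    detp = pd.read_csv(p("detection_p.tsv"), sep="\t", index_col="cpg")
    genotypes = geno.read_vcf(p("genotypes.vcf"))
    cell = meth.CellTypeProportions(
        pd.read_csv(p("cell_proportions.tsv"), sep="\t", index_col="sample"))
    counts = pd.read_csv(p("counts.tsv"), sep="\t", index_col="gene")
    expr_pheno = pd.read_csv(p("expr_phenotypes.tsv"), sep="\t", index_col="sample")
    with open(p("signature.txt")) as fh:
        signature = [line.strip() for line in fh if line.strip()]
    gene_sets = enr.read_gmt(p("gene_sets.gmt"))
    return CohortBundle(
        config=config.sim, phenotypes=pheno, beta=beta, region_beta=region_beta,
        detp=detp, genotypes=genotypes, cell_props=cell, counts=counts,
        expr_phenotypes=expr_pheno, signature=signature,
        signature_effects=pd.Series(1.0, index=signature), gene_sets=gene_sets,
    )
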