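"""Synthetic cohort generator for the full analysis chain.

Emulates the statistical structure the pipeline assumes, so every stage
is testable without restricted cohort data:

* a methylation cohort of 52 exposed / 84 control placental samples with
  covariates, slide/plate batches, Dirichlet cell-type proportions, a
  genome-wide CpG matrix plus a 106-CpG targeted panel around a focal
  locus, a detection-p matrix, and genotypes including a focal common
  SNP (rs1360780-like, MAF 0.30);
* an expression cohort of 494 samples with negative-binomial gene counts
  carrying planted low-rank co-expression modules, the largest of which
  is tied to the focal CpG's methylation (eigengene target correlation
  -0.33; focal-gene target -0.28);
* an external gene signature overlapping the planted module, and a small
  gene-set collection for enrichment.

Methylation is generated on the logit scale (per-CpG baseline, additive
covariate / exposure / genotype effects, Gaussian noise, inverse-logit
back-transform), which keeps betas strictly inside (0, 1).  Exposure and
per-allele SNP effects are specified on the beta scale; the logit-scale
shift that realises each beta-scale target under the noise distribution
is solved with Gauss-Hermite quadrature, so the simulated group mean
difference matches the configured value without post-hoc tuning.

All randomness flows through one ``numpy.random.default_rng`` (PCG64)
seeded from ``SimConfig.seed``; a fixed seed reproduces the bundle
bit-identically.  Every distributional choice here is a stand-in: real
placental array, amplicon and 3' RNA-seq data have no canonical
generative model, so nothing beyond the planted first- and second-order
structure should be read into these layers.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit, polygamma

from .genotype import GenotypeMatrix, write_vcf
from .methylation import BetaMatrix, CellTypeProportions
from .enrichment import GeneSetCollection, write_gmt

__all__ = [
    "SimConfig",
    "CohortBundle",
    "ConfigurationError",
    "simulate_cohort",
    "simulate_null",
    "simulate_two_population_genotypes",
]

FOCAL_CPG = "cg22363520"
SECOND_CPG = "cg04314723"
FOCAL_REGION_CPG = "PCR_2_29"  # targeted-panel alias of the focal CpG
INTERACTION_CPG = "PCR_3_97"
FOCAL_SNP = "rs1360780"
FOCAL_GENE = "FKBP5"

CELL_TYPES = [
    "trophoblast", "syncytiotrophoblast", "stromal",
    "hofbauer", "endothelial", "nrbc",
]
_CELL_BASE = np.array([0.25, 0.44, 0.10, 0.07, 0.09, 0.05])

_REGIONS = [
    ("intron_1", 30, 35_630_000),
    ("intron_2", 10, 35_600_000),
    ("intron_5", 16, 35_580_000),
    ("intron_7", 30, 35_558_000),
    ("proximal_enhancer", 20, 35_695_000),
]


class ConfigurationError(ValueError):
    """A simulation parameter is out of its admissible range."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults emulate an antenatal-corticosteroid placental cohort and a
    companion expression cohort: 52 exposed / 84 control
    methylation samples, a 2.7 percentage-point methylation decrease at
    the exposure-responsive CpGs, a MAF-0.30 focal SNP with a +0.02
    per-allele effect on regional CpGs, 494 expression samples with a
    planted module whose eigengene correlates -0.33 with focal-CpG
    methylation (focal gene -0.28), and a 323-gene signature sharing 60
    genes with that module.
    """

    n_exposed: int = 52
    n_control: int = 84
    n_cpgs: int = 5000
    n_causal_cpgs: int = 3
    exposure_effect: float = -0.027  # beta-scale group difference
    focal_snp_maf: float = 0.30
    snp_effect: float = 0.02  # beta-scale per alternate allele
    interaction_effect: float = 0.0
    n_genes: int = 2000
    n_modules: int = 5
    module_sizes: tuple = ()
    eigengene_meth_corr: float = -0.33
    focal_gene_corr: float = -0.28
    signature_size: int = 323
    signature_module_overlap: int = 60
    n_expr_samples: int = 494
    noise_sd_beta: float = 0.35  # logit-scale residual SD
    nb_dispersion: float = 0.2
    n_snps: int = 300
    n_region_cpgs: int = 106
    detp_fail_frac: float = 0.02
    genotype_missing_rate: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if not self.module_sizes:
            object.__setattr__(self, "module_sizes", (150, 120, 100, 80, 60)[: self.n_modules])
        for name in ("n_exposed", "n_control", "n_cpgs", "n_causal_cpgs", "n_genes",
                     "n_modules", "signature_size", "n_expr_samples", "n_snps",
                     "n_region_cpgs"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive (got {getattr(self, name)})")
        if not 0 < self.focal_snp_maf < 1:
            raise ConfigurationError(f"focal_snp_maf must lie in (0,1), got {self.focal_snp_maf}")
        if len(self.module_sizes) != self.n_modules:
            raise ConfigurationError("module_sizes must list one size per module")
        if sum(self.module_sizes) > self.n_genes:
            raise ConfigurationError("module_sizes sum exceeds n_genes")
        if self.signature_module_overlap > min(self.signature_size, self.module_sizes[0]):
            raise ConfigurationError(
                "signature_module_overlap exceeds min(signature_size, largest module size)"
            )
        if self.signature_size > self.n_genes:
            raise ConfigurationError("signature_size exceeds n_genes")
        if abs(self.eigengene_meth_corr) >= 1:
            raise ConfigurationError("eigengene_meth_corr must lie in (-1, 1)")
        if self.eigengene_meth_corr != 0 and abs(self.focal_gene_corr) >= abs(self.eigengene_meth_corr):
            raise ConfigurationError(
                "focal_gene_corr cannot exceed eigengene_meth_corr in magnitude "
                "(the focal gene reaches methylation only through the module factor)"
            )
        if self.noise_sd_beta <= 0 or self.nb_dispersion <= 0:
            raise ConfigurationError("noise_sd_beta and nb_dispersion must be positive")
        # beta-scale effects must keep expected betas inside (0, 1) at the
        # most extreme baseline used for affected CpGs (0.952)
        for pname, eff, doses in (("exposure_effect", self.exposure_effect, 1),
                                  ("snp_effect", self.snp_effect, 2),
                                  ("interaction_effect", self.interaction_effect, 1)):
            target = 0.952 + eff * doses
            if not 0 < target < 1:
                raise ConfigurationError(
                    f"{pname}={eff} pushes expected betas outside (0, 1)"
                )


@dataclass
class CohortBundle:
    """Everything one simulated study produces."""

    config: SimConfig
    phenotypes: pd.DataFrame  # methylation-cohort samples x covariates
    beta: BetaMatrix
    region_beta: BetaMatrix
    detp: pd.DataFrame
    genotypes: GenotypeMatrix
    cell_props: CellTypeProportions
    counts: pd.DataFrame  # genes x expression samples
    expr_phenotypes: pd.DataFrame
    signature: list
    signature_effects: pd.Series
    gene_sets: GeneSetCollection
    truth: dict = field(default_factory=dict)

    def write(self, outdir: str) -> None:
        """Write the whole bundle as plain-text files."""
        os.makedirs(outdir, exist_ok=True)
        p = lambda name: os.path.join(outdir, name)  # noqa: E731
        self.phenotypes.to_csv(p("phenotypes.tsv"), sep="\t", index_label="sample")
        self.beta.to_tsv(p("beta.tsv"), p("beta_annot.tsv"))
        self.region_beta.to_tsv(p("region_beta.tsv"), p("region_beta_annot.tsv"))
        self.detp.to_csv(p("detection_p.tsv"), sep="\t", index_label="cpg")
        write_vcf(self.genotypes, p("genotypes.vcf"))
        self.cell_props.proportions.to_csv(p("cell_proportions.tsv"), sep="\t", index_label="sample")
        self.counts.to_csv(p("counts.tsv"), sep="\t", index_label="gene")
        self.expr_phenotypes.to_csv(p("expr_phenotypes.tsv"), sep="\t", index_label="sample")
        with open(p("signature.txt"), "w") as fh:
            fh.write("\n".join(self.signature) + "\n")
        write_gmt(self.gene_sets, p("gene_sets.gmt"))
        with open(p("truth.json"), "w") as fh:
            json.dump(_jsonable(self.truth), fh, indent=1, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict()
    if isinstance(obj, (np.ndarray, list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# logit-scale effect calibration
# ---------------------------------------------------------------------------

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(41)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


def smeared_mean_beta(mu: float, sd: float) -> float:
    """E[expit(mu + sd Z)], Z standard normal (Gauss-Hermite, 41 nodes)."""
    return float(expit(mu + sd * _GH_NODES) @ _GH_WEIGHTS)


def logit_shift_for_effect(mu: float, effect: float, sd: float) -> float:
    """Logit shift whose realised beta-scale mean difference is ``effect``.

    Solves E[expit(mu + d + sd Z)] - E[expit(mu + sd Z)] = effect for d.
    """
    if effect == 0:
        return 0.0
    base = smeared_mean_beta(mu, sd)
    target = base + effect
    if not 0 < target < 1:
        raise ConfigurationError(
            f"effect {effect} pushes the mean beta outside (0, 1) at baseline {base:.3f}"
        )
    return float(brentq(lambda d: smeared_mean_beta(mu + d, sd) - target, -30.0, 30.0))


def loading_for_correlation(rho: float, dispersion: float, mean_count: float) -> float:
    """Factor loading giving target gene-factor correlation on the log scale.

    The log-scale noise variance of a negative-binomial count around its
    latent mean is approximated by trigamma(1/dispersion) (the gamma
    mixing component) plus 1/mean (the Poisson component).
    """
    if not 0 < abs(rho) < 1:
        raise ValueError("rho must be in (0, 1) in magnitude")
    noise_var = float(polygamma(1, 1.0 / dispersion)) + 1.0 / mean_count
    return float(np.sign(rho) * np.sqrt(rho**2 / (1 - rho**2) * noise_var))


# ---------------------------------------------------------------------------
# generation stages
# ---------------------------------------------------------------------------


def _phenotypes(cfg: SimConfig, rng) -> pd.DataFrame:
    n = cfg.n_exposed + cfg.n_control
    samples = [f"B{i + 1:04d}" for i in range(n)]
    bet = np.r_[np.ones(cfg.n_exposed), np.zeros(cfg.n_control)]
    df = pd.DataFrame(
        {
            "BET": bet.astype(int),
            "sex": rng.integers(0, 2, n),
            "gestational_age": np.round(rng.normal(38.1, 1.95, n).clip(30, 42), 1),
            "maternal_age": np.round(rng.normal(29.2, 5.8, n).clip(18, 45), 1),
            "smoking": (rng.random(n) < 0.235).astype(int),
            "delivery_cs": (rng.random(n) < 0.26).astype(int),
            "labor": (rng.random(n) < 0.89).astype(int),
            "parity": rng.poisson(0.85, n) + 1,
            "plate": np.where(rng.random(n) < 0.5, "P1", "P2"),
            "slide": [f"S{1 + rng.integers(0, 8)}" for _ in range(n)],
        },
        index=pd.Index(samples, name="sample"),
    )
    return df


def _genotypes(cfg: SimConfig, samples: list, rng) -> GenotypeMatrix:
    n = len(samples)
    records = []
    dosages = []
    # background variants: 10 per chromosome slot, independent, HWE
    chroms = [str(c) for c in range(1, 23)]
    per_chrom = int(np.ceil(cfg.n_snps / len(chroms)))
    v = 0
    for chrom in chroms:
        pos = np.sort(rng.integers(100_000, 200_000_000, per_chrom))
        for p_ in pos:
            if v >= cfg.n_snps:
                break
            maf = rng.uniform(0.05, 0.5)
            d = rng.binomial(2, maf, n).astype(float)
            miss = rng.random(n) < cfg.genotype_missing_rate
            d[miss] = np.nan
            records.append((f"snp{v + 1:05d}", chrom, int(p_), "A", "G"))
            dosages.append(d)
            v += 1
    # focal variant: HWE at the configured MAF, fully called
    records.append((FOCAL_SNP, "6", 35_607_571, "C", "T"))
    dosages.append(rng.binomial(2, cfg.focal_snp_maf, n).astype(float))

    variants = pd.DataFrame(
        records, columns=["variant", "chrom", "pos", "ref", "alt"]
    ).set_index("variant")
    order = variants.assign(_c=variants.chrom.astype(int)).sort_values(["_c", "pos"]).index
    dos = np.array(dosages)[variants.index.get_indexer(order)]
    return GenotypeMatrix(variants.loc[order].drop(columns=[], errors="ignore"),
                          dos, list(samples))


def _cell_props(cfg: SimConfig, samples: list, rng) -> CellTypeProportions:
    alpha = _CELL_BASE * 60.0
    props = rng.dirichlet(alpha, len(samples))
    return CellTypeProportions(pd.DataFrame(props, index=samples, columns=CELL_TYPES))


def _array_methylation(cfg: SimConfig, pheno: pd.DataFrame,
                       cell: CellTypeProportions, rng) -> tuple[BetaMatrix, dict]:
    n = len(pheno)
    m = cfg.n_cpgs
    # baseline mixture: hyper-, hypo- and intermediate-methylated CpGs
    comp = rng.choice(3, m, p=(0.45, 0.30, 0.25))
    base = np.where(
        comp == 0, rng.beta(16, 3, m),
        np.where(comp == 1, rng.beta(3, 16, m), rng.uniform(0.2, 0.8, m)),
    ).clip(0.03, 0.97)

    names = [f"cg{10_000_000 + i:08d}" for i in range(m)]
    causal = [FOCAL_CPG, SECOND_CPG][: cfg.n_causal_cpgs]
    causal += [f"cg_causal_{i}" for i in range(len(causal), cfg.n_causal_cpgs)]
    for i, cid in enumerate(causal):
        names[i] = cid
    base[0] = 0.952
    if m > 1:
        base[1] = 0.90
    for i in range(2, len(causal)):
        base[i] = rng.uniform(0.70, 0.95)

    mu = logit(base)
    eff = np.zeros((m, n))

    sexv = pheno["sex"].to_numpy(float)
    gav = pheno["gestational_age"].to_numpy(float)
    gav = gav - gav.mean()
    # standardised first principal axis of cell proportions
    x = cell.proportions.to_numpy(float)
    xc = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    ct = u[:, 0] * s[0]
    ct = ct / (ct.std() or 1.0)

    sex_cpgs = rng.random(m) < 0.05
    eff[sex_cpgs] += np.outer(rng.normal(0, 0.15, sex_cpgs.sum()), sexv)
    ga_cpgs = rng.random(m) < 0.05
    eff[ga_cpgs] += np.outer(rng.normal(0, 0.02, ga_cpgs.sum()), gav)
    ct_cpgs = rng.random(m) < 0.10
    eff[ct_cpgs] += np.outer(rng.normal(0, 0.10, ct_cpgs.sum()), ct)
    # slide batch: location shift shared by all CpGs of a slide
    slide_shift = {s_: rng.normal(0, 0.08) for s_ in sorted(pheno["slide"].unique())}
    eff += np.array([slide_shift[s_] for s_ in pheno["slide"]])[None, :]

    bet = pheno["BET"].to_numpy(float)
    shifts = {}
    for i, cid in enumerate(causal):
        d = logit_shift_for_effect(mu[i], cfg.exposure_effect, cfg.noise_sd_beta)
        shifts[cid] = d
        eff[i] += d * bet

    betas = expit(mu[:, None] + eff + rng.normal(0, cfg.noise_sd_beta, (m, n)))

    chrom_pool = np.array([str(c) for c in range(1, 23)] + ["X"])
    chrom = chrom_pool[rng.choice(len(chrom_pool), m, p=[0.99 / 22] * 22 + [0.01])]
    chrom[0] = "6"  # the focal CpG sits at the fine-mapped locus
    pos = rng.integers(100_000, 200_000_000, m)
    pos[0] = 35_558_488
    annot = pd.DataFrame({"chrom": chrom, "pos": pos}, index=pd.Index(names, name="cpg"))
    values = pd.DataFrame(betas, index=annot.index, columns=pheno.index)
    truth = {"causal_cpgs": causal, "logit_shifts": shifts,
             "baseline_beta": {c: float(base[i]) for i, c in enumerate(causal)}}
    return BetaMatrix(values, annot), truth


def _detection_p(cfg: SimConfig, beta: BetaMatrix, protected: list, rng) -> pd.DataFrame:
    m, n = beta.values.shape
    detp = rng.uniform(0, 0.005, (m, n))
    sporadic = rng.random((m, n)) < 0.01  # isolated failures, below the 25% rule
    detp[sporadic] = rng.uniform(0.01, 1.0, int(sporadic.sum()))
    eligible = ~beta.cpgs.isin(protected)
    fail = (rng.random(m) < cfg.detp_fail_frac) & eligible
    for i in np.where(fail)[0]:
        bad = rng.random(n) < rng.uniform(0.3, 0.6)
        need = int(np.ceil(0.25 * n))
        if bad.sum() < need:  # guarantee the CpG actually fails the rule
            bad[rng.choice(n, need, replace=False)] = True
        detp[i, bad] = rng.uniform(0.011, 1.0, int(bad.sum()))
    return pd.DataFrame(detp, index=beta.cpgs, columns=beta.samples)


def _region_panel(cfg: SimConfig, pheno: pd.DataFrame, focal_dosage: np.ndarray,
                  rng) -> tuple[BetaMatrix, dict]:
    n = len(pheno)
    names, regions, positions = [], [], []
    amp = 0
    for region, count, start in _REGIONS:
        amp += 1
        for j in range(count):
            names.append(f"PCR_{amp}_{j * 7 + 11}")
            regions.append(region)
            positions.append(start + j * 17)
    names, regions, positions = (names[: cfg.n_region_cpgs],
                                 regions[: cfg.n_region_cpgs],
                                 positions[: cfg.n_region_cpgs])
    # pin the two CpGs with planted roles to their conventional names
    i7 = [i for i, r in enumerate(regions) if r == "intron_7"]
    i5 = [i for i, r in enumerate(regions) if r == "intron_5"]
    focal_idx = i7[0] if i7 else 0
    names[focal_idx] = FOCAL_REGION_CPG
    positions[focal_idx] = 35_558_488
    inter_idx = i5[0] if i5 else (1 if len(names) > 1 else 0)
    if inter_idx != focal_idx:
        names[inter_idx] = INTERACTION_CPG

    m = len(names)
    base = rng.uniform(0.60, 0.95, m)
    base[focal_idx] = 0.952
    mu = logit(base)
    eff = np.zeros((m, n))

    bet = pheno["BET"].to_numpy(float)
    dose = focal_dosage
    plate_shift = {p_: rng.normal(0, 0.10) for p_ in sorted(pheno["plate"].unique())}
    eff += np.array([plate_shift[p_] for p_ in pheno["plate"]])[None, :]

    # exposure effect at the focal panel CpG (the array hit re-measured)
    d_expo = logit_shift_for_effect(mu[focal_idx], cfg.exposure_effect, cfg.noise_sd_beta)
    eff[focal_idx] += d_expo * bet

    # SNP main effects on six panel CpGs across intron 1 / intron 7 / enhancer
    i1 = [i for i, r in enumerate(regions) if r == "intron_1"]
    enh = [i for i, r in enumerate(regions) if r == "proximal_enhancer"]
    snp_idx = (i1[:3] + [i for i in i7 if i != focal_idx][:2] + enh[:1])
    snp_cpgs = []
    for i in snp_idx:
        d_snp = logit_shift_for_effect(mu[i], cfg.snp_effect, cfg.noise_sd_beta)
        eff[i] += d_snp * dose
        snp_cpgs.append(names[i])

    inter_cpg = None
    if cfg.interaction_effect != 0 and inter_idx != focal_idx:
        d_int = logit_shift_for_effect(mu[inter_idx], cfg.interaction_effect,
                                       cfg.noise_sd_beta)
        eff[inter_idx] += d_int * dose * bet
        inter_cpg = names[inter_idx]

    betas = expit(mu[:, None] + eff + rng.normal(0, cfg.noise_sd_beta, (m, n)))
    annot = pd.DataFrame(
        {"chrom": "6", "pos": positions, "region": regions},
        index=pd.Index(names, name="cpg"),
    )
    values = pd.DataFrame(betas, index=annot.index, columns=pheno.index)
    truth = {"focal_region_cpg": FOCAL_REGION_CPG, "snp_cpgs": snp_cpgs,
             "interaction_cpg": inter_cpg}
    return BetaMatrix(values, annot), truth


def _expression(cfg: SimConfig, rng) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, dict]:
    n = cfg.n_expr_samples
    samples = [f"I{i + 1:04d}" for i in range(n)]
    n_bet = max(1, round(0.0243 * n))  # BET-exposed share of the expression cohort
    bet = np.zeros(n, dtype=int)
    bet[rng.choice(n, n_bet, replace=False)] = 1
    expr_pheno = pd.DataFrame(
        {
            "BET": bet,
            "sex": rng.integers(0, 2, n),
            "gestational_age": np.round(rng.normal(40.0, 1.6, n).clip(32, 43), 1),
            "delivery_cs": (rng.random(n) < 0.17).astype(int),
            "labor": (rng.random(n) < 0.9).astype(int),
            "parity": rng.poisson(0.8, n) + 1,
            "hypertension": (rng.random(n) < 0.06).astype(int),
            "diabetes": (rng.random(n) < 0.22).astype(int),
        },
        index=pd.Index(samples, name="sample"),
    )
    # focal-CpG methylation in the expression cohort (beta median ~0.95)
    meth_logit = logit(0.952) + cfg.noise_sd_beta * rng.standard_normal(n)
    meth_beta = expit(meth_logit)
    expr_pheno["focal_cpg_beta"] = meth_beta

    # latent module factors; factor 1 is tied to the focal CpG.  The
    # anchor is the beta-scale methylation (the scale the correlation is
    # later measured on), so the inverse-logit nonlinearity does not
    # attenuate the configured target.
    z_meth = (meth_beta - meth_beta.mean()) / meth_beta.std()
    factors = rng.standard_normal((n, cfg.n_modules))
    rho = cfg.eigengene_meth_corr
    if rho != 0:
        # orthogonalise the noise against the anchor so the factor's
        # *sample* correlation with methylation equals rho exactly; the
        # realised module correlations then vary only through the
        # downstream count noise
        eps = rng.standard_normal(n)
        eps -= eps.mean() + z_meth * (eps @ z_meth) / (z_meth @ z_meth)
        eps /= eps.std()
        factors[:, 0] = rho * z_meth + np.sqrt(1 - rho**2) * eps

    genes = [f"GENE{i + 1:05d}" for i in range(cfg.n_genes)]
    module_labels = pd.Series("none", index=pd.Index(genes, name="gene"))
    start = 0
    for mi, size in enumerate(cfg.module_sizes):
        module_labels.iloc[start : start + size] = f"M{mi + 1}"
        start += size
    genes[0] = FOCAL_GENE  # focal gene belongs to the largest module
    module_labels.index = pd.Index(genes, name="gene")

    base = np.where(
        module_labels.to_numpy() != "none",
        rng.uniform(np.log(100), np.log(600), cfg.n_genes),
        rng.uniform(np.log(20), np.log(800), cfg.n_genes),
    )
    # a slice of background genes is barely expressed, to exercise filtering
    low = (module_labels.to_numpy() == "none") & (rng.random(cfg.n_genes) < 0.05)
    base[low] = rng.uniform(np.log(1.5), np.log(5), int(low.sum()))

    mean_count = float(np.exp(base[~low].mean()))
    log_mu = np.tile(base[:, None], (1, n)).astype(float)
    gene_factor_target = np.zeros(cfg.n_genes)
    for mi in range(cfg.n_modules):
        sel = (module_labels.to_numpy() == f"M{mi + 1}")
        targets = rng.uniform(0.60, 0.85, int(sel.sum()))
        gene_factor_target[sel] = targets
        loadings = np.array(
            [loading_for_correlation(t, cfg.nb_dispersion, mean_count) for t in targets]
        )
        log_mu[sel] += np.outer(loadings, factors[:, mi])
    # the focal gene's loading realises the configured methylation correlation
    if rho != 0 and cfg.focal_gene_corr != 0:
        t_focal = cfg.focal_gene_corr / rho
        i_focal = genes.index(FOCAL_GENE)
        log_mu[i_focal] = base[i_focal] + loading_for_correlation(
            t_focal, cfg.nb_dispersion, mean_count
        ) * factors[:, 0]
        gene_factor_target[i_focal] = t_focal

    mu = np.exp(log_mu)
    shape = 1.0 / cfg.nb_dispersion
    lam = rng.gamma(shape, mu / shape)
    counts = rng.poisson(lam).astype(int)
    counts_df = pd.DataFrame(counts, index=module_labels.index, columns=samples)

    truth = {
        "factors": pd.DataFrame(factors, index=samples,
                                columns=[f"M{i + 1}" for i in range(cfg.n_modules)]),
        "gene_factor_target": pd.Series(gene_factor_target, index=module_labels.index),
        "focal_gene": FOCAL_GENE,
    }
    return counts_df, expr_pheno, module_labels, truth


def _signature_and_sets(cfg: SimConfig, module_labels: pd.Series,
                        rng) -> tuple[list, pd.Series, GeneSetCollection]:
    m1 = module_labels.index[module_labels == "M1"].tolist()
    others = module_labels.index[module_labels != "M1"].tolist()
    sig_in = list(rng.choice(m1, cfg.signature_module_overlap, replace=False))
    sig_out = list(rng.choice(others, cfg.signature_size - cfg.signature_module_overlap,
                              replace=False))
    signature = sig_in + sig_out
    # signed external effects: module genes up-regulated, the rest random sign
    effects = pd.Series(
        np.r_[np.ones(len(sig_in)), rng.choice([-1.0, 1.0], len(sig_out))],
        index=signature,
    )
    n_out1 = min(20, len(others))
    n_in2 = min(30, len(m1))
    n_out2 = min(25, len(others))
    sets = {
        "inflammatory_response": sig_in[:40] + list(rng.choice(others, n_out1, replace=False)),
        "immune_response": list(rng.choice(m1, n_in2, replace=False))
        + list(rng.choice(others, n_out2, replace=False)),
    }
    all_genes = module_labels.index.tolist()
    for i in range(8):
        size = min(int(rng.integers(40, 80)), len(all_genes))
        sets[f"random_set_{i + 1}"] = list(rng.choice(all_genes, size, replace=False))
    desc = {name: "synthetic gene set" for name in sets}
    return signature, effects, GeneSetCollection(sets, desc)


def simulate_cohort(config: SimConfig | None = None) -> CohortBundle:
    """Generate the full synthetic study bundle.

    Deterministic given ``config.seed``; see the module docstring for the
    generative model of each layer.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)

    pheno = _phenotypes(cfg, rng)
    cell = _cell_props(cfg, pheno.index.tolist(), rng)
    geno = _genotypes(cfg, pheno.index.tolist(), rng)
    beta, meth_truth = _array_methylation(cfg, pheno, cell, rng)
    detp = _detection_p(cfg, beta, meth_truth["causal_cpgs"], rng)
    focal_dose = geno.dosage_of(FOCAL_SNP).to_numpy()
    region_beta, region_truth = _region_panel(cfg, pheno, focal_dose, rng)
    counts, expr_pheno, module_labels, expr_truth = _expression(cfg, rng)
    signature, sig_effects, gene_sets = _signature_and_sets(cfg, module_labels, rng)

    truth = {
        "config": dataclasses.asdict(cfg),
        "focal_cpg": FOCAL_CPG,
        "focal_snp": FOCAL_SNP,
        "module_labels": module_labels,
        "module_sizes": {f"M{i + 1}": s for i, s in enumerate(cfg.module_sizes)},
        "signature": signature,
        **meth_truth,
        **region_truth,
        **{k: v for k, v in expr_truth.items()},
    }
    return CohortBundle(
        config=cfg,
        phenotypes=pheno,
        beta=beta,
        region_beta=region_beta,
        detp=detp,
        genotypes=geno,
        cell_props=cell,
        counts=counts,
        expr_phenotypes=expr_pheno,
        signature=signature,
        signature_effects=sig_effects,
        gene_sets=gene_sets,
        truth=truth,
    )


def simulate_null(config: SimConfig | None = None) -> CohortBundle:
    """Same bundle with every planted exposure/genotype/methylation
    effect zeroed (module structure itself remains)."""
    cfg = config or SimConfig()
    cfg = dataclasses.replace(
        cfg, exposure_effect=0.0, snp_effect=0.0, interaction_effect=0.0,
        eigengene_meth_corr=0.0, focal_gene_corr=0.0,
    )
    return simulate_cohort(cfg)


def simulate_two_population_genotypes(
    n_per_pop: int = 50,
    n_snps: int = 200,
    divergence: float = 0.2,
    seed: int = 0,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Two allele-frequency-differentiated populations, for MDS checks.

    Per SNP an ancestral frequency is drawn and the two populations get
    frequencies shifted apart by ``divergence``.  Returns the genotype
    matrix and the 0/1 population labels.
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_pop
    pop = np.r_[np.zeros(n_per_pop, int), np.ones(n_per_pop, int)]
    anc = rng.uniform(0.2, 0.8, n_snps)
    f0 = np.clip(anc - divergence / 2, 0.01, 0.99)
    f1 = np.clip(anc + divergence / 2, 0.01, 0.99)
    dos = np.empty((n_snps, n))
    for j in range(n_snps):
        dos[j, pop == 0] = rng.binomial(2, f0[j], n_per_pop)
        dos[j, pop == 1] = rng.binomial(2, f1[j], n_per_pop)
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, n_snps + 1) * 1000,
            "ref": "A",
            "alt": "G",
        },
        index=pd.Index([f"snp{j + 1:04d}" for j in range(n_snps)], name="variant"),
    )
    samples = [f"P{i + 1:03d}" for i in range(n)]
    return GenotypeMatrix(variants, dos, samples), pop
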