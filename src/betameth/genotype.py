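"""Genotype quality control: variant filters, LD pruning and ancestry axes.

The QC chain mirrors a standard array-genotyping pipeline: per-variant
call-rate / minor-allele-frequency / Hardy-Weinberg filters, sliding-window
LD pruning on dosage correlations, and classical multidimensional scaling
of an identity-by-state distance whose leading coordinates serve as
ancestry covariates in the association models.

Dosages are additive counts of the alternate allele in {0, 1, 2}, with
``nan`` for missing calls.  Relatedness filtering is assumed to have been
done upstream; samples are treated as unrelated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "AncestryComponents",
    "filter_variants",
    "hwe_exact_test",
    "ld_prune",
    "ibs_mds",
    "read_vcf",
    "write_vcf",
    "read_dosage_tsv",
    "write_dosage_tsv",
]


@dataclass
class GenotypeMatrix:
    """SNP-by-sample additive dosage matrix with variant annotation.

    Parameters
    ----------
    variants : pandas.DataFrame
        One row per variant with columns ``chrom``, ``pos`` (1-based),
        ``ref``, ``alt``; indexed by variant id.
    dosages : numpy.ndarray
        ``(n_variants, n_samples)`` float array with entries in
        {0, 1, 2, nan}.
    samples : list of str
    """

    variants: pd.DataFrame
    dosages: np.ndarray
    samples: list = field(default_factory=list)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.variants), len(self.samples)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.variants)} variants x {len(self.samples)} samples"
            )
        if (self.variants["pos"] <= 0).any():
            raise ValueError("variant positions must be positive (1-based)")
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be in {0, 1, 2} or missing")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def call_rate(self) -> np.ndarray:
        """Per-variant fraction of non-missing calls."""
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    def maf(self) -> np.ndarray:
        """Per-variant minor allele frequency over non-missing calls."""
        with np.errstate(invalid="ignore"):
            p_alt = np.nanmean(self.dosages, axis=1) / 2.0
        return np.minimum(p_alt, 1.0 - p_alt)

    def genotype_counts(self, i: int) -> tuple[int, int, int]:
        """(hom-ref, het, hom-alt) counts for variant row ``i``."""
        d = self.dosages[i]
        return (
            int(np.nansum(d == 0)),
            int(np.nansum(d == 1)),
            int(np.nansum(d == 2)),
        )

    def subset_variants(self, ids) -> "GenotypeMatrix":
        idx = self.variants.index.get_indexer(ids)
        if (idx < 0).any():
            missing = [v for v, j in zip(ids, idx) if j < 0]
            raise KeyError(f"unknown variant ids: {missing[:5]}")
        return GenotypeMatrix(self.variants.loc[ids].copy(), self.dosages[idx], list(self.samples))

    def dosage_of(self, variant_id: str) -> pd.Series:
        i = self.variants.index.get_loc(variant_id)
        return pd.Series(self.dosages[i], index=self.samples, name=variant_id)


@dataclass
class AncestryComponents:
    """Leading coordinates of a classical MDS of genotype distances."""

    samples: list
    coordinates: np.ndarray  # (n_samples, k)
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    explained: np.ndarray  # share of each returned axis among positive eigenvalues

    def as_frame(self, prefix: str = "PC") -> pd.DataFrame:
        k = self.coordinates.shape[1]
        return pd.DataFrame(
            self.coordinates,
            index=self.samples,
            columns=[f"{prefix}{i + 1}" for i in range(k)],
        )


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg equilibrium test.

    Uses the conditional (Levene-Haldane) distribution of the heterozygote
    count given the allele counts.  The two-sided p-value is the total
    probability of all heterozygote configurations whose conditional
    probability does not exceed that of the observed one.

    Parameters
    ----------
    n_hom_ref, n_het, n_hom_alt : int
        Genotype counts; non-negative, not all zero.

    Returns
    -------
    float
        Exact p-value in (0, 1].
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n == 0:
        raise ValueError("at least one genotype count must be non-zero")

    n_alt = n_het + 2 * n_hom_alt  # alternate allele count
    n_rare = min(n_alt, 2 * n - n_alt)
    if n_rare == 0:
        return 1.0  # monomorphic: a single configuration exists

    # Heterozygote counts share the parity of the rare-allele count.
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    # log P(het = h | allele counts), up to the shared normalising constant:
    # P(h) = n! / (nAA! h! naa!) * 2^h * nA! na! / (2n)!
    lg = math.lgamma
    logp = np.array(
        [
            h * math.log(2.0)
            - lg((n_rare - h) / 2 + 1)
            - lg(h + 1)
            - lg(n - (n_rare + h) / 2 + 1)
            for h in hets
        ]
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()

    observed = np.where(hets == n_het)[0]
    if observed.size == 0:
        raise ValueError(
            f"heterozygote count {n_het} inconsistent with allele counts"
        )
    p_obs = probs[observed[0]]
    # small relative tolerance guards against ties lost to rounding
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# Variant filters
# ---------------------------------------------------------------------------


def filter_variants(
    geno: GenotypeMatrix,
    callrate_min: float = 0.98,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-6,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply call-rate, MAF and HWE filters per variant.

    Filters are independent per variant, so their order is irrelevant.

    Returns
    -------
    (GenotypeMatrix, pandas.DataFrame)
        The filtered matrix and a per-variant report with boolean columns
        ``fail_callrate``, ``fail_maf``, ``fail_hwe`` and ``kept``.
    """
    cr = geno.call_rate()
    maf = geno.maf()
    hwe_p = np.array([hwe_exact_test(*geno.genotype_counts(i)) for i in range(geno.n_variants)])

    report = pd.DataFrame(
        {
            "callrate": cr,
            "maf": maf,
            "hwe_p": hwe_p,
            "fail_callrate": cr < callrate_min,
            "fail_maf": ~(maf >= maf_min),  # NaN MAF (all missing) fails
            "fail_hwe": ~(hwe_p > hwe_p_min),
        },
        index=geno.variants.index,
    )
    report["kept"] = ~(report.fail_callrate | report.fail_maf | report.fail_hwe)
    kept_ids = report.index[report.kept]
    if len(kept_ids) == 0:
        logger.warning("variant filtering removed every variant")
        out = GenotypeMatrix(geno.variants.iloc[:0].copy(), geno.dosages[:0], list(geno.samples))
    else:
        out = geno.subset_variants(kept_ids)
    logger.info(
        "variant filter: %d/%d kept (callrate>=%.3g, maf>=%.3g, hwe_p>%.3g)",
        len(kept_ids), geno.n_variants, callrate_min, maf_min, hwe_p_min,
    )
    return out, report


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def _dosage_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over shared calls."""
    ok = ~(np.isnan(a) | np.isnan(b))
    x, y = a[ok], b[ok]
    if x.size < 2 or x.std() == 0 or y.std() == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_prune(
    geno: GenotypeMatrix,
    window: int = 200,
    step: int = 100,
    r2_max: float = 0.2,
) -> list:
    """Greedy sliding-window LD pruning on dosage correlations.

    Variants must be sorted by chromosome then position.  Within each
    window of ``window`` variants, while any pair of still-kept variants
    has squared correlation above ``r2_max``, the member of the pair with
    the lower MAF is dropped (ties drop the later variant).  The window
    then advances by ``step`` variants.  Pruning is done independently
    per chromosome.

    Returns the kept variant ids in input order.
    """
    var = geno.variants
    for _, grp in var.groupby("chrom", sort=False):
        if not grp["pos"].is_monotonic_increasing:
            raise ValueError("variants must be sorted by chromosome then position")

    maf = geno.maf()
    keep = np.ones(geno.n_variants, dtype=bool)

    for _, grp in var.groupby("chrom", sort=False):
        idx = var.index.get_indexer(grp.index)
        start = 0
        while start < len(idx):
            win = idx[start : start + window]
            changed = True
            while changed:
                changed = False
                active = [i for i in win if keep[i]]
                # scan pairs; restart after each removal (greedy rule)
                for a_pos in range(len(active)):
                    for b_pos in range(a_pos + 1, len(active)):
                        i, j = active[a_pos], active[b_pos]
                        if _dosage_r2(geno.dosages[i], geno.dosages[j]) > r2_max:
                            if maf[i] < maf[j]:
                                keep[i] = False
                            else:  # ties remove the later variant
                                keep[j] = False
                            changed = True
                            break
                    if changed:
                        break
            if start + window >= len(idx):
                break
            start += step

    kept = [v for v, k in zip(var.index, keep) if k]
    logger.info("LD pruning kept %d/%d variants", len(kept), geno.n_variants)
    return kept


# ---------------------------------------------------------------------------
# IBS distance and classical MDS
# ---------------------------------------------------------------------------


def ibs_distance(geno: GenotypeMatrix) -> np.ndarray:
    """Pairwise identity-by-state distance between samples.

    Similarity between samples i and j is the mean over variants of
    ``(2 - |d_i - d_j|) / 2``; the distance is one minus that.  Missing
    dosages are mean-imputed per variant first (imputation is used for
    this distance only, never in association models).
    """
    d = geno.dosages.copy()
    col_mean = np.nanmean(d, axis=1)
    nan_r, nan_c = np.where(np.isnan(d))
    d[nan_r, nan_c] = col_mean[nan_r]
    # |d_i - d_j| averaged over variants, computed pairwise
    n = geno.n_samples
    dist = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(d[:, i : i + 1] - d[:, i:])  # (variants, n-i)
        dist[i, i:] = diff.mean(axis=0) / 2.0
    dist = dist + dist.T
    np.fill_diagonal(dist, 0.0)
    return dist


def classical_mds(dist: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Torgerson MDS: double-centre squared distances and eigendecompose.

    Returns (coordinates for all positive eigenvalues, positive eigenvalues
    descending).
    """
    n = dist.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dist**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-12, 1e-9 * abs(evals[0]))
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    return coords, evals[pos]


def ibs_mds(geno: GenotypeMatrix, k: int = 4) -> AncestryComponents:
    """Ancestry axes: classical MDS of the IBS distance matrix.

    Parameters
    ----------
    geno : GenotypeMatrix
        Typically the LD-pruned matrix.
    k : int
        Number of leading coordinates to return; must be < n_samples.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= geno.n_samples:
        raise ValueError(f"k={k} must be smaller than n_samples={geno.n_samples}")
    dist = ibs_distance(geno)
    coords, evals = classical_mds(dist, k)
    k_eff = min(k, coords.shape[1])
    explained = evals[:k_eff] / evals.sum()
    logger.info(
        "IBS-MDS: first %d axes explain %.1f%% of positive-eigenvalue variability",
        k_eff, 100 * explained.sum(),
    )
    return AncestryComponents(
        samples=list(geno.samples),
        coordinates=coords[:, :k_eff],
        eigenvalues=evals,
        explained=explained,
    )


# ---------------------------------------------------------------------------
# I/O: minimal VCF (biallelic diploid GT) and TSV dosage
# ---------------------------------------------------------------------------


def write_vcf(geno: GenotypeMatrix, path: str) -> None:
    """Write a minimal VCF 4.2 file with GT-only genotype fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(geno.samples) + "\n")
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for i, (vid, row) in enumerate(geno.variants.iterrows()):
            gts = [
                gt_map.get(d, "./.") if not np.isnan(d) else "./."
                for d in geno.dosages[i]
            ]
            fh.write(
                f"{row.chrom}\t{row.pos}\t{vid}\t{row.ref}\t{row.alt}\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_vcf(path: str) -> GenotypeMatrix:
    """Read biallelic diploid genotypes from a VCF via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue  # only biallelic sites are supported
        ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        gt = np.asarray(rec.gt_types, dtype=float)  # 0,1,2; 3 = unknown
        gt[gt == 3] = np.nan
        rows.append(gt)
    variants = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts},
        index=pd.Index(ids, name="variant"),
    )
    return GenotypeMatrix(variants, np.array(rows).reshape(len(ids), len(samples)), samples)


def write_dosage_tsv(geno: GenotypeMatrix, path: str) -> None:
    df = pd.concat(
        [geno.variants, pd.DataFrame(geno.dosages, index=geno.variants.index, columns=geno.samples)],
        axis=1,
    )
    df.to_csv(path, sep="\t", index_label="variant")


def read_dosage_tsv(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="variant")
    annot_cols = ["chrom", "pos", "ref", "alt"]
    samples = [c for c in df.columns if c not in annot_cols]
    return GenotypeMatrix(df[annot_cols].copy(), df[samples].to_numpy(float), samples)
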