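"""Methylation preprocessing: probe filters and covariate construction.

Works on beta values (fraction methylated, in [0, 1]); beta is also the
modelling scale downstream.  An M-value transform is provided for users
who prefer it but nothing here requires it.

The batch adjustment is deliberately simple: per-CpG mean centering of
each batch onto the global mean.  It is a documented stand-in for
empirical-Bayes batch removal, adequate for location (not scale) batch
effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BetaMatrix",
    "CellTypeProportions",
    "detection_filter",
    "apply_blacklist",
    "celltype_pcs",
    "batch_center",
    "m_values",
]


@dataclass
class BetaMatrix:
    """CpG-by-sample methylation beta values with CpG annotation.

    Parameters
    ----------
    values : pandas.DataFrame
        CpG x sample matrix of betas in [0, 1] (NaN allowed), indexed by
        unique CpG id.
    annot : pandas.DataFrame
        Per-CpG annotation aligned to ``values``: ``chrom``, ``pos``
        (1-based) and optionally ``region`` (e.g. intron / enhancer label).
    """

    values: pd.DataFrame
    annot: pd.DataFrame

    def __post_init__(self):
        if not self.values.index.is_unique:
            raise ValueError("CpG ids must be unique")
        if not self.values.index.equals(self.annot.index):
            raise ValueError("annotation index must match the value matrix")
        v = self.values.to_numpy(float)
        if v.size:
            with np.errstate(invalid="ignore"):
                if np.nanmin(v) < 0 or np.nanmax(v) > 1:
                    raise ValueError("beta values must lie in [0, 1]")

    @property
    def cpgs(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset(self, cpg_ids) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[cpg_ids].copy(), self.annot.loc[cpg_ids].copy())

    def to_tsv(self, values_path: str, annot_path: str | None = None) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="cpg")
        if annot_path:
            self.annot.to_csv(annot_path, sep="\t", index_label="cpg")

    @classmethod
    def from_tsv(cls, values_path: str, annot_path: str) -> "BetaMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col="cpg")
        annot = pd.read_csv(annot_path, sep="\t", index_col="cpg")
        return cls(values, annot.loc[values.index])

    def to_bed(self, path: str) -> None:
        """Export kept CpGs as 0-based half-open BED with the id as name."""
        bed = pd.DataFrame(
            {
                "chrom": self.annot["chrom"],
                "start": self.annot["pos"] - 1,
                "end": self.annot["pos"],
                "name": self.annot.index,
            }
        )
        bed.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class CellTypeProportions:
    """Sample-by-cell-type proportion matrix (rows sum to one)."""

    proportions: pd.DataFrame  # samples x cell types

    def __post_init__(self):
        p = self.proportions.to_numpy(float)
        if (p < 0).any():
            raise ValueError("cell-type proportions must be non-negative")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("cell-type proportions must sum to 1 per sample")


def detection_filter(
    beta: BetaMatrix,
    detp: pd.DataFrame,
    p_thresh: float = 0.01,
    frac: float = 0.25,
) -> BetaMatrix:
    """Drop CpGs with poor detection in too many samples.

    A CpG is removed iff the fraction of samples with detection
    p > ``p_thresh`` is at least ``frac`` (the boundary itself fails:
    "at least" is read inclusively).
    """
    if detp.shape != beta.values.shape or not detp.index.equals(beta.cpgs):
        raise ValueError("detection-p matrix must match the beta matrix shape and index")
    fail_frac = (detp.to_numpy(float) > p_thresh).mean(axis=1)
    keep = fail_frac < frac
    logger.info(
        "detection filter (p>%g in >=%g%% of samples): removed %d/%d CpGs",
        p_thresh, 100 * frac, int((~keep).sum()), len(keep),
    )
    return beta.subset(beta.cpgs[keep])


def apply_blacklist(
    beta: BetaMatrix,
    blacklist: list | None = None,
    drop_sex_chroms: bool = False,
) -> BetaMatrix:
    """Remove blacklisted probes and, optionally, chrX/chrY probes.

    Typical blacklists hold SNP-containing and cross-hybridising probes.
    Unknown blacklist ids are ignored with a warning.
    """
    blacklist = set(blacklist or [])
    unknown = blacklist - set(beta.cpgs)
    if unknown:
        logger.warning("%d blacklist ids not present in the matrix", len(unknown))
    drop = beta.cpgs.isin(blacklist)
    if drop_sex_chroms:
        sex = beta.annot["chrom"].astype(str).str.replace("chr", "", regex=False).isin(["X", "Y"])
        drop = drop | sex.to_numpy()
    logger.info("blacklist/sex-chromosome exclusion removed %d CpGs", int(drop.sum()))
    return beta.subset(beta.cpgs[~drop])


def celltype_pcs(
    props: CellTypeProportions,
    var_target: float = 0.70,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of cell-type proportions for covariate use.

    Column-centred PCA; returns the smallest number of leading components
    whose cumulative explained variance reaches ``var_target`` (at least
    one), together with the full explained-variance-share vector.
    Components are conventionally named ``ctPC1`` ... .
    """
    x = props.proportions.to_numpy(float)
    if x.shape[1] < 2:
        raise ValueError("need at least two cell types")
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= 0:
        raise ValueError("cell-type proportions are constant; no variance to decompose")
    shares = var / total
    k = int(np.searchsorted(np.cumsum(shares), var_target) + 1)
    k = min(k, len(shares))
    scores = u[:, :k] * s[:k]
    cols = [f"ctPC{i + 1}" for i in range(k)]
    logger.info(
        "cell-type PCA: %d components explain %.1f%% (target %.0f%%)",
        k, 100 * shares[:k].sum(), 100 * var_target,
    )
    return pd.DataFrame(scores, index=props.proportions.index, columns=cols), shares


def batch_center(beta: BetaMatrix, batch: pd.Series) -> BetaMatrix:
    """Shift each batch's per-CpG mean onto the global mean.

    A simplified location-only batch adjustment; results are clipped to
    [0, 1] (clipping events are counted in the log).  Requires at least
    two samples per batch so batch means are estimable.
    """
    batch = pd.Series(batch).reindex(beta.samples)
    if batch.isna().any():
        raise ValueError("batch label missing for some samples")
    sizes = batch.value_counts()
    if (sizes < 2).any():
        bad = sizes.index[sizes < 2].tolist()
        raise ValueError(f"singleton batch(es): {bad}")

    v = beta.values.to_numpy(float).copy()
    global_mean = np.nanmean(v, axis=1, keepdims=True)
    for label in sizes.index:
        cols = (batch == label).to_numpy()
        batch_mean = np.nanmean(v[:, cols], axis=1, keepdims=True)
        v[:, cols] += global_mean - batch_mean
    n_clip = int(((v < 0) | (v > 1)).sum())
    if n_clip:
        logger.warning("batch centering clipped %d values into [0, 1]", n_clip)
    v = np.clip(v, 0.0, 1.0)
    out = pd.DataFrame(v, index=beta.cpgs, columns=beta.samples)
    return BetaMatrix(out, beta.annot.copy())


def m_values(beta: BetaMatrix, eps: float = 1e-6) -> pd.DataFrame:
    """log2(beta / (1 - beta)) with betas clipped away from {0, 1}."""
    b = beta.values.to_numpy(float).clip(eps, 1 - eps)
    return pd.DataFrame(np.log2(b / (1 - b)), index=beta.cpgs, columns=beta.samples)
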