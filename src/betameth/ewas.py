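"""Epigenome-wide association: per-CpG OLS with covariates and BH-FDR.

Each CpG's beta values are regressed on the exposure plus covariates
(child sex, gestational age, ancestry MDS axes, maternal age, smoking,
cell-type PCs, ...).  The exposure coefficient is on the beta scale:
an estimate of -0.027 means 2.7 percentage points lower methylation in
exposed samples.  P-values come from the t reference distribution with
residual degrees of freedom, exactly as ``summary(lm(...))`` would give.

The scan is vectorised: one shared design matrix is factorised once and
applied to all CpGs with a common missingness pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .methylation import BetaMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CovariateSet",
    "design_matrix",
    "fit_cpg_model",
    "run_ewas",
    "bh_adjust",
    "group_mean_difference",
    "GENOMEWIDE_P",
    "PRIMARY_COVARIATES",
    "SENSITIVITY_COVARIATES",
]

#: Epigenome-wide significance threshold for 450K/EPIC-scale scans.
GENOMEWIDE_P = 9e-8

#: Covariate presets. The primary adjustment set for the exposure model,
#: and a sensitivity set adding obstetric covariates.
PRIMARY_COVARIATES = [
    "sex", "gestational_age", "PC1", "PC2", "PC3", "PC4",
    "maternal_age", "smoking", "ctPC1", "ctPC2",
]
SENSITIVITY_COVARIATES = PRIMARY_COVARIATES + ["delivery_cs", "labor", "parity"]


@dataclass
class CovariateSet:
    """Sample-by-covariate table plus the name of the tested exposure term.

    ``categorical`` columns are dummy-coded (first level dropped); all
    other columns enter numerically.  The exposure must be binary 0/1.
    """

    data: pd.DataFrame
    exposure: str = "BET"
    categorical: tuple = ()

    def __post_init__(self):
        if self.exposure in self.data.columns:
            vals = set(pd.unique(self.data[self.exposure].dropna()))
            if not vals <= {0, 1, 0.0, 1.0, True, False}:
                raise ValueError(f"exposure column {self.exposure!r} must be binary 0/1")

    def columns_for(self, terms: list[str]) -> pd.DataFrame:
        missing = [t for t in terms if t not in self.data.columns]
        if missing:
            raise KeyError(f"covariate columns not found: {missing}")
        return self.data[terms]


def design_matrix(
    covariates: CovariateSet,
    terms: list[str],
) -> tuple[np.ndarray, list[str]]:
    """Build an intercept-first design matrix from named covariate columns.

    Categorical columns are expanded to dummy indicators with the first
    (sorted) level as reference.  Returns the matrix and column names.
    """
    df = covariates.columns_for(terms)
    cols: list[pd.Series] = []
    names = ["(Intercept)"]
    for term in terms:
        s = df[term]
        if term in covariates.categorical or s.dtype == object:
            levels = sorted(pd.unique(s.dropna()))
            for lev in levels[1:]:
                cols.append((s == lev).astype(float).rename(f"{term}[{lev}]"))
                names.append(f"{term}[{lev}]")
        else:
            cols.append(s.astype(float))
            names.append(term)
    x = np.column_stack([np.ones(len(df))] + [c.to_numpy() for c in cols])
    return x, names


def _check_full_rank(x: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify offending columns via pivoted QR magnitudes
        _, r = np.linalg.qr(x)
        small = [names[i] for i in range(x.shape[1]) if abs(r[i, i]) < 1e-8 * abs(r[0, 0])]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {x.shape[1]}); "
            f"collinear columns: {small or 'unidentified'}"
        )


def ols_multi(x: np.ndarray, y: np.ndarray, names: list[str]) -> dict:
    """OLS of many response columns on one shared design matrix.

    Parameters
    ----------
    x : (n, p) design matrix, full rank.
    y : (n, m) response matrix.

    Returns a dict with ``coef`` (p, m), ``se`` (p, m), ``t``, ``p``,
    ``rss`` (m,), ``df_resid`` and ``names``.  Responses with zero
    residual variance get NaN standard errors and p-values.
    """
    n, p = x.shape
    if n <= p:
        raise ValueError(f"not enough observations (n={n}) for {p} parameters")
    _check_full_rank(x, names)
    xtx_inv = np.linalg.inv(x.T @ x)
    coef = xtx_inv @ x.T @ y
    resid = y - x @ coef
    rss = np.einsum("ij,ij->j", resid, resid)
    df_resid = n - p
    sigma2 = rss / df_resid
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
        tval = coef / se
    pval = 2 * stats.t.sf(np.abs(tval), df_resid)
    degenerate = sigma2 <= np.finfo(float).eps * np.abs(y).max(axis=0, initial=1.0) ** 2
    if degenerate.any():
        se[:, degenerate] = np.nan
        tval[:, degenerate] = np.nan
        pval[:, degenerate] = np.nan
    return {
        "coef": coef, "se": se, "t": tval, "p": pval,
        "rss": rss, "df_resid": df_resid, "names": names,
        "degenerate": degenerate,
    }


def fit_cpg_model(
    y: pd.Series | np.ndarray,
    covariates: CovariateSet,
    term: str,
    extra_terms: list[str] | None = None,
) -> pd.Series:
    """Fit one CpG's covariate-adjusted linear model and test ``term``.

    The design holds every column of ``extra_terms`` (default: all
    covariate columns except ``term``) plus ``term`` itself.  Samples
    with a missing response or covariate are dropped (complete-case).

    Returns a Series with ``estimate``, ``se``, ``t``, ``p``, ``n`` and
    ``degenerate`` (True when the response has no residual variance, in
    which case p is NaN).
    """
    y = pd.Series(np.asarray(y, dtype=float), index=covariates.data.index)
    terms = list(extra_terms) if extra_terms is not None else [
        c for c in covariates.data.columns if c != term
    ]
    if term not in terms:
        terms = terms + [term]
    sub = covariates.columns_for(terms)
    ok = (~y.isna()) & (~sub.isna().any(axis=1))
    cov_cc = CovariateSet(covariates.data.loc[ok], covariates.exposure, covariates.categorical)
    x, names = design_matrix(cov_cc, terms)
    res = ols_multi(x, y[ok].to_numpy()[:, None], names)
    # a categorical test term would expand to several columns; the single
    # tested coefficient interface covers numeric/binary terms only
    j = names.index(term)
    return pd.Series(
        {
            "estimate": res["coef"][j, 0],
            "se": res["se"][j, 0],
            "t": res["t"][j, 0],
            "p": res["p"][j, 0],
            "n": int(ok.sum()),
            "degenerate": bool(res["degenerate"][0]),
        }
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    NaN entries are passed through untouched and do not count toward m.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if (p[ok] < 0).any() or (p[ok] > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def group_mean_difference(y, exposure) -> float:
    """mean(exposed) - mean(control) of a beta vector.

    Multiply by 100 for percentage points.
    """
    y = np.asarray(y, dtype=float)
    e = np.asarray(exposure).astype(bool)
    if e.sum() == 0 or (~e).sum() == 0:
        raise ValueError("both exposure groups must be non-empty")
    return float(np.nanmean(y[e]) - np.nanmean(y[~e]))


def run_ewas(
    beta: BetaMatrix,
    covariates: CovariateSet,
    term: str | None = None,
    genomewide_p: float = GENOMEWIDE_P,
) -> pd.DataFrame:
    """Covariate-adjusted association scan over every CpG.

    Returns a DataFrame sorted by p ascending with columns: estimate, se,
    t, p, q (BH over all tested CpGs), genomewide (p < ``genomewide_p``),
    mean_diff (exposed - control, beta scale), n, chrom, pos and
    neg_log10_p.  CpGs whose model is degenerate keep NaN p and are
    excluded from the BH adjustment.
    """
    term = term or covariates.exposure
    samples = [s for s in beta.samples if s in covariates.data.index]
    if len(samples) < len(beta.samples):
        logger.warning("%d samples lack covariates and are dropped", len(beta.samples) - len(samples))
    cov = CovariateSet(covariates.data.loc[samples], covariates.exposure, covariates.categorical)
    terms = [c for c in cov.data.columns if c != term] + [term]
    cov_ok = ~cov.data[terms].isna().any(axis=1)
    cov = CovariateSet(cov.data.loc[cov_ok], cov.exposure, cov.categorical)

    y_all = beta.values[cov.data.index].to_numpy(float).T  # samples x cpgs
    x, names = design_matrix(cov, terms)
    j = names.index(term)
    exposure = cov.data[term].to_numpy(float).astype(bool)

    n_samp, n_cpg = y_all.shape
    est = np.full(n_cpg, np.nan)
    se = np.full(n_cpg, np.nan)
    tv = np.full(n_cpg, np.nan)
    pv = np.full(n_cpg, np.nan)
    nn = np.zeros(n_cpg, dtype=int)
    mdiff = np.full(n_cpg, np.nan)

    # group CpGs by their sample-missingness pattern so each pattern is
    # solved in one vectorised pass
    nan_mask = np.isnan(y_all)
    patterns, inverse = np.unique(nan_mask, axis=1, return_inverse=True)
    for pi in range(patterns.shape[1]):
        cpg_idx = np.where(inverse == pi)[0]
        keep = ~patterns[:, pi]
        if keep.sum() <= x.shape[1]:
            logger.warning("skipping %d CpGs: too few complete observations", len(cpg_idx))
            continue
        res = ols_multi(x[keep], y_all[np.ix_(keep, cpg_idx)], names)
        est[cpg_idx] = res["coef"][j]
        se[cpg_idx] = res["se"][j]
        tv[cpg_idx] = res["t"][j]
        pv[cpg_idx] = res["p"][j]
        nn[cpg_idx] = int(keep.sum())
        e = exposure[keep]
        ysub = y_all[np.ix_(keep, cpg_idx)]
        mdiff[cpg_idx] = ysub[e].mean(axis=0) - ysub[~e].mean(axis=0)

    out = pd.DataFrame(
        {
            "estimate": est, "se": se, "t": tv, "p": pv,
            "q": bh_adjust(pv),
            "genomewide": pv < genomewide_p,
            "mean_diff": mdiff,
            "n": nn,
        },
        index=beta.cpgs,
    )
    out["chrom"] = beta.annot["chrom"]
    out["pos"] = beta.annot["pos"]
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(out["p"])
    out = out.sort_values("p")
    n_hit = int(out["genomewide"].sum())
    logger.info("EWAS on %r: %d/%d CpGs epigenome-wide significant (p<%g)",
                term, n_hit, len(out), genomewide_p)
    return out
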