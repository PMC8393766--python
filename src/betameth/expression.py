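"""Expression-count preprocessing and methylation-expression (eQTM) tests.

Raw 3' RNA-seq gene counts are filtered for adequate coverage, normalised
with median-of-ratios size factors, and log2-transformed.  The eQTM test
correlates one CpG's beta values with one gene's transformed expression
(Pearson, two-sided t-transform p); an optional covariate-adjusted
variant residualises both variables first (partial correlation).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "filter_counts",
    "size_factors",
    "normalize_transform",
    "pearson_test",
    "eqtm",
    "median_split",
]


def filter_counts(
    counts: pd.DataFrame,
    min_count: int = 10,
    min_frac: float = 0.90,
) -> pd.DataFrame:
    """Keep genes with >= ``min_count`` raw counts in >= ``min_frac`` of samples.

    Both boundaries are inclusive.  Idempotent by construction.
    """
    c = counts.to_numpy()
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    qual_frac = (c >= min_count).mean(axis=1)
    keep = qual_frac >= min_frac
    if keep.sum() == 0:
        logger.warning("count filter removed every gene")
    logger.info("count filter (>=%d in >=%g%%): kept %d/%d genes",
                min_count, 100 * min_frac, int(keep.sum()), len(keep))
    return counts.loc[keep]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    The reference is the per-gene geometric mean over genes expressed in
    every sample; each sample's factor is the median ratio of its counts
    to the reference.  Falls back to library-size factors (scaled to
    geometric mean one) when no gene is all-positive.
    """
    c = counts.to_numpy(float)
    all_pos = (c > 0).all(axis=1)
    if not all_pos.any():
        logger.warning("no gene expressed in all samples; using library-size factors")
        lib = c.sum(axis=0)
        sf = lib / np.exp(np.mean(np.log(lib)))
    else:
        logc = np.log(c[all_pos])
        ref = logc.mean(axis=1, keepdims=True)  # log geometric mean per gene
        sf = np.exp(np.median(logc - ref, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize_transform(counts: pd.DataFrame) -> pd.DataFrame:
    """Size-factor-normalised log2 expression: log2(count / sf + 1).

    A simple variance-stabilising stand-in for count data; size factors
    are logged.  Accepting an externally produced transformed matrix
    instead is always possible since downstream stages only require a
    gene-by-sample numeric frame.
    """
    sf = size_factors(counts)
    logger.info("size factors: min %.3f median %.3f max %.3f",
                sf.min(), sf.median(), sf.max())
    return np.log2(counts.div(sf, axis=1) + 1.0)


def pearson_test(x, y) -> tuple[float, float, int]:
    """Pearson r with a two-sided p from the t transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the vectors")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n


def _residualize(v: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Residuals of v on [1, z] by least squares."""
    x = np.column_stack([np.ones(len(v)), z])
    coef, *_ = np.linalg.lstsq(x, v, rcond=None)
    return v - x @ coef


def eqtm(
    meth,
    expr,
    covariates: pd.DataFrame | None = None,
) -> pd.Series:
    """Expression-quantitative-trait-methylation correlation test.

    Parameters
    ----------
    meth : array-like
        One CpG's beta values across samples.
    expr : array-like
        One gene's transformed expression, same sample order.
    covariates : DataFrame, optional
        Numeric covariates; when given, both variables are residualised
        on them and the partial correlation is reported alongside the
        unadjusted one (p with n - 2 - k degrees of freedom).

    Returns
    -------
    pandas.Series
        ``r``, ``p``, ``n`` and, when adjusted, ``r_adj``, ``p_adj``.
    """
    m = np.asarray(meth, dtype=float)
    e = np.asarray(expr, dtype=float)
    r, p, n = pearson_test(m, e)
    out = {"r": r, "p": p, "n": n}
    if covariates is not None:
        z = covariates.to_numpy(float)
        ok = ~(np.isnan(m) | np.isnan(e) | np.isnan(z).any(axis=1))
        mr = _residualize(m[ok], z[ok])
        er = _residualize(e[ok], z[ok])
        k = z.shape[1]
        n_adj = int(ok.sum())
        r_adj = float(np.corrcoef(mr, er)[0, 1])
        df = n_adj - 2 - k
        if df < 1:
            raise ValueError("not enough observations for the adjusted correlation")
        t = r_adj * np.sqrt(df / (1 - r_adj**2))
        out.update(r_adj=r_adj, p_adj=float(2 * stats.t.sf(abs(t), df)), n_adj=n_adj)
    return pd.Series(out)


def median_split(values) -> tuple[pd.Series, float]:
    """Binary LOW/HIGH labels at the median (values <= median are LOW).

    Returns the labels and the median used.  Raises when all values are
    identical (the split would be degenerate).
    """
    v = pd.Series(values).astype(float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    if v.nunique() < 2:
        raise ValueError("all values identical; median split is degenerate")
    med = float(v.median())
    labels = pd.Series(np.where(v <= med, "LOW", "HIGH"), index=v.index)
    return labels, med
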