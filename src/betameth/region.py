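"""Targeted-panel fine-mapping models around a focal locus.

For a CpG panel measured by targeted bisulfite sequencing the module
fits, per CpG:

* an exposure model (as in the epigenome-wide scan, plus sequencing
  plate as a categorical covariate),
* a SNP main-effect model (additive 0/1/2 dosage),
* a nested comparison testing whether adding the exposure improves the
  genotype-only model (extra-sum-of-squares F; identical to the squared
  t of the added coefficient),
* a SNP x exposure interaction model,

and adjusts each p-value column by BH-FDR across the whole panel.
A binomial direction-consistency statistic summarises how many nominal
hits share an effect direction under a fair-coin null.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .ewas import CovariateSet, bh_adjust, design_matrix, ols_multi
from .methylation import BetaMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "fit_snp_model",
    "additive_comparison",
    "interaction_test",
    "direction_consistency",
    "region_fdr",
    "run_region_models",
    "dominant_recode",
    "genotype_group_labels",
]


def _complete_cases(y: pd.Series, covariates: CovariateSet, extra: dict) -> tuple:
    """Align response, covariates and extra numeric columns; drop NaN rows."""
    df = covariates.data.copy()
    for name, vec in extra.items():
        df[name] = np.asarray(vec, dtype=float)
    y = pd.Series(np.asarray(y, dtype=float), index=covariates.data.index)
    ok = (~y.isna()) & (~df.isna().any(axis=1))
    return y[ok].to_numpy(), CovariateSet(df.loc[ok], covariates.exposure, covariates.categorical)


def _single_term_fit(y, cov: CovariateSet, terms: list[str], term: str) -> pd.Series:
    x, names = design_matrix(cov, terms)
    res = ols_multi(x, y[:, None], names)
    j = names.index(term)
    return pd.Series(
        {
            "estimate": res["coef"][j, 0],
            "se": res["se"][j, 0],
            "t": res["t"][j, 0],
            "p": res["p"][j, 0],
            "n": len(y),
        }
    )


def fit_snp_model(
    y: pd.Series | np.ndarray,
    covariates: CovariateSet,
    snp: pd.Series | np.ndarray,
) -> pd.Series:
    """Additive SNP main-effect model on one CpG's beta values.

    The design is the exposure-model covariate set plus the dosage term;
    samples with a missing dosage are dropped (never imputed).  Raises
    when the remaining dosages are constant.
    """
    yv, cov = _complete_cases(y, covariates, {"snp": snp})
    if np.unique(cov.data["snp"]).size < 2:
        raise ValueError("SNP dosage has no variance among complete cases")
    terms = [c for c in covariates.data.columns] + ["snp"]
    return _single_term_fit(yv, cov, terms, "snp")


def additive_comparison(
    y,
    covariates: CovariateSet,
    snp,
    exposure=None,
) -> pd.Series:
    """Does adding the exposure improve the genotype-only model?

    Extra-sum-of-squares F test of the nested pair

        base: beta ~ covariates + snp
        full: beta ~ covariates + snp + exposure

    ``F = ((RSS0 - RSS1)/1) / (RSS1/df1)`` with p from F(1, df1).  The
    identity F == t^2 of the added coefficient holds and is verified on
    every call (logged self-check).
    """
    extra = {"snp": snp}
    if exposure is not None:
        extra["_exposure"] = exposure
        expo_term = "_exposure"
    else:
        expo_term = covariates.exposure
    yv, cov = _complete_cases(y, covariates, extra)
    base_terms = [c for c in covariates.data.columns if c != expo_term] + ["snp"]
    full_terms = base_terms + [expo_term]

    x0, n0 = design_matrix(cov, base_terms)
    x1, n1 = design_matrix(cov, full_terms)
    if np.linalg.matrix_rank(x1) == np.linalg.matrix_rank(x0):
        # the added column lies in the span of the base design (e.g. the
        # exposure duplicates a base covariate): no improvement possible
        res0 = ols_multi(x0, yv[:, None], n0)
        return pd.Series({"F": 0.0, "p": 1.0, "rss_base": res0["rss"][0],
                          "rss_full": res0["rss"][0],
                          "df_resid": res0["df_resid"], "n": len(yv)})
    res0 = ols_multi(x0, yv[:, None], n0)
    res1 = ols_multi(x1, yv[:, None], n1)
    rss0, rss1 = res0["rss"][0], res1["rss"][0]
    df1 = res1["df_resid"]
    f = max(0.0, (rss0 - rss1)) / (rss1 / df1)
    p = stats.f.sf(f, 1, df1)
    t_add = res1["t"][n1.index(expo_term), 0]
    if np.isfinite(t_add) and not np.isclose(f, t_add**2, rtol=1e-8, atol=1e-10):
        logger.warning("F != t^2 self-check failed: F=%.6g t^2=%.6g", f, t_add**2)
    return pd.Series({"F": f, "p": p, "rss_base": rss0, "rss_full": rss1,
                      "df_resid": df1, "n": len(yv)})


def interaction_test(
    y,
    covariates: CovariateSet,
    snp,
    exposure=None,
) -> pd.Series:
    """Test the SNP x exposure product term, main effects retained.

    Returns the product coefficient's statistics plus the per-sample
    genotype-by-exposure group labels used for plotting conventions
    (``BET.CC``, ``no BET.CT``, ...).  Sparse genotype-by-exposure cells
    trigger a warning with the cell counts.
    """
    extra = {"snp": snp}
    expo_term = covariates.exposure
    if exposure is not None:
        extra["_exposure"] = exposure
        expo_term = "_exposure"
    yv, cov = _complete_cases(y, covariates, extra)
    e = cov.data[expo_term].to_numpy(float)
    d = cov.data["snp"].to_numpy(float)
    if np.unique(e).size < 2:
        raise ValueError("exposure is constant; the product term has no variance")
    if np.unique(d).size < 2:
        raise ValueError("SNP dosage is constant; the product term has no variance")
    cov.data["snp_x_exposure"] = d * e
    terms = [c for c in covariates.data.columns if c != expo_term]
    terms += ["snp", expo_term, "snp_x_exposure"]

    cells = pd.crosstab(d, e)
    if (cells < 6).any().any():
        # per-CpG log noise is pointless when every CpG shares the same
        # genotype/exposure table; run_region_models warns once
        logger.debug("sparse genotype-by-exposure cells:\n%s", cells.to_string())

    out = _single_term_fit(yv, cov, terms, "snp_x_exposure")
    out["cell_counts"] = cells
    return out


def genotype_group_labels(dosage, exposure, ref: str = "C", alt: str = "T") -> pd.Series:
    """Combined genotype/exposure labels, e.g. ``BET.CC`` or ``no BET.CT``."""
    geno = {0: ref + ref, 1: ref + alt, 2: alt + alt}
    d = pd.Series(dosage)
    e = pd.Series(exposure).astype(bool)
    lab = [
        ("BET." if ei else "no BET.") + geno.get(int(di), "NA") if not np.isnan(di) else "NA"
        for di, ei in zip(d, e)
    ]
    return pd.Series(lab, index=d.index)


def dominant_recode(dosage, carrier_genotype: int = 2) -> np.ndarray:
    """Recode additive dosage to a 0/1 carrier indicator.

    ``carrier_genotype=2`` contrasts alt-homozygotes (e.g. TT) against
    the pooled other genotypes (CT/CC).
    """
    d = np.asarray(dosage, dtype=float)
    out = np.where(np.isnan(d), np.nan, (d >= carrier_genotype).astype(float))
    return out


def direction_consistency(k_same: int, n_total: int) -> dict:
    """Fair-coin binomial probability of k of n effects sharing a direction.

    Returns both the point probability P(X = k) and the upper-tail
    probability P(X >= k) under X ~ Binomial(n, 1/2): reporting
    conventions differ between studies, so neither is chosen silently.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= k_same <= n_total:
        raise ValueError("k_same must lie in [0, n_total]")
    return {
        "point": float(stats.binom.pmf(k_same, n_total, 0.5)),
        "tail": float(stats.binom.sf(k_same - 1, n_total, 0.5)),
    }


def region_fdr(results: pd.DataFrame, p_cols: list[str] | None = None) -> pd.DataFrame:
    """Add BH q-value columns across the whole CpG panel.

    Every column named ``*_p`` (or those given in ``p_cols``) gets a
    matching ``*_q`` column adjusted over all panel CpGs; the FDR is
    controlled over all investigated sites, not per region.
    """
    out = results.copy()
    cols = p_cols if p_cols is not None else [c for c in out.columns if c.endswith("_p")]
    for c in cols:
        out[c.removesuffix("_p") + "_q"] = bh_adjust(out[c].to_numpy(float))
    return out


def run_region_models(
    region_beta: BetaMatrix,
    covariates: CovariateSet,
    snp: pd.Series,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Fit all four fine-mapping models for every panel CpG.

    Returns one row per CpG with region label, per-model estimates and
    p-values, and BH q-values over the panel.  Per-CpG model failures
    (e.g. degenerate response) are recorded, not fatal.
    """
    snp = pd.Series(snp).reindex(covariates.data.index)
    expo = covariates.data[covariates.exposure]
    cells = pd.crosstab(snp.dropna(), expo[snp.notna()])
    if (cells < 6).any().any():
        logger.warning("sparse genotype-by-exposure cells (interaction "
                       "estimates unstable):\n%s", cells.to_string())
    rows = []
    for cpg in region_beta.cpgs:
        y = region_beta.values.loc[cpg].reindex(covariates.data.index)
        row: dict = {"cpg": cpg, "region": region_beta.annot.loc[cpg].get("region", "")}
        try:
            m_expo = _exposure_model(y, covariates)
            row.update(exposure_estimate=m_expo["estimate"], exposure_p=m_expo["p"])
            m_snp = fit_snp_model(y, covariates, snp)
            row.update(snp_estimate=m_snp["estimate"], snp_p=m_snp["p"], n=int(m_snp["n"]))
            m_add = additive_comparison(y, covariates, snp)
            row.update(additive_F=m_add["F"], additive_p=m_add["p"])
            m_int = interaction_test(y, covariates, snp)
            row.update(interaction_estimate=m_int["estimate"], interaction_p=m_int["p"])
        except Exception as exc:  # noqa: BLE001 - per-CpG failures are reported
            row["error"] = str(exc)
            logger.warning("region model failed for %s: %s", cpg, exc)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("cpg")
    table = region_fdr(table)
    for model in ("exposure", "snp", "additive", "interaction"):
        qc = f"{model}_q"
        if qc in table:
            n_sig = int((table[qc] < fdr).sum())
            logger.info("%s model: %d/%d panel CpGs significant at FDR %g",
                        model, n_sig, len(table), fdr)
    return table


def _exposure_model(y, covariates: CovariateSet) -> pd.Series:
    """Exposure model on the panel covariates (without the SNP term)."""
    yv, cov = _complete_cases(y, covariates, {})
    terms = [c for c in covariates.data.columns if c != covariates.exposure]
    terms += [covariates.exposure]
    return _single_term_fit(yv, cov, terms, covariates.exposure)
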