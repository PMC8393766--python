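"""Independent brute-force oracles used by several test modules.

These deliberately re-derive each statistic by the most literal route
available (exact fractions, full enumeration, normal equations) and
never share code with the implementation they check.
"""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np


def hwe_exact_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> Fraction:
    """Exact HWE p by full enumeration with rational arithmetic."""
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = n_het + 2 * n_hom_alt
    probs = {}
    total = Fraction(0)
    for h in range(n_alt % 2, min(n_alt, 2 * n - n_alt) + 1, 2):
        n_aa = (n_alt - h) // 2
        n_rr = n - h - n_aa
        if n_rr < 0:
            continue
        # multinomial count of genotype configurations x 2^h orderings of
        # alleles within heterozygotes, conditioned on the allele counts
        w = Fraction(
            comb(n, h) * comb(n - h, n_aa) * 2**h
        )
        probs[h] = w
        total += w
    probs = {h: w / total for h, w in probs.items()}
    p_obs = probs[n_het]
    return sum(p for p in probs.values() if p <= p_obs)


def bh_oracle(pvals) -> np.ndarray:
    """Literal step-up BH: sort, take running minima of m*p/(rank)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = np.inf
    for i in range(m - 1, -1, -1):
        running = min(running, m * p[order[i]] / (i + 1))
        q_sorted[i] = min(1.0, running)
    out = np.empty(m)
    out[order] = q_sorted
    return out


def normal_equations_oracle(x: np.ndarray, y: np.ndarray) -> dict:
    """OLS coefficients/SEs straight from (X'X)^{-1}X'y."""
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    df = x.shape[0] - x.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    return {"coef": beta, "se": se, "df": df}


def tom_oracle(adj: np.ndarray) -> np.ndarray:
    """Triple-loop topological overlap."""
    a = adj.copy().astype(float)
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = a.sum(axis=0)
    t = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n))
            t[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return t


def hypergeom_tail_oracle(n_universe: int, n_set: int, n_draws: int, k: int) -> Fraction:
    """P(X >= k) by summing the exact hypergeometric pmf."""
    total = Fraction(0)
    for kk in range(k, min(n_set, n_draws) + 1):
        total += Fraction(comb(n_set, kk) * comb(n_universe - n_set, n_draws - kk),
                          comb(n_universe, n_draws))
    return total


def enrichment_enumeration_oracle(universe: list, gene_set: set, module: set, k_obs: int) -> Fraction:
    """P(overlap >= k) by enumerating every module-sized subset."""
    n_hits = 0
    n_total = 0
    for draw in combinations(universe, len(module)):
        n_total += 1
        if len(gene_set & set(draw)) >= k_obs:
            n_hits += 1
    return Fraction(n_hits, n_total)
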