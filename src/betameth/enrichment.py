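"""Gene-set overlap and enrichment statistics.

Two tests against an explicit background ("universe" = the genes that
actually survived expression preprocessing):

* a permutation test for the overlap between a co-expression module and
  an external gene signature — B random signature-sized draws from the
  universe, add-one empirical p ``(b + 1) / (B + 1)`` with ties counted
  as extreme (``>= observed``), so the p-value is never zero;
* a hypergeometric upper-tail enrichment over a gene-set collection with
  BH-FDR across sets.

A direction-concordance summary counts sign agreement between two
studies' effect estimates on the overlap genes; its binomial probability
comes from :func:`betameth.region.direction_consistency`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ewas import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "OverlapTestResult",
    "read_gmt",
    "write_gmt",
    "restrict_to_universe",
    "overlap_permutation_test",
    "concordance_summary",
    "hypergeom_enrichment",
]


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions (GMT-style)."""

    sets: dict  # name -> list of member gene ids (deduplicated)
    descriptions: dict

    def __post_init__(self):
        clean = {}
        for name, members in self.sets.items():
            members = list(dict.fromkeys(str(g) for g in members))  # dedupe, keep order
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            clean[name] = members
        self.sets = clean
        for name in self.sets:
            self.descriptions.setdefault(name, "")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str) -> GeneSetCollection:
    """Read a tab-separated GMT file (name, description, members...)."""
    sets, desc = {}, {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets[parts[0]] = parts[2:]
            desc[parts[0]] = parts[1]
    return GeneSetCollection(sets, desc)


def write_gmt(collection: GeneSetCollection, path: str) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, collection.descriptions.get(name, "")] + list(members)) + "\n")


@dataclass
class OverlapTestResult:
    observed: int
    universe_size: int
    signature_size: int
    module_size: int
    B: int
    b: int  # permuted overlaps >= observed
    empirical_p: float
    max_permuted: int
    seed: int

    def as_series(self) -> pd.Series:
        return pd.Series(self.__dict__)


def restrict_to_universe(signature: list, universe: list) -> list:
    """Intersect a signature with the universe, preserving signature order."""
    uni = set(universe)
    kept = [g for g in signature if g in uni]
    logger.info("signature restricted to universe: %d of %d retained (%d dropped)",
                len(kept), len(signature), len(signature) - len(kept))
    if not kept:
        raise ValueError("signature and universe are disjoint")
    return kept


def overlap_permutation_test(
    module: list,
    signature: list,
    universe: list,
    B: int = 1000,
    seed: int = 0,
) -> OverlapTestResult:
    """Permutation null for the module/signature overlap.

    Each of the ``B`` permutations draws ``len(signature)`` genes
    uniformly without replacement from the universe and counts its
    overlap with the module.  ``b`` counts permuted overlaps at least as
    large as the observed one and the empirical p is ``(b+1)/(B+1)``,
    so a result more extreme than every permutation gives ``1/(B+1)``
    (9.99e-4 at the default B = 1000), never zero.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    universe = list(dict.fromkeys(universe))
    uni_set = set(universe)
    if len(set(signature)) > len(universe):
        raise ValueError("signature is larger than the universe")
    signature = [g for g in signature if g in uni_set]
    if not signature:
        raise ValueError("signature and universe are disjoint")
    module_in = uni_set & set(module)
    observed = len(module_in & set(signature))

    rng = np.random.default_rng(seed)
    is_module = np.isin(np.array(universe), np.array(list(module_in)))
    n_sig = len(signature)
    overlaps = np.empty(B, dtype=int)
    for i in range(B):
        draw = rng.choice(len(universe), size=n_sig, replace=False)
        overlaps[i] = int(is_module[draw].sum())
    b = int((overlaps >= observed).sum())
    result = OverlapTestResult(
        observed=observed,
        universe_size=len(universe),
        signature_size=n_sig,
        module_size=len(module_in),
        B=B,
        b=b,
        empirical_p=(b + 1) / (B + 1),
        max_permuted=int(overlaps.max()),
        seed=seed,
    )
    logger.info("overlap test: observed %d, max permuted %d, empirical p = %.3g",
                observed, result.max_permuted, result.empirical_p)
    return result


def concordance_summary(
    module_effects: pd.Series,
    signature_effects: pd.Series,
) -> dict:
    """Count direction-concordant and discordant genes over the overlap.

    Both inputs are signed effect values indexed by gene; only genes
    present in both enter.  Zero effects carry no direction and are
    excluded with a warning.
    """
    common = module_effects.index.intersection(signature_effects.index)
    a = np.sign(module_effects.loc[common].to_numpy(float))
    b = np.sign(signature_effects.loc[common].to_numpy(float))
    nonzero = (a != 0) & (b != 0)
    n_zero = int((~nonzero).sum())
    if n_zero:
        logger.warning("%d overlap genes with zero effect excluded from concordance", n_zero)
    same = int((a[nonzero] == b[nonzero]).sum())
    opposite = int(nonzero.sum()) - same
    return {"same": same, "opposite": opposite, "n": int(nonzero.sum()),
            "excluded_zero": n_zero}


def hypergeom_enrichment(
    module: list,
    collection: GeneSetCollection,
    universe: list,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of a module over gene sets.

    For each set: population = universe (size N), successes = set
    restricted to the universe (size K), draws = module (size n, must be
    contained in the universe), observed overlap k;
    ``p = P(X >= k)``.  Sets emptied by the universe restriction are
    dropped.  q is BH across all tested sets; ``ratio = k / K``.
    """
    uni = list(dict.fromkeys(universe))
    uni_set = set(uni)
    module = list(dict.fromkeys(module))
    outside = [g for g in module if g not in uni_set]
    if outside:
        raise ValueError(
            f"{len(outside)} module genes outside the universe (e.g. {outside[:3]})"
        )
    n_uni = len(uni)
    n_mod = len(module)
    mod_set = set(module)

    rows = []
    for name, members in collection.sets.items():
        in_uni = [g for g in members if g in uni_set]
        if not in_uni:
            continue
        k = len(mod_set & set(in_uni))
        K = len(in_uni)
        p = float(stats.hypergeom.sf(k - 1, n_uni, K, n_mod))
        rows.append(
            {
                "set": name,
                "description": collection.descriptions.get(name, ""),
                "overlap": k,
                "set_size": K,
                "module_size": n_mod,
                "universe_size": n_uni,
                "ratio": k / K,
                "p": p,
                "genes": ",".join(sorted(mod_set & set(in_uni))),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["set", "description", "overlap", "set_size", "module_size",
                     "universe_size", "ratio", "p", "q", "significant", "genes"]
        ).set_index("set")
    table = pd.DataFrame(rows).set_index("set")
    table["q"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = table["q"] < fdr
    table = table.sort_values("p")
    logger.info("enrichment: %d/%d sets significant at FDR %g",
                int(table.significant.sum()), len(table), fdr)
    return table
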