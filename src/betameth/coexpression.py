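"""Weighted co-expression networks, module detection and eigengenes.

The network is built from pairwise Pearson correlations of transformed
expression profiles: an unsigned adjacency ``|r|^beta`` with the soft
power ``beta`` chosen by the scale-free-fit criterion, turned into a
topological overlap matrix (TOM), clustered by average linkage on
``1 - TOM`` with a static tree cut.  Modules are named with the
conventional colour scheme ordered by size (largest = "turquoise"),
genes in clusters below the minimum size are labelled "grey".

Each module is summarised by its eigengene: the first principal
component of the member genes' standardised expression, oriented to
correlate positively with the mean member profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .expression import pearson_test

logger = logging.getLogger(__name__)

__all__ = [
    "MODULE_COLORS",
    "CoexpressionNetwork",
    "ModuleAssignment",
    "adjacency",
    "choose_soft_power",
    "tom",
    "detect_modules",
    "module_eigengene",
    "module_trait_correlation",
    "assign_eigengenes",
]

#: Size-ranked module colour names (the classic palette order).
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue",
]

UNASSIGNED = "grey"


@dataclass
class CoexpressionNetwork:
    """Adjacency + TOM for a gene set at a chosen soft power."""

    genes: list
    power: int
    kind: str  # "unsigned" or "signed"
    tom_matrix: np.ndarray
    connectivity: np.ndarray

    def __post_init__(self):
        t = self.tom_matrix
        if not np.allclose(t, t.T, atol=1e-10):
            raise ValueError("TOM must be symmetric")


@dataclass
class ModuleAssignment:
    """Gene-to-module map with per-module eigengenes."""

    labels: pd.Series  # gene -> colour label
    eigengenes: pd.DataFrame = field(default_factory=pd.DataFrame)  # samples x modules
    variance_explained: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts()

    def members(self, module: str) -> list:
        return self.labels.index[self.labels == module].tolist()


def adjacency(expr: pd.DataFrame, power: int, kind: str = "unsigned") -> np.ndarray:
    """Soft-thresholded adjacency from gene-gene Pearson correlations.

    ``expr`` is genes x samples.  Unsigned: ``|r|^power``;
    signed: ``((1+r)/2)^power``.  Diagonal is set to 1.
    """
    x = expr.to_numpy(float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 genes")
    r = np.corrcoef(x)
    r = np.clip(r, -1.0, 1.0)
    if kind == "unsigned":
        a = np.abs(r) ** power
    elif kind == "signed":
        a = ((1.0 + r) / 2.0) ** power
    else:
        raise ValueError(f"unknown adjacency kind {kind!r}")
    np.fill_diagonal(a, 1.0)
    return a


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """R^2 and slope of log10(freq) on log10(k) over connectivity bins."""
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 3:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    log_k, log_f = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        log_k.append(np.log10(k[sel].mean()))
        log_f.append(np.log10(sel.mean()))
    if len(log_k) < 3:
        return 0.0, 0.0
    lk, lf = np.array(log_k), np.array(log_f)
    slope, intercept = np.polyfit(lk, lf, 1)
    r = np.corrcoef(lk, lf)[0, 1]
    return float(r * r), float(slope)


def choose_soft_power(
    expr: pd.DataFrame,
    powers: list[int] | None = None,
    fit_target: float = 0.8,
    kind: str = "unsigned",
) -> tuple[int, pd.DataFrame]:
    """Smallest power whose scale-free fit R^2 reaches ``fit_target``.

    The fit requires a negative slope (a rising log-log fit is not
    scale-free) and must be sustained at the next power in the grid: the
    R^2 is estimated from ~10 binned points, so a single crossing of the
    target can be bin noise.  When no power qualifies, the power with
    the best R^2 is returned with a warning.  Also returns the per-power
    diagnostic table (R^2, slope, mean and max connectivity).
    """
    powers = powers or list(range(1, 21))
    rows = []
    for p in powers:
        a = adjacency(expr, p, kind)
        k = a.sum(axis=0) - 1.0
        r2, slope = scale_free_fit(k)
        rows.append({"power": p, "r2": r2, "slope": slope,
                     "mean_k": k.mean(), "max_k": k.max()})
    diag = pd.DataFrame(rows).set_index("power")
    fit_ok = (diag.r2 >= fit_target) & (diag.slope < 0)
    sustained = fit_ok & fit_ok.shift(-1, fill_value=True)
    qualifying = diag[sustained]
    if len(qualifying):
        power = int(qualifying.index[0])
    else:
        power = int(diag.r2.idxmax())
        logger.warning(
            "no power reached scale-free fit R^2 >= %.2f; using power %d (R^2=%.2f)",
            fit_target, power, diag.r2.max(),
        )
    logger.info("soft power %d selected (R^2=%.3f)", power, diag.loc[power, "r2"])
    return power, diag


def tom(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a symmetric adjacency.

    ``TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)``
    for i != j, with the diagonal removed from all sums and the output
    diagonal set to 1.
    """
    a = np.asarray(adj, dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be square and symmetric")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=0)
    shared = a @ a
    num = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        t = num / denom
    np.fill_diagonal(t, 1.0)
    return t


def detect_modules(
    net: CoexpressionNetwork,
    min_size: int = 30,
    cut_height: float = 0.99,
) -> ModuleAssignment:
    """Average-linkage clustering of 1 - TOM with a static tree cut.

    The dendrogram is cut at ``cut_height`` of the merge-height range
    (``h_min + cut_height * (h_max - h_min)``), which keeps the cut
    meaningful when high soft powers compress all TOM values towards
    zero; clusters smaller than ``min_size`` are relabelled ``"grey"``.
    Remaining modules get colour names in decreasing size order, so the
    largest module is always "turquoise".  Fully deterministic given the
    network and parameters.
    """
    n = len(net.genes)
    if min_size > n:
        raise ValueError("min_size exceeds the number of genes")
    dissim = 1.0 - net.tom_matrix
    np.fill_diagonal(dissim, 0.0)
    z = linkage(squareform(dissim, checks=False), method="average")
    h_min, h_max = z[:, 2].min(), z[:, 2].max()
    raw = fcluster(z, t=h_min + cut_height * (h_max - h_min), criterion="distance")
    labels = pd.Series(raw, index=net.genes)
    sizes = labels.value_counts()
    keep = sizes.index[sizes >= min_size]
    # colour order: decreasing size, cluster id as deterministic tie-break
    order = sorted(keep, key=lambda c: (-sizes[c], c))
    mapping = {c: MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i + 1}"
               for i, c in enumerate(order)}
    named = labels.map(lambda c: mapping.get(c, UNASSIGNED))
    n_grey = int((named == UNASSIGNED).sum())
    logger.info("detected %d modules (sizes %s); %d genes unassigned",
                len(order), [int(sizes[c]) for c in order], n_grey)
    return ModuleAssignment(
        labels=named,
        params={"min_size": min_size, "cut_height": cut_height,
                "power": net.power, "kind": net.kind},
    )


def module_eigengene(
    expr: pd.DataFrame,
    members: list,
) -> tuple[pd.Series, float]:
    """First principal component of the standardised member profiles.

    ``expr`` is genes x samples.  Member profiles are standardised per
    gene; the eigengene is the first right-singular vector in sample
    space, sign-oriented to correlate positively with the mean
    standardised member profile.  Returns (eigengene, variance explained).
    """
    members = list(members)
    if len(members) < 2:
        raise ValueError("a module needs at least 2 member genes")
    missing = [g for g in members if g not in expr.index]
    if missing:
        raise KeyError(f"member genes absent from the expression matrix: {missing[:5]}")
    x = expr.loc[members].to_numpy(float)
    sd = x.std(axis=1, ddof=0)
    if (sd == 0).any():
        raise ValueError("constant expression profile among module members")
    xs = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    eig = vt[0]
    mean_profile = xs.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    var_explained = float(s[0] ** 2 / (s**2).sum())
    return pd.Series(eig, index=expr.columns, name="eigengene"), var_explained


def module_trait_correlation(eigengene, trait) -> pd.Series:
    """Pearson correlation of a module eigengene with a sample trait."""
    r, p, n = pearson_test(eigengene, trait)
    return pd.Series({"r": r, "p": p, "n": n})


def assign_eigengenes(expr: pd.DataFrame, assignment: ModuleAssignment) -> ModuleAssignment:
    """Fill in eigengenes and variance-explained for every named module."""
    eigs = {}
    var = {}
    for module in assignment.sizes.index:
        if module == UNASSIGNED:
            continue
        e, v = module_eigengene(expr, assignment.members(module))
        eigs[module] = e
        var[module] = v
    assignment.eigengenes = pd.DataFrame(eigs)
    assignment.variance_explained = var
    return assignment
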