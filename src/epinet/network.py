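"""Signed weighted coexpression network, modules, eigengenes and hubs.

The network is built the way the weighted gene coexpression framework
builds it.  Pairwise Pearson correlations of transformed expression are
mapped to edge weights by the signed adjacency

    a_ij = ((1 + cor(x_i, x_j)) / 2) ** beta

so perfectly anti-correlated genes get weight ~0 and the soft-threshold
power beta (default 16) suppresses weak correlations.  Gene-gene
similarity for clustering is the topological overlap

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

which credits shared neighborhoods.  Modules are average-linkage clusters
of 1 − TOM, small clusters fall into the unassigned "grey" bin, modules
with highly correlated eigengenes are merged, and survivors are named by
size with the conventional color sequence (turquoise largest).  A module
eigengene is the first principal component of the module's standardized
expression; module membership kME is each gene's correlation with it; hub
genes sit in the top decile of intramodular connectivity with kME > 0.9
at membership p < 0.01.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

# conventional size-ranked module color order
COLOR_SEQUENCE = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
]
UNASSIGNED = "grey"

__all__ = [
    "NetworkConfig",
    "NetworkState",
    "transform_expression",
    "signed_adjacency",
    "pick_soft_threshold",
    "topological_overlap",
    "detect_modules",
    "module_eigengene",
    "module_membership",
    "intramodular_connectivity",
    "identify_hubs",
    "module_trait_association",
    "export_edges",
    "build_network",
]


@dataclass
class NetworkConfig:
    beta: int = 16
    min_module_size: int = 30
    cut_height: float = 0.97        # absolute dendrogram cut on the 1 − TOM scale
    merge_kme_threshold: float = 0.75
    hub_top_fraction: float = 0.10
    hub_kme_min: float = 0.9
    hub_p_max: float = 0.01

    def __post_init__(self):
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        for name in ("cut_height", "merge_kme_threshold", "hub_top_fraction",
                     "hub_kme_min"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")


@dataclass
class NetworkState:
    genes: list[str]
    adjacency: np.ndarray          # symmetric, zero diagonal
    tom: np.ndarray                # TOM similarity, unit diagonal
    module_labels: pd.Series       # gene -> color label
    eigengenes: pd.DataFrame       # module x sample
    kme: pd.DataFrame              # gene: kme, kme_p (own module)
    connectivity: pd.DataFrame     # gene: k_within, k_total
    hub_flags: pd.Series


def transform_expression(normalized: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(normalized + pseudocount), dropping zero-variance genes."""
    if normalized.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    expr = np.log2(normalized + pseudocount)
    variable = expr.var(axis=1) > 0
    n_dropped = int((~variable).sum())
    if n_dropped:
        logger.info("transform_expression: dropped %d zero-variance genes", n_dropped)
    expr = expr[variable]
    if expr.empty:
        raise ValueError("no variable genes")
    return expr


def _corrcoef(expr: pd.DataFrame) -> np.ndarray:
    cor = np.corrcoef(expr.to_numpy())
    if np.isnan(cor).any():
        raise ValueError("zero-variance gene present; run transform_expression first")
    return np.clip(cor, -1.0, 1.0)


def signed_adjacency(expr: pd.DataFrame, beta: int = 16) -> np.ndarray:
    """Signed soft-threshold adjacency with zero diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    cor = _corrcoef(expr)
    adj = ((1.0 + cor) / 2.0) ** beta
    np.fill_diagonal(adj, 0.0)
    return adj


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log degree-distribution fit.

    Connectivities are binned; log10(bin frequency) is regressed on
    log10(mean bin connectivity).  R^2 carries a negative sign when the
    slope is positive (anti-scale-free).
    """
    k = k[k > 0]
    if k.size < n_bins or np.ptp(k) == 0:
        return math.nan
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        members = k[idx == b]
        if members.size == 0:
            continue
        xs.append(members.mean())
        ys.append(members.size / k.size)
    if len(xs) < 3:
        return math.nan
    res = stats.linregress(np.log10(xs), np.log10(ys))
    r2 = res.rvalue**2
    return -r2 if res.slope > 0 else r2


def pick_soft_threshold(
    expr: pd.DataFrame,
    candidate_betas: Sequence[int] = (1, 2, 4, 6, 8, 10, 12, 14, 16, 18, 20),
    target_r2: float = 0.8,
    default_beta: int = 16,
) -> tuple[int, pd.DataFrame]:
    """Scale-free-topology scan over soft-threshold powers.

    Returns the smallest power whose signed fit R^2 reaches ``target_r2``,
    or the power maximizing signed R^2, with the full scan table.  If every
    fit is degenerate the configured default is returned with a warning.
    """
    if len(candidate_betas) < 2:
        raise ValueError("need at least 2 candidate powers")
    rows = []
    for beta in candidate_betas:
        adj = signed_adjacency(expr, beta)
        k = adj.sum(axis=1)
        rows.append({"beta": beta, "signed_r2": _scale_free_fit(k),
                     "mean_k": float(k.mean()), "max_k": float(k.max())})
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["signed_r2"])
    if valid.empty:
        warnings.warn("all scale-free fits degenerate; falling back to default beta")
        return default_beta, table
    passing = valid[valid["signed_r2"] >= target_r2]
    if not passing.empty:
        return int(passing["beta"].min()), table
    best = valid.loc[valid["signed_r2"].idxmax(), "beta"]
    return int(best), table


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap similarity of a weighted adjacency."""
    A = np.asarray(adjacency, dtype=float)
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    shared = A @ A
    numer = shared + A
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = numer / denom
    tom[~np.isfinite(tom)] = 0.0
    np.fill_diagonal(tom, 1.0)
    return tom


def _merge_modules(
    expr: pd.DataFrame, labels: pd.Series, threshold: float
) -> pd.Series:
    """Iteratively merge modules whose eigengenes correlate above threshold."""
    labels = labels.copy()
    while True:
        modules = sorted(m for m in labels.unique() if m != UNASSIGNED)
        if len(modules) < 2:
            return labels
        eigs = {m: module_eigengene(expr.loc[labels[labels == m].index]) for m in modules}
        best_pair, best_cor = None, threshold
        for i, mi in enumerate(modules):
            for mj in modules[i + 1:]:
                c = float(np.corrcoef(eigs[mi], eigs[mj])[0, 1])
                if c > best_cor:
                    best_pair, best_cor = (mi, mj), c
        if best_pair is None:
            return labels
        mi, mj = best_pair
        labels[labels == mj] = mi


def detect_modules(
    tom: np.ndarray,
    genes: Sequence[str],
    expr: pd.DataFrame,
    config: NetworkConfig | None = None,
) -> pd.Series:
    """Cluster 1 − TOM, cut, drop small clusters to grey, merge, and name.

    Returns a gene-indexed Series of color labels, size-ranked along the
    conventional color sequence; the expression matrix is needed for the
    eigengene-based merge step.
    """
    config = config or NetworkConfig()
    genes = list(genes)
    n = len(genes)
    if n < config.min_module_size:
        warnings.warn("fewer genes than min_module_size; all unassigned")
        return pd.Series(UNASSIGNED, index=genes)
    diss = 1.0 - np.asarray(tom)
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(diss, checks=False), method="average")
    raw = hierarchy.fcluster(link, t=config.cut_height, criterion="distance")

    labels = pd.Series(raw, index=genes, dtype=object)
    sizes = labels.value_counts()
    for cluster, size in sizes.items():
        if size < config.min_module_size:
            labels[labels == cluster] = UNASSIGNED
    # temporary names for the merge step
    keep = [c for c in labels.unique() if c != UNASSIGNED]
    tmp = {c: f"M{idx}" for idx, c in enumerate(keep)}
    labels = labels.map(lambda c: tmp.get(c, UNASSIGNED))
    if keep:
        labels = _merge_modules(expr, labels, config.merge_kme_threshold)
    # final size-ranked color names
    order = labels[labels != UNASSIGNED].value_counts().index
    rename = {m: COLOR_SEQUENCE[i] if i < len(COLOR_SEQUENCE) else f"module{i}"
              for i, m in enumerate(order)}
    return labels.map(lambda m: rename.get(m, UNASSIGNED))


def module_eigengene(module_expr: pd.DataFrame) -> np.ndarray:
    """First principal component of a module's standardized expression.

    Returned as a unit-sample-variance vector over samples, oriented so
    the average correlation with member genes is positive.
    """
    X = module_expr.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    mean = X.mean(axis=1, keepdims=True)
    if X.shape[0] == 1:
        profile = (X - mean)
        profile = profile / (sd if sd.item() > 0 else 1.0)
        return profile.ravel()
    keep = sd.ravel() > 0
    Z = (X[keep] - mean[keep]) / sd[keep]
    if Z.shape[0] == 0:
        raise ValueError("module has no variable genes")
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    eig = vt[0]
    cors = np.array([np.corrcoef(eig, z)[0, 1] for z in Z])
    if np.nanmean(cors) < 0:
        eig = -eig
    eig = eig - eig.mean()
    s = eig.std(ddof=1)
    return eig / s if s > 0 else eig


def _corr_pvalue(r: float, n: int) -> float:
    if n < 3:
        raise ValueError("need at least 3 samples")
    r = min(max(r, -1.0), 1.0)
    if abs(r) == 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def module_membership(
    expr: pd.DataFrame, eigengenes: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """kME (gene-eigengene Pearson correlation) and its p per gene x module."""
    n = expr.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples")
    kme = pd.DataFrame(index=expr.index, columns=eigengenes.index, dtype=float)
    pvals = kme.copy()
    X = expr.to_numpy(dtype=float)
    for module, eig in eigengenes.iterrows():
        e = eig.to_numpy(dtype=float)
        for i, gene in enumerate(expr.index):
            r = float(np.corrcoef(X[i], e)[0, 1])
            kme.loc[gene, module] = r
            pvals.loc[gene, module] = _corr_pvalue(r, n)
    return kme, pvals


def intramodular_connectivity(
    adjacency: np.ndarray, labels: pd.Series
) -> pd.DataFrame:
    """Whole-network and within-module adjacency sums per gene."""
    A = np.asarray(adjacency, dtype=float).copy()
    np.fill_diagonal(A, 0.0)
    genes = list(labels.index)
    lab = labels.to_numpy()
    k_total = A.sum(axis=1)
    k_within = np.array([
        A[i, lab == lab[i]].sum() for i in range(len(genes))
    ])
    return pd.DataFrame({"k_within": k_within, "k_total": k_total}, index=genes)


def identify_hubs(
    connectivity: pd.DataFrame,
    kme: pd.Series,
    kme_p: pd.Series,
    labels: pd.Series,
    config: NetworkConfig | None = None,
) -> pd.Series:
    """Hub calls: top-decile k_within, kME strictly > 0.9, membership p < 0.01.

    ``kme``/``kme_p`` are each gene's membership in its own module.  Grey
    genes are never hubs; in modules smaller than 10 genes the top decile
    means the single best-connected gene.
    """
    config = config or NetworkConfig()
    flags = pd.Series(False, index=labels.index)
    for module, members in labels.groupby(labels):
        if module == UNASSIGNED:
            continue
        idx = members.index
        kw = connectivity.loc[idx, "k_within"]
        if len(idx) < 10:
            threshold = kw.max()
        else:
            threshold = np.quantile(kw, 1.0 - config.hub_top_fraction)
        passed = (
            (kw >= threshold)
            & (kme.loc[idx] > config.hub_kme_min)
            & (kme_p.loc[idx] < config.hub_p_max)
        )
        flags.loc[idx] = passed
    return flags


def module_trait_association(
    eigengenes: pd.DataFrame, traits: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation of each eigengene with each per-sample trait."""
    rows = []
    for module, eig in eigengenes.iterrows():
        e = eig.to_numpy(dtype=float)
        for trait in traits.columns:
            t = traits[trait].to_numpy(dtype=float)
            if np.std(t) == 0:
                rows.append({"module": module, "trait": trait,
                             "cor": math.nan, "p": math.nan, "defined": False})
                continue
            r = float(np.corrcoef(e, t)[0, 1])
            rows.append({"module": module, "trait": trait, "cor": r,
                         "p": _corr_pvalue(r, len(e)), "defined": True})
    return pd.DataFrame(rows)


def export_edges(tom: np.ndarray, genes: Sequence[str],
                 threshold: float = 0.1) -> pd.DataFrame:
    """TOM edge list (gene_a, gene_b, weight) at weight >= threshold,
    for external network viewers."""
    genes = list(genes)
    iu = np.triu_indices(len(genes), k=1)
    weights = np.asarray(tom)[iu]
    keep = weights >= threshold
    return pd.DataFrame({
        "gene_a": [genes[i] for i in iu[0][keep]],
        "gene_b": [genes[j] for j in iu[1][keep]],
        "weight": weights[keep],
    })


def build_network(
    expr: pd.DataFrame, config: NetworkConfig | None = None
) -> NetworkState:
    """Run the full network stage on a transformed expression matrix."""
    config = config or NetworkConfig()
    adj = signed_adjacency(expr, config.beta)
    tom = topological_overlap(adj)
    labels = detect_modules(tom, expr.index, expr, config)
    modules = sorted(m for m in labels.unique() if m != UNASSIGNED)
    eig = pd.DataFrame(
        {m: module_eigengene(expr.loc[labels[labels == m].index]) for m in modules},
        index=expr.columns,
    ).T
    conn = intramodular_connectivity(adj, labels)
    if modules:
        kme_all, p_all = module_membership(expr, eig)
        own_kme = pd.Series(
            [kme_all.loc[g, labels[g]] if labels[g] != UNASSIGNED else math.nan
             for g in expr.index], index=expr.index)
        own_p = pd.Series(
            [p_all.loc[g, labels[g]] if labels[g] != UNASSIGNED else math.nan
             for g in expr.index], index=expr.index)
    else:
        own_kme = pd.Series(math.nan, index=expr.index)
        own_p = pd.Series(math.nan, index=expr.index)
    hubs = identify_hubs(conn, own_kme, own_p, labels, config)
    kme_frame = pd.DataFrame({"kme": own_kme, "kme_p": own_p})
    return NetworkState(list(expr.index), adj, tom, labels, eig, kme_frame,
                        conn, hubs)
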