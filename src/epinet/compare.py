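"""Connectivity comparisons between epistatic and non-epistatic genes.

Degrees come from either the coexpression network (k_total) or a
protein-protein interaction edge list filtered at a confidence cutoff
(default 0.9).  Group location is compared with a two-sided Wilcoxon
rank-sum test; hub enrichment of a gene set is a two-sided Fisher exact
test on the in-set x hub 2x2 table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ConnectivityComparison",
    "read_ppi_edges",
    "ppi_degrees",
    "compare_connectivity",
    "hub_enrichment",
    "map_gene_ids",
]


@dataclass(frozen=True)
class ConnectivityComparison:
    group_a_label: str
    group_b_label: str
    n_a: int
    n_b: int
    mean_a: float
    median_a: float
    mean_b: float
    median_b: float
    wilcoxon_p: float


def read_ppi_edges(path) -> pd.DataFrame:
    """Read a PPI edge list TSV (gene_a, gene_b, confidence).

    A 0-1000 integer confidence dialect is auto-detected and rescaled to
    0-1.  Malformed rows raise with their line number; duplicate edges
    collapse to the maximum confidence; self-edges are dropped.
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_a", "gene_b", "confidence"} - set(df.columns)
    if missing:
        raise ValueError(f"edge list missing columns: {sorted(missing)}")
    conf = pd.to_numeric(df["confidence"], errors="coerce")
    bad = conf.isna()
    if bad.any():
        raise ValueError(f"malformed confidence at line {int(bad.idxmax()) + 2}")
    if conf.max() > 1.0:
        conf = conf / 1000.0
    df = df.assign(confidence=conf)
    df = df[df["gene_a"] != df["gene_b"]]
    key = df.apply(lambda r: tuple(sorted((r["gene_a"], r["gene_b"]))), axis=1)
    df = df.assign(_key=key).groupby("_key", as_index=False).agg(
        gene_a=("gene_a", "first"), gene_b=("gene_b", "first"),
        confidence=("confidence", "max"))
    return df[["gene_a", "gene_b", "confidence"]]


def ppi_degrees(
    edges: pd.DataFrame,
    cutoff: float = 0.9,
    gene_universe: Iterable[str] | None = None,
    include_missing: bool = True,
) -> pd.Series:
    """Distinct-partner counts at a confidence cutoff.

    With a gene universe, genes absent from every retained edge get degree
    0 (``include_missing=True``) or are left out (``False``).
    """
    if not 0 <= cutoff <= 1:
        raise ValueError("cutoff must lie in [0, 1]")
    kept = edges[edges["confidence"] >= cutoff]
    partners: dict[str, set] = {}
    for a, b in zip(kept["gene_a"], kept["gene_b"]):
        partners.setdefault(a, set()).add(b)
        partners.setdefault(b, set()).add(a)
    degrees = {g: len(p) for g, p in partners.items()}
    if gene_universe is not None:
        universe = list(gene_universe)
        if include_missing:
            degrees = {g: degrees.get(g, 0) for g in universe}
        else:
            degrees = {g: degrees[g] for g in universe if g in degrees}
    return pd.Series(degrees, dtype=float).sort_index()


def compare_connectivity(
    degrees: pd.Series,
    epistatic_flags: pd.Series,
    label_a: str = "epistatic",
    label_b: str = "non-epistatic",
) -> ConnectivityComparison:
    """Wilcoxon rank-sum comparison of degree between flagged and unflagged genes."""
    flags = epistatic_flags.reindex(degrees.index)
    a = degrees[flags.fillna(False).astype(bool)].to_numpy(dtype=float)
    b = degrees[~flags.fillna(False).astype(bool)].to_numpy(dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    method = "exact" if max(a.size, b.size) <= 50 else "asymptotic"
    try:
        p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    except ValueError:  # ties with the exact method
        p = stats.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic").pvalue
    return ConnectivityComparison(
        label_a, label_b, a.size, b.size,
        float(a.mean()), float(np.median(a)),
        float(b.mean()), float(np.median(b)), float(p),
    )


def hub_enrichment(
    gene_set: Iterable[str],
    hub_flags: pd.Series,
    gene_universe: Iterable[str] | None = None,
) -> tuple[float, float, np.ndarray]:
    """Fisher exact test of hub status within a gene set.

    Returns (odds ratio, two-sided p, 2x2 table [[set&hub, set&not],
    [notset&hub, notset&not]]).
    """
    universe = list(gene_universe) if gene_universe is not None else list(hub_flags.index)
    genes = set(gene_set) & set(universe)
    if not genes:
        raise ValueError("gene set is empty within the universe")
    hubs = set(hub_flags[hub_flags.astype(bool)].index) & set(universe)
    in_hub = len(genes & hubs)
    in_not = len(genes) - in_hub
    out_hub = len(hubs - genes)
    out_not = len(universe) - len(genes) - out_hub
    table = np.array([[in_hub, in_not], [out_hub, out_not]])
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p), table


def map_gene_ids(
    names: Iterable[str], alias_table: Mapping[str, str] | pd.DataFrame
) -> tuple[dict[str, str], list[str]]:
    """Map gene names through a two-column alias table.

    Returns (mapped, unmapped); unmapped names are reported, never dropped
    silently.  Conflicting duplicate aliases raise.
    """
    if isinstance(alias_table, pd.DataFrame):
        if alias_table.shape[1] < 2:
            raise ValueError("alias table needs two columns (alias, canonical)")
        pairs = list(zip(alias_table.iloc[:, 0], alias_table.iloc[:, 1]))
    else:
        pairs = list(alias_table.items())
    mapping: dict[str, str] = {}
    conflicts = []
    for alias, canonical in pairs:
        if alias in mapping and mapping[alias] != canonical:
            conflicts.append(alias)
        mapping[alias] = canonical
    if conflicts:
        raise ValueError(f"conflicting aliases: {sorted(set(conflicts))}")
    mapped, unmapped = {}, []
    for name in names:
        if name in mapping:
            mapped[name] = mapping[name]
        else:
            unmapped.append(name)
    if unmapped:
        logger.warning("map_gene_ids: %d names unmapped", len(unmapped))
    return mapped, unmapped
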