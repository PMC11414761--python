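"""Gene-expression epistasis under an additive log-scale model.

Because expression change is measured as a log2 fold change, additivity of
the single mutants' effects is the no-interaction null, the log-scale
analogue of the multiplicative fitness null:

    epsilon_exp = GE_xy − (GE_x + GE_y)

with GE_* the log2 fold change of the double mutant and each single mutant
against the ancestor in the stress environment.  Per double mutant, each
gene's epsilon_exp is standardized against the genome-wide distribution
(z = (eps − mean) / SD over all analyzed genes).  Two significance tiers
gate the "epistatic gene" calls:

* tier A — differentially expressed (q below threshold) in at least one of
  the three mutant-vs-ancestor contrasts (either single or the double);
* tier B — tier A's q gate plus |log2fc| > 2 in at least one of those
  contrasts, plus |z| > 2.

Sign balance of positive vs negative epistasis is an exact binomial test;
distribution shape uses Pearson moment skewness and kurtosis; gene sets
are compared in and out of set by Wilcoxon rank-sum and variance F-tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .de import DERecord

logger = logging.getLogger(__name__)

__all__ = [
    "MomentsSummary",
    "GeneSetSummary",
    "epsilon_exp",
    "build_epistasis_table",
    "standardize_epsilon",
    "flag_significant",
    "sign_balance",
    "moments",
    "geneset_summary",
    "read_gene_set",
]


@dataclass(frozen=True)
class MomentsSummary:
    double_id: str
    n: int
    mean_eps: float
    median_eps: float
    skewness: float   # gamma1 = m3 / m2^(3/2), population divisor
    kurtosis: float   # gamma2 = m4 / m2^2, non-excess
    t_vs_zero: float
    p: float


@dataclass(frozen=True)
class GeneSetSummary:
    set_name: str
    double_id: str
    n_in_set: int
    n_sig_epistatic: int
    n_pos: int
    n_neg: int
    binomial_p: float
    wilcoxon_p: float
    f_test_p: float
    de_fraction: float


def epsilon_exp(ge_x: float, ge_y: float, ge_xy: float) -> float:
    """Additive-model epistatic score for one gene."""
    return ge_xy - (ge_x + ge_y)


def _lfc_map(records: Iterable[DERecord]) -> dict[str, float]:
    return {r.gene: r.log2fc for r in records}


def build_epistasis_table(
    de_x: Sequence[DERecord],
    de_y: Sequence[DERecord],
    de_xy: Sequence[DERecord],
    double_id: str,
) -> pd.DataFrame:
    """Per-gene epsilon_exp table for one double mutant.

    Genes missing from any of the three contrasts are skipped and logged.
    Columns: gene, double_id, ge_x, ge_y, ge_xy, epsilon_exp, z.
    """
    mx, my, mxy = _lfc_map(de_x), _lfc_map(de_y), _lfc_map(de_xy)
    common = sorted(set(mx) & set(my) & set(mxy))
    skipped = (set(mx) | set(my) | set(mxy)) - set(common)
    if skipped:
        logger.info("%s: %d genes missing a contrast, skipped", double_id, len(skipped))
    rows = []
    for g in common:
        eps = epsilon_exp(mx[g], my[g], mxy[g])
        rows.append((g, double_id, mx[g], my[g], mxy[g], eps))
    df = pd.DataFrame(rows, columns=["gene", "double_id", "ge_x", "ge_y",
                                     "ge_xy", "epsilon_exp"])
    df["z"] = standardize_epsilon(df["epsilon_exp"].to_numpy())
    return df


def standardize_epsilon(eps: Sequence[float]) -> np.ndarray:
    """Genome-wide standard scores for one double mutant's epsilon values."""
    values = np.asarray(eps, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 genes to standardize")
    sd = values.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero genome-wide SD; z-scores undefined")
    return (values - values.mean()) / sd


def flag_significant(
    table: pd.DataFrame,
    de_tables: Mapping[str, Sequence[DERecord]],
    q_threshold: float = 0.001,
    lfc_threshold: float = 2.0,
    z_threshold: float = 2.0,
) -> pd.DataFrame:
    """Add tier_a / tier_b boolean columns to an epistasis table.

    ``de_tables`` maps the three mutant-vs-ancestor contrast ids (the rho
    single, the rpoB single, and the double) to their DE records.  A gene
    absent from a DE table counts as non-significant in that contrast.
    """
    q_maps, lfc_maps = {}, {}
    for cid, recs in de_tables.items():
        q_maps[cid] = {r.gene: r.q for r in recs}
        lfc_maps[cid] = {r.gene: r.log2fc for r in recs}
        absent = set(table["gene"]) - set(q_maps[cid])
        if absent:
            logger.info("contrast %s: %d genes absent, treated as non-significant",
                        cid, len(absent))
    tier_a, tier_b = [], []
    for gene, z in zip(table["gene"], table["z"]):
        any_q = False
        any_q_and_lfc = False
        for cid in de_tables:
            q = q_maps[cid].get(gene)
            if q is None or not (q < q_threshold):
                continue
            any_q = True
            if abs(lfc_maps[cid][gene]) > lfc_threshold:
                any_q_and_lfc = True
        tier_a.append(any_q)
        tier_b.append(any_q_and_lfc and abs(z) > z_threshold)
    out = table.copy()
    out["tier_a"] = tier_a
    out["tier_b"] = tier_b
    return out


def sign_balance(eps: Sequence[float]) -> tuple[float, int, int]:
    """Two-sided exact binomial test of positive vs negative epsilon.

    Returns (p, n_pos, n_neg); exact zeros count to neither side.
    """
    values = np.asarray(eps, dtype=float)
    n_pos = int((values > 0).sum())
    n_neg = int((values < 0).sum())
    if n_pos + n_neg == 0:
        return math.nan, 0, 0
    p = stats.binomtest(n_pos, n_pos + n_neg, 0.5, alternative="two-sided").pvalue
    return float(p), n_pos, n_neg


def moments(eps: Sequence[float], double_id: str = "") -> MomentsSummary:
    """Distribution summary of one double mutant's epsilon values.

    Skewness and kurtosis use the population (divisor n) central moments:
    gamma1 = m3/m2^1.5 and non-excess gamma2 = m4/m2^2.
    """
    values = np.asarray(eps, dtype=float)
    if values.size < 4:
        raise ValueError("need at least 4 values for moments")
    if values.std() == 0.0:
        raise ValueError("zero variance; moments undefined")
    g1 = float(stats.skew(values, bias=True))
    g2 = float(stats.kurtosis(values, fisher=False, bias=True))
    t, p = stats.ttest_1samp(values, 0.0)
    return MomentsSummary(double_id, values.size, float(values.mean()),
                          float(np.median(values)), g1, g2, float(t), float(p))


def _f_test_two_sided(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided variance-ratio F-test with df (n1-1, n2-1)."""
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        return 1.0
    if vb == 0:
        return 0.0
    F = va / vb
    d1, d2 = a.size - 1, b.size - 1
    cdf = stats.f.cdf(F, d1, d2)
    return float(2.0 * min(cdf, 1.0 - cdf))


def _wilcoxon_two_sided(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum; exact when both sides are small."""
    method = "exact" if max(a.size, b.size) <= 50 else "asymptotic"
    try:
        return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                        method=method).pvalue)
    except ValueError:
        return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                        method="asymptotic").pvalue)


def geneset_summary(
    table: pd.DataFrame,
    gene_set: Iterable[str],
    set_name: str,
    sig_col: str = "tier_b",
) -> GeneSetSummary:
    """In-set vs out-of-set comparison of epsilon for one double mutant.

    ``table`` must carry gene, epsilon_exp, tier_a and the chosen
    significance column.  Reports sign counts and binomial test among the
    set's significant genes, Wilcoxon of epsilon in vs out of set, a
    two-sided variance F-test, and the set's tier-A DE fraction.
    """
    genes = set(gene_set)
    in_mask = table["gene"].isin(genes)
    n_in = int(in_mask.sum())
    if n_in == 0:
        raise ValueError(f"gene set {set_name!r} has no overlap with the analysis universe")
    sub = table[in_mask]
    out = table[~in_mask]
    sig = sub[sub[sig_col]]
    binom_p, n_pos, n_neg = sign_balance(sig["epsilon_exp"])
    if len(out) == 0:
        wil_p = math.nan
        f_p = math.nan
    else:
        wil_p = _wilcoxon_two_sided(sub["epsilon_exp"].to_numpy(),
                                    out["epsilon_exp"].to_numpy())
        f_p = _f_test_two_sided(sub["epsilon_exp"].to_numpy(),
                                out["epsilon_exp"].to_numpy())
    de_fraction = float(sub["tier_a"].mean()) if "tier_a" in sub else math.nan
    return GeneSetSummary(set_name, str(table["double_id"].iloc[0]) if len(table) else "",
                          n_in, int(len(sig)), n_pos, n_neg,
                          binom_p, wil_p, f_p, de_fraction)


def read_gene_set(path) -> dict[str, list[str]]:
    """Read gene sets: plain one-gene-per-line lists or GMT files.

    A GMT line is tab-separated: set name, description, member genes.
    Plain lists become a single set named after the file stem.
    """
    import pathlib

    path = pathlib.Path(path)
    text = path.read_text().strip().splitlines()
    if any("\t" in line for line in text):
        sets = {}
        for line in text:
            parts = line.rstrip().split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line in {path}: {line!r}")
            sets[parts[0]] = parts[2:]
        return sets
    return {path.stem: [line.strip() for line in text if line.strip()]}
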