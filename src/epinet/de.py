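"""Count normalization and a minimal differential-expression layer.

Libraries are made comparable with median-of-ratios size factors: each
sample's factor is the median, over genes whose row geometric mean is
positive, of that sample's count divided by the gene's geometric mean.
The built-in DE test is deliberately simple — a per-gene Welch t-test on
log2(normalized + 1) with Benjamini–Hochberg FDR across genes — and exists
so synthetic end-to-end runs are self-contained; externally produced DE
tables (gene, log2fc, p, q) are ingested for real analyses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "DERecord",
    "size_factors",
    "normalize",
    "simple_de",
    "ingest_de_table",
    "expression_cv",
    "read_count_matrix",
]


@dataclass
class CountMatrix:
    """Gene x sample integer counts with per-sample metadata.

    ``counts`` is a DataFrame indexed by gene with one column per sample;
    ``sample_meta`` is indexed by sample with columns genotype,
    temperature, replicate.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self):
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene labels")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample labels")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        missing = set(self.counts.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples missing from sample sheet: {sorted(missing)}")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


@dataclass(frozen=True)
class DERecord:
    gene: str
    contrast_id: str
    log2fc: float
    p_raw: float
    q: float


def size_factors(counts: pd.DataFrame | CountMatrix) -> pd.Series:
    """Median-of-ratios per-sample scale factors."""
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    mat = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_geo = np.log(mat).mean(axis=1)
    usable = np.isfinite(log_geo)
    if not usable.any():
        raise ValueError("no gene has nonzero counts in every sample")
    ratios = mat[usable] / np.exp(log_geo[usable])[:, None]
    factors = np.median(ratios, axis=0)
    if (factors <= 0).any():
        raise ValueError("nonpositive size factor; too many zero counts")
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame | CountMatrix, factors: pd.Series | None = None) -> pd.DataFrame:
    """Divide each sample's counts by its size factor."""
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    if factors is None:
        factors = size_factors(counts)
    factors = factors.reindex(counts.columns)
    if factors.isna().any() or (factors <= 0).any():
        raise ValueError("every sample needs a positive size factor")
    return counts / factors


def simple_de(
    normalized: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    contrast_id: str,
    pseudocount: float = 1.0,
    equal_var: bool = True,
) -> list[DERecord]:
    """Per-gene two-sample t on log2(normalized + pseudocount), b vs a.

    log2fc is mean(log2 b) − mean(log2 a); q is BH-adjusted across the
    genes of the contrast.  The default pools the two group variances
    (df = n_a + n_b − 2): at the 2–4 replicates typical of these designs a
    per-gene Welch correction spends most of its degrees of freedom
    estimating the df itself and noticeably underpowers the q < 0.001
    gates downstream; pass ``equal_var=False`` for Welch.  Genes with zero
    counts in every sample of the contrast are dropped (logged).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 samples per group")
    sub = normalized[list(group_a) + list(group_b)]
    nonzero = (sub > 0).any(axis=1)
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.info("simple_de %s: dropped %d all-zero genes", contrast_id, n_dropped)
    sub = sub[nonzero]
    log = np.log2(sub + pseudocount)
    a = log[list(group_a)].to_numpy()
    b = log[list(group_b)].to_numpy()
    lfc = b.mean(axis=1) - a.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tt = stats.ttest_ind(b, a, axis=1, equal_var=equal_var)
    p = np.where(np.isfinite(tt.pvalue), tt.pvalue, 1.0)
    q = multipletests(p, method="fdr_bh")[1]
    return [
        DERecord(g, contrast_id, float(l), float(pv), float(qv))
        for g, l, pv, qv in zip(sub.index, lfc, p, q)
    ]


def ingest_de_table(path, contrast_id: str, gene_universe: Iterable[str] | None = None) -> list[DERecord]:
    """Load an externally produced DE table (TSV: gene, log2fc, p, q)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene", "log2fc", "p", "q"} - set(df.columns)
    if missing:
        raise ValueError(f"DE table {path} missing columns: {sorted(missing)}")
    dup = df["gene"][df["gene"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate genes in {contrast_id}: {sorted(set(dup))}")
    for col in ("log2fc", "p", "q"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise ValueError(f"non-numeric {col} in {path} at line {line}")
        df[col] = pd.to_numeric(df[col])
    if gene_universe is not None:
        unknown = set(df["gene"]) - set(gene_universe)
        if unknown:
            logger.warning("%s: %d genes absent from the reference gene list",
                           contrast_id, len(unknown))
    return [
        DERecord(str(r.gene), contrast_id, float(r.log2fc), float(r.p), float(r.q))
        for r in df.itertuples(index=False)
    ]


def expression_cv(normalized: pd.DataFrame, sample_meta: pd.DataFrame) -> pd.DataFrame:
    """Coefficient of variation (sample SD / mean) per gene x genotype.

    Genotypes with a single sample are excluded with a warning; genes with
    zero mean in a genotype get cv = NaN and undefined = True.
    """
    rows = []
    for genotype, meta in sample_meta.groupby("genotype"):
        samples = [s for s in meta.index if s in normalized.columns]
        if len(samples) < 2:
            logger.warning("expression_cv: genotype %r has <2 samples; excluded", genotype)
            continue
        sub = normalized[samples]
        mu = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cv = sd / mu
        for gene in sub.index:
            m = mu[gene]
            rows.append({
                "gene": gene, "genotype": genotype,
                "cv": float(cv[gene]) if m > 0 else math.nan,
                "undefined": not (m > 0),
            })
    return pd.DataFrame(rows)


def read_count_matrix(counts_path, sample_sheet_path,
                      gene_labels=None, sample_labels=None) -> CountMatrix:
    """Read counts plus a sample sheet.

    Accepts a gene x sample TSV (first column 'gene'), or a MatrixMarket
    triplet file (``.mtx``) with one-label-per-line gene and sample files.
    """
    counts_path = str(counts_path)
    if counts_path.endswith(".mtx"):
        from scipy.io import mmread

        if gene_labels is None or sample_labels is None:
            raise ValueError("MTX input needs gene and sample label files")
        mat = mmread(counts_path).toarray()
        genes = [l.strip() for l in open(gene_labels) if l.strip()]
        samples = [l.strip() for l in open(sample_labels) if l.strip()]
        if mat.shape != (len(genes), len(samples)):
            raise ValueError("MTX shape does not match the label files")
        counts = pd.DataFrame(mat, index=genes, columns=samples)
    else:
        counts = pd.read_csv(counts_path, sep="\t")
        if counts.columns[0] != "gene":
            raise ValueError("count matrix must start with a 'gene' column")
        counts = counts.set_index("gene")
    meta = pd.read_csv(sample_sheet_path, sep="\t").set_index("sample")
    return CountMatrix(counts, meta)


def records_frame(records: Iterable[DERecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])
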