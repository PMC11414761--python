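"""Relative fitness from head-to-head competition assays and growth parameters.

A competition assay mixes a focal genotype 1:1 with a marked reference
strain, plates the mixture before and after one growth cycle, and counts
colonies of each competitor.  Relative fitness is the ratio of Malthusian
parameters, the log net fold-expansions over the cycle:

    w_r = ln(D * Nf_mut / Ni_mut) / ln(D * Nf_anc / Ni_anc)

where ``D`` is the fold-expansion implied by the serial-dilution regime
(100-fold daily dilution => D = 100).  Growth curves (cell density vs time)
yield the maximum growth rate mu_max as the slope of a linear fit to
ln(density) over the most linear stretch of the exponential phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_DILUTION = 100.0

__all__ = [
    "CompetitionAssay",
    "RelativeFitnessEstimate",
    "GrowthCurve",
    "GrowthFit",
    "relative_fitness",
    "summarize_fitness",
    "replicate_anova",
    "fit_growth",
    "compare_growth",
    "read_assay_table",
    "read_growth_table",
    "UncountableAssayError",
    "DegenerateDenominatorError",
]


class UncountableAssayError(ValueError):
    """A colony count needed for the fitness ratio is zero or negative."""


class DegenerateDenominatorError(ValueError):
    """The reference competitor's Malthusian parameter is zero."""


@dataclass(frozen=True)
class CompetitionAssay:
    """One replicate's colony counts for a mutant competed against the ancestor."""

    genotype_id: str
    temperature: float
    replicate_id: str
    n_initial_mutant: float
    n_final_mutant: float
    n_initial_ancestor: float
    n_final_ancestor: float
    dilution_factor: float = DEFAULT_DILUTION
    biological_replicate_id: str = ""


@dataclass(frozen=True)
class RelativeFitnessEstimate:
    genotype_id: str
    temperature: float
    w_bar: float
    variance: float  # Var of the mean, s^2 / n
    n: int
    t_vs_one: float = math.nan
    p_raw: float = math.nan
    p_bonferroni: float = math.nan


@dataclass(frozen=True)
class GrowthCurve:
    genotype_id: str
    temperature: float
    replicate_id: str
    times: tuple
    densities: tuple

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        d = np.asarray(self.densities, dtype=float)
        if t.size != d.size:
            raise ValueError("times and densities differ in length")
        if t.size < 5:
            raise ValueError("growth curve needs at least 5 points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(d <= 0):
            raise ValueError("densities must be positive")


@dataclass(frozen=True)
class GrowthFit:
    genotype_id: str
    temperature: float
    replicate_id: str
    mu_max: float
    window: tuple  # (start index, stop index) of the fitted stretch
    r_squared: float
    final_yield: float


def relative_fitness(assay: CompetitionAssay) -> float:
    """Malthusian-parameter ratio of mutant to ancestor for one assay."""
    counts = (
        assay.n_initial_mutant,
        assay.n_final_mutant,
        assay.n_initial_ancestor,
        assay.n_final_ancestor,
    )
    if any(c <= 0 for c in counts):
        raise UncountableAssayError(
            f"uncountable assay for {assay.genotype_id!r}: all four colony "
            f"counts must be positive, got {counts}"
        )
    D = assay.dilution_factor
    m_mut = math.log(D * assay.n_final_mutant / assay.n_initial_mutant)
    m_anc = math.log(D * assay.n_final_ancestor / assay.n_initial_ancestor)
    if m_anc == 0.0:
        raise DegenerateDenominatorError(
            f"degenerate denominator for {assay.genotype_id!r}: the ancestor's "
            "Malthusian parameter is zero"
        )
    return m_mut / m_anc


def _one_sample_t(values: np.ndarray, popmean: float) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    n = values.size
    sd = values.std(ddof=1)
    if sd == 0.0:
        # degenerate: every replicate identical
        if values[0] == popmean:
            return 0.0, 1.0
        return math.inf if values[0] > popmean else -math.inf, 0.0
    t = (values.mean() - popmean) / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return float(t), float(p)


def summarize_fitness(
    assays: Iterable[CompetitionAssay],
    pool_technical: bool = True,
) -> list[RelativeFitnessEstimate]:
    """Per genotype x temperature mean relative fitness with a t-test vs 1.

    Each group's replicates give the mean w̄_r, the unbiased sample variance
    of that mean (s²/n), a two-tailed one-sample t against w̄_r = 1 with
    df = n − 1, and a Bonferroni adjustment across the whole family of
    genotype x temperature tests.

    With ``pool_technical=False`` technical replicates are first averaged
    within biological replicates, and the t-test runs on those averages.
    """
    groups: dict[tuple[str, float], list[CompetitionAssay]] = {}
    for a in assays:
        groups.setdefault((a.genotype_id, a.temperature), []).append(a)

    estimates: list[RelativeFitnessEstimate] = []
    raw_ps: list[float] = []
    for (gid, temp), members in groups.items():
        if pool_technical:
            values = np.array([relative_fitness(a) for a in members])
        else:
            by_bio: dict[str, list[float]] = {}
            for a in members:
                by_bio.setdefault(a.biological_replicate_id, []).append(
                    relative_fitness(a)
                )
            values = np.array([np.mean(v) for v in by_bio.values()])
        n = values.size
        if n < 2:
            estimates.append(
                RelativeFitnessEstimate(gid, temp, float(values.mean()), math.nan, n)
            )
            continue
        var_mean = values.var(ddof=1) / n
        t, p = _one_sample_t(values, 1.0)
        estimates.append(
            RelativeFitnessEstimate(gid, temp, float(values.mean()), float(var_mean),
                                    n, t, p, math.nan)
        )
        raw_ps.append(p)

    m = len(raw_ps)
    out: list[RelativeFitnessEstimate] = []
    for est in estimates:
        if math.isnan(est.p_raw):
            out.append(est)
        else:
            out.append(
                RelativeFitnessEstimate(
                    est.genotype_id, est.temperature, est.w_bar, est.variance,
                    est.n, est.t_vs_one, est.p_raw, min(1.0, est.p_raw * m),
                )
            )
    return out


def replicate_anova(assays: Iterable[CompetitionAssay]) -> tuple[float, tuple[int, int], float]:
    """One-way ANOVA for differences among biological replicates.

    Groups the assay-level w_r values of one genotype x temperature by
    biological replicate and returns (F, (k-1, N-k), p).
    """
    groups: dict[str, list[float]] = {}
    for a in assays:
        groups.setdefault(a.biological_replicate_id, []).append(relative_fitness(a))
    for label, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"biological replicate {label!r} has fewer than 2 assays")
    if len(groups) < 2:
        raise ValueError("need at least 2 biological replicates")
    arrays = [np.asarray(v) for v in groups.values()]
    k = len(arrays)
    N = sum(a.size for a in arrays)
    if np.ptp(np.concatenate(arrays)) == 0:
        return 0.0, (k - 1, N - k), 1.0
    F, p = stats.f_oneway(*arrays)
    return float(F), (k - 1, N - k), float(p)


def _linfit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope, intercept and R^2; R^2 = 1 for a constant y."""
    if np.ptp(y) == 0:
        return 0.0, float(y[0]), 1.0
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return float(slope), float(intercept), 1.0
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return float(slope), float(intercept), r2


def fit_growth(
    curve: GrowthCurve,
    min_window: int = 5,
    yield_rule: str = "max",
) -> GrowthFit:
    """Maximum growth rate from the most linear stretch of ln(density).

    All contiguous windows of at least ``min_window`` points are scored by
    the R² of a straight-line fit to ln(density) vs time; among windows with
    positive slope the highest-R² one wins (earliest window on ties), and
    mu_max is its slope.  If no window has a positive slope (a flat or
    declining culture) mu_max is the largest window slope, floored at 0.

    final_yield is the maximum observed density (``yield_rule="max"``) or
    the density at the fitted window's last point (``yield_rule="window_end"``).
    """
    t = np.asarray(curve.times, dtype=float)
    y = np.log(np.asarray(curve.densities, dtype=float))
    n = t.size
    best = None  # (r2, -start, slope, window)
    best_any_slope = -math.inf
    best_any = None
    for length in range(min_window, n + 1):
        for start in range(0, n - length + 1):
            sl = slice(start, start + length)
            slope, _, r2 = _linfit(t[sl], y[sl])
            if slope > best_any_slope:
                best_any_slope = slope
                best_any = (r2, (start, start + length), slope)
            if slope > 0:
                key = (r2, -start, length)
                if best is None or key > best[0]:
                    best = (key, (start, start + length), slope)
    if best is not None:
        (r2, _, _), window, slope = best
    else:
        r2, window, slope = best_any
        slope = max(0.0, slope)
    if yield_rule == "max":
        final_yield = float(np.max(curve.densities))
    elif yield_rule == "window_end":
        final_yield = float(curve.densities[window[1] - 1])
    else:
        raise ValueError(f"unknown yield_rule {yield_rule!r}")
    return GrowthFit(curve.genotype_id, curve.temperature, curve.replicate_id,
                     float(slope), window, float(r2), final_yield)


def compare_growth(
    values_a: Sequence[float], values_b: Sequence[float], equal_var: bool = False
) -> tuple[float, float, float]:
    """Two-sample two-tailed t-test on a growth parameter (Welch by default).

    Returns (t, df, p).  Used to compare mu_max or yield between genotypes
    or between assay temperatures.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 fits per side")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


# ---------------------------------------------------------------------------
# TSV interfaces

def read_assay_table(path) -> list[CompetitionAssay]:
    """Load competition assays from a TSV with the columns
    genotype, temperature, replicate, bio_replicate, ni_mut, nf_mut,
    ni_anc, nf_anc, dilution."""
    df = pd.read_csv(path, sep="\t")
    required = {"genotype", "temperature", "replicate", "ni_mut", "nf_mut",
                "ni_anc", "nf_anc"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"assay table missing columns: {sorted(missing)}")
    assays = []
    for row in df.itertuples(index=False):
        assays.append(CompetitionAssay(
            genotype_id=str(row.genotype),
            temperature=float(row.temperature),
            replicate_id=str(row.replicate),
            biological_replicate_id=str(getattr(row, "bio_replicate", "")),
            n_initial_mutant=float(row.ni_mut),
            n_final_mutant=float(row.nf_mut),
            n_initial_ancestor=float(row.ni_anc),
            n_final_ancestor=float(row.nf_anc),
            dilution_factor=float(getattr(row, "dilution", DEFAULT_DILUTION)),
        ))
    return assays


def read_growth_table(path) -> list[GrowthCurve]:
    """Load growth curves from long-format TSV: genotype, temperature,
    replicate, time_h, density."""
    df = pd.read_csv(path, sep="\t")
    curves = []
    for (g, T, r), sub in df.groupby(["genotype", "temperature", "replicate"]):
        sub = sub.sort_values("time_h")
        curves.append(GrowthCurve(str(g), float(T), str(r),
                                  tuple(sub["time_h"]), tuple(sub["density"])))
    return curves


def summary_frame(estimates: Iterable[RelativeFitnessEstimate]) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in estimates])
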