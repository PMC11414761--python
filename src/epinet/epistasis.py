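"""Fitness epistasis under a multiplicative null, with variance propagation.

For a double mutant carrying mutations x and y, the epistatic deviation is

    epsilon = w̄_xy − w̄_x · w̄_y

the difference between the double mutant's observed mean relative fitness
and the product expected if the two mutations act multiplicatively.  The
uncertainty of the expectation is the variance of a product of independent
random variables,

    Var(w̄_x · w̄_y) = (Var(w̄_x) + w̄_x²)(Var(w̄_y) + w̄_y²) − w̄_x² w̄_y²

and the deviation's variance adds the double mutant's own uncertainty:

    Var(epsilon) = Var(w̄_xy) + Var(w̄_x · w̄_y).

Significance is a t-test of epsilon / sqrt(Var(epsilon)) with degrees of
freedom tied to the double mutant's replicate count (df = n_xy − 1 by
default).  The module also pools epsilon across double mutants, compares
pooled values across environments by one-way ANOVA, and fits the
diminishing-returns regression of the foreground mutation's fitness effect
against background fitness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fitness import RelativeFitnessEstimate

__all__ = [
    "FitnessEpistasisEstimate",
    "PooledEpistasisSummary",
    "DiminishingReturnsFit",
    "product_variance",
    "epistatic_deviation",
    "pooled_epistasis",
    "epistasis_anova",
    "diminishing_returns",
]


@dataclass(frozen=True)
class FitnessEpistasisEstimate:
    double_id: str
    temperature: float
    epsilon: float
    var_epsilon: float
    var_product: float
    t_stat: float
    df: int
    p_two_tailed: float
    degenerate: bool = False  # zero Var(epsilon); p is a convention, not a test


@dataclass(frozen=True)
class PooledEpistasisSummary:
    temperature: float
    mean_epsilon: float
    ci95_halfwidth: float
    t_stat: float
    df: int
    p: float
    n: int


@dataclass(frozen=True)
class DiminishingReturnsFit:
    temperature: float
    subgroup: str  # "combined" or a foreground-allele label
    slope: float
    intercept: float
    p_slope: float
    n: int


def product_variance(mean_x: float, var_x: float, mean_y: float, var_y: float) -> float:
    """Variance of the product of two independent random variables."""
    if var_x < 0 or var_y < 0:
        raise ValueError("input variances must be nonnegative")
    return (var_x + mean_x**2) * (var_y + mean_y**2) - mean_x**2 * mean_y**2


def epistatic_deviation(
    wx: RelativeFitnessEstimate,
    wy: RelativeFitnessEstimate,
    wxy: RelativeFitnessEstimate,
    double_id: str | None = None,
    df: int | None = None,
) -> FitnessEpistasisEstimate:
    """Multiplicative-null epistatic deviation for one double mutant.

    ``df`` defaults to the double mutant's replicate count minus one.
    """
    for est in (wx, wy, wxy):
        if not (math.isfinite(est.w_bar) and math.isfinite(est.variance)):
            raise ValueError(f"non-finite fitness estimate for {est.genotype_id!r}")
        if est.variance < 0:
            raise ValueError(f"negative variance for {est.genotype_id!r}")
    if wxy.n < 2:
        raise ValueError("double mutant needs at least 2 replicates")

    eps = wxy.w_bar - wx.w_bar * wy.w_bar
    var_prod = product_variance(wx.w_bar, wx.variance, wy.w_bar, wy.variance)
    var_eps = wxy.variance + var_prod
    dof = (wxy.n - 1) if df is None else df
    degenerate = False
    if var_eps == 0.0:
        if eps == 0.0:
            t, p = 0.0, 1.0
        else:
            t = math.copysign(math.inf, eps)
            p = 0.0
        degenerate = True
    else:
        t = eps / math.sqrt(var_eps)
        p = 2.0 * stats.t.sf(abs(t), dof)
    return FitnessEpistasisEstimate(
        double_id or wxy.genotype_id, wxy.temperature, float(eps), float(var_eps),
        float(var_prod), float(t), dof, float(p), degenerate,
    )


def pooled_epistasis(eps: Sequence[float], temperature: float = math.nan) -> PooledEpistasisSummary:
    """Mean epsilon across double mutants with a t-test against zero.

    Returns the mean, the half-width of the 95% confidence interval
    (t_{0.975, n-1} x SE), and the two-tailed one-sample t-test.
    """
    values = np.asarray(eps, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("pooled epistasis needs at least 2 values")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd == 0.0:
        return PooledEpistasisSummary(temperature, mean, 0.0, 0.0, n - 1, 1.0, n)
    se = sd / math.sqrt(n)
    t = mean / se
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    half = float(stats.t.ppf(0.975, n - 1) * se)
    return PooledEpistasisSummary(temperature, mean, half, float(t), n - 1, float(p), n)


def epistasis_anova(groups: dict[float, Sequence[float]]) -> tuple[float, tuple[int, int], float]:
    """One-way fixed-effects ANOVA of epsilon with environment as the factor."""
    if len(groups) < 2:
        raise ValueError("need at least 2 temperature groups")
    arrays = []
    for temp, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 2:
            raise ValueError(f"group {temp} has fewer than 2 values")
        arrays.append(v)
    k = len(arrays)
    N = sum(a.size for a in arrays)
    if np.ptp(np.concatenate(arrays)) == 0:
        return 0.0, (k - 1, N - k), 1.0
    F, p = stats.f_oneway(*arrays)
    return float(F), (k - 1, N - k), float(p)


def diminishing_returns(
    pairs: pd.DataFrame,
    effect: str = "ratio",
) -> list[DiminishingReturnsFit]:
    """Regression of the foreground mutation's fitness effect on background fitness.

    ``pairs`` must have columns ``temperature``, ``foreground_allele``,
    ``w_background`` (the constituent background single's w̄) and ``w_double``.
    The foreground effect is ``w_double / w_background`` (``effect="ratio"``)
    or ``w_double − w_background`` (``effect="diff"``).  An OLS line of
    effect vs background fitness is fitted per temperature, both on the
    combined data and separately per foreground allele; a negative slope is
    the diminishing-returns signature.
    """
    required = {"temperature", "foreground_allele", "w_background", "w_double"}
    missing = required - set(pairs.columns)
    if missing:
        raise ValueError(f"pairing table missing columns: {sorted(missing)}")
    if effect == "ratio":
        eff = pairs["w_double"] / pairs["w_background"]
    elif effect == "diff":
        eff = pairs["w_double"] - pairs["w_background"]
    else:
        raise ValueError(f"unknown effect {effect!r}")
    df = pairs.assign(effect=eff)

    fits: list[DiminishingReturnsFit] = []
    for temp, sub in df.groupby("temperature"):
        subsets = [("combined", sub)] + [
            (str(allele), g) for allele, g in sub.groupby("foreground_allele")
        ]
        for label, g in subsets:
            if len(g) < 3:
                if label == "combined":
                    raise ValueError(f"fewer than 3 pairs at {temp}")
                continue
            res = stats.linregress(g["w_background"], g["effect"])
            fits.append(DiminishingReturnsFit(
                float(temp), label, float(res.slope), float(res.intercept),
                float(res.pvalue), len(g),
            ))
    return fits


def epistasis_frame(estimates: Iterable[FitnessEpistasisEstimate]) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in estimates])
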