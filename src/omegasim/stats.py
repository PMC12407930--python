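"""Null-distribution summaries, empirical p-values, cross-model comparison.

Degenerate replicates (undefined omega, recorded as NaN) are excluded from
all moments, percentiles and tests but always counted and reported.
Empirical percentiles use the add-one (pseudo-count) rule, so a p-value is
never 0 and is bounded below by 1/(n + 1).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _scipy_stats

from .context import NullDistribution
from .errors import AllDegenerateError, ParameterError

ALTERNATIVES = ("greater", "less", "two-sided")


@dataclass(frozen=True)
class DistributionSummary:
    mean: float
    sd: float
    minimum: float
    p2_5: float
    p25: float
    median: float
    p75: float
    p97_5: float
    n_defined: int
    n_degenerate: int


@dataclass(frozen=True)
class ComparisonResult:
    observed_omega: float
    empirical_p: float
    alternative: str
    n_defined: int


def _defined(null: NullDistribution) -> np.ndarray:
    values = np.asarray(null.values, dtype=float)
    defined = values[~np.isnan(values)]
    if defined.size == 0:
        raise AllDegenerateError("every replicate of the null distribution is degenerate")
    return defined


def summarize(null: NullDistribution) -> DistributionSummary:
    """Moments and percentiles over the defined omega values."""
    v = _defined(null)
    q = np.percentile(v, [2.5, 25, 50, 75, 97.5])
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return DistributionSummary(
        mean=float(np.mean(v)),
        sd=sd,
        minimum=float(np.min(v)),
        p2_5=float(q[0]),
        p25=float(q[1]),
        median=float(q[2]),
        p75=float(q[3]),
        p97_5=float(q[4]),
        n_defined=int(v.size),
        n_degenerate=int(null.reps - v.size),
    )


def empirical_percentile(observed: float, null: NullDistribution, alternative: str = "greater") -> ComparisonResult:
    """Add-one empirical p-value of an observed omega against the null.

    greater: p = (1 + #{null >= observed}) / (1 + n); less is symmetric;
    two-sided doubles the smaller one-sided p, capped at 1.
    """
    if alternative not in ALTERNATIVES:
        raise ParameterError(f"alternative must be one of {ALTERNATIVES}, got {alternative!r}")
    v = _defined(null)
    n = v.size
    p_greater = (1 + int((v >= observed).sum())) / (1 + n)
    p_less = (1 + int((v <= observed).sum())) / (1 + n)
    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    else:
        p = min(1.0, 2 * min(p_greater, p_less))
    return ComparisonResult(observed_omega=float(observed), empirical_p=p, alternative=alternative, n_defined=n)


def compare_models(nulls: list[NullDistribution]) -> tuple[float, float]:
    """Kruskal-Wallis omnibus test across the defined values of each null.

    Rank-based and distribution-free; requires at least two distributions
    with at least two defined values each.  Returns (statistic, p-value).
    """
    groups = []
    for null in nulls:
        v = _defined(null)
        if v.size >= 2:
            groups.append(v)
    if len(groups) < 2:
        raise ParameterError("compare_models needs >= 2 distributions with >= 2 defined values each")
    stat, p = _scipy_stats.kruskal(*groups)
    return float(stat), float(p)
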