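"""Mutation-rate estimation from fluctuation assays.

Parallel cultures grown from small inocula are plated on selective
medium; the distribution of resistant-colony counts r_i is heavy-tailed
(Luria-Delbrueck) and encodes m, the expected number of mutational events
per culture.  Two classical estimators are provided:

* the method of the median: m solves  r_median/m - ln(m) = 1.24;
* the p0 method: m = -ln(fraction of cultures with zero mutants).

The rate per locus per generation is mu = m / N, with N the final number
of cells per culture corrected for the fraction plated.  Rates are
returned on the 1e-7 scale used for reporter-gene rate tables.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
from scipy import optimize, stats

from .types import FluctuationExperiment, RateEstimate, RATE_SCALE

log = logging.getLogger(__name__)

#: Constant of the median method's implicit equation.
_MEDIAN_CONSTANT = 1.24


def _median_lower(counts) -> float:
    """Lower-median convention: for even n, the n/2-th order statistic."""
    s = sorted(counts)
    return float(s[(len(s) - 1) // 2])


def _m_from_median(r_med: float) -> float:
    """Solve r/m - ln(m) = 1.24 for m > 0 (unique root; LHS is strictly
    decreasing in m)."""
    if r_med <= 0:
        raise ValueError("median count must be positive for the median method")

    def g(m: float) -> float:
        return r_med / m - math.log(m) - _MEDIAN_CONSTANT

    lo, hi = 1e-12, 1.0
    while g(hi) > 0:
        hi *= 2.0
    m = optimize.brentq(g, lo, hi, xtol=1e-12, rtol=8.9e-16)
    assert abs(g(m)) < 1e-9
    return float(m)


def estimate_m_median(experiment: FluctuationExperiment) -> float:
    """Method-of-the-median estimate of m.

    Raises if the median count is zero; use :func:`estimate_m_p0` then.
    """
    r_med = _median_lower(experiment.counts)
    if r_med == 0:
        raise ValueError(
            "median count is 0; the median method is undefined - use estimate_m_p0"
        )
    return _m_from_median(r_med)


def estimate_m_p0(experiment: FluctuationExperiment) -> float:
    """p0-method estimate: m = -ln(fraction of zero-count cultures)."""
    n = len(experiment.counts)
    zeros = sum(1 for c in experiment.counts if c == 0)
    if zeros == 0:
        raise ValueError(
            "no zero-count cultures; the p0 method is undefined - use the median method"
        )
    return float(-math.log(zeros / n))


def _effective_n(experiment: FluctuationExperiment) -> float:
    # Plating-fraction correction applied to N_t, not to the counts.
    return experiment.n_final / experiment.plating_fraction


def rate_from_m(
    m: float,
    experiment: FluctuationExperiment,
    per_division: bool = False,
) -> float:
    """Rate per locus per generation on the 1e-7 scale: mu = m / N.

    ``per_division`` switches to the alternative divisor 2*N (mutations
    per cell division rather than per final cell); default off.
    """
    if m < 0:
        raise ValueError("m must be non-negative")
    divisor = _effective_n(experiment) * (2.0 if per_division else 1.0)
    return m / divisor / RATE_SCALE


def _median_ci_counts(counts, level: float) -> tuple[float, float]:
    """Nonparametric order-statistic confidence bounds for the median count.

    Uses the exact binomial(n, 1/2) distribution of the number of
    observations below the median.
    """
    s = sorted(counts)
    n = len(s)
    alpha = 1.0 - level
    # largest l with P(X <= l-1) <= alpha/2 and smallest u with
    # P(X >= u) <= alpha/2, X ~ Bin(n, 1/2); 1-based order statistics.
    lo_idx = int(stats.binom.ppf(alpha / 2, n, 0.5))  # 0-based
    hi_idx = n - 1 - lo_idx
    if lo_idx > hi_idx:
        lo_idx, hi_idx = 0, n - 1
    return float(s[lo_idx]), float(s[hi_idx])


def rate_confidence_interval(
    experiment: FluctuationExperiment,
    method: str = "median",
    level: float = 0.95,
) -> tuple[float, float]:
    """Confidence interval for the rate, on the 1e-7 scale.

    For the median method the exact order-statistic bounds on the median
    count are transformed through the median estimator; for the p0 method
    the Clopper-Pearson interval on the zero-culture fraction is
    transformed through -ln.  Distribution-free in either case.
    """
    counts = experiment.counts
    n = len(counts)
    if n < 5:
        warnings.warn(
            "fewer than 5 cultures: median CI falls back to the extreme "
            "order statistics and will be wide",
            stacklevel=2,
        )
    if method == "median":
        c_lo, c_hi = _median_ci_counts(counts, level)
        m_lo = _m_from_median(c_lo) if c_lo > 0 else 0.0
        m_hi = _m_from_median(c_hi) if c_hi > 0 else 0.0
    elif method == "p0":
        zeros = sum(1 for c in counts if c == 0)
        ci = stats.binomtest(zeros, n).proportion_ci(
            confidence_level=level, method="exact"
        )
        # fewer zero cultures -> larger m: bounds invert through -ln.
        m_lo = -math.log(ci.high) if ci.high > 0 else math.inf
        m_hi = -math.log(ci.low) if ci.low > 0 else math.inf
    else:
        raise ValueError(f"unknown CI method {method!r}")
    lo = rate_from_m(m_lo, experiment)
    hi = rate_from_m(m_hi, experiment) if math.isfinite(m_hi) else math.inf
    return (min(lo, hi), max(lo, hi))


def estimate_rate(
    experiment: FluctuationExperiment,
    method: str = "auto",
    level: float = 0.95,
) -> RateEstimate:
    """Point estimate plus CI, choosing the estimator like a bench
    scientist would: the median method when the median count is positive,
    otherwise p0."""
    if method == "auto":
        method = "median" if _median_lower(experiment.counts) > 0 else "p0"
    if method == "median":
        m = estimate_m_median(experiment)
    elif method == "p0":
        m = estimate_m_p0(experiment)
    else:
        raise ValueError(f"unknown method {method!r}")
    rate = rate_from_m(m, experiment)
    if m == 0:
        # all-zero counts: degenerate point estimate, upper limit from the
        # binomial lower confidence bound on the zero fraction.
        lo, hi = 0.0, rate_confidence_interval(experiment, "p0", level)[1]
    else:
        lo, hi = rate_confidence_interval(experiment, method, level)
    lo, hi = min(lo, rate), max(hi, rate)
    log.info(
        "rate estimate (%s): m=%.4g rate=%.4g [%.4g, %.4g] x1e-7 from %d cultures",
        method, m, rate, lo, hi, len(experiment.counts),
    )
    return RateEstimate(m=m, rate=rate, ci_low=lo, ci_high=hi, method=method)
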