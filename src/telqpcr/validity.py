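"""External-validity statistics: partial correlations with Fisher-z intervals,
the 83.4% CI-overlap comparison, and correlation power / sample-size
calculations.

Two independent correlation estimates whose 83.4% confidence intervals do not
overlap differ at approximately the 5% significance level, which is why the
unusual-looking default level is used for between-approach comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .errors import DataError, InsufficientDataError

DEFAULT_CI_LEVEL = 0.834


@dataclass
class CorrelationResult:
    metric: str                 # cross_tissue | age | parent_offspring | ...
    approach: str
    r: float
    n: int                      # effective n (observations minus covariates)
    covariates: list = field(default_factory=list)
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    level: float = DEFAULT_CI_LEVEL


@dataclass
class PowerSpec:
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0 and self.alpha < self.power < 1.0):
            raise ValueError("require 0 < alpha < power < 1")


def partial_correlation(x: Sequence[float], y: Sequence[float],
                        covariates: Optional[np.ndarray] = None,
                        metric: str = "", approach: str = "",
                        covariate_names: Sequence[str] = (),
                        level: float = DEFAULT_CI_LEVEL) -> CorrelationResult:
    """Pearson correlation of x and y after residualising both on covariates.

    Covariates are supplied as an (n, k) numeric array (binary covariates
    coded 0/1); with no covariates this is the plain Pearson correlation.
    The confidence interval uses the Fisher z transform with the effective
    sample size n - k.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if covariates is None:
        cov = np.empty((n, 0))
    else:
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] != n:
            cov = cov.T
    k = cov.shape[1]
    if n <= k + 2:
        raise InsufficientDataError("need n > number of covariates + 2")
    design = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DataError("rank-deficient covariates")
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    r = float(np.corrcoef(rx, ry)[0, 1])
    n_eff = n - k
    lo, hi = fisher_ci(r, n_eff, level) if abs(r) < 1 and n_eff >= 4 else (r, r)
    return CorrelationResult(metric=metric, approach=approach, r=r, n=n_eff,
                             covariates=list(covariate_names),
                             ci_low=lo, ci_high=hi, level=level)


def fisher_ci(r: float, n: int, level: float = DEFAULT_CI_LEVEL) -> Tuple[float, float]:
    """Fisher-z confidence interval: tanh(atanh(r) ± z_(1+level)/2 / sqrt(n-3)).

    For partial correlations pass the effective sample size (n minus the
    number of covariates).
    """
    if not abs(r) < 1:
        raise DataError("|r| must be < 1 for a Fisher interval")
    if n < 4:
        raise InsufficientDataError("Fisher interval requires n >= 4")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    z = math.atanh(r)
    half = stats.norm.ppf((1.0 + level) / 2.0) / math.sqrt(n - 3)
    return math.tanh(z - half), math.tanh(z + half)


def ci_overlap_differs(a: CorrelationResult, b: CorrelationResult) -> bool:
    """True iff the two confidence intervals are disjoint (difference
    declared).  Intervals touching at exactly one point count as overlapping."""
    if a.metric != b.metric:
        raise ValueError("comparing correlations of different metrics")
    return a.ci_high < b.ci_low or b.ci_high < a.ci_low


def _power_of_r_test(n: float, r: float, alpha: float) -> float:
    """Approximate power of the two-sided test of rho = 0 at sample size n,
    as used by R's pwr.r.test: critical r from the t distribution, then a
    Fisher-z normal approximation with a small-sample bias term."""
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, n - 2.0)
    rc = math.sqrt(tcrit ** 2 / (tcrit ** 2 + n - 2.0))
    zr = math.atanh(r) + r / (2.0 * (n - 1.0))
    return float(stats.norm.cdf((zr - math.atanh(rc)) * math.sqrt(n - 3.0)))


def required_n(r: float, spec: PowerSpec = PowerSpec()) -> float:
    """Smallest (real-valued) sample size at which the two-sided test of
    rho = 0 attains ``spec.power`` when the true correlation is ``r``.

    Solved by bisection on the pwr.r.test power function; raises on r = 0
    (no finite sample size detects a null effect).
    """
    if not 0.0 < abs(r) < 1.0:
        raise ValueError("required_n needs 0 < |r| < 1")
    r = abs(r)
    f = lambda n: _power_of_r_test(n, r, spec.alpha) - spec.power
    lo, hi = 3.0 + 1e-6, 1e7
    if f(hi) < 0:
        raise DataError("requested power unattainable below n = 1e7")
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def percent_reduction(n_a: float, n_b: float) -> float:
    """Percent reduction in required sample size going from n_a to n_b."""
    if not n_a > 0:
        raise ValueError("n_a must be positive")
    return 100.0 * (n_a - n_b) / n_a
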