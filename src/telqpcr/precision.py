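"""Replicate-level precision statistics.

CV here is always the coefficient of variation across *natural-log
transformed* replicate estimates (ln[E**Cq]), which approximates normality
better than the raw scale.  CV equality across groups is tested with the
Feltz-Miller asymptotic chi-square statistic; scale differences between
approaches use paired t-tests with Bonferroni control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import DataError, InsufficientDataError


@dataclass
class CVResult:
    sample_id: str
    approach: str
    cv: float
    n: int
    flags: set


@dataclass
class PairedTestResult:
    contrast: Tuple[str, str]
    statistic: float
    df: int
    p: float
    p_bonferroni: float
    n_pairs: int
    flags: set


def replicate_cv(ln_estimates: Sequence[float]) -> float:
    """Sample SD over mean of ln-transformed replicate estimates.

    Raises :class:`DataError` when the mean is zero (CV undefined).
    """
    x = np.asarray(ln_estimates, float)
    if len(x) < 2:
        raise InsufficientDataError("CV requires >= 2 replicates")
    if not np.all(np.isfinite(x)):
        raise DataError("non-finite ln-estimates")
    mean = float(x.mean())
    if mean == 0.0:
        raise DataError("CV undefined: mean of ln-estimates is zero")
    return float(x.std(ddof=1)) / mean


def cv_equality_test(groups: Sequence[Sequence[float]]) -> Tuple[float, int, float]:
    """Feltz-Miller asymptotic test for equality of coefficients of variation.

    With group CVs c_i, weights m_i = n_i - 1 and the weighted mean CV c̄, the
    statistic  D = sum m_i (c_i - c̄)^2 / (c̄^2 (0.5 + c̄^2))  is asymptotically
    chi-square with k-1 degrees of freedom under equal CVs.

    Returns ``(statistic, df, p)``.
    """
    arrs = [np.asarray(g, float) for g in groups]
    k = len(arrs)
    if k < 2:
        raise InsufficientDataError("need >= 2 groups")
    for g in arrs:
        if len(g) < 2:
            raise InsufficientDataError("each group needs n >= 2")
        if g.mean() == 0:
            raise DataError("zero-mean group: CV undefined")
    m = np.array([len(g) - 1 for g in arrs], float)
    c = np.array([g.std(ddof=1) / g.mean() for g in arrs])
    cbar = float((m * c).sum() / m.sum())
    if cbar == 0.0:
        return 0.0, k - 1, 1.0
    d = float((m * (c - cbar) ** 2).sum() / (cbar ** 2 * (0.5 + cbar ** 2)))
    return d, k - 1, float(stats.chi2.sf(d, k - 1))


def paired_t(a: Sequence[float], b: Sequence[float],
             contrast: Tuple[str, str] = ("a", "b"),
             n_contrasts: int = 1) -> PairedTestResult:
    """Two-sided paired t-test on index-matched observations.

    Zero-variance differences are flagged: identical pairs give statistic 0
    and p = 1; a constant non-zero difference leaves the statistic undefined
    (``zero_variance`` flag, p = 0).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or len(a) < 2:
        raise InsufficientDataError("paired t needs equal-length arrays, n >= 2")
    d = a - b
    n = len(d)
    sd = float(d.std(ddof=1))
    flags: set = set()
    if sd == 0.0:
        if float(d.mean()) == 0.0:
            stat, p = 0.0, 1.0
        else:
            stat, p = math.inf * math.copysign(1.0, float(d.mean())), 0.0
            flags.add("zero_variance")
    else:
        stat = float(d.mean()) / (sd / math.sqrt(n))
        p = float(2.0 * stats.t.sf(abs(stat), n - 1))
    return PairedTestResult(
        contrast=contrast, statistic=stat, df=n - 1, p=p,
        p_bonferroni=min(1.0, p * n_contrasts), n_pairs=n, flags=flags,
    )


def bonferroni(p_values: Sequence[float]) -> List[float]:
    """Multiply each p-value by the number of contrasts, capped at 1."""
    ps = [float(p) for p in p_values]
    for p in ps:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value outside [0, 1]: {p}")
    k = len(ps)
    return [min(1.0, p * k) for p in ps]
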