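"""Amplification-efficiency estimation and Cq determination.

Two routes to the per-cycle amplification efficiency E are implemented:

* **standard curve**: ordinary least squares of Cq on log10 known
  concentration over a serial dilution; the slope M gives ``E = 10**(-1/M)``.
* **log-linear reconstruction**: per reaction, OLS of log10 fluorescence on
  cycle number restricted to a common window-of-linearity per amplicon group;
  the slope gives ``E = 10**slope``.

Replicate-level estimates can then be averaged at the sample, plate (analytical
samples and positive controls only — never standards or the water blank) or
batch (amplicon) level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import (AggregationError, InsufficientDataError, InvalidCurveError,
                     WindowFailureError)
from .io import ReactionCurve

#: Default quantification thresholds (shared across all plates of a batch):
#: instrument-style Cq determination and reconstructed (window) Cq.
INSTRUMENT_THRESHOLD = 0.4996
RECONSTRUCTED_THRESHOLD = 0.4260

#: Roles that enter plate- and batch-level efficiency averages.
ANALYTICAL_ROLES = ("sample", "positive_control")


def _ols(x: np.ndarray, y: np.ndarray):
    """Least squares fit of y on x; returns (slope, intercept, r_squared)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    sxy = float(((x - xm) * (y - ym)).sum())
    syy = float(((y - ym) ** 2).sum())
    if sxx == 0.0:
        raise InsufficientDataError("degenerate regression: no spread in x")
    slope = sxy / sxx
    intercept = ym - slope * xm
    ss_res = max(syy - slope * sxy, 0.0)
    r2 = 1.0 if syy == 0.0 else 1.0 - ss_res / syy
    return slope, intercept, r2


@dataclass
class StandardCurveFit:
    """OLS of Cq (y) on log10 concentration (x) over a dilution series."""

    slope_M: float
    intercept: float
    r_squared: float
    efficiency_E: float
    n_points: int


@dataclass
class WindowOfLinearity:
    """A common fluorescence band within which each reaction of an amplicon
    group is treated as exponentially amplifying."""

    amplicon_group: str
    lower_fluorescence: float
    upper_fluorescence: float
    min_points: int
    mean_r_squared: float = float("nan")
    n_feasible: int = 0


@dataclass
class EfficiencyEstimate:
    """An efficiency value with its provenance."""

    value_E: float
    level: str    # replicate | sample | plate | batch | curve_plate | curve_batch
    method: str   # standard_curve | log_linear
    source_reactions: list = field(default_factory=list)
    slope: Optional[float] = None
    intercept: Optional[float] = None
    fit_r_squared: Optional[float] = None
    flags: set = field(default_factory=set)
    sample_id: Optional[str] = None
    plate_id: Optional[str] = None
    role: Optional[str] = None
    amplicon: Optional[str] = None
    replicate_index: Optional[int] = None

    @property
    def valid(self) -> bool:
        return not self.flags and np.isfinite(self.value_E) and self.value_E > 1.0


@dataclass
class CqValue:
    reaction_id: str
    cq: float
    threshold: float
    source: str  # instrument | reconstructed


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def fit_standard_curve(standards: Sequence) -> StandardCurveFit:
    """Fit Cq against log10 known concentration for a dilution series.

    ``standards`` is a sequence of ``(known_concentration, cq)`` pairs.
    Raises :class:`InvalidCurveError` when the slope is non-negative
    (efficiency undefined) and :class:`InsufficientDataError` below three
    distinct concentrations.
    """
    conc = np.array([c for c, _ in standards], float)
    cq = np.array([q for _, q in standards], float)
    if len(np.unique(conc)) < 3:
        raise InsufficientDataError("standard curve needs >= 3 distinct concentrations")
    if not (np.all(np.isfinite(cq)) and np.all(conc > 0)):
        raise InvalidCurveError("standard curve requires finite Cq and positive concentrations")
    slope, intercept, r2 = _ols(np.log10(conc), cq)
    if slope >= 0:
        raise InvalidCurveError("standard-curve slope is non-negative: efficiency undefined")
    return StandardCurveFit(
        slope_M=slope, intercept=intercept, r_squared=r2,
        efficiency_E=10.0 ** (-1.0 / slope), n_points=len(cq),
    )


def baseline_correct(curve: ReactionCurve, n_baseline_cycles: int = 5) -> ReactionCurve:
    """Subtract the mean fluorescence of the first ``n_baseline_cycles`` cycles.

    The subtracted constant and the baseline SD (used for the window search's
    noise floor) are recorded on the returned curve.  Output values may be
    non-positive; they are masked downstream.
    """
    if n_baseline_cycles < 3 or n_baseline_cycles >= len(curve.cycles):
        raise InsufficientDataError(
            f"n_baseline_cycles must be in [3, {len(curve.cycles) - 1}]"
        )
    head = curve.fluorescence[:n_baseline_cycles]
    base = float(head.mean())
    corrected = curve.fluorescence - base
    return curve.with_fluorescence(
        corrected,
        baseline_value=base,
        baseline_sd=float(corrected[:n_baseline_cycles].std(ddof=1)),
    )


def _band_stats(curve: ReactionCurve, lowers: np.ndarray, uppers: np.ndarray,
                min_points: int):
    """Vectorised per-band in-window point counts, slopes and r² for one curve.

    Returns (n_points, slope, r2) arrays over candidate bands; slope/r2 are NaN
    where a band holds fewer than ``min_points`` usable points.
    """
    f = curve.fluorescence
    pos = f > 0
    x = curve.cycles[pos].astype(float)
    y = np.log10(f[pos])
    fv = f[pos]
    mask = (fv >= lowers[:, None]) & (fv <= uppers[:, None])  # bands x points
    n = mask.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sx = mask @ x
        sy = mask @ y
        sxx = mask @ (x * x)
        syy = mask @ (y * y)
        sxy = mask @ (x * y)
        vxx = sxx - sx * sx / np.maximum(n, 1)
        vyy = syy - sy * sy / np.maximum(n, 1)
        vxy = sxy - sx * sy / np.maximum(n, 1)
        slope = vxy / vxx
        r2 = np.where(vyy > 0, vxy * vxy / (vxx * vyy), 1.0)
    bad = (n < min_points) | (vxx <= 0)
    slope = np.where(bad, np.nan, slope)
    r2 = np.where(bad, np.nan, np.clip(r2, 0.0, 1.0))
    return n, slope, r2


def set_window_of_linearity(group_curves: Sequence[ReactionCurve],
                            min_points: int = 4,
                            candidate_grid: int = 50,
                            plateau_fraction: float = 0.9,
                            noise_floor_mult: float = 3.0,
                            min_feasible_fraction: float = 0.8) -> WindowOfLinearity:
    """Choose one fluorescence band for an amplicon group.

    The band maximises the mean r² of per-reaction log10-fluorescence vs cycle
    regressions over in-band points, subject to: every contributing reaction
    has at least ``min_points`` points in the band, and the band lies above the
    reaction's noise floor (``noise_floor_mult`` x baseline SD) and below its
    plateau (``plateau_fraction`` x maximum).  Candidate bounds are
    ``candidate_grid`` log-spaced fluorescence values spanning the group.
    The mean is taken over *all* reactions of the group, a reaction for which
    the band is infeasible contributing zero — so the search prefers bands
    usable by as many reactions as possible over marginally straighter but
    narrower ones.

    Raises :class:`WindowFailureError` when no band satisfies the constraints
    for at least ``min_feasible_fraction`` of the reactions.
    """
    curves = list(group_curves)
    if not curves:
        raise InsufficientDataError("empty amplicon group")
    group = curves[0].amplicon_group

    floors = np.array([
        noise_floor_mult * (c.baseline_sd or 0.0) for c in curves
    ])
    plateaus = np.array([
        plateau_fraction * float(np.max(c.fluorescence)) for c in curves
    ])
    # grid range: smallest usable positive fluorescence to the highest plateau
    gmin, gmax = np.inf, 0.0
    for c, floor, plat in zip(curves, floors, plateaus):
        f = c.fluorescence
        usable = f[(f > 0) & (f >= floor) & (f <= plat)]
        if usable.size:
            gmin = min(gmin, float(usable.min()))
            gmax = max(gmax, float(usable.max()))
    if not np.isfinite(gmin) or gmax <= gmin:
        raise WindowFailureError(
            f"group {group}: no usable fluorescence range",
            offending_reactions=[c.reaction_id for c in curves],
        )
    grid = np.geomspace(gmin, gmax, candidate_grid)
    ii, jj = np.triu_indices(candidate_grid, k=1)
    lowers, uppers = grid[ii], grid[jj]
    n_bands = len(lowers)

    r2_sum = np.zeros(n_bands)
    feasible_count = np.zeros(n_bands, dtype=int)
    per_curve_feasible = np.zeros((len(curves), n_bands), dtype=bool)
    for k, c in enumerate(curves):
        n, _, r2 = _band_stats(c, lowers, uppers, min_points)
        ok = (~np.isnan(r2)) & (lowers >= floors[k]) & (uppers <= plateaus[k])
        per_curve_feasible[k] = ok
        feasible_count += ok
        r2_sum += np.where(ok, np.nan_to_num(r2), 0.0)

    need = min_feasible_fraction * len(curves)
    valid = feasible_count >= need
    if not valid.any():
        best = int(np.argmax(feasible_count))
        offending = [c.reaction_id for k, c in enumerate(curves)
                     if not per_curve_feasible[k, best]]
        raise WindowFailureError(
            f"group {group}: no candidate band feasible for >= "
            f"{min_feasible_fraction:.0%} of {len(curves)} reactions",
            offending_reactions=offending,
        )
    mean_r2 = np.where(valid, r2_sum / len(curves), -np.inf)
    # deterministic selection: best mean r2, then most contributing reactions,
    # then the widest band, then grid order
    width = np.log(uppers / lowers)
    order = np.lexsort((-width, -feasible_count, -mean_r2))
    best = int(order[0])
    return WindowOfLinearity(
        amplicon_group=group,
        lower_fluorescence=float(lowers[best]),
        upper_fluorescence=float(uppers[best]),
        min_points=min_points,
        mean_r_squared=float(mean_r2[best]),
        n_feasible=int(feasible_count[best]),
    )


def estimate_reaction_efficiency(curve: ReactionCurve,
                                 window: WindowOfLinearity) -> EfficiencyEstimate:
    """Per-reaction efficiency from the in-window log-linear regression.

    Reactions with fewer than ``window.min_points`` in-window points are
    flagged ``no_amplification``; a non-positive slope is flagged
    ``invalid_slope``.  Flagged estimates are excluded from all averages.
    """
    f = curve.fluorescence
    mask = (f > 0) & (f >= window.lower_fluorescence) & (f <= window.upper_fluorescence)
    est = EfficiencyEstimate(
        value_E=float("nan"), level="replicate", method="log_linear",
        source_reactions=[curve.reaction_id],
        sample_id=curve.sample_id, plate_id=curve.plate_id,
        role=curve.role, amplicon=curve.amplicon,
        replicate_index=curve.replicate_index,
    )
    if int(mask.sum()) < window.min_points:
        est.flags.add("no_amplification")
        return est
    slope, intercept, r2 = _ols(curve.cycles[mask].astype(float), np.log10(f[mask]))
    est.slope, est.intercept, est.fit_r_squared = slope, intercept, r2
    est.value_E = 10.0 ** slope
    if slope <= 0:
        est.flags.add("invalid_slope")
    return est


def compute_cq(curve: ReactionCurve, threshold: float,
               fit: Optional[EfficiencyEstimate] = None,
               source: str = "reconstructed") -> Optional[CqValue]:
    """Fractional quantification cycle at a fixed fluorescence threshold.

    When an in-window regression ``fit`` is supplied, the crossing of the
    fitted exponential is used: ``Cq = (log10 threshold - intercept) / slope``.
    Otherwise the observed curve is interpolated (log-linearly) between the
    two cycles bracketing its first threshold crossing.  Returns ``None``
    (no-Cq) when the curve never reaches the threshold.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    f = curve.fluorescence
    cyc = curve.cycles
    if float(np.max(f)) < threshold:
        return None
    if fit is not None and fit.slope is not None and fit.slope > 0:
        cq = (math.log10(threshold) - fit.intercept) / fit.slope
        if cyc[0] <= cq <= cyc[-1]:
            return CqValue(curve.reaction_id, float(cq), threshold, source)
        # regression extrapolates outside the run: fall through to interpolation
    idx = int(np.argmax(f >= threshold))
    if idx == 0:
        return CqValue(curve.reaction_id, float(cyc[0]), threshold, source)
    f0, f1 = f[idx - 1], f[idx]
    if f0 > 0:
        frac = (math.log10(threshold) - math.log10(f0)) / (math.log10(f1) - math.log10(f0))
    else:
        frac = (threshold - f0) / (f1 - f0)
    cq = cyc[idx - 1] + frac * (cyc[idx] - cyc[idx - 1])
    return CqValue(curve.reaction_id, float(cq), threshold, source)


def aggregate_efficiencies(estimates: Sequence[EfficiencyEstimate],
                           level: str) -> list:
    """Average replicate-level estimates at ``sample``, ``plate`` or ``batch``
    level.

    Plate and batch averages include analytical samples and positive controls
    only (never standards or the water blank); flagged estimates are excluded
    everywhere.  Batch means average per-reaction values across all plates of
    one amplicon (not plate means).  Raises :class:`AggregationError` when a
    scope is empty after exclusions.
    """
    pool = [e for e in estimates if e.valid]
    if level == "sample":
        keyfn = lambda e: (e.plate_id, e.sample_id)
        pool_lvl = pool
    elif level == "plate":
        keyfn = lambda e: e.plate_id
        pool_lvl = [e for e in pool if e.role in ANALYTICAL_ROLES]
    elif level == "batch":
        keyfn = lambda e: e.amplicon
        pool_lvl = [e for e in pool if e.role in ANALYTICAL_ROLES]
    else:
        raise ValueError(f"unknown aggregation level {level!r}")
    groups: dict = {}
    for e in pool_lvl:
        groups.setdefault(keyfn(e), []).append(e)
    if not groups:
        raise AggregationError(f"no valid estimates to aggregate at level {level!r}")
    out = []
    for key, members in groups.items():
        first = members[0]
        out.append(EfficiencyEstimate(
            value_E=float(np.mean([e.value_E for e in members])),
            level=level, method=first.method,
            source_reactions=[r for e in members for r in e.source_reactions],
            fit_r_squared=None,
            sample_id=first.sample_id if level == "sample" else None,
            plate_id=first.plate_id if level in ("sample", "plate") else None,
            amplicon=first.amplicon,
        ))
    return out
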