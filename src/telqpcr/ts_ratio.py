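"""T/S ratio calculation: replicate estimates, outlier QC, and the seven
approaches to amplification-efficiency estimation.

A telomere-length measurement is the ratio of the telomere-repeat signal (T)
to the single-copy-gene signal (S):

    T/S = (E_T ** Cq_T / E_S ** Cq_S) ** (-1) = E_S ** Cq_S / E_T ** Cq_T

where per-replicate estimates ``E ** Cq`` are averaged on the raw (not log)
scale within T and within S independently before taking the ratio.  The seven
approaches differ in where the Cq comes from (instrument export vs
reconstruction at a fixed threshold) and at which level the efficiency is
estimated (per replicate, sample, plate or batch; by standard curve or by
log-linear reconstruction).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import QCError


@dataclass(frozen=True)
class ApproachSpec:
    """One admissible combination of Cq source and efficiency estimation."""

    name: str
    cq_source: str          # instrument | reconstructed
    efficiency_method: str  # standard_curve | log_linear
    efficiency_level: str   # replicate | sample | plate | batch


#: The seven T/S calculation approaches, in canonical order.
APPROACHES: Dict[str, ApproachSpec] = {
    s.name: s for s in (
        ApproachSpec("RotorGeneCurve", "instrument", "standard_curve", "plate"),
        ApproachSpec("RotorGeneBatch", "instrument", "standard_curve", "batch"),
        ApproachSpec("LinRegRep", "reconstructed", "log_linear", "replicate"),
        ApproachSpec("LinRegSamp", "reconstructed", "log_linear", "sample"),
        ApproachSpec("LinRegPlate", "reconstructed", "log_linear", "plate"),
        ApproachSpec("LinRegBatch", "reconstructed", "log_linear", "batch"),
        ApproachSpec("LinRegCurve", "reconstructed", "standard_curve", "plate"),
    )
}


@dataclass
class QCRule:
    """Replicate outlier rule: drop a replicate whose Cq deviates from the
    triplicate median by more than ``max_dcq`` cycles; a sample fails when
    fewer than ``min_replicates`` remain."""

    max_dcq: float = 0.5
    min_replicates: int = 2


@dataclass
class TSRecord:
    """Per-sample T/S results across approaches (one record per sample)."""

    sample_id: str
    tissue: str
    ts: Dict[str, float] = field(default_factory=dict)
    t_estimate: Dict[str, float] = field(default_factory=dict)
    s_estimate: Dict[str, float] = field(default_factory=dict)
    t_cqs: Dict[str, list] = field(default_factory=dict)
    s_cqs: Dict[str, list] = field(default_factory=dict)
    t_efficiency: Dict[str, float] = field(default_factory=dict)
    s_efficiency: Dict[str, float] = field(default_factory=dict)
    # per-approach ln-replicate estimates, for precision (CV) analyses
    t_ln_replicates: Dict[str, list] = field(default_factory=dict)
    s_ln_replicates: Dict[str, list] = field(default_factory=dict)
    qc_flags: set = field(default_factory=set)


def replicate_estimate(cq: float, efficiency: float) -> float:
    """Raw-scale replicate estimate ``E ** Cq``, evaluated in log space."""
    if not efficiency > 1.0:
        raise ValueError(f"efficiency must exceed 1 (got {efficiency})")
    if not math.isfinite(cq):
        raise ValueError("Cq must be finite")
    return math.exp(cq * math.log(efficiency))


def remove_outlier_replicates(cqs: Sequence[float],
                              rule: QCRule = QCRule()) -> Tuple[List[int], set]:
    """Indices of retained replicates plus QC flags.

    A replicate is an outlier when its Cq deviates from the median of the
    (1-3) replicates by more than ``rule.max_dcq`` cycles.  The flags contain
    ``sample_failed`` when fewer than ``rule.min_replicates`` survive.
    """
    cqs = [float(c) for c in cqs]
    if not 1 <= len(cqs) <= 3:
        raise QCError(f"expected 1-3 replicates, got {len(cqs)}")
    med = float(np.median(cqs))
    retained = [i for i, c in enumerate(cqs) if abs(c - med) <= rule.max_dcq]
    flags = set()
    if len(retained) < len(cqs):
        flags.add("replicates_removed")
    if len(retained) < rule.min_replicates:
        flags.add("sample_failed")
    if not retained:
        flags.add("all_replicates_removed")
    return retained, flags


def sample_estimate(replicate_estimates: Sequence[float]) -> float:
    """Arithmetic mean of raw replicate estimates (never of logs)."""
    vals = [float(v) for v in replicate_estimates]
    if len(vals) < 2:
        raise QCError("sample estimate requires >= 2 retained replicates")
    return float(np.mean(vals))


def compute_ts(t_replicates: Sequence[Tuple[float, float]],
               s_replicates: Sequence[Tuple[float, float]]) -> Tuple[float, float, float]:
    """T/S ratio from retained (Cq, efficiency) pairs for T and for S.

    T and S replicates are aggregated independently (replicate i of T is not
    paired with replicate i of S).  Returns ``(ts, t_estimate, s_estimate)``
    with ``ts = s_estimate / t_estimate``.
    """
    t_est = sample_estimate([replicate_estimate(cq, e) for cq, e in t_replicates])
    s_est = sample_estimate([replicate_estimate(cq, e) for cq, e in s_replicates])
    return s_est / t_est, t_est, s_est


def summarize_ts(records: Sequence[TSRecord]) -> pd.DataFrame:
    """Mean, SD and between-sample CV of T/S per approach, for the whole
    analytical sample and per tissue.

    Groups with fewer than two records are omitted with a warning.  Returns a
    tidy frame with columns group, approach, n, mean, sd, cv.
    """
    recs = [r for r in records if "sample_failed" not in r.qc_flags]
    groups = {
        "all": recs,
        "leukocyte": [r for r in recs if r.tissue == "leukocyte"],
        "buccal": [r for r in recs if r.tissue == "buccal"],
    }
    rows = []
    for gname, members in groups.items():
        if len(members) < 2:
            warnings.warn(f"group {gname!r} has fewer than 2 records; omitted")
            continue
        for name in APPROACHES:
            vals = np.array([m.ts[name] for m in members if name in m.ts])
            if len(vals) < 2:
                continue
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1))
            rows.append({
                "group": gname, "approach": name, "n": len(vals),
                "mean": mean, "sd": sd,
                "cv": sd / mean if mean != 0 else float("nan"),
            })
    return pd.DataFrame(rows, columns=["group", "approach", "n", "mean", "sd", "cv"])
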