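"""End-to-end analysis: read -> QC -> efficiencies -> seven T/S variants ->
precision and validity reports.

All stages are pure functions of the input batch and the configuration; report
frames are sorted deterministically so that repeated runs produce byte-identical
output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import io as qio
from .efficiency import (INSTRUMENT_THRESHOLD, RECONSTRUCTED_THRESHOLD,
                         baseline_correct, compute_cq,
                         estimate_reaction_efficiency, fit_standard_curve,
                         set_window_of_linearity)
from .errors import ConfigError, DataError, TelqpcrError
from .precision import cv_equality_test, paired_t, replicate_cv
from .ts_ratio import (APPROACHES, QCRule, TSRecord, compute_ts,
                       remove_outlier_replicates, summarize_ts)
from .validity import (DEFAULT_CI_LEVEL, ci_overlap_differs,
                       partial_correlation)


@dataclass
class PipelineConfig:
    fluorescence_path: Optional[str] = None
    metadata_path: Optional[str] = None
    cq_path: Optional[str] = None
    outdir: str = "telqpcr_out"
    instrument_threshold: float = INSTRUMENT_THRESHOLD
    reconstructed_threshold: float = RECONSTRUCTED_THRESHOLD
    n_baseline_cycles: int = 5
    min_points: int = 4
    candidate_grid: int = 50
    plateau_fraction: float = 0.9
    noise_floor_mult: float = 3.0
    min_feasible_fraction: float = 0.8
    max_dcq: float = 0.5
    min_replicates: int = 2
    ci_level: float = DEFAULT_CI_LEVEL
    alpha: float = 0.05
    power: float = 0.80
    seed: int = 0
    approaches: tuple = tuple(APPROACHES)

    def __post_init__(self):
        if self.instrument_threshold <= 0 or self.reconstructed_threshold <= 0:
            raise ConfigError("thresholds must be positive")
        if not 0.0 < self.ci_level < 1.0:
            raise ConfigError("CI level must be in (0, 1)")
        unknown = set(self.approaches) - set(APPROACHES)
        if unknown:
            raise ConfigError(f"unknown approaches: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        raw = qio.read_config(path)
        kwargs = {}
        types = {f.name: f.type for f in dc_fields(cls)}
        for key, value in raw.items():
            if key not in types:
                raise ConfigError(f"unknown config key {key!r}")
            if key == "approaches":
                kwargs[key] = tuple(v.strip() for v in value.split(","))
            elif key in ("n_baseline_cycles", "min_points", "candidate_grid",
                         "min_replicates", "seed"):
                kwargs[key] = int(value)
            elif key in ("fluorescence_path", "metadata_path", "cq_path", "outdir"):
                kwargs[key] = value
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except TelqpcrError as exc:
        raise type(exc)(f"[stage {name}] {exc}") from exc


# ---------------------------------------------------------------------------
# per-reaction processing
# ---------------------------------------------------------------------------

def process_reactions(run: qio.RunBatch, config: PipelineConfig):
    """Baseline-correct every curve, set one window of linearity per amplicon
    group, and compute per-reaction efficiencies and Cqs.

    Returns ``(reaction_table, windows)`` where the table has one row per
    reaction with its log-linear efficiency, reconstructed Cq and instrument Cq.
    """
    corrected: Dict[str, list] = {}
    meta = []
    for plate in run.plates():
        for rc in plate.reactions:
            cc = baseline_correct(rc, config.n_baseline_cycles)
            corrected.setdefault(cc.amplicon_group, []).append(cc)
            meta.append((plate, cc))

    windows = {
        group: _stage(
            f"window:{group}", set_window_of_linearity, curves,
            min_points=config.min_points, candidate_grid=config.candidate_grid,
            plateau_fraction=config.plateau_fraction,
            noise_floor_mult=config.noise_floor_mult,
            min_feasible_fraction=config.min_feasible_fraction,
        )
        for group, curves in sorted(corrected.items())
    }

    rows = []
    for plate, cc in meta:
        est = estimate_reaction_efficiency(cc, windows[cc.amplicon_group])
        cqv = compute_cq(cc, config.reconstructed_threshold)
        rows.append({
            "reaction_id": cc.reaction_id, "plate_id": cc.plate_id,
            "well": cc.well, "amplicon": cc.amplicon,
            "amplicon_group": cc.amplicon_group, "role": cc.role,
            "sample_id": cc.sample_id, "replicate_index": cc.replicate_index,
            "known_concentration": cc.known_concentration,
            "efficiency": est.value_E if est.valid else np.nan,
            "slope": est.slope, "r_squared": est.fit_r_squared,
            "cq_reconstructed": cqv.cq if cqv is not None else np.nan,
            "cq_instrument": plate.instrument_cq.get(cc.well, np.nan),
            "flags": ";".join(sorted(est.flags)),
            "true_e": cc.true_e, "true_cq": cc.true_cq,
        })
    return pd.DataFrame(rows), windows


def efficiency_lookups(run: qio.RunBatch, table: pd.DataFrame):
    """All efficiency aggregates the seven approaches draw from.

    Returns a dict with per-replicate, per-sample, per-plate and per-batch
    log-linear means plus per-plate / per-batch standard-curve efficiencies for
    both Cq sources.
    """
    analytical = table["role"].isin(("sample", "positive_control"))
    valid = table["efficiency"].notna()
    look = {
        "replicate": dict(zip(table["reaction_id"], table["efficiency"])),
        "sample": table[valid].groupby(["plate_id", "sample_id"])["efficiency"]
                              .mean().to_dict(),
        "plate": table[valid & analytical].groupby("plate_id")["efficiency"]
                                          .mean().to_dict(),
        "batch": table[valid & analytical].groupby("amplicon")["efficiency"]
                                          .mean().to_dict(),
        "curve_plate_instrument": {}, "curve_plate_reconstructed": {},
    }
    std = table[table["role"] == "standard"]
    for plate_id, grp in std.groupby("plate_id"):
        for source in ("instrument", "reconstructed"):
            pts = grp[["known_concentration", f"cq_{source}"]].dropna()
            try:
                fit = fit_standard_curve(list(pts.itertuples(index=False, name=None)))
                look[f"curve_plate_{source}"][plate_id] = fit.efficiency_E
            except TelqpcrError:
                pass
    for source in ("instrument", "reconstructed"):
        per_plate = look[f"curve_plate_{source}"]
        agg: Dict[str, list] = {}
        for plate in run.plates():
            if plate.plate_id in per_plate:
                agg.setdefault(plate.amplicon, []).append(per_plate[plate.plate_id])
        look[f"curve_batch_{source}"] = {a: float(np.mean(v)) for a, v in agg.items()}
    return look


def _efficiency_for(entry, look, spec, plate_id, amplicon, sample_id):
    """Efficiency feeding one replicate estimate under one approach."""
    if spec.efficiency_method == "standard_curve":
        if spec.efficiency_level == "plate":
            return look[f"curve_plate_{spec.cq_source}"].get(plate_id)
        return look[f"curve_batch_{spec.cq_source}"].get(amplicon)
    if spec.efficiency_level == "replicate":
        return look["replicate"].get(entry["reaction_id"])
    if spec.efficiency_level == "sample":
        return look["sample"].get((plate_id, sample_id))
    if spec.efficiency_level == "plate":
        return look["plate"].get(plate_id)
    return look["batch"].get(amplicon)


def compute_ts_records(run: qio.RunBatch, table: pd.DataFrame, look: dict,
                       config: PipelineConfig,
                       cohort: Optional[qio.CohortTable] = None):
    """T/S ratios for every analytical sample under every configured approach.

    Replicate outliers are removed per (sample, amplicon, Cq source) before
    aggregation; samples keeping fewer than ``min_replicates`` replicates on
    either side are flagged and excluded from that approach.
    """
    rule = QCRule(max_dcq=config.max_dcq, min_replicates=config.min_replicates)
    tissue_of = {}
    if cohort is not None:
        tissue_of = dict(zip(cohort.samples["sample_id"], cohort.samples["tissue"]))

    t_for_sample: Dict[str, str] = {}
    for plate in run.t_plates:
        for rc in plate.reactions:
            if rc.role == "sample":
                t_for_sample.setdefault(rc.sample_id, plate.plate_id)

    by_key = {k: g for k, g in table.groupby(["plate_id", "sample_id"])}
    records, qc_rows = [], []
    for sample_id in sorted(t_for_sample):
        t_plate = t_for_sample[sample_id]
        s_plate = run.pairing[t_plate]
        rec = TSRecord(sample_id=sample_id,
                       tissue=tissue_of.get(sample_id, "unknown"))
        retained: Dict[tuple, list] = {}
        for side, plate_id in (("t", t_plate), ("s", s_plate)):
            grp = by_key.get((plate_id, sample_id))
            for source in ("instrument", "reconstructed"):
                key = (side, source)
                if grp is None:
                    retained[key] = []
                    continue
                entries = [row for _, row in grp.iterrows()
                           if np.isfinite(row[f"cq_{source}"])]
                if not entries:
                    retained[key] = []
                    rec.qc_flags.add(f"no_{source}_cq_{side}")
                    continue
                keep, flags = remove_outlier_replicates(
                    [e[f"cq_{source}"] for e in entries], rule)
                rec.qc_flags |= {f"{side}_{f}" for f in flags if f != "sample_failed"}
                if len(keep) < rule.min_replicates:
                    rec.qc_flags.add("sample_failed")
                retained[key] = [entries[i] for i in keep]

        for name in config.approaches:
            spec = APPROACHES[name]
            pairs = {}
            lns = {}
            ok = True
            for side, plate_id, amplicon in (("t", t_plate, "T"), ("s", s_plate, "S")):
                side_pairs = []
                for entry in retained[(side, spec.cq_source)]:
                    e = _efficiency_for(entry, look, spec, plate_id, amplicon,
                                        sample_id)
                    if e is None or not np.isfinite(e) or e <= 1.0:
                        continue
                    side_pairs.append((float(entry[f"cq_{spec.cq_source}"]), float(e)))
                if len(side_pairs) < rule.min_replicates:
                    ok = False
                pairs[side] = side_pairs
                lns[side] = [cq * math.log(e) for cq, e in side_pairs]
            if not ok:
                rec.qc_flags.add(f"{name}_failed")
                continue
            ts, t_est, s_est = compute_ts(pairs["t"], pairs["s"])
            rec.ts[name] = ts
            rec.t_estimate[name], rec.s_estimate[name] = t_est, s_est
            rec.t_cqs[name] = [cq for cq, _ in pairs["t"]]
            rec.s_cqs[name] = [cq for cq, _ in pairs["s"]]
            rec.t_efficiency[name] = float(np.mean([e for _, e in pairs["t"]]))
            rec.s_efficiency[name] = float(np.mean([e for _, e in pairs["s"]]))
            rec.t_ln_replicates[name] = lns["t"]
            rec.s_ln_replicates[name] = lns["s"]
        records.append(rec)
        if rec.qc_flags:
            qc_rows.append({"sample_id": sample_id,
                            "flags": ";".join(sorted(rec.qc_flags))})
    return records, pd.DataFrame(qc_rows, columns=["sample_id", "flags"])


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def efficiency_report(run: qio.RunBatch, table: pd.DataFrame, look) -> dict:
    """Per-plate efficiencies under the three plate-level regimes (instrument
    standard curve, reconstructed standard curve, log-linear plate mean) plus
    mean/sd per amplicon and paired t-tests between amplicons and regimes."""
    rows = []
    for plate in run.plates():
        rows.append({
            "plate_id": plate.plate_id, "amplicon": plate.amplicon,
            "standard_curve_instrument": look["curve_plate_instrument"].get(plate.plate_id, np.nan),
            "standard_curve_reconstructed": look["curve_plate_reconstructed"].get(plate.plate_id, np.nan),
            "log_linear_plate_mean": look["plate"].get(plate.plate_id, np.nan),
        })
    per_plate = pd.DataFrame(rows)
    regimes = ["standard_curve_instrument", "standard_curve_reconstructed",
               "log_linear_plate_mean"]
    summary = []
    t_ids = [p.plate_id for p in run.t_plates]
    s_ids = [run.pairing[t] for t in t_ids]
    pp = per_plate.set_index("plate_id")
    def _sd(v):
        return float(np.nanstd(v, ddof=1)) if np.isfinite(v).sum() >= 2 else float("nan")

    for regime in regimes:
        tv = pp.loc[t_ids, regime].to_numpy()
        sv = pp.loc[s_ids, regime].to_numpy()
        row = {"regime": regime,
               "t_mean": float(np.nanmean(tv)), "t_sd": _sd(tv),
               "s_mean": float(np.nanmean(sv)), "s_sd": _sd(sv),
               "n_plates": len(tv)}
        if len(tv) >= 2 and np.isfinite(tv).all() and np.isfinite(sv).all():
            row["p_between_amplicons"] = paired_t(tv, sv, ("T", "S")).p
        else:
            row["p_between_amplicons"] = np.nan
        summary.append(row)
    summary = pd.DataFrame(summary)
    contrasts = []
    for a, b in ((0, 1), (1, 2), (0, 2)):
        for amp, ids in (("T", t_ids), ("S", s_ids)):
            va = pp.loc[ids, regimes[a]].to_numpy()
            vb = pp.loc[ids, regimes[b]].to_numpy()
            if len(va) >= 2 and np.isfinite(va).all() and np.isfinite(vb).all():
                res = paired_t(va, vb, (regimes[a], regimes[b]))
                contrasts.append({"amplicon": amp, "regime_a": regimes[a],
                                  "regime_b": regimes[b], "statistic": res.statistic,
                                  "p": res.p})
    return {"summary": summary, "per_plate": per_plate,
            "regime_contrasts": pd.DataFrame(contrasts)}


def precision_report(records, approaches=tuple(APPROACHES)) -> dict:
    """Replicate-level CVs of ln T- and ln S-estimates per approach, pairwise
    paired t-tests (Bonferroni-adjusted), and the Feltz-Miller equality test of
    the between-sample T/S CV across approaches."""
    cv_rows = []
    for rec in records:
        if "sample_failed" in rec.qc_flags:
            continue
        for name in approaches:
            if name not in rec.ts:
                continue
            try:
                cv_rows.append({
                    "sample_id": rec.sample_id, "approach": name,
                    "cv_t": replicate_cv(rec.t_ln_replicates[name]),
                    "cv_s": replicate_cv(rec.s_ln_replicates[name]),
                })
            except DataError:
                continue
    cv = pd.DataFrame(cv_rows, columns=["sample_id", "approach", "cv_t", "cv_s"])
    mean_cv = (cv.groupby("approach")[["cv_t", "cv_s"]].mean()
                 .reindex([a for a in approaches if a in set(cv["approach"])])
                 .reset_index())

    wide = {side: cv.pivot(index="sample_id", columns="approach", values=f"cv_{side}")
            for side in ("t", "s")}
    names = [a for a in approaches if a in set(cv["approach"])]
    n_contrasts = len(names) * (len(names) - 1) // 2
    tests = []
    for side in ("t", "s"):
        w = wide[side].dropna()
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                res = paired_t(w[a], w[b], (a, b), n_contrasts=max(n_contrasts, 1))
                tests.append({"side": side.upper(), "approach_a": a, "approach_b": b,
                              "statistic": res.statistic, "p": res.p,
                              "p_bonferroni": res.p_bonferroni, "n": res.n_pairs})
    groups = []
    for name in names:
        vals = [rec.ts[name] for rec in records
                if name in rec.ts and "sample_failed" not in rec.qc_flags]
        if len(vals) >= 2:
            groups.append(vals)
    if len(groups) >= 2:
        stat, df, p = cv_equality_test(groups)
        equality = {"statistic": stat, "df": df, "p": p}
    else:
        equality = {"statistic": np.nan, "df": 0, "p": np.nan}
    return {"per_sample_cv": cv, "mean_cv": mean_cv,
            "pairwise_tests": pd.DataFrame(tests), "ts_cv_equality": equality}


def _informative(cov: np.ndarray, names):
    """Drop constant covariate columns (they carry no information and make the
    design rank-deficient in homogeneous subsets, e.g. all-female adults)."""
    cov = np.asarray(cov, float)
    keep = [j for j in range(cov.shape[1]) if np.ptp(cov[:, j]) > 0]
    return cov[:, keep], [names[j] for j in keep]


def validity_report(records, cohort: qio.CohortTable,
                    approaches=tuple(APPROACHES),
                    level: float = DEFAULT_CI_LEVEL) -> dict:
    """Cross-tissue, age and parent-offspring partial correlations of T/S per
    approach, with Fisher-z CIs and the pairwise CI-overlap difference matrix."""
    samp = cohort.samples.merge(cohort.persons, on="person_id")
    ts_frame = []
    for rec in records:
        if "sample_failed" in rec.qc_flags:
            continue
        for name, ts in rec.ts.items():
            ts_frame.append({"sample_id": rec.sample_id, "approach": name, "ts": ts})
    ts_frame = pd.DataFrame(ts_frame)
    merged = ts_frame.merge(samp, on="sample_id")
    merged["sex01"] = (merged["sex"] == "M").astype(float)
    merged["tissue01"] = (merged["tissue"] == "leukocyte").astype(float)

    results: list = []
    for name in approaches:
        sub = merged[merged["approach"] == name]
        if len(sub) == 0:
            continue
        # age: controlling for sex and tissue
        if sub["age"].notna().all() and len(sub) > 6:
            cov, names_kept = _informative(
                sub[["sex01", "tissue01"]].to_numpy(), ["sex", "tissue"])
            results.append(partial_correlation(
                sub["ts"], sub["age"], cov, metric="age", approach=name,
                covariate_names=names_kept, level=level))
        # cross-tissue: within-person leukocyte vs buccal, controlling sex/age
        both = sub.pivot_table(index="person_id", columns="tissue", values="ts")
        if {"leukocyte", "buccal"} <= set(both.columns):
            both = both.dropna()
            info = sub.drop_duplicates("person_id").set_index("person_id")
            info = info.loc[both.index]
            if len(both) > 6:
                cov, names_kept = _informative(
                    np.column_stack([info["sex01"], info["age"]]), ["sex", "age"])
                results.append(partial_correlation(
                    both["leukocyte"], both["buccal"], cov,
                    metric="cross_tissue", approach=name,
                    covariate_names=names_kept, level=level))
        # parent-offspring, controlling offspring sex, both ages, tissue
        pairs = cohort.parent_offspring_pairs()
        rep = (sub.sort_values("tissue")  # 'buccal' < 'leukocyte': prefer buccal
                  .drop_duplicates("person_id").set_index("person_id"))
        rows = [(rep.loc[p], rep.loc[c]) for p, c in pairs
                if p in rep.index and c in rep.index]
        if len(rows) > 8:
            parent = np.array([p["ts"] for p, _ in rows])
            child = np.array([c["ts"] for _, c in rows])
            cov, names_kept = _informative(np.column_stack([
                [c["sex01"] for _, c in rows],
                [p["age"] for p, _ in rows],
                [c["age"] for _, c in rows],
                [c["tissue01"] for _, c in rows],
            ]), ["offspring_sex", "parent_age", "offspring_age", "tissue"])
            results.append(partial_correlation(
                parent, child, cov, metric="parent_offspring", approach=name,
                covariate_names=names_kept, level=level))
    grid = pd.DataFrame([{
        "metric": r.metric, "approach": r.approach, "r": r.r, "n": r.n,
        "ci_low": r.ci_low, "ci_high": r.ci_high,
    } for r in results])
    diffs = []
    by_metric: Dict[str, list] = {}
    for r in results:
        by_metric.setdefault(r.metric, []).append(r)
    for metric, group in by_metric.items():
        for i, a in enumerate(group):
            for b in group[i + 1:]:
                diffs.append({"metric": metric, "approach_a": a.approach,
                              "approach_b": b.approach,
                              "differs": ci_overlap_differs(a, b)})
    return {"correlations": grid, "differences": pd.DataFrame(diffs)}


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def analyze_batch(run: qio.RunBatch, config: PipelineConfig = None,
                  cohort: Optional[qio.CohortTable] = None) -> dict:
    """Run the full analysis on an in-memory batch; returns the report bundle."""
    config = config or PipelineConfig()
    table, windows = _stage("reactions", process_reactions, run, config)
    look = _stage("efficiencies", efficiency_lookups, run, table)
    records, qc_log = _stage("ts", compute_ts_records, run, table, look,
                             config, cohort)
    bundle = {
        "reaction_table": table,
        "windows": windows,
        "efficiency_lookups": look,
        "efficiency_report": _stage("efficiency_report", efficiency_report,
                                    run, table, look),
        "records": records,
        "ts_summary": _stage("ts_summary", summarize_ts, records),
        "precision": _stage("precision", precision_report, records,
                            config.approaches),
        "qc_log": qc_log,
    }
    if cohort is not None and cohort.persons["age"].notna().any():
        bundle["validity"] = _stage("validity", validity_report, records, cohort,
                                    config.approaches, config.ci_level)
    return bundle


def run_pipeline(config: PipelineConfig) -> dict:
    """File-level entry point: read inputs, analyse, write report CSVs."""
    if not config.fluorescence_path:
        raise ConfigError("fluorescence_path is required")
    run = _stage("read", qio.read_fluorescence_table, config.fluorescence_path)
    if config.cq_path:
        for plate_id, mapping in qio.read_cq_table(config.cq_path).items():
            run.plate(plate_id).instrument_cq.update(mapping)
    cohort = (qio.read_metadata(config.metadata_path)
              if config.metadata_path else None)
    bundle = analyze_batch(run, config, cohort)

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    qio.write_results(bundle["records"], out / "ts_results.csv")
    bundle["reaction_table"].to_csv(out / "reaction_table.csv", index=False,
                                    float_format="%.12g")
    bundle["ts_summary"].to_csv(out / "ts_summary.csv", index=False,
                                float_format="%.12g")
    bundle["efficiency_report"]["summary"].to_csv(
        out / "efficiency_summary.csv", index=False, float_format="%.12g")
    bundle["efficiency_report"]["per_plate"].to_csv(
        out / "efficiency_per_plate.csv", index=False, float_format="%.12g")
    bundle["efficiency_report"]["regime_contrasts"].to_csv(
        out / "efficiency_regime_tests.csv", index=False, float_format="%.12g")
    bundle["precision"]["mean_cv"].to_csv(out / "precision_mean_cv.csv",
                                          index=False, float_format="%.12g")
    bundle["precision"]["pairwise_tests"].to_csv(out / "precision_tests.csv",
                                                 index=False, float_format="%.12g")
    bundle["qc_log"].to_csv(out / "qc_log.csv", index=False)
    if "validity" in bundle:
        bundle["validity"]["correlations"].to_csv(out / "validity_correlations.csv",
                                                  index=False, float_format="%.12g")
        bundle["validity"]["differences"].to_csv(out / "validity_differences.csv",
                                                 index=False)
    return bundle
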