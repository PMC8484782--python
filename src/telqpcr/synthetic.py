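"""Synthetic study generator: amplification curves with known truth, plates in
the study layout, and a multi-generation two-tissue cohort.

The curve model is a saturating fraction of an exponential,

    F(c) = b0 + b1*c + f_max * u(c) / (u(c) + f_max),   u(c) = f_scale * x0 * E**c,

times multiplicative log-normal noise.  Because the saturating term tends to
``u(c)`` when ``u << f_max``, the early phase is log-linear with slope exactly
``log10 E`` — which is what makes closed-form ground truth (and hence oracle
tests for every estimator) possible.  The ground-truth quantification cycle is
the threshold crossing of the noiseless saturating term.

The cohort generator builds true ln-telomere length from an age component, a
family component transmitted from mother to child, and person/tissue noise,
calibrated so the population cross-tissue, parent-offspring and age
correlations equal the configured targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Union

import numpy as np
import pandas as pd

from .efficiency import INSTRUMENT_THRESHOLD, RECONSTRUCTED_THRESHOLD, compute_cq
from .errors import ConfigError, LayoutError
from .io import CohortTable, PlateRun, ReactionCurve, RunBatch

RngLike = Union[int, np.random.Generator]


def _rng(seed: RngLike) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# amplification curves
# ---------------------------------------------------------------------------

@dataclass
class CurveModelParams:
    """Parameters of the saturating-exponential curve model.

    Fluorescence is in arbitrary instrument units scaled so that plateaus sit
    around ``f_max`` and the quantification thresholds (0.4996 / 0.4260) fall
    inside the exponential phase; ``x0`` is the initial target amount in
    arbitrary units.
    """

    true_E: float = 1.9
    x0: float = 8e-7
    f_scale: float = 1.0
    f_max: float = 10.0
    baseline_intercept: float = 0.02
    baseline_slope: float = 0.0
    noise_sd_rel: float = 0.01
    n_cycles: int = 40

    def __post_init__(self):
        if not 1.0 < self.true_E <= 2.2:
            raise ConfigError("true_E must be in (1, 2.2]")
        if self.x0 < 0 or self.f_scale <= 0 or self.f_max <= 0:
            raise ConfigError("x0 must be >= 0; f_scale, f_max > 0")
        if self.noise_sd_rel < 0 or self.n_cycles < 10:
            raise ConfigError("noise_sd_rel >= 0 and n_cycles >= 10 required")

    def true_cq(self, threshold: float = RECONSTRUCTED_THRESHOLD) -> Optional[float]:
        """Cycle at which the noiseless saturating term crosses ``threshold``
        (closed form); None when the plateau never reaches it."""
        if self.x0 == 0 or threshold >= self.f_max:
            return None
        u_star = threshold * self.f_max / (self.f_max - threshold)
        return math.log(u_star / (self.f_scale * self.x0)) / math.log(self.true_E)


def generate_curve(params: CurveModelParams, seed: RngLike, *,
                   plate_id: str = "T01", well: str = "W001", amplicon: str = "T",
                   role: str = "sample", sample_id: str = "s1",
                   replicate_index: int = 1,
                   known_concentration: Optional[float] = None,
                   cq_threshold: float = RECONSTRUCTED_THRESHOLD) -> ReactionCurve:
    """One synthetic reaction curve with ground truth attached."""
    rng = _rng(seed)
    c = np.arange(1, params.n_cycles + 1)
    u = params.f_scale * params.x0 * params.true_E ** c.astype(float)
    sat = params.f_max * u / (u + params.f_max)
    clean = params.baseline_intercept + params.baseline_slope * c + sat
    noise = np.exp(rng.normal(0.0, params.noise_sd_rel, params.n_cycles)) \
        if params.noise_sd_rel > 0 else 1.0
    return ReactionCurve(
        plate_id=plate_id, well=well, amplicon=amplicon, role=role,
        sample_id=sample_id, replicate_index=replicate_index,
        cycles=c, fluorescence=clean * noise,
        known_concentration=known_concentration,
        true_e=params.true_E, true_cq=params.true_cq(cq_threshold),
    )


def generate_standard_series(amplicon: str, params: CurveModelParams,
                             seed: RngLike, *, base_conc: float = 1e6,
                             n_levels: int = 5, fold: float = 10.0,
                             replicates: int = 3, plate_id: Optional[str] = None,
                             dilution_sd: float = 0.0,
                             well_start: int = 1) -> list:
    """A serial-dilution standard series: ``n_levels`` ``fold``-fold dilutions
    of ``params.x0``, ``replicates`` reactions each, with the known (arbitrary
    unit) concentrations recorded."""
    if n_levels < 3:
        raise ConfigError("standard series needs >= 3 levels")
    rng = _rng(seed)
    plate_id = plate_id or f"{amplicon}01"
    curves = []
    w = well_start
    for k in range(n_levels):
        conc = base_conc * fold ** (-k)
        level_x0 = params.x0 * fold ** (-k)
        if dilution_sd > 0:
            level_x0 *= math.exp(rng.normal(0.0, dilution_sd))
        for rep in range(1, replicates + 1):
            curves.append(generate_curve(
                replace(params, x0=level_x0), rng,
                plate_id=plate_id, well=f"W{w:03d}", amplicon=amplicon,
                role="standard", sample_id=f"std{k + 1}", replicate_index=rep,
                known_concentration=conc,
            ))
            w += 1
    return curves


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortParams:
    """Targets and structure for the synthetic multi-generation cohort.

    True ln-TL decomposes as  L = a*z_age + b*G + c*u  (person level) and
    TL_tissue = sqrt(rho_t)*L + sqrt(1-rho_t)*v  per tissue, where G is a
    family component transmitted mother -> child with loading phi.  With
    a = age_r/sqrt(rho_t), b^2 = family_variance and phi =
    parent_offspring_r/(b^2 * rho_t), the population cross-tissue,
    parent-offspring and age correlations of tissue-level true TL equal the
    configured targets.  ``age_slope_per_year`` (ln-TL per year) may be given
    instead of ``age_r``.
    """

    n_families: int = 25
    mothers_per_family: int = 2
    children_per_mother: int = 2
    cross_tissue_r: float = 0.70
    parent_offspring_r: float = 0.45
    age_r: float = -0.15
    age_slope_per_year: Optional[float] = None
    family_variance: float = 0.8
    sigma_ln_tl: float = 0.3
    mean_ln_tl: float = 0.0
    p_leukocyte_adult: float = 0.5
    p_leukocyte_child: float = 0.02
    p_male_child: float = 0.464
    grandmother_age: tuple = (52.6, 72.2)
    mother_age: tuple = (29.1, 43.6)
    child_age: tuple = (0.5, 24.9)

    def __post_init__(self):
        if not 0.0 < self.cross_tissue_r <= 1.0:
            raise ConfigError("cross_tissue_r must be in (0, 1]")
        if self.age_r is not None and self.age_slope_per_year is not None:
            raise ConfigError("give age_r or age_slope_per_year, not both")
        if self.sigma_ln_tl <= 0 or not 0 < self.family_variance < 1:
            raise ConfigError("sigma_ln_tl > 0 and 0 < family_variance < 1 required")


def generate_cohort(params: CohortParams, seed: RngLike) -> CohortTable:
    """Generate the cohort with true TL per sample (both tissues where drawn)."""
    rng = _rng(seed)
    rows = []
    pid = 0

    def new_person(generation, mother, age_range, sex):
        nonlocal pid
        pid += 1
        rows.append({
            "person_id": f"P{pid:05d}", "generation": generation,
            "mother_id": mother, "age": rng.uniform(*age_range), "sex": sex,
        })
        return rows[-1]["person_id"]

    for _ in range(params.n_families):
        gm = new_person(0, None, params.grandmother_age, "F")
        for _ in range(params.mothers_per_family):
            mo = new_person(1, gm, params.mother_age, "F")
            for _ in range(params.children_per_mother):
                sex = "M" if rng.random() < params.p_male_child else "F"
                new_person(2, mo, params.child_age, sex)
    persons = pd.DataFrame(rows)
    n = len(persons)

    rho_t = params.cross_tissue_r
    ages = persons["age"].to_numpy()
    z_age = (ages - ages.mean()) / ages.std()
    if params.age_slope_per_year is not None:
        a = params.age_slope_per_year * ages.std() / (params.sigma_ln_tl * math.sqrt(rho_t))
    else:
        a = params.age_r / math.sqrt(rho_t)
    b2 = params.family_variance
    c2 = 1.0 - a * a - b2
    if c2 < 0:
        raise ConfigError("age loading too large for the family variance share")
    phi = params.parent_offspring_r / (b2 * rho_t)
    if abs(phi) > 1.0:
        raise ConfigError("parent_offspring_r infeasible given family_variance and "
                          "cross_tissue_r")

    # family component transmitted down the maternal line
    fam = np.empty(n)
    idx = {p: i for i, p in enumerate(persons["person_id"])}
    for i, mother in enumerate(persons["mother_id"]):
        if mother is None:
            fam[i] = rng.standard_normal()
        else:
            fam[i] = phi * fam[idx[mother]] + math.sqrt(1.0 - phi ** 2) * rng.standard_normal()
    latent = a * z_age + math.sqrt(b2) * fam + math.sqrt(c2) * rng.standard_normal(n)

    sample_rows = []
    p_leuk = np.where(persons["generation"] < 2,
                      params.p_leukocyte_adult, params.p_leukocyte_child)
    for i, person in persons.iterrows():
        tissues = ["buccal"] + (["leukocyte"] if rng.random() < p_leuk[i] else [])
        for tissue in tissues:
            tl_tissue = math.sqrt(rho_t) * latent[i] + \
                math.sqrt(1.0 - rho_t) * rng.standard_normal()
            ln_tl = params.mean_ln_tl + params.sigma_ln_tl * tl_tissue
            sample_rows.append({
                "sample_id": f"{person['person_id']}-{tissue[0].upper()}",
                "person_id": person["person_id"], "tissue": tissue,
                "true_tl": math.exp(ln_tl),
            })
    persons = persons.copy()
    persons["complete"] = True
    samples = pd.DataFrame(sample_rows)
    return CohortTable(persons=persons[["person_id", "age", "sex", "mother_id",
                                        "generation", "complete"]],
                       samples=samples)


# ---------------------------------------------------------------------------
# plates and batches
# ---------------------------------------------------------------------------

@dataclass
class PlateLayout:
    """Reaction layout of one 100-well run."""

    samples_per_plate: int = 22
    sample_replicates: int = 3
    n_standards: int = 5
    standard_replicates: int = 3
    n_controls: int = 6
    control_replicates: int = 3
    include_ntc: bool = True
    max_wells: int = 100

    def well_count(self, n_samples: Optional[int] = None) -> int:
        ns = self.samples_per_plate if n_samples is None else n_samples
        return (ns * self.sample_replicates
                + self.n_standards * self.standard_replicates
                + self.n_controls * self.control_replicates
                + int(self.include_ntc))

    def __post_init__(self):
        if self.well_count() > self.max_wells:
            raise LayoutError(
                f"layout needs {self.well_count()} wells, disk has {self.max_wells}"
            )


@dataclass
class BatchParams:
    """Truth-level parameters of a synthetic batch.

    True efficiencies vary between plates (shared drift of reagent
    performance) and, more tightly, between reactions within a plate; T
    reactions amplify less efficiently than S reactions, as observed for
    telomeric repeats.  The same per-sample genome-copies factor feeds the T
    and S wells (same DNA aliquot), so the T/S ratio recovers true TL up to a
    global scale.
    """

    e_mean_t: float = 1.86
    e_mean_s: float = 1.92
    e_sd_within_plate: float = 0.003
    e_sd_between_plates: float = 0.002
    x0_scale_t: float = 8e-7
    x0_scale_s: float = 8e-7
    copies_sd: float = 0.2          # ln-scale spread of genome copies per sample
    pipette_sd: float = 0.02        # ln-scale per-well pipetting error
    std_x0_top: float = 1e-4        # top standard's initial amount
    std_base_conc: float = 1e6      # top standard's nominal concentration (a.u.)
    std_fold: float = 10.0
    dilution_sd: float = 0.003      # ln-scale error per dilution level per plate
    control_tl: float = 1.0         # pooled positive-control pseudo-sample
    e_clip: tuple = (1.5, 2.2)


def _draw_e(rng, mean, params: BatchParams) -> float:
    lo, hi = params.e_clip
    return float(np.clip(rng.normal(mean, params.e_sd_within_plate), lo, hi))


def generate_batch(cohort: CohortTable, seed: RngLike,
                   layout: PlateLayout = None,
                   curve: CurveModelParams = None,
                   batch: BatchParams = None) -> RunBatch:
    """Paired T and S plates for every sample of ``cohort``, in the study
    layout (triplicate samples, five triplicate ten-fold standards, six
    triplicate positive controls, one water blank per 100-well run)."""
    layout = layout or PlateLayout()
    curve = curve or CurveModelParams()
    batch = batch or BatchParams()
    rng = _rng(seed)

    samples = cohort.samples.reset_index(drop=True)
    copies = np.exp(rng.normal(0.0, batch.copies_sd, len(samples)))
    chunks = [samples.iloc[i:i + layout.samples_per_plate]
              for i in range(0, len(samples), layout.samples_per_plate)]

    t_plates, s_plates, pairing = [], [], {}
    for k, chunk in enumerate(chunks, start=1):
        t_id, s_id = f"T{k:02d}", f"S{k:02d}"
        pairing[t_id] = s_id
        for amplicon, plate_id, e_mean, x0_scale in (
            ("T", t_id, batch.e_mean_t, batch.x0_scale_t),
            ("S", s_id, batch.e_mean_s, batch.x0_scale_s),
        ):
            plate = PlateRun(plate_id, amplicon)
            plate_e_mean = e_mean + rng.normal(0.0, batch.e_sd_between_plates)
            w = 0

            def add(role, sample_id, rep, x0, known_concentration=None):
                nonlocal w
                w += 1
                p = replace(curve, x0=x0,
                            true_E=_draw_e(rng, plate_e_mean, batch)
                            if x0 > 0 else curve.true_E)
                rc = generate_curve(
                    p, rng, plate_id=plate_id, well=f"W{w:03d}",
                    amplicon=amplicon, role=role, sample_id=sample_id,
                    replicate_index=rep, known_concentration=known_concentration,
                )
                plate.reactions.append(rc)
                # emulate the instrument's Cq export: threshold crossing of the
                # background-subtracted observed curve
                observed = rc.with_fluorescence(
                    rc.fluorescence - (curve.baseline_intercept
                                       + curve.baseline_slope * rc.cycles)
                )
                cqv = compute_cq(observed, INSTRUMENT_THRESHOLD, source="instrument")
                if cqv is not None:
                    plate.instrument_cq[rc.well] = cqv.cq

            for (j, srow) in enumerate(chunk.itertuples()):
                base = x0_scale * copies[srow.Index] * \
                    (srow.true_tl if amplicon == "T" else 1.0)
                for rep in range(1, layout.sample_replicates + 1):
                    add("sample", srow.sample_id, rep,
                        base * math.exp(rng.normal(0.0, batch.pipette_sd)))
            for lvl in range(layout.n_standards):
                conc = batch.std_base_conc * batch.std_fold ** (-lvl)
                level_x0 = batch.std_x0_top * batch.std_fold ** (-lvl) * \
                    math.exp(rng.normal(0.0, batch.dilution_sd))
                for rep in range(1, layout.standard_replicates + 1):
                    add("standard", f"std{lvl + 1}", rep,
                        level_x0 * math.exp(rng.normal(0.0, batch.pipette_sd)),
                        known_concentration=conc)
            for ctl in range(1, layout.n_controls + 1):
                base = x0_scale * (batch.control_tl if amplicon == "T" else 1.0)
                for rep in range(1, layout.control_replicates + 1):
                    add("positive_control", f"ctrl{ctl}", rep,
                        base * math.exp(rng.normal(0.0, batch.pipette_sd)))
            if layout.include_ntc:
                add("ntc", "ntc", 1, 0.0)
            (t_plates if amplicon == "T" else s_plates).append(plate)
    return RunBatch(t_plates=t_plates, s_plates=s_plates, pairing=pairing)


def simulate_study(n_samples: int, seed: int,
                   cohort_params: CohortParams = None,
                   layout: PlateLayout = None,
                   curve: CurveModelParams = None,
                   batch: BatchParams = None):
    """Complete miniature study: a cohort trimmed to ``n_samples`` samples and
    the corresponding paired-plate batch.  Returns ``(cohort, run_batch)``."""
    cp = cohort_params or CohortParams()
    rng = np.random.default_rng([seed, 0])
    cohort = generate_cohort(cp, rng)
    # grow the cohort until enough samples exist
    while len(cohort.samples) < n_samples:
        cp = replace(cp, n_families=cp.n_families * 2)
        cohort = generate_cohort(cp, np.random.default_rng([seed, 0]))
    keep = cohort.samples.iloc[:n_samples]
    cohort = CohortTable(
        persons=cohort.persons[cohort.persons["person_id"].isin(keep["person_id"])]
        .reset_index(drop=True),
        samples=keep.reset_index(drop=True),
    )
    run = generate_batch(cohort, np.random.default_rng([seed, 1]),
                         layout=layout, curve=curve, batch=batch)
    return cohort, run
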