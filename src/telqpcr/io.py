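"""Data model and CSV readers/writers for qPCR plates, curves and cohort metadata.

The on-disk formats are deliberately plain, instrument-agnostic CSVs:

* **fluorescence table** (long format): one row per well per cycle with columns
  ``plate_id, amplicon, well, amplicon_group, role, sample_id, replicate_index,
  known_concentration, cycle, fluorescence`` and optionally ``instrument_cq``
  (repeated per well) plus synthetic ground-truth columns ``true_e, true_cq``.
* **metadata table**: one row per sample with columns ``sample_id, person_id,
  age, sex, tissue, mother_id`` and optionally ``true_tl``.
* **results table**: one row per sample x approach, written by
  :func:`write_results`.

All parsing uses dot decimal separators regardless of locale, and no reader
mutates its input file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, PairingError

AMPLICONS = ("T", "S")
ROLES = ("sample", "standard", "positive_control", "ntc")
TISSUES = ("leukocyte", "buccal")

#: Amplicon groups: standards are clustered separately from analytical
#: samples and positive controls, per amplicon.
GROUPS = ("G1", "G2", "G3", "G4")


def group_for(amplicon: str, role: str) -> str:
    """Amplicon group implied by (amplicon, role): G1 = T standards,
    G2 = T samples/controls, G3 = S standards, G4 = S samples/controls."""
    if amplicon == "T":
        return "G1" if role == "standard" else "G2"
    if amplicon == "S":
        return "G3" if role == "standard" else "G4"
    raise DataError(f"unknown amplicon {amplicon!r}")


@dataclass
class ReactionCurve:
    """One well's per-cycle fluorescence readout plus its annotations."""

    plate_id: str
    well: str
    amplicon: str
    role: str
    sample_id: str
    replicate_index: int
    cycles: np.ndarray
    fluorescence: np.ndarray
    amplicon_group: Optional[str] = None
    known_concentration: Optional[float] = None
    # bookkeeping set by efficiency.baseline_correct
    baseline_value: Optional[float] = None
    baseline_sd: Optional[float] = None
    # synthetic ground truth (generator output only)
    true_e: Optional[float] = None
    true_cq: Optional[float] = None

    def __post_init__(self):
        self.cycles = np.asarray(self.cycles, dtype=int)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.amplicon_group is None:
            self.amplicon_group = group_for(self.amplicon, self.role)
        self.validate()

    @property
    def reaction_id(self) -> str:
        return f"{self.plate_id}:{self.well}"

    def validate(self) -> None:
        if len(self.cycles) != len(self.fluorescence):
            raise DataError(f"{self.reaction_id}: cycles and fluorescence lengths differ")
        if len(self.cycles) == 0:
            raise DataError(f"{self.reaction_id}: empty curve")
        if self.cycles[0] != 1 or np.any(np.diff(self.cycles) != 1):
            raise DataError(
                f"{self.reaction_id}: cycles must start at 1 and increase without gaps"
            )
        if not np.all(np.isfinite(self.fluorescence)):
            raise DataError(f"{self.reaction_id}: non-finite fluorescence")
        if self.role not in ROLES:
            raise DataError(f"{self.reaction_id}: unknown role {self.role!r}")
        if (self.known_concentration is not None) != (self.role == "standard"):
            raise DataError(
                f"{self.reaction_id}: known_concentration present iff role is standard"
            )
        if self.known_concentration is not None and not self.known_concentration > 0:
            raise DataError(f"{self.reaction_id}: known_concentration must be positive")
        expected = group_for(self.amplicon, self.role)
        if self.amplicon_group != expected:
            raise DataError(
                f"{self.reaction_id}: amplicon group {self.amplicon_group} inconsistent "
                f"with amplicon {self.amplicon} / role {self.role} (expected {expected})"
            )

    def with_fluorescence(self, fluorescence, **extra) -> "ReactionCurve":
        return replace(self, fluorescence=np.asarray(fluorescence, float), **extra)


@dataclass
class PlateRun:
    """One qPCR run (disk): up to 100 reactions of a single amplicon."""

    plate_id: str
    amplicon: str
    reactions: list = field(default_factory=list)
    instrument_cq: dict = field(default_factory=dict)  # well -> Cq

    def __post_init__(self):
        if self.amplicon not in AMPLICONS:
            raise DataError(f"plate {self.plate_id}: unknown amplicon {self.amplicon!r}")
        if len(self.reactions) > 100:
            raise DataError(f"plate {self.plate_id}: more than 100 reactions")
        for rc in self.reactions:
            if rc.plate_id != self.plate_id:
                raise DataError(
                    f"plate {self.plate_id}: reaction {rc.reaction_id} has foreign plate id"
                )


@dataclass
class RunBatch:
    """A batch of paired T and S plates analysed together."""

    t_plates: list
    s_plates: list
    pairing: dict  # t_plate_id -> s_plate_id

    def __post_init__(self):
        t_ids = [p.plate_id for p in self.t_plates]
        s_ids = [p.plate_id for p in self.s_plates]
        if sorted(self.pairing) != sorted(t_ids) or sorted(self.pairing.values()) != sorted(s_ids):
            raise PairingError("pairing must be a bijection between T and S plates")

    def plates(self) -> list:
        return list(self.t_plates) + list(self.s_plates)

    def plate(self, plate_id: str) -> PlateRun:
        for p in self.plates():
            if p.plate_id == plate_id:
                return p
        raise KeyError(plate_id)

    def all_reactions(self) -> list:
        return [rc for p in self.plates() for rc in p.reactions]

    def paired_s_plate(self, t_plate_id: str) -> PlateRun:
        return self.plate(self.pairing[t_plate_id])


@dataclass
class CohortTable:
    """Cohort metadata: persons with family links plus the sample inventory.

    ``persons`` columns: person_id, age, sex, mother_id (may be <NA>),
    plus ``complete`` flagging rows with missing age/sex (kept, not dropped).
    ``samples`` columns: sample_id, person_id, tissue, true_tl (NaN when the
    truth is unknown, i.e. for real data).
    """

    persons: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        bad = set(self.samples["tissue"]) - set(TISSUES)
        if bad:
            raise DataError(f"unknown tissue labels: {sorted(bad)}")
        self._check_parentage()

    def _check_parentage(self) -> None:
        mother = dict(zip(self.persons["person_id"], self.persons["mother_id"]))
        for start in mother:
            seen = set()
            node = start
            while node is not None and not pd.isna(node):
                if node in seen:
                    raise DataError(f"cyclic parentage involving {node!r}")
                seen.add(node)
                node = mother.get(node)

    def parent_offspring_pairs(self) -> list:
        """(mother_id, child_id) pairs where both persons are in the table."""
        known = set(self.persons["person_id"])
        out = []
        for pid, mid in zip(self.persons["person_id"], self.persons["mother_id"]):
            if not pd.isna(mid) and mid in known:
                out.append((mid, pid))
        return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_FLUO_REQUIRED = [
    "plate_id", "well", "amplicon", "role", "sample_id",
    "replicate_index", "known_concentration", "cycle", "fluorescence",
]
_META_REQUIRED = ["sample_id", "person_id", "age", "sex", "tissue", "mother_id"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing column(s) {', '.join(missing)}")


def _opt(row_value):
    return None if pd.isna(row_value) else float(row_value)


def read_fluorescence_table(path) -> RunBatch:
    """Read a long-format fluorescence CSV into a :class:`RunBatch`.

    T and S plates are paired by order of first appearance in the file
    (i-th T plate with i-th S plate), matching how the synthetic generator
    writes them.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, _FLUO_REQUIRED, f"fluorescence table {path}")
    dup = df.duplicated(subset=["plate_id", "well", "cycle"])
    if dup.any():
        first = df[dup].iloc[0]
        raise DataError(
            f"duplicated (plate, well, cycle) starting at "
            f"({first['plate_id']}, {first['well']}, {first['cycle']})"
        )
    plates: dict[str, PlateRun] = {}
    t_order, s_order = [], []
    for (plate_id, well), grp in df.groupby(["plate_id", "well"], sort=False):
        grp = grp.sort_values("cycle")
        head = grp.iloc[0]
        curve = ReactionCurve(
            plate_id=str(plate_id),
            well=str(well),
            amplicon=str(head["amplicon"]),
            role=str(head["role"]),
            sample_id=str(head["sample_id"]),
            replicate_index=int(head["replicate_index"]),
            cycles=grp["cycle"].to_numpy(),
            fluorescence=grp["fluorescence"].to_numpy(),
            known_concentration=_opt(head["known_concentration"]),
            true_e=_opt(head["true_e"]) if "true_e" in grp.columns else None,
            true_cq=_opt(head["true_cq"]) if "true_cq" in grp.columns else None,
        )
        if plate_id not in plates:
            plates[plate_id] = PlateRun(str(plate_id), curve.amplicon)
            (t_order if curve.amplicon == "T" else s_order).append(str(plate_id))
        plates[plate_id].reactions.append(curve)
        if "instrument_cq" in grp.columns and not pd.isna(head["instrument_cq"]):
            plates[plate_id].instrument_cq[curve.well] = float(head["instrument_cq"])
    if len(t_order) != len(s_order):
        raise PairingError(
            f"cannot pair {len(t_order)} T plates with {len(s_order)} S plates"
        )
    return RunBatch(
        t_plates=[plates[i] for i in t_order],
        s_plates=[plates[i] for i in s_order],
        pairing=dict(zip(t_order, s_order)),
    )


def write_fluorescence_table(batch: RunBatch, path) -> None:
    """Inverse of :func:`read_fluorescence_table` (field-for-field round trip)."""
    rows = []
    for plate in batch.plates():
        for rc in plate.reactions:
            cq = plate.instrument_cq.get(rc.well)
            for c, f in zip(rc.cycles, rc.fluorescence):
                rows.append({
                    "plate_id": rc.plate_id, "well": rc.well, "amplicon": rc.amplicon,
                    "role": rc.role, "sample_id": rc.sample_id,
                    "replicate_index": rc.replicate_index,
                    "known_concentration": rc.known_concentration,
                    "cycle": int(c), "fluorescence": float(f),
                    "instrument_cq": cq, "true_e": rc.true_e, "true_cq": rc.true_cq,
                })
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_cq_table(path) -> dict:
    """Read an instrument-exported Cq CSV (plate_id, well, cq) into a
    ``{plate_id: {well: cq}}`` mapping."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["plate_id", "well", "cq"], f"Cq table {path}")
    out: dict = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["plate_id"]), {})[str(row["well"])] = float(row["cq"])
    return out


def read_metadata(path) -> CohortTable:
    """Read the sample metadata CSV into a :class:`CohortTable`.

    Samples with missing age or sex are flagged (``complete = False``) but
    never dropped; cyclic parentage and unknown tissue labels are data errors.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, _META_REQUIRED, f"metadata table {path}")
    persons = (
        df[["person_id", "age", "sex", "mother_id"]]
        .drop_duplicates(subset="person_id")
        .reset_index(drop=True)
    )
    persons["complete"] = persons["age"].notna() & persons["sex"].notna()
    samples = df[["sample_id", "person_id", "tissue"]].copy()
    samples["true_tl"] = df["true_tl"] if "true_tl" in df.columns else np.nan
    own_mother = persons["person_id"] == persons["mother_id"]
    if own_mother.any():
        raise DataError(
            f"person listed as own mother: {persons.loc[own_mother, 'person_id'].iloc[0]!r}"
        )
    return CohortTable(persons=persons, samples=samples.reset_index(drop=True))


def write_metadata(cohort: CohortTable, path) -> None:
    df = cohort.samples.merge(cohort.persons, on="person_id", how="left")
    cols = ["sample_id", "person_id", "age", "sex", "tissue", "mother_id", "true_tl"]
    df[cols].to_csv(path, index=False, float_format="%.17g")


def write_results(records, path) -> None:
    """Write T/S results, one row per sample x approach.

    ``records`` is a sequence of :class:`telqpcr.ts_ratio.TSRecord`.
    An empty sequence writes a header-only file.
    """
    rows = []
    for rec in records:
        for approach, ts in sorted(rec.ts.items()):
            rows.append({
                "sample_id": rec.sample_id,
                "tissue": rec.tissue,
                "approach": approach,
                "ts": ts,
                "t_estimate": rec.t_estimate.get(approach, np.nan),
                "s_estimate": rec.s_estimate.get(approach, np.nan),
                "t_cqs": ";".join(f"{c:.10g}" for c in rec.t_cqs.get(approach, [])),
                "s_cqs": ";".join(f"{c:.10g}" for c in rec.s_cqs.get(approach, [])),
                "t_efficiency": rec.t_efficiency.get(approach, np.nan),
                "s_efficiency": rec.s_efficiency.get(approach, np.nan),
                "qc_flags": ";".join(sorted(rec.qc_flags)),
            })
    cols = ["sample_id", "tissue", "approach", "ts", "t_estimate", "s_estimate",
            "t_cqs", "s_cqs", "t_efficiency", "s_efficiency", "qc_flags"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format="%.17g")


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["sample_id", "approach", "ts"], f"results table {path}")
    return df


# ---------------------------------------------------------------------------
# flat key:value config files
# ---------------------------------------------------------------------------

def read_config(path) -> dict:
    """Parse a flat ``key: value`` text config ('#' starts a comment)."""
    out: dict = {}
    text = Path(path).read_text()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise FormatError(f"{path}:{lineno}: expected 'key: value', got {raw!r}")
        key, value = line.split(":", 1)
        out[key.strip()] = value.strip()
    return out


def write_config(values: Mapping, path) -> None:
    with open(path, "w") as fh:
        for key, value in values.items():
            fh.write(f"{key}: {value}\n")
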