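"""Longitudinal EHR data model and its JSON-lines serialization.

A cohort is a list of :class:`PatientRecord`; each patient is an ordered
sequence of :class:`Visit` objects carrying admission/discharge timestamps
(float hours since an arbitrary cohort epoch), a set of diagnosis codes,
free-text note sections and structured lab results.  The module also derives
the two temporal features the downstream time-series encoder consumes —
visit duration (discharge minus admission) and inter-visit gap (admission
minus previous discharge) — and builds next-visit prediction instances.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

COHORT_SCHEMA = "ehrfusion-cohort/1"

#: Canonical note sections, in the order they are assembled into model input.
NOTE_SECTIONS = ("ChiefComplaint", "CurrentIllness", "MedicalHistory", "AdmissionMedication")


class CohortValidationError(ValueError):
    """A record violates a cohort invariant (names the offending patient)."""


class CohortParseError(ValueError):
    """A JSONL line could not be parsed (names the offending line)."""


@dataclass
class LabResult:
    item_id: str
    value: str
    unit: str = ""
    abnormal: bool = False

    def __post_init__(self):
        if not self.item_id:
            raise CohortValidationError("LabResult.item_id must be non-empty")
        self.value = str(self.value)


@dataclass
class Visit:
    admission_time: float
    discharge_time: float
    diagnoses: set[str] = field(default_factory=set)
    note_sections: dict[str, str] = field(default_factory=dict)
    labs: list[LabResult] = field(default_factory=list)

    def __post_init__(self):
        if self.discharge_time < self.admission_time:
            raise CohortValidationError(
                f"discharge_time {self.discharge_time} precedes admission_time "
                f"{self.admission_time}"
            )
        unknown = set(self.note_sections) - set(NOTE_SECTIONS)
        if unknown:
            raise CohortValidationError(f"unknown note sections: {sorted(unknown)}")
        self.diagnoses = set(self.diagnoses)

    @property
    def duration(self) -> float:
        return self.discharge_time - self.admission_time


@dataclass
class PatientRecord:
    patient_id: str
    visits: list[Visit]

    def __post_init__(self):
        if not self.patient_id:
            raise CohortValidationError("patient_id must be non-empty")
        if not self.visits:
            raise CohortValidationError(f"patient {self.patient_id}: no visits")
        self.visits = sorted(self.visits, key=lambda v: v.admission_time)
        times = [v.admission_time for v in self.visits]
        if any(a >= b for a, b in zip(times, times[1:])):
            raise CohortValidationError(
                f"patient {self.patient_id}: admission times not strictly increasing"
            )

    @property
    def n_visits(self) -> int:
        return len(self.visits)


@dataclass(frozen=True)
class LabelSpace:
    """Fixed, ordered coordinate system for every label and logit vector."""

    codes: tuple[str, ...]

    def __post_init__(self):
        if len(self.codes) == 0:
            raise ValueError("label space must contain at least one code")
        if len(set(self.codes)) != len(self.codes):
            raise ValueError("label space contains duplicate codes")
        object.__setattr__(self, "codes", tuple(self.codes))

    @property
    def d(self) -> int:
        return len(self.codes)

    def index(self, code: str) -> int:
        return self.codes.index(code)

    @classmethod
    def from_file(cls, path) -> "LabelSpace":
        with open(path, encoding="utf-8") as fh:
            codes = [line.strip() for line in fh if line.strip()]
        return cls(tuple(codes))

    def to_file(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(self.codes) + "\n")


@dataclass
class TemporalFeatures:
    """Per-patient w x 2 matrix: column 0 = visit duration, column 1 = gap (hours)."""

    matrix: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.mask.shape[0]:
            raise ValueError("matrix/mask shape mismatch")

    @property
    def w(self) -> int:
        return self.matrix.shape[0]


@dataclass
class PredictionInstance:
    patient_id: str
    history: list[Visit]
    target: np.ndarray

    def __post_init__(self):
        if len(self.history) < 1:
            raise ValueError("history must contain at least one visit")
        self.target = np.asarray(self.target, dtype=np.float64)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def _visit_to_dict(v: Visit) -> dict:
    return {
        "admission_time": v.admission_time,
        "discharge_time": v.discharge_time,
        "diagnoses": sorted(v.diagnoses),
        "note_sections": {s: v.note_sections[s] for s in NOTE_SECTIONS if s in v.note_sections},
        "labs": [
            {"item_id": l.item_id, "value": l.value, "unit": l.unit, "abnormal": l.abnormal}
            for l in v.labs
        ],
    }


def _visit_from_dict(d: dict) -> Visit:
    return Visit(
        admission_time=float(d["admission_time"]),
        discharge_time=float(d["discharge_time"]),
        diagnoses=set(d.get("diagnoses", [])),
        note_sections=dict(d.get("note_sections", {})),
        labs=[
            LabResult(
                item_id=l["item_id"],
                value=l["value"],
                unit=l.get("unit", ""),
                abnormal=bool(l.get("abnormal", False)),
            )
            for l in d.get("labs", [])
        ],
    )


def write_cohort(cohort: list[PatientRecord], path) -> None:
    """Write one JSON object per patient, UTF-8, keys in documented order."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in cohort:
            obj = {"patient_id": rec.patient_id, "visits": [_visit_to_dict(v) for v in rec.visits]}
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def load_cohort(path) -> list[PatientRecord]:
    """Load and validate a JSONL cohort; visits are re-sorted by admission time."""
    cohort: list[PatientRecord] = []
    seen_ids: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CohortParseError(f"line {lineno}: malformed JSON ({exc})") from exc
            try:
                rec = PatientRecord(
                    patient_id=str(obj["patient_id"]),
                    visits=[_visit_from_dict(v) for v in obj["visits"]],
                )
            except (KeyError, CohortValidationError) as exc:
                pid = obj.get("patient_id", f"<line {lineno}>")
                raise CohortValidationError(f"patient {pid}: {exc}") from exc
            if rec.patient_id in seen_ids:
                raise CohortValidationError(f"duplicate patient_id {rec.patient_id}")
            seen_ids.add(rec.patient_id)
            cohort.append(rec)
    return cohort


# ---------------------------------------------------------------------------
# Cohort operations
# ---------------------------------------------------------------------------


def filter_min_visits(cohort: list[PatientRecord], min_visits: int = 2) -> list[PatientRecord]:
    """Keep only patients with at least ``min_visits`` documented visits."""
    if min_visits < 1:
        raise ValueError("min_visits must be >= 1")
    return [p for p in cohort if p.n_visits >= min_visits]


def extract_temporal_features(patient: PatientRecord, max_len: int = 16) -> TemporalFeatures:
    """Durations and inter-visit gaps for one patient, padded/truncated to ``max_len``.

    The gap of a patient's first visit has no predecessor and is set to 0.
    Negative gaps from overlapping admissions are clamped to 0 with a logged
    warning.  If the patient has more than ``max_len`` visits the most recent
    ``max_len`` are kept; the first retained row then keeps its true gap to
    the dropped predecessor.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    visits = patient.visits
    T = len(visits)
    durations = np.array([v.duration for v in visits], dtype=np.float64)
    gaps = np.zeros(T, dtype=np.float64)
    for t in range(1, T):
        gap = visits[t].admission_time - visits[t - 1].discharge_time
        if gap < 0:
            logger.warning(
                "patient %s: visit %d overlaps previous discharge (gap %.1f h); clamped to 0",
                patient.patient_id, t + 1, gap,
            )
            gap = 0.0
        gaps[t] = gap
    full = np.column_stack([durations, gaps])
    if T > max_len:
        full = full[T - max_len:]
    n = full.shape[0]
    matrix = np.zeros((max_len, 2), dtype=np.float64)
    matrix[:n] = full
    mask = np.zeros(max_len, dtype=bool)
    mask[:n] = True
    return TemporalFeatures(matrix=matrix, mask=mask)


def build_label_vector(visit: Visit, labels: LabelSpace) -> np.ndarray:
    """Binary vector over the label space; codes outside the space are ignored."""
    return np.array([1.0 if c in visit.diagnoses else 0.0 for c in labels.codes])


def make_prediction_instances(
    patient: PatientRecord,
    labels: LabelSpace,
    expanding_window: bool = False,
) -> list[PredictionInstance]:
    """Next-visit prediction instances for one patient.

    Default: a single instance — history is every visit except the last,
    target is the label vector of the last visit.  ``expanding_window=True``
    instead emits one instance per proper prefix (history = visits 1..t,
    target = visit t+1) for every t >= 1.
    """
    if patient.n_visits < 2:
        raise ValueError(
            f"patient {patient.patient_id} has {patient.n_visits} visit(s); "
            "filter the cohort with filter_min_visits(2) first"
        )
    if expanding_window:
        return [
            PredictionInstance(
                patient_id=patient.patient_id,
                history=patient.visits[: t + 1],
                target=build_label_vector(patient.visits[t + 1], labels),
            )
            for t in range(patient.n_visits - 1)
        ]
    return [
        PredictionInstance(
            patient_id=patient.patient_id,
            history=patient.visits[:-1],
            target=build_label_vector(patient.visits[-1], labels),
        )
    ]
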