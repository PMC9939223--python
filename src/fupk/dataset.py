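"""Data model and I/O for the fluorouracil TDM analysis dataset.

The rectangular on-disk layout follows the NONMEM convention used in
pharmacometrics: one row per event, dose rows with ``EVID=1`` carrying
``AMT``/``RATE``, observation rows with ``EVID=0`` carrying ``DV`` (plasma
concentration, ng/ml), and per-subject covariate columns repeated on every
row.  This module also houses the deterministic body-composition arithmetic:
Hounsfield-window muscle area, skeletal muscle index (SMI) and the
steady-state AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SubjectRecord",
    "DoseEvent",
    "ConcentrationObservation",
    "AdverseEventRecord",
    "AnalysisDataset",
    "SchemaError",
    "read_dataset",
    "write_dataset",
    "read_ae_table",
    "write_ae_table",
    "apply_time_window_filter",
    "muscle_area_from_hu_grid",
    "compute_smi",
    "compute_auc",
    "dichotomize_grades",
    "AE_TYPES",
    "LLOQ_NG_ML",
]

#: Lower limit of quantification of the 5FU immunoassay (ng/ml).
LLOQ_NG_ML = 86.0

#: Adverse events documented in the study, CTCAE v5 graded.
AE_TYPES = (
    "polyneuropathy",
    "stomatitis",
    "hand_foot_syndrome",
    "fatigue",
    "diarrhea",
    "nausea",
    "emesis",
)

#: Default NONMEM-style column mapping (field name -> CSV column).
DEFAULT_DIALECT: dict[str, str] = {
    "subject_id": "ID",
    "time": "TIME",
    "dv": "DV",
    "amt": "AMT",
    "rate": "RATE",
    "evid": "EVID",
    "mdv": "MDV",
    "cycle": "CYCLE",
    "ss": "SS",
    "height": "HT",
    "bsa": "BSA",
    "age": "AGE",
    "sex": "SEX",
    "smi_psoas": "SMIPM",
    "smi_back": "SMIBM",
    "smi_total_hu": "SMITH",
    "smi_total_seg": "SMITS",
    "ct_offset_days": "CTDAYS",
}

#: Optional laboratory / tumour-marker covariates (numeric-or-missing).
LAB_COLUMNS: dict[str, str] = {
    "creatinine": "CREA",
    "bilirubin": "BILI",
    "alt": "ALT",
    "ast": "AST",
    "ggt": "GGT",
    "ldh": "LDH",
    "ca19_9": "CA199",
    "cea": "CEA",
}

_REQUIRED_FIELDS = ("subject_id", "time", "dv", "amt", "rate", "evid", "mdv")


class SchemaError(ValueError):
    """Raised when a dataset file violates the expected column schema."""


@dataclass(frozen=True)
class SubjectRecord:
    """Per-subject covariates; SMI values in cm²/m², height in m, BSA in m²."""

    subject_id: str
    sex: str = "male"
    age: float = np.nan
    height: float = np.nan
    bsa: float = np.nan
    smi_psoas: float = np.nan
    smi_back: float = np.nan
    smi_total_hu: float = np.nan
    smi_total_seg: float = np.nan
    ct_offset_days: float = np.nan
    labs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        for name in ("height", "bsa", "smi_psoas", "smi_back",
                     "smi_total_hu", "smi_total_seg"):
            v = getattr(self, name)
            if v is not None and np.isfinite(v) and v <= 0:
                raise ValueError(f"{name} must be positive for subject "
                                 f"{self.subject_id}, got {v}")

    def covariate(self, name: str) -> float:
        """Look up a numeric covariate by field name or lab key.

        ``sex`` is returned as a binary code (0 = male, 1 = female).
        """
        if name == "sex":
            return 1.0 if self.sex == "female" else 0.0
        if name in self.labs:
            return self.labs[name]
        return getattr(self, name)


@dataclass(frozen=True)
class DoseEvent:
    subject_id: str
    cycle: int
    dose_amount: float  # mg
    infusion_duration: float  # h
    start_time: float = 0.0  # h

    def __post_init__(self) -> None:
        if self.dose_amount <= 0:
            raise ValueError("dose_amount must be positive")
        if self.infusion_duration <= 0:
            raise ValueError("infusion_duration must be positive")

    @property
    def rate(self) -> float:
        """Zero-order infusion rate (mg/h)."""
        return self.dose_amount / self.infusion_duration


@dataclass(frozen=True)
class ConcentrationObservation:
    subject_id: str
    cycle: int
    time: float  # h since infusion start
    dv: float  # ng/ml
    steady_state_flag: bool = True

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("time must be non-negative")


@dataclass(frozen=True)
class AdverseEventRecord:
    subject_id: str
    ae_type: str
    grade: int

    def __post_init__(self) -> None:
        if self.ae_type not in AE_TYPES:
            raise ValueError(f"unknown ae_type {self.ae_type!r}")
        if self.grade not in (0, 1, 2, 3, 4):
            raise ValueError(f"grade must be in 0..4, got {self.grade}")


@dataclass
class AnalysisDataset:
    """Tidy container tying subjects, dosing, observations and AEs together."""

    subjects: list[SubjectRecord]
    doses: list[DoseEvent]
    observations: list[ConcentrationObservation]
    adverse_events: list[AdverseEventRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = {s.subject_id for s in self.subjects}
        if len(ids) != len(self.subjects):
            raise ValueError("duplicate subject_id in subjects")
        for rec in (*self.doses, *self.observations, *self.adverse_events):
            if rec.subject_id not in ids:
                raise ValueError(
                    f"record references unknown subject_id {rec.subject_id!r}")
        dosed = {d.subject_id for d in self.doses}
        for o in self.observations:
            if o.subject_id not in dosed:
                raise ValueError(
                    f"subject {o.subject_id!r} has observations but no dose")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_observations(self) -> int:
        return len(self.observations)

    def subject(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def subset(self, subject_ids: Iterable[str]) -> "AnalysisDataset":
        keep = set(subject_ids)
        return AnalysisDataset(
            subjects=[s for s in self.subjects if s.subject_id in keep],
            doses=[d for d in self.doses if d.subject_id in keep],
            observations=[o for o in self.observations if o.subject_id in keep],
            adverse_events=[a for a in self.adverse_events
                            if a.subject_id in keep],
        )


# ---------------------------------------------------------------------------
# CSV reading / writing
# ---------------------------------------------------------------------------

def _sex_from_code(code: float) -> str:
    # NONMEM convention here: 0 = male, 1 = female
    return "female" if int(code) == 1 else "male"


def _sex_to_code(sex: str) -> int:
    return 1 if sex == "female" else 0


def read_dataset(path: str | Path,
                 dialect: Mapping[str, str] | None = None,
                 lloq: float | None = LLOQ_NG_ML) -> AnalysisDataset:
    """Read a NONMEM-style rectangular CSV into an :class:`AnalysisDataset`.

    Rows with ``MDV=1`` are excluded from observations but still contribute
    dosing and covariate information.  Covariates are taken per subject from
    the first row (a warning is issued if later rows conflict).  Observations
    below ``lloq`` (ng/ml) are dropped with a warning; pass ``lloq=None`` to
    keep them.
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    for f in _REQUIRED_FIELDS:
        if cols[f] not in df.columns:
            raise SchemaError(f"missing required column {cols[f]!r}")

    def num(row_idx: int, col: str, allow_missing: bool = False) -> float:
        raw = df.at[row_idx, col] if col in df.columns else ""
        raw = raw.strip()
        if raw in ("", ".", "NA", "NaN", "nan"):
            if allow_missing:
                return np.nan
            raise SchemaError(f"row {row_idx + 2}: missing value in {col!r}")
        try:
            return float(raw)
        except ValueError:
            raise SchemaError(
                f"row {row_idx + 2}: non-numeric value {raw!r} in {col!r}"
            ) from None

    subjects: dict[str, SubjectRecord] = {}
    doses: list[DoseEvent] = []
    observations: list[ConcentrationObservation] = []
    n_blq = 0
    for i in df.index:
        sid = str(df.at[i, cols["subject_id"]]).strip()
        evid = int(num(i, cols["evid"]))
        if evid not in (0, 1):
            raise ValueError(f"row {i + 2}: unknown EVID code {evid}")
        cycle = int(num(i, cols["cycle"])) if cols["cycle"] in df.columns else 1
        if sid not in subjects:
            labs = {k: num(i, c, allow_missing=True)
                    for k, c in LAB_COLUMNS.items() if c in df.columns}
            subjects[sid] = SubjectRecord(
                subject_id=sid,
                sex=_sex_from_code(num(i, cols["sex"], True))
                if cols["sex"] in df.columns else "male",
                age=num(i, cols["age"], True) if cols["age"] in df.columns else np.nan,
                height=num(i, cols["height"], True) if cols["height"] in df.columns else np.nan,
                bsa=num(i, cols["bsa"], True) if cols["bsa"] in df.columns else np.nan,
                smi_psoas=num(i, cols["smi_psoas"], True) if cols["smi_psoas"] in df.columns else np.nan,
                smi_back=num(i, cols["smi_back"], True) if cols["smi_back"] in df.columns else np.nan,
                smi_total_hu=num(i, cols["smi_total_hu"], True) if cols["smi_total_hu"] in df.columns else np.nan,
                smi_total_seg=num(i, cols["smi_total_seg"], True) if cols["smi_total_seg"] in df.columns else np.nan,
                ct_offset_days=num(i, cols["ct_offset_days"], True) if cols["ct_offset_days"] in df.columns else np.nan,
                labs=labs,
            )
        else:
            # first value wins; warn on conflict for the key covariates
            if cols["bsa"] in df.columns:
                v = num(i, cols["bsa"], True)
                if np.isfinite(v) and np.isfinite(subjects[sid].bsa) \
                        and v != subjects[sid].bsa:
                    warnings.warn(
                        f"subject {sid}: conflicting BSA on row {i + 2}; "
                        "first value wins", stacklevel=2)
        if evid == 1:
            amt = num(i, cols["amt"])
            rate = num(i, cols["rate"])
            doses.append(DoseEvent(
                subject_id=sid, cycle=cycle, dose_amount=amt,
                infusion_duration=amt / rate,
                start_time=num(i, cols["time"])))
        else:
            mdv = int(num(i, cols["mdv"]))
            if mdv == 1:
                continue
            dv = num(i, cols["dv"])
            if lloq is not None and dv < lloq:
                n_blq += 1
                continue
            ss = bool(int(num(i, cols["ss"], True))) \
                if cols["ss"] in df.columns else True
            observations.append(ConcentrationObservation(
                subject_id=sid, cycle=cycle, time=num(i, cols["time"]),
                dv=dv, steady_state_flag=ss))
    if n_blq:
        warnings.warn(f"dropped {n_blq} observation(s) below the LLOQ "
                      f"({lloq} ng/ml)", stacklevel=2)
    return AnalysisDataset(subjects=list(subjects.values()), doses=doses,
                           observations=observations)


def write_dataset(dataset: AnalysisDataset, path: str | Path,
                  dialect: Mapping[str, str] | None = None) -> Path:
    """Write ``dataset`` as a NONMEM-style CSV readable by :func:`read_dataset`.

    Row order is deterministic: by subject, cycle, time, doses before
    observations at equal times.  Numeric fields use ``repr`` precision so the
    read/write round trip is lossless.
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    path = Path(path)
    subj = {s.subject_id: s for s in dataset.subjects}
    lab_keys = sorted({k for s in dataset.subjects for k in s.labs})
    rows: list[dict[str, object]] = []

    def covrow(s: SubjectRecord) -> dict[str, object]:
        d = {
            cols["sex"]: _sex_to_code(s.sex),
            cols["age"]: s.age,
            cols["height"]: s.height,
            cols["bsa"]: s.bsa,
            cols["smi_psoas"]: s.smi_psoas,
            cols["smi_back"]: s.smi_back,
            cols["smi_total_hu"]: s.smi_total_hu,
            cols["smi_total_seg"]: s.smi_total_seg,
            cols["ct_offset_days"]: s.ct_offset_days,
        }
        for k in lab_keys:
            d[LAB_COLUMNS[k]] = s.labs.get(k, np.nan)
        return d

    events: list[tuple[str, int, float, int, object]] = []
    for d in dataset.doses:
        events.append((d.subject_id, d.cycle, d.start_time, 0, d))
    for o in dataset.observations:
        events.append((o.subject_id, o.cycle, o.time, 1, o))
    subj_order = {s.subject_id: i for i, s in enumerate(dataset.subjects)}
    events.sort(key=lambda e: (subj_order[e[0]], e[1], e[2], e[3]))
    for sid, cycle, t, _, ev in events:
        base = {cols["subject_id"]: sid, cols["cycle"]: cycle, cols["time"]: t}
        base.update(covrow(subj[sid]))
        if isinstance(ev, DoseEvent):
            base.update({cols["evid"]: 1, cols["mdv"]: 1, cols["dv"]: ".",
                         cols["amt"]: ev.dose_amount, cols["rate"]: ev.rate,
                         cols["ss"]: "."})
        else:
            base.update({cols["evid"]: 0, cols["mdv"]: 0, cols["dv"]: ev.dv,
                         cols["amt"]: ".", cols["rate"]: ".",
                         cols["ss"]: int(ev.steady_state_flag)})
        rows.append(base)

    header = [cols[k] for k in ("subject_id", "time", "evid", "mdv", "amt",
                                "rate", "dv", "ss", "cycle", "sex", "age",
                                "height", "bsa", "smi_psoas", "smi_back",
                                "smi_total_hu", "smi_total_seg",
                                "ct_offset_days")]
    header += [LAB_COLUMNS[k] for k in lab_keys]
    out = pd.DataFrame(rows, columns=header)
    out.to_csv(path, index=False, encoding="utf-8")
    return path


def read_ae_table(path: str | Path) -> list[AdverseEventRecord]:
    """Read a CTCAE adverse-event table (columns ID, AETYPE, GRADE)."""
    df = pd.read_csv(path, encoding="utf-8")
    for c in ("ID", "AETYPE", "GRADE"):
        if c not in df.columns:
            raise SchemaError(f"missing required column {c!r}")
    return [AdverseEventRecord(subject_id=str(r.ID), ae_type=str(r.AETYPE),
                               grade=int(r.GRADE))
            for r in df.itertuples(index=False)]


def write_ae_table(records: Sequence[AdverseEventRecord],
                   path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [{"ID": r.subject_id, "AETYPE": r.ae_type, "GRADE": r.grade}
         for r in records],
        columns=["ID", "AETYPE", "GRADE"],
    ).to_csv(path, index=False, encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# Eligibility filtering
# ---------------------------------------------------------------------------

def apply_time_window_filter(
        dataset: AnalysisDataset,
        max_days: float = 205.0) -> tuple[AnalysisDataset, pd.DataFrame]:
    """Drop subjects whose CT scan lies more than ``max_days`` from sampling.

    The window is inclusive: a subject with ``|ct_offset_days| == max_days``
    is retained.  Returns the filtered dataset and an exclusion report with
    columns ``subject_id``, ``ct_offset_days``, ``reason``.
    """
    kept, excluded = [], []
    for s in dataset.subjects:
        if not np.isfinite(s.ct_offset_days):
            raise ValueError(
                f"subject {s.subject_id!r} has no ct_offset_days")
        if abs(s.ct_offset_days) <= max_days:
            kept.append(s.subject_id)
        else:
            excluded.append({
                "subject_id": s.subject_id,
                "ct_offset_days": s.ct_offset_days,
                "reason": f"|CT-to-sampling offset| > {max_days:g} days",
            })
    report = pd.DataFrame(excluded,
                          columns=["subject_id", "ct_offset_days", "reason"])
    return dataset.subset(kept), report


# ---------------------------------------------------------------------------
# Body-composition arithmetic
# ---------------------------------------------------------------------------

def muscle_area_from_hu_grid(grid: np.ndarray,
                             pixel_spacing: tuple[float, float],
                             roi_mask: np.ndarray | None = None,
                             hu_low: float = 35.0,
                             hu_high: float = 50.0) -> float:
    """Muscle cross-sectional area (cm²) from a CT attenuation grid.

    Pixels whose Hounsfield value lies in ``[hu_low, hu_high]`` (inclusive on
    both ends, the skeletal-muscle density window) and inside ``roi_mask``
    are counted and multiplied by the pixel area.  ``pixel_spacing`` is
    (row, column) spacing in mm.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2 or grid.size == 0:
        raise ValueError("grid must be a non-empty 2-D array")
    sy, sx = pixel_spacing
    if sy <= 0 or sx <= 0:
        raise ValueError("pixel spacings must be positive")
    inside = (grid >= hu_low) & (grid <= hu_high)
    if roi_mask is not None:
        roi_mask = np.asarray(roi_mask, dtype=bool)
        if roi_mask.shape != grid.shape:
            raise ValueError("roi_mask shape does not match grid shape")
        inside &= roi_mask
    # mm² -> cm²
    return float(inside.sum()) * sy * sx / 100.0


def compute_smi(muscle_area: float, height: float) -> float:
    """Skeletal muscle index (cm²/m²) = area / height²."""
    if height <= 0:
        raise ValueError("height must be positive")
    if muscle_area < 0:
        raise ValueError("muscle_area must be non-negative")
    return muscle_area / height**2


def compute_auc(css: float, infusion_duration: float) -> float:
    """Steady-state AUC (mg·h/L) = Css (ng/ml) × duration (h) × 10⁻³."""
    if css < 0:
        raise ValueError("css must be non-negative")
    if infusion_duration <= 0:
        raise ValueError("infusion_duration must be positive")
    return css * 1e-3 * infusion_duration


def dichotomize_grades(records: Sequence[AdverseEventRecord],
                       ae_type: str,
                       subject_ids: Iterable[str] | None = None
                       ) -> pd.DataFrame:
    """Collapse CTCAE grades to the severe/non-severe binary endpoint.

    A subject is coded 1 iff its maximum recorded grade for ``ae_type`` is
    >= 2 (CTCAE grades 2-4, "clinically relevant"), else 0.  Subjects listed
    in ``subject_ids`` with no record for this AE are coded 0 and flagged
    ``observed=False``.
    """
    if ae_type not in AE_TYPES:
        raise ValueError(f"unknown ae_type {ae_type!r}")
    max_grade: dict[str, int] = {}
    for r in records:
        if r.ae_type == ae_type:
            max_grade[r.subject_id] = max(max_grade.get(r.subject_id, 0),
                                          r.grade)
    ids = list(subject_ids) if subject_ids is not None \
        else sorted(max_grade)
    rows = [{"subject_id": sid,
             "outcome": int(max_grade.get(sid, 0) >= 2),
             "observed": sid in max_grade} for sid in ids]
    return pd.DataFrame(rows, columns=["subject_id", "outcome", "observed"])
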