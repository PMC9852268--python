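"""VF data model, reliability filters and study inclusion rules.

An exam is a single Humphrey 24-2 test: 54 total-deviation (TD) values plus
global indices (MD, PSD, VFI), reliability indices (false positives, false
negatives, fixation losses), test date, duration and patient age.  A series
is the date-ordered run of exams for one eye.

Reliability follows the study rule: an exam is reliable when false positives
are below 15% and false negatives below 25% (mild/moderate disease) or below
50% (severe disease); all thresholds strict.  Eyes enter analysis only with
at least seven reliable exams.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np

from .grid import blind_spot_mask, mirror_permutation

logger = logging.getLogger(__name__)

N_POINTS = 54

#: MD at or below this (dB) classes an exam as severe for the FN cutoff.
SEVERE_MD_CUTOFF = -12.0

Severity = Literal["mild_moderate", "severe"]


@dataclass(frozen=True)
class VFExam:
    """One visual-field test.

    td is the 54-vector of total-deviation values (dB) in canonical grid
    order; md/psd in dB, vfi/fp/fn in percent, fl a fraction in [0, 1],
    duration in seconds, age in years.
    """

    date: dt.date
    age: float
    td: np.ndarray
    md: float
    psd: float
    vfi: float
    fp: float
    fn: float
    fl: float
    duration: float = 300.0
    strategy: str = ""  # free text (SITA-Standard/Fast/...), carried, ignored

    def __post_init__(self) -> None:
        td = np.asarray(self.td, dtype=float)
        if td.shape != (N_POINTS,):
            raise ValueError(f"td must have {N_POINTS} values, got shape {td.shape}")
        object.__setattr__(self, "td", td)
        for name in ("fp", "fn"):
            v = getattr(self, name)
            if not (np.isnan(v) or 0.0 <= v <= 100.0):
                raise ValueError(f"{name} must lie in [0, 100], got {v}")
        if not (np.isnan(self.vfi) or 0.0 <= self.vfi <= 100.0):
            raise ValueError(f"vfi must lie in [0, 100], got {self.vfi}")


@dataclass
class VFSeries:
    """Date-ordered exams for one eye, with optional clinician label."""

    patient_id: str
    eye_id: str
    laterality: Literal["left", "right"]
    exams: list[VFExam] = field(default_factory=list)
    clinician_label: Optional[bool] = None  # True = worsening

    def __post_init__(self) -> None:
        dates = [e.date for e in self.exams]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("exams must be strictly increasing in date")

    def __len__(self) -> int:
        return len(self.exams)

    def td_matrix(self) -> np.ndarray:
        """(n_exams, 54) TD array."""
        return np.array([e.td for e in self.exams])

    def years(self) -> np.ndarray:
        """Exam times in years since the first exam, at day resolution."""
        t0 = self.exams[0].date
        return np.array([(e.date - t0).days for e in self.exams]) / 365.25


def mirror_to_right_eye(series: VFSeries) -> VFSeries:
    """Reflect a left-eye series about the vertical midline.

    Right-eye input is returned unchanged.  For left eyes the TD vector is
    permuted so index i holds the value at the right-eye-orientation
    location; global indices are reflection-invariant.
    """
    if series.laterality == "right":
        return series
    if series.laterality != "left":
        raise ValueError(f"unknown laterality {series.laterality!r}")
    perm = mirror_permutation()
    exams = [replace(e, td=e.td[perm]) for e in series.exams]
    return VFSeries(series.patient_id, series.eye_id, "right", exams,
                    series.clinician_label)


def exam_severity(exam: VFExam) -> Severity:
    """Stage an exam for the FN reliability cutoff from its own MD."""
    return "severe" if exam.md <= SEVERE_MD_CUTOFF else "mild_moderate"


def is_reliable(exam: VFExam, severity: Optional[Severity] = None) -> bool:
    """Study reliability rule; severity defaults to the exam's own MD stage.

    Strict thresholds: fp < 15 and fn < 25 (mild/moderate) or fn < 50
    (severe).  Missing (NaN) indices make the exam unreliable.
    """
    if severity is None:
        severity = exam_severity(exam)
    if np.isnan(exam.fp) or np.isnan(exam.fn):
        logger.warning("exam on %s has missing reliability indices; treated as unreliable", exam.date)
        return False
    fn_cut = 50.0 if severity == "severe" else 25.0
    return exam.fp < 15.0 and exam.fn < fn_cut


def include_series(series: VFSeries, min_vfs: int = 7) -> tuple[bool, VFSeries]:
    """Drop unreliable exams; include the eye iff >= min_vfs remain."""
    kept = [e for e in series.exams if is_reliable(e)]
    filtered = VFSeries(series.patient_id, series.eye_id, series.laterality,
                        kept, series.clinician_label)
    return len(kept) >= min_vfs, filtered


def baseline_exam(series: VFSeries) -> VFExam:
    """Pseudo-exam averaging the first two exams of the (filtered) series.

    Event-based methods compare follow-ups against this baseline.  Pointwise
    TD and every global index are arithmetic means; the date is the first
    exam's date.
    """
    if len(series.exams) < 2:
        raise ValueError("baseline requires at least 2 exams")
    a, b = series.exams[0], series.exams[1]
    return VFExam(
        date=a.date,
        age=(a.age + b.age) / 2,
        td=(a.td + b.td) / 2,
        md=(a.md + b.md) / 2,
        psd=(a.psd + b.psd) / 2,
        vfi=(a.vfi + b.vfi) / 2,
        fp=(a.fp + b.fp) / 2,
        fn=(a.fn + b.fn) / 2,
        fl=(a.fl + b.fl) / 2,
        duration=(a.duration + b.duration) / 2,
    )


def seeing_td(exam: VFExam) -> np.ndarray:
    """TD at the 52 non-blind-spot points, canonical order."""
    return exam.td[~blind_spot_mask()]


def prepare_series(series: Sequence[VFSeries], min_vfs: int = 7) -> list[VFSeries]:
    """Standard preprocessing: mirror to right-eye orientation, filter
    unreliable exams, keep eyes with >= min_vfs reliable exams."""
    out = []
    for s in series:
        ok, filtered = include_series(mirror_to_right_eye(s), min_vfs=min_vfs)
        if ok:
            out.append(filtered)
    return out
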