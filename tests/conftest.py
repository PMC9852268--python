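import datetime as dt

import numpy as np
import pytest

from vfprog.core import VFExam, VFSeries
from vfprog.grid import seeing_indices


def make_exam(date, td=0.0, md=None, vfi=95.0, psd=1.0, fp=1.0, fn=1.0,
              fl=0.1, age=60.0, duration=300.0):
    """A reliable exam with homogeneous or explicit TD."""
    td = np.full(54, float(td)) if np.isscalar(td) else np.asarray(td, dtype=float)
    if md is None:
        md = float(td[seeing_indices()].mean())
    return VFExam(date=date, age=age, td=td, md=md, psd=psd, vfi=vfi,
                  fp=fp, fn=fn, fl=fl, duration=duration)


def make_series(td_rows, start=dt.date(2015, 1, 6), spacing_days=365,
                md=None, vfi=None, patient_id="P0", eye_id="P0_OD",
                laterality="right", clinician_label=None):
    """Series from an (n, 54) TD array; optional explicit MD/VFI vectors."""
    td_rows = np.asarray(td_rows, dtype=float)
    exams = []
    for i, row in enumerate(td_rows):
        exams.append(make_exam(
            start + dt.timedelta(days=i * spacing_days), td=row,
            md=None if md is None else float(md[i]),
            vfi=95.0 if vfi is None else float(vfi[i]),
            age=60.0 + i * spacing_days / 365.25))
    return VFSeries(patient_id, eye_id, laterality, exams, clinician_label)


def series_times(n, spacing_days=365):
    """Years-since-first for the dates make_series generates."""
    return np.array([i * spacing_days for i in range(n)]) / 365.25


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
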