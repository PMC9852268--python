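"""Reading and writing VF series.

Two documented layouts, both versioned:

* CSV (wide): one row per exam.  Identity columns (patient_id, eye_id,
  laterality, date), exam columns (age, md, psd, vfi, fp, fn, fl, duration,
  strategy, clinician_label) and 54 TD columns named by right-eye-orientation
  grid coordinates with ``m`` marking a minus sign, e.g. ``td_x9_ym3``.
  On disk TD is always right-eye oriented, so ``td_x15_y3`` is the blind spot
  for every row; left-eye values are permuted to their own lattice on read.
  The first line is a comment header ``# vfprog-vf-series v1``.

* JSON: one object with format/version keys and a ``series`` list mirroring
  the in-memory structure.

Writers emit ISO-8601 dates; readers re-sort exams by date (logged) and
raise on malformed rows with their location.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import VFExam, VFSeries
from .grid import grid_coordinates, mirror_permutation

logger = logging.getLogger(__name__)

FORMAT_NAME = "vfprog-vf-series"
FORMAT_VERSION = 1
CSV_HEADER = f"# {FORMAT_NAME} v{FORMAT_VERSION}"

_META_COLS = ["patient_id", "eye_id", "laterality", "date", "age", "md", "psd",
              "vfi", "fp", "fn", "fl", "duration", "strategy", "clinician_label"]


def _coord_name(x: int, y: int) -> str:
    sx = f"m{-x}" if x < 0 else str(x)
    sy = f"m{-y}" if y < 0 else str(y)
    return f"td_x{sx}_y{sy}"


def td_column_names() -> list[str]:
    return [_coord_name(x, y) for x, y in grid_coordinates()]


def _series_to_rows(series: VFSeries) -> list[dict]:
    cols = td_column_names()
    perm = mirror_permutation()
    rows = []
    for e in series.exams:
        td = e.td[perm] if series.laterality == "left" else e.td
        row = {
            "patient_id": series.patient_id, "eye_id": series.eye_id,
            "laterality": series.laterality, "date": e.date.isoformat(),
            "age": e.age, "md": e.md, "psd": e.psd, "vfi": e.vfi,
            "fp": e.fp, "fn": e.fn, "fl": e.fl, "duration": e.duration,
            "strategy": e.strategy,
            "clinician_label": "" if series.clinician_label is None
            else str(bool(series.clinician_label)),
        }
        row.update(dict(zip(cols, td)))
        rows.append(row)
    return rows


def write_vf_series_csv(series: Sequence[VFSeries], path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame([r for s in series for r in _series_to_rows(s)],
                      columns=_META_COLS + td_column_names())
    with open(path, "w") as fh:
        fh.write(CSV_HEADER + "\n")
        df.to_csv(fh, index=False)


def read_vf_series_csv(path: str | Path) -> list[VFSeries]:
    path = Path(path)
    df = pd.read_csv(path, comment="#", dtype={"patient_id": str, "eye_id": str})
    cols = td_column_names()
    missing = [c for c in cols + ["patient_id", "eye_id", "laterality", "date"]
               if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing[:5]}")
    perm = mirror_permutation()
    out = []
    for (pid, eid), grp in df.groupby(["patient_id", "eye_id"], sort=False):
        lat = str(grp["laterality"].iloc[0])
        if lat not in ("left", "right"):
            raise ValueError(f"{path}: eye {eid}: unknown laterality {lat!r}")
        grp = grp.copy()
        grp["_date"] = pd.to_datetime(grp["date"]).dt.date
        if not grp["_date"].is_monotonic_increasing:
            logger.info("eye %s: exams out of date order in %s; re-sorted", eid, path)
            grp = grp.sort_values("_date")
        exams = []
        for idx, row in grp.iterrows():
            td = row[cols].to_numpy(dtype=float)
            if np.isnan(td).any():
                raise ValueError(f"{path}: row {idx}: missing TD values")
            if lat == "left":
                td = td[perm]
            exams.append(VFExam(
                date=row["_date"], age=float(row["age"]), td=td,
                md=float(row["md"]), psd=float(row["psd"]), vfi=float(row["vfi"]),
                fp=float(row["fp"]), fn=float(row["fn"]), fl=float(row["fl"]),
                duration=float(row["duration"]),
                strategy="" if pd.isna(row.get("strategy")) else str(row["strategy"]),
            ))
        lab = grp["clinician_label"].iloc[0]
        label = None if pd.isna(lab) or lab == "" else str(lab) == "True"
        out.append(VFSeries(str(pid), str(eid), lat, exams, label))
    return out


def write_vf_series_json(series: Sequence[VFSeries], path: str | Path) -> None:
    doc = {"format": FORMAT_NAME, "version": FORMAT_VERSION, "series": []}
    for s in series:
        doc["series"].append({
            "patient_id": s.patient_id, "eye_id": s.eye_id,
            "laterality": s.laterality, "clinician_label": s.clinician_label,
            "exams": [{
                "date": e.date.isoformat(), "age": e.age,
                "td": [round(v, 6) for v in e.td.tolist()],
                "md": e.md, "psd": e.psd, "vfi": e.vfi, "fp": e.fp,
                "fn": e.fn, "fl": e.fl, "duration": e.duration,
                "strategy": e.strategy,
            } for e in s.exams],
        })
    Path(path).write_text(json.dumps(doc))


def read_vf_series_json(path: str | Path) -> list[VFSeries]:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != FORMAT_NAME:
        raise ValueError(f"{path}: not a {FORMAT_NAME} file")
    out = []
    for i, s in enumerate(doc["series"]):
        exams = []
        for j, e in enumerate(s["exams"]):
            td = np.asarray(e["td"], dtype=float)
            if td.shape != (54,):
                raise ValueError(f"{path}: series {i} exam {j}: td length {td.size} != 54")
            exams.append(VFExam(
                date=dt.date.fromisoformat(e["date"]), age=e["age"], td=td,
                md=e["md"], psd=e["psd"], vfi=e["vfi"], fp=e["fp"], fn=e["fn"],
                fl=e["fl"], duration=e.get("duration", 300.0),
                strategy=e.get("strategy", ""),
            ))
        if [e.date for e in exams] != sorted(e.date for e in exams):
            logger.info("series %s: exams re-sorted by date", s["eye_id"])
            exams.sort(key=lambda e: e.date)
        out.append(VFSeries(s["patient_id"], s["eye_id"], s["laterality"],
                            exams, s.get("clinician_label")))
    return out


def read_vf_series(path: str | Path) -> list[VFSeries]:
    """Dispatch on extension (.csv or .json)."""
    path = Path(path)
    if path.suffix == ".json":
        return read_vf_series_json(path)
    return read_vf_series_csv(path)


def write_vf_series(series: Sequence[VFSeries], path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        write_vf_series_json(series, path)
    else:
        write_vf_series_csv(series, path)
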