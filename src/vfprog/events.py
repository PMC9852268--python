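"""Event-based progression labelers: GPA-like pointwise change, AGIS score,
CIGTS score.

All three compare follow-up exams against a baseline formed by averaging the
first two reliable exams, and require the change to be *sustained* on three
consecutive follow-up fields:

* GPA-like: a follow-up is flagged when >= 3 of the 52 seeing points have
  dropped below their test-retest change threshold (a per-point table at the
  alpha < 0.05 level, by default simulated from the cohort noise model);
  worsening = 3 consecutive flagged follow-ups.
* AGIS: the 0-20 defect score (nasal 0-2 + superior 0-9 + inferior 0-9,
  from counts/depths of contiguous depressed sites) rises by >= 4 on three
  consecutive follow-ups.
* CIGTS: the 0-20 score built from the total-deviation probability map
  (levels 0-4 at the 5/2/1/0.5% cutoffs, isolated defects down-weighted via
  neighbor levels, sum/10.4) rises by >= 3 on three consecutive follow-ups.

Total deviation (not pattern deviation) is used throughout.  Sector and
depth tables for AGIS ship as a versioned JSON config; the score logic
validates only the structural caps so real trial tables can be dropped in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from .core import VFSeries, baseline_exam, seeing_td, VFExam
from .grid import grid_coordinates, seeing_indices
from .trend import ProgressionCall

SUSTAIN = 3                # consecutive follow-up fields
GPA_MIN_POINTS = 3
AGIS_WORSEN_INCREASE = 4.0
CIGTS_WORSEN_INCREASE = 3.0
CIGTS_DIVISOR = 10.4       # 52 points x level 4 / 10.4 = 20
MIN_EXAMS_EVENT = 5        # 2 baseline + 3 follow-ups


# ---------------------------------------------------------------------------
# AGIS tables

@lru_cache(maxsize=1)
def load_agis_tables() -> dict:
    """Load and structurally validate the shipped AGIS config."""
    with resources.files("vfprog.data").joinpath("agis_tables.json").open() as fh:
        doc = json.load(fh)
    return validate_agis_tables(doc)


def validate_agis_tables(doc: dict) -> dict:
    sites = doc["sites"]
    if len(sites) != 52:
        raise ValueError(f"AGIS table must cover 52 sites, got {len(sites)}")
    sectors = [s["sector"] for s in sites]
    counts = {k: sectors.count(k) for k in ("nasal", "upper", "lower")}
    if counts != {"nasal": 6, "upper": 23, "lower": 23}:
        raise ValueError(f"AGIS sector sizes must be 6/23/23, got {counts}")
    if doc["nasal_rules"]["cap"] != 2 or doc["hemifield_rules"]["cap"] != 9:
        raise ValueError("AGIS component caps must be 2 (nasal) and 9 (hemifields)")
    if any(s["depth_db"] <= 0 for s in sites):
        raise ValueError("AGIS depth cutoffs must be positive dB depressions")
    return doc


def _site_arrays(doc: dict) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Align config sites with the canonical 52 seeing points.

    Returns (sector codes, depth cutoffs, coordinates) ordered like
    seeing_td().  Sector codes: 0 nasal, 1 upper, 2 lower.
    """
    coords = grid_coordinates()[seeing_indices()]
    lookup = {(s["x"], s["y"]): s for s in doc["sites"]}
    code = {"nasal": 0, "upper": 1, "lower": 2}
    try:
        sectors = np.array([code[lookup[(x, y)]["sector"]] for x, y in coords])
        depths = np.array([lookup[(x, y)]["depth_db"] for x, y in coords])
    except KeyError as e:
        raise ValueError(f"AGIS table missing site {e}") from None
    return sectors, depths, coords


def _components(indices: np.ndarray, coords: np.ndarray,
                cross_midline: bool) -> list[list[int]]:
    """Connected components (8-neighborhood, 6-degree steps) among a subset
    of seeing-point indices; optionally forbid edges across the horizontal
    meridian."""
    idx = list(indices)
    pos = {i: coords[i] for i in idx}
    seen: set[int] = set()
    comps = []
    for start in idx:
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            i = stack.pop()
            comp.append(i)
            xi, yi = pos[i]
            for j in idx:
                if j in seen:
                    continue
                xj, yj = pos[j]
                if abs(xi - xj) <= 6 and abs(yi - yj) <= 6:
                    if not cross_midline and yi * yj < 0:
                        continue
                    seen.add(j)
                    stack.append(j)
        comps.append(comp)
    return comps


def agis_score(exam: VFExam, tables: Optional[dict] = None) -> int:
    """AGIS defect score, an integer in [0, 20].

    Nasal component (0-2): 1 point for >= 3 contiguous nasal sites depressed
    beyond their cutoffs, plus 1 when all six nasal sites are depressed by at
    least the deep-nasal level.  Each hemifield (0-9): requires a cluster of
    >= 3 contiguous depressed sites; 1 base point, up to 3 more for the
    number of depressed sites, up to 5 more for the fraction of depressed
    sites at increasing depths.
    """
    doc = validate_agis_tables(tables) if tables is not None else load_agis_tables()
    sectors, depths, coords = _site_arrays(doc)
    td = seeing_td(exam)
    depressed = td <= -depths

    score = 0
    # nasal
    nr = doc["nasal_rules"]
    nasal_idx = np.flatnonzero((sectors == 0) & depressed)
    comps = _components(nasal_idx, coords, nr["contiguity_crosses_midline"])
    if any(len(c) >= nr["min_contiguous"] for c in comps):
        score += 1
        if np.all(td[sectors == 0] <= -nr["deep_all_db"]):
            score += 1

    # hemifields
    hr = doc["hemifield_rules"]
    for sec in (1, 2):
        dep_idx = np.flatnonzero((sectors == sec) & depressed)
        comps = _components(dep_idx, coords, hr["contiguity_crosses_midline"])
        if not any(len(c) >= hr["cluster_min"] for c in comps):
            continue
        comp_score = 1
        n_dep = dep_idx.size
        for lo, hi, pts in hr["count_bins"]:
            if lo <= n_dep <= hi:
                comp_score += pts
        deps = -td[dep_idx]
        for level in hr["depth_increments_db"]:
            if np.mean(deps >= level) >= hr["depth_fraction"]:
                comp_score += 1
        score += min(comp_score, hr["cap"])
    return int(min(score, 20))


# ---------------------------------------------------------------------------
# CIGTS

@dataclass(frozen=True)
class NormativeCutoffs:
    """Per-point TD percentile cutoffs for the probability map.

    cutoffs has shape (52, 4): the TD values (dB, negative) below which a
    point is abnormal at p < 5, 2, 1 and 0.5 percent, in seeing-point order.
    """

    cutoffs: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.cutoffs, dtype=float)
        if c.shape != (52, 4):
            raise ValueError(f"cutoffs must be (52, 4), got {c.shape}")
        if np.any(np.diff(c, axis=1) > 0):
            raise ValueError("cutoffs must be non-increasing across 5/2/1/0.5%")
        object.__setattr__(self, "cutoffs", c)


def td_probability_level(exam: VFExam, normative: NormativeCutoffs) -> np.ndarray:
    """Defect level 0-4 per seeing point from the TD probability cutoffs."""
    td = seeing_td(exam)[:, None]
    return (td < normative.cutoffs).sum(axis=1)


@lru_cache(maxsize=2)
def _neighbor_lists(cross_midline: bool = True) -> tuple[tuple[int, ...], ...]:
    """Immediate grid neighbors among the 52 seeing points."""
    coords = grid_coordinates()[seeing_indices()]
    out = []
    for i, (xi, yi) in enumerate(coords):
        nb = []
        for j, (xj, yj) in enumerate(coords):
            if i == j:
                continue
            if abs(xi - xj) <= 6 and abs(yi - yj) <= 6:
                if not cross_midline and yi * yj < 0:
                    continue
                nb.append(j)
        out.append(tuple(nb))
    return tuple(out)


def cigts_score(exam: VFExam, normative: NormativeCutoffs,
                cross_midline: bool = True) -> float:
    """CIGTS defect score in [0, 20].

    Each point's weight is the minimum of its own probability level and the
    two highest levels among its immediate neighbors, so an isolated defect
    weighs zero; the score is the weight sum over 52 points divided by 10.4.
    """
    levels = td_probability_level(exam, normative)
    nbrs = _neighbor_lists(cross_midline)
    weights = np.empty(52)
    for i in range(52):
        lv = np.sort(levels[list(nbrs[i])])[::-1]
        weights[i] = min(levels[i], lv[0], lv[1]) if lv.size >= 2 else 0
    return float(weights.sum() / CIGTS_DIVISOR)


# ---------------------------------------------------------------------------
# Threshold table (GPA)

@dataclass(frozen=True)
class ThresholdTable:
    """Per-point alpha < 0.05 test-retest change thresholds (dB, <= 0)."""

    thresholds: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        if t.shape != (52,):
            raise ValueError(f"threshold table must have 52 entries, got {t.shape}")
        if np.any(t > 0):
            raise ValueError("change thresholds must be <= 0 dB")
        object.__setattr__(self, "thresholds", t)


# ---------------------------------------------------------------------------
# Sustained-change flags

def _sustained(flags: Sequence[bool], run: int = SUSTAIN) -> bool:
    count = 0
    for f in flags:
        count = count + 1 if f else 0
        if count >= run:
            return True
    return False


def _check_event_preconditions(series: VFSeries) -> None:
    if len(series) < MIN_EXAMS_EVENT:
        raise ValueError(
            f"event-based methods need >= {MIN_EXAMS_EVENT} exams "
            f"(2 baseline + {SUSTAIN} follow-ups); got {len(series)}")


def gpa_flag(series: VFSeries, thresholds: ThresholdTable,
             same_points: bool = False) -> ProgressionCall:
    """GPA-like pointwise event analysis.

    Change at each seeing point is follow-up TD minus the two-exam baseline
    mean; a point qualifies when the change is at or below its threshold.
    Worsening needs >= 3 qualifying points on 3 consecutive follow-ups; with
    ``same_points=True`` the *same* 3 points must qualify throughout the run.
    """
    _check_event_preconditions(series)
    base = seeing_td(baseline_exam(series))
    qual_sets = []
    for exam in series.exams[2:]:
        change = seeing_td(exam) - base
        qual_sets.append(frozenset(np.flatnonzero(change <= thresholds.thresholds).tolist()))
    if same_points:
        flags = []
        for k in range(len(qual_sets) - SUSTAIN + 1):
            inter = frozenset.intersection(*qual_sets[k:k + SUSTAIN])
            flags.append(len(inter) >= GPA_MIN_POINTS)
        worsening = any(flags)
    else:
        per_exam = [len(q) >= GPA_MIN_POINTS for q in qual_sets]
        worsening = _sustained(per_exam)
    return ProgressionCall("gpa", worsening,
                           {"points_per_followup": [len(q) for q in qual_sets],
                            "qualifying_sets": [sorted(q) for q in qual_sets]})


def _score_flag(series: VFSeries, scores: np.ndarray, base_score: float,
                increase: float, method: str) -> ProgressionCall:
    deltas = scores - base_score
    per_exam = (deltas >= increase).tolist()
    return ProgressionCall(method, _sustained(per_exam),
                           {"baseline_score": float(base_score),
                            "followup_scores": scores.tolist(),
                            "increases": deltas.tolist()})


def agis_flag(series: VFSeries, tables: Optional[dict] = None) -> ProgressionCall:
    """Worsening iff the AGIS score rises >= 4 over baseline on 3 consecutive
    follow-up fields."""
    _check_event_preconditions(series)
    base = agis_score(baseline_exam(series), tables)
    scores = np.array([agis_score(e, tables) for e in series.exams[2:]], dtype=float)
    return _score_flag(series, scores, base, AGIS_WORSEN_INCREASE, "agis")


def cigts_flag(series: VFSeries, normative: NormativeCutoffs,
               cross_midline: bool = True) -> ProgressionCall:
    """Worsening iff the CIGTS score rises >= 3 over baseline on 3
    consecutive follow-up fields."""
    _check_event_preconditions(series)
    base = cigts_score(baseline_exam(series), normative, cross_midline)
    scores = np.array([cigts_score(e, normative, cross_midline)
                       for e in series.exams[2:]])
    return _score_flag(series, scores, base, CIGTS_WORSEN_INCREASE, "cigts")
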