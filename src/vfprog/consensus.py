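"""Consensus reference standard and inter-method agreement.

Six algorithmic labelers (GPA, AGIS, CIGTS, MD slope, VFI slope, PLR) each
produce a per-eye worsening flag; the reference standard calls an eye
worsening when at least k = 4 of the six agree.  Because the six split 3
event-based / 3 trend-based, any 4-of-6 consensus necessarily contains at
least one method of each family.

Agreement statistics: pairwise Cohen kappa (large-sample CI and the
conventional verbal band), Fleiss kappa across all raters (seeded bootstrap
CI over eyes), and upset-style overlap counts of the flag combinations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import VFSeries, prepare_series
from .events import NormativeCutoffs, ThresholdTable, agis_flag, cigts_flag, gpa_flag
from .trend import md_slope_flag, plr_flag, vfi_slope_flag

#: canonical method order: event-based then trend-based
METHOD_ORDER = ("gpa", "agis", "cigts", "md", "vfi", "plr")
EVENT_METHODS = ("gpa", "agis", "cigts")
TREND_METHODS = ("md", "vfi", "plr")
DEFAULT_K = 4

#: clinician chart choices mapped to a worsening flag
CLINICIAN_WORSENING = {"likely worsening", "possible worsening"}
CLINICIAN_NOT = {"stable", "possible improvement", "likely improvement"}

KAPPA_BANDS = ((0.2, "slight"), (0.4, "fair"), (0.6, "moderate"),
               (0.8, "substantial"), (np.inf, "almost perfect"))


@dataclass(frozen=True)
class ConsensusLabel:
    n_flagging: int
    worsening: bool


def consensus_label(flags: Sequence[bool], k: int = DEFAULT_K) -> ConsensusLabel:
    """k-of-6 consensus over the method flags, canonical order."""
    if len(flags) != 6:
        raise ValueError(f"expected exactly 6 method flags, got {len(flags)}")
    n = int(sum(bool(f) for f in flags))
    return ConsensusLabel(n_flagging=n, worsening=n >= k)


def map_clinician_choice(choice: str) -> bool:
    """Chart checkbox -> worsening flag (likely/possible worsening are
    worsening; stable and improvement choices are not)."""
    c = choice.strip().lower()
    if c in CLINICIAN_WORSENING:
        return True
    if c in CLINICIAN_NOT:
        return False
    raise ValueError(f"unknown clinician choice {choice!r}")


def label_cohort(series: Sequence[VFSeries], thresholds: ThresholdTable,
                 normative: NormativeCutoffs, k: int = DEFAULT_K,
                 preprocess: bool = True) -> pd.DataFrame:
    """Run all six labelers over a cohort.

    Returns a DataFrame indexed by eye_id with boolean columns in
    METHOD_ORDER, ``n_flagging``, ``consensus`` (k-of-6), ``clinician``
    (if carried on the series), patient_id and the initial MD of the
    filtered series (used for severity stratification).
    """
    if preprocess:
        series = prepare_series(series)
    rows = {}
    for s in series:
        flags = {
            "gpa": gpa_flag(s, thresholds).worsening,
            "agis": agis_flag(s).worsening,
            "cigts": cigts_flag(s, normative).worsening,
            "md": md_slope_flag(s).worsening,
            "vfi": vfi_slope_flag(s).worsening,
            "plr": plr_flag(s).worsening,
        }
        lab = consensus_label([flags[m] for m in METHOD_ORDER], k=k)
        rows[s.eye_id] = {**flags, "n_flagging": lab.n_flagging,
                          "consensus": lab.worsening,
                          "clinician": s.clinician_label,
                          "patient_id": s.patient_id,
                          "initial_md": s.exams[0].md}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "eye_id"
    return df


def consensus_prevalence_by_k(flag_df: pd.DataFrame) -> pd.Series:
    """Fraction of eyes labeled worsening for every k in 1..6."""
    n_flag = flag_df[list(METHOD_ORDER)].sum(axis=1)
    return pd.Series({k: float((n_flag >= k).mean()) for k in range(1, 7)},
                     name="prevalence")


# ---------------------------------------------------------------------------
# Agreement statistics

@dataclass(frozen=True)
class KappaResult:
    kappa: float
    se: Optional[float]
    ci: tuple[float, float]
    band: str
    defined: bool = True


def _band(kappa: float) -> str:
    if np.isnan(kappa):
        return "undefined"
    if kappa < 0:
        return "poor"
    for hi, name in KAPPA_BANDS:
        if kappa < hi or hi is np.inf:
            return name
    return "almost perfect"


def cohen_kappa(flags_a: Sequence[bool], flags_b: Sequence[bool],
                level: float = 0.95) -> KappaResult:
    """Cohen's kappa for two binary raters with its large-sample CI.

    kappa = (p_o - p_e) / (1 - p_e).  Degenerate marginals (chance agreement
    p_e = 1, i.e. both raters constant) make kappa undefined; this is flagged
    rather than silently reported as 0.
    """
    from scipy import stats
    a = np.asarray(flags_a, dtype=bool)
    b = np.asarray(flags_b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("flag vectors must be 1-D and equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 eyes")
    p_o = float(np.mean(a == b))
    pa, pb = a.mean(), b.mean()
    p_e = float(pa * pb + (1 - pa) * (1 - pb))
    if 1 - p_e < 1e-12:
        return KappaResult(np.nan, None, (np.nan, np.nan), "undefined", False)
    kappa = (p_o - p_e) / (1 - p_e)
    se = np.sqrt(p_o * (1 - p_o) / n) / (1 - p_e)
    z = stats.norm.ppf(0.5 + level / 2)
    return KappaResult(float(kappa), float(se),
                       (float(kappa - z * se), float(kappa + z * se)),
                       _band(kappa))


def kappa_matrix(flag_df: pd.DataFrame,
                 methods: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Pairwise Cohen-kappa table over the given flag columns."""
    methods = list(methods or METHOD_ORDER)
    out = pd.DataFrame(np.eye(len(methods)), index=methods, columns=methods)
    for i, mi in enumerate(methods):
        for j in range(i + 1, len(methods)):
            mj = methods[j]
            k = cohen_kappa(flag_df[mi].astype(bool), flag_df[mj].astype(bool)).kappa
            out.loc[mi, mj] = out.loc[mj, mi] = k
    return out


def _fleiss_point(table: np.ndarray) -> float:
    """Fleiss kappa from an (subjects x categories) count table."""
    n = table.sum(axis=1)
    if np.any(n != n[0]):
        raise ValueError("all subjects must have the same number of ratings")
    m = int(n[0])
    N = table.shape[0]
    p_cat = table.sum(axis=0) / (N * m)
    P_i = ((table ** 2).sum(axis=1) - m) / (m * (m - 1))
    P_bar = P_i.mean()
    P_e = float((p_cat ** 2).sum())
    if 1 - P_e < 1e-12:
        return np.nan
    return float((P_bar - P_e) / (1 - P_e))


def fleiss_kappa(flag_matrix: np.ndarray, level: float = 0.95,
                 n_boot: int = 1000, seed: int = 0) -> KappaResult:
    """Fleiss kappa over two categories for an (eyes x raters) boolean
    matrix, with a seeded bootstrap CI over eyes."""
    M = np.asarray(flag_matrix)
    if M.ndim != 2 or M.shape[1] < 2:
        raise ValueError("need an (eyes x raters) matrix with >= 2 raters")
    if pd.isna(M).any():
        raise ValueError("flag matrix has missing entries")
    M = M.astype(bool)
    counts = np.stack([(~M).sum(axis=1), M.sum(axis=1)], axis=1)
    kappa = _fleiss_point(counts)
    rng = np.random.default_rng(seed)
    N = M.shape[0]
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, N, size=N)
        boots.append(_fleiss_point(counts[idx]))
    boots = np.asarray(boots, dtype=float)
    alpha = (1 - level) / 2
    lo, hi = np.nanpercentile(boots, [100 * alpha, 100 * (1 - alpha)])
    return KappaResult(kappa, float(np.nanstd(boots)), (float(lo), float(hi)),
                       _band(kappa), defined=not np.isnan(kappa))


def overlap_counts(flag_df: pd.DataFrame,
                   methods: Optional[Sequence[str]] = None
                   ) -> tuple[pd.Series, pd.Series]:
    """Upset-style summary of the boolean flag matrix.

    Returns (per-method totals, exact-combination counts).  Combination keys
    are '+'-joined method names; their counts sum to the number of eyes
    flagged by at least one method.
    """
    methods = list(methods or METHOD_ORDER)
    flags = flag_df[methods].astype(bool)
    totals = flags.sum(axis=0)
    combos = (
        flags[flags.any(axis=1)]
        .apply(lambda row: "+".join(m for m in methods if row[m]), axis=1)
        .value_counts()
        .sort_index()
    )
    return totals, combos
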