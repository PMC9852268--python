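"""Synthetic longitudinal VF cohorts.

Generates per-eye series whose marginal statistics match the study
population this package targets: about 12 reliable exams per eye spaced
~1.04 years apart, initial MD around -2.5 +/- 3.9 dB, global MD slopes of
-0.17 +/- 0.42 dB/yr, patient age 62 +/- 12 years, and roughly 70% of
patients contributing both eyes.

The generative model is deliberately simple and fully documented (it is a
testing stand-in, not a physiologic simulator):

* per patient, a baseline total-deviation field = a few Gaussian defect
  clusters recentred so the mean TD equals the drawn initial MD; both eyes
  share the shape up to a small independent perturbation;
* each eye's true trajectory is baseline + global linear trend; eyes
  selected as *truly progressing* additionally lose sensitivity in one
  contiguous same-hemifield focal cluster at a steeper slope;
* test-retest noise is heteroscedastic: per-point sd grows linearly with
  defect depth (sd = floor + coef * max(0, -TD_true)), the property that
  makes event-based criteria nontrivial;
* global indices are documented surrogates, not Humphrey formulas:
  MD = mean TD over the 52 seeing points, VFI = 100 * (1 - mean defect
  depth / 30) clipped to [0, 100], PSD = sd of seeing TD;
* reliability indices are drawn near the study's marginals, with a small
  fraction of deliberately unreliable exams to exercise the filters;
* the clinician label is a Bernoulli reading of the progression truth with
  configurable sensitivity/specificity.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy import stats, optimize

from .core import VFExam, VFSeries
from .events import NormativeCutoffs, ThresholdTable
from .grid import grid_coordinates, mirror_permutation, seeing_indices

VFI_DEPTH_SCALE = 30.0  # dB of mean defect depth mapping VFI 100 -> 0


@dataclass
class CohortConfig:
    """Cohort-level generative parameters (defaults = study conditions)."""

    n_patients: int = 100
    p_both_eyes: float = 0.71          # 8705 eyes / 5099 patients
    n_exams_mean: float = 11.9         # reliable exams per eye
    n_exams_sd: float = 4.59
    n_exams_floor: int = 7             # inclusion requires >= 7 reliable
    spacing_mean: float = 1.04         # years
    spacing_sd: float = 0.37
    age_mean: float = 62.0
    age_sd: float = 12.0
    md0_mean: float = -2.51            # dB
    md0_sd: float = 3.86
    slope_mean: float = -0.17          # dB/yr, global trend
    slope_sd: float = 0.42
    frac_progressing: float = 0.15
    focal_slope_mean: float = -1.5     # dB/yr extra decline in the cluster
    focal_slope_sd: float = 0.4
    focal_cluster_size: int = 6
    noise_floor_sd: float = 1.2        # dB at TD_true = 0
    noise_depth_coef: float = 0.2      # dB of sd per dB of defect depth
    p_unreliable: float = 0.05
    fp_mean: float = 0.05              # percent
    fp_sd: float = 0.68
    fn_mean: float = 2.05
    fn_sd: float = 5.42
    fl_mean: float = 0.13
    fl_sd: float = 0.19
    clinician_tpr: float = 0.42
    clinician_fpr: float = 0.16
    start_date: dt.date = field(default_factory=lambda: dt.date(2000, 1, 3))
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if name.endswith("_sd") and v < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("p_both_eyes", "frac_progressing", "p_unreliable",
                     "clinician_tpr", "clinician_fpr"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be a probability")
        if self.spacing_mean <= 0:
            raise ValueError("spacing_mean must be positive")
        if self.n_exams_floor < 1:
            raise ValueError("n_exams_floor must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        import yaml
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "start_date" in doc and isinstance(doc["start_date"], str):
            doc["start_date"] = dt.date.fromisoformat(doc["start_date"])
        return cls(**doc)


@dataclass(frozen=True)
class EyeTruth:
    """Ground truth injected for one synthetic eye."""

    eye_id: str
    global_slope: float
    focal_cluster: tuple[int, ...]   # seeing-point indices, right-eye frame
    focal_slope: float
    truly_progressing: bool


def _floored_count_mean(mu: float, sd: float, floor: int) -> float:
    """E[max(floor, round(N(mu, sd)))] by exact summation."""
    ks = np.arange(floor - 12 * int(sd + 1), int(mu + 12 * sd) + 2)
    p = stats.norm.cdf(ks + 0.5, mu, sd) - stats.norm.cdf(ks - 0.5, mu, sd)
    return float(np.sum(np.maximum(floor, ks) * p))


def _latent_exam_mean(cfg: CohortConfig) -> float:
    """Latent normal mean such that the floored/rounded exam count has the
    configured mean despite the >= floor truncation."""
    target, sd, floor = cfg.n_exams_mean, cfg.n_exams_sd, cfg.n_exams_floor
    if sd == 0:
        return target
    f = lambda mu: _floored_count_mean(mu, sd, floor) - target
    lo, hi = target - 6 * sd, target + 1
    if f(lo) > 0 or f(hi) < 0:  # floor dominates; best effort
        return target
    return float(optimize.brentq(f, lo, hi, xtol=1e-6))


def _grow_cluster(rng: np.random.Generator, size: int) -> np.ndarray:
    """Random contiguous cluster of seeing points within one hemifield."""
    coords = grid_coordinates()[seeing_indices()]
    hemi = 1 if rng.random() < 0.5 else -1
    pool = np.flatnonzero(np.sign(coords[:, 1]) == hemi)
    cluster = [int(rng.choice(pool))]
    while len(cluster) < size:
        frontier = []
        for i in pool:
            if i in cluster:
                continue
            xi, yi = coords[i]
            for j in cluster:
                xj, yj = coords[j]
                if abs(xi - xj) <= 6 and abs(yi - yj) <= 6:
                    frontier.append(int(i))
                    break
        if not frontier:
            break
        cluster.append(int(rng.choice(frontier)))
    return np.array(sorted(cluster))


def _baseline_field(rng: np.random.Generator, md0: float) -> np.ndarray:
    """Baseline true TD over the 52 seeing points with mean exactly md0."""
    coords = grid_coordinates()[seeing_indices()].astype(float)
    td = np.zeros(52)
    for _ in range(rng.poisson(1.5)):
        center = coords[rng.integers(52)]
        depth = rng.uniform(3.0, 15.0)
        width = rng.uniform(5.0, 10.0)
        d2 = ((coords - center) ** 2).sum(axis=1)
        td -= depth * np.exp(-d2 / (2 * width ** 2))
    return td + (md0 - td.mean())


def _surrogate_indices(td_seeing: np.ndarray) -> tuple[float, float, float]:
    """(MD, VFI, PSD) surrogates from seeing-point TD."""
    md = float(td_seeing.mean())
    vfi = float(np.clip(100.0 * (1.0 - np.mean(np.maximum(0.0, -td_seeing))
                                 / VFI_DEPTH_SCALE), 0.0, 100.0))
    psd = float(td_seeing.std(ddof=1))
    return md, vfi, psd


def _noise_sd(cfg: CohortConfig, td_true: np.ndarray) -> np.ndarray:
    return cfg.noise_floor_sd + cfg.noise_depth_coef * np.maximum(0.0, -td_true)


def generate_cohort(cfg: CohortConfig,
                    seed: Optional[int] = None) -> tuple[list[VFSeries], list[EyeTruth]]:
    """Generate a seeded, reproducible cohort.

    Returns (series, truths) aligned by index.  Left eyes are stored on the
    left-eye lattice (as real data would be); truths index the right-eye
    frame.  Exam counts refer to *reliable* exams; deliberately unreliable
    extras are interleaved at rate ``p_unreliable`` for the filters to drop.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    latent_mean = _latent_exam_mean(cfg)
    perm = mirror_permutation()
    seeing = seeing_indices()

    series: list[VFSeries] = []
    truths: list[EyeTruth] = []
    for p in range(cfg.n_patients):
        pid = f"P{p:05d}"
        age0 = rng.normal(cfg.age_mean, cfg.age_sd)
        md0 = rng.normal(cfg.md0_mean, cfg.md0_sd)
        shape = _baseline_field(rng, md0)
        lateralities = ["right"] + (["left"] if rng.random() < cfg.p_both_eyes else [])
        for lat in lateralities:
            eye_id = f"{pid}_{'OD' if lat == 'right' else 'OS'}"
            base = shape + rng.normal(0.0, 0.5, size=52)
            base += (md0 - base.mean())
            g_slope = rng.normal(cfg.slope_mean, cfg.slope_sd)
            progressing = rng.random() < cfg.frac_progressing
            if progressing:
                cluster = _grow_cluster(rng, cfg.focal_cluster_size)
                f_slope = min(-0.1, rng.normal(cfg.focal_slope_mean, cfg.focal_slope_sd))
            else:
                cluster, f_slope = np.array([], dtype=int), 0.0

            n_rel = max(cfg.n_exams_floor, int(round(rng.normal(latent_mean, cfg.n_exams_sd))))
            reliable_flags = [True] * n_rel
            extras = rng.random(n_rel) < cfg.p_unreliable
            for i in np.flatnonzero(extras)[::-1]:
                reliable_flags.insert(int(i), False)

            t = 0.0
            start = cfg.start_date + dt.timedelta(days=int(rng.integers(0, 365)))
            exams = []
            used_days: set[int] = set()
            for rel in reliable_flags:
                day = int(round(t * 365.25))
                while day in used_days:
                    day += 1
                used_days.add(day)
                t = day / 365.25  # trajectories evaluated at day resolution
                td_true = base + g_slope * t
                if progressing:
                    td_true = td_true.copy()
                    td_true[cluster] += f_slope * t
                sd = _noise_sd(cfg, td_true)
                td_s = td_true + rng.normal(0.0, 1.0, size=52) * sd
                md, vfi, psd = _surrogate_indices(td_s)
                if rel:
                    fp = float(np.clip(abs(rng.normal(cfg.fp_mean, cfg.fp_sd)), 0, 14.9))
                    fn_cap = 49.9 if md <= -12 else 24.9
                    fn = float(np.clip(abs(rng.normal(cfg.fn_mean, cfg.fn_sd)), 0, fn_cap))
                else:
                    if rng.random() < 0.5:
                        fp = float(rng.uniform(15.0, 40.0))
                        fn = float(np.clip(abs(rng.normal(cfg.fn_mean, cfg.fn_sd)), 0, 100))
                    else:
                        fp = float(np.clip(abs(rng.normal(cfg.fp_mean, cfg.fp_sd)), 0, 14.9))
                        fn = float(rng.uniform(55.0, 90.0))
                td54 = np.zeros(54)
                td54[seeing] = td_s
                td54[~np.isin(np.arange(54), seeing)] = 0.0
                if lat == "left":
                    td54 = td54[perm]
                exams.append(VFExam(
                    date=start + dt.timedelta(days=day),
                    age=age0 + t, td=td54, md=md, psd=psd, vfi=vfi,
                    fp=fp, fn=fn,
                    fl=float(np.clip(rng.normal(cfg.fl_mean, cfg.fl_sd), 0, 1)),
                    duration=float(max(120.0, rng.normal(300.0, 60.0))),
                    strategy="SITA-Standard",
                ))
                t += max(0.05, rng.normal(cfg.spacing_mean, cfg.spacing_sd))
            p_label = cfg.clinician_tpr if progressing else cfg.clinician_fpr
            label = bool(rng.random() < p_label)
            series.append(VFSeries(pid, eye_id, lat, exams, label))
            truths.append(EyeTruth(eye_id, float(g_slope), tuple(int(i) for i in cluster),
                                   float(f_slope), progressing))
    return series, truths


def simulate_normative_thresholds(cfg: CohortConfig, n_reps: int = 5000,
                                  seed: Optional[int] = None) -> ThresholdTable:
    """Per-point alpha < 0.05 change thresholds from simulated stable eyes.

    Monte Carlo of test-retest change (single follow-up minus two-exam
    baseline mean) in *stable* eyes drawn from the cohort's baseline-field
    distribution, under the heteroscedastic noise model; the threshold is
    the 5th percentile of change at each seeing point.  Because per-point
    noise grows with defect depth, thresholds widen for a damaged cohort;
    with homoscedastic noise (noise_depth_coef = 0, sd s) they converge to
    -1.645 * s * sqrt(1.5).
    """
    if n_reps < 1000:
        warnings.warn(f"{n_reps} replicates is below the recommended 1000; "
                      "thresholds will be noisy", stacklevel=2)
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    changes = np.empty((n_reps, 52))
    for r in range(n_reps):
        field_true = _baseline_field(rng, rng.normal(cfg.md0_mean, cfg.md0_sd))
        sd = _noise_sd(cfg, field_true)
        draws = rng.normal(0.0, 1.0, size=(3, 52)) * sd
        changes[r] = draws[2] - draws[:2].mean(axis=0)
    thr = np.percentile(changes, 5.0, axis=0)
    return ThresholdTable(np.minimum(thr, 0.0))


def default_normative_cutoffs(cfg: CohortConfig) -> NormativeCutoffs:
    """Analytic TD probability-map cutoffs under the normal-eye noise model:
    the 5/2/1/0.5 percent quantiles of N(0, sd_point^2)."""
    sd = _noise_sd(cfg, np.zeros(52))
    z = stats.norm.ppf([0.05, 0.02, 0.01, 0.005])
    return NormativeCutoffs(np.outer(sd, z))
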