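"""Classifier evaluation: ROC/AUC with bootstrap CIs, exact binomial
(Clopper-Pearson) intervals for rates, the minmax AUC estimate for a rater
observed at a single operating point, and severity-stratified performance.

The minmax construction addresses a rater (e.g. a clinician reading charts)
who produces a single binary call, hence one (FPR, TPR) point rather than a
curve.  Assuming the rater's latent ROC is monotone and concave, the least
favorable concave curve through the point is the two-segment polyline
(0,0) -> (FPR, TPR) -> (1,1); its area is the point estimate,

    AUC = FPR * TPR / 2 + (1 - FPR) * (1 + TPR) / 2,

and the most favorable concave curve (the chance-anchored tangent extended
to the top edge) gives the upper bound 1 - FPR / (2 * TPR).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as _skm


@dataclass(frozen=True)
class OperatingPoint:
    tpr: float
    fpr: float
    n_pos: Optional[int] = None
    n_neg: Optional[int] = None

    def __post_init__(self) -> None:
        for r in (self.tpr, self.fpr):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rates must lie in [0, 1], got {r}")


@dataclass(frozen=True)
class RocSummary:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    n_pos: int
    n_neg: int


def roc_auc(scores: Sequence[float], labels: Sequence[bool], level: float = 0.95,
            n_boot: int = 2000, seed: int = 0) -> RocSummary:
    """ROC curve and trapezoidal AUC with a seeded bootstrap CI over eyes."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to build a ROC curve")
    fpr, tpr, thr = _skm.roc_curve(labels, scores)
    auc = float(_skm.auc(fpr, tpr))
    rng = np.random.default_rng(seed)
    n = scores.size
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        lb = labels[idx]
        if lb.all() or not lb.any():
            continue
        boots.append(_skm.roc_auc_score(lb, scores[idx]))
    alpha = (1 - level) / 2
    lo, hi = np.percentile(boots, [100 * alpha, 100 * (1 - alpha)])
    return RocSummary(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc,
                      auc_ci=(float(lo), float(hi)), n_pos=n_pos, n_neg=n_neg)


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial CI from beta quantiles; lower is 0 at k=0, upper 1 at k=n."""
    if not 0 <= k <= n or n <= 0:
        raise ValueError(f"need 0 <= k <= n with n > 0, got k={k}, n={n}")
    alpha = 1 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


@dataclass(frozen=True)
class MinmaxAuc:
    estimate: float
    lower: float
    upper: float
    below_chance: bool


def minmax_auc_binary(point: OperatingPoint) -> MinmaxAuc:
    """Minmax AUC estimate and concave-envelope bounds for a binary rater.

    The point estimate (= lower bound under the concavity assumption) is the
    polyline area through (FPR, TPR); the upper bound extends the chord from
    the origin at slope TPR/FPR until it reaches TPR = 1.  A below-chance
    point (TPR < FPR) is reported as-is with a warning, not mirrored.
    """
    f, t = point.fpr, point.tpr
    below = t < f
    if below:
        warnings.warn(f"operating point (FPR={f}, TPR={t}) is below chance; "
                      "reporting unmirrored estimate", stacklevel=2)
    estimate = f * t / 2 + (1 - f) * (1 + t) / 2
    upper = 1.0 if f == 0 else (1 - f / (2 * t) if t > 0 else 0.5)
    upper = float(np.clip(upper, estimate, 1.0))
    return MinmaxAuc(float(estimate), float(estimate), upper, below)


@dataclass(frozen=True)
class StratumPerformance:
    name: str
    n: int
    n_pos: int
    roc: Optional[RocSummary]


def subgroup_performance(scores: Sequence[float], labels: Sequence[bool],
                         initial_md: Sequence[float], md_cut: float = -6.0,
                         seed: int = 0) -> dict[str, StratumPerformance]:
    """Per-stratum ROC/AUC after splitting eyes on initial MD at ``md_cut``.

    Strata partition the input exactly: ``severe`` is initial MD < md_cut,
    ``mild`` is >= md_cut.  An empty or single-class stratum is reported with
    roc=None rather than raising.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    md = np.asarray(initial_md, dtype=float)
    if not (scores.size == labels.size == md.size):
        raise ValueError("scores, labels and initial_md must be aligned")
    out = {}
    for name, mask in (("severe", md < md_cut), ("mild", md >= md_cut)):
        n = int(mask.sum())
        n_pos = int(labels[mask].sum())
        roc = None
        if 0 < n_pos < n:
            roc = roc_auc(scores[mask], labels[mask], seed=seed)
        else:
            warnings.warn(f"stratum {name!r} (n={n}, positives={n_pos}) cannot "
                          "support a ROC curve", stacklevel=2)
        out[name] = StratumPerformance(name, n, n_pos, roc)
    return out
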