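"""Rasterization and sequence preparation for the worsening classifier.

Each exam's 54-point field is deposited on a 12 x 12 lattice covering
[-30, 30] degrees (5-degree cells) and smoothed with a small isotropic
kernel (radius 1 cell by default) that spreads each point's value into its
neighborhood and fills the lattice cells the 24-2 pattern does not test;
cells outside any kernel support keep the fill value.  The smoothing is
normalized by the deposited-weight map, so altering one VF point only
perturbs the raster inside that point's kernel support.

A RasterSequence stacks the rasters with the 8 per-exam global metrics
(age yr, VFI %, PSD dB, MD dB, FN %, FP %, duration s, FL) and the exam
times; sequences are variable-length and unevenly spaced, with the spacing
passed to the model as a delta-time input channel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.signal import convolve2d

from ..core import VFSeries
from ..grid import grid_coordinates, seeing_indices

RASTER_SIZE = 12
CELL_DEG = 5.0
METRIC_NAMES = ("age", "vfi", "psd", "md", "fn", "fp", "duration", "fl")


def _gaussian_kernel(radius: int, sigma: float) -> np.ndarray:
    ax = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2 * sigma ** 2))
    return k / k.sum()


def rasterize_vf(td: np.ndarray, kernel_radius: int = 1, sigma: float = 0.8,
                 fill: float = 0.0) -> np.ndarray:
    """Map a 54-vector of right-eye-oriented TD onto a 12 x 12 grid.

    Blind-spot points are not deposited; their cells are interpolated from
    neighboring kernel support.
    """
    coords = grid_coordinates()
    seeing = seeing_indices()
    v = np.zeros((RASTER_SIZE, RASTER_SIZE))
    w = np.zeros((RASTER_SIZE, RASTER_SIZE))
    for i in seeing:
        x, y = coords[i]
        col = int((x + 30) // CELL_DEG)
        row = int((30 - y) // CELL_DEG)
        v[row, col] += td[i]
        w[row, col] += 1.0
    k = _gaussian_kernel(kernel_radius, sigma)
    vb = convolve2d(v, k, mode="same")
    wb = convolve2d(w, k, mode="same")
    out = np.full((RASTER_SIZE, RASTER_SIZE), float(fill))
    mask = wb > 1e-10
    out[mask] = vb[mask] / wb[mask]
    return out


@dataclass(frozen=True)
class RasterSequence:
    """Time-ordered classifier input for one eye."""

    eye_id: str
    patient_id: str
    frames: np.ndarray   # (T, 12, 12)
    metrics: np.ndarray  # (T, 8), METRIC_NAMES order
    times: np.ndarray    # (T,) years since first exam
    label: Optional[bool] = None

    def __post_init__(self) -> None:
        T = self.frames.shape[0]
        if self.frames.shape != (T, RASTER_SIZE, RASTER_SIZE) or T < 1:
            raise ValueError(f"frames must be (T, 12, 12) with T >= 1, got {self.frames.shape}")
        if self.metrics.shape != (T, len(METRIC_NAMES)):
            raise ValueError(f"metrics must be (T, 8), got {self.metrics.shape}")
        if self.times.shape != (T,):
            raise ValueError("times must align with frames")

    def __len__(self) -> int:
        return self.frames.shape[0]


def build_sequences(series: Sequence[VFSeries],
                    labels: Mapping[str, bool],
                    kernel_radius: int = 1, sigma: float = 0.8) -> list[RasterSequence]:
    """Rasterize prepared (right-oriented, filtered) series into sequences."""
    out = []
    for s in series:
        frames = np.stack([rasterize_vf(e.td, kernel_radius, sigma) for e in s.exams])
        metrics = np.array([[e.age, e.vfi, e.psd, e.md, e.fn, e.fp, e.duration, e.fl]
                            for e in s.exams])
        out.append(RasterSequence(s.eye_id, s.patient_id, frames, metrics,
                                  s.years(), labels.get(s.eye_id)))
    return out


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint patient-level partition; both eyes of a patient co-assigned."""

    train: frozenset
    val: frozenset
    test: frozenset
    fractions: tuple[float, float, float]
    seed: int

    def __post_init__(self) -> None:
        if (self.train & self.val) or (self.train & self.test) or (self.val & self.test):
            raise ValueError("split sets must be disjoint")


def split_patients(patient_ids: Sequence[str],
                   fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                   seed: int = 0) -> SplitSpec:
    """Reproducible 80/10/10 patient-level split."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    ids = sorted(set(patient_ids))
    if len(ids) < 3:
        raise ValueError("need at least 3 patients to form three splits")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(round(fractions[0] * len(ids)))
    n_val = max(1, int(round(fractions[1] * len(ids))))
    n_train = min(n_train, len(ids) - n_val - 1)
    train = frozenset(ids[i] for i in perm[:n_train])
    val = frozenset(ids[i] for i in perm[n_train:n_train + n_val])
    test = frozenset(ids[i] for i in perm[n_train + n_val:])
    return SplitSpec(train, val, test, tuple(fractions), seed)


def partition_sequences(seqs: Sequence[RasterSequence], spec: SplitSpec
                        ) -> tuple[list[RasterSequence], list[RasterSequence], list[RasterSequence]]:
    parts: dict[str, list[RasterSequence]] = {"train": [], "val": [], "test": []}
    lookup = {**{p: "train" for p in spec.train}, **{p: "val" for p in spec.val},
              **{p: "test" for p in spec.test}}
    for s in seqs:
        parts[lookup[s.patient_id]].append(s)
    assert not ({q.patient_id for q in parts["train"]} & {q.patient_id for q in parts["test"]})
    return parts["train"], parts["val"], parts["test"]


def truncate_sequences(seqs: Sequence[RasterSequence], r: int) -> list[RasterSequence]:
    """Drop the final r exams from each sequence (labels untouched); every
    eye keeps at least one exam."""
    if r < 0:
        raise ValueError("r must be >= 0")
    out = []
    for s in seqs:
        keep = max(1, len(s) - r)
        out.append(replace(s, frames=s.frames[:keep], metrics=s.metrics[:keep],
                           times=s.times[:keep]))
    return out
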