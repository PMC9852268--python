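"""Convolutional-LSTM worsening classifier.

Architecture: a single 2-D convolutional LSTM layer (3 x 3 kernel) runs over
the per-exam rasters; the 8 global metrics and the inter-exam spacing are
broadcast over the grid as extra input channels, which lets one recurrent
layer fuse spatial and scalar information and accept unevenly spaced,
variable-length series.  The final hidden state is global-average-pooled,
batch-normalized, and mapped through a dense sigmoid head to P(worsening).

Training: Adam on binary cross-entropy, mini-batches of equal-length
sequences, early stopping on validation loss.  All randomness (weight
initialization, batch shuffling) flows from a single seed, so fits are
reproducible in single-threaded execution.

Usage follows the Model/Results convention: construct
``ConvLSTMWorseningModel(train, val)``, call ``fit()`` and use the returned
results object for prediction, evaluation and ``summary()``.
"""

from __future__ import annotations

import copy
import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ..evaluation import RocSummary, roc_auc
from .autodiff import Adam, Tensor, concat_channels, conv2d
from .data import RASTER_SIZE, RasterSequence

TD_SCALE = 30.0   # dB scale for raster normalization
DT_SCALE = 2.0    # years


@dataclass
class _Normalizer:
    metric_mean: np.ndarray
    metric_sd: np.ndarray

    @classmethod
    def from_sequences(cls, seqs: Sequence[RasterSequence]) -> "_Normalizer":
        allm = np.concatenate([s.metrics for s in seqs])
        sd = allm.std(axis=0)
        return cls(allm.mean(axis=0), np.where(sd > 1e-9, sd, 1.0))

    def input_tensor(self, s: RasterSequence) -> np.ndarray:
        """(T, 10, 12, 12): raster + 8 z-scored metrics + delta-t channel."""
        T = len(s)
        x = np.empty((T, 10, RASTER_SIZE, RASTER_SIZE))
        x[:, 0] = s.frames / TD_SCALE
        z = (s.metrics - self.metric_mean) / self.metric_sd
        x[:, 1:9] = z[:, :, None, None]
        dt = np.diff(s.times, prepend=s.times[0]) / DT_SCALE
        x[:, 9] = dt[:, None, None]
        return x


class _ConvLSTMNet:
    """Parameter container + forward pass (batch of equal-length sequences)."""

    N_CHANNELS = 10

    def __init__(self, hidden: int = 8, kernel: int = 3, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.hidden, self.kernel = hidden, kernel
        cin = self.N_CHANNELS + hidden
        fan = cin * kernel * kernel
        self.Wc = Tensor(rng.normal(0, 1 / np.sqrt(fan), (4 * hidden, cin, kernel, kernel)),
                         requires_grad=True)
        bc = np.zeros(4 * hidden)
        bc[hidden:2 * hidden] = 1.0  # forget-gate bias
        self.bc = Tensor(bc, requires_grad=True)
        self.gamma = Tensor(np.ones(hidden), requires_grad=True)
        self.beta = Tensor(np.zeros(hidden), requires_grad=True)
        self.Wd = Tensor(rng.normal(0, 1 / np.sqrt(hidden), (hidden, 1)), requires_grad=True)
        self.bd = Tensor(np.zeros(1), requires_grad=True)
        self.run_mean = np.zeros(hidden)
        self.run_var = np.ones(hidden)
        self.bn_momentum = 0.9
        self.bn_eps = 1e-5

    @property
    def params(self) -> list[Tensor]:
        return [self.Wc, self.bc, self.gamma, self.beta, self.Wd, self.bd]

    def forward(self, x: np.ndarray, training: bool) -> Tensor:
        """x: (N, T, 10, 12, 12) -> probabilities (N, 1)."""
        N, T = x.shape[:2]
        H = self.hidden
        pad = self.kernel // 2
        h = Tensor(np.zeros((N, H, RASTER_SIZE, RASTER_SIZE)))
        c = Tensor(np.zeros((N, H, RASTER_SIZE, RASTER_SIZE)))
        for t in range(T):
            xt = Tensor(x[:, t])
            z = conv2d(concat_channels([xt, h]), self.Wc, self.bc, padding=pad)
            i = z.slice_channels(0, H).sigmoid()
            f = z.slice_channels(H, 2 * H).sigmoid()
            o = z.slice_channels(2 * H, 3 * H).sigmoid()
            g = z.slice_channels(3 * H, 4 * H).tanh()
            c = f * c + i * g
            h = o * c.tanh()
        pooled = h.mean(axis=(2, 3))  # (N, H)
        if training and N > 1:
            mu = pooled.mean(axis=0, keepdims=True)
            xc = pooled - mu
            var = (xc * xc).mean(axis=0, keepdims=True)
            xhat = xc / (var + self.bn_eps).sqrt()
            m = self.bn_momentum
            self.run_mean = m * self.run_mean + (1 - m) * mu.data.ravel()
            self.run_var = m * self.run_var + (1 - m) * var.data.ravel()
        else:
            xhat = (pooled - Tensor(self.run_mean[None, :])) \
                / Tensor(np.sqrt(self.run_var + self.bn_eps)[None, :])
        feat = xhat * self.gamma + self.beta
        return (feat @ self.Wd + self.bd).sigmoid()

    def state_dict(self) -> dict:
        return {"params": [p.data.copy() for p in self.params],
                "run_mean": self.run_mean.copy(), "run_var": self.run_var.copy()}

    def load_state_dict(self, state: dict) -> None:
        for p, d in zip(self.params, state["params"]):
            p.data = d.copy()
        self.run_mean = state["run_mean"].copy()
        self.run_var = state["run_var"].copy()


def _bce(p: Tensor, y: np.ndarray) -> Tensor:
    yt = Tensor(y.reshape(-1, 1))
    eps = 1e-7
    return -((yt * (p + eps).log() + (1.0 - yt) * (1.0 - p + eps).log()).mean())


def _length_batches(seqs: Sequence[RasterSequence], batch_size: int,
                    rng: Optional[np.random.Generator] = None) -> list[list[int]]:
    """Mini-batches of indices grouped by sequence length."""
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        by_len.setdefault(len(s), []).append(i)
    batches = []
    for T in sorted(by_len):
        idx = by_len[T]
        if rng is not None:
            idx = [idx[j] for j in rng.permutation(len(idx))]
        batches += [idx[k:k + batch_size] for k in range(0, len(idx), batch_size)]
    if rng is not None:
        order = rng.permutation(len(batches))
        batches = [batches[j] for j in order]
    return batches


class ConvLSTMWorseningModel:
    """Worsening classifier over rasterized VF sequences.

    Parameters
    ----------
    train, val : sequences with boolean labels.  Validation drives early
        stopping; omit it to train for the full epoch budget.
    hidden_channels : width of the convolutional LSTM state.
    seed : controls weight init and batch shuffling.
    """

    def __init__(self, train: Sequence[RasterSequence],
                 val: Optional[Sequence[RasterSequence]] = None,
                 hidden_channels: int = 8, kernel: int = 3, seed: int = 0):
        if not train:
            raise ValueError("training set is empty")
        if any(s.label is None for s in train):
            raise ValueError("all training sequences need labels")
        self.train = list(train)
        self.val = list(val) if val else []
        self.hidden_channels = hidden_channels
        self.kernel = kernel
        self.seed = seed
        self.normalizer = _Normalizer.from_sequences(self.train)

    # -- internal -----------------------------------------------------------
    def _inputs(self, seqs: Sequence[RasterSequence]) -> list[np.ndarray]:
        return [self.normalizer.input_tensor(s) for s in seqs]

    def _eval_loss(self, net: _ConvLSTMNet, xs, ys, batch_size: int) -> float:
        losses, ns = [], []
        for batch in _length_batches_from_arrays(xs, batch_size):
            xb = np.stack([xs[i] for i in batch])
            p = net.forward(xb, training=False)
            losses.append(_bce(p, ys[list(batch)]).data.item() * len(batch))
            ns.append(len(batch))
        return float(np.sum(losses) / np.sum(ns))

    def fit(self, epochs: int = 30, lr: float = 1e-2, batch_size: int = 32,
            patience: int = 6) -> "ConvLSTMWorseningResults":
        rng = np.random.default_rng(self.seed)
        net = _ConvLSTMNet(self.hidden_channels, self.kernel, seed=int(rng.integers(2**31)))
        opt = Adam(net.params, lr=lr)
        xs = self._inputs(self.train)
        ys = np.array([float(s.label) for s in self.train])
        xv = self._inputs(self.val) if self.val else []
        yv = np.array([float(s.label) for s in self.val]) if self.val else np.array([])

        history = []
        best = (np.inf, 0, net.state_dict())
        t0 = time.time()
        for epoch in range(epochs):
            batches = _length_batches(self.train, batch_size, rng)
            ep_loss, n_seen = 0.0, 0
            for batch in batches:
                xb = np.stack([xs[i] for i in batch])
                p = net.forward(xb, training=True)
                loss = _bce(p, ys[batch])
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}: "
                        f"p range [{p.data.min()}, {p.data.max()}]")
                opt.zero_grad()
                loss.backward()
                opt.step()
                ep_loss += loss.data.item() * len(batch)
                n_seen += len(batch)
            rec = {"epoch": epoch, "train_loss": ep_loss / n_seen}
            if self.val:
                vl = self._eval_loss(net, xv, yv, batch_size)
                rec["val_loss"] = vl
                if vl < best[0] - 1e-5:
                    best = (vl, epoch, net.state_dict())
                elif epoch - best[1] >= patience:
                    history.append(rec)
                    break
            history.append(rec)
        if self.val and np.isfinite(best[0]):
            net.load_state_dict(best[2])
        return ConvLSTMWorseningResults(self, net, history,
                                        fit_seconds=time.time() - t0)


def _length_batches_from_arrays(xs: list[np.ndarray], batch_size: int) -> list[list[int]]:
    by_len: dict[int, list[int]] = {}
    for i, x in enumerate(xs):
        by_len.setdefault(x.shape[0], []).append(i)
    return [g[k:k + batch_size] for T, g in sorted(by_len.items())
            for k in range(0, len(g), batch_size)]


@dataclass
class ConvLSTMWorseningResults:
    """Fitted classifier: predictions, evaluation and a summary table."""

    model: ConvLSTMWorseningModel
    net: _ConvLSTMNet
    history: list[dict] = field(default_factory=list)
    fit_seconds: float = 0.0

    def predict_proba(self, seqs: Sequence[RasterSequence],
                      batch_size: int = 64) -> np.ndarray:
        xs = self.model._inputs(seqs)
        out = np.empty(len(seqs))
        for batch in _length_batches_from_arrays(xs, batch_size):
            xb = np.stack([xs[i] for i in batch])
            out[list(batch)] = self.net.forward(xb, training=False).data.ravel()
        return out

    def evaluate(self, seqs: Sequence[RasterSequence], seed: int = 0,
                 n_boot: int = 1000) -> RocSummary:
        scores = self.predict_proba(seqs)
        labels = np.array([bool(s.label) for s in seqs])
        return roc_auc(scores, labels, seed=seed, n_boot=n_boot)

    def summary(self) -> str:
        h = self.history
        lines = [
            "Convolutional-LSTM worsening classifier",
            "=" * 47,
            f"hidden channels        {self.net.hidden:>10d}",
            f"conv kernel            {self.net.kernel:>7d} x {self.net.kernel}",
            f"n train / val          {len(self.model.train):>6d} / {len(self.model.val)}",
            f"epochs run             {len(h):>10d}",
            f"final train loss       {h[-1]['train_loss']:>10.4f}",
        ]
        if "val_loss" in h[-1]:
            best = min(r["val_loss"] for r in h if "val_loss" in r)
            lines.append(f"best val loss          {best:>10.4f}")
        lines.append(f"fit time (s)           {self.fit_seconds:>10.1f}")
        return "\n".join(lines)


def ablate_recent_vfs(train: Sequence[RasterSequence],
                      val: Sequence[RasterSequence],
                      test: Sequence[RasterSequence], r: int,
                      hidden_channels: int = 8, seed: int = 0,
                      **fit_kw) -> tuple[ConvLSTMWorseningResults, RocSummary]:
    """Retrain after dropping the final r exams from every series.

    Labels stay those computed from the full series; r = 0 reproduces the
    base training exactly.
    """
    from .data import truncate_sequences
    if not 0 <= r <= 6:
        raise ValueError("r must be in 0..6")
    tr = truncate_sequences(train, r)
    va = truncate_sequences(val, r)
    te = truncate_sequences(test, r)
    res = ConvLSTMWorseningModel(tr, va, hidden_channels=hidden_channels,
                                 seed=seed).fit(**fit_kw)
    return res, res.evaluate(te, seed=seed)
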