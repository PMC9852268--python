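"""Logistic mixed-effects baseline for worsening detection.

The comparison model receives the same per-exam information as the
convolutional LSTM, flattened to a long table (one row per exam): the 8
global metrics, the inter-exam spacing, and two raster summaries (mean and
minimum of the 12 x 12 grid).  Patient and eye enter as crossed random
intercepts; everything else is a fixed effect.  The model is fitted by
variational Bayes (statsmodels BinomialBayesMixedGLM) with sparse
random-effect design matrices.

Because the temporal ordering is only visible through per-row covariates,
the per-eye worsening probability is the logistic of the eye's mean
fixed-effect linear predictor - new eyes carry no posterior random effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.special import expit

from .dl.data import METRIC_NAMES, RasterSequence
from .evaluation import RocSummary, roc_auc

FIXED_COLS = list(METRIC_NAMES) + ["dt", "raster_mean", "raster_min"]


def sequences_to_long_frame(seqs: Sequence[RasterSequence]) -> pd.DataFrame:
    """One row per exam: ids, label, metrics, spacing, raster summaries."""
    rows = []
    for s in seqs:
        dt = np.diff(s.times, prepend=s.times[0])
        for t in range(len(s)):
            row = {"patient_id": s.patient_id, "eye_id": s.eye_id,
                   "label": None if s.label is None else bool(s.label),
                   "dt": float(dt[t]),
                   "raster_mean": float(s.frames[t].mean()),
                   "raster_min": float(s.frames[t].min())}
            row.update(dict(zip(METRIC_NAMES, s.metrics[t])))
            rows.append(row)
    return pd.DataFrame(rows)


class MixedEffectsWorseningModel:
    """Crossed random-intercept logistic model on per-exam rows."""

    def __init__(self, df: pd.DataFrame, fixed_cols: Optional[list[str]] = None):
        fixed_cols = list(fixed_cols or FIXED_COLS)
        required = {"patient_id", "eye_id", "label", *fixed_cols}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"long table is missing columns {sorted(missing)}")
        if df["patient_id"].nunique() < 2:
            raise ValueError("need >= 2 patients to separate random effects "
                             "from the intercept")
        if df["label"].isna().any():
            raise ValueError("every row needs a label")
        self.df = df.reset_index(drop=True)
        self.fixed_cols = fixed_cols
        X = self.df[fixed_cols].to_numpy(dtype=float)
        self._mean = X.mean(axis=0)
        sd = X.std(axis=0)
        self._sd = np.where(sd > 1e-9, sd, 1.0)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "MixedEffectsWorseningModel":
        return cls(df, **kw)

    @classmethod
    def from_sequences(cls, seqs: Sequence[RasterSequence], **kw
                       ) -> "MixedEffectsWorseningModel":
        return cls(sequences_to_long_frame(seqs), **kw)

    def _design(self, df: pd.DataFrame) -> np.ndarray:
        X = (df[self.fixed_cols].to_numpy(dtype=float) - self._mean) / self._sd
        return np.column_stack([np.ones(len(df)), X])

    def fit(self, vcp_p: float = 2.0, fe_p: float = 2.0,
            fit_method: str = "L-BFGS-B", maxiter: int = 300,
            **fit_kw) -> "MixedEffectsWorseningResults":
        from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

        endog = self.df["label"].astype(float).to_numpy()
        exog = self._design(self.df)
        pats = pd.Categorical(self.df["patient_id"])
        eyes = pd.Categorical(self.df["eye_id"])
        n = len(self.df)
        vc_pat = sparse.csr_matrix(
            (np.ones(n), (np.arange(n), pats.codes)),
            shape=(n, len(pats.categories)))
        vc_eye = sparse.csr_matrix(
            (np.ones(n), (np.arange(n), eyes.codes)),
            shape=(n, len(eyes.categories)))
        exog_vc = sparse.hstack([vc_pat, vc_eye]).tocsr()
        ident = np.concatenate([np.zeros(vc_pat.shape[1], dtype=int),
                                np.ones(vc_eye.shape[1], dtype=int)])
        glm = BinomialBayesMixedGLM(endog, exog, exog_vc, ident,
                                    vcp_p=vcp_p, fe_p=fe_p,
                                    vcp_names=["patient", "eye"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = glm.fit_vb(fit_method=fit_method,
                                 minim_opts={"maxiter": maxiter}, **fit_kw)
            except Exception as e:  # surfaced, never swallowed
                raise RuntimeError(f"mixed-effects fit did not converge: {e}") from e
        return MixedEffectsWorseningResults(self, fit)


@dataclass
class MixedEffectsWorseningResults:
    model: MixedEffectsWorseningModel
    fit: object  # BayesMixedGLMResults

    @property
    def fe_mean(self) -> np.ndarray:
        return np.asarray(self.fit.fe_mean)

    def predict_proba(self, seqs: Optional[Sequence[RasterSequence]] = None,
                      df: Optional[pd.DataFrame] = None) -> pd.Series:
        """Per-eye probability: logistic of the eye-mean fixed-effect linear
        predictor (random effects are zero for unseen eyes)."""
        if df is None:
            if seqs is None:
                df = self.model.df
            else:
                df = sequences_to_long_frame(seqs)
        eta = self.model._design(df) @ self.fe_mean
        per_eye = pd.Series(eta).groupby(df["eye_id"].to_numpy()).mean()
        return pd.Series(expit(per_eye.to_numpy()), index=per_eye.index,
                         name="p_worsening")

    def evaluate(self, seqs: Sequence[RasterSequence], seed: int = 0,
                 n_boot: int = 1000) -> RocSummary:
        probs = self.predict_proba(seqs)
        labels = pd.Series({s.eye_id: bool(s.label) for s in seqs})
        labels = labels.loc[probs.index]
        return roc_auc(probs.to_numpy(), labels.to_numpy(), seed=seed, n_boot=n_boot)

    def random_effect_sd(self) -> dict[str, float]:
        """Posterior-mean random-intercept SDs for patient and eye."""
        vcp = np.asarray(self.fit.vcp_mean)
        return {"patient": float(np.exp(vcp[0])), "eye": float(np.exp(vcp[1]))}

    def summary(self) -> str:
        head = ["Mixed-effects worsening baseline (logistic, VB)",
                "=" * 48,
                f"rows {len(self.model.df)}, eyes {self.model.df['eye_id'].nunique()}, "
                f"patients {self.model.df['patient_id'].nunique()}",
                f"fixed effects: intercept + {', '.join(self.model.fixed_cols)}",
                f"random-intercept SD: {self.random_effect_sd()}"]
        return "\n".join(head) + "\n" + str(self.fit.summary())
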