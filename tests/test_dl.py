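"""Rasterization, patient-level splits, the convLSTM classifier, and the
mixed-effects baseline."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_series
from vfprog.core import prepare_series
from vfprog.dl import (ConvLSTMWorseningModel, build_sequences,
                       partition_sequences, rasterize_vf, split_patients,
                       truncate_sequences)
from vfprog.dl.data import RasterSequence
from vfprog.mixed import (MixedEffectsWorseningModel, sequences_to_long_frame)
from vfprog.synthetic import CohortConfig, generate_cohort


class TestRasterize:
    def test_shape_always_12x12(self, rng):
        for _ in range(5):
            assert rasterize_vf(rng.normal(size=54)).shape == (12, 12)

    def test_constant_field_constant_support(self):
        r = rasterize_vf(np.full(54, -7.0))
        assert np.allclose(r[np.abs(r) > 1e-9], -7.0)

    def test_zero_field_is_fill(self):
        assert np.allclose(rasterize_vf(np.zeros(54)), 0.0)

    def test_locality_of_single_point_change(self, rng):
        td = rng.normal(size=54)
        td2 = td.copy()
        td2[0] += 10.0  # first grid point, top row
        diff = np.abs(rasterize_vf(td) - rasterize_vf(td2))
        changed = np.argwhere(diff > 1e-12)
        # kernel radius 1 cell around the deposited cell
        assert len(changed) > 0
        rows, cols = changed[:, 0], changed[:, 1]
        assert rows.max() - rows.min() <= 2 and cols.max() - cols.min() <= 2

    def test_blind_spot_not_deposited(self):
        td = np.zeros(54)
        from vfprog.grid import blind_spot_mask
        td[blind_spot_mask()] = -30.0
        assert np.allclose(rasterize_vf(td), 0.0)


class TestSplits:
    def test_disjoint_and_complete(self):
        ids = [f"P{i}" for i in range(50)]
        spec = split_patients(ids, seed=3)
        allp = spec.train | spec.val | spec.test
        assert allp == set(ids)
        assert not (spec.train & spec.test)

    def test_reproducible(self):
        ids = [f"P{i}" for i in range(40)]
        assert split_patients(ids, seed=5) == split_patients(ids, seed=5)
        assert split_patients(ids, seed=5) != split_patients(ids, seed=6)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            split_patients(["a", "b", "c"], fractions=(0.5, 0.2, 0.2))

    def test_both_eyes_co_assigned(self):
        cfg = CohortConfig(n_patients=40, seed=8)
        series, truths = generate_cohort(cfg)
        prepped = prepare_series(series)
        seqs = build_sequences(prepped, {t.eye_id: t.truly_progressing for t in truths})
        spec = split_patients([s.patient_id for s in seqs], seed=1)
        tr, va, te = partition_sequences(seqs, spec)
        for part, ids in ((tr, spec.train), (va, spec.val), (te, spec.test)):
            for s in part:
                assert s.patient_id in ids


class TestTruncation:
    def _seqs(self, rng, lengths):
        out = []
        for i, T in enumerate(lengths):
            out.append(RasterSequence(
                f"E{i}", f"P{i}", rng.normal(size=(T, 12, 12)),
                rng.normal(size=(T, 8)), np.arange(T, dtype=float), bool(i % 2)))
        return out

    def test_lengths_and_floor(self, rng):
        seqs = self._seqs(rng, [7, 9, 3])
        for r in range(7):
            trunc = truncate_sequences(seqs, r)
            for s, t in zip(seqs, trunc):
                assert len(t) == max(1, len(s) - r)

    def test_labels_unchanged(self, rng):
        seqs = self._seqs(rng, [8, 8])
        trunc = truncate_sequences(seqs, 6)
        assert [t.label for t in trunc] == [s.label for s in seqs]

    def test_r_zero_identity(self, rng):
        seqs = self._seqs(rng, [7])
        trunc = truncate_sequences(seqs, 0)
        np.testing.assert_array_equal(trunc[0].frames, seqs[0].frames)


@pytest.fixture(scope="module")
def tiny_sequences():
    cfg = CohortConfig(n_patients=14, frac_progressing=0.5, seed=31)
    series, truths = generate_cohort(cfg)
    prepped = prepare_series(series)
    labels = {t.eye_id: t.truly_progressing for t in truths}
    return build_sequences(prepped, labels)[:20]


class TestConvLSTM:
    def test_output_is_probability(self, tiny_sequences):
        res = ConvLSTMWorseningModel(tiny_sequences[:6], hidden_channels=4,
                                     seed=0).fit(epochs=2, batch_size=4)
        p = res.predict_proba(tiny_sequences)
        assert np.all((p > 0) & (p < 1))

    def test_overfits_small_training_set(self, tiny_sequences):
        """Capacity sanity: 20 sequences are driven to ~100% train accuracy."""
        res = ConvLSTMWorseningModel(tiny_sequences, hidden_channels=8,
                                     seed=0).fit(epochs=60, batch_size=8)
        p = res.predict_proba(tiny_sequences)
        y = np.array([s.label for s in tiny_sequences])
        assert ((p > 0.5) == y).mean() >= 0.9
        assert res.history[-1]["train_loss"] < 0.1

    def test_reproducible_under_seed(self, tiny_sequences):
        r1 = ConvLSTMWorseningModel(tiny_sequences, seed=4).fit(epochs=2, batch_size=8)
        r2 = ConvLSTMWorseningModel(tiny_sequences, seed=4).fit(epochs=2, batch_size=8)
        np.testing.assert_array_equal(r1.net.Wc.data, r2.net.Wc.data)
        assert r1.history == r2.history

    def test_variable_length_sequences_accepted(self, tiny_sequences):
        mixed = truncate_sequences(tiny_sequences[:4], 2) + list(tiny_sequences[4:8])
        res = ConvLSTMWorseningModel(mixed, hidden_channels=4, seed=1).fit(
            epochs=2, batch_size=4)
        assert len(res.predict_proba(mixed)) == len(mixed)

    def test_empty_or_unlabeled_train_rejected(self, tiny_sequences):
        with pytest.raises(ValueError):
            ConvLSTMWorseningModel([])
        from dataclasses import replace
        bad = [replace(tiny_sequences[0], label=None)]
        with pytest.raises(ValueError):
            ConvLSTMWorseningModel(bad)

    def test_summary_mentions_architecture(self, tiny_sequences):
        res = ConvLSTMWorseningModel(tiny_sequences[:6], hidden_channels=4,
                                     seed=0).fit(epochs=1, batch_size=4)
        s = res.summary()
        assert "hidden channels" in s and "3 x 3" in s


class TestMixedEffects:
    def test_long_frame_shape(self, tiny_sequences):
        df = sequences_to_long_frame(tiny_sequences)
        assert len(df) == sum(len(s) for s in tiny_sequences)
        assert {"patient_id", "eye_id", "label", "md", "dt",
                "raster_mean"} <= set(df.columns)

    def test_single_patient_rejected(self, tiny_sequences):
        df = sequences_to_long_frame(tiny_sequences[:1])
        with pytest.raises(ValueError, match="patients"):
            MixedEffectsWorseningModel(df)

    def test_no_clustering_reduces_to_logistic(self, rng):
        """With rows independent of patient/eye, FE predictions track a plain
        logistic fit."""
        from sklearn.linear_model import LogisticRegression
        n = 400
        df = pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(n)],
            "eye_id": [f"E{i}" for i in range(n)],
            "md": rng.normal(size=n),
            "dt": rng.normal(size=n),
        })
        eta = 1.5 * df["md"].to_numpy() - 0.5
        df["label"] = rng.random(n) < 1 / (1 + np.exp(-eta))
        m = MixedEffectsWorseningModel(df, fixed_cols=["md", "dt"]).fit()
        p_mixed = m.predict_proba(df=df)
        lr = LogisticRegression().fit(df[["md", "dt"]], df["label"])
        p_lr = pd.Series(lr.predict_proba(df[["md", "dt"]])[:, 1],
                         index=df["eye_id"]).loc[p_mixed.index]
        assert np.corrcoef(p_mixed, p_lr)[0, 1] > 0.98

    def test_fit_and_evaluate(self, tiny_sequences):
        m = MixedEffectsWorseningModel.from_sequences(tiny_sequences).fit()
        probs = m.predict_proba(tiny_sequences)
        assert len(probs) == len({s.eye_id for s in tiny_sequences})
        assert ((probs > 0) & (probs < 1)).all()
        assert "Mixed-effects" in m.summary()
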