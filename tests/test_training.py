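"""Fold stratification, the training loop, and threshold selection."""

import numpy as np
import pytest

from cardiosleep.metrics import severity_class
from cardiosleep.model import ModelHyper, MultiTaskModel
from cardiosleep.training import (
    THRESHOLD_GRID,
    TrainOptions,
    early_stop_trace,
    event_sample_weights,
    make_folds,
    select_thresholds,
    subject_night_tracks,
    train,
)
from cardiosleep.types import SegmentStore

TINY = ModelHyper(
    gru_shared=(4, 4), gru_event=4, gru_sleep=4, conv_filters=(2, 2, 2),
    dense_hidden=8, dropout=0.1,
)


def _subjects_with_ahi():
    # 16 subjects, 4 per severity stratum
    ahis = [1, 2, 3, 4, 6, 8, 10, 12, 16, 20, 25, 28, 35, 40, 50, 60]
    subjects = [f"s{i:02d}" for i in range(16)]
    return subjects, dict(zip(subjects, map(float, ahis)))


class TestMakeFolds:
    def test_exact_divisibility_one_per_stratum(self):
        subjects, ahi = _subjects_with_ahi()
        plan = make_folds(subjects, ahi, seed=0)
        for it in plan.iterations:
            classes = [severity_class(ahi[s]) for s in it["test"]]
            assert sorted(classes) == ["mild", "moderate", "normal", "severe"]

    def test_no_role_leakage(self):
        subjects, ahi = _subjects_with_ahi()
        plan = make_folds(subjects, ahi, seed=1)
        for it in plan.iterations:
            roles = [set(it["train"]), set(it["val"]), set(it["test"])]
            assert not (roles[0] & roles[1])
            assert not (roles[0] & roles[2])
            assert not (roles[1] & roles[2])
            assert roles[0] | roles[1] | roles[2] == set(subjects)

    def test_test_folds_partition_subjects(self):
        subjects, ahi = _subjects_with_ahi()
        plan = make_folds(subjects, ahi, seed=2)
        seen = [s for it in plan.iterations for s in it["test"]]
        assert sorted(seen) == sorted(subjects)

    def test_deterministic_under_seed(self):
        subjects, ahi = _subjects_with_ahi()
        a = make_folds(subjects, ahi, seed=5)
        b = make_folds(subjects, ahi, seed=5)
        assert a.iterations == b.iterations
        c = make_folds(subjects, ahi, seed=6)
        assert a.iterations != c.iterations

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="at least 8"):
            make_folds(["a", "b"], {"a": 1.0, "b": 2.0}, seed=0)

    def test_train_val_split_roughly_75_25(self):
        subjects, ahi = _subjects_with_ahi()
        plan = make_folds(subjects, ahi, seed=3)
        for it in plan.iterations:
            frac = len(it["val"]) / (len(it["val"]) + len(it["train"]))
            assert 0.15 <= frac <= 0.40


class TestEarlyStopping:
    def test_spec_trace(self):
        losses = [1.0, 0.9] + [0.9 + 0.01 * i for i in range(10)]
        ran, best = early_stop_trace(losses, patience=10)
        assert ran == 12
        assert best == 2

    def test_monotone_decrease_runs_to_end(self):
        losses = [1.0 - 0.01 * i for i in range(30)]
        ran, best = early_stop_trace(losses, patience=10)
        assert ran == 30 and best == 30

    def test_plateau_stops_after_patience(self):
        losses = [1.0] + [1.0] * 20
        ran, best = early_stop_trace(losses, patience=10)
        assert ran == 11 and best == 1


def test_event_sample_weights():
    w = event_sample_weights(np.array([1, 0, 0]), 10.0)
    assert w.tolist() == [10.0, 1.0, 1.0]


class TestTrainLoop:
    def test_overfits_tiny_set(self, tiny_store):
        rng = np.random.default_rng(0)
        idx = rng.choice(len(tiny_store), 32, replace=False)
        sub = tiny_store.subset(idx)
        # relabel subjects so train/val are "disjoint"
        val = tiny_store.subset(rng.choice(len(tiny_store), 8, replace=False))
        val.subject_ids = np.array(["zz-val"] * len(val))
        model = MultiTaskModel(TINY, seed=0)
        opts = TrainOptions(max_epochs=8, patience=8, batch_size=16, seed=0)
        model, hist = train(model, sub, val, opts)
        losses = hist["train_loss"].tolist()
        assert losses[-1] < losses[0]
        assert hist.attrs["best_epoch"] >= 1

    def test_overlapping_subjects_rejected(self, tiny_store):
        model = MultiTaskModel(TINY, seed=0)
        with pytest.raises(ValueError, match="overlap"):
            train(model, tiny_store, tiny_store, TrainOptions(max_epochs=1))

    def test_history_and_stopping_rule_consistency(self, tiny_store):
        rng = np.random.default_rng(1)
        tr = tiny_store.subset(rng.choice(len(tiny_store), 24, replace=False))
        va = tiny_store.subset(rng.choice(len(tiny_store), 8, replace=False))
        va.subject_ids = np.array(["zz-val"] * len(va))
        model = MultiTaskModel(TINY, seed=1)
        opts = TrainOptions(max_epochs=6, patience=2, batch_size=16, seed=1)
        model, hist = train(model, tr, va, opts)
        ran, best = early_stop_trace(hist["val_loss"].tolist(), patience=2)
        assert len(hist) == ran
        assert hist.attrs["best_epoch"] == best


class TestThresholds:
    def _store_and_model(self, tiny_store):
        model = MultiTaskModel(TINY, seed=2)
        sel = np.isin(
            tiny_store.subject_ids, np.unique(tiny_store.subject_ids)[:3]
        )
        return model, tiny_store.subset(sel)

    def test_selected_threshold_is_grid_argmax(self, tiny_store):
        """Exhaustive re-evaluation of every grid threshold agrees."""
        model, val = self._store_and_model(tiny_store)
        thr = select_thresholds(model, val)
        p_event, p_sleep = model.predict(val.X)
        tracks = subject_night_tracks(val, p_event, p_sleep)
        ps = np.concatenate(
            [t["pred"].p_sleep[t["center_covered"]] for t in tracks.values()]
        )
        ys = np.concatenate(
            [t["ref_sleep"][t["center_covered"]] for t in tracks.values()]
        )
        best, best_thr = -1.0, None
        for g in THRESHOLD_GRID:
            pred = ps >= g
            tp = int(np.sum(pred & (ys == 1)))
            fp = int(np.sum(pred & (ys == 0)))
            fn = int(np.sum(~pred & (ys == 1)))
            f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
            if f1 > best:
                best, best_thr = f1, float(g)
        assert thr.sleep_thr == best_thr

    def test_tie_breaks_to_lowest_threshold(self):
        # perfectly separated: any threshold in (0.1, 0.9] is optimal;
        # the lowest grid value in the gap must be returned
        model = MultiTaskModel(TINY, seed=3)

        class _Fake:
            def predict(self, X):
                n = len(X)
                ps = np.tile(
                    np.where(np.arange(10) % 2 == 0, 0.95, 0.05), (n, 1)
                )
                pe = np.tile(
                    np.where(np.arange(300) < 150, 0.9, 0.1), (n, 1)
                )
                return pe, ps

        n = 3
        y_sleep = np.tile((np.arange(10) % 2 == 0).astype(np.int8), (n, 1))
        y_event = np.tile((np.arange(300) < 150).astype(np.int8), (n, 1))
        store = SegmentStore(
            X=np.zeros((n, 1200, 2), np.float32),
            y_event=y_event,
            y_sleep=y_sleep,
            start_times_s=np.arange(n) * 180.0,
            subject_ids=np.array(["a"] * n),
        )
        thr = select_thresholds(_Fake(), store)
        assert thr.sleep_thr == pytest.approx(0.06)
        assert thr.event_thr == pytest.approx(0.11)

    def test_no_positive_epochs_raises(self, tiny_store):
        model, val = self._store_and_model(tiny_store)
        val = val.subset(slice(0, 4))
        val.y_sleep = np.zeros_like(val.y_sleep)
        with pytest.raises(ValueError, match="no positive"):
            select_thresholds(model, val)
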