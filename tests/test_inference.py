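"""Whole-night stitching, wake masking, event formation and matching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiosleep.inference import (
    binarize_and_mask,
    events_to_binary,
    match_events,
    merge_events,
    stitch_predictions,
)
from cardiosleep.types import EventInterval, Thresholds


def _merge_oracle(b):
    """Run-length scan, one element at a time."""
    out = []
    start = None
    for i, v in enumerate(b):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(b)))
    return out


class TestMergeEvents:
    def test_examples(self):
        evs = merge_events(np.array([0, 1, 1, 0, 1]))
        assert [(e.start_s, e.end_s) for e in evs] == [(1, 3), (4, 5)]
        assert merge_events(np.zeros(10, int)) == []
        evs = merge_events(np.ones(300, int))
        assert [(e.start_s, e.end_s) for e in evs] == [(0, 300)]

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_runlength_oracle(self, seed):
        b = (np.random.default_rng(seed).random(300) < 0.3).astype(int)
        got = [(e.start_s, e.end_s) for e in merge_events(b)]
        assert got == _merge_oracle(b)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_roundtrip_with_binary_expansion(self, seed):
        b = (np.random.default_rng(seed).random(200) < 0.4).astype(np.int8)
        evs = merge_events(b)
        assert np.array_equal(events_to_binary(evs, 200), b)


def _match_oracle(detected, reference, min_overlap=1.0):
    """Exhaustive greedy matching, re-deriving the rule element by element."""
    used = [False] * len(reference)
    tp = 0
    for d in detected:
        for i, r in enumerate(reference):
            if used[i]:
                continue
            ov = min(d.end_s, r.end_s) - max(d.start_s, r.start_s)
            if ov >= min_overlap and r.start_s < d.end_s:
                used[i] = True
                tp += 1
                break
    return {"TP": tp, "FP": len(detected) - tp,
            "FN": len(reference) - sum(used)}


def _random_intervals(rng, n, span=600.0):
    cuts = np.sort(rng.uniform(0, span, 2 * n))
    out = []
    for i in range(0, 2 * n, 2):
        if cuts[i + 1] - cuts[i] >= 1.0:
            out.append(EventInterval(float(cuts[i]), float(cuts[i + 1])))
    return out


class TestMatchEvents:
    def test_identical_lists(self):
        evs = [EventInterval(0, 10), EventInterval(20, 35)]
        assert match_events(evs, evs) == {"TP": 2, "FP": 0, "FN": 0}

    def test_disjoint_lists(self):
        det = [EventInterval(0, 5), EventInterval(10, 15)]
        ref = [EventInterval(100, 110), EventInterval(120, 130),
               EventInterval(140, 150)]
        assert match_events(det, ref) == {"TP": 0, "FP": 2, "FN": 3}

    def test_partial_overlap_example(self):
        det = [EventInterval(0, 30)]
        ref = [EventInterval(10, 40), EventInterval(50, 70)]
        assert match_events(det, ref) == {"TP": 1, "FP": 0, "FN": 1}

    def test_sub_second_overlap_not_matched(self):
        det = [EventInterval(0.0, 10.5)]
        ref = [EventInterval(10.0, 20.0)]
        assert match_events(det, ref) == {"TP": 0, "FP": 1, "FN": 1}

    def test_overlapping_within_list_rejected(self):
        bad = [EventInterval(0, 10), EventInterval(5, 15)]
        with pytest.raises(ValueError, match="overlap"):
            match_events(bad, [])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        det = _random_intervals(rng, int(rng.integers(0, 12)))
        ref = _random_intervals(rng, int(rng.integers(0, 12)))
        got = match_events(det, ref)
        assert got == _match_oracle(det, ref)
        assert got["TP"] + got["FN"] == len(ref)
        assert got["TP"] + got["FP"] == len(det)


class TestBinarizeAndMask:
    def test_all_wake_suppresses_everything(self):
        thr = Thresholds(0.5, 0.5)
        p_sleep = np.zeros(10)
        p_event = np.ones(300)
        _, eb = binarize_and_mask(p_sleep, p_event, thr)
        assert eb.sum() == 0

    def test_all_sleep_passes_everything(self):
        thr = Thresholds(0.5, 0.5)
        sb, eb = binarize_and_mask(np.ones(10), np.ones(300), thr)
        assert sb.sum() == 10 and eb.sum() == 300

    def test_wake_epoch_splits_event(self):
        thr = Thresholds(0.5, 0.5)
        p_sleep = np.ones(10)
        p_sleep[3] = 0.0  # wake epoch covering seconds 90..120
        p_event = np.zeros(300)
        p_event[80:130] = 1.0
        _, eb = binarize_and_mask(p_sleep, p_event, thr)
        evs = merge_events(eb)
        assert [(e.start_s, e.end_s) for e in evs] == [(80, 90), (120, 130)]

    def test_masking_never_creates_events(self):
        rng = np.random.default_rng(0)
        thr = Thresholds(0.4, 0.6)
        p_sleep = rng.random(20)
        p_event = rng.random(600)
        _, masked = binarize_and_mask(p_sleep, p_event, thr)
        unmasked = (p_event >= thr.event_thr).astype(int)
        assert np.all(masked <= unmasked)


class TestStitch:
    def test_center_window_arithmetic(self):
        starts = np.array([0.0, 180.0, 360.0])
        pe = np.stack([np.full(300, k) for k in range(3)]).astype(float)
        ps = np.stack([np.full(10, k) for k in range(3)]).astype(float)
        tracks = stitch_predictions(starts, pe, ps)
        # total span 2*180 + 300 = 660 s, 22 epochs
        assert tracks.p_event.shape == (660,)
        assert tracks.p_sleep.shape == (22,)
        # segment k contributes seconds [180k+60, 180k+240)
        assert np.all(tracks.p_event[60:240] == 0)
        assert np.all(tracks.p_event[240:420] == 1)
        assert np.all(tracks.p_event[420:600] == 2)
        # edges from outer minutes of first/last segment
        assert np.all(tracks.p_event[:60] == 0)
        assert np.all(tracks.p_event[600:] == 2)
        # epochs: k contributes epochs 6k+2 .. 6k+7
        assert np.all(tracks.p_sleep[2:8] == 0)
        assert np.all(tracks.p_sleep[8:14] == 1)
        assert np.all(tracks.p_sleep[14:20] == 2)
        assert tracks.center_covered[2:20].all()
        assert not tracks.center_covered[:2].any()

    def test_single_segment_uses_all_epochs(self):
        tracks = stitch_predictions(
            np.array([0.0]), np.arange(300.0)[None, :], np.arange(10.0)[None, :]
        )
        assert np.array_equal(tracks.p_sleep, np.arange(10.0))
        assert np.array_equal(tracks.p_event, np.arange(300.0))

    def test_gap_in_grid_reported(self):
        starts = np.array([0.0, 360.0])
        with pytest.raises(ValueError, match="gap"):
            stitch_predictions(
                starts, np.zeros((2, 300)), np.zeros((2, 10))
            )

    def test_off_grid_starts_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            stitch_predictions(
                np.array([0.0, 100.0]), np.zeros((2, 300)), np.zeros((2, 10))
            )
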