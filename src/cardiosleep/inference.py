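"""Stitch per-segment predictions into whole-night tracks and form events.

Overlapping 5-min segments on the 180-s grid each contribute their
central 3 min (the outer minute at each end is the overlap with the
neighboring windows and is discarded); the night's first and last minute
are covered by the outer content of the first and last segment so the
full record has a prediction.  Epoch-level evaluation uses only the
center-covered epochs, while TST/AHI use the full stitched track.

Binarized event seconds are masked by detected wake (a second can only be
part of an event if its 30-s epoch is classified as sleep), merged into
maximal runs, and matched one-to-one against reference events by a
greedy >= 1 s overlap rule.
"""

from __future__ import annotations

import numpy as np

from .types import (
    EPOCH_S,
    SEGMENT_EVENT_LEN,
    SEGMENT_LEN_S,
    SEGMENT_SLEEP_LEN,
    SEGMENT_STEP_S,
    EventInterval,
    Thresholds,
)

__all__ = [
    "stitch_predictions",
    "binarize_and_mask",
    "merge_events",
    "events_to_binary",
    "match_events",
    "NightTracks",
]

_CENTER_OFFSET_S = 60  # dropped at each end of a segment
_CENTER_EPOCHS = slice(2, 8)  # epochs 2..7 of the 10


class NightTracks:
    """Stitched per-night probability tracks.

    Attributes
    ----------
    p_sleep : (n_epochs,) probability of sleep per 30-s epoch
    p_event : (n_seconds,) probability of an SDB event per second
    center_covered : (n_epochs,) bool, True where the value came from a
        segment's central 3 min (the primary evaluation span)
    t0_s : start time of the track (= first segment start)
    """

    def __init__(self, p_sleep, p_event, center_covered, t0_s):
        self.p_sleep = p_sleep
        self.p_event = p_event
        self.center_covered = center_covered
        self.t0_s = t0_s


def stitch_predictions(start_times_s: np.ndarray, p_event_seg: np.ndarray,
                       p_sleep_seg: np.ndarray) -> NightTracks:
    """Combine per-segment tracks of one night into continuous tracks.

    Segments must lie on the 180-s grid; a missing grid position raises
    (gaps are reported, never silently interpolated).
    """
    starts = np.asarray(start_times_s, dtype=float)
    if starts.size == 0:
        raise ValueError("no segments to stitch")
    order = np.argsort(starts)
    starts = starts[order]
    p_event_seg = np.asarray(p_event_seg)[order]
    p_sleep_seg = np.asarray(p_sleep_seg)[order]
    rel = (starts - starts[0]) / SEGMENT_STEP_S
    if not np.allclose(rel, np.round(rel)):
        raise ValueError("segment starts are not on the 180-s grid")
    idx = np.round(rel).astype(int)
    missing = sorted(set(range(idx[-1] + 1)) - set(idx.tolist()))
    if missing:
        gaps = [starts[0] + SEGMENT_STEP_S * m for m in missing]
        raise ValueError(f"gap in segment grid at start times {gaps}")

    n_seg = starts.size
    total_s = int(SEGMENT_STEP_S * (n_seg - 1) + SEGMENT_LEN_S)
    n_sec = total_s
    n_epochs = int(total_s // EPOCH_S)
    p_event = np.full(n_sec, np.nan)
    p_sleep = np.full(n_epochs, np.nan)
    center_covered = np.zeros(n_epochs, dtype=bool)

    for k in range(n_seg):
        sec0 = int(SEGMENT_STEP_S * k)
        ep0 = int(sec0 // EPOCH_S)
        # central 3 min: seconds 60..239, epochs 2..7
        p_event[sec0 + _CENTER_OFFSET_S : sec0 + SEGMENT_LEN_S - _CENTER_OFFSET_S] = (
            p_event_seg[k][_CENTER_OFFSET_S : SEGMENT_LEN_S - _CENTER_OFFSET_S]
        )
        p_sleep[ep0 + 2 : ep0 + 8] = p_sleep_seg[k][_CENTER_EPOCHS]
        center_covered[ep0 + 2 : ep0 + 8] = True
    # edge coverage from the outer minutes of the first and last segment
    p_event[:_CENTER_OFFSET_S] = p_event_seg[0][:_CENTER_OFFSET_S]
    p_sleep[:2] = p_sleep_seg[0][:2]
    last0 = int(SEGMENT_STEP_S * (n_seg - 1))
    p_event[last0 + SEGMENT_LEN_S - _CENTER_OFFSET_S :] = p_event_seg[-1][
        SEGMENT_LEN_S - _CENTER_OFFSET_S :
    ]
    p_sleep[int(last0 // EPOCH_S) + 8 :] = p_sleep_seg[-1][8:]
    if not (np.isfinite(p_event).all() and np.isfinite(p_sleep).all()):
        raise RuntimeError("stitching left uncovered samples")
    return NightTracks(p_sleep, p_event, center_covered, float(starts[0]))


def binarize_and_mask(p_sleep: np.ndarray, p_event: np.ndarray,
                      thresholds: Thresholds) -> tuple[np.ndarray, np.ndarray]:
    """Threshold both tracks; event seconds inside detected wake are zeroed."""
    sleep_binary = (np.asarray(p_sleep) >= thresholds.sleep_thr).astype(np.int8)
    event_binary = (np.asarray(p_event) >= thresholds.event_thr).astype(np.int8)
    sec_epoch = np.minimum(
        (np.arange(event_binary.size) // int(EPOCH_S)), sleep_binary.size - 1
    )
    event_binary &= sleep_binary[sec_epoch]
    return sleep_binary, event_binary


def merge_events(event_binary_1hz: np.ndarray,
                 t0_s: float = 0.0) -> list[EventInterval]:
    """Maximal runs of 1-seconds become half-open detected events."""
    b = np.asarray(event_binary_1hz).astype(np.int8)
    if b.size == 0:
        return []
    edges = np.diff(np.concatenate([[0], b, [0]]))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return [
        EventInterval(t0_s + float(s), t0_s + float(e), "detected")
        for s, e in zip(starts, ends)
    ]


def events_to_binary(events: list[EventInterval], n_seconds: int,
                     t0_s: float = 0.0) -> np.ndarray:
    """Inverse of :func:`merge_events` for integer-aligned interval lists."""
    b = np.zeros(n_seconds, dtype=np.int8)
    for ev in events:
        lo = max(0, int(np.floor(ev.start_s - t0_s)))
        hi = min(n_seconds, int(np.ceil(ev.end_s - t0_s)))
        if hi > lo:
            b[lo:hi] = 1
    return b


def _check_sorted_disjoint(events: list[EventInterval], name: str) -> None:
    for a, b in zip(events, events[1:]):
        if b.start_s < a.start_s:
            raise ValueError(f"{name} events are not sorted by start")
        if b.start_s < a.end_s:
            raise ValueError(f"{name} events overlap within the list")


def match_events(detected: list[EventInterval],
                 reference: list[EventInterval],
                 min_overlap_s: float = 1.0) -> dict[str, int]:
    """Greedy one-to-one matching in time order.

    A detected event is a true positive when it overlaps an as-yet
    unmatched reference event by at least ``min_overlap_s``; leftover
    detected events are false positives, leftover reference events are
    false negatives.
    """
    _check_sorted_disjoint(detected, "detected")
    _check_sorted_disjoint(reference, "reference")
    matched = np.zeros(len(reference), dtype=bool)
    tp = 0
    for det in detected:
        hit = False
        for i in range(len(reference)):
            if matched[i]:
                continue
            if reference[i].start_s >= det.end_s:
                break
            if det.overlap_s(reference[i]) >= min_overlap_s:
                matched[i] = True
                hit = True
                break
        if hit:
            tp += 1
    return {
        "TP": tp,
        "FP": len(detected) - tp,
        "FN": len(reference) - int(matched.sum()),
    }
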