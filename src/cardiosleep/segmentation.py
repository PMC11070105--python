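"""Cut aligned 4 Hz channels into overlapping 5-min training segments.

Windows are 300 s long with a 180 s step (2 min overlap), anchored at
lights-off so every window starts on a 30-s epoch boundary.  Each window
is normalized per channel with "soft" min-max scaling (5th/95th
percentiles map to 0/1, values are not clipped) and labeled at two
resolutions: one binary event label per second (300) and one binary
sleep label per 30-s epoch (10).
"""

from __future__ import annotations

import warnings

import numpy as np

from .preprocess import MAX_MASKED_FRACTION, masked_beat_fraction
from .types import (
    EPOCH_S,
    SEGMENT_EVENT_LEN,
    SEGMENT_LEN_S,
    SEGMENT_SLEEP_LEN,
    SEGMENT_STEP_S,
    SEGMENT_X_LEN,
    SLEEP_STAGES,
    EffortSeries,
    EventInterval,
    RRSeries,
    SegmentTensor,
    SubjectRecord,
)

__all__ = [
    "soft_minmax",
    "map_event_labels",
    "map_sleep_labels",
    "make_segments",
    "segment_starts",
]


def soft_minmax(x: np.ndarray) -> tuple[np.ndarray, bool]:
    """Scale so p5 -> 0 and p95 -> 1 without clipping.

    Returns ``(scaled, ok)``; ``ok`` is False for degenerate spread
    (p95 == p5), in which case the output is all zeros.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("soft_minmax needs a non-empty input")
    p5, p95 = np.percentile(x, [5.0, 95.0])
    if p95 == p5:
        return np.zeros_like(x), False
    return (x - p5) / (p95 - p5), True


def map_event_labels(events: list[EventInterval],
                     window: tuple[float, float]) -> np.ndarray:
    """(300,) binary: second j is 1 iff [start+j, start+j+1) meets any event."""
    start, end = window
    n = int(round(end - start))
    if n != SEGMENT_EVENT_LEN:
        raise ValueError(f"window must span {SEGMENT_EVENT_LEN} s, got {n}")
    y = np.zeros(n, dtype=np.int8)
    for ev in events:
        lo = max(0, int(np.floor(ev.start_s - start)))
        hi = min(n, int(np.ceil(ev.end_s - start)))
        if hi > lo:
            y[lo:hi] = 1
    return y


def map_sleep_labels(hypnogram: list[str],
                     window: tuple[float, float],
                     lights_off_s: float = 0.0) -> np.ndarray:
    """(10,) binary: one label per 30-s epoch, wake = 0, any sleep stage = 1."""
    start, end = window
    off = start - lights_off_s
    if abs(off / EPOCH_S - round(off / EPOCH_S)) > 1e-9:
        raise ValueError("window start must align to a 30-s epoch boundary")
    e0 = int(round(off / EPOCH_S))
    n = int(round((end - start) / EPOCH_S))
    if n != SEGMENT_SLEEP_LEN:
        raise ValueError(f"window must span {SEGMENT_SLEEP_LEN} epochs, got {n}")
    if e0 < 0 or e0 + n > len(hypnogram):
        raise ValueError(
            f"window epochs [{e0}, {e0 + n}) extend past hypnogram of "
            f"length {len(hypnogram)}"
        )
    return np.array(
        [1 if hypnogram[e] in SLEEP_STAGES else 0 for e in range(e0, e0 + n)],
        dtype=np.int8,
    )


def segment_starts(lights_off_s: float, lights_on_s: float) -> np.ndarray:
    """Window starts lights_off + k*180 s such that the window ends in bed."""
    n_fit = int((lights_on_s - lights_off_s - SEGMENT_LEN_S) // SEGMENT_STEP_S) + 1
    if lights_on_s - lights_off_s < SEGMENT_LEN_S:
        return np.array([])
    return lights_off_s + SEGMENT_STEP_S * np.arange(n_fit)


def make_segments(record: SubjectRecord, rr: RRSeries,
                  re: EffortSeries) -> list[SegmentTensor]:
    """All usable 5-min windows of one record.

    ``rr`` and ``re`` must be aligned 4 Hz series starting at lights-off.
    Returns an empty list (with a warning) for records shorter than 5 min.
    """
    if rr.values.size != re.values.size:
        raise ValueError("RR and effort series are not aligned (lengths differ)")
    if abs(rr.t0_s - record.lights_off_s) > 1e-9 or abs(re.t0_s - rr.t0_s) > 1e-9:
        raise ValueError("series must start at lights-off")
    starts = segment_starts(record.lights_off_s, record.lights_on_s)
    if starts.size == 0:
        warnings.warn(
            f"record {record.subject_id} shorter than 5 min; no segments",
            stacklevel=2,
        )
        return []
    fs = 4
    segments: list[SegmentTensor] = []
    for s in starts:
        i0 = int(round((s - rr.t0_s) * fs))
        i1 = i0 + SEGMENT_X_LEN
        if i1 > rr.values.size:
            break  # trailing partial window: dropped, not padded
        rr_n, ok_rr = soft_minmax(rr.values[i0:i1])
        re_n, ok_re = soft_minmax(re.values[i0:i1])
        usable = ok_rr and ok_re
        if masked_beat_fraction(record, (s, s + SEGMENT_LEN_S)) > MAX_MASKED_FRACTION:
            usable = False
        X = np.stack([rr_n, re_n], axis=1).astype(np.float32)
        y_event = map_event_labels(record.events, (s, s + SEGMENT_LEN_S))
        y_sleep = map_sleep_labels(
            record.hypnogram, (s, s + SEGMENT_LEN_S), record.lights_off_s
        )
        segments.append(
            SegmentTensor(
                X=X,
                y_event=y_event,
                y_sleep=y_sleep,
                start_s=float(s),
                subject_id=record.subject_id,
                usable=usable,
            )
        )
    return segments
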