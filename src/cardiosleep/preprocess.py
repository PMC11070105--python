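"""Convert beat times and raw effort into aligned 4 Hz model channels.

The RR tachogram assigns an instantaneous RR value to each beat whose
immediately preceding beat is also artifact-free; values outside the
physiological gate [0.3, 3.0] s (including long intervals bridging masked
stretches) are discarded, and the remaining values are linearly
interpolated onto a uniform 4 Hz grid with nearest-value edge extension.

The respiratory-effort channel is low-pass filtered (anti-alias, > 2 Hz
removed), resampled to 4 Hz, then high-pass filtered with a zero-phase
order-3 Butterworth at 0.05 Hz to remove baseline wander.  Zero-phase
(forward-backward) application keeps the trace time-aligned with the
second-resolution event labels.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .types import EffortSeries, RRSeries, SubjectRecord

__all__ = [
    "RR_GATE_S",
    "MAX_MASKED_FRACTION",
    "rr_tachogram",
    "condition_effort",
    "preprocess_record",
    "masked_beat_fraction",
]

RR_GATE_S = (0.3, 3.0)
TARGET_FS = 4.0
#: Windows with more than this fraction of artifact beats are flagged unusable.
MAX_MASKED_FRACTION = 0.5
_HP_ORDER = 3
_HP_CUTOFF_HZ = 0.05
_LP_CUTOFF_HZ = 2.0


def _grid(span: tuple[float, float]) -> np.ndarray:
    t0, t1 = span
    n = int(round((t1 - t0) * TARGET_FS))
    return t0 + np.arange(n) / TARGET_FS


def rr_tachogram(
    beat_times_s: np.ndarray,
    artifact_mask: np.ndarray | None = None,
    span: tuple[float, float] | None = None,
) -> RRSeries:
    """Uniform 4 Hz RR-interval series over ``span`` (seconds).

    Raises ``ValueError`` when fewer than two valid RR values exist in the
    span.
    """
    t = np.asarray(beat_times_s, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("need at least two beats")
    if not np.all(np.diff(t) > 0):
        raise ValueError("beat times must be strictly increasing")
    mask = (
        np.zeros(t.size, dtype=bool)
        if artifact_mask is None
        else np.asarray(artifact_mask, dtype=bool)
    )
    if mask.size != t.size:
        raise ValueError("artifact mask length must match beat count")
    if span is None:
        span = (float(t[0]), float(t[-1]))

    rr = np.diff(t)
    # RR valid where both bounding beats are clean and the value passes the
    # physiological gate (the gate also removes long masked-gap bridges)
    valid = (~mask[1:]) & (~mask[:-1]) & (rr >= RR_GATE_S[0]) & (rr <= RR_GATE_S[1])
    rr_t = t[1:][valid]
    rr_v = rr[valid]
    grid = _grid(span)
    in_span = (rr_t >= span[0] - 30.0) & (rr_t <= span[1] + 30.0)
    if valid.sum() < 2 or rr_t[(rr_t >= span[0]) & (rr_t <= span[1])].size < 2:
        raise ValueError(
            f"fewer than 2 valid RR values in span {span}; cannot interpolate"
        )
    # np.interp extends edges with the nearest valid value
    values = np.interp(grid, rr_t[in_span], rr_v[in_span])
    return RRSeries(values=values, t0_s=span[0])


def condition_effort(raw: np.ndarray, fs_in: float,
                     t0_s: float = 0.0) -> EffortSeries:
    """Anti-alias, resample to 4 Hz, zero-phase high-pass at 0.05 Hz."""
    x = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("effort input contains non-finite values")
    if fs_in < TARGET_FS:
        raise ValueError(
            f"effort sampling rate {fs_in} Hz below the 4 Hz target; "
            "upsampling of effort is unsupported"
        )
    if fs_in > TARGET_FS:
        sos = signal.butter(4, _LP_CUTOFF_HZ, "lowpass", fs=fs_in, output="sos")
        x = signal.sosfiltfilt(sos, x)
        t_in = np.arange(x.size) / fs_in
        n_out = int(x.size * TARGET_FS // fs_in)
        t_out = np.arange(n_out) / TARGET_FS
        x = np.interp(t_out, t_in, x)
    sos_hp = signal.butter(
        _HP_ORDER, _HP_CUTOFF_HZ, "highpass", fs=TARGET_FS, output="sos"
    )
    y = signal.sosfiltfilt(sos_hp, x)
    return EffortSeries(values=y, t0_s=t0_s)


def masked_beat_fraction(record: SubjectRecord,
                         span: tuple[float, float]) -> float:
    """Fraction of beats inside ``span`` flagged as artifact."""
    t = record.beat_times_s
    sel = (t >= span[0]) & (t < span[1])
    n = int(sel.sum())
    if n == 0:
        return 1.0
    return float(record.beat_artifact_mask[sel].sum()) / n


def preprocess_record(record: SubjectRecord) -> tuple[RRSeries, EffortSeries]:
    """Both 4 Hz channels over the lights-off..lights-on window."""
    span = (record.lights_off_s, record.lights_on_s)
    rr = rr_tachogram(record.beat_times_s, record.beat_artifact_mask, span)
    # effort is assumed recorded over the same lights window
    re = condition_effort(record.effort, record.effort_fs_hz, t0_s=span[0])
    n = min(rr.values.size, re.values.size)
    rr.values = rr.values[:n]
    re.values = re.values[:n]
    return rr, re
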