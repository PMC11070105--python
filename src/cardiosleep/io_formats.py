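"""Read and write subject records, segment stores, model bundles, reports.

A record on disk is a directory::

    record-dir/
      annotations.json   # versioned sidecar: beats, mask, hypnogram,
                         # events, lights window, reference AHI
      effort.npz         # raw effort waveform + sampling rate (lossless)
      effort.edf         # optional EDF export (16-bit, quantized)

The annotation dialect is JSON with schema tag
``cardiosleep-annotations-1``; unknown versions are refused, never
coerced.  All times are seconds from lights-off; events are half-open
``{"start_s": ..., "end_s": ..., "type": ...}`` objects.  CSV exports of
the hypnogram and events are provided for interoperability.  Segment
stores are an ``arrays.npz`` container plus a JSON manifest.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ModelHyper, MultiTaskModel, SingleTaskModel
from .types import EventInterval, SegmentStore, SubjectRecord, Thresholds

__all__ = [
    "ANNOTATION_SCHEMA",
    "write_record",
    "read_record",
    "write_segments",
    "read_segments",
    "save_report",
    "save_model_bundle",
    "load_model_bundle",
    "write_effort_edf",
    "read_effort_edf",
]

ANNOTATION_SCHEMA = "cardiosleep-annotations-1"
SEGMENT_SCHEMA = "cardiosleep-segments-1"


def write_record(record: SubjectRecord, path: str | Path,
                 edf: bool = False, csv: bool = False) -> Path:
    """Write one record to a directory; returns the directory path."""
    d = Path(path)
    d.mkdir(parents=True, exist_ok=True)
    ann = {
        "schema": ANNOTATION_SCHEMA,
        "subject_id": record.subject_id,
        "lights_off_s": record.lights_off_s,
        "lights_on_s": record.lights_on_s,
        "ahi_ref": record.ahi_ref,
        "beat_times_s": record.beat_times_s.tolist(),
        "beat_artifact_mask": record.beat_artifact_mask.astype(int).tolist(),
        "hypnogram": list(record.hypnogram),
        "events": [
            {"start_s": e.start_s, "end_s": e.end_s, "type": e.kind}
            for e in record.events
        ],
    }
    (d / "annotations.json").write_text(json.dumps(ann))
    np.savez(
        d / "effort.npz",
        effort=record.effort,
        fs_hz=np.array(record.effort_fs_hz),
    )
    if edf:
        write_effort_edf(
            d / "effort.edf", record.effort, record.effort_fs_hz, "Effort THO"
        )
    if csv:
        pd.DataFrame(
            [(e.start_s, e.end_s, e.kind) for e in record.events],
            columns=["start_s", "end_s", "type"],
        ).to_csv(d / "events.csv", index=False)
        pd.DataFrame(
            {"epoch": range(len(record.hypnogram)), "stage": record.hypnogram}
        ).to_csv(d / "hypnogram.csv", index=False)
    return d


def read_record(path: str | Path) -> SubjectRecord:
    d = Path(path)
    ann_path = d / "annotations.json"
    if not ann_path.exists():
        raise FileNotFoundError(f"no annotations.json in {d}")
    ann = json.loads(ann_path.read_text())
    schema = ann.get("schema")
    if schema != ANNOTATION_SCHEMA:
        raise ValueError(
            f"unknown annotation schema {schema!r}; expected {ANNOTATION_SCHEMA!r}"
        )
    with np.load(d / "effort.npz") as z:
        effort = z["effort"]
        fs = float(z["fs_hz"])
    events = [
        EventInterval(e["start_s"], e["end_s"], e["type"]) for e in ann["events"]
    ]
    return SubjectRecord(
        subject_id=ann["subject_id"],
        beat_times_s=np.array(ann["beat_times_s"], dtype=float),
        beat_artifact_mask=np.array(ann["beat_artifact_mask"], dtype=bool),
        effort=effort,
        effort_fs_hz=fs,
        hypnogram=list(ann["hypnogram"]),
        events=events,
        lights_off_s=float(ann["lights_off_s"]),
        lights_on_s=float(ann["lights_on_s"]),
        ahi_ref=float(ann["ahi_ref"]),
    )


def write_segments(store: SegmentStore, path: str | Path) -> Path:
    d = Path(path)
    d.mkdir(parents=True, exist_ok=True)
    np.savez(
        d / "arrays.npz",
        X=store.X,
        y_event=store.y_event,
        y_sleep=store.y_sleep,
        start_times_s=store.start_times_s,
        subject_ids=store.subject_ids.astype(str),
        usable=store.usable,
    )
    manifest = {
        "schema": SEGMENT_SCHEMA,
        "n_segments": int(len(store)),
        "x_shape": list(store.X.shape),
        "subjects": sorted(set(store.subject_ids.tolist())),
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return d


def read_segments(path: str | Path) -> SegmentStore:
    d = Path(path)
    manifest = json.loads((d / "manifest.json").read_text())
    if manifest.get("schema") != SEGMENT_SCHEMA:
        raise ValueError(f"unknown segment schema {manifest.get('schema')!r}")
    with np.load(d / "arrays.npz") as z:
        return SegmentStore(
            X=z["X"],
            y_event=z["y_event"],
            y_sleep=z["y_sleep"],
            start_times_s=z["start_times_s"],
            subject_ids=z["subject_ids"],
            usable=z["usable"],
        )


def save_report(per_subject: pd.DataFrame, pooled: dict,
                path: str | Path) -> Path:
    """Machine-readable (CSV + JSON) and human-readable report."""
    d = Path(path)
    d.mkdir(parents=True, exist_ok=True)
    per_subject.to_csv(d / "per_subject.csv", index=False)

    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    (d / "pooled.json").write_text(json.dumps(_clean(pooled), indent=1))
    lines = ["cardiosleep evaluation report", "=" * 30]
    for k, v in pooled.items():
        if isinstance(v, float):
            lines.append(f"{k}: {v:.4f}")
        elif not isinstance(v, (dict, list, np.ndarray)):
            lines.append(f"{k}: {v}")
    (d / "summary.txt").write_text("\n".join(lines) + "\n")
    return d


def save_model_bundle(model, path: str | Path,
                      thresholds: Thresholds | None = None) -> Path:
    d = Path(path)
    d.mkdir(parents=True, exist_ok=True)
    np.savez(d / "weights.npz", **model.state_dict())
    meta = {
        "kind": type(model).__name__,
        "hyper": model.hyper.to_dict(),
        "thresholds": (
            {"sleep_thr": thresholds.sleep_thr, "event_thr": thresholds.event_thr}
            if thresholds
            else None
        ),
    }
    (d / "model.json").write_text(json.dumps(meta, indent=1))
    return d


def load_model_bundle(path: str | Path):
    """Returns ``(model, thresholds_or_None)``."""
    d = Path(path)
    meta = json.loads((d / "model.json").read_text())
    hyper = ModelHyper.from_dict(meta["hyper"])
    cls = {"MultiTaskModel": MultiTaskModel, "SingleTaskModel": SingleTaskModel}[
        meta["kind"]
    ]
    model = cls(hyper)
    with np.load(d / "weights.npz") as z:
        model.load_state_dict({k: z[k] for k in z.files})
    thr = meta.get("thresholds")
    thresholds = Thresholds(thr["sleep_thr"], thr["event_thr"]) if thr else None
    return model, thresholds


# ---------------------------------------------------------------------------
# EDF interchange.  Reading goes through mne; writing uses a minimal EDF
# encoder (16-bit, one-second data records) because no installed library
# exports EDF.  The npz container remains the lossless default.
# ---------------------------------------------------------------------------


def write_effort_edf(path: str | Path, signal: np.ndarray, fs_hz: float,
                     channel: str = "Effort THO") -> Path:
    x = np.asarray(signal, dtype=float)
    spr = int(round(fs_hz))
    if abs(fs_hz - spr) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    n_rec = int(np.ceil(x.size / spr))
    pad = n_rec * spr - x.size
    if pad:
        x = np.concatenate([x, np.full(pad, x[-1] if x.size else 0.0)])
    pmin, pmax = float(x.min()), float(x.max())
    if pmax == pmin:
        pmax = pmin + 1.0
    dmin, dmax = -32768, 32767
    digital = np.round(
        (x - pmin) / (pmax - pmin) * (dmax - dmin) + dmin
    ).astype("<i2")

    def pad_field(s: str, n: int) -> bytes:
        return s[:n].ljust(n).encode("ascii")

    header = b"".join(
        [
            pad_field("0", 8),
            pad_field("X X X X", 80),
            pad_field("X X X", 80),
            pad_field("01.01.00", 8),
            pad_field("00.00.00", 8),
            pad_field(str(256 + 256), 8),
            pad_field("", 44),
            pad_field(str(n_rec), 8),
            pad_field("1", 8),  # record duration, seconds
            pad_field("1", 4),  # number of signals
        ]
    )
    sig_header = b"".join(
        [
            pad_field(channel, 16),
            pad_field("RIP belt", 80),
            pad_field("au", 8),
            pad_field(f"{pmin:.6g}", 8),
            pad_field(f"{pmax:.6g}", 8),
            pad_field(str(dmin), 8),
            pad_field(str(dmax), 8),
            pad_field("", 80),
            pad_field(str(spr), 8),
            pad_field("", 32),
        ]
    )
    Path(path).write_bytes(header + sig_header + digital.tobytes())
    return Path(path)


def read_effort_edf(path: str | Path, channel: str | None = None):
    """Returns ``(signal, fs_hz)``; requires mne."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "reading EDF requires the optional dependency mne "
            "(pip install cardiosleep[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    picks = [channel] if channel else [raw.ch_names[0]]
    if channel is not None and channel not in raw.ch_names:
        raise ValueError(
            f"channel {channel!r} not in EDF (has {raw.ch_names})"
        )
    data = raw.get_data(picks=picks)[0]
    return data, float(raw.info["sfreq"])
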