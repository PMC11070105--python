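"""End-to-end experiment orchestration.

``run_experiment`` drives the full study design on a (typically
synthetic) cohort: preprocess and segment every record, build the
severity-stratified fold plan, and for each cross-validation iteration
train the multi-task model (and optionally the single-task comparison
model), select decision thresholds on the validation subjects, and
predict the held-out test subjects.  Test-set results from all
iterations are combined into one cohort-level report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import binarize_and_mask, match_events, merge_events
from .metrics import (
    bland_altman,
    epoch_metrics,
    estimate_ahi,
    estimate_rei,
    estimate_tst,
    event_prf,
    efficiency_sweep,
    mae,
    severity_class,
    severity_confusion,
    spearman,
)
from .model import ModelHyper, MultiTaskModel, SingleTaskModel
from .preprocess import preprocess_record
from .segmentation import make_segments
from .synthetic import simulate_cohort
from .training import (
    THRESHOLD_GRID,
    TrainOptions,
    make_folds,
    select_thresholds,
    subject_night_tracks,
    train,
)
from .types import FoldPlan, SegmentStore, SimConfig, SubjectRecord, Thresholds

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "segment_cohort",
    "run_experiment",
    "evaluate_subjects",
    "select_event_threshold_single",
]


@dataclass
class ExperimentConfig:
    """Study-scale knobs for one full cross-validated experiment."""

    n_subjects: int = 40
    seed: int = 0
    n_folds: int = 4
    sim: SimConfig = field(default_factory=lambda: SimConfig(tib_hours=4.0))
    hyper: ModelHyper = field(default_factory=ModelHyper.reduced)
    train_options: TrainOptions = field(
        default_factory=lambda: TrainOptions(max_epochs=8, patience=8)
    )
    single_task: bool = False


@dataclass
class ExperimentResult:
    per_subject: pd.DataFrame
    pooled: dict
    fold_plan: FoldPlan
    histories: list[pd.DataFrame]
    thresholds: list[Thresholds]


def segment_cohort(records: list[SubjectRecord]) -> SegmentStore:
    """Preprocess and segment every record into one pooled store."""
    segments = []
    for rec in records:
        rr, re = preprocess_record(rec)
        segments.extend(make_segments(rec, rr, re))
    from .types import SegmentStore as _SS

    return _SS.from_segments(segments)


def select_event_threshold_single(model: SingleTaskModel,
                                  val_store: SegmentStore,
                                  grid: np.ndarray | None = None) -> float:
    """Event threshold for the single-task model (no wake masking)."""
    grid = THRESHOLD_GRID if grid is None else np.asarray(grid)
    p_event = model.predict(val_store.X)
    dummy_sleep = np.ones((len(val_store), 10))
    tracks = subject_night_tracks(val_store, p_event, dummy_sleep)
    ref_events = {sid: merge_events(t["ref_event"]) for sid, t in tracks.items()}
    best_f1, best_thr = -1.0, None
    for thr in grid:
        tp = fp = fn = 0
        for sid, t in tracks.items():
            eb = (t["pred"].p_event >= thr).astype(np.int8)
            counts = match_events(merge_events(eb), ref_events[sid])
            tp += counts["TP"]
            fp += counts["FP"]
            fn += counts["FN"]
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        if f1 > best_f1:
            best_f1, best_thr = f1, float(thr)
    return best_thr


def evaluate_subjects(store: SegmentStore, records: dict[str, SubjectRecord],
                      p_event: np.ndarray, p_sleep: np.ndarray,
                      thresholds: Thresholds,
                      p_event_single: np.ndarray | None = None,
                      event_thr_single: float | None = None) -> pd.DataFrame:
    """Per-subject rows of estimates and agreement statistics."""
    tracks = subject_night_tracks(store, p_event, p_sleep)
    rows = []
    for sid, t in tracks.items():
        rec = records[sid]
        pred = t["pred"]
        sleep_bin, event_bin = binarize_and_mask(
            pred.p_sleep, pred.p_event, thresholds
        )
        cov = t["center_covered"]
        em = epoch_metrics(sleep_bin[cov], t["ref_sleep"][cov])
        tst_est = estimate_tst(sleep_bin)
        detected = merge_events(event_bin)
        ref_events = merge_events(t["ref_event"])
        counts = match_events(detected, ref_events)
        ahi_est = estimate_ahi(len(detected), tst_est)
        row = {
            "subject_id": sid,
            "tst_ref_h": rec.tst_ref_hours,
            "tst_est_h": tst_est,
            "ahi_ref": rec.ahi_ref,
            "ahi_est": ahi_est,
            "sleep_efficiency_ref": rec.sleep_efficiency_ref,
            "severity_ref": severity_class(rec.ahi_ref),
            "severity_est": (
                severity_class(ahi_est) if np.isfinite(ahi_est) else "undefined"
            ),
            "kappa": em["kappa"],
            "f1_sleep": em["f1_sleep"],
            "f1_wake": em["f1_wake"],
            "sensitivity_sleep": em["sensitivity_sleep"],
            "specificity_sleep": em["specificity_sleep"],
            "event_tp": counts["TP"],
            "event_fp": counts["FP"],
            "event_fn": counts["FN"],
            "n_events_det": len(detected),
            "n_events_ref": len(ref_events),
        }
        if p_event_single is not None:
            sel = store.subject_ids == sid
            st_tracks = subject_night_tracks(
                store.subset(sel), p_event_single[sel], np.ones((sel.sum(), 10))
            )[sid]
            eb = (st_tracks["pred"].p_event >= event_thr_single).astype(np.int8)
            det_single = merge_events(eb)
            row["rei_est"] = estimate_rei(len(det_single), rec.tib_hours)
            row["n_events_det_single"] = len(det_single)
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=["subject_id"])
    return pd.DataFrame(rows).sort_values("subject_id").reset_index(drop=True)


def _pool(per_subject: pd.DataFrame) -> dict:
    ok = per_subject[np.isfinite(per_subject["ahi_est"])]
    excluded = per_subject[~np.isfinite(per_subject["ahi_est"])]
    pooled: dict = {}
    if len(excluded):
        pooled["ahi_excluded_subjects"] = {
            "ids": excluded["subject_id"].tolist(),
            "reason": "estimated TST is zero with detected events; AHI undefined",
        }
    tp = int(per_subject["event_tp"].sum())
    fp = int(per_subject["event_fp"].sum())
    fn = int(per_subject["event_fn"].sum())
    pooled["event_counts"] = {"TP": tp, "FP": fp, "FN": fn}
    pooled["event_pooled"] = event_prf(tp, fp, fn)
    pooled["event_mean_per_subject"] = {
        "f1": float(
            np.nanmean(
                [
                    event_prf(r.event_tp, r.event_fp, r.event_fn)["f1"]
                    for r in per_subject.itertuples()
                ]
            )
        )
    }
    pooled["kappa_mean"] = float(np.nanmean(per_subject["kappa"]))
    pooled["tst"] = {
        "spearman_r": spearman(per_subject["tst_ref_h"], per_subject["tst_est_h"]),
        "mae_h": mae(per_subject["tst_ref_h"], per_subject["tst_est_h"]),
        **bland_altman(per_subject["tst_ref_h"], per_subject["tst_est_h"]),
    }
    if len(ok) >= 3:
        pooled["ahi"] = {
            "spearman_r": spearman(ok["ahi_ref"], ok["ahi_est"]),
            "mae": mae(ok["ahi_ref"], ok["ahi_est"]),
            **bland_altman(ok["ahi_ref"], ok["ahi_est"]),
        }
        sev = severity_confusion(ok["ahi_ref"].tolist(), ok["ahi_est"].tolist())
        sev_nbl = severity_confusion(
            ok["ahi_ref"].tolist(), ok["ahi_est"].tolist(), nbl=True
        )
        pooled["severity"] = {
            "accuracy": sev["accuracy"],
            "kappa": sev["kappa"],
            "confusion": sev["confusion"],
            "accuracy_nbl": sev_nbl["accuracy"],
            "kappa_nbl": sev_nbl["kappa"],
            "confusion_nbl": sev_nbl["confusion"],
        }
    if "rei_est" in per_subject.columns and len(ok) >= 3:
        pooled["rei"] = {
            "spearman_r": spearman(ok["ahi_ref"], ok["rei_est"]),
            "mae": mae(ok["ahi_ref"], ok["rei_est"]),
        }
        pooled["efficiency_sweep"] = efficiency_sweep(per_subject).to_dict(
            orient="list"
        )
    return pooled


def pooled_epoch_metrics(store: SegmentStore, records, p_event, p_sleep,
                         thresholds_by_subject: dict[str, Thresholds]) -> dict:
    """Aggregate sleep-wake confusion over all center-covered test epochs."""
    tracks = subject_night_tracks(store, p_event, p_sleep)
    preds, refs = [], []
    for sid, t in tracks.items():
        thr = thresholds_by_subject[sid]
        sleep_bin, _ = binarize_and_mask(t["pred"].p_sleep, t["pred"].p_event, thr)
        cov = t["center_covered"]
        preds.append(sleep_bin[cov])
        refs.append(t["ref_sleep"][cov])
    return epoch_metrics(np.concatenate(preds), np.concatenate(refs))


def run_experiment(cfg: ExperimentConfig, verbose: bool = False) -> ExperimentResult:
    """Simulate, cross-validate, and evaluate; the full study design."""
    records = simulate_cohort(cfg.n_subjects, seed=cfg.seed, base_config=cfg.sim)
    rec_by_id = {r.subject_id: r for r in records}
    store = segment_cohort(records)
    plan = make_folds(
        [r.subject_id for r in records],
        {r.subject_id: r.ahi_ref for r in records},
        seed=cfg.seed,
        n_folds=cfg.n_folds,
    )
    frames = []
    histories = []
    thresholds_all = []
    epoch_preds, epoch_refs = [], []
    for i in range(plan.n_iterations):
        roles = plan.roles(i)
        train_store = store.for_subjects(roles["train"])
        train_store = train_store.subset(train_store.usable)
        val_store = store.for_subjects(roles["val"])
        test_store = store.for_subjects(roles["test"])
        opts = TrainOptions(
            **{**cfg.train_options.__dict__, "seed": cfg.seed * 1000 + i,
               "verbose": verbose}
        )
        model = MultiTaskModel(cfg.hyper, seed=cfg.seed * 100 + i)
        model, hist = train(model, train_store, val_store, opts)
        histories.append(hist)
        thr = select_thresholds(model, val_store)
        thresholds_all.append(thr)
        p_event, p_sleep = model.predict(test_store.X)
        kwargs = {}
        if cfg.single_task:
            st_model = SingleTaskModel(cfg.hyper, seed=cfg.seed * 100 + i)
            st_model, _ = train(st_model, train_store, val_store, opts)
            st_thr = select_event_threshold_single(st_model, val_store)
            kwargs = {
                "p_event_single": st_model.predict(test_store.X),
                "event_thr_single": st_thr,
            }
        frames.append(
            evaluate_subjects(
                test_store, rec_by_id, p_event, p_sleep, thr, **kwargs
            )
        )
        # pooled epoch-level collection
        tracks = subject_night_tracks(test_store, p_event, p_sleep)
        for sid, t in tracks.items():
            sb, _ = binarize_and_mask(t["pred"].p_sleep, t["pred"].p_event, thr)
            cov = t["center_covered"]
            epoch_preds.append(sb[cov])
            epoch_refs.append(t["ref_sleep"][cov])
    per_subject = pd.concat(frames, ignore_index=True)
    pooled = _pool(per_subject)
    pooled["epoch_pooled"] = {
        k: v
        for k, v in epoch_metrics(
            np.concatenate(epoch_preds), np.concatenate(epoch_refs)
        ).items()
        if k != "confusion"
    }
    pooled["epoch_confusion"] = epoch_metrics(
        np.concatenate(epoch_preds), np.concatenate(epoch_refs)
    )["confusion"]
    return ExperimentResult(per_subject, pooled, plan, histories, thresholds_all)
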