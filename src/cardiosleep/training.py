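"""Severity-stratified cross-validation, training loop, threshold selection.

Subjects are grouped by SDB severity (from the reference AHI) and each
stratum is split into four folds.  Per iteration one fold is the test
set; the remaining three are re-pooled and re-stratified into 75% train
and 25% validation.  Training minimizes the sum of a sample-weighted
binary cross-entropy on the per-second event labels (weight 10 for event
seconds, 1 for normal breathing) and an unweighted binary cross-entropy
on the per-epoch sleep labels, with Adam (lr 0.001, weight decay 0.0001,
batch 128) and early stopping after 10 epochs without validation-loss
improvement.  Decision thresholds are selected on validation data only by
exhaustive grid search maximizing F1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import (
    binarize_and_mask,
    match_events,
    merge_events,
    stitch_predictions,
)
from .metrics import severity_class
from .model import MultiTaskModel
from .nn import Adam, bce_with_logits
from .types import FoldPlan, SegmentStore, Thresholds

__all__ = [
    "TrainOptions",
    "make_folds",
    "train",
    "select_thresholds",
    "THRESHOLD_GRID",
    "subject_night_tracks",
]

THRESHOLD_GRID = np.round(np.arange(0.01, 1.0, 0.01), 2)


def make_folds(subjects: list[str], ahi_ref: dict[str, float],
               seed: int = 0, n_folds: int = 4,
               val_fraction: float = 0.25) -> FoldPlan:
    """Severity-stratified fold plan; deterministic under ``seed``."""
    if len(subjects) < 8:
        raise ValueError("need at least 8 subjects for stratified 4-fold CV")
    rng = np.random.default_rng(seed)
    strata: dict[str, list[str]] = {}
    for s in subjects:
        strata.setdefault(severity_class(ahi_ref[s]), []).append(s)
    import warnings

    for name, members in strata.items():
        if len(members) < n_folds:
            warnings.warn(
                f"severity stratum '{name}' has only {len(members)} subjects; "
                "folds will be uneven",
                stacklevel=2,
            )
    # per-stratum random split into n_folds subsets; the rotating offset
    # spreads small strata so no fold ends up empty
    fold_members: list[list[str]] = [[] for _ in range(n_folds)]
    for offset, name in enumerate(sorted(strata)):
        members = sorted(strata[name])
        perm = rng.permutation(len(members))
        for j, idx in enumerate(perm):
            fold_members[(j + offset) % n_folds].append(members[idx])
    iterations = []
    for i in range(n_folds):
        test = sorted(fold_members[i])
        rest = sorted(s for j in range(n_folds) if j != i for s in fold_members[j])
        # re-stratify the remaining subjects into train/val
        rest_strata: dict[str, list[str]] = {}
        for s in rest:
            rest_strata.setdefault(severity_class(ahi_ref[s]), []).append(s)
        train_s: list[str] = []
        val_s: list[str] = []
        for name in sorted(rest_strata):
            members = sorted(rest_strata[name])
            perm = rng.permutation(len(members))
            n = len(members)
            n_val = max(1, int(round(val_fraction * n))) if n > 1 else 0
            for j, idx in enumerate(perm):
                (val_s if j < n_val else train_s).append(members[idx])
        iterations.append(
            {"train": sorted(train_s), "val": sorted(val_s), "test": test}
        )
    plan = FoldPlan(iterations=iterations)
    plan.validate()
    return plan


@dataclass
class TrainOptions:
    lr: float = 1e-3
    weight_decay: float = 1e-4
    batch_size: int = 128
    event_weight: float = 10.0
    patience: int = 10
    max_epochs: int = 200
    seed: int = 0
    verbose: bool = False


def event_sample_weights(y_event: np.ndarray, event_weight: float = 10.0) -> np.ndarray:
    """Per-second weights: ``event_weight`` on event samples, 1 elsewhere."""
    y = np.asarray(y_event, dtype=float)
    return 1.0 + (event_weight - 1.0) * y


def _data_loss(model, X, ye, ys, opts: TrainOptions, train: bool,
               compute_grads: bool = False) -> float:
    multi = isinstance(model, MultiTaskModel)
    if multi:
        ze, zs = model.forward_logits(X, train=train)
    else:
        ze = model.forward_logits(X, train=train)
    w = event_sample_weights(ye, opts.event_weight)
    le, dze = bce_with_logits(ze, ye, w)
    loss = le
    if multi:
        ls, dzs = bce_with_logits(zs, ys)
        loss = loss + ls
    if compute_grads:
        if multi:
            model.backward(dze, dzs)
        else:
            model.backward(dze)
    return loss


def _eval_loss(model, store: SegmentStore, opts: TrainOptions) -> float:
    total = 0.0
    n = 0
    bs = opts.batch_size
    for i in range(0, len(store), bs):
        X = store.X[i : i + bs]
        loss = _data_loss(
            model, X, store.y_event[i : i + bs], store.y_sleep[i : i + bs],
            opts, train=False,
        )
        total += loss * len(X)
        n += len(X)
    return total / max(n, 1)


def refresh_batchnorm_stats(model, store: SegmentStore,
                            batch_size: int = 128, max_batches: int = 30,
                            seed: int = 0) -> None:
    """Recompute batch-norm running statistics for the current weights.

    Weights restored from the best validation epoch come with whatever
    running statistics had accumulated by then, which can lag the weights
    badly early in training; a momentum-free averaging pass over training
    batches (dropout disabled) makes evaluation-mode normalization
    consistent with the restored weights.
    """
    from .nn import BatchNorm, Dropout

    bns = [lay for lay in model._all_layers() if isinstance(lay, BatchNorm)]
    drops = [lay for lay in model._all_layers() if isinstance(lay, Dropout)]
    rates = [d.rate for d in drops]
    for d in drops:
        d.rate = 0.0
    for bn in bns:
        bn.begin_cumulative_stats()
    rng = np.random.default_rng(seed)
    n = len(store)
    order = rng.permutation(n)
    try:
        for i in range(0, min(n, max_batches * batch_size), batch_size):
            idx = order[i : i + batch_size]
            if idx.size < 2:
                continue
            model.forward_logits(store.X[idx], train=True)
    finally:
        for bn in bns:
            bn.end_cumulative_stats()
        for d, r in zip(drops, rates):
            d.rate = r


def train(model, train_store: SegmentStore, val_store: SegmentStore,
          options: TrainOptions | None = None):
    """Fit in place; returns ``(model, history)``.

    History is a DataFrame with one row per epoch (train and validation
    loss); the weights restored at exit are those of the best validation
    epoch.
    """
    opts = options or TrainOptions()
    if set(train_store.subject_ids) & set(val_store.subject_ids):
        raise ValueError("train and validation subject sets overlap")
    optim = Adam(model.params(), lr=opts.lr, weight_decay=opts.weight_decay)
    rng = np.random.default_rng(opts.seed)
    n = len(train_store)
    history = []
    best_val = np.inf
    best_state = model.state_dict()
    best_epoch = 0
    since_best = 0
    for epoch in range(1, opts.max_epochs + 1):
        order = rng.permutation(n)
        total = 0.0
        seen = 0
        for i in range(0, n, opts.batch_size):
            idx = order[i : i + opts.batch_size]
            if idx.size < 2:
                continue  # batch statistics undefined for a single segment
            optim.zero_grad()
            loss = _data_loss(
                model,
                train_store.X[idx],
                train_store.y_event[idx],
                train_store.y_sleep[idx],
                opts,
                train=True,
                compute_grads=True,
            )
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}"
                )
            model.add_l2_gradients()
            optim.step()
            total += loss * idx.size
            seen += idx.size
        train_loss = total / max(seen, 1)
        refresh_batchnorm_stats(
            model, train_store, opts.batch_size, max_batches=4, seed=opts.seed
        )
        val_loss = _eval_loss(model, val_store, opts)
        history.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss}
        )
        if opts.verbose:
            print(f"epoch {epoch}: train {train_loss:.4f} val {val_loss:.4f}")
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= opts.patience:
                break
    model.load_state_dict(best_state)
    refresh_batchnorm_stats(model, train_store, opts.batch_size, seed=opts.seed)
    hist = pd.DataFrame(history)
    hist.attrs["best_epoch"] = best_epoch
    return model, hist


def early_stop_trace(val_losses: list[float], patience: int = 10) -> tuple[int, int]:
    """(epochs run, best epoch) for a given validation-loss sequence.

    Pure reference implementation of the stopping rule used by
    :func:`train`: stop once the validation loss has not decreased for
    ``patience`` consecutive epochs.  Epochs are 1-indexed.
    """
    best = np.inf
    best_epoch = 0
    since = 0
    for i, v in enumerate(val_losses, start=1):
        if v < best:
            best = v
            best_epoch = i
            since = 0
        else:
            since += 1
            if since >= patience:
                return i, best_epoch
    return len(val_losses), best_epoch


def subject_night_tracks(store: SegmentStore, p_event: np.ndarray,
                         p_sleep: np.ndarray) -> dict[str, dict]:
    """Group per-segment outputs by subject and stitch whole-night tracks.

    Returns per subject the stitched prediction tracks together with the
    reference tracks stitched from the segment labels by the same rule.
    """
    out: dict[str, dict] = {}
    for sid in np.unique(store.subject_ids):
        sel = store.subject_ids == sid
        starts = store.start_times_s[sel]
        pred = stitch_predictions(starts, p_event[sel], p_sleep[sel])
        ref = stitch_predictions(
            starts, store.y_event[sel].astype(float), store.y_sleep[sel].astype(float)
        )
        out[sid] = {
            "pred": pred,
            "ref_sleep": ref.p_sleep.astype(np.int8),
            "ref_event": ref.p_event.astype(np.int8),
            "center_covered": pred.center_covered,
        }
    return out


def select_thresholds(model: MultiTaskModel, val_store: SegmentStore,
                      grid: np.ndarray | None = None) -> Thresholds:
    """Exhaustive validation grid search for both decision thresholds.

    The sleep threshold maximizes epoch-level F1 with sleep as the
    positive class (center-covered epochs); the event threshold then
    maximizes event-level F1 after wake masking with the chosen sleep
    threshold.  Ties break toward the lowest threshold.
    """
    grid = THRESHOLD_GRID if grid is None else np.asarray(grid)
    p_event, p_sleep = model.predict(val_store.X)
    tracks = subject_night_tracks(val_store, p_event, p_sleep)

    ps = np.concatenate(
        [t["pred"].p_sleep[t["center_covered"]] for t in tracks.values()]
    )
    ys = np.concatenate(
        [t["ref_sleep"][t["center_covered"]] for t in tracks.values()]
    )
    if ys.sum() == 0:
        raise ValueError("validation set has no positive (sleep) epochs")

    best_f1, sleep_thr = -1.0, None
    for thr in grid:
        pred = ps >= thr
        tp = int(np.sum(pred & (ys == 1)))
        fp = int(np.sum(pred & (ys == 0)))
        fn = int(np.sum(~pred & (ys == 1)))
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        if f1 > best_f1:
            best_f1, sleep_thr = f1, float(thr)

    ref_events = {
        sid: merge_events(t["ref_event"]) for sid, t in tracks.items()
    }
    best_f1e, event_thr = -1.0, None
    for thr in grid:
        tp = fp = fn = 0
        for sid, t in tracks.items():
            sb, eb = binarize_and_mask(
                t["pred"].p_sleep, t["pred"].p_event,
                Thresholds(sleep_thr, float(thr)),
            )
            counts = match_events(merge_events(eb), ref_events[sid])
            tp += counts["TP"]
            fp += counts["FP"]
            fn += counts["FN"]
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        if f1 > best_f1e:
            best_f1e, event_thr = f1, float(thr)
    thr = Thresholds(sleep_thr, event_thr)
    return thr
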