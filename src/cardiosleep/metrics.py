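"""Agreement statistics, AHI/REI/TST estimation, and severity classification.

Severity follows the clinical AHI bands with half-open boundaries:
normal [0, 5), mild [5, 15), moderate [15, 30), severe [30, inf).
Near-boundary double-labeling (NBL) assigns subjects whose reference AHI
lies within a zone around a boundary to both flanking classes; an
estimate counts as correct if it falls in either.  Default zone
half-widths are 10% of each boundary (0.5, 1.5, 3.0 events/h) and are
configurable.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SEVERITY_CLASSES",
    "SEVERITY_BOUNDS",
    "DEFAULT_NBL_ZONES",
    "severity_class",
    "nbl_classes",
    "severity_confusion",
    "confusion_2x2",
    "epoch_metrics",
    "estimate_tst",
    "estimate_ahi",
    "estimate_rei",
    "bland_altman",
    "spearman",
    "mae",
    "event_prf",
    "efficiency_sweep",
]

SEVERITY_CLASSES = ("normal", "mild", "moderate", "severe")
SEVERITY_BOUNDS = (5.0, 15.0, 30.0)
#: boundary -> zone half-width (events/h), 10% of the boundary value
DEFAULT_NBL_ZONES = {5.0: 0.5, 15.0: 1.5, 30.0: 3.0}


def severity_class(ahi: float) -> str:
    if not math.isfinite(ahi) or ahi < 0:
        raise ValueError(f"AHI must be finite and non-negative, got {ahi}")
    for name, bound in zip(SEVERITY_CLASSES, SEVERITY_BOUNDS):
        if ahi < bound:
            return name
    return SEVERITY_CLASSES[-1]


def nbl_classes(ahi: float, zones: dict[float, float] | None = None) -> set[str]:
    """Severity classes compatible with ``ahi`` under near-boundary zones."""
    zones = DEFAULT_NBL_ZONES if zones is None else zones
    base = severity_class(ahi)
    out = {base}
    bounds = sorted(zones)
    for i, b in enumerate(bounds):
        if abs(ahi - b) <= zones[b]:
            lower = SEVERITY_CLASSES[i]
            upper = SEVERITY_CLASSES[i + 1]
            out |= {lower, upper}
    return out


def _kappa_from_confusion(cm: np.ndarray) -> float:
    cm = np.asarray(cm, dtype=float)
    n = cm.sum()
    po = np.trace(cm) / n
    pe = float((cm.sum(axis=0) * cm.sum(axis=1)).sum()) / n**2
    if pe == 1.0:
        return float("nan")
    return (po - pe) / (1.0 - pe)


def severity_confusion(ref_ahi: list[float], est_ahi: list[float],
                       nbl: bool = False,
                       zones: dict[float, float] | None = None) -> dict:
    """4x4 confusion matrix, accuracy and kappa over paired AHI lists.

    With NBL on, an estimate whose class lies in ``nbl_classes(ref_ahi)``
    is tallied on the diagonal of the reference class.
    """
    if len(ref_ahi) != len(est_ahi):
        raise ValueError("reference and estimate lists differ in length")
    k = len(SEVERITY_CLASSES)
    cm = np.zeros((k, k), dtype=int)
    for r, e in zip(ref_ahi, est_ahi):
        cr = severity_class(r)
        ce = severity_class(e)
        if nbl and ce in nbl_classes(r, zones):
            ce = cr
        cm[SEVERITY_CLASSES.index(cr), SEVERITY_CLASSES.index(ce)] += 1
    acc = float(np.trace(cm)) / max(1, cm.sum())
    return {
        "confusion": cm,
        "accuracy": acc,
        "kappa": _kappa_from_confusion(cm) if cm.sum() else float("nan"),
    }


def confusion_2x2(pred: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Rows = reference class (0, 1), columns = predicted class (0, 1)."""
    pred = np.asarray(pred).astype(int)
    ref = np.asarray(ref).astype(int)
    if pred.shape != ref.shape:
        raise ValueError("prediction and reference lengths differ")
    cm = np.zeros((2, 2), dtype=int)
    for r in (0, 1):
        for p in (0, 1):
            cm[r, p] = int(np.sum((ref == r) & (pred == p)))
    return cm


def _prf(tp: float, fp: float, fn: float) -> tuple[float, float, float]:
    sens = tp / (tp + fn) if tp + fn else float("nan")
    prec = tp / (tp + fp) if tp + fp else float("nan")
    if not (tp + fp) or not (tp + fn) or (prec + sens) == 0:
        f1 = float("nan") if not (tp + fp + fn) else 0.0
    else:
        f1 = 2 * prec * sens / (prec + sens)
    return sens, prec, f1


def epoch_metrics(pred_sleep: np.ndarray, ref_sleep: np.ndarray) -> dict:
    """Epoch-per-epoch sleep-wake agreement.

    Reports Cohen's kappa plus F1/sensitivity/specificity for both the
    "sleep as positive" and "wake as positive" conventions.  A
    single-class reference makes kappa undefined; it is reported as NaN
    with a reason.
    """
    cm = confusion_2x2(pred_sleep, ref_sleep)
    out: dict = {"confusion": cm}
    if len(np.unique(np.asarray(ref_sleep))) < 2:
        out["kappa"] = float("nan")
        out["kappa_missing_reason"] = "reference contains a single class"
    else:
        out["kappa"] = _kappa_from_confusion(cm)
    # sleep positive: positive label 1
    tp, fn = cm[1, 1], cm[1, 0]
    fp, tn = cm[0, 1], cm[0, 0]
    sens_s, prec_s, f1_s = _prf(tp, fp, fn)
    out["f1_sleep"] = f1_s
    out["sensitivity_sleep"] = sens_s
    out["specificity_sleep"] = tn / (tn + fp) if tn + fp else float("nan")
    # wake positive: positive label 0
    tp_w, fn_w = cm[0, 0], cm[0, 1]
    fp_w, tn_w = cm[1, 0], cm[1, 1]
    sens_w, prec_w, f1_w = _prf(tp_w, fp_w, fn_w)
    out["f1_wake"] = f1_w
    out["sensitivity_wake"] = sens_w
    out["specificity_wake"] = tn_w / (tn_w + fp_w) if tn_w + fp_w else float("nan")
    return out


def estimate_tst(sleep_binary: np.ndarray) -> float:
    """Total sleep time in hours from a per-epoch binary track."""
    return float(np.asarray(sleep_binary).sum()) * 30.0 / 3600.0


def estimate_ahi(n_events: int, tst_h: float) -> float:
    """Events per hour of sleep; NaN (undefined) when TST is zero."""
    if tst_h < 0:
        raise ValueError("TST must be non-negative")
    if tst_h == 0:
        return float("nan") if n_events > 0 else 0.0
    return n_events / tst_h


def estimate_rei(n_events: int, tib_h: float) -> float:
    """Events per hour of time in bed (respiratory event index)."""
    if tib_h <= 0:
        raise ValueError("TIB must be positive")
    return n_events / tib_h


def bland_altman(ref, est) -> dict[str, float]:
    """Bias and 95% limits of agreement of ``est - ref`` (sample SD)."""
    ref = np.asarray(ref, dtype=float)
    est = np.asarray(est, dtype=float)
    if ref.shape != est.shape or ref.size < 3:
        raise ValueError("need >= 3 paired finite values")
    if not (np.isfinite(ref).all() and np.isfinite(est).all()):
        raise ValueError("inputs must be finite")
    d = est - ref
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return {"bias": bias, "loa_low": bias - 1.96 * sd, "loa_high": bias + 1.96 * sd}


def spearman(ref, est) -> float:
    """Spearman rank correlation (average ranks on ties); NaN if degenerate."""
    ref = np.asarray(ref, dtype=float)
    est = np.asarray(est, dtype=float)
    if np.unique(ref).size < 2 or np.unique(est).size < 2:
        return float("nan")
    return float(stats.spearmanr(ref, est).statistic)


def mae(ref, est) -> float:
    ref = np.asarray(ref, dtype=float)
    est = np.asarray(est, dtype=float)
    return float(np.abs(est - ref).mean())


def event_prf(tp: int, fp: int, fn: int) -> dict[str, float]:
    sens, prec, f1 = _prf(tp, fp, fn)
    return {"sensitivity": sens, "precision": prec, "f1": f1}


def efficiency_sweep(per_subject: pd.DataFrame,
                     cutoffs: list[float] | None = None) -> pd.DataFrame:
    """Spearman R and MAE for AHI_est and REI_est vs AHI_ref below each
    sleep-efficiency cutoff.

    ``per_subject`` needs columns ``sleep_efficiency_ref``, ``ahi_ref``,
    ``ahi_est`` and ``rei_est``.  Subsets with fewer than 3 subjects are
    reported as NaN.
    """
    if per_subject.empty:
        raise ValueError("empty per-subject report")
    if cutoffs is None:
        cutoffs = [0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
    rows = []
    for c in cutoffs:
        sub = per_subject[per_subject["sleep_efficiency_ref"] <= c]
        row = {"cutoff": c, "n": len(sub)}
        if len(sub) >= 3:
            row["r_ahi"] = spearman(sub["ahi_ref"], sub["ahi_est"])
            row["mae_ahi"] = mae(sub["ahi_ref"], sub["ahi_est"])
            row["r_rei"] = spearman(sub["ahi_ref"], sub["rei_est"])
            row["mae_rei"] = mae(sub["ahi_ref"], sub["rei_est"])
        else:
            row.update({k: float("nan") for k in ("r_ahi", "mae_ahi", "r_rei", "mae_rei")})
        rows.append(row)
    return pd.DataFrame(rows)
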