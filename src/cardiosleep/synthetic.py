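"""Synthetic overnight cardiorespiratory records with known ground truth.

The generator emulates the statistical structure the multi-task model must
learn, not validated physiology:

* a two-state semi-Markov wake/sleep alternation calibrated to a target
  sleep efficiency, with NREM/REM substages relabeled cosmetically within
  sleep bouts (the downstream pipeline only uses the binary mapping);
* respiratory events placed as a Poisson process on sleep time, with
  uniform durations, no overlaps, and a minimum inter-event gap;
* an RR tachogram with smooth autocorrelated variability, inflated during
  wake, and an event-locked cyclic signature: gradual RR lengthening
  during the event followed by an abrupt post-event shortening
  (sympathetic-discharge undershoot);
* a respiratory-effort quasi-sinusoid (~0.25 Hz) whose amplitude collapses
  during apneas, drops partially during hypopneas, and breathes more
  irregularly during wake.

Same seed, same config -> bit-identical record.
"""

from __future__ import annotations

import numpy as np

from .types import EPOCH_S, EventInterval, SimConfig, SubjectRecord

__all__ = [
    "simulate_subject",
    "simulate_cohort",
    "DEFAULT_AHI_STRATA",
]

# AHI target ranges per severity stratum (events/h); spans normal..severe.
DEFAULT_AHI_STRATA: tuple[tuple[float, float], ...] = (
    (0.5, 4.0),
    (6.0, 14.0),
    (16.0, 28.0),
    (32.0, 60.0),
)

_MEAN_SLEEP_BOUT_EPOCHS = 40  # 20 min
_MIN_EVENT_GAP_S = 10.0
_APNEA_FLOOR = 0.05
_HYPOPNEA_FLOOR = 0.4
_EVENT_RR_GAIN = 0.15  # peak relative RR lengthening during an event
_POST_EVENT_DIP = 0.10  # relative RR shortening after event end
_POST_EVENT_DIP_S = 10.0
_ARTIFACT_RATE = 0.01
_BREATH_HZ = 0.25
_SLEEP_RR_FACTOR = 1.08  # RR lengthens (heart rate drops) during sleep
_WAKE_MOVEMENT_PROB = 0.4  # per wake epoch: chance of a body-movement burst


def _simulate_hypnogram(cfg: SimConfig, rng: np.random.Generator) -> list[str]:
    """Alternating geometric wake/sleep bouts; starts with sleep latency."""
    n_epochs = int(cfg.tib_hours * 3600 // EPOCH_S)
    se = cfg.sleep_efficiency
    mean_sleep = _MEAN_SLEEP_BOUT_EPOCHS
    mean_wake = mean_sleep * (1.0 - se) / max(se, 1e-9) if se > 0 else n_epochs
    is_sleep = np.zeros(n_epochs, dtype=bool)
    pos = 0
    awake = True  # sleep-onset latency is the first wake bout
    while pos < n_epochs:
        mean = mean_wake if awake else mean_sleep
        if mean <= 0:
            bout = 0
        else:
            # geometric bout length with the requested mean (support >= 1)
            bout = 1 + rng.geometric(min(1.0, 1.0 / mean)) - 1
        if not awake:
            bout = max(bout, 1)
        bout = min(bout, n_epochs - pos)
        if not awake:
            is_sleep[pos : pos + bout] = True
        pos += bout
        awake = not awake
    if se >= 1.0:
        is_sleep[:] = True
    stages = _relabel_sleep_stages(is_sleep, rng)
    return stages


def _relabel_sleep_stages(is_sleep: np.ndarray, rng: np.random.Generator) -> list[str]:
    """Cosmetic NREM/REM substructure: cyclic pattern within sleep epochs."""
    # a rough 90-min cycle: N1, N2, N3, N2, REM in fixed proportions
    cycle = ["N1"] * 4 + ["N2"] * 40 + ["N3"] * 30 + ["N2"] * 16 + ["REM"] * 30
    stages: list[str] = []
    k = int(rng.integers(0, len(cycle)))  # random phase so cohorts vary
    for sl in is_sleep:
        if sl:
            stages.append(cycle[k % len(cycle)])
            k += 1
        else:
            stages.append("W")
    return stages


def _place_events(cfg: SimConfig, stages: list[str], rng: np.random.Generator,
                  tib_s: float) -> list[EventInterval]:
    sleep_mask_epoch = np.array([s != "W" for s in stages])
    tst_s = sleep_mask_epoch.sum() * EPOCH_S
    if tst_s <= 0 or cfg.ahi_target <= 0:
        return []
    n_target = rng.poisson(cfg.ahi_target * tst_s / 3600.0)
    if n_target == 0:
        return []
    # seconds whose containing epoch is sleep (event onsets live here)
    sleep_seconds = np.flatnonzero(
        np.repeat(sleep_mask_epoch, int(EPOCH_S))[: int(tib_s)]
    )
    lo, hi = cfg.event_duration_s
    placed: list[tuple[float, float]] = []
    attempts = 0
    while len(placed) < n_target and attempts < 60 * n_target:
        attempts += 1
        onset = float(rng.choice(sleep_seconds)) + float(rng.random())
        dur = float(rng.uniform(lo, hi))
        end = onset + dur
        if end > tib_s:
            continue
        ok = all(
            onset >= e + _MIN_EVENT_GAP_S or end <= s - _MIN_EVENT_GAP_S
            for s, e in placed
        )
        if ok:
            placed.append((onset, end))
    placed.sort()
    kinds = rng.random(len(placed)) < cfg.hypopnea_fraction
    return [
        EventInterval(s, e, "hypopnea" if h else "apnea")
        for (s, e), h in zip(placed, kinds)
    ]


def _smooth_bump(t: np.ndarray, start: float, end: float, ramp: float) -> np.ndarray:
    """Trapezoidal window over [start, end] with cosine ramps of width `ramp`."""
    up = np.clip((t - start) / ramp, 0.0, 1.0)
    down = np.clip((end - t) / ramp, 0.0, 1.0)
    w = np.minimum(up, down)
    return 0.5 - 0.5 * np.cos(np.pi * w)


def _rr_modulation(t: np.ndarray, events: list[EventInterval]) -> np.ndarray:
    """Event-locked multiplicative RR modulation (1 = baseline)."""
    m = np.ones_like(t)
    for ev in events:
        m += _EVENT_RR_GAIN * _smooth_bump(t, ev.start_s, ev.end_s, ramp=5.0)
        m -= _POST_EVENT_DIP * _smooth_bump(
            t, ev.end_s, ev.end_s + _POST_EVENT_DIP_S, ramp=3.0
        )
    return m


def _simulate_beats(cfg: SimConfig, stages: list[str],
                    events: list[EventInterval], rng: np.random.Generator,
                    tib_s: float):
    rr_base = 60.0 / cfg.hr_base_bpm
    sd_rel = (cfg.hrv_sd_ms / 1000.0) / rr_base
    wake_epoch = np.array([s == "W" for s in stages])
    # generous upper bound on beat count
    n_max = int(tib_s / (rr_base * 0.5)) + 10
    times = np.empty(n_max)
    t = float(rng.random() * rr_base)
    k = 0
    ar = 0.0  # AR(1) smooth HRV state, unit variance scale
    ar_coef = 0.9
    innov_sd = np.sqrt(1.0 - ar_coef**2)
    mod_grid_t = np.arange(0.0, tib_s + 1.0, 0.5)
    mod_grid = _rr_modulation(mod_grid_t, events)
    # smooth wake/sleep heart-rate level: RR lengthens during sleep
    epoch_mid = (np.arange(len(stages)) + 0.5) * EPOCH_S
    level_knots = np.where(wake_epoch, 1.0, _SLEEP_RR_FACTOR)
    while t < tib_s and k < n_max:
        times[k] = t
        k += 1
        epoch = min(int(t // EPOCH_S), len(stages) - 1)
        mult = cfg.wake_hrv_multiplier if wake_epoch[epoch] else 1.0
        ar = ar_coef * ar + innov_sd * rng.standard_normal()
        mod = np.interp(t, mod_grid_t, mod_grid)
        level = np.interp(t, epoch_mid, level_knots)
        rr = rr_base * level * mod * (1.0 + sd_rel * mult * ar)
        rr = float(np.clip(rr, 0.35, 2.5))
        t += rr
    times = times[:k]
    # artifacts: a small fraction of beats jittered and flagged for exclusion
    mask = rng.random(k) < _ARTIFACT_RATE
    jitter = rng.uniform(-0.15, 0.15, size=k) * mask
    jittered = times + jitter
    order_ok = np.all(np.diff(jittered) > 0)
    if order_ok:
        times = jittered
    return times, mask


def _simulate_effort(cfg: SimConfig, stages: list[str],
                     events: list[EventInterval], rng: np.random.Generator,
                     tib_s: float) -> np.ndarray:
    fs = cfg.effort_fs_hz
    n = int(round(tib_s * fs))
    t = np.arange(n) / fs
    # slowly wandering breathing rate around 0.25 Hz
    f_dev = np.interp(
        t,
        np.arange(0.0, tib_s + 30.0, 30.0),
        rng.normal(0.0, 0.02, size=len(np.arange(0.0, tib_s + 30.0, 30.0))),
    )
    phase = 2.0 * np.pi * np.cumsum(_BREATH_HZ + f_dev) / fs
    amp = np.ones(n)
    # wake: irregular depth of breathing
    wake_epoch = np.array([s == "W" for s in stages])
    epoch_idx = np.minimum((t // EPOCH_S).astype(int), len(stages) - 1)
    wake_sec = wake_epoch[epoch_idx]
    slow_irreg = np.interp(
        t,
        np.arange(0.0, tib_s + 10.0, 10.0),
        1.0 + rng.normal(0.0, 0.35, size=len(np.arange(0.0, tib_s + 10.0, 10.0))),
    )
    amp = np.where(wake_sec, np.clip(slow_irreg, 0.3, 1.8), amp)
    for ev in events:
        floor = _HYPOPNEA_FLOOR if ev.kind == "hypopnea" else _APNEA_FLOOR
        w = _smooth_bump(t, ev.start_s, ev.end_s, ramp=2.0)
        amp = amp * (1.0 - (1.0 - floor) * w)
    effort = amp * np.sin(phase)
    # body-movement bursts while awake: large low-frequency excursions
    for e, stage in enumerate(stages):
        if stage == "W" and rng.random() < _WAKE_MOVEMENT_PROB:
            start = e * EPOCH_S + rng.uniform(0.0, EPOCH_S - 8.0)
            dur = rng.uniform(2.0, 8.0)
            i0 = max(0, int((start - 2.0) * fs))
            i1 = min(n, int((start + dur + 2.0) * fs))
            tw = t[i0:i1]
            w = _smooth_bump(tw, start, start + dur, ramp=1.0)
            burst_f = rng.uniform(0.5, 1.5)
            effort[i0:i1] += w * rng.uniform(1.5, 3.5) * np.sin(
                2.0 * np.pi * burst_f * tw + rng.uniform(0.0, 2 * np.pi)
            )
    effort = effort + cfg.noise_sd * rng.standard_normal(n)
    return effort


def simulate_subject(config: SimConfig, subject_id: str = "sim-000") -> SubjectRecord:
    """Generate one overnight record from its private random stream."""
    rng = np.random.default_rng(config.seed)
    tib_s = float(int(config.tib_hours * 3600 // EPOCH_S) * EPOCH_S)
    stages = _simulate_hypnogram(config, rng)
    events = _place_events(config, stages, rng, tib_s)
    beat_times, artifact_mask = _simulate_beats(config, stages, events, rng, tib_s)
    effort = _simulate_effort(config, stages, events, rng, tib_s)
    tst_h = sum(1 for s in stages if s != "W") * EPOCH_S / 3600.0
    ahi_ref = len(events) / tst_h if tst_h > 0 else 0.0
    return SubjectRecord(
        subject_id=subject_id,
        beat_times_s=beat_times,
        beat_artifact_mask=artifact_mask,
        effort=effort,
        effort_fs_hz=config.effort_fs_hz,
        hypnogram=stages,
        events=events,
        lights_off_s=0.0,
        lights_on_s=tib_s,
        ahi_ref=ahi_ref,
    )


def simulate_cohort(
    n_subjects: int,
    seed: int = 0,
    base_config: SimConfig | None = None,
    ahi_strata: tuple[tuple[float, float], ...] = DEFAULT_AHI_STRATA,
    sleep_efficiency_range: tuple[float, float] = (0.6, 0.95),
) -> list[SubjectRecord]:
    """Simulate a cohort whose AHI targets populate all severity strata.

    Subject ``i`` draws its AHI target from stratum ``i % 4`` so every
    severity class is represented; sleep efficiency varies uniformly in
    ``sleep_efficiency_range``.  Deterministic under ``seed``.
    """
    if n_subjects < 4:
        raise ValueError(
            "n_subjects must be at least 4 (one per severity stratum, "
            "stratified cross-validation is impossible otherwise)"
        )
    base = base_config or SimConfig()
    master = np.random.default_rng(seed)
    records = []
    for i in range(n_subjects):
        lo, hi = ahi_strata[i % len(ahi_strata)]
        ahi = float(master.uniform(lo, hi))
        se = float(master.uniform(*sleep_efficiency_range))
        sub_seed = int(master.integers(0, 2**31 - 1))
        cfg = base.with_(ahi_target=ahi, sleep_efficiency=se, seed=sub_seed)
        records.append(simulate_subject(cfg, subject_id=f"sim-{i:03d}"))
    return records
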