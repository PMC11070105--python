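# cardiosleep

Joint sleep-disordered-breathing (SDB) event detection and sleep–wake
classification from RR intervals and respiratory effort, for fully
automatic estimation of total sleep time (TST), the apnea–hypopnea
index (AHI), and SDB severity.

## Why

The AHI — SDB events per hour of **sleep** — is the standard severity
measure, with clinical bands at 5/15/30 events/h.  Surrogate screening
systems that see only cardiorespiratory signals usually cannot measure
sleep, so they divide by time in bed instead (the respiratory event
index, REI), which underestimates severity exactly in the patients who
sleep poorly.  `cardiosleep` trains a single multi-task network on two
4 Hz channels — the RR-interval tachogram and a thoracic
respiratory-effort trace — with two outputs:

* a per-second probability that the moment belongs to an SDB event
  (apnea or hypopnea, any type), and
* a per-30-s-epoch probability of sleep.

From the two binarized tracks the pipeline gets the event count *and*
the TST from the same sensors, masks apparent events detected during
wake, and reports AHI_est = N_detected / TST_est, with agreement
statistics (Cohen's κ, F1, Bland–Altman bias and 95% limits of
agreement, Spearman R, MAE) and severity classification with optional
near-boundary double labeling (NBL).

The network is a shared trunk of bidirectional-GRU blocks (1200 input
samples pooled to 300, i.e. 1 Hz) with an event head at 1 Hz and a
sleep head whose convolutional stack pools 300 → 10 epoch outputs.
Training uses summed binary cross-entropies (event side weighted 10:1
for the class imbalance), Adam (lr 0.001, weight decay 0.0001, batch
128), early stopping on validation loss, and severity-stratified
fourfold cross-validation with strict subject-level separation.
Decision thresholds are selected on validation data only, by grid
search maximizing F1.

Because clinical polysomnography archives are access-restricted, the
package ships a first-class synthetic cohort generator
(`cardiosleep.synthetic`) that emulates the full record structure —
beat times with an artifact mask, an effort waveform, a hypnogram,
scored events, lights window — with event-locked cardiac and
respiratory signatures, configurable sleep efficiency, and AHI from
normal to severe.  See `docs/methods.md` for the model, the generator,
and every design decision.

## Worked example

```python
from cardiosleep import SimConfig, simulate_subject, preprocess_record, make_segments

cfg = SimConfig(tib_hours=8.0, sleep_efficiency=0.85, ahi_target=30.0, seed=7)
rec = simulate_subject(cfg, "demo")
print(f"TIB {rec.tib_hours:.2f} h, TST {rec.tst_ref_hours:.2f} h, "
      f"efficiency {rec.sleep_efficiency_ref:.2f}")
print(f"{len(rec.events)} scored events -> reference AHI {rec.ahi_ref:.1f} events/h")
rr, re = preprocess_record(rec)
segs = make_segments(rec, rr, re)
print(f"{len(segs)} five-minute segments, X shape {segs[0].X.shape}, "
      f"event labels {segs[0].y_event.shape}, sleep labels {segs[0].y_sleep.shape}")
```

prints

```
TIB 8.00 h, TST 6.73 h, efficiency 0.84
179 scored events -> reference AHI 26.6 events/h
159 five-minute segments, X shape (1200, 2), event labels (300,), sleep labels (10,)
```

The record spends 8 h in bed of which 6.73 h are asleep; 179 events
over that sleep time give the reference AHI of 26.6 events/h
("moderate").  An 8-h night yields 159 overlapping 5-min windows
(300-s windows, 180-s step), each a 1200×2 input with 300 one-second
event labels and 10 per-epoch sleep labels.

A full cross-validated experiment is one call (or `cardiosleep run`
from the shell):

```python
from cardiosleep import ExperimentConfig, run_experiment
result = run_experiment(ExperimentConfig(n_subjects=40, seed=1))
print(result.pooled["epoch_pooled"]["kappa"])   # pooled sleep-wake kappa
print(result.pooled["ahi"]["spearman_r"])       # AHI rank agreement
```

The CLI mirrors the stages: `cardiosleep simulate | segment | train |
predict | evaluate | sweep | run` (see `--help` on each).

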