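# Methods

## Problem and pipeline

`cardiosleep` estimates sleep-disordered-breathing (SDB) severity fully
automatically from two surrogate signals: the RR-interval tachogram
(time between successive heartbeats) and thoracic respiratory effort
(RIP belt).  The key obstacle for surrogate SDB screening is the AHI
denominator: the apnea–hypopnea index is events per hour of *sleep*, and
without a sleep measurement one must fall back on events per hour in bed
(REI), which systematically underestimates severity in subjects with low
sleep efficiency.  The pipeline therefore trains one multi-task network
that simultaneously (a) detects SDB events at 1-second resolution and
(b) classifies each 30-s epoch as sleep or wake, so that TST, the event
count, and hence AHI = N_events / TST all come from the same two input
channels.

Stages:

1. **Conditioning.**  Beats with an artifact/ectopic flag are excluded;
   an RR value is defined wherever a beat and its predecessor are both
   clean and the interval passes a physiological gate of [0.3, 3.0] s
   (the gate also removes the long interval that would otherwise bridge
   a masked stretch).  Valid (time, RR) pairs are linearly interpolated
   onto a uniform 4 Hz grid with nearest-value edge extension.  Effort is
   low-pass filtered (anti-alias, content above 2 Hz removed), resampled
   to 4 Hz, and high-pass filtered with an order-3 Butterworth at
   0.05 Hz.  Filtering is applied forward–backward (zero phase): the
   training labels are time-locked to the signals, so phase distortion
   would misalign events against their labels.
2. **Segmentation.**  5-min windows with a 180-s step (2-min overlap)
   anchored at lights-off, so window starts coincide with 30-s epoch
   boundaries.  Each window is normalized per channel by soft min–max:
   the 5th/95th percentiles map to 0/1, without clipping.  A trailing
   partial window is dropped.  Labels per window: 300 one-second binary
   event labels (1 if the second intersects any scored event, regardless
   of type) and 10 per-epoch binary sleep labels (W → 0; N1/N2/N3/REM → 1).
3. **Model.**  Shared trunk of two blocks, each two bidirectional GRU
   layers + batch norm + time max-pool + ReLU + dropout; the two pools
   (2, 2) bring 1200 samples to 300, i.e. 1 Hz.  The event head (two
   BiGRU layers + batch norm + ReLU + dropout, then dense-ReLU and
   dense-sigmoid) keeps 1 Hz.  The sleep head adds a convolutional stack
   on a singleton-channel reshape of its feature block output —
   three subblocks of time-axis convolution + ReLU + batch norm +
   max-pool (5, 3, 2) + dropout — reaching 10 outputs, one per epoch.
   All pooling products are checked at build time (they are forced by
   the label shapes); unit counts, kernel lengths and dropout are free
   capacity in `ModelHyper`.
4. **Training.**  Sum of two binary cross-entropies: the event loss uses
   per-second sample weights (10 on event seconds, 1 on normal
   breathing); the sleep loss is unweighted.  Adam with learning rate
   0.001, weight decay 0.0001 (applied to kernel weights), batch 128,
   shuffled epochs, early stopping after 10 epochs without
   validation-loss improvement, weights restored from the best
   validation epoch.  Kernel L2 regularization (1e-4) is added on top of
   the optimizer weight decay; both are exposed.
5. **Cross-validation.**  Subjects are stratified by severity class of
   the reference AHI (bands [0,5), [5,15), [15,30), [30,∞)) and split
   into four folds, one subject-set per stratum per fold.  Per
   iteration, the three non-test folds are re-pooled, re-stratified, and
   split 75/25 into train/validation.  Thresholds and early stopping see
   validation subjects only; test subjects from all four iterations are
   pooled into one cohort-level report.
6. **Inference.**  Per-segment probability tracks are stitched into
   whole-night tracks keeping each segment's central 3 min (the outer
   minute at each end is the overlap); the night's first and last minute
   come from the outer content of the first/last segment so TST covers
   the full record, while epoch-level agreement metrics use only
   center-covered epochs.  The sleep threshold maximizes epoch-level F1
   (sleep positive) on validation data over the grid 0.01…0.99 (step
   0.01, ties to the lowest value); the event threshold then maximizes
   event-level F1 after wake masking.  Event seconds falling in a
   detected-wake epoch are reassigned to normal breathing; maximal runs
   of event seconds become detected events; matching against reference
   events is greedy, one-to-one, in time order, requiring ≥ 1 s overlap.
7. **Report.**  Cohen's kappa, F1/sensitivity/specificity for both
   positive-class conventions, TST/AHI Bland–Altman (bias ± 1.96·sample
   SD), Spearman R (average ranks on ties), MAE, severity confusion with
   and without near-boundary double labeling, and a sleep-efficiency
   sweep comparing AHI (multi-task) against REI (single-task, events per
   hour in bed, no wake masking).

## Design choices where the design was open

* **Threshold order.**  The sleep threshold is chosen before the event
  threshold because wake masking feeds the event-level F1.
* **Event matching.**  One-to-one greedy matching with a ≥ 1 s overlap is
  a committed interpretation (the rule is pluggable via
  `match_events(min_overlap_s=...)`); no minimum duration is imposed on
  detected events.
* **NBL zones.**  Near-boundary half-widths default to 10% of each
  boundary (0.5, 1.5, 3.0 events/h at 5/15/30) and are configurable; the
  NBL confusion matrix tallies a correct-by-zone pair on the reference
  diagonal, and kappa is computed on that resolved matrix.
* **Severity boundaries.**  Half-open intervals: an AHI of exactly 5,
  15, or 30 belongs to the higher class.
* **Normalization.**  Percentiles are computed per segment and per
  channel (linear-interpolation percentiles).
* **Artifact-heavy windows.**  Segments whose span has more than 50%
  masked beats are flagged unusable and excluded from training;
  interpolated-over artifact periods are otherwise retained.

## Compute engine

No GPU framework is used: layers implement explicit forward/backward
passes over numpy arrays, with the GRU recurrence and its
backpropagation-through-time in numba kernels.  Gate nonlinearities use
a clamped Padé approximation of tanh (max error ≈ 4e-5, far below
float32 training noise) so the inner loops stay cheap on one CPU.
Initialization is Xavier-uniform under a seed; training is bit-reproducible
given (seed, data).  Every layer's backward pass is verified against
central finite differences in float64 (`tests/test_nn.py`); the
finite-difference check randomizes parameters first because zero-initialized
biases put ReLU pre-activations exactly on the kink, where the
subgradient convention and a numeric derivative legitimately differ.

Batch-norm evaluation statistics deserve a note: with short trainings
the exponentially weighted running statistics (momentum 0.8) lag the
restored best-epoch weights, which collapses evaluation-mode outputs.
After every epoch's update and again after restoring the best weights,
the running statistics are therefore recomputed by a momentum-free
averaging pass over training batches with dropout disabled ("precise
BN").  The per-epoch refresh uses 4 batches; the final refresh up to 30.

## Synthetic cohort generator

The generator emulates the *record structure and learnable statistical
signatures* of an annotated overnight cardiorespiratory study, not
validated physiology:

* **Hypnogram**: two-state semi-Markov alternation of wake/sleep bouts
  (geometric lengths, mean sleep bout 20 min; mean wake bout set so the
  expected TST/TIB matches the target sleep efficiency; the first wake
  bout is the sleep-onset latency).  NREM/REM substages are a cosmetic
  relabeling through a fixed 90-min-style cycle — the pipeline maps all
  sleep stages to one class, so substage dynamics carry no information.
* **Events**: Poisson count at the target rate per sleep-hour, onsets
  uniform over sleep seconds, durations uniform in [10, 40] s, rejected
  if they would overlap (10-s minimum gap) or extend past lights-on,
  with resampling so the realized count tracks the Poisson draw.
  A configurable fraction are hypopneas.
* **RR tachogram**: beats are generated sequentially at a base heart
  rate of 65 bpm, with AR(1)-smoothed variability (40 ms scale, inflated
  2.5× during wake), a smooth RR *lengthening* of up to +15% during each
  event with a −10% undershoot for ~10 s after it ends (cyclical
  variation of heart rate), and an RR level shift of +8% during sleep
  (heart rate drops when asleep).  ~1% of beats are jittered and flagged
  as artifacts to exercise the mask-and-interpolate path.
* **Effort**: a quasi-sinusoid at ≈0.25 Hz with slowly wandering rate;
  amplitude collapses to 5% during apneas and 40% during hypopneas with
  2-s ramps, wanders irregularly during wake, and wake epochs carry
  occasional large low-frequency body-movement bursts.  Additive
  Gaussian noise (default SD 0.05 of the unit breathing amplitude).

What passing the recovery test shows — and does not show: the pipeline
can learn event-locked cardiorespiratory signatures and wake/sleep
contrast of this idealized form and assemble them into calibrated
TST/AHI estimates end to end.  It does not certify performance on real
polysomnography, where signatures are weaker, often lag the scored
events, vary across subjects, and coexist with pathologies the
generator does not model (periodic limb movements, Cheyne–Stokes
respiration, position effects, sensor drift).

## Desk-scale study conditions

The recovery experiment (also what `scripts/acceptance.py` reruns) uses
40 subjects, 4 h in bed each, AHI targets cycling through the four
severity strata (ranges 0.5–4, 6–14, 16–28, 32–60 events/h), sleep
efficiency uniform in [0.60, 0.95], the reduced model (GRU width 8,
conv filters 4, dense width 16), batch 128, at most 8 epochs per fold,
and the full fourfold stratified cross-validation with multi-task
models only.  These sizes keep a complete run in the tens of minutes on
one CPU while leaving the method, loss, thresholds and evaluation
identical to the full design.  The single-task comparison model and the
sleep-efficiency sweep run at smaller scale in the test suite and
through the CLI.

## Numerical notes and limitations

* Percentile normalization returns all zeros and an unusable flag when
  p95 = p5 (flat channel).
* `estimate_ahi` is undefined (NaN) when estimated TST is zero with
  detected events; such subjects are excluded from AHI agreement and
  listed with a reason in the pooled report.
* Spearman R is reported missing for constant inputs; kappa for a
  single-class reference.
* Stitching refuses gaps in the 180-s segment grid rather than
  interpolating them.
* EDF export quantizes to 16 bits; the npz container is the lossless
  default.
* The event matcher's ≥ 1 s overlap rule makes no allowance for
  post-event signatures: a detection shortly *after* a scored event
  counts as a false positive plus a false negative even though it would
  contribute correctly to AHI.
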