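# Methods

This note documents the models, the synthetic-data generator, and the
numerical and design choices behind `surgrsd`.

## Problem setting

Time is discretised at 1 Hz (annotations and frame features are per-second,
matching 1-FPS sampling of surgical video); every step interval is half-open
`[start, end)` in integer seconds, and a surgery's intervals tile `[0, T)`
exactly.  RSD is reported in minutes; all internal arithmetic is in seconds
so that identities such as `rsd(t)·60 + t = T` hold exactly in floating
point.  An "out of patient" / de-identified label can be folded into the
preceding step at read time (`merge_label_into_previous`), reproducing the
convention used when such frames are annotated as part of the previous step.

## Statistical estimators

**Naive.**  `T_ref` is the arithmetic mean of training total durations;
prediction `max(0, T_ref − t_el)`.  It is exact when all surgeries are
identical and is the degenerate limit of sequence matching (below).

**Step-inferred.**  The per-step reference `t_ref_s` is the mean *total* time
spent in step `s` across the training videos that contain it (repeated
occurrences within a video pool into one total).  The canonical order ranks
steps by their mean normalised first-occurrence time (first start divided by
`T`, averaged over videos containing the step); ties break by step code.
At inference the elapsed time in the current step is cumulative over its
occurrences so far.  A step unseen in training falls back to the sum of
references after the last known canonical position.  The method assumes a
sequential mandatory workflow; pituitary-style workflows violate this
(optional and repeatable steps), which is exactly why it underperforms and
why it is kept as the instructive baseline.

**Sequence matching.**  Sequences are run-length compressed before
comparison (on a per-second stream this equals the per-interval label
sequence; compression is idempotent).  The query's elapsed sequence at time
`t` contains every interval that has started by `t` (an interval joins the
sequence at its start second).  Each historical video contributes its
compressed elapsed sequence truncated at `min(t, T_i)` — a finished video
contributes its full sequence.  Distance is the Levenshtein edit distance
(unit-cost insert/delete/substitute, iterative DP); with instrument
annotations the total distance is the unweighted sum of the step-sequence
and instrument-sequence distances, each compressed and truncated the same
way.  The k nearest histories (default k = 3) define
`T_ref = mean(T_i)` and the prediction is `max(0, T_ref − t_el)`.

*Tie-breaking:* equal distances break by `|T_i − median training T|`, then by
history index — deterministic and unbiased toward any archetype.  Selected
neighbours are restored to history order before averaging so that
`k = |history|` reproduces the naive estimator bit-for-bit.

*Complexity:* a pairwise distance only changes when an element enters the
query's or that history's compressed sequence, so per-second series are
computed by recomputing each pair only at those event seconds and holding
the value constant in between.

## Temporal model

A two-layer LSTM (hidden size default 128; the desk-scale benchmarks in the
tests use 32) over per-second inputs, with up to three linear heads on the
top layer: step logits, instrument logits, and a scalar normalised RSD.  The
input at second `t` is the frame feature vector concatenated with the
elapsed time in hours (`t/3600`, keeping the scalar O(1)); with prior-step
context enabled, also the step probability vector predicted at `t−1` and the
mean of the last `t̂ = 30` probability vectors.  At cold start both blocks
are the uniform distribution — probability-valid and uninformative.  Context
features come from the model's own running predictions during both training
and inference (teacher-free online unrolling) and are treated as constants
in the backward pass (no gradient flows through the fed-back
probabilities).

**Loss.**  Unweighted sum (weights 1,1,1, configurable) of class-weighted
cross-entropy for the step head, class-weighted cross-entropy for the
instrument head when enabled, and Smooth L1 (β = 1) on RSD divided by a
normalisation factor of 10 (RSD in minutes), which keeps the regression and
classification magnitudes comparable during joint training.  Class weights
are inverse-frequency, `w_c = N / (C_present · n_c)`, with unobserved
classes weighted 0 and excluded from the loss normaliser.  The realised
classification-to-regression loss ratio is logged per epoch as a diagnostic
rather than being set as a target.

**Training.**  Adam (default schedule: 40 epochs, lr 1e-3 for the first
half, 1e-4 for the second), full-video unrolling with truncated
backpropagation through time in windows of 512 s (hidden state carried,
gradients cut at window boundaries), global gradient-norm clipping at 5.
The checkpoint with the best validation full-duration RSD MAE is kept (last
epoch if there is no validation split).  Everything is plain numpy with
hand-derived backward passes (verified against finite differences in the
tests), so runs are deterministic given the seed.

**Inference** is strictly per-second and causal; RSD is denormalised to
minutes and floored at 0.  Variants: `rsd` (no step head), `s_rsd`
(+step head), `si_rsd` (+instrument head), `full` (+prior-step context,
which requires the step head).

## Workflow simulator

The generator emulates the structural properties that make pituitary RSD
hard, with three variability sources: optional-step dropout (6 optional
steps, inclusion probability 0.4), adjacent transpositions of the 8 core
steps (probability 0.15 per adjacent pair), and insertion of a repeatable
haemostasis-like step after any step (probability 0.15, skipped where it
would create an adjacent duplicate).  Optional steps have fixed "home"
slots spread evenly across the core order.

Per-step durations are log-normal — positive and right-skewed, matching the
long-tailed per-step distributions seen in real annotation data; no
distributional family is established for these durations, so log-normal is a
modelling choice.  A two-component duration-scale mixture (default
multipliers 1.0 and 1.7 with weights 0.75/0.25) creates fast/slow surgery
archetypes, giving sequence-aware methods population structure to exploit
and creating duration outliers.  The defaults (per-step medians summing to
≈39 min of core work, σ = 0.65 in log-space) were calibrated by simulation
so that total durations over large cohorts match the published cohort-level
statistics: median ≈ 64 min, IQR ≈ 53–84 min, mean ≈ 72 min — with a heavy
right tail (mean > median).  Only cohort-level statistics were calibrated;
per-step medians are a plausibility choice.

`archetype_marker_step` optionally makes one optional step present exactly
in long-archetype surgeries — an early visible cue that the operation will
run long, standing in for real covariates such as CSF-leak repair that
co-occur with long surgeries.  Instrument streams, when enabled, are a
per-step categorical emission: each step prefers a small step-specific
instrument subset (derived deterministically from the config seed), with
within-interval switching probability 0.02/s.

Frame embeddings stand in for a frozen video encoder's output: one unit-norm
random centroid per step plus isotropic Gaussian noise.  What this does *not*
emulate: visual ambiguity between steps that look alike, encoder drift,
camera-out events, lighting, or any correlation between image content and
duration beyond step identity.  Tests passing on these embeddings show the
temporal machinery learns and the architecture behaves as designed — not
that a real encoder would reach the same accuracy.

## Benchmark designs

The package's seeded benchmarks (tests and `scripts/acceptance.py`) use
scaled or structured variants of the generator:

* **Statistical benchmark** (60 train / 20 test): full-length durations so
  the last-20-minute window is a genuine late-surgery window, σ = 0.45 so
  the archetype structure dominates within-archetype noise, and an
  archetype-marker step so workflow sequences actually carry duration
  information — the regime sequence matching is designed for.  Without
  sequence→duration correlation no sequence method can beat duration
  averaging, so this structure is a precondition of the comparison, not a
  handicap on the baselines.
* **Temporal benchmarks**: 5-step workflows at 1/8 duration scale (surgeries
  of a few minutes) so that training runs in seconds on one CPU; D = 16
  embeddings; hidden size 32 and 8–10 epochs.  The learning-sanity benchmark
  uses near-noiseless embeddings (σ = 0.05); the context benchmark uses
  noisy embeddings (σ = 0.5) plus a marker cohort, because temporally
  smoothed self-predictions only add information when single frames are
  ambiguous.

## Numerical choices and edge cases

* Second-level statistical predictions compute `max(0, T_ref_sec − t)/60`,
  so a k = 1 match to an identical history reproduces the ground truth
  bit-for-bit.
* Wilcoxon signed-rank: zero differences dropped before ranking; exact
  two-sided p for n < 26 from the signed-rank distribution built by dynamic
  programming over doubled midranks (ties allowed); normal approximation
  with continuity and tie correction beyond.  All-zero differences return
  p = 1 with a degenerate flag.
* Macro-F1 averages only over classes present in the ground truth (avoids
  0/0 for classes never annotated).
* MAE windows: `lastK` is the final `60K` seconds; shorter videos use their
  full duration.  Cohort MAE is the unweighted mean over videos (long
  surgeries do not dominate), dispersion is the sample sd over videos.
* `x/10·10` can differ from `x` by one ulp; the normalisation round trip is
  exact to machine precision, not bitwise.
* Outlier injection scales every interval duration (rounded, floored at
  1 s) and re-aligns the instrument stream to the new total.

## Limitations

* The simulator's step-duration independence (given the archetype) is a
  simplification; real step durations correlate through patient anatomy and
  surgeon.
* Surgeon identity and experience are not modelled.
* The temporal model processes one video at a time (batch size 1); this is
  deliberate at desk scale but slow for large cohorts.
* The step-inferred canonicalisation (mean normalised first-occurrence time)
  is one of several defensible orderings; its weakness on non-sequential
  workflows is inherent to the method, not the canonicalisation.
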