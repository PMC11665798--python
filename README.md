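# surgrsd

Intra-operative **Remaining Surgery Duration (RSD)** prediction for endoscopic
pituitary surgery, with a surgical-workflow simulator and an evaluation
harness.

## The problem

During surgery, anaesthetists need to know how much longer the operation will
take: when to titrate down anaesthetic agents, when to give pain relief and
antiemetics, when to call for the next patient.  These decisions hinge on the
last 10–20 minutes of the operation, so a clinically useful predictor should
be accurate precisely there.  Endoscopic transsphenoidal pituitary surgery is
a hard case: its workflow has 8 core and 6 optional steps, the order varies,
haemostasis can recur at any point, and total durations are long-tailed
(median ≈ 64 min, IQR ≈ 53–84 min).

At elapsed time `t_el` in a surgery of (unknown) total duration `T`, the
target is

```
t_rsd = T − t_el,        progress p = t_el / T
```

This package implements a ladder of predictors of `t_rsd`, all strictly
causal (the estimate at second `t` uses only information from seconds ≤ `t`):

* **Naive** — `t_rsd = max(0, T_ref − t_el)` with `T_ref` the mean total
  duration of the training split.
* **Step-inferred** — per-step reference durations `t_ref_s`; prediction is
  the remaining time in the current step plus the references of all later
  steps in a canonical order:
  `t_rsd = max(0, t_ref_s − t_el_s) + Σ_{i>s} t_ref_i`.
  Assumes a sequential mandatory workflow, which pituitary surgery violates —
  it is the instructive weak baseline.
* **Sequence matching (k-NN)** — the elapsed step sequence, run-length
  compressed, is compared by Levenshtein distance with each historical
  surgery's sequence truncated at the same timestamp; `T_ref` is the mean
  full duration of the k = 3 nearest neighbours.  With instrument
  annotations, the distance is the unweighted sum of the step-sequence and
  instrument-sequence distances.
* **Temporal model** — a two-layer LSTM over per-second frame features with
  multi-task heads (step, optional instrument, RSD), trained with weighted
  cross-entropy + Smooth L1 on RSD normalised by a factor of 10.  The full
  variant appends **prior-step context** to each input frame: the step
  probabilities predicted one second earlier and their mean over the last 30
  seconds,

  ```
  l_t = f(I_t) ⊕ s_{t−1},   s_{t−1} = g(l_{t−1})_step ⊕ (1/t̂) Σ_{i=1..t̂} g(l_{t−i})_step
  ```

  Ablation variants: `rsd` (regression only), `s_rsd` (+step head),
  `si_rsd` (+instrument head), `full` (+prior context).

Because real endoscopic video datasets are private, the package ships a
**workflow simulator** that generates per-second step (and instrument)
annotation streams and synthetic per-frame embeddings with the structure
above — core/optional steps, variable order, a repeatable haemostasis-like
step, log-normal step durations, and a two-component duration-scale mixture
("fast" and "slow" surgery archetypes) calibrated to the published
cohort-level statistics.

Evaluation follows the field's convention: MAE in minutes computed per video
and mean-averaged over videos, over the full duration and the last 20 / last
10 minutes; paired Wilcoxon signed-rank tests between methods; macro-F1 for
step recognition.

## Worked example

```
python examples/02_statistical_baselines.py
```

```
naive reference duration T_ref = 63.1 min

last-20-min MAE, mean over 20 test videos (lower is better):
  naive               9.99 +- 6.17 min
  step-inferred      10.08 +- 3.93 min
  sequence matching   6.33 +- 3.12 min

paired Wilcoxon p (sequence matching vs naive): 0.0483
```

On a simulated 60-train / 20-test cohort whose workflow sequences carry
duration information (an early optional step co-occurs with the long-surgery
archetype), sequence matching roughly halves the late-surgery error of the
duration-only baselines, and the paired test shows the improvement is
consistent across videos.  `examples/03_temporal_model.py` trains the
multi-task temporal model (test macro-F1 0.948, RSD MAE 0.90 min vs naive
1.35 min on its small benchmark) and `examples/04_prior_step_context.py`
shows the prior-step-context variant improving late-surgery MAE on
archetype-marker cohorts (1.27 vs 1.33 min).

A thin CLI wraps the same pipeline:

```
surgrsd simulate --out cohort/ --n-train 70 --n-val 8 --n-test 10 --seed 0 --embeddings-dim 16
surgrsd predict  --cohort cohort/ --method seqmatch --k 3 --out preds.csv
surgrsd train    --cohort cohort/ --features cohort/features --variant s_rsd --out model/
surgrsd evaluate --pred preds.csv --cohort cohort/ --out report.json
surgrsd compare  --pred-a a.csv --pred-b b.csv --cohort cohort/ --window last20
surgrsd run      --config run.yaml   # simulate -> fit/train -> predict -> evaluate
```

## Layout

```
src/surgrsd/workflow.py     annotation data model, I/O, ground-truth RSD
src/surgrsd/simulate.py     workflow + embedding simulator
src/surgrsd/statistical.py  naive / step-inferred / sequence-matching estimators
src/surgrsd/temporal/       numpy LSTM multi-task model (nn.py, model.py)
src/surgrsd/evaluation.py   windowed MAE, Wilcoxon, macro-F1
src/surgrsd/experiment.py   end-to-end runs (one cohort, many methods)
src/surgrsd/cli.py          `surgrsd` command-line interface
docs/methods.md             models, simulator design, numerical choices
examples/                   narrative scripts, one per capability
```
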