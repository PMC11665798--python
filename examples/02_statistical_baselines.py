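"""Fit the three statistical RSD estimators and compare them late in surgery.

Naive uses only the mean historical duration; step-inferred adds per-step
reference durations in a canonical order; sequence matching finds the k=3
historical surgeries whose elapsed step sequences (run-length compressed,
truncated at the same timestamp) are closest in Levenshtein distance and
averages their full durations.  On a cohort where workflow sequences carry
duration information, sequence matching is far more accurate in the
clinically decisive last 20 minutes.
"""

import numpy as np

import surgrsd as sr
from surgrsd.evaluation import per_video_mae, wilcoxon_paired

# archetype_marker_step: an early optional step that co-occurs with the
# long-duration surgery archetype (e.g. CSF-leak repair)
config = sr.scaled_config(sigma=0.45, archetype_marker_step=10, seed=105)
timelines, split = sr.sample_cohort(config, 60, 0, 20)
train = [timelines[v] for v in split.train]

naive = sr.fit_naive(train)
step = sr.fit_step_inferred(train)
seqmatch = sr.fit_sequence_match(train, k=3)
print(f"naive reference duration T_ref = {naive.T_ref_min:.1f} min")

mae = {"naive": [], "step-inferred": [], "sequence matching": []}
for vid in split.test:
    tl = timelines[vid]
    mae["naive"].append(per_video_mae(sr.predict_naive_series(naive, tl), tl, "last20"))
    mae["step-inferred"].append(
        per_video_mae(sr.predict_step_inferred_series(step, tl), tl, "last20")
    )
    mae["sequence matching"].append(
        per_video_mae(sr.predict_sequence_match_series(seqmatch, tl), tl, "last20")
    )

print("\nlast-20-min MAE, mean over 20 test videos (lower is better):")
for name, vals in mae.items():
    print(f"  {name:18s} {np.mean(vals):5.2f} +- {np.std(vals, ddof=1):.2f} min")

p, _ = wilcoxon_paired(mae["sequence matching"], mae["naive"])
print(f"\npaired Wilcoxon p (sequence matching vs naive): {p:.4f}")
print("p < 0.05 means the improvement is consistent across videos, not an average effect")
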