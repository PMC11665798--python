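"""Prior-step context: feeding the model's own step estimates back as input.

The full model variant concatenates, to each frame feature, the step
probabilities it predicted one second earlier and their mean over the last 30
seconds.  On a cohort where an early optional step flags the long-duration
surgery archetype and the frame features are noisy, this temporally smoothed
workflow memory improves late-surgery RSD accuracy over the identical model
without context.
"""

import numpy as np

import surgrsd as sr
from surgrsd import temporal as tm
from surgrsd.evaluation import per_video_mae

seed = 301
config = sr.scaled_config(
    duration_scale=1 / 8, sigma=0.45, n_core=5, n_optional=1,
    repeat_step_code=3, repeat_prob_per_step=0.1, order_swap_prob=0.1,
    archetype_marker_step=6,  # optional step 6 present only in long surgeries
    duration_scale_archetypes=((1.0, 0.7), (1.9, 0.3)), seed=seed,
)
timelines, split = sr.sample_cohort(config, 30, 4, 8)
embedding = sr.make_embedding_config(config.all_codes, dim=16, noise_sd=0.5, seed=seed + 1)
rng = np.random.default_rng(seed + 2)
tracks = {v: sr.sample_frame_embeddings(timelines[v], embedding, rng) for v in timelines}

for variant, label in (("full", "with prior-step context"), ("s_rsd", "without context")):
    model_config = tm.variant_config(
        variant, feature_dim=16, n_steps=6, hidden_size=32,
        epochs=8, lr_schedule=((4, 1e-3), (4, 1e-4)), seed=seed,
    )
    model = tm.train(tracks, timelines, split, model_config)
    maes = [
        per_video_mae(tm.predict_online(model, tracks[v])[0], timelines[v], "last20")
        for v in split.test
    ]
    print(f"{label:28s} last-20-min MAE = {np.mean(maes):.2f} min")
print("lower MAE with context = the smoothed workflow memory lets the model "
      "commit earlier to the long-surgery archetype")
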