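"""Synthetic surgical-workflow and frame-embedding generator.

Emulates the structure of endoscopic pituitary surgery workflows so that every
predictor in this package is trainable and testable without access to real
operating-theatre video:

* a fixed set of **core** (mandatory) steps performed in a canonical order,
  with occasional transpositions of adjacent steps;
* **optional** steps, each present in only a fraction of surgeries;
* a **repeatable** haemostasis-like step that may be inserted after any other
  step (bleeding control can happen at any stage);
* right-skewed (log-normal) per-step durations and a two-component
  duration-scale mixture that creates "fast" and "slow" surgery archetypes,
  giving the cohort a long-tailed total-duration distribution.

Default duration parameters are calibrated so a large simulated cohort matches
the published cohort-level statistics of the pituitary case series this
package targets: median total duration ~64 min (IQR 53-84), mean ~74 +- 35 min.

Per-second frame embeddings stand in for the output of a frozen video encoder:
each second's feature vector is the centroid of its active step plus isotropic
Gaussian noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .workflow import (
    CohortSplit,
    StepInterval,
    StepVocabulary,
    WorkflowTimeline,
    write_split,
    write_timeline,
)

__all__ = [
    "SimulatorConfig",
    "EmbeddingConfig",
    "FrameFeatureTrack",
    "default_config",
    "default_vocabulary",
    "make_embedding_config",
    "sample_workflow",
    "sample_cohort",
    "sample_frame_embeddings",
    "inject_outlier",
    "cohort_duration_stats",
    "write_cohort",
    "write_features",
    "read_features",
]

# Calibrated per-step median durations in seconds (log-normal scale parameter
# exp(mu)).  Codes 1..8 are core, 9..14 optional; 8 is the repeatable
# haemostasis-like step.  Together with sigma=0.65 and the default archetype
# mixture these reproduce cohort totals of median ~64 min, IQR ~53-84 min.
_DEFAULT_STEP_MEDIANS_SEC: dict[int, float] = {
    1: 281.0,  # nasal corridor
    2: 328.0,  # sphenoidotomy
    3: 234.0,  # septal work
    4: 234.0,  # sellar exposure
    5: 187.0,  # durotomy
    6: 655.0,  # tumour excision
    7: 374.0,  # reconstruction
    8: 140.0,  # haemostasis (repeatable)
    9: 140.0,  # turbinate lateralisation
    10: 234.0,  # CSF-leak repair
    11: 187.0,  # fat-graft harvest
    12: 140.0,  # nasal packing
    13: 117.0,  # debris clearance
    14: 94.0,  # biopsy
}

_DEFAULT_STEP_NAMES: dict[int, str] = {
    1: "nasal_corridor",
    2: "sphenoidotomy",
    3: "septal_work",
    4: "sellar_exposure",
    5: "durotomy",
    6: "tumour_excision",
    7: "reconstruction",
    8: "haemostasis",
    9: "turbinate_lateralisation",
    10: "csf_leak_repair",
    11: "fat_graft_harvest",
    12: "nasal_packing",
    13: "debris_clearance",
    14: "biopsy",
}


@dataclass(frozen=True)
class SimulatorConfig:
    """Parameters of the workflow generator.

    ``step_duration_params`` maps step code -> (mu, sigma) of a log-normal in
    log-seconds.  ``duration_scale_archetypes`` is a list of
    (multiplier, mixture weight) pairs; one archetype is drawn per surgery and
    its multiplier scales every step duration, producing fast/slow surgery
    subpopulations.  When ``archetype_marker_step`` is set to an optional step
    code, that step is included exactly in surgeries of the largest-multiplier
    archetype (an early visible cue that the surgery will run long) instead of
    by ``optional_inclusion_prob``.
    """

    n_core: int = 8
    n_optional: int = 6
    optional_inclusion_prob: float = 0.4
    order_swap_prob: float = 0.15
    repeat_step_code: int = 8
    repeat_prob_per_step: float = 0.15
    step_duration_params: Mapping[int, tuple[float, float]] = field(
        default_factory=lambda: {
            code: (float(np.log(med)), 0.65)
            for code, med in _DEFAULT_STEP_MEDIANS_SEC.items()
        }
    )
    duration_scale_archetypes: tuple[tuple[float, float], ...] = (
        (1.0, 0.75),
        (1.7, 0.25),
    )
    archetype_marker_step: int | None = None
    n_instruments: int = 0
    instrument_switch_prob: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.optional_inclusion_prob <= 1.0:
            raise ValueError("optional_inclusion_prob must be in [0,1]")
        if not 0.0 <= self.order_swap_prob <= 1.0:
            raise ValueError("order_swap_prob must be in [0,1]")
        if not 0.0 <= self.repeat_prob_per_step <= 1.0:
            raise ValueError("repeat_prob_per_step must be in [0,1]")
        for code, (_, sigma) in self.step_duration_params.items():
            if sigma < 0:
                raise ValueError(f"sigma for step {code} must be >= 0")
        w = sum(w for _, w in self.duration_scale_archetypes)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("archetype mixture weights must sum to 1")
        if self.repeat_step_code not in self.all_codes:
            raise ValueError(
                f"repeat_step_code {self.repeat_step_code} outside the vocabulary"
            )
        missing = [c for c in self.all_codes if c not in self.step_duration_params]
        if missing:
            raise ValueError(f"no duration parameters for step(s) {missing}")
        if self.archetype_marker_step is not None and (
            self.archetype_marker_step not in self.optional_codes
        ):
            raise ValueError("archetype_marker_step must be an optional step code")

    @property
    def core_codes(self) -> tuple[int, ...]:
        return tuple(range(1, self.n_core + 1))

    @property
    def optional_codes(self) -> tuple[int, ...]:
        return tuple(range(self.n_core + 1, self.n_core + self.n_optional + 1))

    @property
    def all_codes(self) -> tuple[int, ...]:
        return self.core_codes + self.optional_codes


def default_config(**overrides) -> SimulatorConfig:
    """The calibrated default simulator configuration (14-step vocabulary)."""
    return replace(SimulatorConfig(), **overrides) if overrides else SimulatorConfig()


def scaled_config(
    duration_scale: float = 1.0, sigma: float = 0.65, **overrides
) -> SimulatorConfig:
    """Default config with all step-duration medians scaled by a factor.

    Useful for quick benchmarks: ``duration_scale=1/8`` yields surgeries of a
    few minutes with the same workflow structure.
    """
    params = {
        code: (float(np.log(med * duration_scale)), sigma)
        for code, med in _DEFAULT_STEP_MEDIANS_SEC.items()
    }
    return SimulatorConfig(step_duration_params=params, **overrides)


def default_vocabulary(config: SimulatorConfig | None = None) -> StepVocabulary:
    config = config or SimulatorConfig()
    entries = []
    for code in config.all_codes:
        name = _DEFAULT_STEP_NAMES.get(code, f"step_{code}")
        entries.append((code, name, code in config.core_codes))
    return StepVocabulary(tuple(entries))


# ---------------------------------------------------------------------------
# Workflow sampling


def _optional_slots(config: SimulatorConfig) -> dict[int, int]:
    """Home position of each optional step: index in the core order after which
    it is inserted, spread evenly across the workflow."""
    slots: dict[int, int] = {}
    for j, code in enumerate(config.optional_codes):
        slots[code] = round(j * (config.n_core - 1) / max(config.n_optional - 1, 1))
    return slots


def sample_workflow(
    config: SimulatorConfig,
    rng: np.random.Generator,
    video_id: str = "sim",
) -> WorkflowTimeline:
    """Draw one synthetic surgery timeline.

    All core steps are always present.  Deterministic given (config, rng state).
    """
    multipliers = np.array([m for m, _ in config.duration_scale_archetypes])
    weights = np.array([w for _, w in config.duration_scale_archetypes])
    archetype = int(rng.choice(len(multipliers), p=weights))
    mult = float(multipliers[archetype])
    long_archetype = int(np.argmax(multipliers))

    # canonical core order with adjacent transpositions
    order = list(config.core_codes)
    for i in range(len(order) - 1):
        if rng.random() < config.order_swap_prob:
            order[i], order[i + 1] = order[i + 1], order[i]

    # optional-step insertion at evenly spread home slots
    slots = _optional_slots(config)
    seq = list(order)
    for code in reversed(config.optional_codes):
        if code == config.archetype_marker_step:
            include = archetype == long_archetype
        else:
            include = rng.random() < config.optional_inclusion_prob
        if include:
            seq.insert(slots[code] + 1, code)

    # repeatable-step insertion after any element (skip if it would create an
    # adjacent duplicate, which would merge into one interval)
    out_seq: list[int] = []
    for i, code in enumerate(seq):
        out_seq.append(code)
        if (
            rng.random() < config.repeat_prob_per_step
            and code != config.repeat_step_code
            and (i + 1 >= len(seq) or seq[i + 1] != config.repeat_step_code)
        ):
            out_seq.append(config.repeat_step_code)

    # durations
    intervals: list[StepInterval] = []
    t = 0
    for code in out_seq:
        mu, sigma = config.step_duration_params[code]
        dur = int(round(float(np.exp(mu + sigma * rng.standard_normal())) * mult))
        dur = max(dur, 1)
        intervals.append(StepInterval(code, t, t + dur))
        t += dur

    instr = None
    if config.n_instruments > 0:
        instr = _sample_instruments(intervals, config, rng)
    return WorkflowTimeline(video_id=video_id, intervals=tuple(intervals), instrument_intervals=instr)


def _instrument_affinity(config: SimulatorConfig) -> np.ndarray:
    """Deterministic per-step categorical emission weights over instruments.

    Each step prefers a small step-specific subset of the instrument
    vocabulary, so the instrument stream carries workflow information the way
    real tool usage does.  Derived from config.seed only (not the draw rng) so
    all surgeries of a cohort share the same emission model.
    """
    rng = np.random.default_rng(config.seed + 7919)
    n_steps = config.n_core + config.n_optional
    aff = np.full((n_steps + 1, config.n_instruments), 0.02)
    for code in range(1, n_steps + 1):
        k = min(3, config.n_instruments)
        pref = rng.choice(config.n_instruments, size=k, replace=False)
        aff[code, pref] = 1.0
    return aff / aff.sum(axis=1, keepdims=True)


def _sample_instruments(
    intervals: Sequence[StepInterval],
    config: SimulatorConfig,
    rng: np.random.Generator,
) -> tuple[StepInterval, ...]:
    aff = _instrument_affinity(config)
    labels: list[int] = []
    for iv in intervals:
        p = aff[iv.step_label]
        cur = int(rng.choice(config.n_instruments, p=p)) + 1  # codes 1..n
        for _ in range(iv.duration_sec):
            if labels and rng.random() < config.instrument_switch_prob:
                cur = int(rng.choice(config.n_instruments, p=p)) + 1
            labels.append(cur)
    # merge per-second labels into intervals
    out: list[StepInterval] = []
    start = 0
    for t in range(1, len(labels) + 1):
        if t == len(labels) or labels[t] != labels[start]:
            out.append(StepInterval(labels[start], start, t))
            start = t
    return tuple(out)


def sample_cohort(
    config: SimulatorConfig,
    n_train: int,
    n_val: int,
    n_test: int,
    id_prefix: str = "vid",
) -> tuple[dict[str, WorkflowTimeline], CohortSplit]:
    """Draw an independent cohort of surgeries and its split manifest.

    Reproducible: the rng is seeded from ``config.seed`` alone.
    """
    if min(n_train, n_val, n_test) < 0:
        raise ValueError("split counts must be >= 0")
    rng = np.random.default_rng(config.seed)
    n = n_train + n_val + n_test
    ids = [f"{id_prefix}{i:04d}" for i in range(n)]
    timelines = {vid: sample_workflow(config, rng, video_id=vid) for vid in ids}
    split = CohortSplit(
        train=tuple(ids[:n_train]),
        val=tuple(ids[n_train : n_train + n_val]),
        test=tuple(ids[n_train + n_val :]),
    )
    return timelines, split


# ---------------------------------------------------------------------------
# Frame embeddings


@dataclass(frozen=True)
class EmbeddingConfig:
    """Synthetic per-frame feature model: one centroid per step + Gaussian noise."""

    dim: int
    step_centroids: Mapping[int, np.ndarray]
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim <= 0:
            raise ValueError("dim must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for code, c in self.step_centroids.items():
            if np.asarray(c).shape != (self.dim,):
                raise ValueError(f"centroid for step {code} is not length {self.dim}")


@dataclass
class FrameFeatureTrack:
    """Per-second encoder feature vectors and elapsed time for one surgery."""

    video_id: str
    features: np.ndarray  # (T, D)
    elapsed_sec: np.ndarray  # (T,)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.elapsed_sec = np.asarray(self.elapsed_sec, dtype=np.int64)
        if self.features.ndim != 2 or len(self.features) != len(self.elapsed_sec):
            raise ValueError("features must be (T, D) aligned with elapsed_sec")

    @property
    def T(self) -> int:
        return len(self.features)

    @property
    def dim(self) -> int:
        return self.features.shape[1]


def make_embedding_config(
    step_codes: Sequence[int], dim: int, noise_sd: float = 0.1, seed: int = 0
) -> EmbeddingConfig:
    """Unit-norm random centroids per step, reproducible from the seed."""
    rng = np.random.default_rng(seed)
    centroids = {}
    for code in step_codes:
        v = rng.standard_normal(dim)
        centroids[int(code)] = v / np.linalg.norm(v)
    return EmbeddingConfig(dim=dim, step_centroids=centroids, noise_sd=noise_sd, seed=seed)


def sample_frame_embeddings(
    timeline: WorkflowTimeline,
    config: EmbeddingConfig,
    rng: np.random.Generator | None = None,
) -> FrameFeatureTrack:
    """Feature at second t = centroid(step at t) + isotropic Gaussian noise."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    labels = timeline.step_labels_per_sec()
    missing = {lab for lab in labels if lab not in config.step_centroids}
    if missing:
        raise ValueError(f"no centroid for step(s) {sorted(missing)}")
    feats = np.stack([np.asarray(config.step_centroids[lab], dtype=np.float64) for lab in labels])
    if config.noise_sd > 0:
        feats = feats + config.noise_sd * rng.standard_normal(feats.shape)
    return FrameFeatureTrack(
        video_id=timeline.video_id,
        features=feats,
        elapsed_sec=np.arange(timeline.T, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# Outlier injection and cohort statistics


def inject_outlier(timeline: WorkflowTimeline, scale: float) -> WorkflowTimeline:
    """Scale every interval duration by ``scale`` (rounded, floored at 1 s).

    Emulates surgeries that run significantly shorter or longer than the
    cohort they are evaluated against.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")

    def _scaled(intervals: Sequence[StepInterval]) -> tuple[StepInterval, ...]:
        out = []
        t = 0
        for iv in intervals:
            dur = max(int(round(iv.duration_sec * scale)), 1)
            out.append(StepInterval(iv.step_label, t, t + dur))
            t += dur
        return tuple(out)

    new_steps = _scaled(timeline.intervals)
    new_instr = None
    if timeline.instrument_intervals is not None:
        new_instr = list(_scaled(timeline.instrument_intervals))
        # re-align the instrument stream's total length with the step stream
        T = new_steps[-1].end_sec
        last = new_instr[-1]
        if last.end_sec != T:
            if T > last.start_sec:
                new_instr[-1] = StepInterval(last.step_label, last.start_sec, T)
            else:
                while new_instr and new_instr[-1].start_sec >= T:
                    new_instr.pop()
                if new_instr:
                    last = new_instr[-1]
                    new_instr[-1] = StepInterval(last.step_label, last.start_sec, T)
        new_instr = tuple(new_instr) if new_instr else None
    return WorkflowTimeline(
        video_id=timeline.video_id, intervals=new_steps, instrument_intervals=new_instr
    )


def cohort_duration_stats(timelines: Mapping[str, WorkflowTimeline] | Sequence[WorkflowTimeline]) -> dict[str, float]:
    """Median / IQR / mean +- sd of total durations, in minutes."""
    if isinstance(timelines, Mapping):
        ts = [tl.T_minutes for tl in timelines.values()]
    else:
        ts = [tl.T_minutes for tl in timelines]
    arr = np.asarray(ts)
    return {
        "n": int(arr.size),
        "median_min": float(np.median(arr)),
        "q1_min": float(np.percentile(arr, 25)),
        "q3_min": float(np.percentile(arr, 75)),
        "mean_min": float(arr.mean()),
        "sd_min": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
    }


# ---------------------------------------------------------------------------
# On-disk cohort layout


def write_cohort(
    out_dir: str | Path,
    timelines: Mapping[str, WorkflowTimeline],
    split: CohortSplit,
    vocabulary: StepVocabulary | None = None,
) -> None:
    """Write annotation CSVs, split manifest, vocabulary, and a stats summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for vid, tl in timelines.items():
        write_timeline(tl, out_dir / f"{vid}.csv")
    write_split(split, out_dir / "split.json")
    if vocabulary is not None:
        vocabulary.to_json(out_dir / "steps.json")
    (out_dir / "stats.json").write_text(
        json.dumps(cohort_duration_stats(timelines), indent=1)
    )


def write_features(
    out_dir: str | Path, tracks: Mapping[str, FrameFeatureTrack]
) -> None:
    """One .npy matrix (T, D) per video."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for vid, track in tracks.items():
        np.save(out_dir / f"{vid}.npy", track.features.astype(np.float32))


def read_features(features_dir: str | Path) -> dict[str, FrameFeatureTrack]:
    features_dir = Path(features_dir)
    out = {}
    for p in sorted(features_dir.glob("*.npy")):
        mat = np.load(p)
        out[p.stem] = FrameFeatureTrack(
            video_id=p.stem, features=mat, elapsed_sec=np.arange(len(mat))
        )
    return out
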