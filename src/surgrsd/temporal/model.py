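"""Recurrent multi-task remaining-surgery-duration predictor.

A two-layer LSTM over per-second frame features with up to three output
heads — surgical step, instrument, and RSD — trained jointly with a weighted
cross-entropy + Smooth L1 loss.  The model optionally feeds its own recent
step-probability estimates back into the input ("prior step context"): the
input at second t is the frame feature concatenated with the normalised
elapsed time, the step probabilities predicted at t-1, and the mean step
probabilities over the last ``context_window`` seconds.

RSD regression targets are divided by a normalisation factor (default 10,
RSD in minutes) so the regression and classification loss magnitudes are
comparable during joint training.

Four standard variants:

========== ========= =========== =============
variant    step head instr. head prior context
========== ========= =========== =============
``rsd``    no        no          no
``s_rsd``  yes       no          no
``si_rsd`` yes       yes         no
``full``   yes       optional    yes
========== ========= =========== =============

Inference is strictly causal: the prediction at second t is a function of
frames 0..t only.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from ..simulate import FrameFeatureTrack
from ..workflow import CohortSplit, RSDSeries, WorkflowTimeline
from .nn import (
    Adam,
    Linear,
    LSTMLayer,
    clip_gradients,
    smooth_l1,
    softmax,
    weighted_cross_entropy,
)

__all__ = [
    "TemporalModelConfig",
    "ContextState",
    "StepProbSeries",
    "TemporalRSDModel",
    "variant_config",
    "build_context_feature",
    "normalize_rsd",
    "denormalize_rsd",
    "class_weights",
    "multitask_loss",
    "train",
    "predict_online",
]

VARIANTS = ("rsd", "s_rsd", "si_rsd", "full")


@dataclass(frozen=True)
class TemporalModelConfig:
    """Hyper-parameters of the temporal RSD model.

    ``lr_schedule`` is piecewise constant, a tuple of (n_epochs, lr) phases;
    the default trains 40 epochs at 1e-3 then 1e-4 (20 each).  ``loss_weights``
    multiplies the (step, instrument, RSD) loss terms; the default is an
    unweighted sum.
    """

    feature_dim: int
    n_steps: int
    n_instruments: int = 0
    hidden_size: int = 128
    n_recurrent_layers: int = 2
    use_step_head: bool = True
    use_instrument_head: bool = False
    use_prior_context: bool = False
    context_window: int = 30
    rsd_norm_factor: float = 10.0
    smooth_l1_beta: float = 1.0
    epochs: int = 40
    lr_schedule: tuple[tuple[int, float], ...] = ((20, 1e-3), (20, 1e-4))
    loss_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tbptt_window: int = 512
    grad_clip: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_dim < 1 or self.n_steps < 1 or self.hidden_size < 1:
            raise ValueError("feature_dim, n_steps, hidden_size must be >= 1")
        if self.context_window < 1:
            raise ValueError("context_window must be >= 1")
        if self.rsd_norm_factor <= 0:
            raise ValueError("rsd_norm_factor must be positive")
        if self.use_prior_context and not self.use_step_head:
            raise ValueError("prior step context requires the step head")
        if self.use_instrument_head and self.n_instruments < 1:
            raise ValueError("instrument head requires n_instruments >= 1")
        if self.n_recurrent_layers != 2:
            raise ValueError("the architecture uses exactly 2 recurrent layers")

    @property
    def input_dim(self) -> int:
        base = self.feature_dim + 1  # + normalised elapsed time
        if self.use_prior_context:
            base += 2 * self.n_steps
        return base


def variant_config(variant: str, feature_dim: int, n_steps: int, **overrides) -> TemporalModelConfig:
    """Configuration for one of the standard ablation variants."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    flags = {
        "rsd": dict(use_step_head=False, use_instrument_head=False, use_prior_context=False),
        "s_rsd": dict(use_step_head=True, use_instrument_head=False, use_prior_context=False),
        "si_rsd": dict(use_step_head=True, use_instrument_head=True, use_prior_context=False),
        "full": dict(use_step_head=True, use_prior_context=True),
    }[variant]
    return TemporalModelConfig(feature_dim=feature_dim, n_steps=n_steps, **{**flags, **overrides})


# ---------------------------------------------------------------------------
# Prior-step context


@dataclass
class ContextState:
    """Running context: step probabilities at t-1 and a FIFO of recent ones."""

    n_steps: int
    window: int
    last_step_probs: np.ndarray = field(init=False)
    recent: deque = field(init=False)

    def __post_init__(self) -> None:
        self.last_step_probs = np.full(self.n_steps, 1.0 / self.n_steps)
        self.recent = deque(maxlen=self.window)

    def mean_recent(self) -> np.ndarray:
        if not self.recent:
            return np.full(self.n_steps, 1.0 / self.n_steps)
        return np.mean(np.stack(self.recent), axis=0)

    def update(self, probs: np.ndarray) -> None:
        if probs.shape != (self.n_steps,):
            raise ValueError("probability vector has wrong length")
        self.last_step_probs = probs
        self.recent.append(probs)


def build_context_feature(
    frame_feature: np.ndarray,
    elapsed_sec: float,
    state: ContextState,
    config: TemporalModelConfig,
) -> np.ndarray:
    """Input vector at one second: [feature; t_el/3600; p_{t-1}; mean recent p].

    The two probability blocks are appended only when prior context is
    enabled; at cold start (empty buffer) both default to the uniform
    distribution.
    """
    frame_feature = np.asarray(frame_feature, dtype=np.float64)
    if frame_feature.shape != (config.feature_dim,):
        raise ValueError(
            f"frame feature has shape {frame_feature.shape}, expected ({config.feature_dim},)"
        )
    parts = [frame_feature, np.array([elapsed_sec / 3600.0])]
    if config.use_prior_context:
        parts.extend([state.last_step_probs, state.mean_recent()])
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# Targets, weights, losses


def normalize_rsd(rsd_minutes, factor: float):
    """Scale RSD (minutes) by the normalisation factor; exact inverse below."""
    if factor <= 0:
        raise ValueError("normalisation factor must be positive")
    return np.asarray(rsd_minutes) / factor if np.ndim(rsd_minutes) else rsd_minutes / factor


def denormalize_rsd(rsd_norm, factor: float):
    if factor <= 0:
        raise ValueError("normalisation factor must be positive")
    return np.asarray(rsd_norm) * factor if np.ndim(rsd_norm) else rsd_norm * factor


def class_weights(labels: Sequence[int], n_classes: int) -> np.ndarray:
    """Inverse-frequency weights: w_c = N / (C_present * n_c); unobserved -> 0."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("cannot derive class weights from empty labels")
    if labels.max() >= n_classes or labels.min() < 0:
        raise ValueError("label index outside [0, n_classes)")
    counts = np.bincount(labels, minlength=n_classes).astype(float)
    present = counts > 0
    w = np.zeros(n_classes)
    w[present] = labels.size / (present.sum() * counts[present])
    return w


def multitask_loss(
    step_logits: np.ndarray | None,
    step_true: np.ndarray | None,
    instr_logits: np.ndarray | None,
    instr_true: np.ndarray | None,
    rsd_pred_norm: np.ndarray,
    rsd_true_norm: np.ndarray,
    step_class_weights: np.ndarray | None,
    config: TemporalModelConfig,
    instr_class_weights: np.ndarray | None = None,
) -> float:
    """Joint loss: weighted CE (step) + weighted CE (instrument) + Smooth L1 (RSD)."""
    for arr in (step_logits, instr_logits, rsd_pred_norm, rsd_true_norm):
        if arr is not None and not np.all(np.isfinite(arr)):
            raise FloatingPointError("non-finite value in loss inputs")
    w_step, w_instr, w_rsd = config.loss_weights
    total = 0.0
    if step_logits is not None:
        loss_s, _ = weighted_cross_entropy(step_logits, step_true, step_class_weights)
        total += w_step * loss_s
    if instr_logits is not None:
        loss_i, _ = weighted_cross_entropy(instr_logits, instr_true, instr_class_weights)
        total += w_instr * loss_i
    loss_r, _ = smooth_l1(rsd_pred_norm, rsd_true_norm, config.smooth_l1_beta)
    total += w_rsd * loss_r
    return float(total)


# ---------------------------------------------------------------------------
# Model


@dataclass
class StepProbSeries:
    """Per-second step probabilities (and optionally instrument probabilities).

    Columns follow ``step_codes`` order; rows are causally generated.
    """

    video_id: str
    probs: np.ndarray  # (T, S)
    step_codes: tuple[int, ...]
    instr_probs: np.ndarray | None = None
    instrument_codes: tuple[int, ...] | None = None

    def argmax_labels(self) -> np.ndarray:
        codes = np.asarray(self.step_codes)
        return codes[self.probs.argmax(axis=1)] if len(self.probs) else np.array([], dtype=int)


class TemporalRSDModel:
    """Two-layer LSTM with step / instrument / RSD heads (numpy, batch size 1)."""

    def __init__(
        self,
        config: TemporalModelConfig,
        step_codes: Sequence[int],
        instrument_codes: Sequence[int] | None = None,
    ):
        if len(step_codes) != config.n_steps:
            raise ValueError(
                f"{len(step_codes)} step codes but config.n_steps={config.n_steps}"
            )
        self.config = config
        self.step_codes = tuple(int(c) for c in step_codes)
        self.instrument_codes = (
            tuple(int(c) for c in instrument_codes) if instrument_codes else None
        )
        rng = np.random.default_rng(config.seed)
        H = config.hidden_size
        self.l1 = LSTMLayer(config.input_dim, H, rng)
        self.l2 = LSTMLayer(H, H, rng)
        self.head_rsd = Linear(H, 1, rng)
        self.head_step = Linear(H, config.n_steps, rng) if config.use_step_head else None
        self.head_instr = (
            Linear(H, config.n_instruments, rng) if config.use_instrument_head else None
        )
        self.step_class_weights: np.ndarray | None = None
        self.instr_class_weights: np.ndarray | None = None
        self.training_log: list[dict] = []

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> dict[str, np.ndarray]:
        p = {}
        p.update(self.l1.params("l1"))
        p.update(self.l2.params("l2"))
        p.update(self.head_rsd.params("head_rsd"))
        if self.head_step is not None:
            p.update(self.head_step.params("head_step"))
        if self.head_instr is not None:
            p.update(self.head_instr.params("head_instr"))
        return p

    def _snapshot(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.parameters().items()}

    def _restore(self, snap: Mapping[str, np.ndarray]) -> None:
        for k, v in self.parameters().items():
            v[...] = snap[k]

    # -- persistence --------------------------------------------------------

    def save(self, model_dir: str | Path) -> None:
        model_dir = Path(model_dir)
        model_dir.mkdir(parents=True, exist_ok=True)
        np.savez(model_dir / "weights.npz", **self.parameters())
        meta = {
            "config": _config_to_dict(self.config),
            "step_codes": list(self.step_codes),
            "instrument_codes": list(self.instrument_codes) if self.instrument_codes else None,
            "step_class_weights": (
                self.step_class_weights.tolist() if self.step_class_weights is not None else None
            ),
            "instr_class_weights": (
                self.instr_class_weights.tolist()
                if self.instr_class_weights is not None
                else None
            ),
        }
        (model_dir / "config.yaml").write_text(yaml.safe_dump(meta))
        with open(model_dir / "log.jsonl", "w") as fh:
            for entry in self.training_log:
                fh.write(json.dumps(entry) + "\n")

    @classmethod
    def load(cls, model_dir: str | Path) -> "TemporalRSDModel":
        model_dir = Path(model_dir)
        meta = yaml.safe_load((model_dir / "config.yaml").read_text())
        config = _config_from_dict(meta["config"])
        model = cls(config, meta["step_codes"], meta.get("instrument_codes"))
        weights = np.load(model_dir / "weights.npz")
        model._restore({k: weights[k] for k in weights.files})
        if meta.get("step_class_weights") is not None:
            model.step_class_weights = np.asarray(meta["step_class_weights"])
        if meta.get("instr_class_weights") is not None:
            model.instr_class_weights = np.asarray(meta["instr_class_weights"])
        log_path = model_dir / "log.jsonl"
        if log_path.exists():
            model.training_log = [
                json.loads(line) for line in log_path.read_text().splitlines() if line
            ]
        return model

    # -- forward passes -----------------------------------------------------

    def _base_inputs(self, track: FrameFeatureTrack) -> np.ndarray:
        """Frame features + normalised elapsed-time scalar, (T, D+1)."""
        if track.dim != self.config.feature_dim:
            raise ValueError(
                f"track dimension {track.dim} != configured feature_dim "
                f"{self.config.feature_dim}"
            )
        tel = track.elapsed_sec[:, None] / 3600.0
        return np.concatenate([track.features, tel], axis=1)


def _config_to_dict(config: TemporalModelConfig) -> dict:
    d = asdict(config)
    d["lr_schedule"] = [list(pair) for pair in config.lr_schedule]
    d["loss_weights"] = list(config.loss_weights)
    return d


def _config_from_dict(d: dict) -> TemporalModelConfig:
    d = dict(d)
    d["lr_schedule"] = tuple((int(n), float(lr)) for n, lr in d["lr_schedule"])
    d["loss_weights"] = tuple(float(x) for x in d["loss_weights"])
    return TemporalModelConfig(**d)


# ---------------------------------------------------------------------------
# Inference


def predict_online(
    model: TemporalRSDModel, track: FrameFeatureTrack
) -> tuple[RSDSeries, StepProbSeries | None]:
    """Causal per-second prediction: output at t depends on frames 0..t only.

    RSD is denormalised to minutes and floored at zero.  When the step head
    exists, the per-second step probabilities (the model's own context source)
    are returned alongside.
    """
    cfg = model.config
    if track.T == 0:
        empty = RSDSeries(video_id=track.video_id, rsd_pred_min=[])
        probs = (
            StepProbSeries(track.video_id, np.zeros((0, cfg.n_steps)), model.step_codes)
            if model.head_step is not None
            else None
        )
        return empty, probs
    base = model._base_inputs(track)
    state = ContextState(cfg.n_steps, cfg.context_window)
    h1, c1 = model.l1.init_state()
    h2, c2 = model.l2.init_state()
    rsd_out = np.empty(track.T)
    step_probs = np.empty((track.T, cfg.n_steps)) if model.head_step is not None else None
    instr_probs = (
        np.empty((track.T, cfg.n_instruments)) if model.head_instr is not None else None
    )
    for t in range(track.T):
        if cfg.use_prior_context:
            x = np.concatenate([base[t], state.last_step_probs, state.mean_recent()])
        else:
            x = base[t]
        h1, c1, _ = model.l1.step(x, h1, c1)
        h2, c2, _ = model.l2.step(h1, h2, c2)
        rsd_out[t] = model.head_rsd.forward(h2[None, :])[0, 0]
        if model.head_step is not None:
            p = softmax(model.head_step.forward(h2[None, :])[0])
            step_probs[t] = p
            state.update(p)
        if model.head_instr is not None:
            instr_probs[t] = softmax(model.head_instr.forward(h2[None, :])[0])
    rsd_min = np.maximum(denormalize_rsd(rsd_out, cfg.rsd_norm_factor), 0.0)
    series = RSDSeries(video_id=track.video_id, rsd_pred_min=rsd_min.tolist())
    probs = None
    if model.head_step is not None:
        probs = StepProbSeries(
            video_id=track.video_id,
            probs=step_probs,
            step_codes=model.step_codes,
            instr_probs=instr_probs,
            instrument_codes=model.instrument_codes,
        )
    return series, probs


# ---------------------------------------------------------------------------
# Training


def _targets_for(
    timeline: WorkflowTimeline,
    step_index: Mapping[int, int],
    instr_index: Mapping[int, int] | None,
    cfg: TemporalModelConfig,
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    steps = np.array([step_index[s] for s in timeline.step_labels_per_sec()])
    instr = None
    if instr_index is not None:
        instr = np.array([instr_index[s] for s in timeline.instrument_labels_per_sec()])
    t = np.arange(timeline.T)
    rsd_norm = normalize_rsd((timeline.T - t) / 60.0, cfg.rsd_norm_factor)
    return steps, instr, rsd_norm


def _train_chunk_batch(
    model: TemporalRSDModel,
    X: np.ndarray,
    step_t: np.ndarray | None,
    instr_t: np.ndarray | None,
    rsd_t: np.ndarray,
    states: tuple,
    opt: Adam,
) -> tuple[dict[str, float], tuple]:
    """One truncated-BPTT update when the full input chunk is known up front."""
    cfg = model.config
    (h1, c1), (h2, c2) = states
    H1, s1, cache1 = model.l1.forward_sequence(X, h1, c1)
    H2, s2, cache2 = model.l2.forward_sequence(H1, h2, c2)
    return _heads_and_update(model, X, H1, H2, cache1, cache2, None, step_t, instr_t, rsd_t, opt) , (s1, s2)


def _heads_and_update(
    model: TemporalRSDModel,
    X: np.ndarray,
    H1: np.ndarray,
    H2: np.ndarray,
    cache1: list,
    cache2: list,
    step_logits: np.ndarray | None,
    step_t: np.ndarray | None,
    instr_t: np.ndarray | None,
    rsd_t: np.ndarray,
    opt: Adam,
) -> dict[str, float]:
    cfg = model.config
    w_step, w_instr, w_rsd = cfg.loss_weights
    grads: dict[str, np.ndarray] = {}
    dH2 = np.zeros_like(H2)
    parts = {"step": 0.0, "instr": 0.0, "rsd": 0.0}

    rsd_pred = model.head_rsd.forward(H2)[:, 0]
    loss_r, drsd = smooth_l1(rsd_pred, rsd_t, cfg.smooth_l1_beta)
    parts["rsd"] = loss_r
    g, dh = model.head_rsd.backward(H2, (w_rsd * drsd)[:, None])
    grads.update({f"head_rsd.{k}": v for k, v in g.items()})
    dH2 += dh

    if model.head_step is not None and step_t is not None:
        logits = step_logits if step_logits is not None else model.head_step.forward(H2)
        loss_s, dlogits = weighted_cross_entropy(logits, step_t, model.step_class_weights)
        parts["step"] = loss_s
        g, dh = model.head_step.backward(H2, w_step * dlogits)
        grads.update({f"head_step.{k}": v for k, v in g.items()})
        dH2 += dh

    if model.head_instr is not None and instr_t is not None:
        logits_i = model.head_instr.forward(H2)
        loss_i, dlogits_i = weighted_cross_entropy(
            logits_i, instr_t, model.instr_class_weights
        )
        parts["instr"] = loss_i
        g, dh = model.head_instr.backward(H2, w_instr * dlogits_i)
        grads.update({f"head_instr.{k}": v for k, v in g.items()})
        dH2 += dh

    g2, dH1 = model.l2.backward_sequence(cache2, dH2)
    grads.update({f"l2.{k}": v for k, v in g2.items()})
    g1, _ = model.l1.backward_sequence(cache1, dH1)
    grads.update({f"l1.{k}": v for k, v in g1.items()})

    if not all(np.all(np.isfinite(v)) for v in grads.values()):
        raise FloatingPointError("non-finite gradient during training")
    clip_gradients(grads, cfg.grad_clip)
    opt.step(model.parameters(), grads)
    parts["total"] = w_step * parts["step"] + w_instr * parts["instr"] + w_rsd * parts["rsd"]
    return parts


def _train_chunk_stepwise(
    model: TemporalRSDModel,
    base: np.ndarray,
    step_t: np.ndarray,
    instr_t: np.ndarray | None,
    rsd_t: np.ndarray,
    states: tuple,
    context: ContextState,
    opt: Adam,
) -> tuple[dict[str, float], tuple]:
    """One truncated-BPTT update with prior-step context built on the fly.

    Context features come from the model's own running predictions
    (teacher-free online unrolling) and are treated as constants in the
    backward pass.
    """
    cfg = model.config
    (h1, c1), (h2, c2) = states
    T = len(base)
    cache1: list = []
    cache2: list = []
    X = np.empty((T, cfg.input_dim))
    H1 = np.empty((T, cfg.hidden_size))
    H2 = np.empty((T, cfg.hidden_size))
    logits = np.empty((T, cfg.n_steps))
    for t in range(T):
        x = np.concatenate([base[t], context.last_step_probs, context.mean_recent()])
        X[t] = x
        h1, c1, e1 = model.l1.step(x, h1, c1)
        cache1.append(e1)
        H1[t] = h1
        h2, c2, e2 = model.l2.step(h1, h2, c2)
        cache2.append(e2)
        H2[t] = h2
        lg = model.head_step.forward(h2[None, :])[0]
        logits[t] = lg
        context.update(softmax(lg))
    parts = _heads_and_update(
        model, X, H1, H2, cache1, cache2, logits, step_t, instr_t, rsd_t, opt
    )
    return parts, ((h1, c1), (h2, c2))


def _epoch_lr(schedule: Sequence[tuple[int, float]], epoch: int) -> float:
    acc = 0
    for n, lr in schedule:
        acc += n
        if epoch < acc:
            return lr
    return schedule[-1][1]


def train(
    tracks: Mapping[str, FrameFeatureTrack],
    timelines: Mapping[str, WorkflowTimeline],
    split: CohortSplit,
    config: TemporalModelConfig,
    step_codes: Sequence[int] | None = None,
    instrument_codes: Sequence[int] | None = None,
) -> TemporalRSDModel:
    """Train on the split's train videos, selecting the checkpoint with the
    best validation full-duration RSD MAE (last epoch if no validation split).

    Deterministic given ``config.seed``.
    """
    cfg = config
    for vid in split.train + split.val:
        if vid not in tracks or vid not in timelines:
            raise ValueError(f"video {vid} missing from tracks or timelines")
        if tracks[vid].T != timelines[vid].T:
            raise ValueError(
                f"video {vid}: track length {tracks[vid].T} != timeline T {timelines[vid].T}"
            )
    if step_codes is None:
        step_codes = sorted({iv.step_label for tl in timelines.values() for iv in tl.intervals})
    step_index = {c: i for i, c in enumerate(step_codes)}
    instr_index = None
    if cfg.use_instrument_head:
        if instrument_codes is None:
            instrument_codes = sorted(
                {
                    iv.step_label
                    for tl in timelines.values()
                    if tl.instrument_intervals is not None
                    for iv in tl.instrument_intervals
                }
            )
        if len(instrument_codes) != cfg.n_instruments:
            raise ValueError(
                f"{len(instrument_codes)} instrument codes but n_instruments={cfg.n_instruments}"
            )
        instr_index = {c: i for i, c in enumerate(instrument_codes)}

    model = TemporalRSDModel(cfg, step_codes, instrument_codes)
    train_steps = np.concatenate(
        [
            [step_index[s] for s in timelines[vid].step_labels_per_sec()]
            for vid in split.train
        ]
    ).astype(int)
    model.step_class_weights = class_weights(train_steps, cfg.n_steps)
    if instr_index is not None:
        train_instr = np.concatenate(
            [
                [instr_index[s] for s in timelines[vid].instrument_labels_per_sec()]
                for vid in split.train
            ]
        ).astype(int)
        model.instr_class_weights = class_weights(train_instr, cfg.n_instruments)

    targets = {
        vid: _targets_for(timelines[vid], step_index, instr_index, cfg)
        for vid in split.train
    }
    bases = {vid: model._base_inputs(tracks[vid]) for vid in split.train}

    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam()
    best_val = np.inf
    best_snap = model._snapshot()
    order = list(split.train)
    for epoch in range(cfg.epochs):
        opt.lr = _epoch_lr(cfg.lr_schedule, epoch)
        rng.shuffle(order)
        sums = {"total": 0.0, "step": 0.0, "instr": 0.0, "rsd": 0.0}
        n_chunks = 0
        for vid in order:
            base = bases[vid]
            step_t, instr_t, rsd_t = targets[vid]
            states = (model.l1.init_state(), model.l2.init_state())
            context = ContextState(cfg.n_steps, cfg.context_window)
            for lo in range(0, len(base), cfg.tbptt_window):
                hi = min(lo + cfg.tbptt_window, len(base))
                sl = slice(lo, hi)
                it = instr_t[sl] if instr_t is not None else None
                if cfg.use_prior_context:
                    parts, states = _train_chunk_stepwise(
                        model, base[sl], step_t[sl], it, rsd_t[sl], states, context, opt
                    )
                else:
                    parts, states = _train_chunk_batch(
                        model, base[sl], step_t[sl], it, rsd_t[sl], states, opt
                    )
                for k in sums:
                    sums[k] += parts[k]
                n_chunks += 1
        val_mae = None
        if split.val:
            maes = []
            for vid in split.val:
                series, _ = predict_online(model, tracks[vid])
                gt = (timelines[vid].T - np.arange(timelines[vid].T)) / 60.0
                maes.append(float(np.abs(np.asarray(series.rsd_pred_min) - gt).mean()))
            val_mae = float(np.mean(maes))
            if val_mae < best_val:
                best_val = val_mae
                best_snap = model._snapshot()
        cls_loss = sums["step"] + sums["instr"]
        entry = {
            "epoch": epoch,
            "lr": opt.lr,
            "train_loss": sums["total"] / max(n_chunks, 1),
            "loss_step": sums["step"] / max(n_chunks, 1),
            "loss_instr": sums["instr"] / max(n_chunks, 1),
            "loss_rsd": sums["rsd"] / max(n_chunks, 1),
            # realised classification:regression loss ratio (diagnostic)
            "cls_to_rsd_ratio": (cls_loss / sums["rsd"]) if sums["rsd"] > 0 else None,
            "val_mae": val_mae,
        }
        model.training_log.append(entry)
    if split.val:
        model._restore(best_snap)
    return model
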