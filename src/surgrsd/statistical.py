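"""Annotation-driven statistical RSD estimators.

Three estimators of remaining surgery duration (RSD) that use only workflow
annotations and historical duration statistics:

``Naive``
    A single reference full duration ``T_ref`` (the mean total duration of the
    training split); predicts ``max(0, T_ref - t_el)``.

``Step-inferred``
    Per-step reference durations from the training split; predicts the
    remaining time in the current step plus the reference durations of all
    later steps in a canonical order.  Assumes a sequential mandatory
    workflow — an assumption pituitary surgery violates (optional and
    repeatable steps), which is precisely why it underperforms here.

``Sequence matching``
    The elapsed step sequence of the ongoing surgery is compared, by
    Levenshtein distance on run-length-compressed sequences, with each
    historical surgery's elapsed sequence truncated at the same timestamp;
    ``T_ref`` is the mean full duration of the k nearest neighbours (k=3 by
    default).  When instrument annotations exist, the distance is the
    unweighted sum of step-sequence and instrument-sequence distances.

All public predictions are in minutes; internal time bookkeeping is in
seconds so that second-level predictions are exact where the mathematics is
exact (e.g. a k=1 match to an identical historical surgery reproduces the
ground truth bit-for-bit).
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .workflow import (
    RSDSeries,
    WorkflowTimeline,
    elapsed_step_sequence,
    run_length_compress,
)

__all__ = [
    "FitError",
    "PredictionError",
    "NaiveModel",
    "StepInferredModel",
    "SequenceMatchModel",
    "fit_naive",
    "predict_naive",
    "predict_naive_series",
    "fit_step_inferred",
    "predict_step_inferred",
    "predict_step_inferred_series",
    "levenshtein",
    "fit_sequence_match",
    "predict_sequence_match",
    "predict_sequence_match_series",
]


class FitError(ValueError):
    """Raised when an estimator cannot be fitted (e.g. empty training split)."""


class PredictionError(ValueError):
    """Raised when a prediction is requested outside the model's domain."""


# ---------------------------------------------------------------------------
# Naive


@dataclass(frozen=True)
class NaiveModel:
    """Reference full duration, stored in seconds for exact second arithmetic."""

    T_ref_sec: float

    @property
    def T_ref_min(self) -> float:
        return self.T_ref_sec / 60.0


def fit_naive(train: Sequence[WorkflowTimeline]) -> NaiveModel:
    """T_ref = arithmetic mean of training total durations."""
    if len(train) == 0:
        raise FitError("naive estimator requires at least one training timeline")
    return NaiveModel(T_ref_sec=float(np.mean([tl.T for tl in train])))


def predict_naive(model: NaiveModel, tel_min: float) -> float:
    """RSD in minutes at elapsed time ``tel_min`` minutes: max(0, T_ref - t_el)."""
    if tel_min < 0:
        raise PredictionError("elapsed time must be >= 0")
    return max(0.0, model.T_ref_min - tel_min)


def predict_naive_series(model: NaiveModel, timeline: WorkflowTimeline) -> RSDSeries:
    preds = [max(0.0, model.T_ref_sec - t) / 60.0 for t in range(timeline.T)]
    return RSDSeries(video_id=timeline.video_id, rsd_pred_min=preds)


# ---------------------------------------------------------------------------
# Step-inferred


@dataclass(frozen=True)
class StepInferredModel:
    """Canonical step order plus per-step reference durations (seconds).

    ``canonical_order`` ranks steps by mean normalised first-occurrence time
    across the training split; ``t_ref_sec`` is the mean total time spent in
    each step across the training videos that contain it.
    """

    canonical_order: tuple[int, ...]
    t_ref_sec: Mapping[int, float]

    @property
    def t_ref_min(self) -> dict[int, float]:
        return {s: v / 60.0 for s, v in self.t_ref_sec.items()}


def fit_step_inferred(train: Sequence[WorkflowTimeline]) -> StepInferredModel:
    if len(train) == 0:
        raise FitError("step-inferred estimator requires at least one training timeline")
    totals: dict[int, list[float]] = {}
    first_norm: dict[int, list[float]] = {}
    for tl in train:
        per_step_total: dict[int, int] = {}
        per_step_first: dict[int, int] = {}
        for iv in tl.intervals:
            per_step_total[iv.step_label] = (
                per_step_total.get(iv.step_label, 0) + iv.duration_sec
            )
            per_step_first.setdefault(iv.step_label, iv.start_sec)
        for s, tot in per_step_total.items():
            totals.setdefault(s, []).append(float(tot))
            first_norm.setdefault(s, []).append(per_step_first[s] / tl.T)
    order = tuple(
        sorted(totals, key=lambda s: (float(np.mean(first_norm[s])), s))
    )
    t_ref = {s: float(np.mean(v)) for s, v in totals.items()}
    return StepInferredModel(canonical_order=order, t_ref_sec=t_ref)


def predict_step_inferred(
    model: StepInferredModel, current_step: int, tel_step_min: float
) -> float:
    """RSD (minutes): remaining time in the current step + later steps' references."""
    if tel_step_min < 0:
        raise PredictionError("elapsed time in step must be >= 0")
    if current_step not in model.canonical_order:
        raise PredictionError(f"step {current_step} absent from the canonical order")
    return _step_inferred_sec(model, current_step, tel_step_min * 60.0) / 60.0


def _step_inferred_sec(
    model: StepInferredModel, current_step: int, tel_step_sec: float
) -> float:
    pos = model.canonical_order.index(current_step)
    rem_current = max(0.0, model.t_ref_sec[current_step] - tel_step_sec)
    rem_later = sum(
        model.t_ref_sec[s] for s in model.canonical_order[pos + 1 :]
    )
    return rem_current + rem_later


def _remaining_after_pos_sec(model: StepInferredModel, pos: int) -> float:
    return sum(model.t_ref_sec[s] for s in model.canonical_order[pos + 1 :])


def predict_step_inferred_series(
    model: StepInferredModel, timeline: WorkflowTimeline
) -> RSDSeries:
    """Per-second predictions over [0, T).

    The elapsed time in the current step is the cumulative time spent in that
    step so far (all occurrences).  A step unseen in training falls back to
    the sum of references after the last known canonical position.
    """
    preds: list[float] = []
    spent: dict[int, int] = {}
    last_known_pos = -1
    for iv in timeline.intervals:
        s = iv.step_label
        known = s in model.canonical_order
        if known:
            last_known_pos = model.canonical_order.index(s)
        for t in range(iv.start_sec, iv.end_sec):
            tel_step = spent.get(s, 0) + (t - iv.start_sec)
            if known:
                rsd_sec = _step_inferred_sec(model, s, float(tel_step))
            else:
                rsd_sec = _remaining_after_pos_sec(model, last_known_pos)
            preds.append(rsd_sec / 60.0)
        spent[s] = spent.get(s, 0) + iv.duration_sec
    return RSDSeries(video_id=timeline.video_id, rsd_pred_min=preds)


# ---------------------------------------------------------------------------
# Levenshtein distance


def levenshtein(a: Sequence, b: Sequence) -> int:
    """Edit distance: minimum single-symbol insertions/deletions/substitutions.

    Iterative two-row dynamic programme; symmetric; 0 iff the sequences are
    equal.
    """
    if len(a) < len(b):
        a, b = b, a
    if len(b) == 0:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, x in enumerate(a, start=1):
        cur = [i] + [0] * len(b)
        for j, y in enumerate(b, start=1):
            cur[j] = min(
                prev[j] + 1,  # deletion
                cur[j - 1] + 1,  # insertion
                prev[j - 1] + (x != y),  # substitution / match
            )
        prev = cur
    return prev[-1]


# ---------------------------------------------------------------------------
# Sequence matching


@dataclass(frozen=True)
class _History:
    video_id: str
    T_sec: int
    # compressed step sequence and, per element, the earliest second at which
    # it enters the elapsed sequence (interval start + 1)
    step_seq: tuple[int, ...]
    step_entry_sec: tuple[int, ...]
    instr_seq: tuple[int, ...] | None = None
    instr_entry_sec: tuple[int, ...] | None = None


@dataclass(frozen=True)
class SequenceMatchModel:
    """k-NN over historical surgeries by elapsed-sequence Levenshtein distance."""

    histories: tuple[_History, ...]
    k: int
    use_instruments: bool = False
    _median_T_sec: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.k > len(self.histories):
            raise ValueError(
                f"k={self.k} exceeds the {len(self.histories)} historical videos"
            )


def _compress_with_entries(
    timeline: WorkflowTimeline, stream: str
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    intervals = (
        timeline.intervals if stream == "step" else timeline.instrument_intervals
    )
    labels: list[int] = []
    entries: list[int] = []
    for iv in intervals:
        if not labels or labels[-1] != iv.step_label:
            labels.append(iv.step_label)
            # the interval joins the elapsed sequence once tel >= start_sec
            entries.append(iv.start_sec)
    return tuple(labels), tuple(entries)


def fit_sequence_match(
    train: Sequence[WorkflowTimeline], k: int = 3, use_instruments: bool = False
) -> SequenceMatchModel:
    if len(train) == 0:
        raise FitError("sequence matching requires at least one training timeline")
    histories = []
    for tl in train:
        step_seq, step_entry = _compress_with_entries(tl, "step")
        instr_seq = instr_entry = None
        if use_instruments:
            if tl.instrument_intervals is None:
                raise FitError(
                    f"{tl.video_id}: instrument matching requested but the "
                    "timeline has no instrument annotations"
                )
            instr_seq, instr_entry = _compress_with_entries(tl, "instrument")
        histories.append(
            _History(tl.video_id, tl.T, step_seq, step_entry, instr_seq, instr_entry)
        )
    return SequenceMatchModel(
        histories=tuple(histories),
        k=k,
        use_instruments=use_instruments,
        _median_T_sec=float(np.median([h.T_sec for h in histories])),
    )


def _truncate(seq: tuple[int, ...], entries: tuple[int, ...], tel_sec: float) -> tuple[int, ...]:
    """Prefix of the compressed sequence whose elements entered before tel."""
    n = bisect_right(entries, tel_sec)
    return seq[:n]


def _neighbour_T_ref_sec(
    model: SequenceMatchModel, distances: Sequence[float]
) -> float:
    """Mean full duration of the k nearest histories.

    Ties at the distance boundary break by closeness of the history's full
    duration to the training median, then by history index; the selected
    indices are restored to history order before the mean so that k = |history|
    reproduces the naive estimator's mean bit-for-bit.
    """
    order = sorted(
        range(len(model.histories)),
        key=lambda i: (
            distances[i],
            abs(model.histories[i].T_sec - model._median_T_sec),
            i,
        ),
    )
    chosen = sorted(order[: model.k])
    return float(np.mean([float(model.histories[i].T_sec) for i in chosen]))


def predict_sequence_match(
    model: SequenceMatchModel,
    query_steps: Sequence[int],
    tel_min: float,
    query_instruments: Sequence[int] | None = None,
) -> float:
    """RSD (minutes) for a query compressed elapsed step sequence at ``tel_min``.

    Each history contributes its compressed elapsed sequence truncated at the
    same elapsed time (its full sequence if it has already finished).
    """
    if tel_min < 0:
        raise PredictionError("elapsed time must be >= 0")
    if model.use_instruments and query_instruments is None:
        raise PredictionError("model was fitted with instruments; query lacks them")
    tel_sec = tel_min * 60.0
    q_steps = tuple(run_length_compress(query_steps))
    q_instr = (
        tuple(run_length_compress(query_instruments))
        if query_instruments is not None
        else None
    )
    distances = []
    for h in model.histories:
        d = levenshtein(q_steps, _truncate(h.step_seq, h.step_entry_sec, tel_sec))
        if model.use_instruments:
            d += levenshtein(
                q_instr, _truncate(h.instr_seq, h.instr_entry_sec, tel_sec)
            )
        distances.append(float(d))
    T_ref_sec = _neighbour_T_ref_sec(model, distances)
    return max(0.0, T_ref_sec - tel_sec) / 60.0


def predict_sequence_match_series(
    model: SequenceMatchModel, timeline: WorkflowTimeline
) -> RSDSeries:
    """Per-second predictions over [0, T), causally.

    Distances only change when a new element enters either the query's or a
    history's compressed elapsed sequence, so each pairwise distance is
    recomputed only at those event times and held constant in between.
    """
    if model.use_instruments and timeline.instrument_intervals is None:
        raise PredictionError(
            f"{timeline.video_id}: instrument matching requested but the "
            "timeline has no instrument annotations"
        )
    T = timeline.T
    q_steps, q_step_entry = _compress_with_entries(timeline, "step")
    q_instr = q_instr_entry = None
    if model.use_instruments:
        q_instr, q_instr_entry = _compress_with_entries(timeline, "instrument")

    q_events = {e for e in q_step_entry if e < T}
    if model.use_instruments:
        q_events.update(e for e in q_instr_entry if e < T)

    # per-history event seconds: its distance can only change when an element
    # enters its own or the query's compressed sequence
    hist_events: list[set[int]] = []
    all_events: set[int] = {0} | q_events
    for h in model.histories:
        ev = {e for e in h.step_entry_sec if e < T}
        if model.use_instruments:
            ev.update(e for e in h.instr_entry_sec if e < T)
        ev |= q_events
        ev.add(0)
        hist_events.append(ev)
        all_events |= ev
    event_list = sorted(all_events)

    distances = [0.0] * len(model.histories)
    preds = [0.0] * T
    for idx, t0 in enumerate(event_list):
        for i, h in enumerate(model.histories):
            if t0 in hist_events[i]:
                d = levenshtein(
                    _truncate(q_steps, q_step_entry, t0),
                    _truncate(h.step_seq, h.step_entry_sec, t0),
                )
                if model.use_instruments:
                    d += levenshtein(
                        _truncate(q_instr, q_instr_entry, t0),
                        _truncate(h.instr_seq, h.instr_entry_sec, t0),
                    )
                distances[i] = float(d)
        T_ref_sec = _neighbour_T_ref_sec(model, distances)
        t1 = event_list[idx + 1] if idx + 1 < len(event_list) else T
        for t in range(t0, t1):
            preds[t] = max(0.0, T_ref_sec - t) / 60.0
    return RSDSeries(video_id=timeline.video_id, rsd_pred_min=preds)
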