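"""Canonical data model and I/O for per-second surgical workflow annotations.

A surgery is represented as a :class:`WorkflowTimeline`: an ordered list of
step intervals that tile ``[0, T)`` at one-second resolution (annotations are
sampled at 1 frame per second).  From a timeline the ground-truth remaining
surgery duration (RSD) at any elapsed time, the elapsed step sequence, and its
run-length compression are derived.

Conventions
-----------
* Time is discretised at 1 Hz integer seconds; every interval is half-open
  ``[start_sec, end_sec)``.
* RSD is reported in **minutes**; all internal bookkeeping is in seconds.
* Annotation files are CSV with header ``sec,step`` (optionally
  ``,instrument``), one row per second, 0-based seconds.  A cohort is a
  directory of such files plus a JSON split manifest
  ``{"train": [...], "val": [...], "test": [...]}``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "StepInterval",
    "WorkflowTimeline",
    "CohortSplit",
    "RSDSeries",
    "StepVocabulary",
    "MalformedAnnotationError",
    "VocabularyError",
    "read_timeline",
    "write_timeline",
    "read_split",
    "write_split",
    "read_cohort",
    "ground_truth_rsd",
    "ground_truth_progress",
    "elapsed_step_sequence",
    "run_length_compress",
    "intervals_from_labels",
    "labels_from_intervals",
]


class MalformedAnnotationError(ValueError):
    """Raised when a per-second annotation stream has a gap, overlap, or is empty."""


class VocabularyError(ValueError):
    """Raised when an annotation label is outside the declared step vocabulary."""


@dataclass(frozen=True)
class StepInterval:
    """One maximal run of a single step: label over ``[start_sec, end_sec)``."""

    step_label: int
    start_sec: int
    end_sec: int

    def __post_init__(self) -> None:
        if self.end_sec <= self.start_sec:
            raise ValueError(
                f"interval end {self.end_sec} must exceed start {self.start_sec}"
            )
        if self.start_sec < 0:
            raise ValueError(f"negative start_sec {self.start_sec}")

    @property
    def duration_sec(self) -> int:
        return self.end_sec - self.start_sec


@dataclass(frozen=True)
class StepVocabulary:
    """Declared step labels: integer codes with names and a core/optional flag."""

    entries: tuple[tuple[int, str, bool], ...]  # (code, name, core)

    @property
    def codes(self) -> frozenset[int]:
        return frozenset(code for code, _, _ in self.entries)

    @property
    def core_codes(self) -> tuple[int, ...]:
        return tuple(code for code, _, core in self.entries if core)

    @property
    def optional_codes(self) -> tuple[int, ...]:
        return tuple(code for code, _, core in self.entries if not core)

    def name_of(self, code: int) -> str:
        for c, name, _ in self.entries:
            if c == code:
                return name
        raise VocabularyError(f"unknown step code {code}")

    @classmethod
    def from_json(cls, path: str | Path) -> "StepVocabulary":
        raw = json.loads(Path(path).read_text())
        return cls(tuple((e["code"], e["name"], bool(e["core"])) for e in raw))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                [
                    {"code": c, "name": n, "core": core}
                    for c, n, core in self.entries
                ],
                indent=1,
            )
        )


@dataclass
class WorkflowTimeline:
    """One surgery: contiguous, non-overlapping step intervals covering [0, T).

    The same step label may recur in non-adjacent intervals (haemostasis-like
    repeatable steps).  ``instrument_intervals`` optionally carries a parallel
    annotation stream over an instrument vocabulary with the same tiling.
    """

    video_id: str
    intervals: tuple[StepInterval, ...]
    instrument_intervals: tuple[StepInterval, ...] | None = None

    def __post_init__(self) -> None:
        self.intervals = tuple(self.intervals)
        if not self.intervals:
            raise MalformedAnnotationError(f"{self.video_id}: empty annotation")
        _check_tiling(self.intervals, self.video_id)
        if self.instrument_intervals is not None:
            self.instrument_intervals = tuple(self.instrument_intervals)
            _check_tiling(self.instrument_intervals, self.video_id)
            if self.instrument_intervals[-1].end_sec != self.T:
                raise MalformedAnnotationError(
                    f"{self.video_id}: instrument stream length "
                    f"{self.instrument_intervals[-1].end_sec} != T={self.T}"
                )

    @property
    def T(self) -> int:
        """Total duration in seconds."""
        return self.intervals[-1].end_sec

    @property
    def T_minutes(self) -> float:
        return self.T / 60.0

    def step_at(self, t: int) -> int:
        """Step label active at second ``t`` (0 <= t < T)."""
        if not 0 <= t < self.T:
            raise ValueError(f"t={t} outside [0, {self.T})")
        for iv in self.intervals:
            if iv.start_sec <= t < iv.end_sec:
                return iv.step_label
        raise AssertionError("unreachable: intervals tile [0, T)")

    def step_labels_per_sec(self) -> list[int]:
        return labels_from_intervals(self.intervals)

    def instrument_labels_per_sec(self) -> list[int]:
        if self.instrument_intervals is None:
            raise ValueError(f"{self.video_id}: no instrument annotations")
        return labels_from_intervals(self.instrument_intervals)


def _check_tiling(intervals: Sequence[StepInterval], video_id: str) -> None:
    if intervals[0].start_sec != 0:
        raise MalformedAnnotationError(
            f"{video_id}: gap at second 0 (first interval starts at "
            f"{intervals[0].start_sec})"
        )
    for prev, cur in zip(intervals, intervals[1:]):
        if cur.start_sec != prev.end_sec:
            kind = "gap" if cur.start_sec > prev.end_sec else "overlap"
            raise MalformedAnnotationError(
                f"{video_id}: {kind} at second {min(prev.end_sec, cur.start_sec)}"
            )


@dataclass(frozen=True)
class CohortSplit:
    """Train/val/test video-id lists; pairwise disjoint."""

    train: tuple[str, ...]
    val: tuple[str, ...]
    test: tuple[str, ...]

    def __post_init__(self) -> None:
        tr, va, te = set(self.train), set(self.val), set(self.test)
        if tr & va or tr & te or va & te:
            raise ValueError("split lists must be pairwise disjoint")

    @property
    def all_ids(self) -> tuple[str, ...]:
        return self.train + self.val + self.test


@dataclass
class RSDSeries:
    """Per-second RSD predictions (minutes) for one video: one value per second in [0, T)."""

    video_id: str
    rsd_pred_min: "list[float]"

    def __len__(self) -> int:
        return len(self.rsd_pred_min)


# ---------------------------------------------------------------------------
# Label <-> interval conversions


def intervals_from_labels(labels: Sequence[int]) -> tuple[StepInterval, ...]:
    """Merge a per-second label stream into maximal constant-label intervals."""
    if len(labels) == 0:
        raise MalformedAnnotationError("empty annotation")
    out: list[StepInterval] = []
    start = 0
    for t in range(1, len(labels) + 1):
        if t == len(labels) or labels[t] != labels[start]:
            out.append(StepInterval(int(labels[start]), start, t))
            start = t
    return tuple(out)


def labels_from_intervals(intervals: Sequence[StepInterval]) -> list[int]:
    out: list[int] = []
    for iv in intervals:
        out.extend([iv.step_label] * iv.duration_sec)
    return out


# ---------------------------------------------------------------------------
# I/O


def read_timeline(
    path: str | Path,
    step_vocabulary: Iterable[int] | StepVocabulary | None = None,
    instrument_vocabulary: Iterable[int] | None = None,
    merge_label_into_previous: int | None = None,
) -> WorkflowTimeline:
    """Read a per-second ``sec,step[,instrument]`` CSV into a timeline.

    Adjacent identical labels are merged into intervals.  Seconds must be
    0-based, contiguous and duplicate-free; the first violation is reported.

    ``merge_label_into_previous`` relabels every second carrying that label
    (e.g. an "out of patient" marker) with the preceding step's label, the
    convention used when de-identified frames are treated as part of the
    previous step.  Leading occurrences are merged forward instead.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise MalformedAnnotationError(f"{path.name}: empty annotation")
    if "sec" not in df.columns or "step" not in df.columns:
        raise MalformedAnnotationError(f"{path.name}: expected columns sec,step")
    secs = df["sec"].to_numpy()
    for i, s in enumerate(secs):
        if s != i:
            kind = "gap" if s > i else "overlap"
            raise MalformedAnnotationError(f"{path.name}: {kind} at second {i}")
    steps = [int(x) for x in df["step"].to_list()]
    if merge_label_into_previous is not None:
        steps = _merge_into_previous(steps, merge_label_into_previous)
    if step_vocabulary is not None:
        codes = (
            step_vocabulary.codes
            if isinstance(step_vocabulary, StepVocabulary)
            else set(step_vocabulary)
        )
        bad = [s for s in steps if s not in codes]
        if bad:
            raise VocabularyError(f"{path.name}: unknown step label {bad[0]}")
    instr_ivs = None
    if "instrument" in df.columns:
        instr = [int(x) for x in df["instrument"].to_list()]
        if instrument_vocabulary is not None:
            icodes = set(instrument_vocabulary)
            bad = [s for s in instr if s not in icodes]
            if bad:
                raise VocabularyError(f"{path.name}: unknown instrument label {bad[0]}")
        instr_ivs = intervals_from_labels(instr)
    return WorkflowTimeline(
        video_id=path.stem,
        intervals=intervals_from_labels(steps),
        instrument_intervals=instr_ivs,
    )


def _merge_into_previous(steps: list[int], label: int) -> list[int]:
    out = list(steps)
    # leading run: merge forward into the first real step
    first_real = next((i for i, s in enumerate(out) if s != label), None)
    if first_real is None:
        raise MalformedAnnotationError("annotation contains only the merged label")
    for i in range(first_real):
        out[i] = out[first_real]
    for i in range(first_real + 1, len(out)):
        if out[i] == label:
            out[i] = out[i - 1]
    return out


def write_timeline(timeline: WorkflowTimeline, path: str | Path) -> None:
    """Write a timeline back to the per-second CSV format (inverse of read)."""
    data: dict[str, list[int]] = {
        "sec": list(range(timeline.T)),
        "step": timeline.step_labels_per_sec(),
    }
    if timeline.instrument_intervals is not None:
        data["instrument"] = timeline.instrument_labels_per_sec()
    pd.DataFrame(data).to_csv(path, index=False)


def read_split(path: str | Path) -> CohortSplit:
    raw = json.loads(Path(path).read_text())
    return CohortSplit(
        train=tuple(raw["train"]), val=tuple(raw["val"]), test=tuple(raw["test"])
    )


def write_split(split: CohortSplit, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {"train": list(split.train), "val": list(split.val), "test": list(split.test)},
            indent=1,
        )
    )


def read_cohort(
    cohort_dir: str | Path,
    split_path: str | Path | None = None,
    **read_kwargs,
) -> tuple[Mapping[str, WorkflowTimeline], CohortSplit | None]:
    """Read every annotation CSV in a directory (and the split manifest if present)."""
    cohort_dir = Path(cohort_dir)
    timelines = {
        p.stem: read_timeline(p, **read_kwargs)
        for p in sorted(cohort_dir.glob("*.csv"))
    }
    split = None
    if split_path is None:
        candidate = cohort_dir / "split.json"
        split_path = candidate if candidate.exists() else None
    if split_path is not None:
        split = read_split(split_path)
    return timelines, split


# ---------------------------------------------------------------------------
# Ground truth and sequence extraction


def ground_truth_rsd(timeline: WorkflowTimeline, t: float) -> float:
    """Remaining surgery duration at elapsed time ``t`` seconds, in minutes.

    RSD is total duration minus elapsed time: at ``t`` seconds into a surgery
    of ``T`` seconds the remaining time is ``(T - t) / 60`` minutes.
    """
    if not 0 <= t <= timeline.T:
        raise ValueError(f"t={t} outside [0, {timeline.T}]")
    return (timeline.T - t) / 60.0


def ground_truth_progress(timeline: WorkflowTimeline, t: float) -> float:
    """Progress p = elapsed / total, in [0, 1]."""
    if not 0 <= t <= timeline.T:
        raise ValueError(f"t={t} outside [0, {timeline.T}]")
    return t / timeline.T


def elapsed_step_sequence(
    timeline: WorkflowTimeline, t: float, stream: str = "step"
) -> list[int]:
    """Labels of all intervals that have started by time ``t``, in order.

    The interval containing ``t`` is included (truncated), so at an interval
    boundary the newly started step already appears.  Repeated steps are
    preserved as separate entries.  ``stream`` selects the step or instrument
    annotation stream.
    """
    if t <= 0:
        raise ValueError(f"t={t} must be positive")
    if stream == "step":
        intervals = timeline.intervals
    elif stream == "instrument":
        if timeline.instrument_intervals is None:
            raise ValueError(f"{timeline.video_id}: no instrument annotations")
        intervals = timeline.instrument_intervals
    else:
        raise ValueError(f"unknown stream {stream!r}")
    return [iv.step_label for iv in intervals if iv.start_sec <= t]


def run_length_compress(seq: Sequence[int]) -> list[int]:
    """Collapse maximal runs of identical labels to a single occurrence.

    Used before Levenshtein comparison to reduce computational cost; on a
    per-second label stream this yields exactly the per-interval step sequence.
    Idempotent.
    """
    out: list[int] = []
    for x in seq:
        if not out or out[-1] != x:
            out.append(x)
    return out
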