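"""Evaluation harness: windowed per-video MAE, Wilcoxon comparisons, macro-F1.

RSD accuracy is reported as mean absolute error in minutes, computed
*per video* and then mean-averaged over videos so that long surgeries do not
dominate.  Clinically the most relevant windows are the last 20 and last 10
minutes of the surgery (anaesthetic wash-out planning), so MAE is reported
for the full duration and those two terminal windows.

Method comparisons use the paired Wilcoxon signed-rank test on per-video MAE
values.  Step-recognition quality uses the macro-averaged F1 score, which
weights all steps equally regardless of class imbalance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _scipy_stats
from sklearn.metrics import f1_score as _sk_f1_score

from .workflow import RSDSeries, WorkflowTimeline

__all__ = [
    "WINDOWS",
    "EvalReport",
    "mean_absolute_error",
    "per_video_mae",
    "cohort_mae",
    "wilcoxon_paired",
    "macro_f1",
    "evaluate_predictions",
    "compare_methods",
]

WINDOWS = ("full", "last20", "last10")


def mean_absolute_error(pred: Sequence[float], truth: Sequence[float]) -> float:
    """Plain MAE between two aligned value sequences (minutes)."""
    p = np.asarray(pred, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape or p.size == 0:
        raise ValueError("prediction and truth must be equal-length and non-empty")
    return float(np.abs(p - t).mean())


def per_video_mae(
    pred: RSDSeries, timeline: WorkflowTimeline, window: str = "full"
) -> float:
    """Mean |prediction - ground truth| in minutes over the chosen window.

    ``lastK`` windows cover the seconds in [max(0, T - 60K), T); a video
    shorter than the window contributes its full duration.
    """
    if window not in WINDOWS:
        raise ValueError(f"window must be one of {WINDOWS}")
    if len(pred) != timeline.T:
        raise ValueError(
            f"{pred.video_id}: prediction covers {len(pred)} s but T={timeline.T} s"
        )
    T = timeline.T
    start = 0
    if window == "last20":
        start = max(0, T - 20 * 60)
    elif window == "last10":
        start = max(0, T - 10 * 60)
    t = np.arange(start, T)
    gt = (T - t) / 60.0
    return mean_absolute_error(pred.rsd_pred_min[start:], gt)


def cohort_mae(per_video: Sequence[float]) -> tuple[float, float]:
    """Unweighted mean and sample sd over videos (videos weigh equally)."""
    arr = np.asarray(per_video, dtype=float)
    if arr.size == 0:
        raise ValueError("cohort MAE requires at least one video")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


# ---------------------------------------------------------------------------
# Paired Wilcoxon signed-rank test
#
# Exact distribution for n < 26 even in the presence of tied |differences|
# (midranks doubled to keep the rank-sum distribution on integers); normal
# approximation with continuity correction beyond.  Zero differences are
# dropped before ranking (wilcox convention).


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p under the null that each signed rank is +/- with
    probability 1/2: P(|W+ - M| >= |w_obs - M|), M the null mean."""
    r2 = np.rint(2.0 * ranks).astype(int)  # doubled midranks are integers
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = 2.0 * w_plus
    dev = abs(w2 - total / 2.0)
    support = np.arange(total + 1)
    p = counts[np.abs(support - total / 2.0) >= dev - 1e-9].sum()
    return float(min(p, 1.0))


def wilcoxon_paired(
    mae_a: Sequence[float], mae_b: Sequence[float]
) -> tuple[float, bool]:
    """Two-sided paired Wilcoxon signed-rank p-value on per-video values.

    Returns ``(p, degenerate)``; all-zero differences give (1.0, True).
    """
    a = np.asarray(mae_a, dtype=float)
    b = np.asarray(mae_b, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("inputs must be equal-length, non-empty, paired by video")
    d = a - b
    d = d[d != 0.0]
    if d.size == 0:
        return 1.0, True
    ranks = _scipy_stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    n = d.size
    if n < 26:
        return _exact_signed_rank_p(ranks, w_plus), False
    mean = n * (n + 1) / 4.0
    # tie-corrected variance of W+
    tie_term = float((ranks**3 - ranks).sum()) / 48.0  # conservative with midranks
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
    return float(2.0 * _scipy_stats.norm.sf(abs(z))), False


def macro_f1(
    pred_labels: Sequence[int], true_labels: Sequence[int]
) -> float:
    """Unweighted mean of per-class F1 over the classes present in the truth."""
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ValueError("prediction and truth must have equal length")
    present = np.unique(true)
    return float(
        _sk_f1_score(true, pred, labels=present, average="macro", zero_division=0.0)
    )


# ---------------------------------------------------------------------------
# Report assembly


@dataclass
class EvalReport:
    """Per-video and cohort MAE per window, optional macro-F1, comparisons."""

    per_video_mae: dict[str, dict[str, float]] = field(default_factory=dict)
    cohort_mae: dict[str, tuple[float, float]] = field(default_factory=dict)
    macro_f1: float | None = None
    comparisons: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_video_mae": self.per_video_mae,
            "cohort_mae": {
                w: {"mean": m, "sd": s} for w, (m, s) in self.cohort_mae.items()
            },
            "macro_f1": self.macro_f1,
            "comparisons": self.comparisons,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def evaluate_predictions(
    predictions: Mapping[str, RSDSeries],
    timelines: Mapping[str, WorkflowTimeline],
    step_predictions: Mapping[str, Sequence[int]] | None = None,
) -> EvalReport:
    """Windowed per-video and cohort MAE (and macro-F1 if step labels given)."""
    report = EvalReport()
    for vid, pred in predictions.items():
        tl = timelines[vid]
        report.per_video_mae[vid] = {
            w: per_video_mae(pred, tl, w) for w in WINDOWS
        }
    for w in WINDOWS:
        report.cohort_mae[w] = cohort_mae(
            [report.per_video_mae[vid][w] for vid in predictions]
        )
    if step_predictions is not None:
        all_pred: list[int] = []
        all_true: list[int] = []
        for vid, labels in step_predictions.items():
            all_pred.extend(int(x) for x in labels)
            all_true.extend(timelines[vid].step_labels_per_sec())
        report.macro_f1 = macro_f1(all_pred, all_true)
    return report


def compare_methods(
    per_video_by_method: Mapping[str, Mapping[str, float]], window: str = "last20"
) -> list[dict]:
    """Pairwise Wilcoxon comparisons of per-video MAE between methods.

    ``per_video_by_method`` maps method name -> {video_id -> MAE}; all
    methods must cover the same videos (pairing is per video).
    """
    methods = list(per_video_by_method)
    if not methods:
        return []
    vids = sorted(per_video_by_method[methods[0]])
    out = []
    for i, ma in enumerate(methods):
        for mb in methods[i + 1 :]:
            a = [per_video_by_method[ma][v] for v in vids]
            b = [per_video_by_method[mb][v] for v in vids]
            p, degenerate = wilcoxon_paired(a, b)
            out.append(
                {
                    "method_a": ma,
                    "method_b": mb,
                    "window": window,
                    "wilcoxon_p": p,
                    "degenerate": degenerate,
                }
            )
    return out
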