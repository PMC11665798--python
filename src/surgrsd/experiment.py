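"""End-to-end experiment orchestration: simulate -> fit/train -> predict -> evaluate.

One experiment runs many RSD methods on one cohort, so every method predicts
the same test videos and paired statistical comparisons come for free.  All
outputs embed the run's seed and a hash of its configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import statistical as st
from . import temporal as tm
from .evaluation import WINDOWS, EvalReport, compare_methods, evaluate_predictions
from .simulate import (
    SimulatorConfig,
    default_config,
    default_vocabulary,
    make_embedding_config,
    read_features,
    sample_cohort,
    sample_frame_embeddings,
    scaled_config,
    write_cohort,
    write_features,
)
from .workflow import CohortSplit, RSDSeries, WorkflowTimeline, read_cohort

__all__ = [
    "RunConfig",
    "StageError",
    "run_experiment",
    "fit_predict_statistical",
    "predictions_to_csv",
    "read_predictions_csv",
]


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """One cohort + many methods.

    ``methods`` entries are dicts with at least ``name`` and ``kind``
    (naive | step | seqmatch | temporal) plus method hyper-parameters
    (``k``, ``use_instruments``, ``variant``, ``epochs``, ``hidden_size``...).
    When ``cohort_dir`` is None a cohort is simulated into the output
    directory using ``sim`` overrides.
    """

    out_dir: str
    seed: int = 0
    cohort_dir: str | None = None
    features_dir: str | None = None
    sim: dict = field(default_factory=dict)  # SimulatorConfig overrides + cohort sizes
    embedding: dict = field(default_factory=dict)  # dim, noise_sd
    methods: list = field(default_factory=lambda: [{"name": "naive", "kind": "naive"}])
    compare_window: str = "last20"
    log_level: str = "INFO"

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)


# ---------------------------------------------------------------------------
# Predictions on disk


def predictions_to_csv(
    predictions: Mapping[str, RSDSeries], path: str | Path, meta: str = ""
) -> None:
    """Write ``video_id,sec,rsd_pred_min`` rows; ``meta`` becomes a # comment."""
    path = Path(path)
    frames = [
        pd.DataFrame(
            {
                "video_id": vid,
                "sec": np.arange(len(series)),
                "rsd_pred_min": series.rsd_pred_min,
            }
        )
        for vid, series in predictions.items()
    ]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["video_id", "sec", "rsd_pred_min"]
    )
    with open(path, "w") as fh:
        if meta:
            fh.write(f"# {meta}\n")
        df.to_csv(fh, index=False)


def read_predictions_csv(path: str | Path) -> dict[str, RSDSeries]:
    df = pd.read_csv(path, comment="#")
    out = {}
    for vid, grp in df.groupby("video_id", sort=True):
        grp = grp.sort_values("sec")
        out[str(vid)] = RSDSeries(
            video_id=str(vid), rsd_pred_min=grp["rsd_pred_min"].to_list()
        )
    return out


# ---------------------------------------------------------------------------
# Statistical methods: fit on train, predict the test split per second


def fit_predict_statistical(
    kind: str,
    timelines: Mapping[str, WorkflowTimeline],
    split: CohortSplit,
    k: int = 3,
    use_instruments: bool = False,
) -> dict[str, RSDSeries]:
    train_tls = [timelines[v] for v in split.train]
    test_tls = [timelines[v] for v in split.test]
    if kind == "naive":
        model = st.fit_naive(train_tls)
        return {tl.video_id: st.predict_naive_series(model, tl) for tl in test_tls}
    if kind == "step":
        model = st.fit_step_inferred(train_tls)
        return {
            tl.video_id: st.predict_step_inferred_series(model, tl) for tl in test_tls
        }
    if kind == "seqmatch":
        model = st.fit_sequence_match(train_tls, k=k, use_instruments=use_instruments)
        return {
            tl.video_id: st.predict_sequence_match_series(model, tl)
            for tl in test_tls
        }
    raise ValueError(f"unknown statistical method kind {kind!r}")


# ---------------------------------------------------------------------------
# Full experiment


def _simulate_stage(cfg: RunConfig, out: Path):
    sim_kwargs = dict(cfg.sim)
    n_train = sim_kwargs.pop("n_train", 70)
    n_val = sim_kwargs.pop("n_val", 8)
    n_test = sim_kwargs.pop("n_test", 10)
    sim_kwargs.setdefault("seed", cfg.seed)
    # YAML round-trips lists; restore the tuple/int-keyed structures
    if "step_duration_params" in sim_kwargs:
        sim_kwargs["step_duration_params"] = {
            int(k): tuple(v) for k, v in sim_kwargs["step_duration_params"].items()
        }
    if "duration_scale_archetypes" in sim_kwargs:
        sim_kwargs["duration_scale_archetypes"] = tuple(
            tuple(pair) for pair in sim_kwargs["duration_scale_archetypes"]
        )
    scale_keys = {k: sim_kwargs.pop(k) for k in ("duration_scale", "sigma") if k in sim_kwargs}
    if scale_keys:
        sim_config = scaled_config(**scale_keys, **sim_kwargs)
    else:
        sim_config = default_config(**sim_kwargs)
    timelines, split = sample_cohort(sim_config, n_train, n_val, n_test)
    cohort_dir = out / "cohort"
    write_cohort(cohort_dir, timelines, split, default_vocabulary(sim_config))
    features_dir = None
    if cfg.embedding:
        dim = int(cfg.embedding.get("dim", 16))
        noise_sd = float(cfg.embedding.get("noise_sd", 0.1))
        emb = make_embedding_config(
            sim_config.all_codes, dim=dim, noise_sd=noise_sd, seed=cfg.seed + 1
        )
        rng = np.random.default_rng(cfg.seed + 2)
        tracks = {
            vid: sample_frame_embeddings(tl, emb, rng) for vid, tl in timelines.items()
        }
        features_dir = out / "features"
        write_features(features_dir, tracks)
    return cohort_dir, features_dir


def run_experiment(cfg: RunConfig) -> EvalReport:
    """Run every configured method on one cohort and write a combined report.

    Outputs under ``cfg.out_dir``: per-method ``predictions_<name>.csv``,
    ``report.json`` (per-method MAE rows + pairwise Wilcoxon p-values), and a
    ``manifest.json`` listing what was produced.  Any stage failure raises
    :class:`StageError` naming the stage, after writing the partial manifest.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = f"config_hash={cfg.config_hash()} seed={cfg.seed}"
    manifest: dict[str, object] = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "outputs": [],
    }

    def _fail(stage: str, exc: Exception) -> StageError:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return StageError(stage, str(exc))

    # -- data stage
    try:
        if cfg.cohort_dir is None:
            cohort_dir, features_dir = _simulate_stage(cfg, out)
        else:
            cohort_dir = Path(cfg.cohort_dir)
            features_dir = Path(cfg.features_dir) if cfg.features_dir else None
        timelines, split = read_cohort(cohort_dir)
        if split is None:
            raise ValueError(f"no split manifest in {cohort_dir}")
    except StageError:
        raise
    except Exception as exc:
        raise _fail("simulate" if cfg.cohort_dir is None else "load", exc) from exc

    tracks = None
    report = EvalReport()
    per_video_by_method: dict[str, dict[str, float]] = {}
    method_rows: dict[str, dict] = {}

    for spec in cfg.methods:
        name = spec.get("name", spec["kind"])
        kind = spec["kind"]
        try:
            step_preds = None
            if kind in ("naive", "step", "seqmatch"):
                preds = fit_predict_statistical(
                    kind,
                    timelines,
                    split,
                    k=int(spec.get("k", 3)),
                    use_instruments=bool(spec.get("use_instruments", False)),
                )
            elif kind == "temporal":
                if tracks is None:
                    if features_dir is None:
                        raise ValueError("temporal method requested but no features")
                    tracks = read_features(features_dir)
                feat_dim = next(iter(tracks.values())).dim
                step_codes = sorted(
                    {iv.step_label for tl in timelines.values() for iv in tl.intervals}
                )
                overrides = {
                    k_: v
                    for k_, v in spec.items()
                    if k_ not in ("name", "kind", "variant")
                }
                overrides.setdefault("seed", cfg.seed)
                tcfg = tm.variant_config(
                    spec.get("variant", "s_rsd"),
                    feature_dim=feat_dim,
                    n_steps=len(step_codes),
                    **overrides,
                )
                model = tm.train(tracks, timelines, split, tcfg, step_codes=step_codes)
                preds = {}
                step_preds = {}
                for vid in split.test:
                    series, probs = tm.predict_online(model, tracks[vid])
                    preds[vid] = series
                    if probs is not None:
                        step_preds[vid] = probs.argmax_labels().tolist()
                step_preds = step_preds or None
            else:
                raise ValueError(f"unknown method kind {kind!r}")

            csv_path = out / f"predictions_{name}.csv"
            predictions_to_csv(preds, csv_path, meta=meta)
            manifest["outputs"].append(csv_path.name)
            method_report = evaluate_predictions(preds, timelines, step_preds)
            per_video_by_method[name] = {
                vid: vals[cfg.compare_window]
                for vid, vals in method_report.per_video_mae.items()
            }
            method_rows[name] = method_report.to_dict()
        except Exception as exc:
            raise _fail(
                "features" if "features" in str(exc) else f"method:{name}", exc
            ) from exc

    try:
        report.comparisons = compare_methods(per_video_by_method, cfg.compare_window)
        combined = {
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            "methods": method_rows,
            "comparisons": report.comparisons,
        }
        (out / "report.json").write_text(json.dumps(combined, indent=1))
        manifest["outputs"].append("report.json")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    except Exception as exc:
        raise _fail("evaluate", exc) from exc
    # surface cohort-level numbers on the returned report object
    for name, row in method_rows.items():
        for vid, vals in row["per_video_mae"].items():
            report.per_video_mae[f"{name}/{vid}"] = vals
    return report
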