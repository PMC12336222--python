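"""End-to-end orchestration: simulate -> preprocess -> features -> select ->
balance -> train -> evaluate, with a validated config, per-stage seeds and
reproducible artifacts."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import boost, evaluation, features, resampling, selection, signals, synthetic

log = logging.getLogger("bcgsleep")

_STAGE_OFFSETS = {
    "simulate": 1,
    "selection": 2,
    "smote": 3,
    "train": 4,
    "split": 5,
    "cv": 6,
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed fan-out (kept below 2**31)."""
    return (global_seed * 10_007 + _STAGE_OFFSETS[stage]) % (2**31 - 1)


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "bcgsleep_out"
    # simulate
    simulate: bool = True
    n_epochs: int = 240  # 2 h by default
    fs: float = 100.0
    noise_sigma: float = 0.05
    recording_prefix: str | None = None  # read instead of simulating
    # stage toggles
    run_selection: bool = True
    run_smote: bool = True
    # selection
    selection_iters: int = 3
    weight_ratio: float = 0.796
    attention_epochs: int = 50
    tree_rounds: int = 200
    # smote
    smote_k: int = 5
    # classifier
    boost_iters: int = 645
    learning_rate: float = 0.4546
    s_worst: int = 3
    gap: int = 19
    warmup: int = 34
    # evaluation
    folds: int = 5
    use_cv: bool = False  # default: single stratified 8:2 split

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("out_dir")  # artifact location does not affect the computation
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:12]


def _fit_predict_factory(cfg: PipelineConfig):
    """Builds the train-fold-only fit/predict closure used in evaluation."""

    def fit_predict(train: pd.DataFrame, test: pd.DataFrame):
        cols = [c for c in train.columns if c != "stage"]
        if cfg.run_selection:
            res = selection.iterative_select(
                train,
                n_iter=cfg.selection_iters,
                weight_ratio=cfg.weight_ratio,
                attention_config=selection.AttentionConfig(
                    epochs=cfg.attention_epochs, seed=stage_seed(cfg.seed, "selection")
                ),
                tree_config=selection.TreeConfig(
                    n_rounds=cfg.tree_rounds, seed=stage_seed(cfg.seed, "selection")
                ),
            )
            cols = res.selected
            log.info("selection kept %d features", len(cols))
        tr = train[cols + ["stage"]]
        if cfg.run_smote:
            tr, _ = resampling.smote_resample(
                tr,
                resampling.SmoteConfig(
                    k_neighbors=cfg.smote_k, seed=stage_seed(cfg.seed, "smote")
                ),
            )
            log.info("after SMOTE: %d rows", len(tr))
        params = boost.FastAbcParams(
            n_iter=cfg.boost_iters,
            learning_rate=cfg.learning_rate,
            s=cfg.s_worst,
            gap=cfg.gap,
            warmup=cfg.warmup,
            seed=stage_seed(cfg.seed, "train"),
        )
        model = boost.fit(
            tr[cols].to_numpy(dtype=float), tr["stage"].to_numpy(), params
        )
        fit_predict.last_model = model
        fit_predict.last_columns = cols
        return model.predict(test[cols].to_numpy(dtype=float))

    return fit_predict


def run(cfg: PipelineConfig) -> dict:
    """Run the configured pipeline and write artifacts; returns the metrics."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": cfg.config_hash(), "seed": cfg.seed}

    # --- input signal
    if cfg.simulate:
        hyp = synthetic.generate_hypnogram(
            cfg.n_epochs, seed=stage_seed(cfg.seed, "simulate")
        )
        rec = synthetic.generate_recording(
            None, hyp, fs=cfg.fs, seed=stage_seed(cfg.seed, "simulate"),
            noise_sigma=cfg.noise_sigma,
        )
        rec.save(out / "recording", seed=cfg.seed)
    elif cfg.recording_prefix:
        rec = synthetic.BCGRecording.load(cfg.recording_prefix)
        if rec.stages is None:
            raise ValueError("stage labels are required: provide a hypnogram CSV")
    else:
        raise ValueError("either enable simulate or provide recording_prefix")
    log.info("recording: %.0f s at %.0f Hz, %d epochs", rec.duration, rec.fs, rec.n_epochs)

    # --- preprocess + features
    jj, bb = signals.process_recording(rec)
    table, mask = features.assemble(jj, bb, stages=rec.stages)
    table.to_csv(out / "features.csv", index=False)
    (out / "features.json").write_text(
        json.dumps({**stamp, "n_epochs": len(table),
                    "n_features": len(features.REGISTRY_NAMES),
                    "registry_checksum": features.registry_checksum(),
                    "n_imputed": int(mask.values.sum())}, indent=2)
    )
    log.info("feature table: %s", table.shape)

    fit_predict = _fit_predict_factory(cfg)
    metrics: dict = dict(stamp)
    if cfg.use_cv:
        cv = evaluation.cross_validate(
            table, fit_predict, folds=cfg.folds, seed=stage_seed(cfg.seed, "cv")
        )
        cv.pooled.to_csv(out / "confusion_pooled.csv")
        metrics["cv_mean"] = cv.mean_metrics
        metrics["cv_folds"] = cv.fold_metrics
    else:
        train, test = evaluation.split_8_2(table, seed=stage_seed(cfg.seed, "split"))
        y_pred = fit_predict(train, test)
        cm = evaluation.ConfusionMatrix.from_predictions(test["stage"], y_pred)
        cm.to_csv(out / "confusion.csv")
        metrics["test"] = evaluation.overall_metrics(cm)
        metrics["per_class"] = {
            c: evaluation.per_class_metrics(cm, c) for c in cm.classes
        }
        fit_predict.last_model.save(out / "model.json")
        (out / "selected_features.txt").write_text(
            "\n".join(fit_predict.last_columns) + "\n"
        )
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
    return metrics
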