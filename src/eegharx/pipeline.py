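"""End-to-end orchestration with a single config and provenance manifests.

``run_all`` executes simulate/ingest -> preprocess -> features -> select ->
tune/train -> evaluate -> explain and writes every stage artifact plus a
manifest recording all parameters, derived stage seeds, library versions and
row-count conservation identities (epochs generated = kept + rejected;
feature rows = kept - dropped).

One global seed expands deterministically into per-stage seeds: stage seed i
is the i-th word of ``numpy.random.SeedSequence(seed).generate_state(6)``
reduced mod 2**31 (order: simulate, ica, split, tune, train, explain).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import yaml

from . import evaluate, explain, features, io, preprocess, selection, simulate

logger = logging.getLogger(__name__)

STAGE_NAMES = ("simulate", "ica", "split", "tune", "train", "explain")


def derive_stage_seeds(seed: int) -> dict[str, int]:
    words = np.random.SeedSequence(seed).generate_state(len(STAGE_NAMES))
    return {name: int(w % (2**31)) for name, w in zip(STAGE_NAMES, words)}


@dataclass
class PipelineConfig:
    """All stage parameters in one place; every field validates against its
    stage's preconditions before any computation starts."""

    simulation: simulate.SimulationConfig = field(default_factory=simulate.SimulationConfig)
    input_recording: str | None = None  # EDF or CSV path; overrides simulation
    notch_freq_hz: float = 60.0
    band_pass_hz: tuple[float, float] = (0.5, 44.0)
    snr_threshold_db: float = 25.0
    epoch_length_s: float = 10.0
    welch: features.WelchParams = field(default_factory=features.WelchParams)
    select_k: int = 20
    model_family: str = "random_forest"
    grid: list[tuple[int, int]] | None = None
    cv_folds: int = 10
    test_fraction: float = 0.2
    lime: explain.LimeConfig = field(default_factory=explain.LimeConfig)
    n_explanations: int = 5
    seed: int = 0

    def validate(self) -> None:
        self.simulation.validate()
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.select_k < 1:
            raise ValueError("select_k must be >= 1")
        if self.model_family not in selection.FAMILIES:
            raise ValueError(f"unknown model family {self.model_family!r}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.epoch_length_s <= 0:
            raise ValueError("epoch_length_s must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "simulation" in d:
            sim = d["simulation"]
            if "profiles" in sim:
                sim["profiles"] = [simulate.ActivityProfile(**p) for p in sim["profiles"]]
            d["simulation"] = simulate.SimulationConfig(**sim)
        if "welch" in d:
            d["welch"] = features.WelchParams(**d["welch"])
        if "lime" in d:
            d["lime"] = explain.LimeConfig(**d["lime"])
        if "band_pass_hz" in d:
            d["band_pass_hz"] = tuple(d["band_pass_hz"])
        if "grid" in d and d["grid"] is not None:
            d["grid"] = [tuple(g) for g in d["grid"]]
        cfg = cls(**d)
        cfg.validate()
        return cfg


def _library_versions() -> dict[str, str]:
    import scipy
    import sklearn
    import xgboost

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "xgboost": xgboost.__version__,
    }


def run_all(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute every stage; returns the run directory.

    Artifacts: ``features.csv`` (+ ``features_meta.json`` sidecar),
    ``model.joblib`` + ``model_manifest.json``, ``evaluation.json``,
    ``evaluation.txt``, ``explanations/*.json`` and ``manifest.json``.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = derive_stage_seeds(config.seed)

    # ---- simulate / ingest -------------------------------------------------
    if config.input_recording:
        path = Path(config.input_recording)
        recording = (
            io.read_edf(path) if path.suffix.lower() == ".edf" else io.read_csv(path)
        )
        logger.info("[ingest] %s: %d channels, %.0f s", path, recording.n_channels,
                    recording.duration_s)
    else:
        sim_cfg = dataclasses.replace(config.simulation, seed=seeds["simulate"])
        recording = simulate.generate_recording(sim_cfg)

    # ---- preprocess --------------------------------------------------------
    epochs = preprocess.preprocess_recording(
        recording,
        notch_freq=config.notch_freq_hz,
        band_pass=config.band_pass_hz,
        snr_threshold_db=config.snr_threshold_db,
        epoch_length_s=config.epoch_length_s,
        ica_seed=seeds["ica"],
    )
    n_generated, n_kept = epochs.n_epochs, epochs.n_kept
    n_rejected = n_generated - n_kept

    # ---- features ----------------------------------------------------------
    table = features.build_feature_table(epochs, welch_params=config.welch)
    n_dropped = n_kept - len(table)
    table.to_csv(out / "features.csv", index=False)
    with open(out / "features_meta.json", "w") as fh:
        json.dump(
            {
                "bands": {b.name: [b.f_low, b.f_high] for b in features.DEFAULT_BANDS},
                "welch_params": dataclasses.asdict(config.welch),
                "columns": features.feature_columns(),
            },
            fh, indent=2,
        )

    # ---- split / select / tune / train ------------------------------------
    train_tbl, test_tbl = selection.split_train_test(
        table, config.test_fraction, seed=seeds["split"]
    )
    sel = selection.score_features(train_tbl, k=config.select_k)
    logger.info("[select] fitted on training partition only (%d rows)", len(train_tbl))
    train_sel = selection.select_top_k(train_tbl, config.select_k, result=sel)
    test_sel = test_tbl[train_sel.columns]
    spec = selection.tune_hyperparameters(
        train_sel, config.model_family, grid=config.grid,
        folds=config.cv_folds, seed=seeds["tune"],
    )
    spec = dataclasses.replace(spec, seed=seeds["train"])
    model = selection.train(train_sel, spec, folds=config.cv_folds)
    joblib.dump(model, out / "model.joblib")
    with open(out / "model_manifest.json", "w") as fh:
        json.dump(
            {
                "spec": dataclasses.asdict(spec),
                "feature_names": model.feature_names,
                "selection_scores": {f: sel.scores[f] for f in model.feature_names},
                "seeds": seeds,
            },
            fh, indent=2,
        )

    # ---- evaluate ----------------------------------------------------------
    y_true = list(test_sel["label"])
    y_pred = model.predict(test_sel)
    proba = model.predict_proba(test_sel)
    report = evaluate.evaluate_predictions(y_true, y_pred, proba, model.classes)
    (out / "evaluation.json").write_text(report.to_json())
    (out / "evaluation.txt").write_text(report.to_text_table() + "\n")

    # ---- explain -----------------------------------------------------------
    expl_dir = out / "explanations"
    expl_dir.mkdir(exist_ok=True)
    lime_cfg = dataclasses.replace(config.lime, seed=seeds["explain"])
    n_expl = min(config.n_explanations, len(test_sel))
    for i in range(n_expl):
        e = explain.explain_instance(
            model, test_sel.iloc[i].drop("label"), train_sel, lime_cfg,
            instance_id=f"test-{i}",
        )
        (expl_dir / f"explanation_{i:03d}.json").write_text(e.to_json())

    # ---- manifest ----------------------------------------------------------
    manifest = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "parameters": {
            "notch_freq_hz": config.notch_freq_hz,
            "band_pass_hz": list(config.band_pass_hz),
            "snr_threshold_db": config.snr_threshold_db,
            "epoch_length_s": config.epoch_length_s,
            "select_k": config.select_k,
            "model_family": config.model_family,
            "cv_folds": config.cv_folds,
            "test_fraction": config.test_fraction,
        },
        "library_versions": _library_versions(),
        "row_counts": {
            "epochs_generated": n_generated,
            "epochs_kept": n_kept,
            "epochs_rejected": n_rejected,
            "rejected_fraction": n_rejected / n_generated if n_generated else 0.0,
            "feature_rows": len(table),
            "dropped_for_missing": n_dropped,
            "train_rows": len(train_tbl),
            "test_rows": len(test_tbl),
        },
        "accuracy": report.accuracy,
    }
    assert manifest["row_counts"]["epochs_generated"] == n_kept + n_rejected
    assert manifest["row_counts"]["feature_rows"] == n_kept - n_dropped
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("[run-all] finished: accuracy %.4f, artifacts in %s", report.accuracy, out)
    return out
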