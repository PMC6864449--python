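"""Pipeline orchestration: simulate -> preprocess -> featurize -> train ->
evaluate / cross-validate, driven by one YAML config.

Every pipeline constant (50-800 Hz band, 50,000-frame target, 8 x 8
decimation, dropout 0.35, 70/30 split, k = 5) lives in the default config
rather than being hard-coded; the 12.5 s and 27.8 s variants are
selectable by a single ``preset`` key.  Feature vectors are cached on
disk keyed by a hash of the featurization config, so model sweeps skip
re-featurizing.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .audio_io import ClassLabel, Manifest, read_wav
from .classifiers import TrainConfig, build_model
from .evaluation import (
    CVReport,
    EvalReport,
    evaluate_predictions,
    kfold_cv,
    split_train_test,
)
from .features import (
    TARGET_FRAMES_12_5_S,
    TARGET_FRAMES_27_8_S,
    DecimationConfig,
    FramingConfig,
    feature_length,
    featurize,
)
from .preprocess import FilterSpec
from .synth import SynthConfig

log = logging.getLogger("pcglearn")

__all__ = ["PipelineConfig", "featurize_manifest", "run_pipeline", "sweep_dropout"]

PRESETS = {"12.5s": TARGET_FRAMES_12_5_S, "27.8s": TARGET_FRAMES_27_8_S}


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline stages in one place; see the package README for the
    meaning of each section."""

    filter: FilterSpec = FilterSpec()
    framing: FramingConfig = FramingConfig()
    decimate: DecimationConfig = DecimationConfig()
    train: TrainConfig = TrainConfig()
    synth: SynthConfig = SynthConfig()
    model: str = "rnn"
    dropout_rate: float = 0.35
    cv_folds: int = 5
    seed: int = 0

    @classmethod
    def with_preset(cls, preset: str = "12.5s", **kwargs) -> "PipelineConfig":
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
        return cls(framing=FramingConfig(target_frames=PRESETS[preset]), **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        preset = raw.pop("preset", None)
        sections = {
            "filter": FilterSpec,
            "framing": FramingConfig,
            "decimate": DecimationConfig,
            "train": TrainConfig,
            "synth": SynthConfig,
        }
        kwargs = {}
        for name, typ in sections.items():
            if name in raw:
                section = raw.pop(name)
                if name == "synth" and "n_per_class" in section:
                    section["n_per_class"] = {
                        ClassLabel.parse(k): int(v)
                        for k, v in section["n_per_class"].items()
                    }
                for key in ("bpm_range", "duration_range_s", "murmur_band"):
                    if name == "synth" and key in section:
                        section[key] = tuple(section[key])
                kwargs[name] = typ(**section)
        kwargs.update(raw)
        cfg = cls(**kwargs)
        if preset is not None:
            cfg = replace(
                cfg, framing=FramingConfig(target_frames=PRESETS[preset])
            )
        return cfg

    def to_yaml(self, path: str | Path) -> Path:
        data = asdict(self)
        data["synth"]["n_per_class"] = {
            k.name.lower(): v for k, v in self.synth.n_per_class.items()
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
        return Path(path)

    def config_hash(self) -> str:
        data = asdict(self)
        data["synth"]["n_per_class"] = {
            k.name.lower(): v for k, v in self.synth.n_per_class.items()
        }
        blob = json.dumps(data, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def feature_hash(self) -> str:
        """Hash over the stages that determine feature vectors only."""
        blob = json.dumps(
            [asdict(self.filter), asdict(self.framing), asdict(self.decimate)],
            sort_keys=True,
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def featurize_manifest(
    cfg: PipelineConfig,
    manifest: Manifest,
    *,
    cache_dir: str | Path | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Featurize every manifest entry; returns (X, y).

    With ``cache_dir``, features are stored as a CSV keyed by the
    featurization-config hash and reloaded on identical reruns.
    """
    cache_path = None
    if cache_dir is not None:
        cache_path = Path(cache_dir) / f"features_{cfg.feature_hash()}.csv"
        if cache_path.exists():
            log.info("feature cache hit: %s", cache_path)
            df = pd.read_csv(cache_path)
            y = df["label"].to_numpy(dtype=np.int64)
            X = df.drop(columns=["id", "label"]).to_numpy(dtype=np.float64)
            return X, y
    t0 = time.time()
    rows, labels, ids = [], [], []
    for path, label in manifest:
        rec = read_wav(manifest.resolve(path), label=label)
        fv = featurize(rec, cfg.framing, cfg.decimate, cfg.filter)
        rows.append(fv.values)
        labels.append(int(label))
        ids.append(rec.id)
    X = np.asarray(rows)
    y = np.asarray(labels, dtype=np.int64)
    log.info("featurized %d recordings -> %s in %.1fs", len(y), X.shape,
             time.time() - t0)
    if cache_path is not None:
        cache_path.parent.mkdir(parents=True, exist_ok=True)
        df = pd.DataFrame(X)
        df.insert(0, "label", y)
        df.insert(0, "id", ids)
        df.to_csv(cache_path, index=False)
    return X, y


def _make_model(cfg: PipelineConfig, init_seed: int):
    return build_model(
        cfg.model,
        input_len=feature_length(cfg.framing, cfg.decimate),
        dropout_rate=cfg.dropout_rate,
        init_seed=init_seed,
    )


def run_pipeline(
    cfg: PipelineConfig,
    manifest: Manifest,
    *,
    out_dir: str | Path | None = None,
) -> EvalReport:
    """Featurize, split 70/30 (stratified), train the configured model and
    evaluate on the held-out set.

    With ``out_dir``, writes ``report.json``, ``history.csv`` and a run
    manifest recording the config hash and seed.
    """
    X, y = featurize_manifest(cfg, manifest, cache_dir=out_dir)
    train_idx, test_idx = split_train_test(
        y, cfg.train.split_ratio, seed=cfg.seed
    )
    log.info("split: %d train / %d test", len(train_idx), len(test_idx))
    model = _make_model(cfg, init_seed=cfg.seed)
    t0 = time.time()
    model.fit(X[train_idx], y[train_idx], replace(cfg.train, seed=cfg.seed))
    log.info("trained %s in %.1fs", cfg.model, time.time() - t0)
    pred = model.predict(X[test_idx])
    loss = model.evaluate_loss(X[test_idx], y[test_idx])
    report = evaluate_predictions(y[test_idx], pred, loss=loss)
    log.info("test accuracy %.1f%% (n=%d)", report.accuracy_pct, report.n)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(
            json.dumps(report.to_dict(), indent=2)
        )
        if model.history:
            pd.DataFrame(model.history).to_csv(
                out_dir / "history.csv", index=False
            )
        (out_dir / "run.json").write_text(
            json.dumps(
                {"config_hash": cfg.config_hash(), "seed": cfg.seed,
                 "model": cfg.model},
                indent=2,
            )
        )
    return report


def run_cv(
    cfg: PipelineConfig,
    manifest: Manifest,
    *,
    out_dir: str | Path | None = None,
) -> CVReport:
    """Stratified k-fold cross-validation of the configured model over the
    full manifest."""
    X, y = featurize_manifest(cfg, manifest, cache_dir=out_dir)
    report = kfold_cv(
        X,
        y,
        lambda fold: _make_model(cfg, init_seed=cfg.seed + fold),
        replace(cfg.train, seed=cfg.seed),
        k=cfg.cv_folds,
        seed=cfg.seed,
        verbose=True,
    )
    log.info("%d-fold weighted accuracy %.2f%%", report.k,
             report.weighted_accuracy_pct)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "cv_report.json").write_text(
            json.dumps(report.to_dict(), indent=2)
        )
    return report


def sweep_dropout(
    cfg: PipelineConfig,
    manifest: Manifest,
    rates: tuple[float, ...] = (0.05, 0.20, 0.35),
    *,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """One full train/evaluate per dropout rate (shared feature cache);
    returns a (rate, accuracy, loss) table."""
    if not rates:
        raise ValueError("need at least one dropout rate")
    X, y = featurize_manifest(cfg, manifest, cache_dir=out_dir)
    train_idx, test_idx = split_train_test(y, cfg.train.split_ratio, seed=cfg.seed)
    rows = []
    for rate in rates:
        model = build_model(
            cfg.model,
            input_len=X.shape[1],
            dropout_rate=rate,
            init_seed=cfg.seed,
        )
        model.fit(X[train_idx], y[train_idx], replace(cfg.train, seed=cfg.seed))
        pred = model.predict(X[test_idx])
        loss = model.evaluate_loss(X[test_idx], y[test_idx])
        report = evaluate_predictions(y[test_idx], pred, loss=loss)
        rows.append(
            {"dropout_rate": rate,
             "accuracy_pct": round(report.accuracy_pct, 1),
             "loss": loss}
        )
        log.info("dropout %.2f -> accuracy %.1f%%", rate, report.accuracy_pct)
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "dropout_sweep.csv", index=False)
    return table
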