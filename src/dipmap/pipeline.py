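"""End-to-end experiment orchestration.

``run_experiment`` executes the whole analysis as one reproducible run:
simulate a cohort, band-pass filter it, build per-trial activation-image
datasets for every requested window, then train and evaluate the CNN in
both regimes — per-interval (one dataset per window) and combined (all
initial-dip windows pooled) — for every requested depth.  All randomness
descends from a single master seed through named stage seeds, so any
stage can be reproduced in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import cnn as cnn_mod
from .hrf import GammaHrfParams
from .metrics import UndefinedMetricError, confusion, eq1_metrics, roc_auc
from .preprocessing import FilterSpec, bandpass
from .protocol import SessionProtocol
from .simulate import (
    ChannelGeometry,
    NoiseParams,
    default_geometry,
    default_profiles,
    make_cohort,
)
from .tmap import ImageDataset, TMapParams, build_dataset

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "ConfigError", "stage_seed", "run_experiment"]

INITIAL_DIP_WINDOWS = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)
DELAYED_HR_WINDOW = 14.0


class ConfigError(ValueError):
    """Invalid or inconsistent experiment configuration."""


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the master."""
    digest = hashlib.blake2s(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class ExperimentConfig:
    """Everything one experiment needs, serialisable to YAML."""

    n_subjects: int = 11
    n_trials: int = 6
    windows: tuple[float, ...] = INITIAL_DIP_WINDOWS
    delayed_window: float = DELAYED_HR_WINDOW
    depths: tuple[int, ...] = (22,)
    image_size: int = 227
    base_filters: int = 8
    max_filters: int = 128
    epochs: int = 100
    learn_rate: float = 0.01
    momentum: float = 0.9
    batch_size: int = 32
    split: float = 0.7
    seed: int = 0
    geometry_path: str | None = None
    amplitude: float = 1.0
    noise: NoiseParams = field(default_factory=NoiseParams)
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    run_per_interval: bool = True
    run_combined: bool = True
    run_delayed: bool = True

    def __post_init__(self) -> None:
        for w in (*self.windows, self.delayed_window):
            if not 0 < w <= 30:
                raise ConfigError(f"window {w} s outside (0, 30]")
        if self.geometry_path is not None and not Path(self.geometry_path).exists():
            raise ConfigError(f"geometry file not found: {self.geometry_path}")

    def geometry(self) -> ChannelGeometry:
        if self.geometry_path is None:
            return default_geometry()
        return ChannelGeometry.from_json(self.geometry_path)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["noise"] = asdict(self.noise)
        d["filter_spec"] = asdict(self.filter_spec)
        d["windows"] = [float(w) for w in self.windows]
        d["depths"] = [int(k) for k in self.depths]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "noise" in d:
            d["noise"] = NoiseParams(**d["noise"])
        if "filter_spec" in d:
            d["filter_spec"] = FilterSpec(**d["filter_spec"])
        for key in ("windows", "depths"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _dataset_manifest(ds: ImageDataset) -> str:
    """Order-independent checksum of a dataset's images and metadata."""
    h = hashlib.sha256()
    h.update(ds.images.astype(np.float32).tobytes())
    h.update("|".join(ds.labels.tolist()).encode())
    h.update(ds.meta.to_csv(index=False).encode())
    return h.hexdigest()


def _train_eval(
    ds: ImageDataset,
    depth: int,
    config: ExperimentConfig,
    seed: int,
    with_metrics: bool = False,
) -> dict:
    arch = cnn_mod.build_architecture(
        depth, input_size=config.image_size,
        base_filters=config.base_filters, max_filters=config.max_filters,
    )
    train_ds, val_ds = cnn_mod.split_dataset(ds, ratio=config.split, seed=seed)
    tcfg = cnn_mod.TrainConfig(
        epochs=config.epochs, learn_rate=config.learn_rate,
        momentum=config.momentum, batch_size=config.batch_size,
        split=config.split, seed=seed,
    )
    model, history = cnn_mod.train(arch, train_ds, tcfg)
    preds = model.predict(val_ds.images)
    acc = float(np.mean(preds == val_ds.labels))
    out = {
        "accuracy": acc,
        "n_train": len(train_ds),
        "n_val": len(val_ds),
        "final_train_loss": history.loss[-1] if history.loss else None,
        "curves": {"loss": history.loss, "accuracy": history.accuracy},
    }
    if with_metrics:
        counts = confusion(val_ds.labels, preds)
        try:
            out["metrics"] = eq1_metrics(counts).to_dict()
        except UndefinedMetricError as err:  # e.g. a class never predicted
            out["metrics"] = None
            out["metrics_undefined"] = str(err)
        scores = model.predict_proba(val_ds.images)
        pos_idx = model.classes_.index("RHTF") if "RHTF" in model.classes_ else 1
        auc_val, _ = roc_auc(scores[:, pos_idx], val_ds.labels,
                             positive_class=model.classes_[pos_idx])
        out["auc"] = auc_val
    return out


def run_experiment(config: ExperimentConfig, out_dir=None) -> dict:
    """Run simulate → filter → t-maps → train → evaluate; return the report.

    The report carries per-depth accuracies for every per-interval
    dataset, the combined initial-dip dataset (with confusion metrics and
    AUC) and the delayed-response dataset, plus dataset manifests and
    stage timings.  If ``out_dir`` is given, ``report.json`` and
    ``config.yaml`` are written there.
    """
    t0 = time.time()
    timings: dict[str, float] = {}
    geometry = config.geometry()
    profile_rhtf, profile_rhlf = default_profiles(geometry, amplitude=config.amplitude)

    logger.info("simulating cohort: %d subjects x 2 sessions", config.n_subjects)
    cohort = make_cohort(
        config.n_subjects, config.n_trials, profile_rhtf, profile_rhlf,
        config.noise, seed=stage_seed(config.seed, "simulate"), geometry=geometry,
    )
    timings["simulate"] = time.time() - t0

    t1 = time.time()
    cohort = [s.with_data(bandpass(s.data, config.filter_spec)) for s in cohort]
    timings["preprocess"] = time.time() - t1

    t1 = time.time()
    tparams = TMapParams(image_size=config.image_size)
    hrf_params = GammaHrfParams()
    per_window: dict[float, ImageDataset] = {}
    for w in config.windows:
        per_window[w] = build_dataset(cohort, [w], tparams, hrf_params)
    if config.run_delayed:
        per_window[config.delayed_window] = build_dataset(
            cohort, [config.delayed_window], tparams, hrf_params
        )
    combined = ImageDataset.concat([per_window[w] for w in config.windows])
    timings["tmaps"] = time.time() - t1

    report: dict = {
        "config": json.loads(json.dumps(asdict(config), default=str)),
        "dataset_manifests": {
            **{f"window_{w}": _dataset_manifest(ds) for w, ds in per_window.items()},
            "combined": _dataset_manifest(combined),
        },
        "per_interval": {},
        "combined": {},
        "delayed": {},
    }

    for depth in config.depths:
        seed_d = stage_seed(config.seed, f"train:{depth}")
        if config.run_per_interval:
            report["per_interval"][str(depth)] = {}
            for w in config.windows:
                t1 = time.time()
                res = _train_eval(per_window[w], depth, config, stage_seed(seed_d, f"w{w}"))
                res.pop("curves")
                report["per_interval"][str(depth)][str(w)] = res
                logger.info("depth %d window %.1fs: acc %.3f (%.1fs)",
                            depth, w, res["accuracy"], time.time() - t1)
        if config.run_combined:
            t1 = time.time()
            res = _train_eval(combined, depth, config, seed_d, with_metrics=True)
            report["combined"][str(depth)] = res
            logger.info("depth %d combined: acc %.3f (%.1fs)",
                        depth, res["accuracy"], time.time() - t1)
        if config.run_delayed:
            t1 = time.time()
            res = _train_eval(
                per_window[config.delayed_window], depth, config,
                stage_seed(seed_d, "delayed"),
            )
            res.pop("curves")
            report["delayed"][str(depth)] = res
            logger.info("depth %d delayed %.0fs: acc %.3f (%.1fs)",
                        depth, config.delayed_window, res["accuracy"], time.time() - t1)

    timings["total"] = time.time() - t0
    report["timings_s"] = {k: round(v, 3) for k, v in timings.items()}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
        (out / "report.json").write_text(json.dumps(report, indent=1))
    return report
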