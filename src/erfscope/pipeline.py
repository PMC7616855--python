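"""End-to-end experiment orchestration with seeded reproducibility.

Two study drivers mirror the analyses the library supports:

* :func:`run_erf_survey` — train every requested ERF variant on a dataset
  and tabulate test accuracy against the analytic ERF.
* :func:`run_scrambling_study` — the base/follow-up program: train a base
  per seed and dataset, attach follow-up networks (aggregating, optionally
  pointwise, and aggregating with a fixed train-time scramble), and probe
  the unscrambled model with global and local test-time scrambling.

Every run writes ``results.csv`` plus a ``manifest.json`` (config echo,
seeds, version) into its output directory, enough to reproduce the run.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .architectures import make_erf_variant, build_network, compute_erf, count_parameters
from .scrambling import FollowUpSpec, compose, make_global_permutation, test_time_scramble
from .synthetic import SyntheticSpec, SyntheticDataset, generate
from .training import (TrainConfig, train, evaluate, shift_augment,
                       scrambling_ratio, upsample_images)

__all__ = ["ExperimentConfig", "run_erf_survey", "run_scrambling_study"]


@dataclass
class ExperimentConfig:
    """Serializable description of one experiment run."""

    variants: list = field(default_factory=lambda: ["erf11"])
    width_multiplier: float = 0.125
    input_size: int = 64
    dataset: dict = field(default_factory=lambda: {
        "kind": "synthetic", "spec": {"cue_type": "arrangement"}})
    base_train: dict = field(default_factory=lambda: {
        "epochs": 10, "batch_size": 64})
    followup_train: dict = field(default_factory=lambda: {
        "epochs": 40, "constant_epochs": 20, "lr_initial": 0.02,
        "batch_size": 64, "weight_decay": 1e-4})
    followup_width: int | None = None  # None -> base output width
    include_pointwise: bool = True
    scramble_window: int = 2
    upsample: int = 1                  # integer input upsampling factor
    augment_shift: int = 4
    seeds: list = field(default_factory=lambda: [0, 1, 2])
    out_dir: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "ExperimentConfig":
        raw = Path(path).read_text()
        d = (yaml.safe_load(raw) if str(path).endswith((".yml", ".yaml"))
             else json.loads(raw))
        return cls.from_dict(d)


def _load_dataset(cfg: ExperimentConfig, seed: int) -> SyntheticDataset:
    d = cfg.dataset
    if d["kind"] == "synthetic":
        spec = SyntheticSpec.from_dict({**d["spec"],
                                        "image_size": cfg.input_size,
                                        "seed": seed})
        return generate(spec)
    if d["kind"] == "directory":
        return SyntheticDataset.load(d["path"])
    raise ValueError(f"unknown dataset kind {d['kind']!r}")


def _write_outputs(out_dir: str | None, results: pd.DataFrame,
                   config: ExperimentConfig) -> None:
    if out_dir is None:
        return
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results.to_csv(out / "results.csv", index=False)
    cfg = config.to_dict()
    manifest = {
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
        "seeds": list(config.seeds),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _train_base(cfg: ExperimentConfig, variant, xtr, ytr, n_classes,
                seed: int):
    spec = make_erf_variant(variant, width_multiplier=cfg.width_multiplier,
                            n_classes=n_classes,
                            input_size=cfg.input_size * cfg.upsample,
                            seed=seed)
    net = build_network(spec)
    aug = shift_augment(cfg.augment_shift) if cfg.augment_shift else None
    tc = TrainConfig(**{**cfg.base_train, "seed": seed})
    train(net, xtr, ytr, tc, augment=aug)
    return net


def run_erf_survey(config: ExperimentConfig) -> pd.DataFrame:
    """Accuracy as a function of the architecture's ERF."""
    if not config.variants:
        raise ValueError("no variants configured")
    rows = []
    for seed in config.seeds:
        ds = _load_dataset(config, seed)
        xtr, ytr = ds.train_arrays()
        xte, yte = ds.test_arrays()
        xtr = upsample_images(xtr, config.upsample)
        xte = upsample_images(xte, config.upsample)
        for variant in config.variants:
            net = _train_base(config, variant, xtr, ytr, ds.n_classes, seed)
            metrics = evaluate(net, xte, yte)
            rows.append({
                "variant": str(variant), "seed": seed,
                "erf": compute_erf(net.spec).network_erf,
                "parameters": count_parameters(net.spec),
                "test_accuracy": metrics.accuracy,
            })
    results = pd.DataFrame(rows)
    _write_outputs(config.out_dir, results, config)
    return results


def run_scrambling_study(config: ExperimentConfig):
    """The base/follow-up scrambling program on one dataset.

    Per seed: train the base standalone; train an aggregating follow-up on
    the frozen base (unscrambled), optionally a pointwise follow-up, and an
    aggregating follow-up with a fixed global train-time scramble; then
    probe the unscrambled aggregating model with per-image global and local
    test-time scrambling.  Returns ``(results, reports)`` where ``results``
    has one accuracy row per (seed, condition) and ``reports`` maps
    (seed, condition) to per-class :class:`ScramblingReport`-ready metrics.
    """
    variant = config.variants[0]
    aug = shift_augment(config.augment_shift) if config.augment_shift else None
    rows, reports = [], {}
    for seed in config.seeds:
        ds = _load_dataset(config, seed)
        xtr, ytr = ds.train_arrays()
        xte, yte = ds.test_arrays()
        xtr = upsample_images(xtr, config.upsample)
        xte = upsample_images(xte, config.upsample)
        base = _train_base(config, variant, xtr, ytr, ds.n_classes, seed)
        base_metrics = evaluate(base, xte, yte)
        rows.append({"seed": seed, "condition": "base",
                     "accuracy": base_metrics.accuracy})

        ftc = TrainConfig(**{**config.followup_train, "seed": seed + 1})
        grid = base.features(xte[:1]).shape[2]

        # aggregating follow-up, unscrambled
        agg = compose(base, FollowUpSpec("aggregating",
                                         width=config.followup_width,
                                         seed=seed + 1))
        train(agg, xtr, ytr, ftc, augment=aug)
        agg_metrics = evaluate(agg, xte, yte)
        rows.append({"seed": seed, "condition": "base+followup",
                     "accuracy": agg_metrics.accuracy})

        if config.include_pointwise:
            pw = compose(base, FollowUpSpec("pointwise",
                                            width=config.followup_width,
                                            seed=seed + 1))
            train(pw, xtr, ytr, ftc, augment=aug)
            rows.append({"seed": seed, "condition": "base+followup_1x1",
                         "accuracy": evaluate(pw, xte, yte).accuracy})

        # aggregating follow-up with fixed train-time global scramble
        perm = make_global_permutation(grid, grid, seed=seed + 2)
        scr = compose(base, FollowUpSpec("aggregating",
                                         width=config.followup_width,
                                         seed=seed + 1),
                      permutation=perm, train_time_scramble=True)
        train(scr, xtr, ytr, ftc, augment=aug)
        rows.append({"seed": seed, "condition": "base+followup_train_scrambled",
                     "accuracy": evaluate(scr, xte, yte).accuracy})

        # test-time scrambling of the unscrambled aggregating model
        for scope in ("global", "local"):
            clean, scrambled = test_time_scramble(
                agg, xte, scope=scope, window=config.scramble_window,
                seed=seed + 3)
            after = evaluate(None, xte, yte, predictions=scrambled)
            rows.append({"seed": seed,
                         "condition": f"base+followup_test_{scope}",
                         "accuracy": after.accuracy})
            if scope == "global":
                before = evaluate(None, xte, yte, predictions=clean)
                reports[(seed, "test_global")] = scrambling_ratio(
                    before, after)
    results = pd.DataFrame(rows)
    _write_outputs(config.out_dir, results, config)
    return results, reports
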