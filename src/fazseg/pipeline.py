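"""End-to-end orchestration: simulate -> train (k-fold) -> evaluate -> report.

A run is described by a nested configuration (usually a YAML file) with one
section per stage; every source of randomness derives from the single
global seed, so a rerun with the same configuration reproduces the same
report files bit-for-bit.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from .evaluate import group_report, metrics_table, plot_sweep, threshold_sweep
from .model import FAZSegmentationModel
from .network import NetworkConfig
from .synthetic import generate_cohort
from .train import TrainConfig, make_cv_splits

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline"]

#: Every recognized key with its default.  The defaults are the scaled-down
#: desk profile: 6 subjects at 128 x 128, a reduced network, short training.
DEFAULT_CONFIG = {
    "seed": 0,
    "synthetic": {"n_subjects": 6, "n_high_myopia": 2, "size": 128, "scan_mm": 3.0},
    "network": {
        "input_size": 128,
        "n_pool": 5,
        "channel_schedule": [8, 16, 32, 32, 32, 32],
        "se_reduction": 4,
        "kernel_size": 3,
    },
    "train": {
        "initial_lr": 5e-3,
        "patience_epochs": 30,
        "lr_factor": 0.5,
        "max_epochs": 12,
        "batch_size": 4,
        "loss_name": "bce",
        "augment_training": True,
    },
    "cv": {"k": 2, "folds": [1]},
    "evaluate": {"threshold": 0.44, "sweep_step": 0.01, "refine_first": True},
}


def _merge(defaults: dict, override: dict, path="") -> dict:
    out = {}
    for key in override:
        if key not in defaults:
            raise ValueError(f"unknown config key: {path + key}")
    for key, val in defaults.items():
        if key in override and isinstance(val, dict):
            out[key] = _merge(val, override[key], path + key + ".")
        elif key in override:
            out[key] = override[key]
        else:
            out[key] = val
    return out


def load_config(path=None) -> dict:
    """Load a YAML run configuration merged over the documented defaults."""
    if path is None:
        return json.loads(json.dumps(DEFAULT_CONFIG))
    import yaml

    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, user)


def run_pipeline(config: dict, out_dir: str, progress=None) -> dict:
    """Execute the full pipeline and write report files under ``out_dir``.

    Stages: cohort simulation, participant-based stratified CV split,
    per-fold training, held-out prediction, threshold sweep, per-group
    metric report, and per-image area quantification.  Returns a dict of
    the written artifact paths plus the pooled summary numbers.
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    os.makedirs(out_dir, exist_ok=True)
    seed = int(cfg["seed"])
    ss = np.random.SeedSequence(seed)
    sim_seed, cv_seed, train_seed = [int(s) for s in ss.generate_state(3) >> 1]

    syn = cfg["synthetic"]
    samples = generate_cohort(
        syn["n_subjects"], syn["n_high_myopia"], sim_seed,
        size=(syn["size"], syn["size"]), scan_mm=syn["scan_mm"],
    )
    subjects = sorted({(s.subject_id, s.myopia_class) for s in samples})
    splits = make_cv_splits(subjects, k=cfg["cv"]["k"], seed=cv_seed)

    net_config = NetworkConfig(
        input_size=cfg["network"]["input_size"],
        n_pool=cfg["network"]["n_pool"],
        channel_schedule=tuple(cfg["network"]["channel_schedule"]),
        se_reduction=cfg["network"]["se_reduction"],
        kernel_size=cfg["network"]["kernel_size"],
    )

    all_metrics = []
    all_probs = []
    all_gts = []
    logs = []
    for fold in splits:
        if fold.fold_id not in cfg["cv"]["folds"]:
            continue
        tc = TrainConfig(seed=train_seed + fold.fold_id, **cfg["train"])
        model = FAZSegmentationModel.from_cohort(
            samples, fold, net_config=net_config, train_config=tc
        )
        result = model.fit(progress=progress)
        result.save(os.path.join(out_dir, f"fold{fold.fold_id}_checkpoint.npz"))
        st = result.state
        logs.append(
            pd.DataFrame(
                {
                    "fold": fold.fold_id,
                    "epoch": np.arange(1, st.epoch + 1),
                    "lr": st.lr_history,
                    "train_loss": st.loss_history,
                    "test_correct_rate": st.test_score_history,
                }
            )
        )
        m = result.metrics(cfg["evaluate"]["threshold"])
        m.insert(0, "fold", fold.fold_id)
        all_metrics.append(m)
        all_probs.extend(result.predict_proba())
        all_gts.extend(s.gt for s in model.test_samples)

    if not all_metrics:
        raise ValueError("cv.folds selected no folds")

    metrics = pd.concat(all_metrics, ignore_index=True)
    step = cfg["evaluate"]["sweep_step"]
    grid = np.round(np.arange(0.0, 1.0 + 1e-9, step), 6)
    sweep = threshold_sweep(all_probs, all_gts, grid=grid,
                            refine_first=cfg["evaluate"]["refine_first"])
    report = group_report(metrics)

    paths = {
        "metrics": os.path.join(out_dir, "metrics.csv"),
        "sweep": os.path.join(out_dir, "sweep.csv"),
        "report": os.path.join(out_dir, "group_report.csv"),
        "train_log": os.path.join(out_dir, "train_log.csv"),
        "sweep_plot": os.path.join(out_dir, "sweep.png"),
        "config": os.path.join(out_dir, "config.json"),
    }
    metrics.to_csv(paths["metrics"], index=False)
    sweep.to_csv(paths["sweep"], index=False)
    report.to_csv(paths["report"], index=False)
    pd.concat(logs, ignore_index=True).to_csv(paths["train_log"], index=False)
    plot_sweep(sweep, paths["sweep_plot"])
    with open(paths["config"], "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)

    pooled = report[report["group"] == "all"].iloc[0]
    return {
        "paths": paths,
        "mean_dsc": float(pooled["dsc_mean"]),
        "sd_dsc": float(pooled["dsc_sd"]),
        "sensitivity": float(pooled["sensitivity_mean"]),
        "specificity": float(pooled["specificity_mean"]),
        "area_r": float(pooled["area_r"]),
        "argmax_threshold": float(sweep.attrs["argmax_threshold"]),
        "n_images_evaluated": int(len(metrics)),
    }
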