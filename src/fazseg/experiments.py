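"""Canned desk-scale experiments.

The scaled-down study is the CPU surrogate for the full clinical
experiment: a 12-subject synthetic cohort (3 high myopes, matching the
study's 12/45 proportion) at 128 x 128, one participant-based stratified
fold (9 train / 3 test subjects, i.e. 81 / 27 images), the reduced network,
and a 15-epoch training run.  It returns the pooled and per-group
segmentation metrics, the predicted-vs-true area correlation, and the
threshold sweep of the held-out probability maps.
"""

from __future__ import annotations

import numpy as np

from .model import FAZSegmentationModel
from .network import NetworkConfig
from .synthetic import generate_cohort
from .train import TrainConfig, make_cv_splits

__all__ = ["scaled_down_study"]


def scaled_down_study(
    seed: int = 0,
    n_subjects: int = 12,
    n_high_myopia: int = 3,
    k_folds: int = 4,
    max_epochs: int = 15,
    threshold: float = 0.44,
    progress=None,
) -> dict:
    """Run the desk-scale train/evaluate experiment and return its results.

    Returns a dict with the fitted ``results`` object, the per-image
    ``metrics`` table, the per-group ``report``, the threshold ``sweep``,
    and scalar summaries (pooled mean/SD DSC, worst per-group mean DSC,
    area Pearson R, best threshold).
    """
    ss = np.random.SeedSequence(seed)
    sim_seed, cv_seed, train_seed = [int(s) for s in ss.generate_state(3) >> 1]

    samples = generate_cohort(n_subjects, n_high_myopia, sim_seed, size=(128, 128))
    subjects = sorted({(s.subject_id, s.myopia_class) for s in samples})
    fold = make_cv_splits(subjects, k=k_folds, seed=cv_seed)[0]

    model = FAZSegmentationModel.from_cohort(
        samples,
        fold,
        net_config=NetworkConfig.scaled_down(),
        train_config=TrainConfig.scaled_down(seed=train_seed, max_epochs=max_epochs),
    )
    results = model.fit(progress=progress)

    metrics = results.metrics(threshold)
    report = results.report(threshold)
    sweep = results.sweep()
    group_means = metrics.groupby("bc_group")["dsc"].mean()
    pooled = report[report["group"] == "all"].iloc[0]

    return {
        "results": results,
        "fold": fold,
        "metrics": metrics,
        "report": report,
        "sweep": sweep,
        "mean_dsc": float(pooled["dsc_mean"]),
        "sd_dsc": float(pooled["dsc_sd"]),
        "min_group_dsc": float(group_means.min()),
        "sensitivity": float(pooled["sensitivity_mean"]),
        "specificity": float(pooled["specificity_mean"]),
        "area_r": float(pooled["area_r"]),
        "best_threshold": float(sweep.attrs["argmax_threshold"]),
    }
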