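"""High-level modelling interface.

``FAZSegmentationModel`` bundles the data (training and held-out samples),
the architecture and the optimization protocol; ``fit()`` runs the training
loop and returns a ``FAZSegmentationResults`` carrying the fitted network,
the optimization trajectory, and evaluation methods (threshold sweep,
per-group metric report, area quantification) plus a printable summary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import SyntheticSample
from .evaluate import group_report, metrics_table, pearson_r, threshold_sweep
from .network import NetworkConfig, SegmentationNetwork, save_checkpoint
from .postprocess import refine
from .preprocess import normalize_minmax
from .quantify import compute_area
from .train import TrainConfig, TrainState, train_model

__all__ = ["FAZSegmentationModel", "FAZSegmentationResults"]


class FAZSegmentationModel:
    """sFAZ segmentation model over a cohort of (image, mask) samples.

    Parameters
    ----------
    train_samples, test_samples : lists of SyntheticSample
        Subject-disjoint training and held-out sets (all nine B/C
        renderings of a subject on the same side).
    net_config : NetworkConfig, optional
        Architecture; defaults to the CPU-scale reduced network when the
        sample size is 128 and to the full network otherwise.
    train_config : TrainConfig, optional
        Optimization protocol; defaults to the scaled-down profile for the
        reduced network.
    """

    def __init__(self, train_samples, test_samples, net_config=None, train_config=None):
        if not train_samples or not test_samples:
            raise ValueError("both train and test samples are required")
        size = train_samples[0].image.shape[0]
        if net_config is None:
            net_config = (NetworkConfig.scaled_down() if size == 128
                          else NetworkConfig(input_size=size))
        if train_config is None:
            train_config = (TrainConfig.scaled_down() if size == 128 else TrainConfig())
        self.train_samples = list(train_samples)
        self.test_samples = list(test_samples)
        self.net_config = net_config
        self.train_config = train_config

    @classmethod
    def from_cohort(cls, samples, fold, net_config=None, train_config=None):
        """Build from a full cohort and a FoldSplit (participant-based)."""
        train = [s for s in samples if s.subject_id in fold.train_subjects]
        test = [s for s in samples if s.subject_id in fold.test_subjects]
        return cls(train, test, net_config=net_config, train_config=train_config)

    def fit(self, progress=None) -> "FAZSegmentationResults":
        network, state = train_model(
            self.train_config, self.net_config, self.train_samples,
            self.test_samples, progress=progress,
        )
        return FAZSegmentationResults(self, network, state)


class FAZSegmentationResults:
    """Fitted model: predictions, evaluation tables, and a summary."""

    def __init__(self, model: FAZSegmentationModel, network: SegmentationNetwork,
                 state: TrainState):
        self.model = model
        self.network = network
        self.state = state
        self._probs = None

    # -- prediction ----------------------------------------------------
    def predict_proba(self, samples=None) -> np.ndarray:
        """Per-pixel sFAZ probabilities for the given (default held-out) samples."""
        if samples is None:
            if self._probs is None:
                self._probs = self._forward(self.model.test_samples)
            return self._probs
        return self._forward(samples)

    def _forward(self, samples):
        imgs = np.stack([normalize_minmax(s.image).astype(np.float32) for s in samples])
        return self.network.predict_proba(imgs)

    def predict_mask(self, samples=None, threshold: float = 0.44):
        """Refined binary masks (largest component, holes filled)."""
        probs = self.predict_proba(samples)
        return [refine(p, threshold) for p in probs]

    def predict_area(self, samples=None, threshold: float = 0.44) -> pd.DataFrame:
        """Physical sFAZ areas (mm^2) of predictions and ground truth."""
        samples = self.model.test_samples if samples is None else samples
        masks = self.predict_mask(samples, threshold)
        rows = []
        for s, m in zip(samples, masks):
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "bc_group": s.bc.group_id,
                    "n_pixels": m.n_foreground,
                    "area_pred_mm2": compute_area(m, s.image.scan_mm).area_mm2,
                    "area_gt_mm2": compute_area(s.gt, s.image.scan_mm).area_mm2,
                }
            )
        return pd.DataFrame(rows)

    # -- evaluation ----------------------------------------------------
    def sweep(self, grid=None, refine_first: bool = True) -> pd.DataFrame:
        """Mean-DSC-vs-threshold curve on the held-out set."""
        gts = [s.gt for s in self.model.test_samples]
        return threshold_sweep(self.predict_proba(), gts, grid=grid,
                               refine_first=refine_first)

    def metrics(self, threshold: float = 0.44) -> pd.DataFrame:
        """Per-image DSC/sensitivity/specificity/area rows on the held-out set."""
        return metrics_table(self.model.test_samples, self.predict_proba(), threshold)

    def report(self, threshold: float = 0.44) -> pd.DataFrame:
        """Per-B/C-group mean +/- SD table plus the pooled row."""
        return group_report(self.metrics(threshold))

    def save(self, path):
        save_checkpoint(path, self.network, meta={
            "best_test_score": float(self.state.best_test_score),
            "epochs": self.state.epoch,
        })

    def summary(self, threshold: float = 0.44) -> str:
        """Human-readable fit and evaluation summary."""
        m = self.metrics(threshold)
        try:
            r, p = pearson_r(m["area_pred"], m["area_gt"])
            r_txt = f"{r:.3f} (p = {p:.2e})"
        except ValueError:
            r_txt = "undefined"
        lines = [
            "sFAZ segmentation results",
            "=" * 48,
            f"network input size      {self.network.config.input_size}",
            f"channel schedule        {list(self.network.config.channel_schedule)}",
            f"train / test images     {len(self.model.train_samples)} / {len(self.model.test_samples)}",
            f"epochs run              {self.state.epoch}",
            f"final learning rate     {self.state.current_lr:.2e}",
            f"checkpoints saved       {self.state.checkpoints_saved}",
            f"best test correct rate  {self.state.best_test_score:.4f}",
            "-" * 48,
            f"threshold               {threshold:.2f}",
            f"DSC (mean +/- SD)       {m['dsc'].mean():.3f} +/- {m['dsc'].std(ddof=0):.3f}",
            f"sensitivity             {m['sensitivity'].mean():.3f} +/- {m['sensitivity'].std(ddof=0):.3f}",
            f"specificity             {m['specificity'].mean():.3f} +/- {m['specificity'].std(ddof=0):.3f}",
            f"area correlation R      {r_txt}",
        ]
        return "\n".join(lines)
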