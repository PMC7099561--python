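"""Network training: Adam, plateau LR halving, best-on-test checkpointing,
and participant-based stratified cross-validation.

Training follows three rules: (1) the learning rate is halved whenever the
training loss fails to reach a new best within a trailing 30-epoch window;
(2) Adam is the optimizer; (3) the model is snapshotted every time the test
"correct rate" (mean pixel accuracy on the held-out subjects) strictly
improves, and the best snapshot is what the run returns.  Cross-validation
partitions *subjects* — all nine B/C renderings of a subject stay on one
side of every fold — stratified on myopia status.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .datatypes import SyntheticSample
from .network import NetworkConfig, SegmentationNetwork
from .preprocess import AUGMENTATIONS, augment_arrays, normalize_minmax
from . import autodiff as ad

__all__ = [
    "TrainConfig",
    "FoldSplit",
    "TrainState",
    "make_cv_splits",
    "lr_schedule_step",
    "maybe_checkpoint",
    "train_model",
    "Adam",
]


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    Defaults follow the reference protocol: initial learning rate 1e-4,
    halved (``lr_factor`` 0.5) after a 30-epoch loss plateau, Adam with the
    standard moment coefficients.  The scaled-down profile used for
    CPU-scale experiments raises the learning rate and shortens the run for
    the much smaller network.
    """

    initial_lr: float = 1e-4
    patience_epochs: int = 30
    lr_factor: float = 0.5
    max_epochs: int = 300
    batch_size: int = 4
    loss_name: str = "bce"  # or "dice"
    seed: int = 0
    augment_training: bool = True

    def __post_init__(self):
        if not 0 < self.lr_factor < 1:
            raise ValueError("lr_factor must lie in (0, 1)")
        if self.patience_epochs < 1:
            raise ValueError("patience_epochs must be >= 1")
        if self.loss_name not in ("bce", "dice"):
            raise ValueError("loss_name must be 'bce' or 'dice'")

    @staticmethod
    def scaled_down(seed: int = 0, max_epochs: int = 15) -> "TrainConfig":
        return TrainConfig(initial_lr=5e-3, max_epochs=max_epochs, batch_size=4, seed=seed)


@dataclass(frozen=True)
class FoldSplit:
    fold_id: int
    test_subjects: tuple
    train_subjects: tuple


@dataclass
class TrainState:
    """Mutable record of the optimization trajectory."""

    epoch: int = 0
    current_lr: float = 0.0
    loss_history: list = field(default_factory=list)
    test_score_history: list = field(default_factory=list)
    best_test_score: float = -np.inf
    checkpoints_saved: int = 0
    lr_history: list = field(default_factory=list)
    lr_reduction_epochs: list = field(default_factory=list)


def make_cv_splits(subjects, k: int = 5, seed: int = 0) -> list:
    """Partition subjects into k folds, stratified on myopia class.

    ``subjects`` is a sequence of (subject_id, myopia_class) pairs.  Within
    each stratum subjects are shuffled and dealt round-robin, so fold sizes
    differ by at most one and each fold's high-myopia count is within one of
    the proportional share.  Deterministic under ``seed``.
    """
    subjects = list(subjects)
    if k > len(subjects):
        raise ValueError("more folds than subjects")
    rng = np.random.default_rng(seed)
    folds = [[] for _ in range(k)]
    offset = 0
    for cls in ("high", "low"):
        stratum = [s for s, c in subjects if c == cls]
        order = rng.permutation(len(stratum))
        for pos, idx in enumerate(order):
            folds[(offset + pos) % k].append(stratum[idx])
        offset += len(stratum)
    all_ids = [s for s, _ in subjects]
    splits = []
    for i, test in enumerate(folds):
        test_set = set(test)
        splits.append(
            FoldSplit(
                fold_id=i + 1,
                test_subjects=tuple(sorted(test)),
                train_subjects=tuple(sorted(s for s in all_ids if s not in test_set)),
            )
        )
    return splits


def lr_schedule_step(state: TrainState, config: TrainConfig) -> float:
    """Halve the LR when the trailing-window loss has not improved.

    If the minimum loss over the last ``patience_epochs`` epochs is no
    better than the best loss achieved before that window, the rate drops by
    ``lr_factor``; otherwise it is unchanged.  With fewer than
    ``patience_epochs + 1`` recorded epochs there is no pre-window best yet,
    so the rate stays.  Each reduction re-anchors the window, so a plateau
    spanning two full windows produces exactly two reductions.
    """
    if not state.loss_history:
        raise ValueError("no completed epochs")
    n = len(state.loss_history)
    w = config.patience_epochs
    anchor = state.lr_reduction_epochs[-1] if state.lr_reduction_epochs else 0
    if n <= w or n - anchor < w:
        return state.current_lr
    window_min = min(state.loss_history[-w:])
    best_before = min(state.loss_history[:-w])
    if window_min >= best_before:
        state.lr_reduction_epochs.append(n)
        return state.current_lr * config.lr_factor
    return state.current_lr


def maybe_checkpoint(state: TrainState, test_score: float, model_params, sink=None) -> TrainState:
    """Snapshot parameters when the test score strictly improves.

    ``sink(model_params)`` performs the persistence; by default the params
    are deep-copied onto ``state.best_params``.  I/O failures propagate.
    """
    if not np.isfinite(test_score):
        raise ValueError("test score must be finite")
    if test_score > state.best_test_score:
        state.best_test_score = test_score
        state.checkpoints_saved += 1
        if sink is not None:
            sink(model_params)
        else:
            state.best_params = copy.deepcopy(model_params)
    return state


class Adam:
    """Adam optimizer over a flat parameter list."""

    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1c = 1 - self.beta1 ** self.t
        b2c = 1 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p.data -= (self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)).astype(p.data.dtype)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def _dice_loss(logits, targets):
    probs = ad.sigmoid(logits)
    t = ad.Tensor(np.asarray(targets, dtype=np.float32))
    inter = (probs * t).sum()
    return 1.0 - (2.0 * inter + 1.0) / (probs.sum() + t.sum() + 1.0)


def _prepare_arrays(samples):
    imgs = np.stack([normalize_minmax(s.image).astype(np.float32) for s in samples])
    gts = np.stack([s.gt.pixels.astype(np.float32) for s in samples])
    return imgs, gts


def correct_rate(network: SegmentationNetwork, images: np.ndarray, gts: np.ndarray) -> float:
    """Mean pixel accuracy of thresholded (0.5) predictions over a set."""
    probs = network.predict_proba(images)
    return float(((probs >= 0.5) == (gts > 0.5)).mean())


def train_model(
    config: TrainConfig,
    net_config: NetworkConfig,
    train: list,
    test: list,
    progress=None,
):
    """Run the full optimization loop and return (best network, TrainState).

    Per epoch: shuffled minibatches of (optionally randomly augmented)
    training pairs -> loss -> Adam update; then the epoch's mean loss is
    recorded, the plateau LR rule applied, the test correct rate computed
    and the parameters snapshotted if it strictly improved.  Training and
    test subject sets must be disjoint.
    """
    train_subj = {s.subject_id for s in train}
    test_subj = {s.subject_id for s in test}
    if train_subj & test_subj:
        raise ValueError(f"subject leakage between train and test: {train_subj & test_subj}")

    rng = np.random.default_rng(config.seed)
    network = SegmentationNetwork(net_config, seed=int(rng.integers(2**31 - 1)))
    optimizer = Adam(network.parameters(), lr=config.initial_lr)
    state = TrainState(current_lr=config.initial_lr)
    state.best_params = network.state_arrays()

    train_imgs, train_gts = _prepare_arrays(train)
    test_imgs, test_gts = _prepare_arrays(test)
    aug_names = list(AUGMENTATIONS)
    n = len(train_imgs)

    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = [], []
            for i in idx:
                img, gt = train_imgs[i], train_gts[i]
                if config.augment_training:
                    img, gt = augment_arrays(img, gt, aug_names[rng.integers(6)])
                xb.append(img)
                yb.append(gt)
            x = np.stack(xb)[:, None]
            y = np.stack(yb)[:, None]
            logits = network.forward_logits(x)
            if config.loss_name == "bce":
                loss = ad.bce_with_logits(logits, y)
            else:
                loss = _dice_loss(logits, y)
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))

        state.epoch = epoch + 1
        state.loss_history.append(float(np.mean(losses)))
        new_lr = lr_schedule_step(state, config)
        state.current_lr = new_lr
        optimizer.lr = new_lr
        state.lr_history.append(new_lr)

        score = correct_rate(network, test_imgs, test_gts)
        state.test_score_history.append(score)
        maybe_checkpoint(state, score, network.state_arrays())
        if progress is not None:
            progress(state)

    network.load_state_arrays(state.best_params)
    network.train(False)
    return network, state
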