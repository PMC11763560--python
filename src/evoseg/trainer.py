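"""Build, train and evaluate segmentation networks from genomes.

The network follows the canonical U-Net reading of the genome: two 3x3
convolutions (ReLU) per level, 2x2 max pooling, learned transposed-conv
upsampling, optional skip concatenation, dropout once per level, sigmoid
output.  Training minimizes mean per-pixel binary cross-entropy with Adam
(default learning rate 1e-4), monitors validation Dice on predictions
binarized at 0.5, and early-stops on validation loss with best-weight
restoration.

``UNetSegmenter`` wraps the harness as a scikit-learn-style estimator:
``fit(X, y)`` on image/mask arrays, ``predict(X)`` for binary masks,
``score(X, y)`` for mean Dice.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.model_selection import KFold

from .genome import Genome, deserialize_genome, serialize_genome
from .nn.network import UNet, _sigmoid, check_divisibility
from .operators import dice_coefficient
from .phantom import SegmentationDataset

__all__ = [
    "TrainConfig",
    "ModelSpec",
    "build_model",
    "bce_loss",
    "train",
    "kfold_cv",
    "predict_mask",
    "UNetSegmenter",
    "save_model",
    "load_model",
]

_PROB_FLOOR = 1e-7  # keeps log() finite in the cross-entropy


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    ``learning_rate`` defaults to the Adam step size 1e-4 used for full
    refinement runs; short desk-scale runs typically raise it.
    ``early_stop_patience`` counts epochs without a validation-loss
    improvement larger than ``min_delta`` before stopping (best weights
    restored).
    """

    learning_rate: float = 1e-4
    max_epochs: int = 30
    batch_size: int = 8
    early_stop_patience: int = 10
    min_delta: float = 0.0
    binarize_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass
class ModelSpec:
    """A genome realized as a network for a fixed input size."""

    genome: Genome
    input_height: int
    input_width: int
    net: UNet

    @property
    def n_params(self) -> int:
        return self.net.n_params


def build_model(genome: Genome, input_shape: tuple[int, int], seed: int = 0) -> ModelSpec:
    """Realize a genome as a trainable network.

    Raises if the input sides are not divisible by ``2**(depth-1)``, the
    factor the pooling/upsampling pyramid requires.
    """
    h, w = int(input_shape[0]), int(input_shape[1])
    check_divisibility(h, w, genome.depth)
    return ModelSpec(genome=genome, input_height=h, input_width=w,
                     net=UNet(genome, seed=seed))


def bce_loss(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean per-pixel binary cross-entropy on probabilities.

    Predictions are floored away from {0, 1} by 1e-7 so the logarithms
    stay finite.
    """
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"shape mismatch: {y_true.shape} vs {y_pred.shape}")
    p = np.clip(y_pred, _PROB_FLOOR, 1.0 - _PROB_FLOOR)
    return float(-np.mean(y_true * np.log(p) + (1.0 - y_true) * np.log(1.0 - p)))


def _mean_image_dice(masks: np.ndarray, probs: np.ndarray, threshold: float) -> float:
    scores = [
        dice_coefficient(masks[i], probs[i] > threshold)
        for i in range(masks.shape[0])
    ]
    return float(np.mean(scores))


def train(
    model: ModelSpec,
    train_data: SegmentationDataset,
    val_data: SegmentationDataset,
    cfg: TrainConfig,
) -> tuple[ModelSpec, float, pd.DataFrame]:
    """Optimize a model on a train/validation split.

    Returns the model with its best-validation-loss weights restored, the
    best validation Dice observed across epochs, and the per-epoch log
    (epoch, train_loss, val_loss, val_dice).
    """
    if len(train_data) == 0 or len(val_data) == 0:
        raise ValueError("both sides of the split must be nonempty")
    net = model.net
    from .nn.layers import Adam

    opt = Adam(net._all_layers(), lr=cfg.learning_rate)
    net.init_head_bias(float(train_data.masks.mean()))
    rng = np.random.default_rng(cfg.seed)
    best_val_loss = np.inf
    best_val_dice = 0.0
    best_state = net.state_dict()
    bad_epochs = 0
    rows = []
    n = len(train_data)
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = train_data.images[idx]
            yb = train_data.masks[idx].astype(np.float32)
            logits = net.forward(xb, train=True)
            probs = _sigmoid(logits)
            loss = bce_loss(yb, probs)
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged: non-finite loss at epoch {epoch}")
            epoch_losses.append(loss)
            dlogits = ((probs - yb) / probs.size).astype(np.float32)
            net.backward(dlogits)
            opt.step()
        val_probs = net.predict_proba(val_data.images)
        val_loss = bce_loss(val_data.masks.astype(np.float64), val_probs)
        val_dice = _mean_image_dice(val_data.masks, val_probs, cfg.binarize_threshold)
        rows.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(epoch_losses)),
                "val_loss": val_loss,
                "val_dice": val_dice,
            }
        )
        best_val_dice = max(best_val_dice, val_dice)
        if val_loss < best_val_loss - cfg.min_delta:
            best_val_loss = val_loss
            best_state = net.state_dict()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.early_stop_patience:
                break
    net.load_state_dict(best_state)
    return model, best_val_dice, pd.DataFrame(rows)


def kfold_cv(
    genome: Genome,
    dataset: SegmentationDataset,
    k: int,
    cfg: TrainConfig,
) -> tuple[list[float], float, float]:
    """Seeded k-fold cross-validation of a genome.

    Folds partition the dataset (disjoint, exhaustive, reproducible for a
    given ``cfg.seed``).  Returns the per-fold best validation Dice scores
    with their mean and (population) standard deviation.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(dataset) < k:
        raise ValueError(f"dataset of {len(dataset)} samples cannot form {k} folds")
    splitter = KFold(n_splits=k, shuffle=True, random_state=cfg.seed)
    scores = []
    h, w = dataset.images.shape[1:]
    for fold_i, (train_idx, val_idx) in enumerate(splitter.split(dataset.images)):
        model = build_model(genome, (h, w), seed=cfg.seed + fold_i)
        _, best_dice, _ = train(
            model, dataset.subset(train_idx), dataset.subset(val_idx), cfg
        )
        scores.append(best_dice)
    return scores, float(np.mean(scores)), float(np.std(scores))


def predict_mask(model: ModelSpec, image: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary mask for one image: sigmoid probabilities thresholded."""
    image = np.asarray(image, dtype=np.float32)
    if image.shape != (model.input_height, model.input_width):
        raise ValueError(
            f"image shape {image.shape} does not match model input "
            f"({model.input_height}, {model.input_width})"
        )
    probs = model.net.predict_proba(image[None])[0]
    return (probs > threshold).astype(np.uint8)


class UNetSegmenter(BaseEstimator):
    """Scikit-learn-style segmentation estimator for one genome.

    ``fit(X, y)`` takes images ``(n, H, W)`` in [0, 1] and binary masks of
    the same shape, holds out ``validation_fraction`` of the samples, and
    trains the genome's network.  ``predict(X)`` returns binary masks and
    ``score(X, y)`` the mean per-image Dice.

    Fitted attributes: ``model_`` (the realized network), ``best_val_dice_``,
    ``epoch_log_`` (per-epoch DataFrame), ``n_params_``.
    """

    def __init__(
        self,
        genome: Genome | None = None,
        learning_rate: float = 1e-4,
        max_epochs: int = 30,
        batch_size: int = 8,
        early_stop_patience: int = 10,
        min_delta: float = 0.0,
        binarize_threshold: float = 0.5,
        validation_fraction: float = 0.2,
        seed: int = 0,
    ) -> None:
        self.genome = genome
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.early_stop_patience = early_stop_patience
        self.min_delta = min_delta
        self.binarize_threshold = binarize_threshold
        self.validation_fraction = validation_fraction
        self.seed = seed

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate,
            max_epochs=self.max_epochs,
            batch_size=self.batch_size,
            early_stop_patience=self.early_stop_patience,
            min_delta=self.min_delta,
            binarize_threshold=self.binarize_threshold,
            seed=self.seed,
        )

    def fit(self, X, y) -> "UNetSegmenter":
        if self.genome is None:
            raise ValueError("UNetSegmenter requires a genome")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")
        data = SegmentationDataset(np.asarray(X), np.asarray(y))
        rng = np.random.default_rng(self.seed)
        order = rng.permutation(len(data))
        n_val = max(1, int(round(self.validation_fraction * len(data))))
        if n_val >= len(data):
            raise ValueError("validation split would consume the whole dataset")
        val_idx, train_idx = order[:n_val], order[n_val:]
        h, w = data.images.shape[1:]
        model = build_model(self.genome, (h, w), seed=self.seed)
        model, best_dice, log = train(
            model, data.subset(train_idx), data.subset(val_idx), self._train_config()
        )
        self.model_ = model
        self.best_val_dice_ = best_dice
        self.epoch_log_ = log
        self.n_params_ = model.n_params
        return self

    def predict_proba(self, X) -> np.ndarray:
        return self.model_.net.predict_proba(np.asarray(X, dtype=np.float32))

    def predict(self, X) -> np.ndarray:
        probs = self.predict_proba(X)
        return (probs > self.binarize_threshold).astype(np.uint8)

    def score(self, X, y) -> float:
        probs = self.predict_proba(X)
        masks = (np.asarray(y) > 0).astype(np.uint8)
        return _mean_image_dice(masks, probs, self.binarize_threshold)


def save_model(model: ModelSpec, path) -> None:
    """Checkpoint: NPZ of weights plus the genome JSON alongside."""
    path = Path(path)
    state = model.net.state_dict()
    np.savez(
        path,
        __genome__=np.array(serialize_genome(model.genome)),
        __input__=np.array([model.input_height, model.input_width]),
        **state,
    )


def load_model(path) -> ModelSpec:
    with np.load(Path(path), allow_pickle=False) as data:
        genome = deserialize_genome(str(data["__genome__"]))
        h, w = (int(v) for v in data["__input__"])
        model = build_model(genome, (h, w))
        state = {k: data[k] for k in data.files if not k.startswith("__")}
    model.net.load_state_dict(state)
    return model
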