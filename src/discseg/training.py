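"""Training loop: Adam, per-pixel BCE, per-epoch loss logging.

The optimizer settings mirror the study conditions — Adam with learning
rate 1.0e-3 and the same configuration applied to all three network
families so their comparison is not confounded by tuning. The loss is
per-pixel binary cross-entropy, the canonical pairing with a sigmoid
pixel classifier; soft Dice is available behind ``TrainConfig.loss`` but
is deliberately not the default, so the Dice evaluation metric remains
independent of the objective optimized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .architectures import SegmentationModel
from .nn import Adam
from .nn.losses import LOSSES, bce_loss

__all__ = ["TrainConfig", "LossCurve", "bce_loss", "train"]


@dataclass
class TrainConfig:
    """Optimizer and schedule settings for one training run."""

    learning_rate: float = 1e-3
    epochs: int = 2000
    batch_size: int = 8
    loss: str = "bce"
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.loss not in LOSSES:
            raise ValueError(f"loss must be one of {sorted(LOSSES)}")


@dataclass
class LossCurve:
    """Per-epoch mean training loss, with optional validation loss."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] | None = None

    def __len__(self) -> int:
        return len(self.train_loss)

    def to_frame(self) -> pd.DataFrame:
        d = {"epoch": np.arange(1, len(self.train_loss) + 1), "train_loss": self.train_loss}
        if self.val_loss is not None:
            d["val_loss"] = self.val_loss
        return pd.DataFrame(d)

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _epoch_loss(model: SegmentationModel, x: np.ndarray, y: np.ndarray,
                loss_fn, batch_size: int) -> float:
    total, n = 0.0, 0
    for s in range(0, len(x), batch_size):
        xb, yb = x[s : s + batch_size], y[s : s + batch_size]
        p = model.forward(xb[..., None], train=False)[..., 0]
        loss, _ = loss_fn(p, yb)
        total += loss * len(xb)
        n += len(xb)
    return total / n


def train(
    model: SegmentationModel,
    train_images: np.ndarray,
    train_masks: np.ndarray,
    config: TrainConfig,
    val_images: np.ndarray | None = None,
    val_masks: np.ndarray | None = None,
    checkpoint_dir: str | Path | None = None,
) -> LossCurve:
    """Fit ``model`` in place on NHW image/mask arrays; returns the loss curve.

    Shuffle order is drawn from ``config.seed`` and the whole loop is
    deterministic, so identical configs reproduce identical curves.
    When ``checkpoint_dir`` is given, the best (lowest training loss) and
    final weights are written there. Aborts with a diagnostic if the loss
    goes non-finite.
    """
    x = np.asarray(train_images, dtype=np.float32)
    y = np.asarray(train_masks, dtype=np.float32)
    if len(x) == 0:
        raise ValueError("training set is empty")
    if x.shape != y.shape:
        raise ValueError(f"image array {x.shape} and mask array {y.shape} differ")

    loss_fn = LOSSES[config.loss]
    opt = Adam(model.parameters(), learning_rate=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    curve = LossCurve(val_loss=[] if val_images is not None else None)
    best = np.inf

    ckpt = Path(checkpoint_dir) if checkpoint_dir is not None else None
    if ckpt is not None:
        ckpt.mkdir(parents=True, exist_ok=True)

    for epoch in range(config.epochs):
        order = rng.permutation(len(x))
        total, n_seen = 0.0, 0
        for s in range(0, len(x), config.batch_size):
            sel = order[s : s + config.batch_size]
            xb = x[sel][..., None]
            yb = y[sel]
            p = model.forward(xb, train=True)[..., 0]
            loss, dp = loss_fn(p, yb)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch + 1}: {loss}"
                )
            opt.zero_grad()
            model.backward(dp[..., None])
            opt.step()
            total += loss * len(sel)
            n_seen += len(sel)
        epoch_loss = total / n_seen
        curve.train_loss.append(epoch_loss)
        if val_images is not None:
            curve.val_loss.append(
                _epoch_loss(model, np.asarray(val_images, dtype=np.float32),
                            np.asarray(val_masks, dtype=np.float32),
                            loss_fn, config.batch_size)
            )
        if ckpt is not None and epoch_loss < best:
            best = epoch_loss
            model.save(ckpt / "best")
    if ckpt is not None:
        model.save(ckpt / "final")
        curve.save(ckpt / "loss_curve.csv")
    return curve
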