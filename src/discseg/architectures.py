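"""The three encoder-decoder segmentation networks.

Three families share one contract — grayscale patch in, per-pixel
foreground probability map of the same spatial shape out, sigmoid head:

* **3DiscNet** — an asymmetric encoder-decoder: the encoder applies
  ``depth`` convolution/pooling stages with dropout behind both the
  convolutions and the poolings; the decoder is shallower, with
  ``depth - 1`` learned (transposed-convolution) upsampling stages and a
  final non-learned 2x nearest-neighbour upsampling. The published layer
  schedule is given only graphically, so the builder is configuration
  driven and this default schedule is a reconstruction, not ground truth.
* **U-Net** — symmetric encoder/decoder with two convolutions per stage,
  transposed-convolution upsampling, and skip connections that concatenate
  each encoder feature map onto the same-resolution decoder stage.
* **SegNet-Basic** — constant-width encoder whose max-pooling layers store
  the argmax index of every pooling window; the decoder upsamples
  exclusively by scattering values back through those indices
  (no learned upsampling, no skips), then convolves.

All three end in a 1-channel 1x1 convolution + sigmoid, replacing the
soft-max classifiers of the original U-Net/SegNet designs, because the
task is binary (disc vs background).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .nn import (
    Conv2D,
    ConvTranspose2x2,
    Dropout,
    MaxPool2D,
    MaxUnpool2D,
    NearestUpsample2x,
    Param,
    ReLU,
    Sigmoid,
)

FAMILIES = ("threediscnet", "unet", "segnet_basic")


@dataclass
class SegmentationModelSpec:
    """Architecture family plus the knobs shared by all three builders.

    ``input_size`` must be divisible by ``2**depth`` so every pooled
    resolution is integral. ``dropout_rate`` defaults to 0.3, applied
    behind convolutional and max-pooling layers where the family uses
    dropout. The output activation is always sigmoid.
    """

    family: str
    input_size: tuple[int, int] = (224, 256)
    depth: int = 4
    base_filters: int = 64
    kernel_size: int = 3
    dropout_rate: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        h, w = self.input_size
        m = 2**self.depth
        if h % m or w % m:
            raise ValueError(
                f"input size {self.input_size} not divisible by 2^depth = {m}"
            )
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["input_size"] = list(self.input_size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentationModelSpec":
        d = dict(d)
        d["input_size"] = tuple(d["input_size"])
        return cls(**d)


class SegmentationModel:
    """Base class: layer bookkeeping, prediction, (de)serialization."""

    def __init__(self, spec: SegmentationModelSpec):
        self.spec = spec
        self.rng = np.random.default_rng(spec.seed)

    def _all_layers(self) -> list:
        raise NotImplementedError

    def parameters(self) -> list[Param]:
        out = []
        for layer in self._all_layers():
            out.extend(layer.params())
        return out

    def n_params(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def save(self, path: str | Path) -> None:
        """Write weights as ``<path>.npz`` and the spec as ``<path>.json``."""
        path = Path(path)
        arrays = {f"p{i}": p.value for i, p in enumerate(self.parameters())}
        np.savez(path.with_suffix(".npz"), **arrays)
        path.with_suffix(".json").write_text(json.dumps(self.spec.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SegmentationModel":
        path = Path(path)
        spec = SegmentationModelSpec.from_dict(json.loads(path.with_suffix(".json").read_text()))
        model = build_model(spec)
        with np.load(path.with_suffix(".npz")) as data:
            params = model.parameters()
            if len(data.files) != len(params):
                raise ValueError("checkpoint does not match the architecture spec")
            for i, p in enumerate(params):
                arr = data[f"p{i}"]
                if arr.shape != p.value.shape:
                    raise ValueError("checkpoint tensor shape mismatch")
                p.value[...] = arr
        return model


def _as_batch(patch: np.ndarray) -> tuple[np.ndarray, bool, bool]:
    x = np.asarray(patch, dtype=np.float32)
    squeeze_batch = squeeze_ch = False
    if x.ndim == 2:
        x = x[None, :, :, None]
        squeeze_batch = squeeze_ch = True
    elif x.ndim == 3:
        x = x[..., None]
        squeeze_ch = True
    return x, squeeze_batch, squeeze_ch


def predict(model: SegmentationModel, patch: np.ndarray) -> np.ndarray:
    """Foreground-probability map for a patch or batch of patches.

    Runs in inference mode (dropout disabled), so repeated calls on the
    same input return identical maps. Accepts ``(H, W)``, ``(N, H, W)``
    or ``(N, H, W, 1)`` input and mirrors that shape in the output.
    """
    x, squeeze_batch, squeeze_ch = _as_batch(patch)
    if x.shape[1:3] != tuple(model.spec.input_size):
        raise ValueError(
            f"patch spatial shape {x.shape[1:3]} does not match model input "
            f"{tuple(model.spec.input_size)}"
        )
    y = model.forward(x, train=False)
    if squeeze_ch:
        y = y[..., 0]
    if squeeze_batch:
        y = y[0]
    return y


class _Chain:
    """Run a layer list forward/backward, honoring SegNet index pairing."""

    @staticmethod
    def forward(layers, x, train):
        for layer in layers:
            x = layer.forward(x, train=train)
        return x

    @staticmethod
    def backward(layers, dy):
        for layer in reversed(layers):
            dy = layer.backward(dy)
        return dy


class ThreeDiscNet(SegmentationModel):
    """Asymmetric encoder-decoder with dropout behind convs and poolings."""

    def __init__(self, spec: SegmentationModelSpec):
        super().__init__(spec)
        k, rate = spec.kernel_size, spec.dropout_rate
        f = [spec.base_filters * 2**d for d in range(spec.depth)]
        layers: list = []
        in_ch = 1
        for d in range(spec.depth):
            layers += [
                Conv2D(in_ch, f[d], k, self.rng),
                ReLU(),
                Dropout(rate, self.rng),
                MaxPool2D(),
                Dropout(rate, self.rng),
            ]
            in_ch = f[d]
        layers += [Conv2D(in_ch, f[-1], k, self.rng), ReLU(), Dropout(rate, self.rng)]
        in_ch = f[-1]
        # decoder: depth-1 learned upsamplings, then one non-learned 2x stage
        for d in range(spec.depth - 1, -1, -1):
            if d == 0:
                layers += [NearestUpsample2x(), Conv2D(in_ch, f[0], k, self.rng), ReLU()]
                in_ch = f[0]
            else:
                layers += [
                    ConvTranspose2x2(in_ch, f[d], self.rng),
                    Conv2D(f[d], f[d], k, self.rng),
                    ReLU(),
                ]
                in_ch = f[d]
        layers += [Conv2D(in_ch, 1, 1, self.rng), Sigmoid()]
        self.layers = layers

    def _all_layers(self):
        return self.layers

    def forward(self, x, train=False):
        return _Chain.forward(self.layers, x, train)

    def backward(self, dy):
        return _Chain.backward(self.layers, dy)


class UNet(SegmentationModel):
    """Symmetric encoder-decoder with concatenating skip connections."""

    def __init__(self, spec: SegmentationModelSpec):
        super().__init__(spec)
        k = spec.kernel_size
        f = [spec.base_filters * 2**d for d in range(spec.depth + 1)]
        self.enc_blocks = []
        in_ch = 1
        for d in range(spec.depth):
            self.enc_blocks.append(
                [
                    Conv2D(in_ch, f[d], k, self.rng),
                    ReLU(),
                    Conv2D(f[d], f[d], k, self.rng),
                    ReLU(),
                ]
            )
            in_ch = f[d]
        self.pools = [MaxPool2D() for _ in range(spec.depth)]
        self.bottleneck = [
            Conv2D(in_ch, f[spec.depth], k, self.rng),
            ReLU(),
            Dropout(spec.dropout_rate, self.rng),
            Conv2D(f[spec.depth], f[spec.depth], k, self.rng),
            ReLU(),
        ]
        in_ch = f[spec.depth]
        self.ups = []
        self.dec_blocks = []
        for d in range(spec.depth - 1, -1, -1):
            self.ups.append(ConvTranspose2x2(in_ch, f[d], self.rng))
            self.dec_blocks.append(
                [
                    Conv2D(2 * f[d], f[d], k, self.rng),  # skip doubles the channels
                    ReLU(),
                    Conv2D(f[d], f[d], k, self.rng),
                    ReLU(),
                ]
            )
            in_ch = f[d]
        self.head = [Conv2D(in_ch, 1, 1, self.rng), Sigmoid()]

    def _all_layers(self):
        out = []
        for blk in self.enc_blocks:
            out += blk
        out += self.pools + self.bottleneck + self.ups
        for blk in self.dec_blocks:
            out += blk
        return out + self.head

    def forward(self, x, train=False):
        skips = []
        for blk, pool in zip(self.enc_blocks, self.pools):
            x = _Chain.forward(blk, x, train)
            skips.append(x)
            x = pool.forward(x, train=train)
        x = _Chain.forward(self.bottleneck, x, train)
        self._skip_ch = []
        for up, blk, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            x = up.forward(x, train=train)
            self._skip_ch.append(skip.shape[-1])
            x = np.concatenate([skip, x], axis=-1)
            x = _Chain.forward(blk, x, train)
        return _Chain.forward(self.head, x, train)

    def backward(self, dy):
        dy = _Chain.backward(self.head, dy)
        dskips = []
        for up, blk, ch in zip(reversed(self.ups), reversed(self.dec_blocks), reversed(self._skip_ch)):
            dy = _Chain.backward(blk, dy)
            dskips.append(dy[..., :ch])
            dy = up.backward(dy[..., ch:])
        dy = _Chain.backward(self.bottleneck, dy)
        for blk, pool, dskip in zip(reversed(self.enc_blocks), reversed(self.pools), reversed(dskips)):
            dy = pool.backward(dy) + dskip
            dy = _Chain.backward(blk, dy)
        return dy

    def concat_channels(self) -> list[tuple[int, int]]:
        """(encoder, decoder) channel counts at each concatenation, shallowest last."""
        f = [self.spec.base_filters * 2**d for d in range(self.spec.depth)]
        return [(f[d], f[d]) for d in range(self.spec.depth - 1, -1, -1)]


class SegNetBasic(SegmentationModel):
    """Constant-width encoder-decoder upsampling via stored pooling indices.

    Follows the original SegNet-Basic design — constant filter width,
    conv/ReLU/pool encoder stages, index-driven decoder, no dropout —
    with the soft-max classifier replaced by a 1-channel sigmoid.
    """

    def __init__(self, spec: SegmentationModelSpec):
        super().__init__(spec)
        k, f = spec.kernel_size, spec.base_filters
        self.layers: list = []
        pools = []
        in_ch = 1
        for _ in range(spec.depth):
            pool = MaxPool2D()
            self.layers += [Conv2D(in_ch, f, k, self.rng), ReLU(), pool]
            pools.append(pool)
            in_ch = f
        for pool in reversed(pools):
            self.layers += [MaxUnpool2D(pool), Conv2D(in_ch, f, k, self.rng), ReLU()]
        self.layers += [Conv2D(f, 1, 1, self.rng), Sigmoid()]

    def _all_layers(self):
        return self.layers

    def forward(self, x, train=False):
        return _Chain.forward(self.layers, x, train)

    def backward(self, dy):
        return _Chain.backward(self.layers, dy)


_BUILDERS = {
    "threediscnet": ThreeDiscNet,
    "unet": UNet,
    "segnet_basic": SegNetBasic,
}


def build_model(spec: SegmentationModelSpec) -> SegmentationModel:
    """Construct the network named by ``spec.family``."""
    return _BUILDERS[spec.family](spec)


def build_threediscnet(spec: SegmentationModelSpec) -> ThreeDiscNet:
    if spec.family != "threediscnet":
        raise ValueError(f"spec.family is {spec.family!r}, expected 'threediscnet'")
    return ThreeDiscNet(spec)


def build_unet(spec: SegmentationModelSpec) -> UNet:
    if spec.family != "unet":
        raise ValueError(f"spec.family is {spec.family!r}, expected 'unet'")
    return UNet(spec)


def build_segnet_basic(spec: SegmentationModelSpec) -> SegNetBasic:
    if spec.family != "segnet_basic":
        raise ValueError(f"spec.family is {spec.family!r}, expected 'segnet_basic'")
    return SegNetBasic(spec)
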