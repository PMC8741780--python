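"""Image/mask I/O, ROI cropping, patch resizing, and train/test splits.

Conventions implemented here:

* masks are RGB images whose disc pixels are filled white
  (RGB 255, 255, 255); a pixel decodes to foreground iff **all** channels
  reach ``white_threshold`` (default 128), which survives JPEG ringing;
* the region of interest is a fixed 161 x 184 pixel box (top-left origin,
  0-based, half-open ranges) cropped from the nominal 512 x 512 slice;
* cropped ROIs are resized to the network input resolution, 224 x 256 by
  default — bilinear for images, nearest-neighbour for masks so labels
  stay binary;
* splits put ``floor(fraction * n)`` samples in the training set, the
  rule consistent with 111 -> 88/23, 106 -> 84/22 and 217 -> 173/44.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize as _sk_resize

from .phantom import Sample

DEFAULT_ROI = (161, 184)
DEFAULT_INPUT_SIZE = (224, 256)
WHITE_THRESHOLD = 128

_PIL_EXTS = {".png", ".jpg", ".jpeg"}
_DICOM_EXTS = {".dcm", ".dicom"}


@dataclass
class ROISpec:
    """Fixed crop window: 0-based top-left ``origin`` plus height/width."""

    origin: tuple[int, int] = (0, 0)
    height: int = DEFAULT_ROI[0]
    width: int = DEFAULT_ROI[1]

    @classmethod
    def centered(cls, image_shape: tuple[int, int], height: int | None = None,
                 width: int | None = None) -> "ROISpec":
        """ROI of the default (or given) size centered in the image."""
        h = height if height is not None else DEFAULT_ROI[0]
        w = width if width is not None else DEFAULT_ROI[1]
        ih, iw = image_shape
        return cls(origin=((ih - h) // 2, (iw - w) // 2), height=h, width=w)


@dataclass
class PatchPair:
    """Model-ready image/mask pair; image intensities scaled to [0, 1]."""

    image_patch: np.ndarray
    mask_patch: np.ndarray
    sample_id: str = ""
    roi: ROISpec | None = None

    def __post_init__(self):
        if self.image_patch.shape != self.mask_patch.shape:
            raise ValueError("image and mask patches must share shape")


def read_grayscale(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG/DICOM slice as an 8-bit grayscale grid.

    RGB inputs are converted by ITU-R 601 luminance. DICOM pixel data is
    min-max scaled to 0-255 over the slice; multi-frame DICOM is rejected.
    """
    path = Path(path)
    ext = path.suffix.lower()
    if ext in _PIL_EXTS:
        with Image.open(path) as im:
            if im.mode in ("L", "I;16", "I"):
                arr = np.asarray(im)
                if arr.dtype != np.uint8:
                    arr = _minmax_to_uint8(arr.astype(np.float64))
                return arr
            return np.asarray(im.convert("RGB").convert("L"))
    if ext in _DICOM_EXTS:
        import pydicom

        ds = pydicom.dcmread(path)
        if int(getattr(ds, "NumberOfFrames", 1)) > 1:
            raise ValueError(f"multi-frame DICOM not supported: {path}")
        return _minmax_to_uint8(ds.pixel_array.astype(np.float64))
    raise ValueError(f"unsupported image format {ext!r} for {path}")


def _minmax_to_uint8(arr: np.ndarray) -> np.ndarray:
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    return np.rint((arr - lo) / (hi - lo) * 255.0).astype(np.uint8)


def write_grayscale(path: str | Path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="L").save(path)


def encode_mask(mask: np.ndarray) -> np.ndarray:
    """Binary grid -> RGB grid with foreground exactly (255, 255, 255)."""
    m = (np.asarray(mask) > 0).astype(np.uint8) * 255
    return np.stack([m, m, m], axis=-1)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    Image.fromarray(encode_mask(mask), mode="RGB").save(path)


def decode_mask(rgb_image: np.ndarray, white_threshold: int = WHITE_THRESHOLD) -> np.ndarray:
    """Foreground iff every channel >= ``white_threshold``; returns uint8 {0,1}."""
    arr = np.asarray(rgb_image)
    if arr.ndim != 3 or arr.shape[-1] < 3:
        raise ValueError(f"expected a 3-channel image, got shape {arr.shape}")
    return np.all(arr[..., :3] >= white_threshold, axis=-1).astype(np.uint8)


def read_mask(path: str | Path, white_threshold: int = WHITE_THRESHOLD) -> np.ndarray:
    with Image.open(path) as im:
        return decode_mask(np.asarray(im.convert("RGB")), white_threshold)


def crop_roi(image: np.ndarray, roi: ROISpec) -> np.ndarray:
    """Exact subarray copy of the ROI rectangle (no interpolation)."""
    r0, c0 = roi.origin
    r1, c1 = r0 + roi.height, c0 + roi.width
    h, w = image.shape[:2]
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
        raise ValueError(
            f"ROI rows [{r0},{r1}) cols [{c0},{c1}) exceeds image bounds {h}x{w}"
        )
    return image[r0:r1, c0:c1].copy()


def resize_patch(grid: np.ndarray, target_size: tuple[int, int], mode: str = "image") -> np.ndarray:
    """Resize to ``target_size``; bilinear for images, nearest for masks."""
    th, tw = target_size
    if th < 1 or tw < 1:
        raise ValueError("target dimensions must be >= 1")
    if grid.size == 0:
        raise ValueError("cannot resize an empty grid")
    if mode == "image":
        out = _sk_resize(
            grid.astype(np.float64), (th, tw), order=1, mode="edge",
            anti_aliasing=False, preserve_range=True,
        )
        return out
    if mode == "mask":
        out = _sk_resize(
            grid, (th, tw), order=0, mode="edge", anti_aliasing=False,
            preserve_range=True,
        )
        return (out > 0).astype(np.uint8)
    raise ValueError(f"mode must be 'image' or 'mask', got {mode!r}")


def preprocess_sample(
    sample: Sample,
    roi: ROISpec | None = None,
    input_size: tuple[int, int] = DEFAULT_INPUT_SIZE,
) -> PatchPair:
    """ROI-crop then resize one sample into a network-ready patch pair."""
    if roi is None:
        roi = ROISpec.centered(sample.image.shape)
    img = resize_patch(crop_roi(sample.image, roi), input_size, mode="image") / 255.0
    msk = resize_patch(crop_roi(sample.mask, roi), input_size, mode="mask")
    sid = f"{sample.subject_id}_{sample.side}_{sample.jaw_state}"
    return PatchPair(image_patch=img, mask_patch=msk, sample_id=sid, roi=roi)


def patches_to_arrays(pairs: list[PatchPair]) -> tuple[np.ndarray, np.ndarray]:
    """Stack patch pairs into float32 NHW image/mask arrays for training."""
    x = np.stack([p.image_patch for p in pairs]).astype(np.float32)
    y = np.stack([p.mask_patch for p in pairs]).astype(np.float32)
    return x, y


@dataclass
class DatasetSplit:
    """Disjoint train/test index sets over a sample list."""

    train: list
    test: list
    fraction: float
    seed: int
    stratum: str = "both"

    def save(self, path: str | Path, ids: list[str] | None = None) -> None:
        rows = [{"index": i, "role": "train"} for i in self.train] + [
            {"index": i, "role": "test"} for i in self.test
        ]
        df = pd.DataFrame(rows)
        if ids is not None:
            df["sample_id"] = [ids[i] for i in df["index"]]
        df.to_csv(path, index=False)


def split_dataset(
    samples: list,
    fraction: float = 0.8,
    seed: int = 0,
    stratum: str = "both",
) -> DatasetSplit:
    """Random split with ``floor(fraction * n)`` training samples.

    ``stratum`` restricts the pool by sample group before splitting:
    ``normal``, ``displaced``, or ``both`` (the full pool, split as one).
    Returned ``train``/``test`` are indices into the *original* list.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    if stratum not in ("normal", "displaced", "both"):
        raise ValueError("stratum must be 'normal', 'displaced' or 'both'")
    if stratum == "both":
        idx = list(range(len(samples)))
    else:
        idx = [i for i, s in enumerate(samples) if _group_of(s) == stratum]
    n = len(idx)
    if n < 2:
        raise ValueError(f"need at least 2 samples in stratum {stratum!r}, got {n}")
    order = np.random.default_rng(seed).permutation(n)
    n_train = math.floor(fraction * n)
    train = [idx[i] for i in order[:n_train]]
    test = [idx[i] for i in order[n_train:]]
    return DatasetSplit(train=train, test=test, fraction=fraction, seed=seed, stratum=stratum)


def _group_of(sample) -> str:
    if isinstance(sample, Sample):
        return sample.group
    if isinstance(sample, dict):
        return sample["group"]
    return getattr(sample, "group")
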