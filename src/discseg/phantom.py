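"""Synthetic sagittal TMJ phantoms with exact ground-truth disc masks.

The articular disc appears on proton density-weighted sagittal MR images
as a low-signal biconcave structure sitting between the mandibular
condyle and the temporal fossa. Clinical images cannot be redistributed,
so this module draws the statistical skeleton of such a dataset:

* a dark biconcave disc (an ellipse with two symmetric elliptical
  "bites" removed above and below its long axis), rotated to a
  per-subject orientation;
* a bright condyle-like ellipse beneath the disc, which translates
  forward and downward in the open-mouth jaw state;
* a mid-gray fossa/soft-tissue background, degraded by a low-order
  polynomial bias field, Gaussian blur, and additive Gaussian noise.

The mask is the exact pixel support of the rendered disc *before* any
degradation, stored with disc pixels filled white (RGB 255, 255, 255)
— the convention used for expert annotations made in image editors.
"Displaced" subjects have the disc shifted anteriorly (toward the face,
i.e. lower column indices) by ``displacement_offset`` pixels; subjects
flagged as reducing return the disc to the normal position in the
open-mouth state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

GROUPS = ("normal", "displaced")
JAW_STATES = ("closed", "open")
SIDES = ("left", "right")

MASK_FOREGROUND_RGB = (255, 255, 255)

#: geometry defaults below are expressed for this reference image size and
#: scaled linearly for other sizes
REFERENCE_SIZE = 512


class ShapeError(ValueError):
    """The configured crescent geometry has no pixel support."""


@dataclass
class DiscShape:
    """Biconcave crescent: outer ellipse minus two symmetric elliptical bites.

    ``outer_axes``/``inner_axes`` are (horizontal, vertical) semi-axes in
    pixels; ``thickness`` is the remaining disc thickness at its center in
    pixels; ``angle_deg`` rotates the whole shape counterclockwise.
    """

    outer_axes: tuple[float, float] = (42.0, 16.0)
    inner_axes: tuple[float, float] = (30.0, 12.0)
    thickness: float = 10.0
    angle_deg: float = -15.0

    def validate(self) -> None:
        ao, bo = self.outer_axes
        ai, bi = self.inner_axes
        if min(ao, bo, ai, bi) <= 0:
            raise ShapeError("ellipse semi-axes must be positive")
        if ai >= ao:
            raise ShapeError("inner (bite) ellipse must be horizontally inside the outer")
        if self.thickness <= 0:
            raise ShapeError("central thickness must be positive")
        if self.thickness >= 2 * bo:
            raise ShapeError("central thickness exceeds the outer ellipse: no bite")


@dataclass
class PhantomParams:
    """Everything needed to render one deterministic phantom slice."""

    image_size: tuple[int, int] = (512, 512)
    disc_shape: DiscShape = field(default_factory=DiscShape)
    disc_center: tuple[float, float] = (230.0, 270.0)  # (row, col)
    displacement_offset: float = 30.0
    jaw_state: str = "closed"
    group: str = "normal"
    reduction: bool = False
    noise_sd: float = 6.0
    blur_sigma: float = 1.2
    bias_field_amplitude: float = 0.08
    disc_intensity: float = 55.0
    background_intensity: float = 150.0
    condyle_intensity: float = 205.0
    seed: int = 0

    def __post_init__(self):
        if self.jaw_state not in JAW_STATES:
            raise ValueError(f"jaw_state must be one of {JAW_STATES}")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")


@dataclass
class Sample:
    """One grayscale slice with its binary ground-truth mask and metadata."""

    image: np.ndarray
    mask: np.ndarray
    subject_id: str
    group: str
    jaw_state: str
    side: str

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError("mask shape must equal image shape")
        if not self.mask.any():
            raise ValueError("mask must contain at least one foreground pixel")


def _ellipse_mask(rows, cols, center, axes, angle_deg):
    cy, cx = center
    a, b = axes  # horizontal, vertical semi-axes
    th = math.radians(angle_deg)
    dy = rows - cy
    dx = cols - cx
    u = dx * math.cos(th) + dy * math.sin(th)
    v = -dx * math.sin(th) + dy * math.cos(th)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def render_crescent(image_size, center, shape: DiscShape) -> np.ndarray:
    """Exact pixel support of the biconcave disc (bool grid)."""
    shape.validate()
    h, w = image_size
    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    ao, bo = shape.outer_axes
    ai, bi = shape.inner_axes
    th = math.radians(shape.angle_deg)
    # bite centers sit above/below the disc's long axis, in the rotated frame
    off = bi + shape.thickness / 2.0
    dy = off * math.cos(th)
    dx = -off * math.sin(th)
    cy, cx = center
    body = _ellipse_mask(rows, cols, center, (ao, bo), shape.angle_deg)
    upper = _ellipse_mask(rows, cols, (cy - dy, cx - dx), (ai, bi), shape.angle_deg)
    lower = _ellipse_mask(rows, cols, (cy + dy, cx + dx), (ai, bi), shape.angle_deg)
    crescent = body & ~upper & ~lower
    if not crescent.any():
        raise ShapeError("crescent has zero pixel area for the configured geometry")
    return crescent


def _effective_disc_center(params: PhantomParams) -> tuple[float, float]:
    cy, cx = params.disc_center
    displaced = params.group == "displaced"
    if displaced and params.reduction and params.jaw_state == "open":
        displaced = False  # disc reduces back onto the condyle on opening
    if displaced:
        cx = cx - params.displacement_offset  # anterior = toward lower columns
    return cy, cx


def generate_phantom(params: PhantomParams) -> Sample:
    """Render one phantom slice; bit-identical for identical params + seed."""
    h, w = params.image_size
    scale = min(h, w) / REFERENCE_SIZE
    rng = np.random.default_rng(params.seed)

    center = _effective_disc_center(params)
    disc = render_crescent(params.image_size, center, params.disc_shape)

    img = np.full((h, w), params.background_intensity, dtype=np.float64)

    # condyle: bright ellipse below the disc; opens forward and downward
    cy, cx = center
    cond_dy, cond_dx = 55.0 * scale, 0.0
    if params.jaw_state == "open":
        cond_dy += 18.0 * scale
        cond_dx -= 28.0 * scale
    condyle = _ellipse_mask(
        np.mgrid[0:h, 0:w][0].astype(np.float64),
        np.mgrid[0:h, 0:w][1].astype(np.float64),
        (cy + cond_dy, cx + cond_dx),
        (34.0 * scale, 40.0 * scale),
        0.0,
    )
    img[condyle] = params.condyle_intensity

    # temporal fossa: slightly brighter band above the disc
    fossa = _ellipse_mask(
        np.mgrid[0:h, 0:w][0].astype(np.float64),
        np.mgrid[0:h, 0:w][1].astype(np.float64),
        (cy - 45.0 * scale, cx + 10.0 * scale),
        (70.0 * scale, 28.0 * scale),
        8.0,
    )
    img[fossa] = 0.5 * (params.background_intensity + params.condyle_intensity)

    img[disc] = params.disc_intensity

    if params.bias_field_amplitude > 0:
        yy, xx = np.mgrid[0:h, 0:w]
        yy = yy / max(h - 1, 1) - 0.5
        xx = xx / max(w - 1, 1) - 0.5
        c = rng.uniform(-1.0, 1.0, size=5)
        poly = c[0] * yy + c[1] * xx + c[2] * yy * xx + c[3] * yy**2 + c[4] * xx**2
        img += params.bias_field_amplitude * 255.0 * poly

    if params.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, params.blur_sigma)
    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape)

    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return Sample(
        image=img,
        mask=disc.astype(np.uint8),
        subject_id="",
        group=params.group,
        jaw_state=params.jaw_state,
        side="left",
    )


@dataclass
class CohortManifest:
    """Table of generated samples with file paths and metadata."""

    table: pd.DataFrame

    COLUMNS = ("image_path", "mask_path", "subject_id", "group", "jaw_state", "side")

    def __len__(self) -> int:
        return len(self.table)

    def counts(self) -> pd.DataFrame:
        return self.table.groupby(["group", "jaw_state"]).size().reset_index(name="n")

    def save(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path) -> "CohortManifest":
        t = pd.read_csv(path)
        missing = set(cls.COLUMNS) - set(t.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        return cls(table=t)

    def validate_paths(self) -> None:
        for _, row in self.table.iterrows():
            for key in ("image_path", "mask_path"):
                if not Path(row[key]).exists():
                    raise FileNotFoundError(f"{key} {row[key]} does not exist")


def _subject_params(base: PhantomParams, rng: np.random.Generator) -> PhantomParams:
    """Per-subject anatomical variation around the defaults."""
    h, w = base.image_size
    scale = min(h, w) / REFERENCE_SIZE
    shape = base.disc_shape
    jitter = lambda v, frac: v * rng.uniform(1.0 - frac, 1.0 + frac)
    disc_shape = DiscShape(
        outer_axes=(jitter(shape.outer_axes[0], 0.15), jitter(shape.outer_axes[1], 0.15)),
        inner_axes=(jitter(shape.inner_axes[0], 0.12), jitter(shape.inner_axes[1], 0.12)),
        thickness=jitter(shape.thickness, 0.2),
        angle_deg=shape.angle_deg + rng.uniform(-10.0, 10.0),
    )
    cy, cx = base.disc_center
    center = (cy + rng.uniform(-8, 8) * scale, cx + rng.uniform(-8, 8) * scale)
    return replace(base, disc_shape=disc_shape, disc_center=center)


def generate_cohort_samples(
    n_patients: int = 10,
    n_controls: int = 10,
    slices_per_subject: tuple[int, int] = (4, 7),
    seed: int = 0,
    image_size: tuple[int, int] = (512, 512),
    base_params: PhantomParams | None = None,
) -> list[Sample]:
    """Generate the cohort fully in memory; deterministic under ``seed``.

    Each subject contributes a random number of slices in
    ``slices_per_subject`` (inclusive), alternating sides and jaw states
    so both appear for every subject with >= 4 slices. Patients are
    ``displaced`` (half of them with reduction); controls are ``normal``.
    """
    if n_patients < 0 or n_controls < 0:
        raise ValueError("subject counts must be >= 0")
    if n_patients + n_controls < 1:
        raise ValueError("cohort needs at least one subject")
    lo, hi = slices_per_subject
    if lo < 1 or hi < lo:
        raise ValueError("slices_per_subject must be a nondecreasing range with lo >= 1")
    rng = np.random.default_rng(seed)
    if base_params is None:
        h, w = image_size
        s = min(h, w) / REFERENCE_SIZE
        base_params = PhantomParams(
            image_size=image_size,
            disc_shape=DiscShape(
                outer_axes=(42.0 * s, 16.0 * s),
                inner_axes=(30.0 * s, 12.0 * s),
                thickness=max(10.0 * s, 2.0),
                angle_deg=-15.0,
            ),
            disc_center=(230.0 / REFERENCE_SIZE * h, 270.0 / REFERENCE_SIZE * w),
            displacement_offset=30.0 * s,
        )

    samples: list[Sample] = []
    subjects = [("displaced", i) for i in range(n_patients)] + [
        ("normal", i) for i in range(n_controls)
    ]
    for group, i in subjects:
        sid = f"{'P' if group == 'displaced' else 'C'}{i + 1:02d}"
        sp = _subject_params(replace(base_params, group=group), rng)
        reduction = group == "displaced" and i % 2 == 0
        n_slices = int(rng.integers(lo, hi + 1))
        for s_idx in range(n_slices):
            jaw = JAW_STATES[s_idx % 2]
            side = SIDES[(s_idx // 2) % 2]
            slice_seed = int(rng.integers(0, 2**31 - 1))
            p = replace(sp, jaw_state=jaw, reduction=reduction, seed=slice_seed)
            sample = generate_phantom(p)
            sample.subject_id = sid
            sample.side = side
            samples.append(sample)
    return samples


def generate_cohort(
    out_dir: str | Path,
    n_patients: int = 10,
    n_controls: int = 10,
    slices_per_subject: tuple[int, int] = (4, 7),
    seed: int = 0,
    image_size: tuple[int, int] = (512, 512),
    base_params: PhantomParams | None = None,
) -> CohortManifest:
    """Write a phantom cohort (PNG images + white-fill RGB PNG masks + CSV)."""
    from . import dataio  # local import: dataio also imports nothing from here

    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    samples = generate_cohort_samples(
        n_patients, n_controls, slices_per_subject, seed, image_size, base_params
    )
    rows = []
    counters: dict[str, int] = {}
    for s in samples:
        k = counters.get(s.subject_id, 0)
        counters[s.subject_id] = k + 1
        stem = f"{s.subject_id}_{s.side}_{s.jaw_state}_{k:02d}"
        img_path = out_dir / "images" / f"{stem}.png"
        mask_path = out_dir / "masks" / f"{stem}_mask.png"
        dataio.write_grayscale(img_path, s.image)
        dataio.write_mask(mask_path, s.mask)
        rows.append(
            {
                "image_path": str(img_path),
                "mask_path": str(mask_path),
                "subject_id": s.subject_id,
                "group": s.group,
                "jaw_state": s.jaw_state,
                "side": s.side,
            }
        )
    manifest = CohortManifest(table=pd.DataFrame(rows, columns=CohortManifest.COLUMNS))
    manifest.save(out_dir / "manifest.csv")
    return manifest


def load_cohort(manifest: CohortManifest | str | Path) -> list[Sample]:
    """Reload a written cohort into memory (masks decoded from white fill)."""
    from . import dataio

    if not isinstance(manifest, CohortManifest):
        manifest = CohortManifest.load(manifest)
    out = []
    for _, row in manifest.table.iterrows():
        out.append(
            Sample(
                image=dataio.read_grayscale(row["image_path"]),
                mask=dataio.read_mask(row["mask_path"]),
                subject_id=row["subject_id"],
                group=row["group"],
                jaw_state=row["jaw_state"],
                side=row["side"],
            )
        )
    return out
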