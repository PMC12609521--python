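"""Illuminant-transfer augmentation and the geometric baseline.

The augmentation re-renders a training image as if it had been captured
under a different light source (equivalently, a different camera): estimate
the image's own illuminant, sample a target illuminant uniformly from a
pre-calculated pool, and apply a diagonal von Kries transform with gains
``g_c = target_c / source_c`` to the field-of-view pixels.  Labels are
untouched by construction — the augmentation is purely photometric.

Gains are rescaled to mean 1 by default (brightness preservation), so the
transfer changes tint without a global exposure swing; with preservation off
and no clipping the transform is exactly invertible.

A standard geometric baseline (random rotation within ±15°, horizontal flip,
scale in [0.8, 1.2]) is provided for comparison; it resamples the image
bilinearly and the labels nearest-neighbour with identical parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .illuminants import ESTIMATORS, IlluminantPool, IlluminantVector, sample_illuminant
from .labels import LabelMap

__all__ = [
    "AugmentationRecord",
    "GeometricAugParams",
    "chromatic_adapt",
    "illuminant_augment",
    "geometric_augment",
]

_MIN_SOURCE = 1e-6
_CLIP_WARN = 0.05


@dataclass(frozen=True)
class AugmentationRecord:
    """Provenance of one photometric augmentation."""

    source_illuminant: IlluminantVector
    target_illuminant: IlluminantVector
    pool_row: int | None
    gains: np.ndarray
    clipped_fraction: float

    def to_dict(self) -> dict:
        return {
            "source_illuminant": self.source_illuminant.e.tolist(),
            "target_illuminant": self.target_illuminant.e.tolist(),
            "pool_row": self.pool_row,
            "gains": np.asarray(self.gains).tolist(),
            "clipped_fraction": self.clipped_fraction,
        }


@dataclass(frozen=True)
class GeometricAugParams:
    """Baseline geometric-augmentation ranges."""

    rotation_range: float = 15.0        # degrees, symmetric about 0
    allow_flip: bool = True
    scale_range: tuple[float, float] = (0.8, 1.2)

    def __post_init__(self) -> None:
        if self.rotation_range < 0:
            raise ValueError("rotation_range must be >= 0 (symmetric about 0)")
        lo, hi = self.scale_range
        if not 0 < lo <= hi:
            raise ValueError("scale_range must be positive and ordered")


def chromatic_adapt(
    image: np.ndarray,
    fov: np.ndarray,
    source: IlluminantVector,
    target: IlluminantVector,
    brightness_preserve: bool = True,
    pool_row: int | None = None,
) -> tuple[np.ndarray, AugmentationRecord]:
    """Von Kries diagonal transform mapping ``source`` to ``target``.

    FOV pixels are multiplied per channel by ``g_c = target_c / source_c``
    (rescaled to mean 1 if ``brightness_preserve``) and clipped to [0, 1];
    pixels outside the FOV are unchanged.  The returned record reports the
    gains and the fraction of FOV pixels where clipping occurred.
    """
    image = np.asarray(image, dtype=np.float64)
    fov = np.asarray(fov).astype(bool)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (H, W, 3)")
    if fov.shape != image.shape[:2]:
        raise ValueError("FOV mask shape does not match image")
    if (source.e <= _MIN_SOURCE).any():
        raise ValueError(
            f"degenerate source illuminant: component <= {_MIN_SOURCE} cannot be divided"
        )

    gains = target.e / source.e
    if brightness_preserve:
        gains = gains / gains.mean()

    out = image.copy()
    adapted = image[fov] * gains[None, :]
    clipped = float(np.mean((adapted > 1.0).any(axis=1) | (adapted < 0.0).any(axis=1)))
    out[fov] = np.clip(adapted, 0.0, 1.0)
    if clipped > _CLIP_WARN:
        warnings.warn(
            f"chromatic adaptation clipped {clipped:.1%} of FOV pixels",
            RuntimeWarning,
            stacklevel=2,
        )
    record = AugmentationRecord(
        source_illuminant=source,
        target_illuminant=target,
        pool_row=pool_row,
        gains=gains,
        clipped_fraction=clipped,
    )
    return out, record


def illuminant_augment(
    image: np.ndarray,
    fov: np.ndarray,
    pool: IlluminantPool,
    rng: np.random.Generator | int,
    source_estimator: str = "grayworld",
    brightness_preserve: bool = True,
) -> tuple[np.ndarray, AugmentationRecord]:
    """One full photometric augmentation draw.

    Estimates the image's own illuminant with ``source_estimator``, samples
    a target row uniformly from the pool, and applies the von Kries
    transfer.  Label maps need no handling: the operation touches only pixel
    colors.
    """
    if source_estimator not in ESTIMATORS:
        raise KeyError(
            f"unknown estimator {source_estimator!r}; choose from {sorted(ESTIMATORS)}"
        )
    source = ESTIMATORS[source_estimator](image, fov)
    target, row = sample_illuminant(pool, rng)
    return chromatic_adapt(
        image, fov, source, target, brightness_preserve=brightness_preserve, pool_row=row
    )


def geometric_augment(
    image: np.ndarray,
    labels: LabelMap,
    params: GeometricAugParams,
    rng: np.random.Generator | int,
) -> tuple[np.ndarray, LabelMap]:
    """Random rotation / flip / scale applied identically to image and labels.

    One rotation angle ~ U(−r, +r) degrees, a horizontal flip with
    probability 0.5 if allowed, and a scale ~ U(scale_range) are drawn, then
    applied about the image center.  The image is resampled bilinearly, the
    labels nearest-neighbour (interpolation must never mix class ids); the
    canvas size is preserved and uncovered regions are filled with
    background/black.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.shape[:2] != labels.shape:
        raise ValueError("image and label shapes disagree")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    angle = rng.uniform(-params.rotation_range, params.rotation_range)
    flip = bool(params.allow_flip and rng.uniform() < 0.5)
    scale = rng.uniform(*params.scale_range)

    H, W = labels.shape
    center = np.array([(H - 1) / 2.0, (W - 1) / 2.0])
    th = np.deg2rad(angle)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    fl = np.diag([1.0, -1.0 if flip else 1.0])
    # affine_transform maps output coords to input coords: invert the
    # forward transform out = scale · R(θ) · F · (in − c) + c.
    A = (fl @ rot.T) / scale
    offset = center - A @ center

    out_img = np.stack(
        [
            ndimage.affine_transform(
                image[:, :, c], A, offset=offset, order=1, mode="constant", cval=0.0
            )
            for c in range(image.shape[2])
        ],
        axis=2,
    )
    out_grid = ndimage.affine_transform(
        labels.grid, A, offset=offset, order=0, mode="constant", cval=0
    )
    return np.clip(out_img, 0.0, 1.0), LabelMap(out_grid, labels.schema)
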