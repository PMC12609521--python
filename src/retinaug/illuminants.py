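"""Scene-illuminant estimation and the pre-calculated illuminance pool.

Color constancy estimates the chromaticity of the light source that produced
an image, so the image can be re-rendered under a different source.  Three
classical global estimators are provided:

* **Gray World** — the average scene reflectance is assumed achromatic, so
  the per-channel mean over the field of view estimates the illuminant.
* **Retinex (white patch)** — the brightest surface is assumed to reflect
  the illuminant; implemented as a per-channel percentile (default 0.99,
  1.0 gives the strict per-channel max) for robustness to specular specks.
* **PCA bright/dark** — the pixels with the largest and smallest projection
  onto the mean color direction (default 3.5% each) are selected and the
  dominant eigenvector of their uncentred second-moment matrix taken as the
  illuminant direction.

All estimates are unit-L2-normalized: only the chromatic direction is used
downstream; magnitude is handled by the adaptation gain normalization.

A pool of illuminants is built by running every estimator on every reference
image (one row per pair, the I[M×3] matrix with per-row provenance) and is
sampled uniformly during augmentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "IlluminantVector",
    "IlluminantPool",
    "ESTIMATORS",
    "estimate_gray_world",
    "estimate_retinex",
    "estimate_pca",
    "build_pool",
    "sample_illuminant",
]

_NORM_TOL = 1e-9


@dataclass(frozen=True)
class IlluminantVector:
    """A unit-L2-norm, componentwise-nonnegative RGB illuminance direction."""

    e: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.e, dtype=np.float64)
        if e.shape != (3,):
            raise ValueError("illuminant must be a 3-vector")
        if (e < 0).any():
            raise ValueError("illuminant components must be nonnegative")
        n = float(np.linalg.norm(e))
        if n == 0.0:
            raise ValueError("zero illuminant vector")
        if abs(n - 1.0) > _NORM_TOL:
            raise ValueError(f"illuminant not unit-norm (‖e‖={n!r})")
        object.__setattr__(self, "e", e)

    @classmethod
    def from_raw(cls, v: np.ndarray) -> "IlluminantVector":
        """Unit-normalize an arbitrary nonnegative 3-vector."""
        v = np.asarray(v, dtype=np.float64)
        n = float(np.linalg.norm(v))
        if n == 0.0 or not math.isfinite(n):
            raise ValueError("cannot normalize a zero/non-finite vector")
        return cls(v / n)

    def cosine(self, other: "IlluminantVector") -> float:
        return float(np.clip(self.e @ other.e, -1.0, 1.0))

    def __array__(self, dtype=None, copy=None) -> np.ndarray:
        return np.asarray(self.e, dtype=dtype)


def _fov_pixels(image: np.ndarray, fov: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    fov = np.asarray(fov).astype(bool)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (H, W, 3)")
    if fov.shape != image.shape[:2]:
        raise ValueError("FOV mask shape does not match image")
    if not fov.any():
        raise ValueError("empty FOV mask")
    return image[fov]


def estimate_gray_world(image: np.ndarray, fov: np.ndarray) -> IlluminantVector:
    """Gray-world estimate: unit-normalized per-channel mean over the FOV."""
    px = _fov_pixels(image, fov)
    mean = px.mean(axis=0)
    if not (mean > 0).any():
        raise ValueError("degenerate image: zero channel means over FOV")
    return IlluminantVector.from_raw(mean)


def estimate_retinex(
    image: np.ndarray, fov: np.ndarray, percentile: float = 0.99
) -> IlluminantVector:
    """White-patch estimate: per-channel upper percentile over the FOV.

    ``percentile`` is a fraction in (0, 1]; 1.0 selects the strict
    per-channel maximum.  The order statistic at one-based rank
    ``ceil(percentile * n)`` is used, matching exhaustive sorting.
    """
    if not 0.0 < percentile <= 1.0:
        raise ValueError("percentile must lie in (0, 1]")
    px = _fov_pixels(image, fov)
    n = px.shape[0]
    rank = max(1, math.ceil(percentile * n))  # 1-based
    v = np.sort(px, axis=0)[rank - 1]
    if not (v > 0).any():
        raise ValueError("degenerate image: zero percentile vector over FOV")
    return IlluminantVector.from_raw(v)


def estimate_pca(
    image: np.ndarray, fov: np.ndarray, fraction: float = 0.035
) -> IlluminantVector:
    """Bright-and-dark-pixel PCA estimate.

    Projects FOV pixels onto the mean color direction, selects the
    ``fraction`` with the largest and the ``fraction`` with the smallest
    projection, and returns the dominant eigenvector of the selected pixels'
    uncentred 3×3 second-moment matrix, sign-fixed to nonnegative
    components and unit-normalized.
    """
    if not 0.0 < fraction <= 0.5:
        raise ValueError("fraction must lie in (0, 0.5]")
    px = _fov_pixels(image, fov)
    n = px.shape[0]
    k = math.ceil(fraction * n)
    if k < 3:
        raise ValueError(f"too few FOV pixels for fraction={fraction} (k={k} < 3)")
    mean = px.mean(axis=0)
    nm = float(np.linalg.norm(mean))
    if nm == 0.0:
        raise ValueError("degenerate image: zero mean color over FOV")
    proj = px @ (mean / nm)
    order = np.argsort(proj, kind="stable")
    sel = px[np.concatenate([order[:k], order[-k:]])]
    moment = sel.T @ sel
    evals, evecs = np.linalg.eigh(moment)
    if evals[-1] <= 0:
        raise ValueError("rank-0 selected-pixel matrix; cannot estimate illuminant")
    v = evecs[:, -1]
    # eigh sign is arbitrary; orient toward nonnegative components
    if v.sum() < 0:
        v = -v
    if (v < -1e-9).any():
        raise ValueError("mixed-sign principal direction: non-physical illuminant")
    return IlluminantVector.from_raw(np.clip(v, 0.0, None))


ESTIMATORS = {
    "grayworld": estimate_gray_world,
    "retinex": estimate_retinex,
    "pca": estimate_pca,
}


@dataclass
class IlluminantPool:
    """The pre-calculated M×3 illuminance matrix with per-row provenance.

    One row per (reference image, estimator) pair, so
    M = n_references × n_estimators always.
    """

    matrix: np.ndarray
    source_ids: list[str]
    estimator_names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 3:
            raise ValueError("pool matrix must be M×3")
        if not (len(self.source_ids) == len(self.estimator_names) == self.matrix.shape[0]):
            raise ValueError("provenance length must equal row count")
        for row in self.matrix:
            IlluminantVector(row)  # validates unit norm / nonnegativity

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def row(self, i: int) -> IlluminantVector:
        return IlluminantVector(self.matrix[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r": self.matrix[:, 0],
                "g": self.matrix[:, 1],
                "b": self.matrix[:, 2],
                "source_id": self.source_ids,
                "estimator": self.estimator_names,
            }
        )

    def to_csv(self, path) -> None:
        # repr-precision floats give IEEE-754 round-trip fidelity
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "IlluminantPool":
        df = pd.read_csv(path, float_precision="round_trip")
        required = {"r", "g", "b", "source_id", "estimator"}
        if not required.issubset(df.columns):
            raise ValueError(f"pool CSV missing columns {sorted(required - set(df.columns))}")
        return cls(
            df[["r", "g", "b"]].to_numpy(dtype=np.float64),
            df["source_id"].astype(str).tolist(),
            df["estimator"].astype(str).tolist(),
        )


def build_pool(
    refs: list[tuple[np.ndarray, np.ndarray]],
    estimators: list[str] = ("grayworld", "retinex", "pca"),
    source_ids: list[str] | None = None,
) -> IlluminantPool:
    """Run every estimator on every reference image; image-index-major order.

    Any estimator failure aborts the build with an error naming the image
    and estimator — rows are never silently dropped.
    """
    if not refs:
        raise ValueError("reference list is empty")
    bad = [e for e in estimators if e not in ESTIMATORS]
    if bad:
        raise KeyError(f"unknown estimator(s): {bad}; choose from {sorted(ESTIMATORS)}")
    if not estimators:
        raise ValueError("estimator list is empty")
    if source_ids is None:
        source_ids = [f"ref{i:04d}" for i in range(len(refs))]
    if len(source_ids) != len(refs):
        raise ValueError("source_ids length must match refs")

    rows, srcs, ests = [], [], []
    for sid, (image, fov) in zip(source_ids, refs):
        for est in estimators:
            try:
                vec = ESTIMATORS[est](image, fov)
            except Exception as exc:
                raise RuntimeError(f"estimator {est!r} failed on image {sid!r}: {exc}") from exc
            rows.append(vec.e)
            srcs.append(sid)
            ests.append(est)
    return IlluminantPool(np.vstack(rows), srcs, ests)


def sample_illuminant(
    pool: IlluminantPool, rng: np.random.Generator | int
) -> tuple[IlluminantVector, int]:
    """Draw one pool row uniformly at random; returns (vector, row index)."""
    if len(pool) == 0:
        raise ValueError("cannot sample from an empty pool")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    idx = int(rng.integers(0, len(pool)))
    return pool.row(idx), idx
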