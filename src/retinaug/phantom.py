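"""Synthetic fundus phantoms with exact ground truth.

Real fundus photographs cannot ship with a library, so this module renders
fundus-*like* images whose generating geometry, reflectance and illuminant
are known exactly: a circular field of view on a black surround containing a
retinal background, dark vessels radiating from a bright optic disc, a
darker fovea, and the four diabetic-retinopathy lesion types (MA = small
dark-red dots, HE = larger dark-red blobs, EX = bright yellow clusters,
CWS = pale fluffy blobs).  No clinical realism is claimed — the phantoms
exist so that illuminant estimation, chromatic adaptation, label merging,
losses and metrics can be tested against exact ground truth.

The appearance model is a von Kries world: the stored image is an
elementwise product of a seed-determined reflectance field and a global
illuminant vector, plus optional Gaussian noise, clipped to [0, 1].  All
anatomical structures share the retina's reflectance *chromaticity* (they
are scalar multiples of the base color), so on noise-free phantoms every
global color-constancy estimator recovers exactly
``normalize(mean_reflectance ∘ illuminant)``.  Lesions carry class-distinct
chromatic offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .illuminants import IlluminantVector
from .labels import FULL9, LabelMap

__all__ = ["PhantomSpec", "PhantomSample", "generate_phantom", "generate_reference_set"]

# Luminance multipliers on the base retinal reflectance (uniform chromaticity).
_VESSEL_LUM = 0.45
_FOVEA_LUM = 0.70
_OD_LUM = 1.70

# Absolute lesion reflectances (class-distinct chromaticities), RGB in [0,1].
_LESION_REFLECTANCE = {
    "MA": (0.32, 0.08, 0.05),   # small dark red dot
    "HE": (0.38, 0.10, 0.07),   # larger dark red blob
    "EX": (0.85, 0.80, 0.20),   # bright yellow cluster
    "CWS": (0.75, 0.72, 0.62),  # pale fluffy blob
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic fundus image.

    Coordinates are (row, col), 0-based, origin top-left.  ``None`` centers
    and radii are resolved to canonical positions relative to the FOV.
    """

    height: int = 128
    width: int = 128
    fov_radius_frac: float = 0.92
    n_vessels: int = 6
    od_center: tuple[float, float] | None = None
    od_radius: float | None = None
    fovea_center: tuple[float, float] | None = None
    fovea_radius: float | None = None
    lesion_counts: dict[str, int] = field(
        default_factory=lambda: {"MA": 4, "HE": 2, "EX": 2, "CWS": 1}
    )
    lesion_radius_range: tuple[float, float] = (1.5, 4.0)
    base_chromaticity: tuple[float, float, float] = (0.50, 0.25, 0.15)
    illuminant: IlluminantVector = field(
        default_factory=lambda: IlluminantVector.from_raw(np.array([1.0, 0.8, 0.6]))
    )
    noise_sd: float = 0.0
    seed: int = 0

    # -- resolved geometry -------------------------------------------------
    @property
    def fov_center(self) -> tuple[float, float]:
        return ((self.height - 1) / 2.0, (self.width - 1) / 2.0)

    @property
    def fov_radius(self) -> float:
        return self.fov_radius_frac * min(self.height, self.width) / 2.0

    def resolved(self) -> "PhantomSpec":
        """Fill in default OD/fovea geometry and validate all invariants."""
        if not 0.0 < self.fov_radius_frac <= 1.0:
            raise ValueError("fov_radius_frac must lie in (0, 1]")
        if self.n_vessels < 0:
            raise ValueError("n_vessels must be >= 0")
        if any(v < 0 for v in self.lesion_counts.values()):
            raise ValueError("lesion counts must be >= 0")
        unknown = set(self.lesion_counts) - set(_LESION_REFLECTANCE)
        if unknown:
            raise KeyError(f"unknown lesion class(es): {sorted(unknown)}")
        lo, hi = self.lesion_radius_range
        if not 0 < lo <= hi:
            raise ValueError("lesion_radius_range must be positive and ordered")
        if min(self.base_chromaticity) <= 0:
            raise ValueError("base_chromaticity components must be positive")

        cy, cx = self.fov_center
        R = self.fov_radius
        od_c = self.od_center if self.od_center is not None else (cy, cx + 0.45 * R)
        od_r = self.od_radius if self.od_radius is not None else 0.16 * R
        fv_c = self.fovea_center if self.fovea_center is not None else (cy, cx - 0.35 * R)
        fv_r = self.fovea_radius if self.fovea_radius is not None else 0.12 * R
        if od_r <= 0 or fv_r <= 0:
            raise ValueError("structure radii must be positive")
        for name, (sy, sx) in (("optic disc", od_c), ("fovea", fv_c)):
            if np.hypot(sy - cy, sx - cx) > R:
                raise ValueError(f"{name} center lies outside the FOV disc")
        return replace(
            self, od_center=od_c, od_radius=od_r, fovea_center=fv_c, fovea_radius=fv_r
        )


@dataclass
class PhantomSample:
    """A rendered phantom: image, 9-class labels, FOV mask and ground truth."""

    image: np.ndarray
    labels: LabelMap
    fov: np.ndarray
    true_illuminant: IlluminantVector
    reflectance: np.ndarray  # pre-illuminant field, exposed for oracle tests
    spec: PhantomSpec


def _disc(yy: np.ndarray, xx: np.ndarray, center: tuple[float, float], r: float) -> np.ndarray:
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= r * r


def _draw_vessels(
    spec: PhantomSpec, rng: np.random.Generator, fov: np.ndarray
) -> np.ndarray:
    """Rasterize wiggly polylines radiating from the optic disc."""
    H, W = spec.height, spec.width
    mask = np.zeros((H, W), dtype=bool)
    oy, ox = spec.od_center  # type: ignore[misc]
    R = spec.fov_radius
    for _ in range(spec.n_vessels):
        ang = rng.uniform(0.0, 2.0 * np.pi)
        length = rng.uniform(0.8 * R, 1.8 * R)
        amp = rng.uniform(0.02 * R, 0.08 * R)
        freq = rng.uniform(1.0, 3.0)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        t = np.linspace(0.0, 1.0, max(8, int(2 * length)))
        wiggle = amp * np.sin(2 * np.pi * freq * t + phase)
        ry = oy + t * length * np.sin(ang) + wiggle * np.cos(ang)
        rx = ox + t * length * np.cos(ang) - wiggle * np.sin(ang)
        iy = np.clip(np.round(ry).astype(int), 0, H - 1)
        ix = np.clip(np.round(rx).astype(int), 0, W - 1)
        mask[iy, ix] = True
        # one-pixel thickening for visibility at small sizes
        mask[np.clip(iy + 1, 0, H - 1), ix] = True
    return mask & fov


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render one phantom deterministically from its spec.

    The returned labels record the generating geometry exactly; lesions
    override anatomy, and among lesions precedence is MA > CWS > HE > EX
    (the merge precedence used throughout the package).
    """
    spec = spec.resolved()
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.width
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)

    fov = _disc(yy, xx, spec.fov_center, spec.fov_radius)
    if not fov.any():
        raise ValueError("degenerate spec: empty FOV")

    grid = np.zeros((H, W), dtype=np.int64)
    grid[fov] = FULL9.id_of("retina")
    lum = np.zeros((H, W), dtype=np.float64)
    lum[fov] = 1.0

    fovea = _disc(yy, xx, spec.fovea_center, spec.fovea_radius) & fov  # type: ignore[arg-type]
    grid[fovea] = FULL9.id_of("FV")
    lum[fovea] = _FOVEA_LUM

    vessels = _draw_vessels(spec, rng, fov)
    grid[vessels] = FULL9.id_of("vessel")
    lum[vessels] = _VESSEL_LUM

    od = _disc(yy, xx, spec.od_center, spec.od_radius) & fov  # type: ignore[arg-type]
    grid[od] = FULL9.id_of("OD")
    lum[od] = _OD_LUM

    base = np.asarray(spec.base_chromaticity, dtype=np.float64)
    reflectance = lum[:, :, None] * base[None, None, :]

    # Lesions: random centers inside 0.9·R, painted lowest precedence first
    # so MA (highest) lands last on any overlap.
    cy, cx = spec.fov_center
    inner = 0.88 * spec.fov_radius
    lo, hi = spec.lesion_radius_range
    for name in ("EX", "HE", "CWS", "MA"):
        for _ in range(int(spec.lesion_counts.get(name, 0))):
            ang = rng.uniform(0.0, 2.0 * np.pi)
            rad = inner * np.sqrt(rng.uniform(0.0, 1.0))
            ly, lx = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
            lr = rng.uniform(lo, hi)
            m = _disc(yy, xx, (ly, lx), lr) & fov
            grid[m] = FULL9.id_of(name)
            reflectance[m] = _LESION_REFLECTANCE[name]

    image = reflectance * spec.illuminant.e[None, None, :]
    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, size=image.shape)
        image = image + noise * fov[:, :, None]
    image = np.clip(image, 0.0, 1.0)

    return PhantomSample(
        image=image,
        labels=LabelMap(grid, FULL9),
        fov=fov,
        true_illuminant=spec.illuminant,
        reflectance=reflectance,
        spec=spec,
    )


def generate_reference_set(
    n: int, seed: int, height: int = 64, width: int = 64
) -> list[tuple[np.ndarray, np.ndarray, IlluminantVector]]:
    """Generate ``n`` reference phantoms under varied red-dominant illuminants.

    Stands in for a directory of reference fundus images when building an
    illuminant pool; the true illuminants are returned so recovery can be
    verified.  Illuminant chromaticities are drawn from a seed-determined
    spread of plausible fundus tints (red component dominant).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    master = np.random.default_rng(seed)
    out = []
    for i in range(n):
        raw = np.array(
            [1.0, master.uniform(0.40, 0.90), master.uniform(0.15, 0.65)]
        )
        illum = IlluminantVector.from_raw(raw)
        sub_seed = int(master.integers(0, 2**31 - 1))
        spec = PhantomSpec(
            height=height,
            width=width,
            n_vessels=4,
            lesion_counts={"MA": 1, "HE": 1, "EX": 1, "CWS": 0},
            illuminant=illum,
            noise_sd=0.005,
            seed=sub_seed,
        )
        sample = generate_phantom(spec)
        out.append((sample.image, sample.fov, illum))
    return out
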