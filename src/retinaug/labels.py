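"""Field-of-view masks and multi-class label maps for fundus segmentation.

A fundus photograph shows a circular retinal field of view (FOV) on a black
camera surround.  Lesion segmentation benefits from anatomical context: the
optic disc is easily confused with hard exudates, and vessels with
hemorrhages, so the background is split into anatomical subclasses (retina,
vessel, optic disc, fovea) and merged with the four diabetic-retinopathy
lesion classes (microaneurysm MA, hemorrhage HE, hard exudate EX,
cotton-wool spot CWS) into a single nine-class map.

This module provides the deterministic mask algebra: Otsu thresholding for
FOV extraction, schema-aware label maps, anatomy/lesion merging with a fixed
overlap precedence, and one-hot encoding for the loss functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "ClassSchema",
    "LabelMap",
    "DR_M1",
    "ANAT5",
    "FULL9",
    "SCHEMAS",
    "PALETTE9",
    "otsu_threshold",
    "extract_fov",
    "merge_anatomy_lesions",
    "one_hot",
    "MergeReport",
]

LESION_NAMES = ("MA", "HE", "EX", "CWS")

#: Overlap precedence among lesions, highest first (ascending typical size,
#: so the smallest lesion is never absorbed by a larger overlapping one).
LESION_PRECEDENCE = ("MA", "CWS", "HE", "EX")


@dataclass(frozen=True)
class ClassSchema:
    """An ordered list of class names mapped to integer ids 0..C-1.

    Background is always id 0.
    """

    name: str
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.classes)) != len(self.classes):
            raise ValueError(f"duplicate class names in schema {self.name!r}")
        if self.classes[0] != "background":
            raise ValueError("class id 0 must be 'background'")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def id_of(self, name: str) -> int:
        try:
            return self.classes.index(name)
        except ValueError:
            raise KeyError(f"class {name!r} not in schema {self.name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.classes


#: Lesions-only schema (baseline model): background + four DR lesions.
DR_M1 = ClassSchema("DR-M1", ("background", "MA", "HE", "EX", "CWS"))
#: Anatomy-only schema: background + retina, vessel, optic disc, fovea.
ANAT5 = ClassSchema("ANAT5", ("background", "retina", "vessel", "OD", "FV"))
#: Full nine-class schema: anatomy subclasses plus the four lesions.
FULL9 = ClassSchema(
    "FULL9", ("background", "retina", "vessel", "OD", "FV", "MA", "HE", "EX", "CWS")
)

SCHEMAS = {s.name: s for s in (DR_M1, ANAT5, FULL9)}

#: Fixed indexed-PNG palette for the nine-class schema (id -> RGB).  Colors
#: are artifact constants chosen for visual distinctness; subset schemas use
#: the first C entries.
PALETTE9 = np.array(
    [
        (0, 0, 0),        # background
        (128, 64, 32),    # retina
        (64, 0, 128),     # vessel
        (255, 255, 0),    # OD
        (0, 64, 160),     # FV
        (255, 0, 0),      # MA
        (160, 0, 64),     # HE
        (255, 160, 0),    # EX
        (224, 224, 224),  # CWS
    ],
    dtype=np.uint8,
)


@dataclass
class LabelMap:
    """Per-pixel integer class ids under a named schema."""

    grid: np.ndarray
    schema: ClassSchema

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError("label grid must be 2-D (H, W)")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise TypeError("label grid must be integer-typed")
        if self.grid.size and (self.grid.min() < 0 or self.grid.max() >= self.schema.n_classes):
            bad = np.unique(self.grid[(self.grid < 0) | (self.grid >= self.schema.n_classes)])
            raise ValueError(
                f"label ids {bad.tolist()} invalid under schema "
                f"{self.schema.name!r} (C={self.schema.n_classes})"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape  # type: ignore[return-value]

    def mask_of(self, class_name: str) -> np.ndarray:
        """Boolean mask of pixels carrying ``class_name``."""
        return self.grid == self.schema.id_of(class_name)


# ---------------------------------------------------------------------------
# Otsu thresholding and FOV extraction
# ---------------------------------------------------------------------------

def otsu_threshold(gray: np.ndarray, nbins: int = 256) -> float:
    """Threshold maximizing between-class variance over an ``nbins`` histogram.

    The histogram spans [min, max] of the input.  The returned threshold is
    the *upper edge* value of the qualifying bin: pixels strictly above it
    belong to the upper class.  Ties in the between-class variance are broken
    toward the lowest qualifying bin.

    Raises ``ValueError`` on a constant image (no second class exists).
    """
    gray = np.asarray(gray, dtype=np.float64).ravel()
    lo, hi = float(gray.min()), float(gray.max())
    if lo == hi:
        raise ValueError("Otsu threshold undefined on a constant image")

    hist, edges = np.histogram(gray, bins=nbins, range=(lo, hi))
    p = hist.astype(np.float64) / hist.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])

    # Cumulative class probabilities/means for split after bin k (k in 0..nbins-2).
    w0 = np.cumsum(p)[:-1]
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    w1 = 1.0 - w0
    valid = (w0 > 0) & (w1 > 0)
    sigma_b = np.full(nbins - 1, -np.inf)
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma_b[valid] = (mu_t * w0[valid] - mu[:-1][valid]) ** 2 / (
            w0[valid] * w1[valid]
        )
    k = int(np.argmax(sigma_b))  # argmax returns the first (lowest) maximizer
    return float(edges[k + 1])


def extract_fov(image: np.ndarray, channel: int = 0) -> np.ndarray:
    """Extract the circular field of view from a fundus image.

    Otsu-thresholds one channel (red by default — the dominant channel in
    fundus imagery, giving the highest surround/retina contrast), closes
    thin dark gaps (vessels crossing the FOV rim would otherwise cut
    corridors into the disc), keeps the largest connected component above
    threshold, and fills its holes.

    Returns a boolean H×W mask.  Raises ``ValueError`` if no foreground
    pixel survives thresholding.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (H, W, 3)")
    plane = image[:, :, channel]
    t = otsu_threshold(plane)
    fg = plane > t
    if not fg.any():
        raise ValueError("empty foreground after Otsu thresholding")
    fg = ndimage.binary_closing(fg, structure=np.ones((5, 5)), border_value=0)
    lab, n = ndimage.label(fg)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    largest = 1 + int(np.argmax(sizes))
    mask = ndimage.binary_fill_holes(lab == largest)
    return mask


# ---------------------------------------------------------------------------
# Anatomy / lesion merging
# ---------------------------------------------------------------------------

@dataclass
class MergeReport:
    """Bookkeeping from a merge: lesion pixels clipped to the FOV."""

    clipped_outside_fov: dict[str, int] = field(default_factory=dict)

    @property
    def total_clipped(self) -> int:
        return sum(self.clipped_outside_fov.values())


def merge_anatomy_lesions(
    anatomy: LabelMap,
    lesions: dict[str, np.ndarray],
    out_schema: ClassSchema = FULL9,
) -> tuple[LabelMap, MergeReport]:
    """Overlay lesion masks on an anatomy map, producing ``out_schema`` ids.

    Anatomy ids are re-coded into the output schema, then lesion ids are
    written wherever a lesion mask is set.  Lesions dominate anatomy (a
    hemorrhage pixel on a vessel is a hemorrhage); among overlapping lesions
    the fixed precedence MA > CWS > HE > EX applies, so the result never
    depends on the input dict order.  Lesion pixels outside the anatomy's
    non-background region are clipped (not painted) and counted in the
    returned :class:`MergeReport`.
    """
    if anatomy.schema is not ANAT5 and anatomy.schema.classes != ANAT5.classes:
        raise ValueError("anatomy map must use the ANAT5 schema")
    unknown = set(lesions) - set(LESION_NAMES)
    if unknown:
        raise KeyError(f"unknown lesion name(s): {sorted(unknown)}")
    for name in lesions:
        if name not in out_schema:
            raise KeyError(f"lesion {name!r} has no id in schema {out_schema.name!r}")

    # Re-code anatomy ids into the output schema.
    recode = np.zeros(anatomy.schema.n_classes, dtype=np.int64)
    for i, cname in enumerate(anatomy.schema.classes):
        recode[i] = out_schema.id_of(cname) if cname in out_schema else 0
    grid = recode[anatomy.grid]

    fov = anatomy.grid != 0
    report = MergeReport()
    # Paint in reverse precedence so the highest-precedence lesion lands last.
    for name in reversed(LESION_PRECEDENCE):
        if name not in lesions:
            continue
        mask = np.asarray(lesions[name]).astype(bool)
        if mask.shape != anatomy.shape:
            raise ValueError(f"lesion {name!r} mask shape {mask.shape} != {anatomy.shape}")
        outside = int(np.count_nonzero(mask & ~fov))
        if outside:
            report.clipped_outside_fov[name] = outside
        grid[mask & fov] = out_schema.id_of(name)
    return LabelMap(grid, out_schema), report


def one_hot(labels: LabelMap) -> np.ndarray:
    """Encode a label map as an H×W×C binary tensor (one 1 per pixel)."""
    C = labels.schema.n_classes
    eye = np.eye(C, dtype=np.float64)
    return eye[labels.grid]
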