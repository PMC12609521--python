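"""Image, mask, config and run-record I/O.

Images are 8- or 16-bit PNG/TIFF, mapped to float [0,1] by the bit-depth
maximum on read; 8-bit round-trips are bit-exact.  Label maps travel as
indexed PNG (one class id per pixel) with the package's fixed palette
embedded, so masks survive editing in ordinary viewers.  Every CLI run can
drop a JSON run record (config + seed + input checksums) sufficient to
reproduce it bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml
from PIL import Image

from .labels import PALETTE9, SCHEMAS, ClassSchema, LabelMap

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_labelmap",
    "write_labelmap",
    "load_config",
    "write_run_record",
    "file_checksum",
]

_SUPPORTED = {".png", ".tif", ".tiff"}


def read_image(path: str | Path) -> np.ndarray:
    """Read an RGB PNG/TIFF into a float64 (H, W, 3) array in [0, 1]."""
    path = Path(path)
    if path.suffix.lower() not in _SUPPORTED:
        raise ValueError(f"unsupported image format {path.suffix!r}: {path}")
    try:
        if path.suffix.lower() == ".png":
            with Image.open(path) as im:
                arr = np.asarray(im)
        else:  # TIFF: PIL lacks multichannel 16-bit support
            arr = iio.imread(path)
    except Exception as exc:
        raise ValueError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 2:
        raise ValueError(f"grayscale input {path}: an RGB image is required")
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValueError(f"unsupported channel layout {arr.shape} in {path}")
    arr = arr[:, :, :3]
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    raise ValueError(f"unsupported bit depth {arr.dtype} in {path}")


def write_image(path: str | Path, image: np.ndarray, bitdepth: int = 8) -> None:
    """Write a float [0,1] RGB array as 8-bit PNG/TIFF (16-bit TIFF only)."""
    path = Path(path)
    image = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    if bitdepth == 8:
        Image.fromarray(np.round(image * 255.0).astype(np.uint8)).save(path)
    elif bitdepth == 16:
        if path.suffix.lower() == ".png":
            raise ValueError("16-bit PNG write is not supported; use TIFF")
        iio.imwrite(path, np.round(image * 65535.0).astype(np.uint16))
    else:
        raise ValueError("bitdepth must be 8 or 16")


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask (any nonzero pixel is True) from PNG."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return arr > 0


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    Image.fromarray(np.where(np.asarray(mask).astype(bool), 255, 0).astype(np.uint8)).save(path)


def read_labelmap(path: str | Path, schema: ClassSchema | str) -> LabelMap:
    """Read an indexed PNG as a label map, validating ids against the schema."""
    if isinstance(schema, str):
        schema = SCHEMAS[schema]
    with Image.open(path) as im:
        if im.mode != "P":
            raise ValueError(f"{path}: label maps must be indexed PNG (mode 'P')")
        grid = np.asarray(im).astype(np.int64)
    bad = np.unique(grid[grid >= schema.n_classes])
    if bad.size:
        raise ValueError(
            f"{path}: ids {bad.tolist()} out of range for schema {schema.name!r}"
        )
    return LabelMap(grid, schema)


def write_labelmap(path: str | Path, labels: LabelMap) -> None:
    """Write a label map as indexed PNG with the fixed class palette."""
    im = Image.fromarray(labels.grid.astype(np.uint8), mode="P")
    palette = np.zeros((256, 3), dtype=np.uint8)
    palette[: len(PALETTE9)] = PALETTE9
    im.putpalette(palette.ravel().tolist())
    im.save(path)


CONFIG_VERSION = 1


def load_config(path: str | Path, allowed_keys: set[str]) -> dict:
    """Load a YAML config, rejecting unknown keys.

    Silent misconfiguration (a typoed ``alpha`` or estimator name) would
    invalidate experiments, so unknown keys are errors, not warnings.  The
    file must carry ``schema_version: 1``.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    version = cfg.pop("schema_version", None)
    if version != CONFIG_VERSION:
        raise ValueError(
            f"{path}: missing or unsupported schema_version "
            f"(expected {CONFIG_VERSION}, got {version!r})"
        )
    unknown = set(cfg) - allowed_keys
    if unknown:
        raise ValueError(f"{path}: unknown config key(s): {sorted(unknown)}")
    return cfg


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_run_record(
    out_dir: str | Path,
    command: str,
    params: dict,
    seed: int | None,
    inputs: list[str | Path] = (),
) -> Path:
    """Drop a machine-readable record sufficient to reproduce the run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "command": command,
        "params": params,
        "seed": seed,
        "input_checksums": {str(p): file_checksum(p) for p in inputs},
    }
    path = out_dir / "run_record.json"
    path.write_text(json.dumps(record, indent=2, default=str) + "\n")
    return path
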