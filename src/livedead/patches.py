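"""Raw image pairs, bit-depth conversion, and overlapping patch extraction.

Raw microscope captures (16-bit, 1344x1024 px at full scale) are cropped into
registered 224x224 patch pairs with a sliding window. Patches overlap by
default (stride 112, i.e. 50%) to augment the number of images; a trailing
patch flush with each far edge is added whenever the stride grid does not
land exactly on the border, so no pixel is lost. Offsets are 0-based,
top-left origin, half-open ``[offset, offset + patch)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

PATCH_SIZE = 224
DEFAULT_STRIDE = 112

__all__ = [
    "RawImagePair",
    "PatchPair",
    "DatasetLoadResult",
    "convert_16bit_to_8bit",
    "grid_offsets",
    "crop_patches",
    "load_dataset",
]


@dataclass
class RawImagePair:
    """A bright-field image and its spatially registered fluorescence image."""

    raw_image_id: str
    bright_field: np.ndarray
    fluorescence: np.ndarray
    condition: str = "no_treatment"

    def __post_init__(self) -> None:
        if self.bright_field.shape != self.fluorescence.shape:
            raise ValueError(
                f"channel shape mismatch for {self.raw_image_id}: "
                f"{self.bright_field.shape} vs {self.fluorescence.shape}"
            )
        if self.bright_field.ndim != 2:
            raise ValueError("images must be 2-D single-channel arrays")

    @property
    def shape(self) -> tuple[int, int]:
        return self.bright_field.shape


@dataclass
class PatchPair:
    """One registered 224x224 crop of both channels, with provenance.

    The fluorescence crop keeps its raw intensity scale (weak labels are
    computed on raw intensities); ``bright_field_8bit`` provides the display /
    classifier view.
    """

    patch_id: str
    raw_image_id: str
    x_offset: int
    y_offset: int
    bright_field: np.ndarray
    fluorescence: np.ndarray

    @property
    def bright_field_8bit(self) -> np.ndarray:
        return convert_16bit_to_8bit(self.bright_field)


@dataclass
class DatasetLoadResult:
    pairs: list[RawImagePair] = field(default_factory=list)
    unpaired: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


def convert_16bit_to_8bit(image: np.ndarray) -> np.ndarray:
    """Linearly rescale a 16-bit image to unsigned 8-bit.

    Full-range mapping ``v / 257`` (65535 -> 255) with rounding half away
    from zero. Out-of-range input values are clamped and logged rather than
    rejected.
    """
    arr = np.asarray(image, dtype=np.float64)
    if arr.min() < 0 or arr.max() > 65535:
        logger.warning("input values outside [0, 65535]; clamping")
        arr = np.clip(arr, 0, 65535)
    # values are non-negative, so floor(v + 0.5) rounds half away from zero
    return np.floor(arr / 257.0 + 0.5).astype(np.uint8)


def grid_offsets(length: int, patch_size: int, stride: int) -> list[int]:
    """Offsets {0, stride, 2*stride, ...} plus a trailing offset flush with
    the far edge when the grid does not land exactly on it."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if patch_size > length:
        raise ValueError(f"patch size {patch_size} exceeds dimension {length}")
    offsets = list(range(0, length - patch_size + 1, stride))
    if offsets[-1] + patch_size < length:
        offsets.append(length - patch_size)
    return offsets


def crop_patches(pair: RawImagePair, patch_size: int = PATCH_SIZE,
                 stride: int = DEFAULT_STRIDE) -> list[PatchPair]:
    """Crop a raw pair into registered patch pairs on a sliding-window grid."""
    h, w = pair.shape
    xs = grid_offsets(w, patch_size, stride)
    ys = grid_offsets(h, patch_size, stride)
    out = []
    for y in ys:
        for x in xs:
            out.append(PatchPair(
                patch_id=f"{pair.raw_image_id}_x{x}_y{y}",
                raw_image_id=pair.raw_image_id,
                x_offset=x, y_offset=y,
                bright_field=pair.bright_field[y:y + patch_size, x:x + patch_size],
                fluorescence=pair.fluorescence[y:y + patch_size, x:x + patch_size],
            ))
    return out


def load_dataset(manifest_path: str | Path) -> DatasetLoadResult:
    """Load raw image pairs from a channel manifest CSV.

    The manifest has columns (raw_image_id, channel, path, condition) with
    one row per channel image; paths are resolved relative to the manifest.
    Ids lacking either channel are reported in ``result.unpaired``, never
    silently dropped. Raises ``FileNotFoundError`` for missing files and
    ``ValueError`` for channel dimension mismatches.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    required = {"raw_image_id", "channel", "path"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    base = manifest_path.parent
    result = DatasetLoadResult()
    for rid, group in df.groupby("raw_image_id", sort=True):
        channels = dict(zip(group["channel"], group["path"]))
        if not {"bright_field", "fluorescence"}.issubset(channels):
            result.unpaired.append(str(rid))
            logger.warning("raw_image_id %s lacks a complete channel pair", rid)
            continue
        imgs = {}
        for ch in ("bright_field", "fluorescence"):
            p = base / channels[ch]
            if not p.exists():
                raise FileNotFoundError(f"missing image file: {p}")
            imgs[ch] = _read_image(p)
        condition = str(group["condition"].iloc[0]) if "condition" in group else "no_treatment"
        result.pairs.append(RawImagePair(
            raw_image_id=str(rid), bright_field=imgs["bright_field"],
            fluorescence=imgs["fluorescence"], condition=condition,
        ))
    return result


def _read_image(path: Path) -> np.ndarray:
    if path.suffix.lower() in {".tif", ".tiff"}:
        return tifffile.imread(path)
    import imageio.v3 as iio

    return np.asarray(iio.imread(path))


def write_patch_manifest(patches: list[PatchPair], path: str | Path) -> pd.DataFrame:
    """Write a patch manifest CSV (patch_id, parent id, offsets)."""
    df = pd.DataFrame([
        {"patch_id": p.patch_id, "raw_image_id": p.raw_image_id,
         "x_offset": p.x_offset, "y_offset": p.y_offset}
        for p in patches
    ])
    df.to_csv(path, index=False)
    return df
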