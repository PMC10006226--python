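"""Micrograph and ROI ingestion.

Reads histology micrographs plus per-nucleus binary masks, converts to
grayscale, crops each ROI to its mask bounding box and quantizes gray
levels for downstream co-occurrence analysis.

Conventions
-----------
* Gray levels are 0-based (``0 .. G-1``); bounding boxes use 0-based,
  half-open row/col intervals.
* A mask image marks a pixel as inside the ROI iff it is nonzero.
* Grayscale conversion uses ITU-R BT.601 luma weights.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Sequence

import imageio.v3 as iio
import numpy as np

__all__ = [
    "Micrograph",
    "RoiRecord",
    "GrayPatch",
    "QuantizationConfig",
    "rgb_to_gray",
    "load_image",
    "load_roi",
    "quantize_gray",
    "read_manifest",
    "write_manifest",
    "MANIFEST_COLUMNS",
]

MANIFEST_COLUMNS = ("roi_id", "image_path", "mask_path", "group", "animal_id")

#: BT.601 luma weights for R, G, B.
_LUMA = np.array([0.299, 0.587, 0.114])

VALID_LEVELS = (8, 16, 32, 64, 128, 256)
QuantStrategy = Literal["minmax", "bitshift", "sigma3"]


@dataclass(frozen=True)
class Micrograph:
    """A single micrograph: 2-D grayscale or 3-channel RGB integer pixels."""

    pixels: np.ndarray
    bit_depth: int = 8
    source_path: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim not in (2, 3) or (px.ndim == 3 and px.shape[2] != 3):
            raise ValueError(f"expected 2-D grayscale or H×W×3 RGB pixels, got shape {px.shape}")
        if px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError("micrograph must be at least 2×2 pixels")
        hi = 2**self.bit_depth - 1
        if px.min() < 0 or px.max() > hi:
            raise ValueError(f"intensities outside [0, {hi}] for bit depth {self.bit_depth}")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def is_gray(self) -> bool:
        return self.pixels.ndim == 2


@dataclass(frozen=True)
class RoiRecord:
    """One manifest row: a nucleus ROI with its group label and animal of origin."""

    roi_id: str
    image_path: str
    mask_path: str
    group: int  # 1 = AKI, 0 = control
    animal_id: str

    def __post_init__(self) -> None:
        if self.group not in (0, 1):
            raise ValueError(f"group must be 0 or 1, got {self.group!r}")


@dataclass
class GrayPatch:
    """One nuclear ROI cropped to its mask bounding box.

    ``intensities`` holds the working gray levels (quantized to ``levels``
    once :func:`quantize_gray` has run); ``raw`` keeps the original 8-bit
    grayscale values so that wavelet energies can be computed on
    unquantized data.
    """

    intensities: np.ndarray
    mask: np.ndarray
    levels: int
    origin: tuple[int, int] = (0, 0)
    raw: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.intensities.shape != self.mask.shape:
            raise ValueError("intensities and mask shapes differ")
        if self.mask.sum() < 8:
            raise ValueError("ROI must contain at least 8 masked-in pixels")
        inside = self.intensities[self.mask]
        if inside.min() < 0 or inside.max() > self.levels - 1:
            raise ValueError(f"masked-in intensities outside [0, {self.levels - 1}]")
        if self.raw is None:
            self.raw = self.intensities.copy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class QuantizationConfig:
    """Gray-level quantization policy applied per ROI.

    ``minmax`` stretches the masked-in range to ``0 .. levels-1`` (the
    default: makes features invariant to illumination); ``bitshift``
    drops low bits of the 8-bit value; ``sigma3`` clips to mean ± 3 SD of
    the masked-in pixels before min-max stretching.
    """

    levels: int = 64
    strategy: QuantStrategy = "minmax"

    def __post_init__(self) -> None:
        if self.levels not in VALID_LEVELS:
            raise ValueError(f"levels must be a power of two in {VALID_LEVELS}, got {self.levels}")
        if self.strategy not in ("minmax", "bitshift", "sigma3"):
            raise ValueError(f"unknown quantization strategy {self.strategy!r}")


def rgb_to_gray(micrograph: Micrograph) -> Micrograph:
    """Convert a 3-channel micrograph to 8-bit grayscale (BT.601 luma).

    Luminance = round(0.299·R + 0.587·G + 0.114·B). A grayscale input is
    returned unchanged.
    """
    if micrograph.is_gray:
        return micrograph
    px = micrograph.pixels.astype(np.float64)
    if micrograph.bit_depth != 8:
        # rescale to 8 bit before applying the luma weights
        px = px * (255.0 / (2**micrograph.bit_depth - 1))
    gray = np.rint(px @ _LUMA).astype(np.uint8)
    return Micrograph(pixels=gray, bit_depth=8, source_path=micrograph.source_path)


def load_image(path: str | Path) -> Micrograph:
    """Read a PNG/BMP/TIFF image from disk as a :class:`Micrograph`."""
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha if present
        arr = arr[:, :, :3]
    bit_depth = 16 if arr.dtype == np.uint16 else 8
    return Micrograph(pixels=arr, bit_depth=bit_depth, source_path=str(path))


def _mask_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return rows[0], rows[-1] + 1, cols[0], cols[-1] + 1


def load_roi(
    record: RoiRecord,
    quantization: QuantizationConfig = QuantizationConfig(),
    root: str | Path | None = None,
) -> GrayPatch:
    """Load one ROI: read image + mask, gray-convert, crop, quantize.

    Paths in ``record`` are resolved relative to ``root`` when given.
    Raises ``ValueError`` on an empty mask or an image/mask shape mismatch.
    """
    base = Path(root) if root is not None else Path(".")
    img = rgb_to_gray(load_image(base / record.image_path))
    mask_arr = iio.imread(base / record.mask_path)
    if mask_arr.ndim == 3:
        mask_arr = mask_arr[:, :, 0]
    mask = mask_arr != 0
    if mask.shape != img.pixels.shape:
        raise ValueError(
            f"ROI {record.roi_id}: mask shape {mask.shape} != image shape {img.pixels.shape}"
        )
    if not mask.any():
        raise ValueError(f"ROI {record.roi_id}: mask is empty")
    r0, r1, c0, c1 = _mask_bbox(mask)
    patch = GrayPatch(
        intensities=img.pixels[r0:r1, c0:c1].copy(),
        mask=mask[r0:r1, c0:c1].copy(),
        levels=256,
        origin=(int(r0), int(c0)),
    )
    return quantize_gray(patch, quantization.levels, quantization.strategy)


def quantize_gray(patch: GrayPatch, levels: int, strategy: QuantStrategy = "minmax") -> GrayPatch:
    """Quantize a patch's gray levels to ``levels`` bins.

    Quantization statistics (min/max/mean/SD) come from masked-in pixels
    only; the mapping is then applied to the whole patch. Monotone
    non-decreasing in input intensity for every strategy.
    """
    if levels not in VALID_LEVELS:
        raise ValueError(f"levels must be a power of two in {VALID_LEVELS}, got {levels}")
    vals = patch.raw.astype(np.float64)
    inside = vals[patch.mask]

    if strategy == "bitshift":
        shift = 8 - int(np.log2(levels))
        q = patch.raw.astype(np.int64) >> shift
    elif strategy in ("minmax", "sigma3"):
        if strategy == "sigma3":
            mu, sd = inside.mean(), inside.std()
            lo, hi = mu - 3.0 * sd, mu + 3.0 * sd
            vals = np.clip(vals, lo, hi)
            inside = np.clip(inside, lo, hi)
        vmin, vmax = inside.min(), inside.max()
        if vmax == vmin:
            q = np.zeros(patch.shape, dtype=np.int64)
        else:
            q = np.rint((np.clip(vals, vmin, vmax) - vmin) / (vmax - vmin) * (levels - 1))
            q = q.astype(np.int64)
    else:
        raise ValueError(f"unknown quantization strategy {strategy!r}")

    return GrayPatch(
        intensities=q, mask=patch.mask, levels=levels, origin=patch.origin, raw=patch.raw
    )


def read_manifest(path: str | Path) -> list[RoiRecord]:
    """Read the ROI manifest CSV (`roi_id,image_path,mask_path,group,animal_id`)."""
    records: list[RoiRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(MANIFEST_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        for row in reader:
            records.append(
                RoiRecord(
                    roi_id=row["roi_id"],
                    image_path=row["image_path"],
                    mask_path=row["mask_path"],
                    group=int(row["group"]),
                    animal_id=row["animal_id"],
                )
            )
    return records


def write_manifest(records: Sequence[RoiRecord], path: str | Path) -> None:
    """Write ROI records to a manifest CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for r in records:
            writer.writerow([r.roi_id, r.image_path, r.mask_path, r.group, r.animal_id])


def iter_patches(
    records: Sequence[RoiRecord],
    quantization: QuantizationConfig = QuantizationConfig(),
    root: str | Path | None = None,
) -> Iterator[tuple[RoiRecord, GrayPatch]]:
    """Yield ``(record, patch)`` for every manifest row."""
    for rec in records:
        yield rec, load_roi(rec, quantization, root=root)
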