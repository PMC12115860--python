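"""Image container, normalization, coordinate conventions and raster/report I/O.

Conventions used throughout the package:

* images are 2-D arrays of gray values in ``[0, 1]`` (float64), row 0 at top;
* pixel addressing is 0-based ``(row, col)``;
* 8-bit rasters are mapped linearly to ``[0, 1]`` by division by 255;
* classification maps use the integer labels :data:`BACKGROUND`,
  :data:`MAIN_SPOT` and :data:`DIFFRACTION`, written to disk with the
  gray palette 0 / 255 / 128.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

logger = logging.getLogger(__name__)

# Pixel classes of a classification map.
BACKGROUND = 0
MAIN_SPOT = 1
DIFFRACTION = 2

#: gray palette used when a classification map is written as an 8-bit raster
MASK_PALETTE = {BACKGROUND: 0, MAIN_SPOT: 255, DIFFRACTION: 128}
_PALETTE_INVERSE = {v: k for k, v in MASK_PALETTE.items()}


@dataclass(frozen=True)
class GrayImage:
    """A single-channel image with gray values in ``[0, 1]``.

    Parameters
    ----------
    pixels : ndarray of shape (M, N)
        Gray values; every value must be finite and in ``[0, 1]``.
    provenance : str
        Free-text tag recording where the raster came from (a file path,
        ``"synthetic"``, or a processing-stage note).
    """

    pixels: np.ndarray
    provenance: str = "unknown"

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError(f"GrayImage requires a 2-D raster, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("GrayImage values must be finite")
        if arr.min() < 0.0 or arr.max() > 1.0:
            raise ValueError("GrayImage values must lie in [0, 1]")
        arr = arr.copy()
        arr.setflags(write=False)
        object.__setattr__(self, "pixels", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray, note: str | None = None) -> "GrayImage":
        """Return a new image with ``pixels``, appending ``note`` to provenance."""
        prov = self.provenance if note is None else f"{self.provenance}|{note}"
        return GrayImage(pixels, provenance=prov)


def normalize_image(raw: np.ndarray, provenance: str = "array") -> GrayImage:
    """Map an 8-bit raster (values 0–255) linearly onto ``[0, 1]``.

    Raises
    ------
    ValueError
        If any value lies outside ``[0, 255]``.
    """
    arr = np.asarray(raw)
    if arr.size and (arr.min() < 0 or arr.max() > 255):
        raise ValueError("raw gray values must lie in [0, 255]")
    return GrayImage(arr.astype(np.float64) / 255.0, provenance=provenance)


def denormalize(img: GrayImage) -> np.ndarray:
    """Re-quantize a normalized image to an 8-bit raster (inverse of normalize)."""
    return np.rint(img.pixels * 255.0).astype(np.uint8)


def read_image(path: str | Path) -> GrayImage:
    """Read a single-channel 8-bit PNG/TIFF image.

    Multi-channel inputs are converted to a single channel by averaging the
    channels (luminance average); the conversion is logged.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3:
        logger.warning("multi-channel input %s converted to single channel by luminance average", path)
        arr = arr.astype(np.float64).mean(axis=2)
        arr = np.rint(arr)
    if arr.ndim != 2:
        raise IOError(f"{path}: expected a 2-D single-channel image, got shape {arr.shape}")
    if not np.issubdtype(np.asarray(arr).dtype, np.number):
        raise IOError(f"{path}: non-numeric image payload")
    if arr.min() < 0 or arr.max() > 255:
        raise IOError(f"{path}: expected 8-bit gray values in [0, 255]")
    return normalize_image(np.asarray(arr, dtype=np.uint8), provenance=str(path))


def write_image(img: GrayImage, path: str | Path) -> None:
    """Write a normalized image as a single-channel 8-bit raster (PNG/TIFF)."""
    iio.imwrite(Path(path), denormalize(img))


def write_mask(classmap: np.ndarray, path: str | Path) -> None:
    """Write a classification map using the 0/255/128 gray palette."""
    classmap = np.asarray(classmap)
    out = np.zeros(classmap.shape, dtype=np.uint8)
    for label, gray in MASK_PALETTE.items():
        out[classmap == label] = gray
    iio.imwrite(Path(path), out)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a classification map written by :func:`write_mask`."""
    arr = iio.imread(Path(path))
    out = np.zeros(arr.shape, dtype=np.uint8)
    for gray, label in _PALETTE_INVERSE.items():
        out[arr == gray] = label
    return out


def write_ring_report(stack, path: str | Path) -> None:
    """Write a surface stack as a CSV ring report (one record per ring)."""
    import pandas as pd

    records = []
    for i, ring in enumerate(stack.rings):
        records.append(
            {
                "ring_id": i,
                "center_row": ring.center[0],
                "center_col": ring.center[1],
                "inner_radius_px": ring.inner_radius,
                "ring_width_px": ring.width,
                "orientation": ring.orientation,
                "z_relative": ring.z,
            }
        )
    pd.DataFrame.from_records(
        records,
        columns=[
            "ring_id",
            "center_row",
            "center_col",
            "inner_radius_px",
            "ring_width_px",
            "orientation",
            "z_relative",
        ],
    ).to_csv(Path(path), index=False)


def read_ring_report(path: str | Path):
    """Read a CSV ring report back into a list of rings."""
    import pandas as pd

    from .rings import RingModel

    df = pd.read_csv(Path(path))
    rings = []
    for _, row in df.iterrows():
        rings.append(
            RingModel(
                center=(float(row["center_row"]), float(row["center_col"])),
                inner_radius=float(row["inner_radius_px"]),
                width=float(row["ring_width_px"]),
                orientation=str(row["orientation"]),
                z=None if pd.isna(row["z_relative"]) else float(row["z_relative"]),
            )
        )
    return rings
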