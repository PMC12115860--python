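"""Post-de-diffraction beautification of degraded rings.

Once a ring's ideal geometry is known (measured directly or corrected via
the proportionality laws), the spot is snapped to its ideal annulus:
everything outside the annulus in the ring's neighbourhood is set to the
background gray value, dim pixels inside are repaired from their vertical
neighbour toward the ring's bright mid-row (the vertical falloff makes
that the informative neighbour), and pixels that stay too dim are set to
maximum brightness so the spot stands out against the background.
"""

from __future__ import annotations

import numpy as np

from .raster import GrayImage
from .rings import RingModel


def annulus_mask(shape: tuple[int, int], ring: RingModel) -> np.ndarray:
    """Boolean mask of a ring's ideal annulus (half-open in radius).

    A focused point ring (``r = 0``) maps to the full disk of diameter
    ``d`` around the center rather than a half-plane annulus.
    """
    m, n = shape
    cr, cc = ring.center
    rows = np.arange(m)[:, None] - cr
    cols = np.arange(n)[None, :] - cc
    dist = np.hypot(rows, cols)
    if ring.inner_radius == 0:
        return dist < ring.width / 2.0 + 0.5
    half = rows <= 0 if ring.orientation == "upper" else rows >= 0
    return (dist >= ring.inner_radius) & (dist < ring.outer_radius) & half


def _neighbourhood(shape: tuple[int, int], ring: RingModel, margin: int) -> np.ndarray:
    """The ring's own annular neighbourhood: the ideal annulus dilated by
    ``margin`` pixels radially and across the flat edge.  Restricting the
    trim to this band leaves nested neighbouring rings untouched."""
    m, n = shape
    cr, cc = ring.center
    rows = np.arange(m)[:, None] - cr
    cols = np.arange(n)[None, :] - cc
    dist = np.hypot(rows, cols)
    if ring.inner_radius == 0:
        return dist < ring.width / 2.0 + 0.5 + margin
    half = rows <= margin if ring.orientation == "upper" else rows >= -margin
    return (
        (dist >= max(ring.inner_radius - margin, 0.0))
        & (dist < ring.outer_radius + margin)
        & half
    )


def _default_background(pixels: np.ndarray, annulus: np.ndarray) -> float:
    outside = pixels[~annulus]
    return float(np.median(outside)) if outside.size else 0.0


def _mid_row(ring: RingModel) -> float:
    cr = ring.center[0]
    if ring.inner_radius == 0:
        return cr
    half_extent = ring.outer_radius / 2.0
    return cr - half_extent if ring.orientation == "upper" else cr + half_extent


def beautify_ring(
    img: GrayImage,
    ring: RingModel,
    tau_low: float = 0.1,
    background_value: float | None = None,
    margin: int = 8,
) -> GrayImage:
    """Snap a ring to its ideal annulus and repair dim pixels.

    Within the ring's neighbourhood (annulus bounding box plus ``margin``):
    pixels outside the ideal annulus become ``background_value`` (default:
    the median gray outside the annulus); in-annulus pixels dimmer than
    ``tau_low`` take the gray of the adjacent longitudinal pixel (same
    column, one row toward the ring's bright mid-row); if that is still
    dimmer than ``tau_low`` the pixel is set to 1 (maximum brightness).
    Idempotent.
    """
    if ring.width <= 0:
        raise ValueError("degenerate ring: width must be > 0")
    if not 0.0 < tau_low < 1.0:
        raise ValueError("tau_low must lie in (0, 1)")
    annulus = annulus_mask(img.shape, ring)
    if background_value is None:
        background_value = _default_background(img.pixels, annulus)
    region = _neighbourhood(img.shape, ring, margin)
    out = img.pixels.copy()

    out[region & ~annulus] = background_value

    mid = _mid_row(ring)
    dim_rows, dim_cols = np.nonzero(annulus & (img.pixels < tau_low))
    m = img.shape[0]
    for row, col in zip(dim_rows.tolist(), dim_cols.tolist()):
        if abs(row - mid) < 0.5:
            candidates = [r for r in (row - 1, row + 1) if 0 <= r < m]
            neighbour = max(candidates, key=lambda r: img.pixels[r, col])
        else:
            neighbour = row + 1 if row < mid else row - 1
            neighbour = min(max(neighbour, 0), m - 1)
        value = img.pixels[neighbour, col]
        out[row, col] = value if value >= tau_low else 1.0
    return img.with_pixels(out, note="beautified")


def trim_to_standard_line(
    img: GrayImage,
    ring: RingModel,
    tau_low: float = 0.1,
    background_value: float | None = None,
    margin: int = 8,
    max_sweeps: int = 100,
) -> GrayImage:
    """Trim protrusions against the ideal annulus and fill in-annulus voids.

    Mass beyond the ideal annulus (within the ring's neighbourhood) is set
    to the background value; voids inside the annulus (gray < ``tau_low``)
    are filled with the mean gray of their 8-connected non-void in-annulus
    neighbours, sweeping alternately top-down and bottom-up until no void
    remains (at most ``max_sweeps`` sweeps).  Idempotent on clean rings.

    Raises
    ------
    ValueError
        If the annulus is entirely void, so no fill source exists.
    """
    if ring.width <= 0:
        raise ValueError("degenerate ring: width must be > 0")
    annulus = annulus_mask(img.shape, ring)
    if background_value is None:
        background_value = _default_background(img.pixels, annulus)
    region = _neighbourhood(img.shape, ring, margin)
    out = img.pixels.copy()
    out[region & ~annulus] = background_value

    void = annulus & (out < tau_low)
    if void.any() and not (annulus & ~void).any():
        raise ValueError("annulus fully void: nothing to fill from")

    m, n = img.shape
    for sweep in range(max_sweeps):
        coords = np.argwhere(void)
        if coords.size == 0:
            break
        if sweep % 2 == 1:
            coords = coords[::-1]
        filled_any = False
        for row, col in coords:
            values = []
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    rr, ccol = row + dr, col + dc
                    if 0 <= rr < m and 0 <= ccol < n and annulus[rr, ccol] and not void[rr, ccol]:
                        values.append(out[rr, ccol])
            if values:
                out[row, col] = float(np.mean(values))
                void[row, col] = False
                filled_any = True
        if not filled_any:
            break
    return img.with_pixels(out, note="trimmed")
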