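"""Local-background prediction and spot-interval screening.

The background gray level of a pixel is predicted as the mean of the 40
pixels that lie inside the 7x7 window centred on it but outside its 3x3
neighbourhood.  A pixel whose gray value exceeds the prediction by more than
a threshold ``tau_e`` is flagged as a target (spot) pixel -- at this stage no
distinction is made between main-spot and diffraction pixels.  Connected
groups of flagged pixels yield rectangular *spot intervals*, one per imaged
reflective surface, that confine all later per-row processing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .raster import GrayImage

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class BackgroundModel:
    """Fixed-weight local-mean background predictor.

    The offset set ``Sj`` is the ``window x window`` square minus the
    ``core x core`` neighbourhood, each offset carrying weight
    ``1/|Sj|`` (40 offsets of weight 1/40 for the 7x7 / 3x3 default).
    At borders the offset set is clipped to the frame and the weight
    rescaled so the weights always sum to 1.

    Parameters
    ----------
    window : int
        Side of the outer square window (odd), default 7.
    core : int
        Side of the excluded central neighbourhood (odd), default 3.
    tau_e : float
        Residual threshold in normalized gray units above which a pixel is
        flagged as a target pixel, default 0.08.
    """

    window: int = 7
    core: int = 3
    tau_e: float = 0.08

    def __post_init__(self) -> None:
        if self.window % 2 == 0 or self.core % 2 == 0 or self.core >= self.window:
            raise ValueError("window and core must be odd with core < window")
        if not 0.0 < self.tau_e < 1.0:
            raise ValueError("tau_e must lie in (0, 1)")

    @property
    def offsets(self) -> list[tuple[int, int]]:
        """The background offset set ``Sj`` as (l, k) pairs."""
        half_w, half_c = self.window // 2, self.core // 2
        return [
            (l, k)
            for l in range(-half_w, half_w + 1)
            for k in range(-half_w, half_w + 1)
            if max(abs(l), abs(k)) > half_c
        ]

    @property
    def kernel(self) -> np.ndarray:
        """Binary footprint of ``Sj`` as a window x window array."""
        kern = np.ones((self.window, self.window), dtype=np.float64)
        half_w, half_c = self.window // 2, self.core // 2
        kern[half_w - half_c : half_w + half_c + 1, half_w - half_c : half_w + half_c + 1] = 0.0
        return kern


@dataclass(frozen=True)
class SpotInterval:
    """Rectangular pixel region screened as containing one surface's spot.

    Row and column ranges are half-open ``[r0, r1)`` / ``[c0, c1)``.
    """

    row_range: tuple[int, int]
    col_range: tuple[int, int]
    surface_index: int = 0

    def __post_init__(self) -> None:
        if self.row_range[0] >= self.row_range[1] or self.col_range[0] >= self.col_range[1]:
            raise ValueError("SpotInterval must be non-empty")
        if min(self.row_range[0], self.col_range[0]) < 0:
            raise ValueError("SpotInterval must lie within image bounds")

    @property
    def extent(self) -> int:
        """Largest side of the interval, used to order surfaces."""
        return max(self.row_range[1] - self.row_range[0], self.col_range[1] - self.col_range[0])

    def contains(self, other: "SpotInterval") -> bool:
        return (
            self.row_range[0] <= other.row_range[0]
            and self.row_range[1] >= other.row_range[1]
            and self.col_range[0] <= other.col_range[0]
            and self.col_range[1] >= other.col_range[1]
        )

    def overlaps(self, other: "SpotInterval") -> bool:
        return (
            self.row_range[0] < other.row_range[1]
            and other.row_range[0] < self.row_range[1]
            and self.col_range[0] < other.col_range[1]
            and other.col_range[0] < self.col_range[1]
        )


def background_map(
    img: GrayImage,
    model: BackgroundModel | None = None,
    exclude: np.ndarray | None = None,
) -> np.ndarray:
    """Predicted background gray level ``Y`` at every pixel.

    Each value is the mean of the in-bounds ``Sj`` pixels; at borders the
    mean runs over the clipped offset set so it stays a true average.

    ``exclude`` optionally removes pixels from every ``Sj`` (the background
    set is meant to hold *background* pixels; when replacing flagged pixels
    the flagged set itself must not contribute).  A pixel whose clipped set
    becomes empty falls back to the global median of unexcluded pixels.
    """
    model = model or BackgroundModel()
    kern = model.kernel
    if exclude is None:
        total = ndimage.correlate(img.pixels, kern, mode="constant", cval=0.0)
        count = ndimage.correlate(np.ones_like(img.pixels), kern, mode="constant", cval=0.0)
        return total / count
    keep = ~np.asarray(exclude, dtype=bool)
    total = ndimage.correlate(img.pixels * keep, kern, mode="constant", cval=0.0)
    count = ndimage.correlate(keep.astype(np.float64), kern, mode="constant", cval=0.0)
    kept = img.pixels[keep]
    fallback = float(np.median(kept)) if kept.size else 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(count > 0, total / np.maximum(count, 1e-12), fallback)
    return out


def predict_background(
    img: GrayImage, pixel: tuple[int, int], model: BackgroundModel | None = None
) -> float:
    """Predicted background gray ``Y`` at a single pixel (mean over ``Sj``)."""
    model = model or BackgroundModel()
    row, col = pixel
    m, n = img.shape
    values = [
        img.pixels[row - l, col - k]
        for l, k in model.offsets
        if 0 <= row - l < m and 0 <= col - k < n
    ]
    return float(np.mean(values))


def residual_map(img: GrayImage, model: BackgroundModel | None = None) -> np.ndarray:
    """Residual ``E = f - Y`` at every pixel (in ``[-1, 1]``)."""
    return img.pixels - background_map(img, model)


def residual(img: GrayImage, pixel: tuple[int, int], model: BackgroundModel | None = None) -> float:
    """Residual ``E = f - Y`` at a single pixel."""
    return float(img.pixels[pixel]) - predict_background(img, pixel, model)


def screen_targets(img: GrayImage, model: BackgroundModel | None = None) -> np.ndarray:
    """Boolean mask of target pixels: residual ``E`` strictly above ``tau_e``.

    Diffraction pixels are flagged together with main-spot pixels at this
    stage; the distinction is made later by the gradient classifier.
    """
    model = model or BackgroundModel()
    return residual_map(img, model) > model.tau_e


def brightness_mask(img: GrayImage, model: BackgroundModel | None = None) -> np.ndarray:
    """Pixels brighter than the global background median by more than ``tau_e``.

    The local-mean residual is blind to the *interior* of spots wider than
    its window, so interval detection unions this absolute test with the
    residual mask; see :func:`target_mask`.
    """
    model = model or BackgroundModel()
    return img.pixels > float(np.median(img.pixels)) + model.tau_e


def target_mask(img: GrayImage, model: BackgroundModel | None = None) -> np.ndarray:
    """Combined target mask used by interval detection (residual OR brightness)."""
    model = model or BackgroundModel()
    return screen_targets(img, model) | brightness_mask(img, model)


def _merge_groups(boxes: list[tuple[int, int, int, int]]) -> list[list[int]]:
    """Group box indices whose boxes overlap without one containing the other."""

    def _interval(b):
        return SpotInterval((b[0], b[1]), (b[2], b[3]))

    n = len(boxes)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = _interval(boxes[i]), _interval(boxes[j])
            if a.overlaps(b) and not (a.contains(b) or b.contains(a)):
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def spot_components(
    mask: np.ndarray,
    min_component_px: int = 20,
    merge_radius: int = 2,
) -> list[tuple[SpotInterval, np.ndarray]]:
    """Surface-level components of a target mask.

    Connected components (8-connectivity) smaller than ``min_component_px``
    are dropped; components closer than ``2 * merge_radius`` pixels are
    joined (fragments of one broken spot); bounding boxes that overlap are
    merged unless one is nested inside the other -- nested intervals belong
    to distinct, concentric surfaces and keep distinct indices.  Returns
    ``(interval, component mask)`` pairs ordered by decreasing extent; the
    per-component masks let nested surfaces be measured independently.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    if merge_radius > 0:
        work = ndimage.binary_dilation(mask, structure=_EIGHT, iterations=merge_radius)
    else:
        work = mask
    labels, _ = ndimage.label(work, structure=_EIGHT)
    boxes: list[tuple[int, int, int, int]] = []
    masks: list[np.ndarray] = []
    for idx, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        sub = mask[sl] & (labels[sl] == idx)
        if int(sub.sum()) < min_component_px:
            continue
        rows = np.flatnonzero(sub.any(axis=1))
        cols = np.flatnonzero(sub.any(axis=0))
        if rows.size == 0:
            continue
        r0 = sl[0].start + int(rows[0])
        r1 = sl[0].start + int(rows[-1]) + 1
        c0 = sl[1].start + int(cols[0])
        c1 = sl[1].start + int(cols[-1]) + 1
        boxes.append((r0, r1, c0, c1))
        component = np.zeros_like(mask)
        component[sl] = sub
        masks.append(component)
    if not boxes:
        return []
    merged: list[tuple[tuple[int, int, int, int], np.ndarray]] = []
    for group in _merge_groups(boxes):
        r0 = min(boxes[i][0] for i in group)
        r1 = max(boxes[i][1] for i in group)
        c0 = min(boxes[i][2] for i in group)
        c1 = max(boxes[i][3] for i in group)
        combined = np.zeros_like(mask)
        for i in group:
            combined |= masks[i]
        merged.append(((r0, r1, c0, c1), combined))
    merged.sort(key=lambda bm: (-(max(bm[0][1] - bm[0][0], bm[0][3] - bm[0][2])), bm[0][0], bm[0][2]))
    return [
        (SpotInterval((r0, r1), (c0, c1), surface_index=i), cmask)
        for i, ((r0, r1, c0, c1), cmask) in enumerate(merged)
    ]


def detect_spot_intervals(
    mask: np.ndarray,
    min_component_px: int = 20,
    merge_radius: int = 2,
) -> list[SpotInterval]:
    """One :class:`SpotInterval` per surviving component of the target mask.

    See :func:`spot_components` for the component rules; this returns just
    the intervals, ordered by decreasing extent.
    """
    return [iv for iv, _ in spot_components(mask, min_component_px, merge_radius)]
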