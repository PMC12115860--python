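"""Per-row gradient computation and run-length de-diffraction.

A row of a semi-annular spot image has a characteristic signature: the gray
level jumps sharply upward at one edge of the spot, stays nearly constant
across the spot body (the central-difference gradient is ~0), and jumps
sharply downward at the other edge.  Diffraction speckle, by contrast, shows
rapidly alternating positive and negative gradients with only short
zero-gradient stretches between them.  Classifying each row's maximal
zero-gradient runs by their length therefore separates main-spot pixels
from diffraction pixels; diffraction pixels are then erased by replacing
them with the locally predicted background gray level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import BACKGROUND, DIFFRACTION, MAIN_SPOT, GrayImage
from .screening import BackgroundModel, SpotInterval, background_map, target_mask


@dataclass(frozen=True)
class ClassifierParams:
    """Thresholds of the run-length row classifier.

    eps_zero
        Gradient magnitude at or below which a pixel counts as
        zero-gradient (spot body / flat background), normalized units.
    tau_jump
        Gradient magnitude above which a pixel counts as an edge jump.
    l_min
        Minimum zero-run length, in pixels, for a run between a positive
        and a negative jump to be accepted as main-spot.
    """

    eps_zero: float = 0.01
    tau_jump: float = 0.05
    l_min: int = 8

    def __post_init__(self) -> None:
        if not (0.0 <= self.eps_zero < self.tau_jump <= 0.5):
            raise ValueError("require 0 <= eps_zero < tau_jump <= 0.5")
        if self.l_min < 1:
            raise ValueError("l_min must be >= 1")


@dataclass(frozen=True)
class GradientRow:
    """Central differences of one row with jump/zero annotations.

    ``values[k]`` holds the gradient at column ``k``; the two endpoint
    columns carry no gradient and are NaN.  ``zero_runs`` are the maximal
    half-open column intervals where ``|gradient| <= eps_zero``.
    """

    values: np.ndarray
    jump_pos: np.ndarray
    jump_neg: np.ndarray
    zero_runs: tuple[tuple[int, int], ...]

    @property
    def n_cols(self) -> int:
        return self.values.size


def _runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal half-open [start, stop) runs of True in a 1-D boolean array."""
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def central_difference_row(
    row: np.ndarray, params: ClassifierParams | None = None
) -> GradientRow:
    """Central-difference gradient of one image row.

    ``grad[k] = (g[k+1] - g[k-1]) / 2`` for interior columns; the first and
    last column carry no gradient.  Rows shorter than 3 are rejected.
    """
    params = params or ClassifierParams()
    row = np.asarray(row, dtype=np.float64)
    if row.ndim != 1 or row.size < 3:
        raise ValueError("row must be 1-D with length >= 3")
    grad = np.full(row.size, np.nan)
    grad[1:-1] = (row[2:] - row[:-2]) / 2.0
    interior = np.zeros(row.size, dtype=bool)
    interior[1:-1] = True
    jump_pos = np.flatnonzero(interior & (grad > params.tau_jump))
    jump_neg = np.flatnonzero(interior & (grad < -params.tau_jump))
    zero = interior & (np.abs(grad) <= params.eps_zero)
    return GradientRow(
        values=grad,
        jump_pos=jump_pos,
        jump_neg=jump_neg,
        zero_runs=tuple(_runs_of(zero)),
    )


# run-token codes used by the classifier state machine
_Z, _POS, _NEG, _MID = 0, 1, 2, 3


def _tokenize(grad: GradientRow, params: ClassifierParams) -> np.ndarray:
    n = grad.n_cols
    tok = np.full(n, -1, dtype=np.int8)  # -1 = endpoint, no gradient
    g = grad.values
    interior = ~np.isnan(g)
    tok[interior & (np.abs(g) <= params.eps_zero)] = _Z
    tok[interior & (g > params.tau_jump)] = _POS
    tok[interior & (g < -params.tau_jump)] = _NEG
    tok[interior & (tok == -1)] = _MID
    # A single moderate-gradient column flanked by zero-gradient columns is
    # folded into the zero run: 8-bit quantization plus ~1 DN of sensor noise
    # occasionally breaks an otherwise flat plateau at one pixel, and a
    # one-pixel interruption carries no edge information.
    mid = np.flatnonzero(tok == _MID)
    for k in mid:
        if 0 < k < n - 1 and tok[k - 1] == _Z and tok[k + 1] == _Z:
            tok[k] = _Z
    return tok


def classify_row(grad: GradientRow, params: ClassifierParams | None = None) -> np.ndarray:
    """Classify every column of a row as background / main-spot / diffraction.

    Scanning left to right: a zero-gradient run of length >= ``l_min`` whose
    nearest non-moderate neighbours are a positive jump on the left and a
    negative jump on the right is labelled main-spot together with its
    bounding jump columns; shorter runs between jumps, unpaired jumps and
    moderate-gradient columns are labelled diffraction; everything else
    (including a row with no jumps at all) is background.
    """
    params = params or ClassifierParams()
    n = grad.n_cols
    labels = np.full(n, BACKGROUND, dtype=np.uint8)
    tok = _tokenize(grad, params)

    # collapse into (type, start, stop) runs over interior columns
    runs: list[list[int]] = []
    for k in range(n):
        t = tok[k]
        if t == -1:
            continue
        if runs and runs[-1][0] == t and runs[-1][2] == k:
            runs[-1][2] = k + 1
        else:
            runs.append([t, k, k + 1])

    def _nearest(idx: int, step: int) -> int | None:
        """Index of the nearest non-moderate run from ``idx`` in direction ``step``."""
        j = idx + step
        while 0 <= j < len(runs) and runs[j][0] == _MID:
            j += step
        return j if 0 <= j < len(runs) else None

    consumed_main = np.zeros(len(runs), dtype=bool)
    for i, (t, start, stop) in enumerate(runs):
        if t != _Z or stop - start < params.l_min:
            continue
        left, right = _nearest(i, -1), _nearest(i, +1)
        if left is None or right is None:
            continue
        if runs[left][0] == _POS and runs[right][0] == _NEG:
            # The bounding jumps join the segment, but only the two columns
            # nearest the run: an edge occupies at most two gradient
            # columns, and longer jump runs continue into speckle.
            lo = max(runs[left][1], runs[left][2] - 2)
            hi = min(runs[right][2], runs[right][1] + 2)
            labels[lo:hi] = MAIN_SPOT
            consumed_main[i] = True

    for i, (t, start, stop) in enumerate(runs):
        if consumed_main[i]:
            continue
        if t in (_POS, _NEG, _MID):
            seg = labels[start:stop]
            seg[seg != MAIN_SPOT] = DIFFRACTION
        elif t == _Z:
            # Short zero run against an edge jump: diffraction -- unless it
            # touches the segment boundary, where its true length is unknown
            # (the interval box clips flat background, not speckle).
            left, right = _nearest(i, -1), _nearest(i, +1)
            near_jump = any(
                j is not None and runs[j][0] in (_POS, _NEG) for j in (left, right)
            )
            at_boundary = start <= 1 or stop >= n - 1
            if stop - start < params.l_min and near_jump and not at_boundary:
                labels[start:stop] = DIFFRACTION
    return labels


def dediffract(
    img: GrayImage,
    intervals: list[SpotInterval],
    params: ClassifierParams | None = None,
    model: BackgroundModel | None = None,
    context_px: int = 4,
) -> tuple[GrayImage, np.ndarray]:
    """Erase diffraction pixels inside the spot intervals.

    Rows inside each interval are processed top-down, left to right; pixels
    labelled main-spot are preserved bit-identically, pixels labelled
    diffraction are replaced by the local background prediction ``Y``, and
    everything outside every interval is untouched.  Target pixels flagged
    by the screening stage that the row classifier did not accept as
    main-spot are also treated as diffraction.

    Each interval is widened by ``context_px`` columns and rows (clipped to
    the frame) before processing: interval boxes hug the spot, and a spot
    run touching the segment boundary would otherwise lose the edge jump
    that pairs it.

    Returns the cleaned image and the full classification map.
    """
    params = params or ClassifierParams()
    model = model or BackgroundModel()
    classmap = np.full(img.shape, BACKGROUND, dtype=np.uint8)
    if not intervals:
        return img.with_pixels(img.pixels, note="dediffracted"), classmap

    is_main = np.zeros(img.shape, dtype=bool)
    is_diff = np.zeros(img.shape, dtype=bool)
    flagged = target_mask(img, model)
    m, n = img.shape

    for interval in intervals:
        r0 = max(0, interval.row_range[0] - context_px)
        r1 = min(m, interval.row_range[1] + context_px)
        c0 = max(0, interval.col_range[0] - context_px)
        c1 = min(n, interval.col_range[1] + context_px)
        if c1 - c0 < 3:
            continue
        for row in range(r0, r1):
            seg = img.pixels[row, c0:c1]
            grad = central_difference_row(seg, params)
            labels = classify_row(grad, params)
            is_main[row, c0:c1] |= labels == MAIN_SPOT
            is_diff[row, c0:c1] |= labels == DIFFRACTION
        is_diff[r0:r1, c0:c1] |= flagged[r0:r1, c0:c1]

    is_diff &= ~is_main
    classmap[is_diff] = DIFFRACTION
    classmap[is_main] = MAIN_SPOT

    cleaned = img.pixels.copy()
    if is_diff.any():
        # Replacement values come from Sj sets purged of flagged/spot pixels:
        # inside a dense speckle band the plain local mean is itself bright.
        background = background_map(img, model, exclude=flagged | is_main | is_diff)
        cleaned[is_diff] = np.clip(background[is_diff], 0.0, 1.0)
    return img.with_pixels(cleaned, note="dediffracted"), classmap
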