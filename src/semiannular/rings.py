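"""Semi-annular ring geometry and the defocus proportionality laws.

An out-of-focus reflective surface at axial defocus ``z`` images as a
half-annulus whose inner radius ``r`` and ring width ``d`` both scale
linearly with ``z``:

    r_i = kappa_r * z_i        d_i = kappa_d * z_i

so that for any two surfaces ``r1/r2 = d1/d2 = z1/z2``.  A surface exactly
at focus (``z = 0``) images as a point whose extent is the diffraction-
limited Airy footprint.  Two nested rings are *just resolved* when the
inner edge of the outer ring touches the outer edge of the inner ring,
``r2 = r1 + d1``.

All rings of one stack share the optical-axis center; the midpoint of a
ring's inner arc (its *apex*) sits at ``center + r`` along the opening
direction, which is what moves linearly with defocus and lets the focused
spot's position be extrapolated from two defocused rings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .raster import GrayImage
from .screening import SpotInterval

ORIENTATIONS = ("upper", "lower")


@dataclass(frozen=True)
class RingModel:
    """One semi-annular spot.

    Parameters
    ----------
    center : (row, col)
        Optical-axis center on the image (shared by all rings of a stack).
    inner_radius : float
        Distance ``r`` from the axis to the inner edge, pixels; ``r = 0``
        with a positive ``width`` is a focused point spot.
    width : float
        Ring width ``d`` (outer minus inner radius), pixels, > 0.
    orientation : str
        Which half-plane holds the annulus: ``"upper"`` (rows above the
        center row) or ``"lower"``; encodes the defocus sign.
    reliable : bool
        Set by measurement stages when the mid-row run was unbroken.
    corrected : bool
        Set when the width was replaced by the stack prediction.
    z : float or None
        Defocus distance in relative units, if known.
    """

    center: tuple[float, float]
    inner_radius: float
    width: float
    orientation: str = "upper"
    reliable: bool = True
    corrected: bool = False
    z: float | None = None

    def __post_init__(self) -> None:
        if self.inner_radius < 0:
            raise ValueError("inner_radius must be >= 0")
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")

    @property
    def outer_radius(self) -> float:
        return self.inner_radius + self.width

    @property
    def apex(self) -> tuple[float, float]:
        """Midpoint of the inner arc: center shifted by r into the half-plane."""
        row, col = self.center
        step = -self.inner_radius if self.orientation == "upper" else self.inner_radius
        return (row + step, col)


@dataclass(frozen=True)
class SurfaceStack:
    """Ordered rings of one image with the shared proportionality scales."""

    rings: tuple[RingModel, ...]
    kappa_r: float
    kappa_d: float
    residuals: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        zs = [r.z for r in self.rings]
        if any(z is None for z in zs):
            raise ValueError("every ring of a stack needs a defocus z")
        if any(b <= a for a, b in zip(zs, zs[1:])):
            raise ValueError("stack z values must be strictly increasing")


def are_rings_resolved(
    inner: RingModel, outer: RingModel, center_tol: float = 1.0
) -> bool:
    """True iff the two nested rings do not overlap (``r2 >= r1 + d1``).

    Equality is the just-resolved boundary and counts as resolved.  The
    rings must share center (within ``center_tol`` pixels) and orientation.
    """
    if inner.inner_radius > outer.inner_radius:
        inner, outer = outer, inner
    if inner.orientation != outer.orientation:
        raise ValueError("cannot compare rings of different orientation")
    if math.dist(inner.center, outer.center) > center_tol:
        raise ValueError("cannot compare rings with mismatched centers")
    return outer.inner_radius >= inner.outer_radius


def _scale(values: list[tuple[float, float]]) -> float:
    """Median of per-ring scales; with an even count, of the two middle
    values the one from the smaller-z ring is used (the first, innermost
    ring is the trusted reference)."""
    ratios = sorted(((v / z), z) for v, z in values)
    n = len(ratios)
    if n % 2 == 1:
        return ratios[n // 2][0]
    lo, hi = ratios[n // 2 - 1], ratios[n // 2]
    return lo[0] if lo[1] <= hi[1] else hi[0]


def fit_stack_scales(rings: list[RingModel]) -> SurfaceStack:
    """Fit the shared scales ``kappa_r`` and ``kappa_d`` from reliable rings.

    Each scale is the median over reliable rings of ``r_i/z_i`` resp.
    ``d_i/z_i``; per-ring width residuals against the fit are reported.
    """
    ordered = tuple(sorted(rings, key=lambda r: r.z))
    reliable = [r for r in ordered if r.reliable and r.z]
    if not reliable:
        raise ValueError("cannot fit scales: no reliable ring with known z")
    kappa_d = _scale([(r.width, r.z) for r in reliable])
    kappa_r = _scale([(r.inner_radius, r.z) for r in reliable])
    residuals = tuple(r.width - kappa_d * r.z for r in ordered)
    return SurfaceStack(rings=ordered, kappa_r=kappa_r, kappa_d=kappa_d, residuals=residuals)


def correct_ring_widths(stack: SurfaceStack, width_tol: float = 3.0) -> SurfaceStack:
    """Replace ring widths that deviate from the stack prediction.

    Any ring whose measured width differs from ``kappa_d * z`` by more than
    ``width_tol`` pixels gets the predicted width and is flagged corrected.
    Idempotent: corrected widths satisfy the prediction exactly.
    """
    new_rings = []
    for ring in stack.rings:
        predicted = stack.kappa_d * ring.z
        if abs(ring.width - predicted) > width_tol:
            new_rings.append(replace(ring, width=predicted, corrected=True))
        else:
            new_rings.append(ring)
    residuals = tuple(r.width - stack.kappa_d * r.z for r in new_rings)
    return replace(stack, rings=tuple(new_rings), residuals=residuals)


def infer_focus_center(
    point_a: tuple[float, float],
    z_a: float,
    point_b: tuple[float, float],
    z_b: float,
) -> tuple[float, float]:
    """Extrapolate the focused spot's position from two defocused rings.

    With inner-arc apex reference points ``x_i = c + kappa * z_i`` the
    focused position is ``c = (z_b * x_a - z_a * x_b) / (z_b - z_a)``,
    applied per coordinate.  Degenerate when ``z_a == z_b``.
    """
    if z_a == z_b:
        raise ValueError("cannot infer focus center from equal defocus distances")
    return tuple(
        (z_b * a - z_a * b) / (z_b - z_a) for a, b in zip(point_a, point_b)
    )


def defocus_from_ring(
    ring: RingModel,
    kappa_r: float | None = None,
    kappa_d: float | None = None,
    positive_orientation: str = "upper",
) -> float:
    """Signed defocus estimate from a ring's geometry.

    ``|z|`` is the mean of ``r/kappa_r`` and ``d/kappa_d`` over whichever
    scales are supplied; the sign follows the configured orientation
    convention (by default upper rings are positive defocus).
    """
    estimates = []
    if kappa_r is not None and kappa_r > 0:
        estimates.append(ring.inner_radius / kappa_r)
    if kappa_d is not None and kappa_d > 0:
        estimates.append(ring.width / kappa_d)
    if not estimates:
        raise ValueError("cannot estimate defocus without a scale")
    magnitude = float(np.mean(estimates))
    return magnitude if ring.orientation == positive_orientation else -magnitude


def airy_pixel_footprint(
    resolving_distance_um: float, magnification: float, pixel_pitch_um: float
) -> int:
    """Detector-pixel extent of the diffraction-limited resolving distance.

    The resolving distance is magnified onto the detector and divided by
    the pixel pitch, rounded to the nearest whole pixel (minimum 1).
    """
    if min(resolving_distance_um, magnification, pixel_pitch_um) <= 0:
        raise ValueError("all arguments must be > 0")
    return max(1, round(resolving_distance_um * magnification / pixel_pitch_um))


def reconstruct_missing_ring(
    stack: SurfaceStack,
    z: float,
    center: tuple[float, float] | None = None,
    orientation: str | None = None,
    focus_footprint_px: int = 2,
) -> RingModel:
    """Predict the ring of a surface whose spot is missing or degraded.

    For ``z > 0`` the ring has ``r = kappa_r * z`` and ``d = kappa_d * z``
    at the stack's shared center; for ``z = 0`` (the focused surface) a
    point spot of ``focus_footprint_px`` pixels is returned instead.
    """
    reliable = [r for r in stack.rings if r.reliable]
    if center is None:
        if len(reliable) < 1:
            raise ValueError("cannot reconstruct: no reliable ring and no center given")
        centers = np.array([r.center for r in reliable])
        center = tuple(np.mean(centers, axis=0))
    if orientation is None:
        orientation = reliable[0].orientation if reliable else stack.rings[0].orientation
    if z <= 0:
        return RingModel(
            center=center,
            inner_radius=0.0,
            width=float(focus_footprint_px),
            orientation=orientation,
            reliable=False,
            corrected=True,
            z=0.0,
        )
    return RingModel(
        center=center,
        inner_radius=stack.kappa_r * z,
        width=stack.kappa_d * z,
        orientation=orientation,
        reliable=False,
        corrected=True,
        z=z,
    )


def _row_runs(mask_row: np.ndarray) -> list[tuple[int, int]]:
    padded = np.diff(np.concatenate(([0], mask_row.view(np.int8), [0])))
    return list(zip(np.flatnonzero(padded == 1).tolist(), np.flatnonzero(padded == -1).tolist()))


def measure_ring(
    img: GrayImage,
    interval: SpotInterval,
    spot_threshold: float = 0.1,
    mask: np.ndarray | None = None,
    point_extent_px: int = 6,
) -> RingModel:
    """Measure a ring's geometry from a cleaned spot inside an interval.

    The flat (diameter) side of the half-annulus is located as the extreme
    spot row on the side of maximal horizontal extent; the spot runs of the
    row through it give the inner and outer radii, and the orientation
    follows from which half-plane holds the spot mass.  A compact blob no
    larger than ``point_extent_px`` is reported as a focused point spot
    (``r = 0``).  The ring is flagged unreliable when no clean two-run row
    is found near the flat side.

    ``mask`` optionally restricts the measurement to one connected
    component (needed when nested intervals overlap).
    """
    r0, r1 = interval.row_range
    c0, c1 = interval.col_range
    region = img.pixels[r0:r1, c0:c1]
    spot = region > spot_threshold
    if mask is not None:
        spot &= np.asarray(mask, dtype=bool)[r0:r1, c0:c1]
    if not spot.any():
        return RingModel(
            center=((r0 + r1) / 2, (c0 + c1) / 2),
            inner_radius=0.0,
            width=1.0,
            reliable=False,
        )
    rows = np.flatnonzero(spot.any(axis=1))
    cols = np.flatnonzero(spot.any(axis=0))
    height = int(rows[-1] - rows[0] + 1)
    width_extent = int(cols[-1] - cols[0] + 1)

    if max(height, width_extent) <= point_extent_px:
        rr, cc = np.nonzero(spot)
        return RingModel(
            center=(r0 + float(rr.mean()), c0 + float(cc.mean())),
            inner_radius=0.0,
            width=float(max(height, width_extent)),
            orientation="upper",
            reliable=True,
            z=0.0,
        )

    def _extent(row_idx: int) -> int:
        on = np.flatnonzero(spot[row_idx])
        return 0 if on.size == 0 else int(on[-1] - on[0] + 1)

    if _extent(int(rows[-1])) >= _extent(int(rows[0])):
        orientation, flat_row, step = "upper", int(rows[-1]), -1
    else:
        orientation, flat_row, step = "lower", int(rows[0]), +1

    best = None
    for dy in range(0, 4):
        row_idx = flat_row + step * dy
        if not (0 <= row_idx < spot.shape[0]):
            break
        runs = _row_runs(spot[row_idx])
        if len(runs) == 2:
            best = (dy, runs)
            break
    if best is None:
        # fall back to the widest row's outermost run; flagged unreliable
        widths = [_extent(int(r)) for r in rows]
        row_idx = int(rows[int(np.argmax(widths))])
        runs = _row_runs(spot[row_idx])
        cc_est = float(cols.mean())
        left, right = runs[0], runs[-1]
        inner_off = max(1.0, (right[0] - cc_est + cc_est - left[1] + 1) / 2.0)
        outer_off = (right[1] - 1 - cc_est + cc_est - left[0]) / 2.0
        return RingModel(
            center=(r0 + float(flat_row), c0 + cc_est),
            inner_radius=inner_off,
            width=max(1.0, outer_off - inner_off + 1),
            orientation=orientation,
            reliable=False,
        )

    dy, (left, right) = best
    cc_est = (left[0] + right[1] - 1) / 2.0
    inner_off = (right[0] - cc_est + cc_est - (left[1] - 1)) / 2.0
    outer_off = ((right[1] - 1) - cc_est + cc_est - left[0]) / 2.0
    inner_radius = math.hypot(inner_off, dy)
    outer_radius = math.hypot(outer_off + 1, dy)
    reliable = dy <= 1 and abs((left[1] - left[0]) - (right[1] - right[0])) <= 2
    return RingModel(
        center=(r0 + float(flat_row), c0 + cc_est),
        inner_radius=float(inner_radius),
        width=float(outer_radius - inner_radius),
        orientation=orientation,
        reliable=bool(reliable),
    )
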