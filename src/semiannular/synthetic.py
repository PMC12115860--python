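"""Synthetic semi-annular autofocus scenes with ground truth.

The generator emulates the phenomenology of the CCD frames the algorithm is
built for: nested half-annular rings whose inner radius and width scale
linearly with defocus, a Gaussian vertical intensity falloff (the middle of
the spot is brighter than its upper and lower ends), diffraction speckle
packed against the outer edge of each ring with rapidly sign-alternating
gray-level gradients, additive Gaussian sensor noise, and final 8-bit
quantization.  It is deliberately *not* a wave-optics simulation -- the
de-diffraction algorithm only consumes the gradient statistics of the
speckle, not its physical origin.

Speckle gray values are drawn independently per pixel: a strictly
period-two ripple would be invisible to the central difference (``g[k+1] -
g[k-1]`` cancels at Nyquist), whereas independent values produce exactly
the frequent sign-alternating gradients that characterize diffraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .gradients import ClassifierParams, dediffract
from .raster import BACKGROUND, DIFFRACTION, MAIN_SPOT, GrayImage
from .rings import RingModel, SurfaceStack, are_rings_resolved, measure_ring
from .screening import BackgroundModel, spot_components, target_mask


@dataclass(frozen=True)
class SurfaceSpec:
    """One reflective surface of a scene.

    ``width_override`` renders the ring with a degraded (wrong) width while
    keeping its inner radius at the proportional position -- used to emulate
    mis-imaged rings that the width-correction stage must repair.  With no
    override the rendered geometry satisfies the proportionality laws
    exactly by construction.
    """

    z: float
    orientation: str = "upper"
    peak_intensity: float = 0.9
    width_override: float | None = None

    def __post_init__(self) -> None:
        if self.z < 0:
            raise ValueError("z must be >= 0")
        if not 0.0 < self.peak_intensity <= 1.0:
            raise ValueError("peak_intensity must lie in (0, 1]")


@dataclass(frozen=True)
class DiffractionSpec:
    """Phenomenological speckle model: ripples hugging the outer ring edge.

    ``speckle_count`` angular sectors per ring, each about ``speckle_width``
    pixels of arc, are filled with independent per-pixel gray values in
    ``[0.25, 1] * amplitude`` inside a band of ``outer_band`` pixels outside
    the outer radius.  ``amplitude = 0`` disables speckle.
    """

    speckle_count: int = 0
    speckle_width: int = 3
    amplitude: float = 0.0
    outer_band: int = 0


@dataclass(frozen=True)
class SceneSpec:
    """Full description of a synthetic scene.

    Defaults echo the geometry of the system the algorithm was designed
    around: ring width 17 px and inner-arc apex offset 64 px per unit
    defocus, ~1 DN of 8-bit sensor noise.
    """

    shape: tuple[int, int] = (480, 480)
    center: tuple[int, int] = (400, 240)
    surfaces: tuple[SurfaceSpec, ...] = (SurfaceSpec(z=1.0), SurfaceSpec(z=2.0))
    kappa_r: float = 64.0
    kappa_d: float = 17.0
    vertical_falloff: float = 120.0
    diffraction: DiffractionSpec = field(default_factory=DiffractionSpec)
    noise_sigma: float = 0.004
    focus_footprint_px: int = 2
    focus_intensity: float = 0.9
    seed: int = 0

    def ring_geometry(self, surface: SurfaceSpec) -> tuple[float, float]:
        """(inner radius, width) of a surface's rendered ring."""
        r = self.kappa_r * surface.z
        d = surface.width_override if surface.width_override is not None else self.kappa_d * surface.z
        return r, d

    def validate(self) -> None:
        m, n = self.shape
        cr, cc = self.center
        if not (0 <= cr < m and 0 <= cc < n):
            raise ValueError("scene center must lie inside the frame")
        for s in self.surfaces:
            r, d = self.ring_geometry(s)
            reach = r + d + self.diffraction.outer_band
            vertical = cr - reach if s.orientation == "upper" else m - 1 - (cr + reach)
            if vertical < 0 or cc - reach < 0 or cc + reach > n - 1:
                raise ValueError(
                    f"ring of surface z={s.z} (reach {reach:.1f} px) exceeds the frame"
                )


def scene_to_dict(spec: SceneSpec) -> dict:
    """JSON-ready representation of a scene spec."""
    return {
        "shape": list(spec.shape),
        "center": list(spec.center),
        "surfaces": [
            {
                "z": s.z,
                "orientation": s.orientation,
                "peak_intensity": s.peak_intensity,
                "width_override": s.width_override,
            }
            for s in spec.surfaces
        ],
        "kappa_r": spec.kappa_r,
        "kappa_d": spec.kappa_d,
        "vertical_falloff": spec.vertical_falloff,
        "diffraction": {
            "speckle_count": spec.diffraction.speckle_count,
            "speckle_width": spec.diffraction.speckle_width,
            "amplitude": spec.diffraction.amplitude,
            "outer_band": spec.diffraction.outer_band,
        },
        "noise_sigma": spec.noise_sigma,
        "focus_footprint_px": spec.focus_footprint_px,
        "focus_intensity": spec.focus_intensity,
        "seed": spec.seed,
    }


def scene_from_dict(data: dict) -> SceneSpec:
    """Build a scene spec from a JSON-style dict (missing keys use defaults)."""
    kwargs = dict(data)
    if "shape" in kwargs:
        kwargs["shape"] = tuple(kwargs["shape"])
    if "center" in kwargs:
        kwargs["center"] = tuple(kwargs["center"])
    if "surfaces" in kwargs:
        kwargs["surfaces"] = tuple(SurfaceSpec(**s) for s in kwargs["surfaces"])
    if "diffraction" in kwargs:
        kwargs["diffraction"] = DiffractionSpec(**kwargs["diffraction"])
    return SceneSpec(**kwargs)


@dataclass(frozen=True)
class SceneTruth:
    """Ground truth of a rendered scene."""

    classmap: np.ndarray
    rings: tuple[RingModel, ...]
    stack: SurfaceStack | None


def _half_plane(dy: np.ndarray, orientation: str) -> np.ndarray:
    return dy <= 0 if orientation == "upper" else dy >= 0


def render_scene(spec: SceneSpec) -> tuple[GrayImage, SceneTruth]:
    """Render a scene and its per-pixel / per-surface ground truth.

    Rendering is deterministic under a fixed seed.  Rings are rasterized
    half-open in radius (``r <= dist < r + d``) so that two just-resolved
    rings (``r2 = r1 + d1``) are pixel-disjoint.  Quantization to 8 bits is
    applied last so that normalization round-trips.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    m, n = spec.shape
    cr, cc = spec.center
    rows = np.arange(m)[:, None] - cr
    cols = np.arange(n)[None, :] - cc
    dist = np.hypot(rows, cols)

    image = np.zeros((m, n), dtype=np.float64)
    classmap = np.full((m, n), BACKGROUND, dtype=np.uint8)
    main = np.zeros((m, n), dtype=bool)
    speckle = np.zeros((m, n), dtype=bool)
    truth_rings: list[RingModel] = []

    for surface in sorted(spec.surfaces, key=lambda s: s.z):
        if surface.z == 0:
            f = spec.focus_footprint_px
            r0 = cr - (f - 1) // 2
            c0 = cc - (f - 1) // 2
            block = np.zeros((m, n), dtype=bool)
            block[r0 : r0 + f, c0 : c0 + f] = True
            image[block] = np.maximum(image[block], spec.focus_intensity)
            main |= block
            truth_rings.append(
                RingModel(center=(float(cr), float(cc)), inner_radius=0.0,
                          width=float(f), orientation=surface.orientation, z=0.0)
            )
            continue
        r, d = spec.ring_geometry(surface)
        half = _half_plane(rows, surface.orientation)
        ring_mask = (dist >= r) & (dist < r + d) & half
        extent = r + d
        mid_row = cr - extent / 2.0 if surface.orientation == "upper" else cr + extent / 2.0
        factor = np.exp(-((np.arange(m) - mid_row) ** 2) / (2.0 * spec.vertical_falloff**2))
        intensity = surface.peak_intensity * factor[:, None] * np.ones((1, n))
        image[ring_mask] = np.maximum(image[ring_mask], intensity[ring_mask])
        main |= ring_mask
        truth_rings.append(
            RingModel(center=(float(cr), float(cc)), inner_radius=float(r),
                      width=float(d), orientation=surface.orientation, z=float(surface.z))
        )

        dspec = spec.diffraction
        if dspec.amplitude > 0 and dspec.outer_band > 0 and dspec.speckle_count > 0:
            band = (dist >= r + d) & (dist < r + d + dspec.outer_band) & half
            # angular sectors measured from the opening direction
            up = -rows if surface.orientation == "upper" else rows
            phi = np.arctan2(cols, up)  # in [-pi/2, pi/2] within the half-plane
            r_mid = r + d + dspec.outer_band / 2.0
            sector_half = max(dspec.speckle_width / max(r_mid, 1.0), 0.01) / 2.0
            centers = rng.uniform(-math.pi / 2, math.pi / 2, size=dspec.speckle_count)
            covered = np.zeros((m, n), dtype=bool)
            for c in centers:
                covered |= np.abs(phi - c) <= sector_half
            band &= covered
            values = dspec.amplitude * rng.uniform(0.25, 1.0, size=(m, n))
            sel = band & ~main
            image[sel] = np.maximum(image[sel], values[sel])
            speckle |= sel

    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=(m, n))
    image = np.clip(image, 0.0, 1.0)
    image = np.rint(image * 255.0) / 255.0  # 8-bit quantization, applied last

    classmap[speckle & ~main] = DIFFRACTION
    classmap[main] = MAIN_SPOT

    positive = [rm for rm in truth_rings if rm.z and rm.z > 0]
    stack = None
    if positive:
        stack = SurfaceStack(
            rings=tuple(sorted(positive, key=lambda rm: rm.z)),
            kappa_r=spec.kappa_r,
            kappa_d=spec.kappa_d,
        )
    return GrayImage(image, provenance="synthetic"), SceneTruth(
        classmap=classmap, rings=tuple(truth_rings), stack=stack
    )


@dataclass(frozen=True)
class ProbeResult:
    """Outcome of a resolution probe."""

    raw_min: float
    processed_min: float
    separations: tuple[float, ...]
    raw_resolved: tuple[bool, ...]
    processed_resolved: tuple[bool, ...]


def _measure_scene_rings(img, model, params, min_component_px, merge_radius, spot_threshold):
    comps = spot_components(target_mask(img, model), min_component_px, merge_radius)
    return [
        measure_ring(img, iv, spot_threshold=spot_threshold, mask=cm) for iv, cm in comps
    ]


def _is_resolved(rings_measured: list[RingModel]) -> bool:
    rings_measured = [rm for rm in rings_measured if rm.width >= 2 and rm.inner_radius > 0]
    if len(rings_measured) < 2:
        return False
    rings_measured.sort(key=lambda rm: rm.outer_radius, reverse=True)
    outer, inner = rings_measured[0], rings_measured[1]
    try:
        return are_rings_resolved(inner, outer, center_tol=2.0)
    except ValueError:
        return False


def resolution_probe(
    template: SceneSpec,
    z1: float,
    separations,
    params: ClassifierParams | None = None,
    model: BackgroundModel | None = None,
    min_component_px: int = 20,
    merge_radius: int = 2,
    spot_threshold: float = 0.1,
    fine_step: float | None = None,
) -> ProbeResult:
    """Smallest resolvable surface separation, raw vs after the pipeline.

    For each separation the two-surface template is rendered with surfaces
    at ``z1`` and ``z1 + sep``; the raw image and the de-diffracted image
    are each screened, their rings measured, and the just-resolved test
    applied.  ``separations`` is scanned in increasing order (coarse grid);
    if ``fine_step`` is given, the interval between the last unresolvable
    and the first resolvable coarse separation is re-scanned at that step.
    Returns the minimum resolvable separation for each path (``inf`` when
    none resolves).
    """
    params = params or ClassifierParams()
    model = model or BackgroundModel()
    if len(template.surfaces) != 2:
        raise ValueError("resolution probe needs a two-surface template")

    def evaluate(sep: float) -> tuple[bool, bool]:
        base = template.surfaces[0]
        spec = replace(
            template,
            surfaces=(replace(base, z=z1), replace(template.surfaces[1], z=z1 + sep)),
        )
        img, _ = render_scene(spec)
        raw_ok = _is_resolved(
            _measure_scene_rings(img, model, params, min_component_px, merge_radius, spot_threshold)
        )
        intervals = [
            iv for iv, _ in spot_components(target_mask(img, model), min_component_px, merge_radius)
        ]
        cleaned, _ = dediffract(img, intervals, params, model)
        proc_ok = _is_resolved(
            _measure_scene_rings(cleaned, model, params, min_component_px, merge_radius, spot_threshold)
        )
        return raw_ok, proc_ok

    seps = sorted(float(s) for s in separations)
    raw_flags, proc_flags = [], []
    for sep in seps:
        raw_ok, proc_ok = evaluate(sep)
        raw_flags.append(raw_ok)
        proc_flags.append(proc_ok)

    def first_true(flags) -> int | None:
        for i, ok in enumerate(flags):
            if ok:
                return i
        return None

    def refine(idx: int | None, flags) -> float:
        if idx is None:
            return math.inf
        coarse_min = seps[idx]
        if fine_step is None or idx == 0:
            return coarse_min
        lo = seps[idx - 1]
        sep = lo + fine_step
        while sep < coarse_min - 1e-9:
            raw_ok, proc_ok = evaluate(sep)
            ok = raw_ok if flags is raw_flags else proc_ok
            if ok:
                return sep
            sep += fine_step
        return coarse_min

    raw_min = refine(first_true(raw_flags), raw_flags)
    processed_min = refine(first_true(proc_flags), proc_flags)
    return ProbeResult(
        raw_min=raw_min,
        processed_min=processed_min,
        separations=tuple(seps),
        raw_resolved=tuple(raw_flags),
        processed_resolved=tuple(proc_flags),
    )
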