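"""The one-shot processing pipeline.

Stage order: interval screening -> per-row gradient de-diffraction ->
re-screening of the cleaned image -> ring measurement -> stack fitting and
width correction -> optional focus-point reconstruction -> annulus
refinement -> report.  Re-screening after de-diffraction is the mechanism
that recovers surfaces the raw screening under-counted when diffraction
glued neighbouring rings together.
"""

from __future__ import annotations

import json
import logging
import types
from dataclasses import replace
from pathlib import Path

import numpy as np

from .config import PipelineConfig
from .gradients import ClassifierParams, dediffract
from .raster import GrayImage, write_image, write_mask, write_ring_report
from .refine import beautify_ring
from .rings import (
    RingModel,
    are_rings_resolved,
    correct_ring_widths,
    fit_stack_scales,
    measure_ring,
    reconstruct_missing_ring,
)
from .screening import BackgroundModel, spot_components, target_mask

logger = logging.getLogger(__name__)


class PipelineResult(types.SimpleNamespace):
    """Artifacts of one pipeline run.

    Attributes: ``summary`` (JSON-ready dict), ``cleaned`` (GrayImage),
    ``classmap`` (uint8 map), ``refined`` (GrayImage), ``rings`` (list of
    RingModel, points included), ``stack`` (SurfaceStack or None).
    """


def _round(value, ndigits: int = 4):
    """Round floats and cast numpy scalars so summaries are JSON-stable."""
    if isinstance(value, (float, np.floating)):
        return round(float(value), ndigits)
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, np.integer)):
        return int(value)
    if isinstance(value, (list, tuple)):
        return [_round(v, ndigits) for v in value]
    if isinstance(value, dict):
        return {k: _round(v, ndigits) for k, v in value.items()}
    return value


def _assign_z(rings: list[RingModel], config: PipelineConfig) -> list[RingModel]:
    """Attach relative defocus values to measured rings."""
    points = [r for r in rings if r.inner_radius == 0]
    annuli = sorted((r for r in rings if r.inner_radius > 0), key=lambda r: r.inner_radius)
    out = [replace(p, z=0.0) for p in points]
    if config.z_mode == "equal_spacing":
        out += [replace(r, z=float(i + 1)) for i, r in enumerate(annuli)]
    else:
        if annuli:
            r_min = annuli[0].inner_radius
            out += [replace(r, z=r.inner_radius / r_min) for r in annuli]
    return out


def run_pipeline(
    source: GrayImage | "SceneSpec" | str | Path,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full pipeline on an image, an image path, or a scene spec.

    Returns a :class:`PipelineResult`; when ``outdir`` is given the cleaned
    image, classification mask, refined image, CSV ring report and JSON
    summary are also written there.
    """
    config = config or PipelineConfig()
    logger.info("pipeline config: %s", json.dumps(config.to_dict(), sort_keys=True))

    from .synthetic import SceneSpec, render_scene  # lazy: avoid import cycle

    if isinstance(source, (str, Path)):
        from .raster import read_image

        img = read_image(source)
    elif isinstance(source, SceneSpec):
        img, _ = render_scene(source)
    elif isinstance(source, GrayImage):
        img = source
    else:
        raise TypeError(f"unsupported pipeline input: {type(source)!r}")

    model = BackgroundModel(tau_e=config.tau_e)
    params = ClassifierParams(
        eps_zero=config.eps_zero, tau_jump=config.tau_jump, l_min=config.l_min
    )

    comps_raw = spot_components(
        target_mask(img, model), config.min_component_px, config.merge_radius
    )
    intervals_raw = [iv for iv, _ in comps_raw]
    logger.info("raw screening: %d interval(s)", len(intervals_raw))

    cleaned, classmap = dediffract(img, intervals_raw, params, model)
    n_erased = int(np.sum(cleaned.pixels != img.pixels))
    logger.info("dediffract: %d pixel(s) replaced", n_erased)

    comps_clean = spot_components(
        target_mask(cleaned, model), config.min_component_px, config.merge_radius
    )
    logger.info("re-screening: %d interval(s)", len(comps_clean))

    measured = [
        measure_ring(cleaned, iv, spot_threshold=config.spot_threshold, mask=cm)
        for iv, cm in comps_clean
    ]
    measured = [r for r in measured if r.width >= 1]
    rings = _assign_z(measured, config)

    stack = None
    corrections = 0
    annuli = [r for r in rings if r.inner_radius > 0]
    points = [r for r in rings if r.inner_radius == 0]
    if annuli:
        try:
            stack = fit_stack_scales(annuli)
            stack = correct_ring_widths(stack, config.width_tol)
            corrections = sum(1 for r in stack.rings if r.corrected)
            annuli = list(stack.rings)
        except ValueError:
            logger.warning("no reliable ring: stack scales not fitted")

    if config.reconstruct_focus and stack is not None and not points and len(annuli) >= 2:
        focus = reconstruct_missing_ring(
            stack, 0.0, focus_footprint_px=config.focus_footprint_px
        )
        points.append(focus)
        logger.info("reconstructed focus point at %s", focus.center)

    all_rings = points + annuli

    refined = cleaned
    if config.refine:
        for ring in annuli:
            if ring.reliable or ring.corrected:
                refined = beautify_ring(
                    refined,
                    ring,
                    tau_low=config.tau_low,
                    background_value=config.background_value(),
                )
        for point in points:
            refined = _draw_point(refined, point)

    resolved_pairs = []
    ordered = sorted(annuli, key=lambda r: r.inner_radius)
    for inner, outer in zip(ordered, ordered[1:]):
        try:
            verdict = are_rings_resolved(inner, outer, center_tol=2.0)
        except ValueError:
            verdict = None
        resolved_pairs.append(verdict)

    summary = {
        "provenance": img.provenance,
        "surface_count": len(all_rings),
        "intervals_raw": len(intervals_raw),
        "intervals_clean": len(comps_clean),
        "pixels_replaced": n_erased,
        "corrections_applied": corrections,
        "rings": [
            {
                "ring_id": i,
                "center_row": r.center[0],
                "center_col": r.center[1],
                "inner_radius_px": r.inner_radius,
                "ring_width_px": r.width,
                "orientation": r.orientation,
                "z_relative": r.z,
                "reliable": r.reliable,
                "corrected": r.corrected,
            }
            for i, r in enumerate(all_rings)
        ],
        "resolved_pairs": resolved_pairs,
        "kappa_r": stack.kappa_r if stack else None,
        "kappa_d": stack.kappa_d if stack else None,
        "config": config.to_dict(),
    }
    summary = _round(summary)
    if not all_rings:
        logger.warning("no surfaces found; empty report")

    result = PipelineResult(
        summary=summary,
        cleaned=cleaned,
        classmap=classmap,
        refined=refined,
        rings=all_rings,
        stack=stack,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_image(cleaned, outdir / "cleaned.png")
        write_mask(classmap, outdir / "classes.png")
        write_image(refined, outdir / "refined.png")
        write_ring_report(types.SimpleNamespace(rings=all_rings), outdir / "rings.csv")
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    return result


def _draw_point(img: GrayImage, point: RingModel) -> GrayImage:
    """Paint a focused point spot (maximum brightness) onto the image."""
    f = max(1, int(round(point.width)))
    cr, cc = (int(round(c)) for c in point.center)
    r0 = max(0, cr - (f - 1) // 2)
    c0 = max(0, cc - (f - 1) // 2)
    out = img.pixels.copy()
    out[r0 : r0 + f, c0 : c0 + f] = 1.0
    return img.with_pixels(out, note="focus-point")
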