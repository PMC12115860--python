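"""Ring geometry: proportionality laws, resolvability, measurement."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from semiannular import (
    RingModel,
    SceneSpec,
    SurfaceSpec,
    airy_pixel_footprint,
    are_rings_resolved,
    correct_ring_widths,
    defocus_from_ring,
    fit_stack_scales,
    infer_focus_center,
    measure_ring,
    reconstruct_missing_ring,
    render_scene,
    spot_components,
    target_mask,
)
from conftest import make_scene


def ring(r, d, z=None, center=(100.0, 100.0), reliable=True, orientation="upper"):
    return RingModel(center=center, inner_radius=r, width=d, z=z,
                     reliable=reliable, orientation=orientation)


def rasterize_half_annulus(shape, center, r, d, orientation="upper"):
    """Independent rasterizer for the overlap oracle (half-open in radius)."""
    rows = np.arange(shape[0])[:, None] - center[0]
    cols = np.arange(shape[1])[None, :] - center[1]
    dist = np.hypot(rows, cols)
    half = rows <= 0 if orientation == "upper" else rows >= 0
    return (dist >= r) & (dist < r + d) & half


class TestResolvability:
    def test_boundary_counts_as_resolved(self):
        assert are_rings_resolved(ring(64, 17), ring(81, 20))

    def test_strict_violation_is_unresolved(self):
        assert not are_rings_resolved(ring(64, 17), ring(80, 20))

    def test_mismatched_rings_are_rejected(self):
        with pytest.raises(ValueError):
            are_rings_resolved(ring(10, 5), ring(30, 5, orientation="lower"))
        with pytest.raises(ValueError):
            are_rings_resolved(ring(10, 5), ring(30, 5, center=(100.0, 104.0)))

    def test_agrees_with_rasterized_overlap_on_random_stacks(self, rng):
        center = (80.0, 80.0)
        for _ in range(200):
            r1 = float(rng.integers(8, 30))
            d1 = float(rng.integers(3, 15))
            r2 = float(rng.integers(8, 60))
            if r2 < r1:
                r1, r2 = r2, r1
            d2 = float(rng.integers(3, 15))
            a = rasterize_half_annulus((161, 161), center, r1, d1)
            b = rasterize_half_annulus((161, 161), center, r2, d2)
            overlap = (a & b).any()
            verdict = are_rings_resolved(ring(r1, d1, center=center), ring(r2, d2, center=center))
            assert verdict == (not overlap)


class TestStackScales:
    def test_single_ring(self):
        stack = fit_stack_scales([ring(64, 17, z=1.0)])
        assert stack.kappa_d == 17.0
        assert stack.kappa_r == 64.0

    def test_median_of_three_ratios(self):
        stack = fit_stack_scales(
            [ring(30, 10, z=1.0), ring(60, 21, z=2.0), ring(90, 29, z=3.0)]
        )
        assert stack.kappa_d == 10.0  # median of 10, 10.5, 9.667
        predicted = [stack.kappa_d * r.z for r in stack.rings]
        assert predicted == [10.0, 20.0, 30.0]

    def test_even_count_trusts_the_smaller_z_ring(self):
        stack = fit_stack_scales([ring(64, 17, z=1.0), ring(128, 25, z=2.0)])
        assert stack.kappa_d == 17.0

    def test_unreliable_rings_are_excluded_from_the_fit(self):
        stack = fit_stack_scales(
            [ring(64, 17, z=1.0), ring(128, 25, z=2.0, reliable=False)]
        )
        assert stack.kappa_d == 17.0
        with pytest.raises(ValueError):
            fit_stack_scales([ring(64, 17, z=1.0, reliable=False)])


class TestWidthCorrection:
    def test_degraded_second_ring_is_doubled(self):
        stack = fit_stack_scales([ring(64, 17, z=1.0), ring(128, 25, z=2.0)])
        corrected = correct_ring_widths(stack, width_tol=3.0)
        widths = [r.width for r in corrected.rings]
        assert widths == [17.0, 34.0]
        assert not corrected.rings[0].corrected
        assert corrected.rings[1].corrected

    def test_consistent_stack_is_unchanged(self):
        stack = fit_stack_scales([ring(30, 10, z=1.0), ring(60, 20, z=2.0)])
        corrected = correct_ring_widths(stack)
        assert [r.width for r in corrected.rings] == [10.0, 20.0]
        assert not any(r.corrected for r in corrected.rings)

    def test_only_the_outlier_changes(self):
        stack = fit_stack_scales(
            [ring(30, 10, z=1.0), ring(60, 27, z=2.0), ring(90, 30, z=3.0)]
        )
        corrected = correct_ring_widths(stack, width_tol=3.0)
        assert [r.corrected for r in corrected.rings] == [False, True, False]
        assert corrected.rings[1].width == 20.0

    def test_idempotent(self):
        stack = fit_stack_scales([ring(64, 17, z=1.0), ring(128, 25, z=2.0)])
        once = correct_ring_widths(stack)
        twice = correct_ring_widths(once)
        assert [r.width for r in once.rings] == [r.width for r in twice.rings]

    def test_proportionality_closure_after_correction(self):
        stack = correct_ring_widths(
            fit_stack_scales([ring(30, 10, z=1.0), ring(60, 27, z=2.0), ring(90, 30, z=3.0)])
        )
        rings_ok = [r for r in stack.rings if r.reliable or r.corrected]
        for a in rings_ok:
            for b in rings_ok:
                if not (a.corrected or b.corrected):
                    continue
                assert a.width * b.z == pytest.approx(b.width * a.z)


class TestFocusCenter:
    def test_extrapolates_the_focused_spot_position(self):
        c = infer_focus_center((118.0, 180.0), 1.0, (182.0, 180.0), 2.0)
        assert c == (54.0, 180.0)

    def test_coincident_points_give_that_point(self):
        assert infer_focus_center((40.0, 40.0), 1.0, (40.0, 40.0), 3.0) == (40.0, 40.0)

    def test_equal_defocus_is_degenerate(self):
        with pytest.raises(ValueError):
            infer_focus_center((1.0, 2.0), 1.0, (3.0, 4.0), 1.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        c=st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
        kappa=st.floats(0.5, 80),
        z1=st.floats(0.1, 5),
        dz=st.floats(0.1, 5),
    )
    def test_forward_simulation_inverts_exactly(self, c, kappa, z1, dz):
        z2 = z1 + dz
        x1 = (c[0] + kappa * z1, c[1])
        x2 = (c[0] + kappa * z2, c[1])
        back = infer_focus_center(x1, z1, x2, z2)
        assert back[0] == pytest.approx(c[0], abs=1e-6)
        assert back[1] == pytest.approx(c[1], abs=1e-6)


class TestDefocus:
    def test_proportional_scales_recover_z(self):
        rm = ring(96, 30, z=None)
        assert defocus_from_ring(rm, kappa_r=32.0) == pytest.approx(3.0)
        assert defocus_from_ring(rm, kappa_r=32.0, kappa_d=10.0) == pytest.approx(3.0)
        assert defocus_from_ring(replace(rm, orientation="lower"), kappa_r=32.0) == pytest.approx(-3.0)
        with pytest.raises(ValueError):
            defocus_from_ring(rm)

    def test_recovery_within_5_percent_at_one_pixel_noise(self, rng):
        kappa_r, kappa_d = 32.0, 10.0
        for _ in range(100):
            z = float(rng.uniform(1.0, 4.0))
            noisy = ring(
                kappa_r * z + rng.uniform(-1, 1), kappa_d * z + rng.uniform(-1, 1)
            )
            est = defocus_from_ring(noisy, kappa_r=kappa_r, kappa_d=kappa_d)
            assert abs(est - z) / z <= 0.05


class TestAiryFootprint:
    @pytest.mark.parametrize(
        "args, expected",
        [((0.68, 20, 5.5), 2), ((5.5, 1, 5.5), 1), ((1.0, 11, 5.5), 2)],
    )
    def test_known_footprints(self, args, expected):
        assert airy_pixel_footprint(*args) == expected

    def test_rejects_nonpositive_arguments(self):
        with pytest.raises(ValueError):
            airy_pixel_footprint(0.0, 20, 5.5)


class TestReconstruction:
    def test_same_z_reproduces_an_existing_ring(self):
        stack = fit_stack_scales([ring(32, 10, z=1.0), ring(64, 20, z=2.0)])
        rebuilt = reconstruct_missing_ring(stack, 2.0)
        assert rebuilt.inner_radius == 64.0
        assert rebuilt.width == 20.0
        assert rebuilt.center == (100.0, 100.0)

    def test_focus_point_has_airy_footprint(self):
        stack = fit_stack_scales([ring(32, 10, z=1.0), ring(64, 20, z=2.0)])
        point = reconstruct_missing_ring(stack, 0.0, focus_footprint_px=2)
        assert point.inner_radius == 0.0
        assert point.width == 2.0
        assert point.z == 0.0

    def test_leave_one_out_recovers_a_dropped_ring(self):
        spec = make_scene(n_surfaces=3, kappa_r=28.0, kappa_d=8.0, seed=21)
        spec = replace(spec, center=(130, 128))
        img, truth = render_scene(spec)
        comps = spot_components(target_mask(img))
        measured = sorted(
            (measure_ring(img, iv, mask=cm) for iv, cm in comps),
            key=lambda r: r.inner_radius,
        )
        assert len(measured) == 3
        kept = [replace(measured[0], z=1.0), replace(measured[2], z=3.0)]
        stack = fit_stack_scales(kept)
        rebuilt = reconstruct_missing_ring(stack, 2.0)
        dropped_truth = truth.stack.rings[1]
        assert rebuilt.inner_radius == pytest.approx(dropped_truth.inner_radius, abs=1.0)
        assert rebuilt.width == pytest.approx(dropped_truth.width, abs=1.0)
        assert rebuilt.center[0] == pytest.approx(dropped_truth.center[0], abs=1.0)
        assert rebuilt.center[1] == pytest.approx(dropped_truth.center[1], abs=1.0)


class TestMeasureRing:
    def test_noise_free_ring_is_measured_exactly(self, noisefree_two_ring):
        _, img, truth = noisefree_two_ring
        comps = spot_components(target_mask(img))
        measured = sorted(
            (measure_ring(img, iv, mask=cm) for iv, cm in comps),
            key=lambda r: r.inner_radius,
        )
        for got, want in zip(measured, truth.stack.rings):
            assert got.reliable
            assert got.orientation == want.orientation
            assert got.inner_radius == pytest.approx(want.inner_radius, abs=1.0)
            assert got.width == pytest.approx(want.width, abs=1.0)
            assert got.center[0] == pytest.approx(want.center[0], abs=1.0)
            assert got.center[1] == pytest.approx(want.center[1], abs=1.0)

    def test_focused_point_spot_measures_r_zero(self):
        spec = SceneSpec(
            shape=(64, 64), center=(32, 32), surfaces=(SurfaceSpec(z=0.0),),
            focus_footprint_px=2, noise_sigma=0.0,
        )
        img, _ = render_scene(spec)
        comps = spot_components(target_mask(img), min_component_px=2)
        assert len(comps) == 1
        point = measure_ring(img, comps[0][0], mask=comps[0][1])
        assert point.inner_radius == 0.0
        assert point.width == 2.0
        assert point.z == 0.0

    def test_degraded_width_feeds_the_correction_stage(self):
        spec = make_scene(n_surfaces=2, seed=33)
        spec = replace(
            spec,
            surfaces=(SurfaceSpec(z=1.0), SurfaceSpec(z=2.0, width_override=14.0)),
        )
        img, _ = render_scene(spec)
        comps = spot_components(target_mask(img))
        measured = sorted(
            (measure_ring(img, iv, mask=cm) for iv, cm in comps),
            key=lambda r: r.inner_radius,
        )
        measured = [replace(r, z=float(i + 1)) for i, r in enumerate(measured)]
        assert measured[1].width == pytest.approx(14.0, abs=1.0)
        corrected = correct_ring_widths(fit_stack_scales(measured), width_tol=3.0)
        assert corrected.rings[1].corrected
        assert corrected.rings[1].width == pytest.approx(2 * corrected.rings[0].width)
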