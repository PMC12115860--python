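"""Shared fixtures: small synthetic scenes with ground truth.

Scenes are 256x256 so the whole suite stays fast; geometry mirrors the
package defaults (half-annuli opening upward, radius/width proportional to
defocus) at a reduced scale.
"""

from __future__ import annotations

import numpy as np
import pytest

from semiannular import (
    DiffractionSpec,
    SceneSpec,
    SurfaceSpec,
    render_scene,
)


def make_scene(
    n_surfaces: int = 2,
    diffraction: DiffractionSpec | None = None,
    seed: int = 7,
    kappa_r: float = 32.0,
    kappa_d: float = 10.0,
    noise_sigma: float = 0.004,
    **kwargs,
) -> SceneSpec:
    surfaces = tuple(SurfaceSpec(z=float(i + 1)) for i in range(n_surfaces))
    return SceneSpec(
        shape=(256, 256),
        center=(140, 128),
        surfaces=surfaces,
        kappa_r=kappa_r,
        kappa_d=kappa_d,
        vertical_falloff=90.0,
        diffraction=diffraction or DiffractionSpec(),
        noise_sigma=noise_sigma,
        seed=seed,
        **kwargs,
    )


@pytest.fixture(scope="session")
def clean_two_ring():
    """Two noise-quantization-only rings at z = 1, 2 (no speckle)."""
    spec = make_scene(n_surfaces=2)
    img, truth = render_scene(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def noisefree_two_ring():
    """Two rings with no noise at all: geometry is exact."""
    spec = make_scene(n_surfaces=2, noise_sigma=0.0)
    img, truth = render_scene(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def speckled_one_ring():
    """One ring with a dense speckle band hugging its outer edge."""
    spec = make_scene(
        n_surfaces=1,
        diffraction=DiffractionSpec(speckle_count=200, speckle_width=3, amplitude=0.5, outer_band=16),
        seed=13,
    )
    img, truth = render_scene(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def speckled_two_ring():
    """Two rings with speckle in between (bands stop short of the next ring)."""
    spec = make_scene(
        n_surfaces=2,
        diffraction=DiffractionSpec(speckle_count=200, speckle_width=3, amplitude=0.5, outer_band=16),
        seed=13,
    )
    img, truth = render_scene(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def adhesion_scene():
    """Three-surface scenario: surface at focus (spot too small to screen),
    two defocused rings glued together by a bright speckle band, the outer
    ring rendered with a degraded width.  Reproduces the failure mode the
    re-screening + reconstruction stages must fix."""
    spec = SceneSpec(
        shape=(256, 256),
        center=(120, 128),
        surfaces=(SurfaceSpec(z=1.0), SurfaceSpec(z=2.0, width_override=14.0)),
        kappa_r=32.0,
        kappa_d=10.0,
        vertical_falloff=90.0,
        diffraction=DiffractionSpec(speckle_count=300, speckle_width=3, amplitude=0.5, outer_band=24),
        noise_sigma=0.004,
        seed=5,
    )
    img, truth = render_scene(spec)
    return spec, img, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
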