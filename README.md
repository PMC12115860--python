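# semiannular

De-diffraction and geometry analysis of semi-annular laser autofocus spot
images.

## The problem

A semi-annular laser autofocus microscope observes the reflective surfaces
of a transparent sample through a half-annular aperture. A surface at axial
defocus *z* images on the detector as a half-ring whose inner radius *r*
and ring width *d* both grow linearly with defocus:

    d₁ / d₂ = z₁ / z₂        r₁ / r₂ = z₁ / z₂

so each surface's defocus distance and sign can be read off its ring. Two
nested rings are *just resolved* when the inner edge of the outer ring
touches the outer edge of the inner one, `r₂ = r₁ + d₁` — the corresponding
axial separation is the interlayer resolution of the instrument.

Diffraction from the aperture packs speckle against the outer edge of each
ring. The speckle inflates the apparent ring width, glues neighbouring
rings together, and makes the screening stage under-count surfaces, all of
which degrades the interlayer resolution. This package removes the speckle
per frame and restores the rings, for anyone building or post-processing
such an autofocus system (and for the general problem of separating a
smooth bright target from high-frequency clutter by gradient statistics).

## The algorithm

1. **Background screening.** Each pixel's background gray is predicted as
   the mean of the 40 pixels inside its 7×7 window but outside its 3×3
   neighbourhood (`Y = Σ W·f`, `W = 1/40`). Pixels with residual
   `E = f − Y` above a threshold are target pixels; connected groups give
   one rectangular *spot interval* per surface, confining all later work.
2. **Gradient de-diffraction.** Within each interval, every row's central
   difference `Δg_k = (g_{k+1} − g_{k−1}) / 2` is computed. A long run of
   near-zero gradients between a sharp positive and a sharp negative jump
   is a main-spot segment; short runs and jumpy stretches are diffraction
   and are replaced by the local background prediction.
3. **Ring geometry.** Ring radii and widths are measured at the flat edge
   of each half-annulus; the shared scales `κ_r = r/z`, `κ_d = d/z` are
   fitted by a median over reliable rings; widths that disagree with the
   fit are corrected; a missing ring — or the focused surface's point spot,
   with its diffraction-limited Airy footprint — is reconstructed from its
   neighbours.
4. **Refinement.** Degraded rings are snapped to their ideal annulus:
   protrusions become background, dim in-annulus pixels are repaired from
   their vertical neighbour or set to full brightness.

A synthetic scene generator provides ground truth (per-pixel classes and
per-surface ring parameters) for every stage, including a resolution probe
that measures the smallest resolvable surface separation before and after
processing.

## Worked example

Render a two-surface scene at defocus ratio 1:2 whose outer ring is
degraded (rendered at 25 px instead of the proportional width) and buried
in speckle, then run the full pipeline:

```python
import semiannular as sa

spec = sa.SceneSpec(
    surfaces=(sa.SurfaceSpec(z=1.0), sa.SurfaceSpec(z=2.0, width_override=25.0)),
    diffraction=sa.DiffractionSpec(speckle_count=300, amplitude=0.5, outer_band=20),
    seed=1,
)
img, truth = sa.render_scene(spec)
result = sa.run_pipeline(img, sa.PipelineConfig(z_mode="equal_spacing"))
print(result.summary)
```

prints (abridged):

```
surface_count        2
intervals_raw        2       # surfaces found by raw screening
intervals_clean      2       # surfaces found after de-diffraction
pixels_replaced      14792   # speckle pixels erased
corrections_applied  1
kappa_r 64.0   kappa_d 17.5
ring 0: r= 64.0  d=17.5  z=1  reliable
ring 1: r=128.0  d=35.0  z=2  corrected
resolved_pairs [true]
```

The inner ring measures `r = 64`, `d = 17.5`; the degraded outer ring's
measured width (≈25 px) disagrees with the proportionality prediction
`κ_d·z = 35`, so it is corrected and flagged. The pair passes the
just-resolved test. The same pipeline is available from the shell:

```sh
semiannular simulate --out scene.png
semiannular pipeline scene.png --outdir out/
```

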