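# Methods

This note records the model behind each stage, the tunable parameters, the
numerical choices made where the design was open, and what the synthetic
benchmark does and does not show.

## Image model and conventions

Images are single-channel 8-bit rasters mapped linearly to `[0, 1]`
(division by exactly 255, so re-quantization is the identity on 8-bit
input). Addressing is 0-based `(row, col)` with row 0 at top. Ring
geometry uses a shared optical-axis center per image; a half-annulus spans
radii `[r, r + d)` in the upper or lower half-plane, the orientation
encoding the defocus sign. The half-open radial interval is deliberate:
two rings at the just-resolved boundary `r₂ = r₁ + d₁` are then
pixel-disjoint, so the analytic resolvability test and a rasterized
overlap test agree exactly at the boundary.

The "center of the inner diameter" of a ring — the quantity that moves
linearly with defocus and from which the focused spot's position is
extrapolated — is the ring's *apex*, the midpoint of its inner arc, at
`center + r` along the opening direction.

## Background screening

The background predictor is a fixed-weight local mean: the 40 pixels of
the 7×7 window minus the 3×3 core, weight 1/40 each. The 7×7−3×3 reading
is the unique symmetric geometry consistent with a 40-pixel set. At
borders the offset set is clipped and the weight rescaled to `1/|set|`,
preserving the weights-sum-to-one invariant instead of discarding a border
band.

A pixel is a *target* when its residual `E = f − Y` exceeds `tau_e`
(default 0.08 normalized units, chosen so the generator's dimmest true
ring pixels at contrast ≈ 0.1 are caught; configurable). Diffraction and
main-spot pixels are both flagged at this stage.

A local mean with a 7-pixel window is blind to the *interior* of spots
wider than the window — rings in this problem are 17–50 px wide — so a
pure residual mask reduces each ring to two thin edge arcs. Interval
detection therefore unions the residual mask with an absolute brightness
test (gray above the global median by more than `tau_e`). The residual
screen itself (`screen_targets`) remains the pure `E > tau_e` rule.

Interval detection labels the combined mask with 8-connectivity, drops
components below `min_component_px` (default 20, suppressing noise
specks), joins components closer than twice `merge_radius` (default 2;
fragments of one broken spot), and merges overlapping bounding boxes —
*unless* one box is nested inside the other. Nested boxes are concentric
rings of distinct surfaces and must keep distinct indices; merging every
overlap would collapse any two nested rings into one surface. Each
surviving component also carries its pixel mask so that nested surfaces
can be measured without contaminating each other.

## Gradient de-diffraction

Per row, the central difference `Δg_k = (g_{k+1} − g_{k−1})/2` (the
two-sided stencil divided by two; endpoints carry no gradient). Columns
are tokenized: *zero* (`|Δg| ≤ eps_zero`), *jump* (`|Δg| > tau_jump`,
signed), *moderate* otherwise. Defaults `eps_zero = 0.01`,
`tau_jump = 0.05`: the generator's ring edges (contrast ≥ 0.2 over ≤ 2 px)
always jump, its plateau ripple (8-bit quantization plus ~1 DN noise)
reads as zero. A single moderate column flanked by zero columns is folded
into the zero run — sensor noise occasionally breaks an otherwise flat
plateau at one pixel, and a one-pixel interruption carries no edge
information.

A zero run of length ≥ `l_min` whose nearest non-moderate neighbours are
a positive jump on the left and a negative jump on the right is labelled
main-spot, together with the two jump columns nearest the run on each
side. The cap at two columns reflects that an edge occupies at most two
gradient columns; longer jump runs continue into speckle. Consequently a
gradual edge's outermost "foot" pixel can be labelled diffraction — a
1–2 px ambiguity band around edges that the class-agreement tests exclude.
`l_min` defaults to 8: the classification examples this system produces
accept runs of 16 and 47 and reject 5, bounding the threshold in (5, 16].

Everything jumpy, moderate, or flagged by screening but not accepted as
main-spot is diffraction. Exception: a short zero run touching the segment
boundary is left as background — the interval box clips flat background,
not speckle, so its true run length is unknown. Intervals are widened by
`context_px = 4` before processing for the same reason: a spot run
touching the box boundary would otherwise lose the edge jump that pairs
it.

Diffraction pixels are replaced by the local background prediction at that
pixel, *with all flagged/classified pixels excluded from the offset sets*.
The background set is meant to hold background pixels; inside a dense
speckle band the unpurged local mean is itself bright, and replacing
speckle with it would leave the band glowing at a third of its original
intensity. Pixels whose purged set is empty fall back to the global median
of unflagged pixels. Main-spot pixels are preserved bit-identically.

## Ring measurement and the proportionality stack

A ring is measured at the flat (diameter) edge of its half-annulus: the
extreme spot row on the side of maximal horizontal extent. The two spot
runs of that row give the inner and outer radii (as offsets from the
symmetry column, hypotenuse-corrected if the measurement falls a row or
two inward) and the width as the run pixel count; orientation follows from
which half-plane holds the spot mass. A compact blob (≤ 6 px) is a focused
point spot, `r = 0`. A ring is *reliable* when a clean two-run row exists
within one row of the flat edge and the runs agree in width within 2 px.

Stack scales are medians of per-ring ratios `d_i/z_i` and `r_i/z_i` over
reliable rings; with an even count, of the two middle values the one from
the smaller-z ring wins — the innermost ring is the trusted reference.
Widths deviating from `κ_d·z` by more than `width_tol` (default 3 px,
conservative against the ≥ 10 px discrepancies this correction exists for)
are replaced by the prediction and flagged corrected; the correction is
idempotent. Relative defocus is assigned either from measured radii
(`z ∝ r`, default) or as equal spacing when the sample is known to have
equally spaced surfaces. Absolute defocus requires an external calibration
constant (µm per pixel); none is baked in, because it is not derivable
from image content.

The focused surface's spot is reconstructed as a point of
`focus_footprint_px` pixels (default 2 — e.g. a 0.68 µm resolving distance
at 20× magnification on a 5.5 µm pitch rounds to 2 whole pixels) at the
stack's shared center.

## Refinement

`beautify_ring` operates in the ring's own annular neighbourhood (the
ideal annulus dilated by `margin = 8` px) — not its bounding box, which
would wipe nested inner rings. Outside the annulus: the background value
(default: median gray outside the annulus). Inside, pixels dimmer than
`tau_low` (default 0.1, just above the generator's noise ceiling) take the
gray of the same-column neighbour one row toward the ring's bright
mid-row; on the mid-row itself the brighter vertical neighbour is used. A
pixel still dim after replacement is set to 1.0 so the spot stands out.
`trim_to_standard_line` instead fills in-annulus voids with the mean of
their 8-connected non-void in-annulus neighbours, sweeping alternately
top-down and bottom-up (to avoid directional bias) for at most 100 sweeps.
Both operations are idempotent.

## Synthetic scenes

The generator is phenomenological, not wave-optical: the algorithm
consumes gradient statistics, not physics. Each surface draws a
half-annulus with `r = κ_r z`, `d = κ_d z` (defaults `κ_r = 64`,
`κ_d = 17` px per unit defocus, echoing the geometry the package models —
a first ring of width 17 px and apex offset 64 px), peak intensity 0.9,
and a Gaussian intensity falloff in row position about the ring's vertical
midpoint (σ default 120 px): the middle of the spot is brighter, the upper
and lower ends dimmer. Diffraction speckle fills random angular sectors of
a band hugging the outer edge, with *independent* per-pixel gray values in
`[0.25, 1] × amplitude` — a strictly period-two ripple would be invisible
to the central difference (Nyquist cancellation), whereas independent
values produce exactly the frequent sign-alternating gradients that
characterize diffraction. Gaussian noise (σ default 0.004 ≈ 1 DN of
8-bit) is added, the image clipped and quantized to 8 bits last so
normalization round-trips. A surface may carry a `width_override` to
emulate a mis-imaged ring for the correction stage; otherwise the rendered
geometry satisfies the proportionality laws exactly by construction.

What this does *not* emulate: physical diffraction structure (Airy
lobes, coherent interference), vignetting, hot pixels, aberration-induced
asymmetry, or motion. Passing tests show the algorithm handles the stated
gradient phenomenology at realistic contrast and noise; they do not
certify behaviour on optical effects outside that model.

## Resolution probe and study conditions

The probe renders a two-surface template at surface separations scanned
coarse-to-fine, runs screening → de-diffraction → re-screening →
measurement on each frame, and reports the smallest separation at which
the measured rings pass the just-resolved test, for the raw and the
processed image. The strong-diffraction study condition uses `κ_r = 24`,
`κ_d = 12`, a speckle band of 3× the first ring's width (band ≥ ring width
is the strong-adhesion regime), amplitude 0.5, 384×384 frames, fixed
seeds — sizes chosen so the full probe runs in seconds on one CPU. Under
these conditions the processed minimum separation is under half the raw
minimum, and the beautified ring width under 0.3× the diffraction-inflated
raw width.

## Known limitations

* The row classifier is purely horizontal (matching the method it
  implements); speckle aligned into smooth horizontal plateaus of length
  ≥ `l_min` would be kept as spot.
* Ring measurement assumes the flat edge is present in the frame and the
  half-annulus opens vertically; rotated geometries are out of scope.
* Under-counting at raw screening is expected when speckle glues rings
  (that is the failure mode the re-screening stage repairs); severe
  adhesion that survives de-diffraction still under-counts.
* The local-mean screen cannot flag the interior of very wide spots; the
  brightness union handles this but ties interval detection to a global
  background median, which assumes a mostly dark frame.
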