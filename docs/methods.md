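# Methods

## Problem and model

A soft, slender body (the motivating system is the octopus arm, tracked
underwater at 150 Hz with five retroreflective markers) is described
per frame by (1) the curvature of each three-marker segment and (2) the
orientation of the distal segment relative to the proximal one. The
arm is split into a proximal segment (markers 1–3) and a distal segment
(markers 3–5); the shared middle marker makes the two segments span the
whole marker chain with no gap. All positions are in mm internally;
any unit scaling happens at the reader boundary.

### Curvature

For markers P₁, P₂, P₃ of one segment:

- **k_o = 1/R** (mm⁻¹), R the circumradius of the triangle, computed
  with Heron's formula from the side lengths. k_o compares postures
  only at fixed marker spacing: halving the scale doubles k_o.
- **k_b** (degrees), the angle between the chords P₂−P₁ and P₃−P₂.
  For markers equally spaced along a circular arc, k_b equals the arc
  angle per chord (exterior-angle identity) whatever the radius, so it
  is robust to differences in marker spacing between segments. The
  chord convention is forward differences; a centered-difference
  variant would measure the same exterior angle for symmetric
  configurations but is not what the chord picture defines, so forward
  chords are used throughout.

Both are zero exactly when the markers are colinear. Coincident
markers indicate corrupted data, not a posture, and raise
`DegenerateGeometryError` rather than returning NaN.

### Segment frames and the three angles

Each segment's local coordinate system is built as: K̂ = (P₁−P₃)
normalised (the "straight" direction of the segment, pointing
proximally), Î = (P₂−P₃)×K̂ normalised (normal to the bend plane),
Ĵ = K̂×Î. The triad is right-handed and orthonormal to 1e-12. With
fixed body axes e₁ = proximal Î, e₃ = distal k̂ and the floating axis
e₂ = e₃×e₁ normalised:

- α = arcsin(−e₂·K̂) — flexion(−)/extension(+), inherently limited to
  [−90°, +90°] by the arcsin;
- β = arccos(e₁·e₃) − 90° — abduction(+)/adduction(−). This is the
  direct inversion of the defining relation cos(β + 90°) = e₁·e₃ and
  yields a signed value in [−90°, +90°]; reported abduction values for
  real arms cluster near 0°, consistent with the signed convention.
- γ = atan2((e₂×ĵ)·e₃, e₂·ĵ) — external(+)/internal(−) rotation on
  (−180°, +180°]. The signed sine is obtained by projecting e₂×ĵ onto
  the distal long axis e₃, the axis the rotation is about; this is the
  quadrant-resolving reference that lets γ cover a full revolution.
  The boundary value −180° is mapped to +180°.

Sign conventions follow the right-side-of-body rule of the original
joint coordinate system. All three angles are invariant under a common
rigid motion of all six markers (verified to 1e-9 in the tests).

### Degeneracies

- Colinear segment (‖(P₂−P₃)×K̂‖ / ‖P₂−P₃‖ < 1e-10, a scale-free
  test): no bend plane, `ColinearityError`. Physically this is the
  perfectly straight arm; in practice marker noise keeps real data off
  the exact degeneracy, and the nearly-straight posture label covers
  the neighbourhood where the bend normal (hence β, γ) is unstable.
- e₁ ∥ e₃ (‖e₃×e₁‖ < 1e-8): floating axis undefined — the analogue of
  gimbal lock, reached when the distal long axis aligns with the
  proximal bend normal. `SingularConfigurationError` carries the angle
  between the axes. Near (but above) the tolerance the angles remain
  finite and degrade continuously; no smoothing or regularisation is
  applied.

## Posture taxonomy

Labels are assigned per frame from configurable thresholds (degrees):

1. `nearly_straight` — both segment k_b < `straight_kb_max` (15);
2. `complex_bending` — max(|β|, |γ|) > `nonplanar_min` (30);
3. `simple_bending` — both k_b ≥ `straight_kb_max` and
   max(|β|, |γ|) ≤ `nonplanar_min`;
4. `unclassified` — anything else, including frames whose angles are
   unavailable (gaps, degeneracies) and that are not nearly straight.

The ordering makes the straight label depend on curvature only (the
orientation angles are noise-dominated for a near-straight arm) and
makes classification monotone in `straight_kb_max`. The defaults were
chosen so published exemplar postures of this kind (single-trial
curvature rows paired with the corresponding printed orientation
angles) fall in their intended classes; posture identification in the
source studies was visual, so the numeric taxonomy is a reproducible
convenience, not a claimed equivalence. Group *averages* over many
arms need not classify like individual frames (a nine-arm average of
"straight" postures can exceed the per-frame straight threshold on the
proximal segment); `summarize` therefore groups by whatever labels the
frames carry and never re-classifies.

"Overall curvature" for picking the straightest / most bent frame of a
recording (`find_extreme_posture`) is max(k_b proximal, k_b distal) —
the simplest scalar consistent with a minimum-overall-curvature
criterion.

## Synthetic generator

The generators emulate the target acquisition: five markers, 150 Hz,
static postures, optional isotropic Gaussian marker noise (the
simplest defensible model of optical jitter; real marker error is
neither isotropic nor white, see Limitations). Defaults: arc radius
50 mm and marker spacing 20 mm (k_o = 0.02 mm⁻¹, k_b ≈ 22.9°/chord —
mid-range for the bending postures the method targets), noise 0, 100
frames.

- **Planar arc**: markers equally spaced (arc length) along one or two
  tangent-continuous circular arcs in a plane. Ground truth: k_o = 1/R
  and k_b = spacing/R per segment, β = γ = 0, and
  α = δ_prox + δ_dist where δ is the per-chord arc angle (each chord
  long-axis is the arc tangent at the segment's middle marker; the two
  tangents differ by the arc swept between them, and the construction's
  bend-normal orientation makes the sign positive).
- **Imposed rotation**: the distal segment is a rigid copy of the
  proximal one, translated to share the middle marker and rotated
  about one anatomical axis of the proximal frame through that marker.
  Frame construction is rigid-motion-equivariant, so the recovered
  angles equal the imposed one on the chosen axis and zero elsewhere —
  the construction is its own ground truth. The rotation axes are −Î
  (flexion), −Ĵ (abduction) and +K̂ (long axis) so that the recorded
  angle carries the analysis sign convention (a +θ rotation about Î
  reads as α = −θ under the arcsin(−e₂·K̂) definition).
- **Noise study**: Monte-Carlo bias/RMSE per output quantity over a
  grid of specs, one analysed frame per replicate (postures are
  static, so frames are exchangeable with replicates). Child seeds are
  spawned deterministically from the spec seed.

What passing the closed loop (generator → analysis → ground truth
within 1e-6° / 1e-9 relative) shows: the geometry and sign conventions
are implemented consistently. What it does not show: performance on
real arms, where markers wobble on deforming skin, spacing varies along
the arm, segments are not circular arcs, and occlusions create gaps —
only the noise study and the gap-handling tests probe those partially.

## Numerical choices

- arccos/arcsin arguments clamped to [−1, 1]; Heron's square-root
  argument clamped at 0 — both absorb 1-ulp excursions near
  degeneracies instead of producing NaN.
- Text IO parses floats with Python's correctly rounded parser and
  writes 17 significant digits, making write → read ulp-exact.
- Gap interpolation is per-coordinate linear, only for interior runs of
  length ≤ `max_gap_frames`; leading/trailing gaps are never invented.
- Smoothing (opt-in, default off — the method reports no filtering) is
  a centered moving average over valid samples, `min_periods=1` at the
  edges; gap frames stay masked.

## Problem sizes

The test suite validates oracle agreement on 10³ random triples,
angle-range properties on 10⁵ random configurations, Monte-Carlo
properties at 200 replicates per condition, and the full-revolution
twist sweep at 361 one-degree steps; the whole suite runs in well under
a minute, and `scripts/acceptance.py` recomputes the sweep span in a
few seconds.

## Known limitations

- Three markers per segment fit at most a circular arc; higher-order
  bending within a segment is invisible.
- The angles describe relative orientation of segment chords, not
  motion at any anatomical joint — a soft arm has none.
- Near-straight segments have an ill-defined bend normal, so β and γ
  are unstable there; the raw Î direction is kept (no outward-bend
  flipping), and the nearly-straight label is the practical guard.
- C3D input requires the optional `ezc3d` dependency; TSV/CSV are the
  first-class formats.
- The noise model is isotropic and temporally white; real optical
  jitter and skin-deformation artefacts are not.
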