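# softarm

3D posture kinematics for long, thin, **soft** bodies — octopus arms,
trunks, tongues, continuum robots — tracked with a small number of
ordered motion-capture markers.

A muscular hydrostat has no skeleton and no predefined joints: it can
bend anywhere, in any direction, and twist about its own long axis.
Classical rigid-body joint angles do not apply directly, and a single
curvature number cannot say *in which plane* each part of the arm is
bending. `softarm` implements a compact method for this problem, for an
arm instrumented with five (or more) markers split into a proximal
segment (markers 1–3) and a distal segment (markers 3–5) that share the
middle marker:

**Two curvature measures per 3-marker segment**

- circumradius curvature, via Heron's formula on the triangle with side
  lengths *a, b, c* and semiperimeter *s*:

  k_o = 4·√(s(s−a)(s−b)(s−c)) / (abc) = 1/R   [mm⁻¹]

  the inverse radius of the circle through the three markers;
  sensitive to marker spacing;

- chord-angle curvature, the angle between consecutive chord vectors
  v₁ = P₂−P₁ and v₂ = P₃−P₂:

  k_b = arccos(v̂₁ · v̂₂)   [degrees]

  which, for equally spaced markers on a circle, equals the angular
  spacing independent of radius — much less sensitive to segment
  length.

**Three relative-orientation angles between the segments**

Each segment carries a right-handed local coordinate system in the
joint-coordinate-system (Grood–Suntay) style, adapted to a soft body:
long axis K̂ = (P₁−P₃)/|P₁−P₃|, bend normal Î = (P₂−P₃)×K̂ normalised,
and Ĵ = K̂×Î (lower case î, ĵ, k̂ for the distal segment). With fixed
body axes e₁ = Î, e₃ = k̂ and floating axis e₂ = e₃×e₁/|e₃×e₁|:

- α (flexion−/extension+) = arcsin(−e₂·K̂), range [−90°, +90°]
- β (abduction+/adduction−) = arccos(e₁·e₃) − 90°, range [−90°, +90°]
- γ (external+/internal− rotation) = atan2((e₂×ĵ)·e₃, e₂·ĵ),
  range (−180°, +180°]

The two-argument tangent for γ is the key modification for soft bodies:
a soft arm can twist far beyond ±90°, where sine- or cosine-only
definitions fold back. γ resolves the full 360° revolution. When e₁
and e₃ become parallel the floating axis is undefined (the gimbal-lock
analogue) and a `SingularConfigurationError` is raised; exactly
colinear markers raise a `ColinearityError` since no bend plane exists.

On top of the geometry the package provides marker-table IO (TSV/CSV,
optional C3D via `ezc3d`), gap interpolation, a per-frame analysis
pipeline with a configurable posture taxonomy (nearly straight / simple
bending / complex bending), group summaries, and synthetic-arm
generators with analytic ground truth for validation.

## Worked example

Generate a noiseless 5-marker arm whose distal segment is a copy of the
proximal one twisted by +155° about the long axis, then analyse it:

```sh
$ softarm simulate --posture rotation --axis long_axis --angle 155 \
    --frames 3 --out arm.tsv
wrote 3 frames to arm.tsv
wrote ground truth to arm.tsv.truth.csv

$ softarm analyze arm.tsv --out results.csv
wrote 3 frames to results.csv

$ head -2 results.csv
frame,time_s,k_o_prox,k_b_prox,k_o_dist,k_b_dist,alpha,beta,gamma,label
0,0.0,0.020000000000000018,22.918311805232975,0.020000000000000042,22.91831180523293,-1.7099171840030874e-15,0.0,155.00000000000003,complex_bending
```

Reading the row: both segments lie on a 50 mm arc, so k_o = 0.02 mm⁻¹
(= 1/50) and k_b = 22.92° (each chord spans 20 mm / 50 mm = 0.4 rad of
arc). The imposed twist is recovered as γ = 155.000° — well beyond the
±90° a sine/cosine definition could report — with α = β = 0 to
machine precision, and the frame is labelled `complex_bending` because
|γ| exceeds the 30° non-planarity threshold. `softarm summarize
results.csv --by label` prints per-label means and standard deviations;
`softarm config init` prints every tunable default (segment triples,
classification thresholds, smoothing, gap handling).

The same operations are available as a library:

```python
from softarm import SyntheticArmSpec, generate_imposed_rotation, analyze_trajectory

traj, truth = generate_imposed_rotation(
    SyntheticArmSpec(imposed_rotation=("long_axis", 155.0), n_frames=1)
)
angles = analyze_trajectory(traj)[0].angles  # alpha, beta, gamma in degrees
```

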