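# Methods

## Coordinate and sign conventions

All positions are in cm at the isocenter plane (SAD = 100 cm). The
leaf-travel axis is *u*; each bank has a bank coordinate whose positive
direction is the bank retracting: Y2's equals +*u*, Y1's equals −*u*. A
displayed position *d* is the intended field-edge location in bank
coordinates, so a pair displayed (y2, y1) opens the axis interval
[−y1, +y2] of width y2 + y1 — e.g. (18, −10) → [10, 18], 8 cm, and
(12.1, −9.9) → [9.9, 12.1], 2.2 cm. The RLO lookup *r(d)* is
piecewise-linear between tabulated nodes and clamps to the end values
outside them (the interpolation rule of the commercial system it emulates
is unpublished; linear-with-clamping is the simplest continuous choice and
is exact at the nodes, which are the only positions the procedure uses).
The effective apex position is *e = d − r(d)*: a positive offset moves the
leaf toward the opposing bank, a negative one retracts it.

Backup diaphragms trail each bank by 2.0 cm in bank coordinates
(displayed + 2), i.e. their edges sit 2 cm outside the leaf tips and never
define an in-field edge.

## The dose engine

The engine stands in for a treatment planning system's photon calculation,
reduced to what the calibration procedure consumes: a relative planar
fluence map with a realistic, position-dependent rounded-tip penumbra. It
is not a dose model — no MU, no depth dose, no heterogeneity.

**Geometry.** A point source sits on the axis. Each leaf is a slab of
thickness *t* along the beam whose tip is a circle of radius *R* centered
in the leaf mid-plane at distance *z_l* from the source; the material
region is the convex set `{|z − z_l| ≤ t/2, u on the leaf side of the tip
circle}`. The tip circle is anchored so that its apex (the material point
furthest toward the opening) projects from the source exactly to *u = e*
at the isocenter plane. Apex anchoring is a convention, not a claim about
the real machine: the calibration corrects whatever residual offset the
convention induces, exactly as it corrects a commercial system's.

**Transport.** The material path of the ray to each grid point has a
closed form (the ray-inside set is one interval of the convex region:
union of a body half-space cut and a circle chord, times the ray
obliquity). Primary fluence is `exp(−μ·L)` through both banks, X jaws and
backup jaws are ideal blockers, and the result is floored at the leakage
transmission, convolved with an isotropic Gaussian, and scaled to 100 at
the open-aperture center. Fluence rows are computed once per distinct leaf
pair configuration, so a 500×600 grid beam costs milliseconds.

**Edge behavior this produces.** Near the axis the tip bulge throws its
shadow symmetrically and the 50% edge lands slightly *beyond* the displayed
value (positive table entries); far off-axis the oblique rays see a long
chord through the tip and the edge falls *short* (increasingly negative
entries). This is the qualitative shape of published vendor tables, with
the on-axis maximum and the monotone fall-off toward full retraction.

## Parameters (elekta80 preset)

| parameter | value | meaning |
|---|---|---|
| `source_to_iso_distance` | 100 cm | SAD; plane of all positions |
| `source_to_leaf_plane` | 38.0 cm | source → leaf mid-plane |
| `tip_radius` | 4.0 cm | effective rounded-tip radius |
| `leaf_thickness` | 7.5 cm | slab thickness along the beam |
| `mu` | 0.9 cm⁻¹ | effective attenuation of leaf material |
| `transmission_floor` | 0.017 | leakage under a full leaf |
| `blur_sigma` | 0.10 cm | Gaussian penumbra kernel at isocenter |
| grid spacing | 0.05 cm | planar dose resolution (0.5 mm) |

`tip_radius` and `source_to_leaf_plane` are *effective* parameters, not a
mechanical drawing. The tangent-shadow offset of the tip grows as
`R·e²/(2·z_l·SAD)` with slope `R·e/(z_l·SAD)`; commercial beam models (as
reflected in their published edge sweeps) show an offset that varies by
only ~0.02 cm per cm of travel at full retraction, and the one-pass
correction converges precisely because that dependence is weak (the
residual after one pass scales like slope × offset). The preset values put
the slope at ≈0.019 cm/cm at e = 18 cm — measured closed-loop residual
0.038 mm — while keeping offset magnitudes (−0.08 … +0.10 cm) in the range
of real tables. A literal Elekta tip (R = 15 cm at z_l ≈ 33.6 cm) in this
slab geometry gives a slope ≈0.07 cm/cm, which no single correction pass
can beat to 0.1 mm; a system needing that geometry should iterate the
derivation (trivially available by re-deriving from the previous result).
SSD (98 cm) and calculation depth (2 cm) place the scoring plane at the
isocenter; their dosimetric effect (source size, shallow-depth scatter) is
folded into `blur_sigma` rather than modeled explicitly, because the
procedure needs a smooth realistic penumbra, not absolute dosimetry.

The `varian120` preset (60 pairs, central 40 × 0.5 cm) uses R = 8 cm at
z_l = 50.9 cm; its offset slope is ≈0.028 cm/cm, so its one-pass residual
margin is smaller.

## Edge detection and the update rule

Profiles are taken through the center of one leaf pair (pair 19 for the
sweep, pair 8 for the Picket Fence; both parameters), normalized to 100 at
the midpoint between the two displayed edges, and the 50% level is located
by linear interpolation between the two bracketing samples nearest each
displayed edge. The 50% point sits at the penumbra inflection, so the
interpolation error is far below the grid spacing (halving the grid moves
edges by ~0.002 cm). If a noisy floor produces several crossings, the one
nearest the displayed edge wins. 50% means 50 of the open-field-center
normalization, not of any local plateau.

The update rule per sweep row is exact arithmetic: `modified_b = r_used +
(edge_b − d)` per bank, then the bank average, carried at full floating
precision and rounded to 4 decimals only on file output. The
`rlo_used` column is the table lookup at the displayed position (node
evaluation; the sweep positions are the table nodes). In this engine the
two banks' edges at a given displayed value are mirror images of the same
geometry, so the bank average is a numerical no-op; it is kept because the
procedure defines it (a physical machine, and the bundled reference
sweeps, show genuine bank asymmetry).

## Picket Fence simulation

Strips of width `shift + overlap` (2.2 cm for the 2 mm test, 2.3 cm for
3 mm) are centered at 11, 9, …, −11 cm — twelve strips, X jaws at
X1 = 20/X2 = 2 — and their planar doses are summed on a common grid, then
rescaled so the single-strip plateau (median composite value at the strip
centers) is 100. The "3 mm" variant is read as a 3 mm *overlap* with the
strip centers kept fixed and the width widened symmetrically; the printed
endpoints for that variant are not published, so symmetric widening is
assumed. Posts are local maxima above 130% of plateau separated by at
least 1 cm, with parabolic sub-grid refinement. With this engine's
penumbra (~0.5 cm edge width, comparable to the overlap) the 2 mm posts
peak near 137% of plateau and the 3 mm posts near 153% — well above the
detection threshold but below the loss-free doubling a very sharp beam
would give. A constant table error of −0.25 cm widens every strip by
0.5 cm and inflates the posts by far more than 5%, which is what makes the
test a useful table check.

## Light-field conversion

The light-field edge is the geometric shadow boundary: the extreme
isocenter projection of the tip-face arc within the slab, which is the
source-tangent ray where the tangency lies inside the slab and the arc
corner otherwise (closed form via the tangency condition
`z_l·sinθ + u_c·cosθ = −R`). The conversion offset per displayed position
is light edge minus radiation (50%) edge for the same effective placement,
averaged over the banks; it is fitted with ordinary least squares and the
fitted line is *added* to the dosimetric table to make the
light-field-calibration table (so subtracting the line recovers the
dosimetric table exactly — the documented, tested sign convention). In
this engine both edges scale with position almost identically, so the
conversion is nearly constant (≈ −0.09 cm, slope ≈ 6·10⁻⁵): the fit's
residual rms (≈0.001 cm) is small in absolute terms, which is the claim
that matters; a real machine's conversion curve may carry a genuine slope
(e.g. a light/X-ray source offset), which the same machinery absorbs.

## What the engine does and does not emulate

Passing tests show the *procedure* is correct — the sweep design, the
edge detection, the update arithmetic, one-pass convergence,
starting-table independence, and the QA analyses — on a collimator model
with a realistic rounded-tip penumbra. They do not certify any real
machine's numbers: the bundled commercial-TPS sweep tables are inputs to
the (exactly reproducible) arithmetic, not targets for the engine; bank
asymmetries, tongue-and-groove, interleaf leakage structure, leaf-side
focusing, film response and absolute dose are all outside the model.

## Numerical choices

- Grid nodes on multiples of the spacing; auto-sized grids cover the open
  aperture plus a 2.5 cm margin; the blur kernel is truncated at 4σ
  (`mode="nearest"`), so widening the margin leaves interior values
  unchanged at double precision.
- Normalization uses bilinear interpolation at the aperture center; a
  center value at or below 3× the leakage floor raises a normalization
  error (no open field).
- Degenerate inputs: zero-width pairs are legal beams (closed junction);
  tables must be strictly increasing in position; table files are sorted
  on read and duplicate positions rejected; negative pair widths and
  protruding backup jaws are rejected at construction.
- The closed-loop verification reruns the identical sweep, so grid-phase
  effects cancel to ~10⁻³ cm; residuals are reported in cm (CLI: mm).
- Everything is deterministic; the CLI's outputs are byte-identical across
  runs and every output file carries the tool version and a parameter echo
  in `#` comments.

## Problem sizes

The standard configuration throughout — tests and the acceptance script —
is the full-size study: 15-beam sweeps on 0.5 mm grids (~500×600 points
per beam), 12-strip composites, and closed-loop verification as a second
full sweep. A sweep takes well under a second on one core; the whole suite
runs in a few seconds.
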