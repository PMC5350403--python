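# Methods

## Scope and fidelity

`stemopt` reproduces a design-optimization *methodology* for cemented
femoral stems at desk scale. The stem geometry, the shielding and damage
metrics and the orthogonal-array optimizer are implemented in full; the
3-D tetrahedral finite-element analysis of a scanned cortical femur is
deliberately replaced by a one-dimensional composite-beam surrogate. The
CSV stress-field interface (`stemopt.surrogate.import_stress_field`) is
the seam where users with a 3-D solver can re-inject full-fidelity fields;
everything downstream (fatigue, metrics, optimization) is agnostic to the
field's origin.

## Geometry

Each variable cross section is two superellipse halves
`|x/a|^p + |y/b|^p = 1` joined along the common b-axis (local y). The
frontal half (x ≥ 0) uses semiaxis a₁ and the opposite half a₂ — the
assignment of halves to the anterior/posterior sides is a fixed convention
of this package. The curve is parameterized as
`x = a(θ)·sgn(cos θ)|cos θ|^(2/p)`, `y = b·sgn(sin θ)|sin θ|^(2/p)`; both
halves share b and p, so the curve is closed and continuous (the approach
to the junction scales as ε^(2/p)).

Section area, centroid and second moments are computed by polygonal
(Green's-theorem) quadrature of the sampled boundary, converging as
O(n⁻²); the default n = 2048 reproduces the gamma-function closed form
`4ab·Γ(1+1/p)²/Γ(1+2/p)` to better than 10⁻⁵ relative. The composite
solver exposes `n_profile` for callers needing tighter agreement (the
oracle tests use n = 65536, ≈10⁻⁹ relative).

Skeleton defaults (all configurable, `SkeletonConfig`): total length
185 mm; distal circular section r = 6 mm; axis–neck junction at 0.75 L;
neck-shaft angle 135°; four-point Bezier transition spanning 0.10 L on
each side of the junction, inner control points at 1/3 spacing along each
axis; stations 1–3 at fractions {0, 0.25, 0.55} of L (normals along the
axis), station 4 at the Bezier midpoint (normal = spline tangent),
stations 5–6 at fractions {0.3, 0.75} of the 35 mm neck axis. The paper
trail for these placements does not exist in any source; they are package
defaults chosen to produce a plausible stem silhouette.

The loft is a cubic B-spline (third-order NURBS with unit weights)
through the six station rings on a chordal parameterization —
`scipy.interpolate.make_interp_spline` stands behind this surface, and
`trimesh` behind STL export and watertightness checks. Lengthwise slicing
(e.g. 11 layers for a graded stem) only records boundary planes; the loft
is not re-cut.

**Cement and admissibility.** The canal is a per-station circular/elliptic
profile; radial thickness is the closed-form polar-radius difference
between canal and stem on a dense angle grid. Defaults (canal radii 8.5,
10.5, 12.0, 14.0 mm at stations 1–4) make the mid-bound oval design a
uniform 2.5 mm mantle. A design is admissible iff thickness stays within
[2.0, 3.0] mm at every in-canal station *and* section areas are monotone
nonincreasing from station 4 to the tip. The taper rule operationalizes
"clinically admissible" as *insertable* (no distal bulge); it is a
documented interpretation and can be disabled. Semiaxis search intervals
guarantee the thickness window only for oval (p = 2) sections; high
exponents bulge diagonally and are caught by the checker — this tension
between profile and mantle is part of the design problem.

## Structural surrogate

Transformed-section Euler beam, cantilevered at the distal femur. At each
axial station all constituents share ε₀ and κ with
`ε₀ = N/ΣEA`, `κ = M/ΣEI`, `σ = E(ε₀ + κy)`. All default sections are
symmetric about the bending (medial y) axis: the common b semiaxis lies in
the bending plane and a₁/a₂ asymmetry only offsets the centroid along the
frontal x-axis, which does not couple into Ixx — an intentional modeling
simplification.

Default femur (mm): 250 long, outer radius 12.5 → 16.0 and natural canal
6.5 → 11.0 distal → proximal, linearly interpolated between four stations.
These radii lie within adult anatomy (thick diaphyseal cortex, thin
metaphyseal shell) and were **calibrated once** so that the default
Ti-6Al-4V assembly reproduces the experimentally reported 40–50% mean
surface-stress reduction; they were not adjusted afterwards. The intact
canal contents (marrow/cancellous bone) default to zero modulus
(`core_modulus = 0`); setting `core_modulus` to the bone modulus yields a
solid intact section, which is how the homogeneous-limit identity
(implanted field ≡ intact field when stem and cement take the bone
modulus) is made exact and is tested.

Loads: joint force on the femoral head (offset +40 mm medial, +40 mm
above the resection), abductor at the greater trochanter (−25 mm lateral,
−10 mm below the resection), both in the medial plane; magnitudes/angles
2.5 kN @ 10° and 1.5 kN @ 15°. The lever arms are package defaults (no
source dimensions exist) and configurable.

Surface samples: 95 axial × 32 circumferential = 3040 locations over the
femur. Stresses are reported as the peak equivalent uniaxial magnitude
|σ|; the walking cycle is taken as zero-to-peak (R = 0, constant-amplitude
proportional loading), so alternating = mean = peak/2 at every node. The
shielding coefficient is invariant to that common factor; the factor
matters only for cement fatigue, where it is applied. The beam stress is
uniaxial, so its von Mises equivalent is |σ| and the Goodman-then-von-Mises
ordering question is moot; imported multiaxial fields must settle that
ordering upstream.

Cement nodes: 40 axial × 16 circumferential points at ring mid-thickness
over the cemented span (640 nodes by default).

**Neutral-axis caveat.** Under combined axial + bending load the zero
crossing of σ shifts slightly between intact and implanted sections, so a
handful of near-neutral-axis sample points can show higher implanted
stress even for a stiff stem. Station-mean stresses are strictly reduced;
reduction percentages are therefore reported as ratios of means, never
means of pointwise ratios.

## Fatigue

Basquin curve S = A·N^b with defaults A = 36.6 MPa, b = −0.065 — a
log-log linear fit in the range of published PMMA bone-cement S–N data
(~14 MPa fatigue strength at 2×10⁶ cycles). The original S–N source is
cited in the literature but its coefficients are not printed anywhere
available, so the curve is configuration (`SNCurve`) and every damage
number is meaningful only relative to the curve used. Lives clamp to
[1, 10⁸] cycles; stresses at/below the 10⁸-cycle strength are runout.
Goodman correction uses PMMA ultimate strength 70 MPa (configurable;
mean stress ≥ σ_u raises). Damage is binary with a *strict* inequality
(life exactly equal to the design life counts as intact). The damage
parameter is reported as a percentage of cement nodes (the raw damage sum
divided by i_max, ×100), which is how tabulated values are expressed.

The smooth 1-D beam produces cement stresses of a few MPa for realistic
assemblies — below the fatigue strength — so the default pipeline yields
0% damage; real mantles are damaged by 3-D stress concentrations the
surrogate cannot represent. The fatigue pipeline is therefore validated
with planted synthetic fields (`fixtures.make_cement_field`), which invert
the S–N + Goodman chain to place an exact number of failing nodes.

## Objective and optimizer

`J = (damage/max damage)² + (SS/max SS)²` with running maxima updated
before each evaluation (dynamic normalization). Consequences, both
tested: J ∈ [0, 2]; rankings made at evaluation time are not preserved
under post-hoc renormalization once maxima have grown — the JSONL
design-of-experiments log stores the maxima at evaluation time so runs
can be renormalized afterwards. A term whose running maximum is zero
(e.g. damage, see above) contributes zero. Inadmissible designs receive
2.0 + (summed constraint breach) instead of a solve, keeping arrays
complete.

Orthogonal arrays come from Sylvester–Hadamard matrices (L4…L64; 20
factors → L32) and are exhaustively checked for balance and pairwise
orthogonality. Levels: x ∓ 0.2·(domain width) for continuous variables,
p ∓ 1 for exponents, box-projected (projection is idempotent; integers
are rounded then clipped). Main effects use the mean response per level
("smaller is better"); a −10·log₁₀(mean y²) S/N-ratio variant is a config
switch.

Restart selection ("VVP"): the original density is defined in an appendix
that is not available, so the package implements a documented
interpretation — normalize the store to the unit box, weight each
coordinate by the store's variance, pick the vertex maximizing its
minimum weighted distance to the others (plain max–min available via
config). Ties break to the lowest index; a single seeded generator drives
all randomness.

Each restart iterates the array step until no improvement (bounded by
`inner_iterations`), reading "locally minimize" as a local search; a
single array step cannot localize an optimum because both levels sit a
fixed ±0.2 width from the current value. For the same reason the
converged objective is quantized by the 0.2-width move lattice: on a unit
5-sphere each coordinate lands within 0.1 of the optimum, bounding the
converged objective by 0.05, but which restart achieves it depends on the
seed. Falling back to the best evaluated run when the predicted optimum
underperforms (factor interactions) implements the T1 branch; duplicate
optima (within tolerance in the unit box) trigger the T2 skip; the
restart budget is T3.

## Synthetic generators

`fixtures` provides pure-function generators: tapered tube femurs, paired
surface fields with a planted reduction profile (optionally noisy), and
cement fields with an exact planted damaged-node count. They emulate
magnitudes and grid layout of real fields, **not** the spatial correlation
or multiaxiality of a 3-D FEA — passing tests demonstrate the correctness
of the formulas and pipeline plumbing, not predictive accuracy for any
real femur.

## Default problem sizes

Surface grid 95×32, cement grid 40×16, boundary quadrature 2048 points,
thickness grid 720 angles; optimizer 10 initial vertices, 30 restarts,
L32 arrays. The whole default pipeline evaluates a design in ~5 ms, and
the test suite and acceptance script each run in seconds. Smoke
configurations in the tests use coarser grids (16×8) and 2 restarts.

## Known limitations

- 1-D beam: no interface shear/micromotion, no torsion, no hoop stresses,
  no contact or debonding; cancellous bone excluded.
- Cement damage at desk scale is ~0; damage-vs-shielding trade-offs only
  emerge with imported 3-D fields or synthetic cement stresses.
- The Bezier/neck region is treated as axial stations for section
  properties (plane orientation ignored in the beam).
- Exponent levels p ∓ 1 make the integer search myopic for wide exponent
  ranges (widest here is [2, 4], which is fully reachable).
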