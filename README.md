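# stemopt

Design optimization of the femoral stem of a **cemented total hip
prosthesis**. Two failure drivers pull the design in opposite directions:

- **Stress shielding** — a stiff stem carries load that the proximal femur
  would otherwise see, the surrounding cortical bone is under-stressed and
  resorbs, loosening the prosthesis over decades.
- **Cement fatigue damage** — a compliant, slender stem loads the PMMA
  cement mantle harder, nucleating fatigue cracks that debond the fixation.

`stemopt` implements a self-regulated pipeline that balances the two:
parametric stem geometry → structural solve of the femur–cement–implant
assembly → shielding and fatigue-damage metrics → a Taguchi
orthogonal-array global search over the stem shape. It targets engineers
and researchers exploring implant cross-section design, including
functionally graded (lengthwise layered-modulus) stems.

## Model

**Geometry.** The stem skeleton is a straight prosthesis axis blended into
the neck axis by a four-point Bezier spline, carrying six key cross
sections (distal section: fixed circle, r = 6 mm; total length L = 185 mm).
Each variable section is a closed curve built from two superellipse halves

    |x/a|^p + |y/b|^p = 1

sharing the common semiaxis *b*: the frontal half uses semiaxis *a₁*, the
opposite half *a₂*, both with the same integer exponent *p* (*p* = 2 is an
ellipse, *p* = 3–4 approaches a trapezoidal profile). Five variable
sections × (a₁, a₂, b, p) give the 20-variable design vector. A cubic
B-spline loft (a third-order NURBS with unit weights) interpolates the
sections; designs are admissible when the cement mantle stays between
2.0 and 3.0 mm and the section areas taper monotonically toward the tip.

**Structural surrogate.** The 3-D finite-element analysis of the original
workflow is replaced by a transformed-section composite Euler beam: bone
tube, cement ring and stem share axial strain and curvature, each carrying
σ = E(ε₀ + κy). The walking load case is a 2.5 kN joint force at 10° to
the femur axis plus a 1.5 kN abductor force at 15°; materials are cortical
bone 18.6 GPa, PMMA 2.28 GPa, Ti-6Al-4V 110 GPa (ν = 0.3 throughout), or
an 11-layer functionally graded schedule (120 → 10 GPa proximal to
distal). Externally computed stress fields can be imported from CSV in
place of the surrogate.

**Metrics.** With σᵢ, σᵢ′ the equivalent stresses at N = 3040 preselected
femur-surface locations (intact / implanted) and σ_av the mean intact
stress:

    SS = (1/σ_av) · sqrt( Σᵢ (σᵢ − σᵢ′)² )             (stress shielding)

Cement damage: per cement node, Goodman mean-stress correction
σ_eq = σ_a/(1 − σ_m/σ_u), power-law S–N life N = (σ_eq/A)^(1/b), binary
damage dᵢ = 1 iff Nᵢ < design life (2×10⁶ cycles); the **critical cement
damage accumulation parameter** is 100·Σdᵢ/i_max (%). The scalarized
objective uses running maxima over all designs evaluated so far:

    J = (damage/max damage)² + (SS/max SS)²  ∈ [0, 2]

**Optimizer.** From 10 random vertices, each of up to 30 restarts picks
the stored vertex farthest from the rest (variance-weighted max–min
distance), builds two levels per variable (x ∓ 0.2·Δx continuous, p ∓ 1
integer, box-projected), and iterates a 32-run two-level orthogonal-array
(L32) main-effects step to a local optimum, which joins the vertex store.

## Worked example

Evaluate the default design (mid-interval semiaxes, oval sections) as a
Ti-6Al-4V stem in the default surrogate femur:

```bash
stemopt evaluate
```

```json
{
  "config_hash": "9c0c539aa254",
  "admissible": true,
  "damage_pct": 0.0,
  "stress_shielding_coef": 17.77288490334614,
  "mean_stress_reduction_pct": 43.05503831170814,
  "violations": [],
  "penalty": 0.0
}
```

Reading the numbers: the design keeps the cement mantle inside 2–3 mm
(`admissible`), the smooth beam surrogate predicts cement stresses below
the S–N fatigue strength at 2×10⁶ cycles (`damage_pct` 0 — the 3-D stress
concentrations that damage real mantles are beyond a 1-D beam), and the
stiff stem reduces the mean bone surface stress over the implanted span by
≈ 43% (`mean_stress_reduction_pct`), inside the 40–50% band reported for
Ti stems; `stress_shielding_coef` is the same comparison as the
root-sum-of-squares coefficient used by the optimizer. Other entry points:

```bash
stemopt build --slices 11        # STL + profiles + constraint report (FGM slicing)
stemopt optimize --restarts 5    # orthogonal-array search, JSONL log + optima table
stemopt import-stress --path fea_export.csv   # plug in external 3D FEA fields
```

The same functionality is available as a library (`stemopt.geometry`,
`stemopt.surrogate`, `stemopt.fatigue`, `stemopt.metrics`,
`stemopt.optimizer`, `stemopt.pipeline`, `stemopt.fixtures`).

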