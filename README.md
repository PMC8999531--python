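# implantbar

Analytical stress assessment of bar-splinted dental implant arrays on a
Winkler elastic foundation.

## The problem

A common restoration for the edentulous mandible is a complete removable
overdenture locked onto a metal bar that splints four intraosseous
implants. Mastication loads applied at a denture tooth — especially on the
distal cantilever, behind the most posterior implant — are transferred
through the rigid bar into the implants and the surrounding bone. The
clinical questions are mechanical ones: how large are the stresses in the
implants and in the peri-implant bone, which implant governs, how much
load is safe, and how far distally may the dentition be loaded?

`implantbar` answers these questions with a closed-form mechanical model
aimed at treatment planning: it needs only the implant coordinates and
sizes, the bone Poisson ratio, the load magnitude and position, and the
allowable stresses — no CT segmentation or finite-element meshing.

## The model

* The assembly "implants + bar + denture base" is a single **absolutely
  rigid body** (the metal is ~100× stiffer than bone) with six degrees of
  freedom: translations `(Δx, Δy, Δz)` of the centre of rigidity `C` and
  small rotations `(Θx, Θy, Θz)` about the central axes.
* Each implant (length `H`, diameter `d`, vertical, at `(x_i, y_i)` in
  central coordinates) is bedded in bone through a thin **Winkler layer**:
  the contact line load is `q_i(ζ) = −C u_i(ζ)` with
  `C = diag(C_n, C_n, C_τ)`, `C_n = E_b π d / h`, and rigidity ratio
  `γ = C_n / C_τ = 2(1 + ν_b)`.
* For a layout mirror-symmetric about the sagittal plane, the 6×6
  stiffness is diagonal and a vertical load `P` at pole `(x_p, y_p)` gives

  ```
  Δz = −P / (4 C_τ H),   Θx = −P y_p / (C_τ a_x² H),   Θy = P x_p / (C_τ a_y² H)
  a_x² = Σ y_i² + γH²/3,  a_y² = Σ x_i² + γH²/3
  ```

  with `Δx = Δy = Θz = 0`. Arbitrary layouts (irregular quadrangles, ≥3
  implants) are handled by an exactly assembled 6×6 solver.
* Rod statics (`dQ/dζ = −q`, `dM/dζ = −Q×k`, free apex) yield internal
  actions and, per implant, the neck stresses

  ```
  σ_impl = (P/S0) · max± |s_i ± (2/3) γ (H/d) b|           (max-normal-stress)
  σ_bone = (P/Sl) · sqrt(γ²/4 · b² + 3 s_i²)               (von Mises)
  s_i = 1/4 + x_p x_i / a_y² + y_p y_i / a_x²,   b = sqrt((H x_p/a_y²)² + (H y_p/a_x²)²)
  ```

  where `S0 = πd²/4`, `Sl = πdH`. Stresses depend on the bed only through
  `γ` and are exactly linear in `P`, making allowable-load inversion exact.
* A brute-force **spring oracle** (N Winkler springs per implant, midpoint
  quadrature) cross-validates every closed form.

Units are mm / N / MPa; `Z` is upward, the load acts in `−Z`, compression
is negative.

## Worked example

Two clinically representative placements are bundled: variant 1, a wide
trapezoid (implants at X = ±21, ±12 mm), and variant 2, a narrow one
(±16, ±6 mm) whose bar is almost straight. Both carry a seven-tooth arch
loaded with 100 N per tooth, with allowables of 150 MPa (titanium) and
3 MPa (bone interface).

```python
>>> import implantbar as ib
>>> cfg = ib.reference_config(2)                      # narrow trapezoid
>>> load6 = cfg.load_cases()[5]                       # tooth 6, 100 N
>>> r = ib.analyze(cfg.implant_array(), cfg.bone_bed(), load6, cfg.limits())
>>> round(r.peaks.implant_max, 2), round(r.peaks.bone_max, 2), r.peaks.governing_bone
(67.98, 2.56, 4)
```

The supporting (fourth) implant carries ~68 MPa — safe against 150 MPa —
and the bone next to it ~2.56 MPa, safe against 3 MPa. Loading the second
molar instead overloads the bone:

```sh
$ implantbar check --variant 2
tooth 1: implant 20.33 MPa, bone 0.7894 MPa (implant 3) -> pass
...
tooth 6: implant 67.98 MPa, bone 2.562 MPa (implant 4) -> pass
tooth 7: implant 98.83 MPa, bone 3.495 MPa (implant 4) -> FAIL
max loadable tooth: 6
$ implantbar safe-load --variant 2 | tail -1
tooth 7: P_max = 85.84 N
```

So the narrow layout should either be loaded no further than the sixth
tooth or have its mastication load limited to ~86 N at the molar; the wide
layout (`--variant 1`) passes everywhere (`max loadable tooth: 7`). Other
commands: `solve` (one case, JSON summary), `sweep` (per-tooth peak
table), `profile` (per-station CSV along the implant), `fixtures` (emit a
config to edit), with flags `--general` (arbitrary layouts), `--oracle`
(spring-model cross-check), `--gamma`, `--grid`.

## Scope

Vertical loads, parallel equal implants, homogeneous bed, perfect contact
(no resorption), no thread-level stress concentration. See
`docs/methods.md` for assumptions, parameter choices and limitations.
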