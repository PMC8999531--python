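# Methods

## Mechanical model

The package models a bar-retained overdenture on `n` parallel vertical
cylindrical implants (default and clinically typical: `n = 4`, at the
vertices of an equilateral trapezoid). Three assumptions define the model:

1. **Rigid frame.** Implants, bar and denture base move as one rigid
   body. Justified by the two-orders-of-magnitude stiffness contrast
   between the metal framework and bone; it reduces the kinematics to six
   scalars (three translations of the centre of rigidity, three small
   rotations).
2. **Winkler interface.** Each implant is conjugated with the bone
   through a thin elastic layer of thickness `h << d` representing the
   thread zone with young regenerated tissue. Contact stresses are
   proportional to the local relative displacement: normal stress
   `σ_n = −E_b u_n / h`, tangential `σ_τ = −E_b u_τ / (2(1+ν_b) h)`,
   giving line-load rigidities `C_n = E_b π d / h` and `C_τ = C_n / γ`
   with `γ = 2(1+ν_b)`.
3. **Perfect contact.** No separation, slip or resorption at the
   interface.

Equilibrium of the rigid body against the bed reactions yields a 6×6
linear system. Two solution paths are provided:

* **Closed form** (`solve_frame_symmetric`): for a four-implant layout
  mirror-symmetric about the sagittal plane the central axes are
  principal, the matrix is diagonal, and the kinematics are the explicit
  formulas quoted in the README. The solver *verifies* the symmetry
  (mirror match within 1e−9 mm after centring) and refuses otherwise.
* **General assembly** (`solve_frame_general`): for any centred layout
  the stiffness blocks integrate in closed form (integrands are at most
  quadratic in the axial coordinate), the translation–rotation coupling
  vanishes identically, and asymmetry appears only as the product of
  inertia `Σ x_i y_i` coupling the two tilts. The system is solved with
  a dense linear solve; a condition-number guard raises `RankError` for
  degenerate inputs (unreachable for ≥2 distinct implants with positive
  rigidities, but kept as a safety net).

The centre of rigidity is always recomputed from the implant coordinates
— printed or user-supplied centres are never trusted, since a stale
centre silently corrupts every downstream moment arm.

## Internal actions and stresses

The bed reaction on each implant, `q_i(ζ) = −C(Δ + Θ×r_i)`, is *exactly*
linear in `ζ` for a rigid frame — on any layout, not just symmetric ones.
The rod equilibrium equations are therefore integrated analytically
(polynomial antiderivatives with the free-apex condition
`Q(−H/2) = M(−H/2) = 0`): `Q` is quadratic, `M` cubic, and no numerical
quadrature enters either solution path. The independent spring oracle
(below) deliberately does *not* reuse these integrals.

Stresses follow the strength-of-materials scheme for a circular section
(`S0 = πd²/4`, `J = πd⁴/64`, `W = πd³/32`, `Sl = πdH`):

* outer-fibre axial stress `σ± = Q_ζ/S0 ± |M|/W` (and, at an arbitrary
  section point, `Q_ζ/S0 + M_η ξ/J + M_ξ η/J`);
* bone interface stresses `σ_n = |q_⊥|/(πd)` (reported as a magnitude),
  `σ_τ = q_ζ/(πd)`;
* equivalent stresses: `max(|σ⁺|, |σ⁻|)` for the implant
  (max-normal-stress criterion, appropriate for compression with
  bending of titanium) and `sqrt(σ_n² + 3σ_τ²)` for the bone interface
  (von Mises energy criterion).

Both equivalent stresses attain their maximum at the implant neck
`ζ = H/2`; the grid peaks are cross-checked against the closed-form neck
expressions to 1e−12 relative in the test suite. Two structural facts are
worth stating because the tests rely on them: the final stresses contain
the bed parameters only through `γ` (so `E_b` and `h` drop out — they
affect displacements only), and every stress is exactly linear in `P`.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `H`, `d` | implant length/diameter, mm | 10, 4 | bundled configs |
| `ν_b` | bone Poisson ratio | 0.35 | sets `γ = 2.7` |
| `γ` | `C_n/C_τ` | from `ν_b` | overridable for sensitivity studies |
| `E_b` | averaged bone modulus, MPa | 1000 | displacements only; placeholder of realistic order |
| `h` | interface thickness, mm | 0.1 | displacements only; placeholder, `h << d` |
| `P` | vertical load per tooth, N | 100 | typical mastication force |
| `[σ]_impl` | allowable implant stress, MPa | 150 | titanium, with fatigue margin |
| `[σ]_bone` | allowable bone stress, MPa | 3 | "healthy" bone interface |
| grid | axial stations on `[−H/2, H/2]` | 101 | evaluation only; closed forms are exact at the nodes |

## Derived design quantities

* `allowable_load`: by linearity, the largest safe load at a pole is
  `min([σ]_impl/s_impl(1 N), [σ]_bone/s_bone(1 N))` — exact, no search.
* `max_loadable_tooth`: the largest tooth index `t` such that *all*
  teeth `1..t` pass both criteria; a denture "loaded no further than
  tooth t" must be safe everywhere mesial of `t` too. (Per-tooth
  verdicts are still available from `sweep`/`check` output.)
* Governing implant: lowest index on exact ties (relevant only for the
  perfectly central load, where all four implants tie).

## Spring oracle

`discretized_frame_solve` replaces each implant by `N` segments
(default 1000) with independent spring triplets `(C_n, C_n, C_τ)` per
unit length at the segment midpoints, assembles the 6×6 stiffness by
midpoint quadrature and samples the reactions discretely. Midpoint
quadrature is second-order: tenfold refinement shrinks the kinematics
error ~100×, and the central-load case (constant integrand) is exact at
any `N`. The oracle also accepts oblique load directions, used only to
stress-test global equilibrium. Agreement with the closed form is better
than 0.1% at `N = 1000` (typically ~1e−6) on the bundled layouts and on
randomized symmetric trapezoids.

## Synthetic layouts

`trapezoid_layout` and `random_symmetric_trapezoid` generate sagittally
symmetric equilateral-trapezoid placements with half-spans of 4–25 mm,
row offsets up to ~20 mm, `H` in 8–14 mm and `d` in 3.5–5 mm — the range
of mandibular full-arch practice. They emulate layout geometry only:
passing property tests demonstrates the statics, not the biology — real
bone is inhomogeneous in depth, implants may tilt, and occlusal loads
have lateral components, none of which the generator (or the model)
represents.

## Numerical choices

* Symmetry tolerance 1e−9 mm (mirror match after centring); layouts
  failing it are routed to the general solver.
* Peak location on the grid prefers the highest axial station on ties:
  the bone equivalent stress is even in `ζ`, so its grid maximum ties at
  both implant ends and the analytical argmax (the neck) is reported.
* Equilibrium residuals are scaled by `P` (forces) and `P·L` (moments,
  `L` = max of implant length and layout extent); closed-form profiles
  integrate exactly, discrete profiles sum with their own quadrature
  weights, so both sit at machine precision (< 1e−9 with margin).
* Coincident implants (< 1e−9 mm apart), non-positive sizes, out-of-range
  `ν_b` and non-positive loads or allowables are rejected at
  construction with specific error types.

## Limitations

Vertical loads only in the analysis pipeline (the closed form has no
lateral-load terms; the oracle's oblique mode is a robustness device,
not a clinical path). Parallel implants of equal size; homogeneous bed
in depth; no thread-level stress concentration (peak implant stresses
are therefore smoother than finite-element values at the thread roots);
no separation or resorption, hence no load-history effects; fatigue life
is out of scope — the strength verdicts are static comparisons against
allowable stresses.
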