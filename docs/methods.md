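# Methods

## Geometric model

The graft is a straight 6 mm-internal-diameter tube joining the host artery at
a 60° planar end-to-side anastomosis. The junction itself is represented only
by its centreline layout — the toe/heel stations and the monitoring planes at
1, 5 and 50 mm distal of the toe — not as a filleted solid; the ridged lumen
is constructed for the straight graft segment, which is what external meshing
tools consume.

A ridge cross-section is a circle or ellipse whose centre lies **exactly on
the lumen circle** (centre-to-centre distance = lumen radius R). This
convention makes the single circular reference ridge (r = 1.5 mm, R = 3 mm)
carry a lens area of 3.157 mm² in closed form, which is the constant the whole
design family preserves. Its consequences:

- **Circle–circle lens.** Closed-form two-circle intersection with d = R;
  exact at the r = 0 and r = 2R limits.
- **Ellipse–disc intersection.** No convenient closed form exists for a
  wide, flat ellipse against a circle, so the area is computed by polygon
  clipping (shapely): both outlines discretized, starting at 4096 vertices and
  doubling until the clipped area changes by < 10⁻⁶ mm². Clipping was chosen
  over quadrature for robustness when the ellipse is much flatter than the
  local lumen curvature (L₂/L₁ ≈ 2 occurs in the design family).
- **Inverse solvers.** The per-ridge radius is found by bisection on the
  monotone closed-form lens area (|Δarea| < 10⁻⁹ mm²); the tangential
  semi-axis L₂ at fixed L₁ by Brent's method on the clipped area, bracketed in
  (0, 2R] where the area is monotone in L₂.

A known source-table inconsistency: the tabulated ratios L₁/D = 0.174 and
0.141 for the double/triple designs imply radii 1.044/0.846 mm while the
solver (and the accompanying text) gives 1.042/0.844 mm. The solver value is
authoritative here; tests accept ±0.003 mm.

The helical ridge path has angular rate 360°/H per unit axial length, with the
**trailing edge pinned**: the distal end of the ridge sits at the configured
orientation regardless of ridge length, and the proximal end moves when the
length changes. Angles are measured from the toe line (0°), heel at 180°,
positive anticlockwise viewed looking downstream; the source study states the
orientations but not the sense, so the sense is a configurable convention with
this default, and handedness (default clockwise, matching the observed distal
swirl direction) is independent of it. The ridge ends abruptly at the trailing
edge with no taper and spans one full pitch by default; both are configurable
since the proximal extent is not specified by the study.

Surface export sweeps the star-shaped boundary r(θ, z) — lumen radius except
where a ray first enters a ridge ellipse, found by exact ray–ellipse
intersection — and triangulates consecutive rings, capping the ends with
triangle fans. The result is watertight with Euler characteristic 2 (verified
via trimesh, which also writes STL). Units are mm throughout the geometry
layer and SI elsewhere; conversion happens only at module boundaries.

## Rheology

Carreau–Yasuda with the standard whole-blood constants (μ₀ = 22 mPa·s,
μ∞ = 2.2 mPa·s, λ = 0.11 s, a = 0.644, n = 0.392); γ̇ = 0 is evaluated exactly
(the law is finite there, no epsilon floor). The scalar shear rate is
√(2 tr D̿²), frame-invariant and zero for rigid rotation. The Reynolds number
uses an explicit constant `nominal_viscosity` (default 3.5 mPa·s), because the
characterization value Re ≈ 570 for the 0.317 m/s, 6 mm inlet is only
reproduced by a constant reference viscosity near 3.5 mPa·s — a
Carreau–Yasuda characteristic viscosity at γ̇ = 8V/D would give Re ≈ 500. The
choice is therefore surfaced as a documented parameter instead of being buried
in the formula.

## Synthetic fields and what they do (and do not) show

The study conditions the generators emulate: period T = 0.9 s sampled at
Δt = 0.01 s (91 samples including both endpoints), monitoring-plane radius
3 mm, plane grids n_r = 64 × n_θ = 128, surface grids n_z = 200 × n_θ = 128.
The pipeline drivers use reduced surface grids (40 × 32) purely as the
package's own default problem size; every result shown is grid-converged at
that size for the constant and square-wave fields involved, which are exact on
any grid.

- **Polar cell-centred plane grids** with exact annular-sector areas: cell
  areas tile the disc to machine precision, so area-weighted means and area
  fractions carry no masking error. Patch-type generators snap the patch to
  whole cells and record the achieved fraction; recovery is exact by
  construction, to one cell against the requested fraction.
- **Square-wave WSS histories** place the sign switches half a sample off the
  switch nodes. Under the trapezoid rule this makes *both* time integrals
  (vector and magnitude) exact, so OSI = ½(1 − |1 − 2p|) and
  RRT = 1/((1 − 2p)A) hold to machine precision rather than to discretization
  error. This requires p·(n_t − 1) to be an integer, validated at
  construction.
- **The inlet waveform** is parameterized, not digitized: a baseline plus two
  periodic von Mises-shaped pulses (widths κ_peak = 40, κ_reversal = 150),
  with the five constraints — value and zero slope at the peak (0.25 s) and at
  the reversal (0.41 s), and the cycle mean — solved exactly (the pulse means
  use e^(−κ)I₀(κ)). Amplitudes are free parameters since only the phase times
  are tabulated; defaults are mean 0.317 m/s (the steady inlet velocity of the
  study), peak 0.8 m/s and reversal −0.2 m/s, typical triphasic femoral
  values. The constructor verifies on a dense grid that the imposed extrema
  are global and rejects infeasible combinations.

What passing these tests shows: the postprocessor computes every index
correctly on fields whose answers are known. What it does not show: anything
about real anastomotic flow — the synthetic planes have idealized symmetry, no
skewed jet, no vortex breakdown, and the WSS patterns have no spatial
structure beyond what each test imposes. The CFD result columns of the design
table (pressure drop, plane-3 V_yz, WSS means, recirculation percentages) are
therefore shipped as *recorded* data with explicit provenance, and the
pipeline's "recomputation" of them runs on synthetic fields calibrated to
those recorded values — it validates the measurement chain, not the flow
physics.

## Index computation

Time integration is composite trapezoid on the uniform sampling (the source
study does not state its quadrature). RRT is computed as T/|∫τ⃗dt| — the
algebraically identical form 1/((1−2·OSI)·TAWSS) is asserted in tests to
relative 10⁻¹⁰ — and a vector integral that cancels below 10⁻¹² of the
magnitude integral is flagged divergent (+inf) rather than returned as a huge
finite number; OSI at identically zero nodes is NaN. Both are flags, not
errors, so whole-surface maps always render.

TAWSSG keeps exactly the three diagonal Cartesian derivative terms
∂τx/∂x, ∂τy/∂y, ∂τz/∂z (the form used in the spiral-graft literature), built
from surface-tangential central differences on the cylinder grid — periodic in
θ, one-sided at the axial ends — projected onto the Cartesian axes. The more
common full-gradient-tensor Frobenius norm is available behind
`full_tensor=True`, off by default. τ₀ = 0.82 Pa is taken as a given constant;
the flow conditions behind it are not derivable from the published values.
"Recirculation" is operationalized as the negative-axial-velocity area
fraction on a monitoring plane, not a 3D bubble detection.

The unfold map cuts the cylinder along a configurable angle (default 0° =
ventral/toe line) so the arterial bed maps to the vertical centre π·R; it is
an exact bijection and is round-tripped in tests.

## Design table and reporting

The 13-configuration table ships as a packaged CSV; geometric entries are
re-derived by the solvers at build time, result columns carry provenance
`recorded` and can only be replaced by recomputed values explicitly.
Normalization divides each metric by the reference configuration (single
circular ridge, 180°, H_ref); percent changes and recirculation differences
are plain arithmetic on the recorded values, displayed at mixed precision
(3-decimal percentages where the source prints them, whole percentages
elsewhere) while full precision is retained in the CSVs. One master seed is
forked per configuration via `numpy.random.SeedSequence`; reruns with the same
config are byte-identical.

## Known limitations

- No flow solving: Navier–Stokes, pressure drop and mesh generation are out of
  scope by design; the pressure-drop column is reference data only.
- The anastomosis junction solid (suture line, fillets) is not constructed;
  out-of-plane helical centrelines are not supported.
- Unstructured CFD meshes must be resampled to the structured polar/cylinder
  grids before import.
- The ellipse–disc solver assumes the ridge is wall-centred; free-floating
  ridge positions would need a different constraint.
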