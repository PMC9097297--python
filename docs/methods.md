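# Methods

This note records the model, the numerical protocol, and the design
choices behind `tunspec`, in enough detail to reproduce or modify any
stage.

## Coordinates and units

All dynamics happens in mass-scaled Cartesian coordinates
`x̃ = √m · x`, in which the kinetic metric is the identity and ħ = 1.
The 2D benchmark surface uses dimensionless model units (mass m = 3.5 in
both directions); molecular adapters are expected in hartree/bohr with
per-coordinate electron-mass scaling, converting to cm⁻¹ only at
reporting.  Energies of the benchmark are referenced to the left minimum,
V(x_L) = 0.

## The benchmark surface

Each well is an exact quadratic form `V_L/R = ½ (x-x_{L/R})ᵀ H_{L/R}
(x-x_{L/R})` with minima at (∓β, 0), β = 2.0, and Hessians whose
eigenvalues are (α₁, α₂) with eigenvectors inclined by ±θ to the x axis
(θ = π/12; the sign flip makes equal-parameter surfaces mirror
symmetric).  The full surface blends the wells as

    V₀(x) = V_L V_R / (V_L + V_R),
    V(x)  = V₀(x) + d · V_L² / (V_L² + V_R²),

defaults α₁ = 1.6, α₂ = 4.0, d = 0.  Both the harmonic-mean blend and the
quartically flat switch leave the minima, the minimum energies (0 and d)
and the Hessians at the minima *exactly* at their prescribed values: the
leading corrections near either minimum are quartic in the displacement.
A startup self-check asserts these harmonic limits at construction.
Gradients are analytic; Hessians are symmetrized central differences of
the analytic gradient (step 1e-6 in mass-scaled units, accurate to
~1e-9), which is ample for the width propagation.

The barrier top of the default surface sits at V ≈ 1.68 on the optimized
tunneling path, giving well-separated scales: harmonic level spacings
~0.7–1.1, ground-state splitting ~8e-4.

## Minimum action path

The tunneling path minimizes the Jacobi action `W₀ = ∫ √(2(V - V_min)) dS`
between the minima.  The string discretization uses 301 beads (201
recommended for molecules), a trapezoid-in-momentum discrete action, and
a semi-implicit update: beads move along the perpendicular component of
the discrete action gradient, with the stiff elastic part of the gradient
treated implicitly by a tridiagonal solve (pseudo-time step 2.0,
backtracked on action increase), followed by equal-arc-length
reparameterization through a spline each iteration.  Convergence is
declared when the largest perpendicular component of the discrete action
gradient falls below 1e-6; the default surface converges in a few hundred
iterations.  The step rule and schedule are this package's own choices —
only the convergence metric is inherited from the protocol.

For wells offset by d the path is optimized on the modified surface
`Ṽ = V - Θ(S - S_cp) d` with the connection point fixed a priori at the
middle bead; both endpoints then sit at Ṽ = 0, and the converged path has
a tangent kink at S_cp whose dividing-plane normal is taken as the
renormalized mean of the one-sided tangents.

Geometry, potential, and every Hessian element are evaluated at the beads
and interpolated versus arc length with natural cubic splines.  Natural
end conditions leave an O(h²) edge error within a few bead spacings of
the endpoints; all barrier-region quantities are far from the edges.

## Instanton fields

Per side, with p₀(S) = √(2(V - floor)) (floor = 0 or d):

* Width matrices from the Riccati equation `p₀ dA/dS = H(S) - A²`, RK4
  with ten substeps per bead interval, started at S = ε with A(ε) = A₀ =
  H₀^{1/2} (the ε "jump": 0.1 for the model surface, 0.25 suggested for
  molecules; below ε the wavefunction is the exact harmonic form, which
  is what the matching condition implies).  A is symmetrized and saved at
  every bead, then splined; the spline feeds everything downstream.  The
  tangential eigenvalue of A (≈ dp₀/dS) legitimately changes sign past
  the barrier top; only transverse width eigenvalues are monitored for
  caustic blow-up, and the propagation range stops short of the other
  side's classical turning point where such a caustic is unavoidable.
* Amplitude transport `p₀ dW₁/dS = ½ Tr(A - A₀)`.
* Excited states (ν quanta in mode e): prefactor `(F + Uᵀ Δx)^ν` with
  `p₀ dU/dS = (ω_e - A) U`, U(0) the excited normal mode, and
  `F(S) = F(ε) exp(ω_e τ(S))`, `F(ε) = U₀ᵀ(x(ε) - x_min)`, τ the
  imaginary time ∫ dS/p₀ from ε.  On a separable surface a transverse
  mode keeps F ≡ 0 exactly; on a 1D harmonic cut F(S) = S reproduces the
  exact first excited state.

## Herring couplings

The coupling of two localized states is
`h = -(p₀^L + p₀^R)/2 · ∫_plane φ^L φ^R dΣ` over the dividing plane at
the connection point (the normal-derivative difference of the Herring
flux reduces to this at leading semiclassical order).  With at most one
quantum per side the plane integral is a Gaussian with linear prefactors
and is evaluated in closed form: `A̅ = A^L + A^R` restricted to the
plane (tangent projected out; for equal-energy wells the tangent is an
eigenvector of A̅ with zero eigenvalue), det′ the product of its nonzero
eigenvalues (zero threshold 1e-8 relative, with the zero count checked
against the expected nullspace and any mismatch aborting), and the
tangent-kink term `b = p₀^L τ̂_L - p₀^R τ̂_R` completing the square.  For
multiple excitations the same integrand is integrated by tensor-product
Gauss–Hermite quadrature in the eigenbasis of A̅ (20 points per
transverse dimension by default; practical up to ~6 transverse
dimensions).  The two routes agree to machine precision where both apply.
Local wavefunctions are taken positive at their minima, which fixes the
sign of h; spectra are invariant under this choice.

The element is exactly invariant under moving the connection point only
for degenerate local states; `tm_sensitivity` scans S_cp over the central
third of the path and reports half the peak-to-peak variation as the
error estimate.  Even at resonance a small residual drift (~1e-3 relative
for the benchmark surface) remains: the invariance identity holds exactly
only for straight paths, and path curvature couples the tangential and
transverse blocks at the next semiclassical order.  On the θ = 0
separable surface the resonant drift is < 1e-8.

## Effective barrier

`V_eff = V_max + Σ_t (ν_t + ½) λ_t - E_state`, with λ_t the nonzero
eigenvalues of the tangent-projected width matrix at the potential
maximum of the path and E_state the state's local harmonic energy.  The
longitudinal mode (identified as the mode of maximal overlap with the
path tangent at the minimum) contributes to E_state but not to the
barrier-top zero point, so one longitudinal quantum lowers V_eff by
exactly ω₁.  V_eff diagnoses instanton reliability: the benchmark's
ground/transverse barriers (1.221/0.976) give couplings accurate to a few
percent, while the longitudinal barrier (0.545) brings the known
overestimation of shallow tunneling (~10% here).

## Local states (VSCF/VCISD)

The well potential is expanded to 1-mode + 2-mode terms around the
minimum in normal coordinates.  Cuts are sampled at the 8 Gauss–Hermite
DVR points of each mode (zeros of H₈ scaled by 1/√ω) and fitted to
polynomials of orders 1..8 through the origin — with eight points the fit
interpolates exactly; pair residuals are fitted to the 64 tensor
monomials q₁^a q₂^b (a, b ≥ 1) on the rectangular grid, likewise exactly
determined.  In 2D this representation is complete on the grid.

The VSCF basis frequency per mode is E₁ - E₀ of the fitted cut solved in
a 100-function sine DVR on a box 1.6× the outermost DVR point; if the
order-8 tail turns the box edges down (narrow wells at large detunings do
this), the box is shrunk with a warning until the cut is confining.  VSCF
uses 7 such harmonic-oscillator functions per mode (16 recommended for
molecules), converging mean-field energies to 1e-9 with one damped retry
on oscillation.  VCISD spans products of VSCF modals with at most two
modes excited and at most 6 quanta per mode (in 2D this is the full 49-
configuration space).  States are labeled by the dominant CI coefficient;
a top-two weight ratio above 0.9 sets an ambiguity flag.  Enlarging the
basis beyond the plateau is deliberately avoided: high modals probe the
unphysical tails of the fitted polynomial and produce intruder states.

## Tunneling matrix

Intra-well off-diagonal elements are zero by construction (the VCI basis
makes them small; they are neglected, not computed).  The off-diagonal
block holds h_ij between L state i and R state j; `[[E_L, h], [h^T, E_R]]`
is symmetric as a matrix without any further manipulation, and h_ij vs
h_ji (couplings of *different* state pairs) are kept distinct — averaging
them is optional and meaningful only for symmetric wells with a
one-to-one mode correspondence, where their difference (recorded as a
diagnostic) reflects the finite accuracy of the Herring evaluation.  An
optional zero pattern forces symmetry-forbidden couplings to exact zero
when a preserved mirror symmetry is declared.

Doublets are identified by the dominant mode label of each eigenvector
(weights summed over both wells, ties broken by energy adjacency).  The
pair splitting is `√(ΔE² + 4h²)`, reported next to its weak-coupling
expansion `|ΔE| + 2h²/|ΔE|` (residual O(h⁴/ΔE³)).  The mixing angle of a
pair is `φ = arctan(2|h|/|ΔE|)` — 90° means complete delocalization,
small φ localization; the generalized (many-state) form reads the
rotation off both doublet eigenvectors restricted to the doublet's own
L/R components and reduces to the pair formula exactly for 2×2.  Applied
to the published partially deuterated malonaldehyde tables, the pair form
gives 35.3° and the 16×16 form 36.8°.

Avoided crossings along a parameter sweep are located by a coarse grid
scan bracketing the minimal gap followed by bounded golden-section/Brent
refinement inside the bracketing cell (default parameter tolerance 1e-4);
an unbracketed minimum is returned flagged.

## Exact reference

The 2D reference solver is a Colbert–Miller sinc DVR on a uniform grid,
applied as a matrix-free Lanczos eigensolve (generous Krylov space,
ncv = 96).  The box is the bounding box of the classically allowed region
at 1.5× the barrier estimate, padded by 20% of the width but at least 1.0
length unit per side — box truncation is invisible to grid refinement and
must be padded generously; the pad was sized so that further enlargement
moves the benchmark levels by < 1e-8.  Correctness is certified by the
gate that the requested levels move by < 1e-6 under grid doubling (one
automatic enlargement retry, then abort), not by the choice of DVR.
Sweep evaluations run at 128² points, where doubling moves levels by
~1e-6 — three orders below the gaps being tracked; the located crossing
is re-solved at 160² with the gate active.

## Benchmark study sizes

The shipped drivers use the full protocol sizes everywhere: 301 beads,
residual 1e-6, ε = 0.1, 8 DVR points, order-8 fits, basis 7, excitation
cap 6, three states per well in the tunneling matrix (the states visible
in the study's six-level window), DVR boxes as above.  The avoided-
crossing searches use 5–7 grid points per bracket plus ~25 refinement
evaluations per curve; the full acceptance run is a few minutes on one
CPU.

## What the benchmark does and does not show

The 2D surface exercises every ingredient — curved paths, unequal well
shapes and depths, transverse/longitudinal excitation, resonance and
off-resonance — but it has no translations or rotations to project, no
caustics before the turning-point cutoff, and its 2-mode representation
is exact.  Molecular applications additionally stress the trans/rot
projection (implemented and tested on toy geometries), bead alignment,
and the n-mode truncation error, none of which the benchmark can
validate; the malonaldehyde reference checks only re-derive published
matrix results from published inputs.  Rotational coupling and
finite-temperature rates are out of scope; one path per well pair is
assumed (no multi-channel enumeration).

## Known limitations

* The connection-point invariance at resonance is limited by path
  curvature (~1e-3 relative drift on the benchmark); treat the
  sensitivity spread as the coupling's error bar.
* Longitudinally excited couplings inherit the instanton's systematic
  overestimation when the effective barrier is shallow.
* The closed-form coupling handles at most one quantum per side; the
  quadrature route extends to multiple excitations but scales
  exponentially with transverse dimensionality (practical ≤ 6).
* VCISD labels — and therefore the pairing of states across wells —
  require cleanly assignable normal-mode excitations; the ambiguity flag
  marks where that assumption frays.
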