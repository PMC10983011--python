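# Methods

This note documents the models, closed forms and numerical choices behind
`orbopt`, in the order the library composes them.

## Orbital-rotation parameterization and the energy oracle

The determinant is varied through `C′ = C·exp(−K)` with `K` antisymmetric
and nonzero only in the occupied–virtual blocks; the free parameters κ (one
occ×vir block per spin channel, row-major, occupied index outer) are the
entire optimization space, `N_scf = Σ_spins n_occ·n_vir`.  Occupied–occupied
and virtual–virtual rotations leave the energy invariant and are excluded.

The HF oracle defines `E(κ)` **globally** against the fixed post-startup
reference orbitals, and its gradient is the *exact* derivative of that
function: the derivative of the matrix exponential is contracted with the
energy's orbital derivative through the adjoint of the Fréchet derivative
(`scipy.linalg.expm_frechet`, one extra call per evaluation).  Production
codes instead re-expand around the current orbitals each iteration, which
agrees to second order; the global formulation was chosen because it makes
every optimizer act on a single smooth function — the finite-difference
contract (`|g_i − ∂E/∂κ_i| ≤ 1e-8` at step 1e-5) holds at *every* κ, and
cross-method stationary points are exactly comparable.  At κ = 0 (and at
convergence) the gradient reduces to the Fock-matrix form: `g_(i,a) = 2 F_ai`
per singly-occupied spin channel and `4 F_ai` for the restricted
doubly-occupied case — the per-spin factor of 2 times the occupancy.  The
convergence measure max |F_ov| is always read directly from the rotated-basis
Fock matrix.

The diagonal Hessian model is `factor·(ε_a − ε_i)` with the same occupancy
factor as the gradient and a floor (default 0.025 E_h/rad², configurable) so
degenerate or inverted gaps never produce an indefinite seed.  The model
keeps only the one-electron part of the true diagonal; for H2/STO-3G at
convergence the neglected two-electron terms (`12(ia|ia) − 4(ii|aa)` in the
restricted case) amount to ≈ 11% of the finite-difference value, which is
the accuracy one should expect of it generally.

## Fixtures and the integral engine

Six molecular fixtures cover closed and open shells and strained bonds: H2
(0.7414 Å) and the same molecule stretched 2.5×, HeH⁺, H2O, linear
symmetric H3 (doublet) and O2 (triplet), all in STO-3G.  Integral tables
(overlap, core Hamiltonian, chemists'-notation two-electron tensor, nuclear
repulsion) are produced at first access by the in-repo McMurchie–Davidson
engine — Hermite expansion coefficients by recursion, Boys function via
`hyp1f1` — and validated against literature total energies (He
−2.8077840 E_h, H2 −1.1166844 E_h at 1.400 bohr, H2O −74.965901 E_h at its
optimized geometry) during development.  A tightly converged Roothaan
fixed-point solver with Fock-matrix DIIS (`roothaan_reference`) is the
independent brute-force oracle for converged energies; it shares no code
path with the rotation-based optimizers.  Fixtures round-trip through an
HDF5 container whose loader re-validates the integrity invariants (SPD
overlap, 8-fold permutational symmetry to 1e-10, electron-count parity), so
a corrupted file fails naming the violated invariant.

What the suite does *not* emulate: production basis sets, density
functionals, relativistic Hamiltonians, integral screening, and — most
importantly — the near-degenerate open-shell electronic structures of
transition-metal complexes.  The desk-scale systems here converge in a
handful of iterations for every method; passing tests demonstrate
correctness of the machinery and the qualitative value of the resetting
rules (on the synthetic shoulder surface), not production-scale robustness
statistics.

## Implicit BFGS Hessian

A positive diagonal seed plus (Δκ, Δg) update pairs, applied matrix-free:
forward products apply the rank-2 updates in chronological order (O(depth²)
vector work), inverse products use the two-loop recursion, which is the
exact algebraic inverse of the same update sequence.  Pairs violating the
curvature condition `Δκ·Δg > 1e-12·|Δκ||Δg|` are stored but never applied,
keeping the operator SPD.  The ring buffer holds 20 pairs; the *depth*
(number of most-recent active pairs) can be reduced — the resetting rules
use this — and is restored implicitly when a new pair is pushed.  After a
DIIS depth reset the BFGS pairs are kept (depth reduction only), not
discarded; this is configurable at the call sites.

## GDIIS, the C²-DIIS solver and the resetting rules

Error vectors are quasi-Newton steps `e_i = −H⁻¹ g_i`; the extrapolation
minimizes `‖Σ c_i e_i‖²` under `Σ c_i = 1` over the last m ≤ 5 iterates,
then takes one full-space quasi-Newton step from the extrapolated point:
`κ_{n+1} = Σ c_i κ_i − H⁻¹ Σ c_i g_i` (with m = 1 this is a pure variable
metric step).  The vanilla baseline solves the bordered linear system
directly.

The stabilized solver works in the eigenbasis of `B_{ij} = e_i·e_j`.  The
constrained minimizer expands as `c ∝ Σ_j (u_j/λ_j) q_j` (`u_j = q_j·1`);
the `1/λ` weights are exactly where numerical noise enters.  Candidates are
therefore the renormalized partial sums of this expansion, truncated at each
eigenvalue with dominant terms kept first — the full sum *is* the exact
Lagrangian solution, the truncations are its noise-filtered variants.
Candidates with vanishing renormalization are skipped; candidates with
`c·c > 100` **and** `c·B·c < 1e-5` (large oscillating coefficients with a
spuriously small predicted error — the signature of corruption) are
rejected; the surviving candidate with the smallest predicted error wins.
If everything is rejected the caller resets the history depth to 1.

Three resetting rules, evaluated in order before each extrapolation:

1. **Disparity.** While `min_i B_ii / max_i B_ii < 1e-8` and m > 1, drop the
   oldest point.  The exact functional form of the published condition was
   not recoverable; the ratio test implements its stated motivation (error
   norms differing by orders of magnitude destroy the extrapolation's
   predictive power) and is isolated behind one predicate.
2. **Shoulder.** If the history point with the smallest `B_ii` lies more
   than 1e-4 E_h *above* the current energy, or consecutive `B_ii` are far
   from descending order (`B_ii·15 < B_{i+1,i+1}`), reset m = 1 and discard
   the old points permanently; the next step is a pure variable-metric step.
   Both sub-conditions share the reset action.
3. **Rotation bound.** A proposed step with ‖Δκ‖ > π (a rotation beyond
   180°) indicates a corrupted Hessian update: the BFGS depth is reduced one
   pair at a time, recomputing the step, until the norm is acceptable; if
   the seed-only step still exceeds π it is scaled back to π.

## RS-RFO

The step comes from the lowest eigenpair of the α-scaled augmented system

    M(α) = [[H/α, g/√α], [gᵀ/√α, 0]],   δκ = v_κ/(√α·v_0),

whose step norm ‖δκ(α)‖ is monotone decreasing in α; α = 1 is the plain
rational-function step, and the restriction is enforced by bracketing +
bisection on α until the norm lies in [0.9, 1.0]·limit (each trial is one
α-microiteration; the loose band avoids churn).  The α placement — scaling
the parameter block of the metric — was chosen precisely because it makes
this map monotone, which is the testable contract.  The eigenpair is found
by a Davidson solver on matrix-vector products only (the Hessian is never
formed), preconditioned by the diagonal of the augmented system built from
the Hessian seed, with subspace restarts at 30 vectors and a residual
tolerance of 1e-8 by default; when the subspace reaches the full dimension
the Ritz pair is exact and returned.  The per-iteration protocol: push the
BFGS pair, take a restricted step with limit 10.0; if the restricted step
still exceeds π, set the BFGS depth to 1 and re-step with limit π.

## Gradient-enhanced Kriging

The surrogate interpolates energies and full gradients exactly.  Distances
use per-dimension characteristic lengths, `r² = Σ_k (Δκ_k/l_k)²`, and the
correlation is Matérn 5/2, `φ(r) = (1 + √5 r + (5/3)r²)e^{−√5 r}`, scaled by
a signal variance σ².  Its Taylor expansion at r = 0 has no cubic term
(`φ = 1 − (5/6)r² + (25/24)r⁴ + O(r⁵)`), so the kernel is C⁴ there and all
coordinate derivatives used — up to third, for the predictor's analytic
Hessian — are well behaved; the closed forms reduce to products of
exponentials and the separation vector and are verified against central
differences to 1e-6 or better.

The generalized covariance system orders the value vector energies-first
(`E_1..E_n`, then the gradient block of each point), uses a constant trend
`μ = max_i E_i + 10.0 E_h` recomputed at each rebuild, and is solved by
Cholesky factorization with a diagonal nugget of 1e-10 relative to the mean
diagonal, escalated tenfold (up to 1e-6) on factorization failure.  The
nugget bounds the interpolation residual at roughly `(μ−E)·nugget/σ²`
(~1e-9 in practice) and leaves the same-order residual variance at the data
points themselves.

Characteristic lengths are not fitted.  A single-point surrogate with zero
gradient data has predictor `Ê(κ) = μ + (E_1−μ)φ(r)`, whose Hessian at the
data point is `(μ−E_1)·(5/3)/l_k²` per dimension.  Requiring this to equal a
prescribed eigenvalue h_k of the approximate Hessian gives the closed form

    l_k = sqrt((5/3)·(μ − E_max)/h_k),   μ − E_max = 10.0 E_h,

so stiff directions get short lengths and the surrogate *reproduces the
approximate Hessian exactly when built from one point* — the defining
property, tested by central differences (step scaled to l_k to avoid
cancellation).  The property is independent of σ²; σ = 10 E_h is fixed so
the prior standard deviation matches the trend offset.  The predicted
variance is the simple-Kriging form `σ² − vᵀM⁻¹v`, clipped at zero; far from
all data the prediction reverts to μ and the variance to its σ² plateau.

## S-GEK/RVO

Per macro-iteration: run the RS-RFO step logic to get the prediction vector,
build the subspace from 2m candidates — the displacements and gradient
differences of the last m−1 iterations, the latest gradient, and the RS-RFO
prediction — by modified Gram–Schmidt (two passes, relative drop tolerance
1e-10), project the gradient and the implicit Hessian (`H_r = Vᵀ(HV)`, one
hessvec per basis vector), and diagonalize H_r to define the regression
frame; characteristic lengths come from its eigenvalues (floored like the
seed) and are rebuilt every iteration.  The GEK data are the last ≤ m
history points re-projected into the fresh frame (history is stored
full-space; projected points that collide within 1e-8 scaled distance are
dropped oldest-first).  Model depth equals m = 5 so the linear system never
exceeds m(1+2m) = 55 — the dimensionality-reduction contract, asserted by
the tests on every iteration.

The RVO step is one rational-function step computed from the surrogate's
analytic gradient and Hessian at the current point — which the interpolation
and the single-point Hessian property make locally exact — with the
restriction enforced by the same α-microiteration machinery as RS-RFO,
except the restricted quantity is the surrogate's predicted standard
deviation at the step endpoint (alongside the step-length limit inherited
from the RS-RFO reset logic).  The restricted measure is the *additional*
uncertainty `sqrt(max(s²(z₀+δ) − s²(z₀), 0))`: the nugget's residual
variance at the expansion point is numerical noise, not model uncertainty,
and subtracting it keeps the restriction meaningful near convergence.  A
full inner minimization of the surrogate was deliberately not used: with a
locally exact single-step model the S-GEK step coincides with the RS-RFO
step whenever the surrogate adds no information (verified to 1e-8 on a
quadratic), which is the "never worse than RS-RFO" guarantee the subspace
construction is designed around — the RS-RFO prediction is always in the
span.

The variance limit is adaptive: initialized to 0.3·|last energy change|
(floored at 1e-6 E_h; before any step, the Newton-decrement estimate
`|g|²/median(seed)` stands in for the last change), halved when a step
raises the energy, doubled (capped at 10× the initial value) when it lowers
it.  The policy lives in one object so alternatives can be swapped.  A
degenerate GEK system (coincident projected points, factorization failure)
falls back to a restricted step on the projected quadratic model, flagged in
the trace.

## Driver, startup and statistics

Convergence requires all three criteria simultaneously — |ΔE| < 1e-9 E_h
between consecutive iterations (the "consecutive" reading of the energy
test), max |F_ov| < 1.5e-4, ‖Δκ‖ < 1e-3 — under a hard cap of 400 total
iterations; hitting the cap returns a trace with `converged = False`, never
an exception.  An input already satisfying the Fock criterion converges with
zero iterations.  Note that a genuinely minimizing step cannot satisfy
|ΔE| < 1e-9 on the same iteration it descends, so even a one-step method
records a confirming (null) second iteration before the flag is set.

Startup for fixtures is deliberately minimal and deterministic: a
core-Hamiltonian (or caller-provided) orbital guess followed by
`n_startup_iterations` = 2 plain Roothaan steps.  This is *not* equivalent
to production startup protocols (EDIIS-based preliminary iterations);
comparisons between methods inside this package remain internally consistent
because all methods share the identical startup state.  Iteration counts are
reported both total and post-startup, with the cap applied to the total.

Benchmark statistics follow the conventions box plots depend on: mean and
sample SD (ddof = 1) over converged runs only, counts of runs above 120
iterations and not converged by 400, quartiles by linear interpolation (the
"type 7" convention — pinned because the quartile oracle in the tests
depends on it), whiskers ending on the outermost data points within 1.5·IQR
of the box, and pairwise converged-energy differences (sign convention:
reference minus other, reference configurable) flagged above 5e-7 E_h.

## Synthetic surfaces

`quadratic` (prescribed SPD spectrum) and `anharmonic_well` (quartic
perturbation) are the closed-form test beds.  The `shoulder` surface is
built to reproduce the inflection-point stall: along one coordinate a long
near-flat plateau (constant slope 0.01), a steep sigmoid drop (amplitude 1,
width 0.2) at the edge x = 2, and a stiff cubic-hinge far wall (onset 2.8,
stiffness 50) confining a narrow basin; all other coordinates are unit
quadratics.  E″ changes sign exactly at the edge.  The curvature *model*
along the shoulder coordinate is deliberately stiff (1.0, against a true
plateau curvature near zero) — mirroring the SCF situation where the
gap-based diagonal guess cannot see a flat direction.  With these defaults
vanilla GDIIS creeps along the plateau, overshoots at the edge, and is
pulled back by the extrapolation indefinitely (energy after 100+ iterations
still far above the minimum), while the resetting variant detects the
shoulder (rule 2), caps the rotations (rule 3) and converges in ~45
iterations; RS-RFO and S-GEK/RVO converge in ~15.  This is the qualitative
analog of the published failure-rate contrast between the vanilla and
resetting variants.

## Problem sizes and determinism

The test suite and the acceptance script use desk-scale sizes throughout:
fixtures up to 10 AOs (O2, 30 rotation parameters), dense-oracle
equivalences at dimensions 25–50 with 50 random instances, GEK contracts at
n = 11 points in K = 21 dimensions, and 100–150-iteration caps for the
shoulder regression.  All randomness flows through explicitly seeded
generators; repeated runs are bit-identical, and `scripts/acceptance.py`
derives every random draw from its `--seed` argument.

## Known limitations

* The oracle's global-κ formulation costs one Fréchet-derivative call per
  evaluation and would not be the implementation of choice at production
  scale.
* The exact published forms of the disparity condition and of the C²-DIIS
  eigenproblem could not be recovered; both interpretations are documented
  above and isolated behind single functions.
* The non-identity metric S in the rational-function model is accepted but
  untested; the Gaussian kernel alternative and likelihood-based length
  fitting are out of scope.
* Open-shell systems with genuine near-degeneracy (the hard cases for these
  methods) are not represented in the fixture suite; the shoulder surface is
  the synthetic stand-in for that failure mode.
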