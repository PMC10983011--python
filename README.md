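# orbopt

Orbital optimization for SCF/KS-DFT wave functions, packaged as a small,
fully testable laboratory.  Three convergence-acceleration procedures of
increasing sophistication are implemented over a common pluggable
energy/gradient oracle:

* **r-GDIIS** — GDIIS (direct inversion in the iterative subspace over
  orbital-rotation parameters) with a stabilized eigenvalue-based coefficient
  solver and three *resetting rules* that guard the extrapolation against
  error-norm disparity, shoulder (inflection-point) stalls and corrupted
  quasi-Newton updates.  A vanilla GDIIS is kept as the baseline.
* **RS-RFO** — restricted-step rational-function optimization: the step is
  the lowest eigenvector of the gradient-augmented Hessian, found by a
  matrix-free Davidson solver over an implicitly BFGS-updated Hessian, with
  the step length enforced through the scale parameter α.
* **S-GEK/RVO** — subspace gradient-enhanced Kriging: a Gaussian-process
  surrogate (Matérn 5/2, per-dimension characteristic lengths) that
  interpolates recent energies *and* gradients exactly, built in a ≤2*m*
  dimensional subspace spanned by recent displacements, gradient differences,
  the latest gradient and the RS-RFO prediction; the step is restricted by
  the surrogate's predicted *variance* instead of a fixed length.

## The model

The SCF determinant is parameterized by orbital rotations
`C′ = C·exp(−κ)`, where `κ` is the antisymmetric matrix whose only free
entries couple occupied and virtual orbitals — a parameter space of size
`N_scf = Σ_spins n_occ·n_vir`.  The gradient is `2 F_ai` per spin channel
(`4 F_ai` for doubly-occupied restricted orbitals), with `F` the Fock matrix
in the rotated MO basis; the diagonal Hessian model is the scaled orbital
energy gap `ε_a − ε_i`, floored to stay positive definite.  Convergence uses
the standard composite criterion: consecutive energy change < 1e-9 E_h,
max |F_ov| < 1.5e-4, ‖Δκ‖ < 1e-3.

Oracles provided:

* a minimal restricted/unrestricted Hartree–Fock engine over six bundled
  STO-3G fixtures (H2, H2 stretched 2.5×, HeH+, H2O, linear H3 doublet,
  triplet O2) whose integral tables are generated by an in-repo
  McMurchie–Davidson Gaussian integral engine;
* synthetic model surfaces (`quadratic`, `anharmonic_well`, `shoulder`) —
  the shoulder surface reproduces the plateau/edge failure mode that
  motivates the resetting rules.

## Worked example

```bash
$ orbopt run --fixture H2O --method s-gek-rvo
startup  E = -73.232724109996
startup  E = -74.945787980822
iter   1  E = -74.962621641590  |g| = 5.446e-02  |F_ov| = 1.008e-02  step = 6.676e-03  [-]
iter   2  E = -74.963018354084  |g| = 7.688e-03  |F_ov| = 1.235e-03  step = 1.523e-02  [-]
iter   3  E = -74.963023040615  |g| = 1.274e-03  |F_ov| = 1.900e-04  step = 1.519e-03  [-]
iter   4  E = -74.963023162862  |g| = 2.429e-05  |F_ov| = 5.993e-06  step = 2.389e-04  [-]
iter   5  E = -74.963023162867  |g| = 7.339e-07  |F_ov| = 1.631e-07  step = 6.280e-07  [-]
converged: E = -74.963023162867 E_h after 5 iterations (+2 startup)
```

The two startup lines are the deterministic core-guess Roothaan iterations;
each following line is one S-GEK/RVO macro-iteration: total energy (E_h),
gradient norm, largest occupied–virtual Fock element and step norm.  The
converged energy agrees with the brute-force Roothaan fixed-point reference
and with the other three methods to better than 1e-9 E_h.

The same front end runs the synthetic surfaces.  On the shoulder surface the
baseline stalls while the resetting variant converges — the qualitative
signature the resetting rules exist for:

```bash
$ orbopt run --surface shoulder --dimension 6 --method gdiis     # not converged after 400
$ orbopt run --surface shoulder --dimension 6 --method r-gdiis   # converged in 45 iterations
```

`orbopt benchmark --out report/` runs every method over the bundled suite and
writes the statistics table (mean/SD of post-startup iteration counts, >120
and not-converged-by-400 counts, quartiles with 1.5·IQR whiskers, pairwise
converged-energy differences flagged above 5e-7 E_h) as JSON and TSV.

Python API, equivalently:

```python
from orbopt import make_fixture, optimize, RunConfig

trace = optimize(make_fixture("H2O"), RunConfig(method="s-gek-rvo"))
print(trace.converged, trace.final_energy, trace.post_startup_count)
```

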