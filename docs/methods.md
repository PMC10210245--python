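# Methods

## The model

`tbfit` inverts time-resolved pump–probe scattering data by *forward
optimization in a trajectory basis*.  Instead of reconstructing structures
from the data directly — an ill-posed inverse problem — the photoexcited
molecular ensemble is modelled as a weighted superposition of semiclassical
trajectories (trajectory basis functions, TBFs) produced by nonadiabatic
dynamics simulations, and the weights are fitted so that the predicted
observable matches the measurement.  The trajectories act as physically
motivated constraints: any solution automatically satisfies continuity in
time and starts from a sensible Franck–Condon geometry.

With geometry-only observables and time-independent expansion coefficients,
the model ensemble is fully described by a weight vector **w** with
w_n ≥ 0 and Σ w_n = 1.  The observable is built in two stages:

1. **Forward mapping (scattering physics).**  Rotationally averaged
   independent-atom-model (IAM) intensities.  Elastic scattering of a
   randomly oriented molecule follows the Debye formula

       I_el(q) = Σ_A Σ_B f_A(q) f_B(q) sinc(q·R_AB),

   with the A = B self terms entering through sinc → 1, so that
   I_el(0) = (Σ_A Z_A)² for X-rays.  The inelastic term is the
   geometry-independent atomic sum Σ_A S_A(q).  Electron diffraction uses
   the converted factors (Z_A − f_A(s))/s²; the s → 0 singularity is
   excluded by a hard cutoff (10⁻³ Å⁻¹), not regularized, because
   experimental s-grids never reach zero and silent regularization would
   mask configuration errors.  Probe prefactors (Thomson/Rutherford cross
   sections, polarization, s⁻⁴) are multiplicative in q only and cancel
   exactly in the percent-difference observable; they are deliberately not
   applied.

2. **Apparatus mapping (measurement physics).**  The observable compared to
   experiment is the percent-difference signal

       %ΔI_mod(q, t) = 100 · γ_eff(q) · (I_mod(q, t) / I_off(q) − 1),

   where I_off is the unpumped reference intensity and γ_eff is either a
   uniform excitation fraction γ ∈ [0, 1] or a sampled q-dependent profile
   γ(q) scaled by a uniform factor x (long interaction regions make the
   effective excitation vary with q; only x is optimized).  The signal is
   then convolved in time with a unit-area Gaussian of FWHM τ_c (the
   instrument response), shifted onto the experimental delay axis via
   t′ = t + t₀, and box-averaged into the experimental time bins.

Because every stage is linear in **w** (Σ w_n = 1 makes the −1 offset
distribute over trajectories) and linear in the scalar excitation
parameter, the model is a matrix–vector product once the per-trajectory
processed signals are cached.  The optimizer exploits this heavily.

## The objective

    F(w, c) = Σ_ij p_ij [ %ΔI_mod(q_i, t_j; w, c) − %ΔI_exp(q_i, t_j) ]²,

with a confidence matrix p ∈ [0, 1] per data point and global parameters
c = (t₀, τ_c, γ or x).  When per-point standard deviations are available
the package builds p ∝ 1/σ rescaled to max 1 (invalid points → 0); any
externally supplied confidence matrix is accepted, so other weighting
schemes (e.g. photon-count-based) can be reproduced exactly.  A threshold
p_conf^min zeroes all entries below it, removing those points from the fit.

## Optimization

*One-step* (good data): for each c on a full factorial scan grid, the
weights are fitted by bound-constrained trust-region-reflective least
squares (`scipy.optimize.least_squares`, analytic Jacobian) from a pool of
N_init Monte-Carlo initial weight vectors (i.i.d. uniform components,
normalized).  Weights live on the box [0, 1]^N and are renormalized to the
simplex inside every model evaluation; this enforces Σ w = 1 exactly and
makes the objective invariant to the overall scale of w (tested).  The best
converged minimum over pool and scan is the global candidate.

*Two-step* (noisy data): step one integrates the signal over the
highest-confidence q band (default: the contiguous band where the
time-summed confidence-weighted |signal| exceeds half its maximum) and, for
each (t₀, τ_c), fits the scalar γ in closed form against the equal-weight
ensemble — near time zero the wavepacket has dispersed little, so equal
weights are a good approximation.  Step two compares the top-ranked
step-one parameter sets — several of them, since the integrated signal
constrains τ_c only weakly — by *held-out validation misfit*: for each
candidate (t₀, τ_c), weights and γ are fitted on the even q rows (a convex
problem, single start) and scored on the odd rows.  Raw in-sample F is
deliberately not used for this comparison: refitted weights partially
absorb a wrong t₀ or τ_c by fitting noise, so the refit at a wrong cell
can out-F the true cell, while held-out rows expose it.  The winning set
then gets the full Monte-Carlo-initialized weight optimization with γ
freed, and the solution is flagged when γ drifts more than 25% (default,
configurable) from its step-one value — a self-consistency check on the
step-one globals.

With γ free the objective is convex: substituting u = γ·w turns it into
nonnegative linear least squares.  The test suite uses `scipy.optimize.nnls`
on this substitution as an independent oracle for the trust-region path.

Ties among equal-F minima are broken by lower RAE, then lower weight
variance, then init order — a deterministic reporting convention.
Degenerate (duplicate) trajectories are permitted; the data cannot
distinguish them and the degeneracy is reported, not resolved.

### Fit-quality metrics

- **RAE** — Σ|%ΔI_mod − %ΔI_exp| / Σ|%ΔI_th − %ΔI_exp|, with %ΔI_th the
  equal-weight (unoptimized) model; < 1 means the optimization improved on
  plain theory; independent of grid size.
- **RMSE** over the N_q × N_t grid.
- **Var_w** — mean squared deviation of the weights from their mean.
- **D_b** — Euclidean distance of a solution's weights from the best
  solution's (plots conventionally show D_b²).

## Numerical choices

- **Form factors.**  Elastic X-ray factors use the Cromer–Mann four-Gaussian
  parameterization with published coefficients for H, C, N, O, S, shipped as
  package data (f(0) = Z verified to < 0.1%), valid to q = 25 Å⁻¹.
  Inelastic factors are shipped as sampled tables evaluated with monotone
  (PCHIP) interpolation and no silent extrapolation.  The shipped samples
  are generated from the Heisenberg-type closure S_A(q) = Z_A − f_A(q)²/Z_A,
  which satisfies S(0) ≈ 0, S → Z, and additivity; because the inelastic
  term is geometry-independent it largely cancels in the percent-difference
  signal, so the closure's deviation from published tabulations is
  inconsequential for the fitted observable.  Users can substitute their own
  tables.
- **Convolution edges.**  The model is a δ-pulse-excited difference signal:
  identically zero before excitation (leading edge zero-padded) and
  near-stationary at late delays (trailing edge holds the last value).
  Convolution happens on the fine model grid *before* binning; binning first
  would alias the instrument response.
- **Binning.**  Each experimental point is the exact continuous box average
  of the piecewise-linear model signal over a bin centered on the
  experimental time stamp (closed-form integral of the linear interpolant).
  This makes bin averages of linear signals exact and pure t₀ shifts exact.
- **Time alignment.**  Trajectories are resampled onto a single model grid
  by linear interpolation per Cartesian coordinate (propagator steps are
  fs-scale, so the interpolation error is negligible).  Trajectories ending
  early hold their last frame by default ("hold" policy; dissociative
  trajectories reach asymptotes, so this is physically sensible); a "strict"
  policy raises instead.
- **Tolerances.**  Solver tolerances default to 10⁻⁸ (function, step,
  gradient).  Weight-sum validation tolerance is 10⁻⁹.
- **Randomness.**  One seeded generator per concern (ensemble geometry,
  noise realization, initial-weight pool), all recorded; every stochastic
  stage is bit-reproducible from its seed.

## The synthetic-data generator

Real trajectory ensembles and beam-time data cannot ship with a package, so
`tbfit.synthetic` generates a toy study whose identifiability structure
mirrors the triatomic-photodissociation use case:

- **Molecule.**  A C/S/S triatomic (CS₂-like), equilibrium C–S bond
  1.55 Å.
- **Bound trajectories** oscillate in both bonds (mean period 150 fs,
  amplitudes up to ~0.3 Å) about anharmonically outward-shifted means (up to
  0.2 Å — vibrationally hot molecules), with excited-state bending (static
  bends up to 40° plus 90-fs-period bend oscillations).  Oscillations are
  essentially undamped: isolated molecules do not dissipate.
- **Dissociative trajectories** break one bond after onsets stratified over
  0–150 fs with asymptotic speeds around 0.03 Å/fs (≈1 eV of translational
  release on a sulfur-mass fragment); the surviving CS fragment keeps
  vibrating, its amplitude and mean-bond shift forming a persistent
  late-time fingerprint.
- **Stratified sampling.**  Per-trajectory parameters are drawn one per
  equal subinterval of their range (Latin-hypercube style) so the basis
  samples its configuration space generously instead of clustering —
  mirroring the generous initial-condition sampling that trajectory-basis
  fitting relies on.  With clustered draws, near-duplicate trajectories make
  per-trajectory weights unidentifiable at realistic noise (their class
  totals remain identifiable; this is exactly the regime real fits report).

The **reference fixture** (the package's standard test conditions) is 40
trajectories (10 bound, 30 dissociative) over 1 ps on a 4 fs grid, 8 of
them active with a sparsity pattern echoing a published best-fit table
(44.7% down to 1.67%; bound total 28%); detector grid 384 q points on
1.2–10 Å⁻¹ and 25 fs bins over −50…975 fs; true apparatus parameters
t₀ = −20 fs, τ_c = 50 fs FWHM (a modern ultrafast-scattering
cross-correlation), γ = 4% (typical pump excitation); additive Gaussian
noise with σ = 10% of the peak |signal|.  These sizes keep the full
two-step inversion around two minutes on one core.

What the generator does **not** emulate: electronic-state-specific
scattering, Poisson photon statistics (noise is Gaussian heteroscedastic
only), detector artifacts, q-resolution effects, or quantitatively accurate
CS₂/CHD dynamics.  Passing recovery tests therefore demonstrates the
correctness and conditioning of the inversion machinery under controlled,
realistic-scale conditions — not that any specific published experimental
fit is reproduced.

## Design decisions that were genuinely open

- The percent-difference model form is 100·γ_eff·(I_mod/I_off − 1); an
  alternative normalization by the integrated laser-on/off intensity ratio
  exists in the literature and is deliberately out of scope here beyond the
  γ(q) profile hook.
- The two-step refinement re-runs step two for several step-one candidates
  because the integrated signal is nearly flat in τ_c; the full objective
  decides.  Refining only the single top candidate is cheaper but measurably
  worse at choosing τ_c.
- The iterative initial-pool resampling scheme (jittered incumbent plus
  fresh uniform draws) is a simple documented biasing scheme; more targeted
  schemes exist but are not implemented.
- α-style balancing across multiple simultaneous experiment types is
  accepted in configuration (fixed to 1) but no auto-balancing is
  implemented; single-experiment fits are the scope.

## Known limitations

- IAM only: no ab initio or state-specific scattering, no relativistic
  form-factor corrections, no coherent-mixed terms, no alignment.
- Per-trajectory weights are identifiable only as far as the trajectory
  signals are distinguishable at the instrument resolution; duplicate or
  near-duplicate trajectories yield flat objective directions, which are
  reported (near-zero curvature, equal-F splits), not resolved.
- Embedded form-factor data covers H, C, N, O, S; other elements require
  user-supplied tables.
- No time-warping of trajectories to compensate systematic simulation
  errors; the apparatus mapping covers instrument effects only.
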