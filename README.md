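# tbfit — trajectory-basis inversion of ultrafast scattering data

`tbfit` analyzes time-resolved pump–probe X-ray scattering (UXS) and
electron diffraction (UED) data by *forward optimization in a trajectory
basis*.  Given an ensemble of semiclassical trajectories from nonadiabatic
dynamics simulations, it fits the trajectory weights — together with the
experiment's global parameters (time zero t₀, instrument response τ_c,
excitation fraction γ) — so that the model's percent-difference signal
reproduces the measured one.  The result is a physically constrained,
continuity-preserving interpretation of the experiment: which reaction
pathways contribute, and with what yield.

It is aimed at gas-phase ultrafast-science groups who already run
surface-hopping / Ehrenfest / multiple-spawning simulations and want to
match them quantitatively against beam-time data.

## Model

The photoexcited ensemble is a weighted sum of N trajectories with weights
w_n ≥ 0, Σ w_n = 1.  Scattering is computed in the rotationally averaged
independent atom model (Debye formula)

    I_el(q) = Σ_A Σ_B f_A(q) f_B(q) sinc(q·R_AB),    I_inel(q) = Σ_A S_A(q),

for X-ray or (via f_e = (Z − f)/s²) electron probes.  The observable is the
percent-difference signal

    %ΔI_mod(q, t) = 100 · γ_eff(q) · ( I_mod(q, t) / I_off(q) − 1 ),

convolved in time with a Gaussian instrument response (FWHM τ_c), shifted
by t₀, and box-averaged into the experimental time bins.  The fit minimizes
the confidence-weighted least-squares objective

    F(w, c) = Σ_ij p_ij [ %ΔI_mod(q_i, t_j; w, c) − %ΔI_exp(q_i, t_j) ]²,

with per-point confidences p ∈ [0, 1] (from measured standard deviations,
p ∝ 1/σ, or user supplied), by trust-region-reflective least squares from
Monte-Carlo-sampled initial weights, scanning or re-fitting the global
parameters (one-step and two-step modes).  Reported diagnostics: F, the
relative absolute error RAE (< 1 = better than the unweighted simulation),
RMSE, weight variance, and the distance D_b between solutions.
See `docs/methods.md` for the full account.

## Worked example

Fit a synthetic pseudo-experiment with known ground truth (40 CS₂-like
trajectories, 8 of them truly active, 10% peak noise):

```python
import tbfit as tb
from tbfit.model import TrajectoryBasisModel
from tbfit.optimize import OptimizationConfig

ens, ref, signal, sigma, conf, truth = tb.synthetic.reference_fixture(seed=0)
model = TrajectoryBasisModel(signal, ens, ref, sigma=sigma)
cfg = OptimizationConfig(
    n_init=24, seed=3,
    t0_grid=(-40, -30, -20, -10, 0),
    tau_c_grid=(30, 40, 50, 60, 70),
    n_step2_candidates=25,
)
results = model.fit(method="two_step", config=cfg)
print(results.summary())
print(tb.score_recovery(results.best, truth))
```

Output (abridged):

```
Trajectory-basis inversion results
==============================================
method:            two_step
trajectories:      40 (bound: 10, dissociative: 30)
probe:             xray
t0:                -20 fs
tau_c (FWHM):      50 fs
gamma:             0.04095
target function F: 65.4389
RAE:               0.8578
RMSE:              0.0637
Var_w:             0.005316

dominant trajectories (weight > 1%):
  dissoc_006       dissociative    43.35%
  bound_007        bound           16.55%
  ...

class fractions:   bound 30.6%, dissociative 69.4%
gamma drift (step1 -> step2): 3.4%

{'linf': 0.0263, 'l2': 0.0573, 'max_class_fraction_error': 0.0264,
 't0_error': 0.0, 'tau_c_error': 0.0, 'gamma_rel_error': 0.0238}
```

The fit recovers the generating weights to L∞ ≈ 0.026 per trajectory, the
bound fraction to ≈ 2.6 points, t₀ and τ_c exactly (on their 10 fs scan
grids), and γ to ≈ 2% relative — i.e. the inversion identifies the eight
active trajectories and their yields from noisy data.  RAE < 1 says the
fitted model misfits the data less than the unweighted (equal-weight)
simulation; here most of the residual is the 10% noise floor itself.

A command-line interface mirrors this: `tbfit simulate` writes a synthetic
fixture (XYZ trajectories + manifest + signal), `tbfit invert` fits it from
a YAML config, `tbfit metrics` evaluates fit metrics for externally
produced signals.

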