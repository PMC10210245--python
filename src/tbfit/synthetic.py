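"""Synthetic fixtures: toy trajectory ensembles and pseudo-experiments with
known ground truth.

The toy molecule is a linear triatomic (default C/S/S, i.e. CS2-like) whose
trajectories fall into two classes: *bound* trajectories execute damped
stretching oscillations of both bonds, while *dissociative* trajectories
break one bond after an onset delay and separate at a constant asymptotic
speed.  This reproduces the two qualitative signal motifs of triatomic
photodissociation data — an enhancement/depletion band from bond-length
changes at intermediate q and a low-q rise accompanying dissociation — so
recovery tests exercise the same identifiability structure real fits face.

Pseudo-experiments push a known sparse weight vector and known apparatus
parameters through the exact forward model and add heteroscedastic Gaussian
noise; the truth record allows recovery scoring of any subsequent fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .apparatus import GlobalParams, ReferenceSignal, forward_model
from .elements import get_species
from .ensemble_io import (
    Geometry,
    SignalMatrix,
    Trajectory,
    TrajectoryEnsemble,
    build_ensemble,
)
from .metrics import ConfidenceMatrix, class_totals, confidence_from_sigma
from .optimize import OptimizationResult
from .scattering import ProbeKind

__all__ = [
    "ToyEnsembleSpec",
    "PseudoExperimentSpec",
    "make_toy_ensemble",
    "reference_geometry",
    "make_pseudo_experiment",
    "score_recovery",
    "reference_fixture_weights",
    "reference_fixture",
]


@dataclass
class ToyEnsembleSpec:
    """Parameters of the toy triatomic ensemble.

    Defaults emulate CS2 photodissociation phenomenology at desk scale:
    equilibrium C-S bond length 1.55 A; vibrationally hot bound molecules
    with persistent stretching oscillations (isolated molecules do not
    dissipate), anharmonic outward mean-bond shifts, and excited-state
    bending (the excited state is bent); dissociation onsets spread over the
    first 150 fs with asymptotic separation speeds around 0.03 A/fs (about
    1 eV of translational release on a sulfur-mass fragment); 1 ps span on a
    4 fs grid.

    Per-trajectory parameters are stratified (one draw per equal
    subinterval of each range, randomly paired) so the ensemble samples its
    configuration space generously rather than clustering, mirroring the
    generous initial-condition sampling trajectory-basis fits rely on.
    """

    n_bound: int = 10
    n_dissociative: int = 30
    symbols: tuple = ("S", "C", "S")
    r0: float = 1.55  # A, equilibrium bond length
    period: float = 150.0  # fs, mean stretching period (stratified +-35%)
    amplitude: float = 0.18  # A, mean stretch amplitude (stratified 0.3-1.7x)
    damping: float = 2000.0  # fs, stretch damping time (weak: isolated molecules)
    mean_shift: float = 0.20  # A, max anharmonic outward mean-bond shift
    bend_mean_max: float = 40.0  # deg, max static bend of hot/excited molecules
    bend_amp_max: float = 35.0  # deg, max bending oscillation amplitude
    bend_period: float = 90.0  # fs, mean bending period (stratified +-30%)
    onset: float = 75.0  # fs, mean dissociation onset
    onset_jitter: float = 75.0  # fs, uniform onset spread (onsets in 0-150 fs)
    speed: float = 0.03  # A/fs, mean asymptotic separation speed (0.4-1.6x)
    t_max: float = 1000.0  # fs
    dt: float = 4.0  # fs
    seed: int = 0

    def __post_init__(self):
        if self.n_bound < 0 or self.n_dissociative < 0:
            raise ValueError("trajectory counts must be >= 0")
        if self.n_bound + self.n_dissociative == 0:
            raise ValueError("ensemble must contain at least one trajectory")
        for name in ("period", "speed", "r0", "dt", "t_max"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


def _frames_from_bonds(symbols, r_left, r_right, bend_deg=None):
    """Triatomic frames from bond-length and bend time courses.

    The central atom sits at the origin; the terminal atoms lie in the xz
    plane at distances ``r_left`` / ``r_right``.  ``bend_deg`` is the
    deviation from linearity (0 = linear along z), opening symmetrically.
    """
    species = tuple(get_species(s) for s in symbols)
    n = len(np.atleast_1d(r_left))
    bend = np.zeros(n) if bend_deg is None else np.deg2rad(np.atleast_1d(bend_deg))
    frames = []
    for rl, rr, b in zip(np.atleast_1d(r_left), np.atleast_1d(r_right), bend):
        s, c = np.sin(b / 2.0), np.cos(b / 2.0)
        pos = np.array([[rl * s, 0.0, -rl * c], [0.0, 0.0, 0.0], [rr * s, 0.0, rr * c]])
        frames.append(Geometry(species, pos))
    return frames


def _stratified(rng, lo, hi, n):
    """One uniform draw per equal subinterval of [lo, hi], randomly ordered."""
    edges = np.linspace(lo, hi, n + 1)
    vals = edges[:-1] + (edges[1] - edges[0]) * rng.uniform(size=n)
    return rng.permutation(vals)


def _smooth_ramp(t, onset, speed, width=10.0):
    """Smoothly switched-on linear separation: ~0 before onset, v*(t-onset) after."""
    z = (t - onset) / width
    return speed * width * np.logaddexp(0.0, z)  # softplus


def make_toy_ensemble(spec: ToyEnsembleSpec) -> TrajectoryEnsemble:
    """Generate the labelled toy ensemble on its model time grid.

    Bound trajectories: both bonds oscillate about outward-shifted means
    with random phases while the molecule bends.  Dissociative trajectories:
    one bond separates after a stratified onset at a stratified asymptotic
    speed; the surviving fragment keeps vibrating, and its amplitude and
    mean-bond shift form the trajectory's late-time fingerprint.
    Bit-identical for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.t_max + spec.dt / 2, spec.dt)
    trajectories = []

    def bond(phase, amp, period, shift):
        env = np.exp(-t / spec.damping)
        return spec.r0 + shift + amp * env * np.sin(2 * np.pi * t / period + phase)

    def bend(mean, amp, period, phase):
        return mean + amp * np.sin(2 * np.pi * t / period + phase)

    nb, nd = spec.n_bound, spec.n_dissociative
    # stratified per-trajectory fingerprints; secondary parameters free-drawn
    b_amp = _stratified(rng, 0.3 * spec.amplitude, 1.7 * spec.amplitude, nb) if nb else []
    b_shift = _stratified(rng, 0.0, spec.mean_shift, nb) if nb else []
    b_bend = _stratified(rng, 0.0, spec.bend_mean_max, nb) if nb else []
    for i in range(nb):
        period = spec.period * rng.uniform(0.65, 1.35)
        left = bond(rng.uniform(0, 2 * np.pi), b_amp[i], period, b_shift[i])
        right = bond(
            rng.uniform(0, 2 * np.pi),
            b_amp[i] * rng.uniform(0.8, 1.2),
            period * rng.uniform(0.9, 1.1),
            b_shift[i] * rng.uniform(0.8, 1.2),
        )
        bnd = bend(
            b_bend[i],
            spec.bend_amp_max * rng.uniform(0.2, 1.0),
            spec.bend_period * rng.uniform(0.7, 1.3),
            rng.uniform(0, 2 * np.pi),
        )
        frames = _frames_from_bonds(spec.symbols, left, right, bnd)
        trajectories.append(Trajectory(f"bound_{i:03d}", t, frames, "bound"))

    d_on = (
        _stratified(rng, spec.onset - spec.onset_jitter, spec.onset + spec.onset_jitter, nd)
        if nd else []
    )
    d_sp = _stratified(rng, 0.4 * spec.speed, 1.6 * spec.speed, nd) if nd else []
    d_amp = _stratified(rng, 0.1 * spec.amplitude, 1.8 * spec.amplitude, nd) if nd else []
    d_shift = _stratified(rng, 0.0, spec.mean_shift, nd) if nd else []
    for i in range(nd):
        # the surviving C-S fragment keeps vibrating; its amplitude and hot
        # mean-bond shift are the late-time fingerprint of the trajectory
        left = bond(
            rng.uniform(0, 2 * np.pi), d_amp[i], spec.period * rng.uniform(0.65, 1.35),
            d_shift[i],
        )
        right = bond(
            rng.uniform(0, 2 * np.pi), spec.amplitude * rng.uniform(0.6, 1.4),
            spec.period * rng.uniform(0.65, 1.35), 0.0,
        ) + _smooth_ramp(t, max(0.0, d_on[i]), d_sp[i])
        bnd = bend(
            spec.bend_mean_max * rng.uniform(0.0, 0.6),
            spec.bend_amp_max * rng.uniform(0.2, 0.8),
            spec.bend_period * rng.uniform(0.7, 1.3),
            rng.uniform(0, 2 * np.pi),
        )
        frames = _frames_from_bonds(spec.symbols, left, right, bnd)
        trajectories.append(Trajectory(f"dissoc_{i:03d}", t, frames, "dissociative"))

    return build_ensemble(trajectories, t)


def reference_geometry(spec: ToyEnsembleSpec) -> Geometry:
    """Equilibrium (unpumped) geometry of the toy molecule."""
    return _frames_from_bonds(spec.symbols, [spec.r0], [spec.r0])[0]


def reference_fixture_weights(n_bound: int = 10, n_dissociative: int = 30,
                              seed: int = 0) -> np.ndarray:
    """Sparse ground-truth weights for the reference recovery fixture.

    Eight active trajectories out of ``n_bound + n_dissociative``, with the
    sparsity pattern of a published best-fit weight table (two bound, six
    dissociative, spanning ~45% down to ~1.7%); placement within each class
    is drawn from ``seed``.
    """
    active = np.array([44.7, 17.8, 10.4, 10.2, 7.42, 4.42, 3.39, 1.67]) / 100.0
    bound_weights = [active[1], active[3]]  # 17.8%, 10.2%
    dissoc_weights = [active[0], active[2], active[4], active[5], active[6], active[7]]
    # smaller ensembles get a truncated version of the same pattern
    bound_weights = bound_weights[:n_bound]
    dissoc_weights = dissoc_weights[:n_dissociative]
    if not bound_weights and not dissoc_weights:
        raise ValueError("empty ensemble")
    rng = np.random.default_rng(seed)
    w = np.zeros(n_bound + n_dissociative)
    w[rng.choice(n_bound, size=len(bound_weights), replace=False)] = bound_weights
    w[n_bound + rng.choice(n_dissociative, size=len(dissoc_weights), replace=False)] = (
        dissoc_weights
    )
    return w / w.sum()


@dataclass
class PseudoExperimentSpec:
    """Parameters of a synthetic pseudo-experiment with known truth.

    Noise is Gaussian and heteroscedastic: ``sigma_scale`` sets a constant
    floor as a fraction of the peak |signal|; ``sigma_map`` (same shape as
    the signal) optionally multiplies it point by point, e.g. to emulate a
    corrupted band.  ``noise_seed`` controls only the noise realization.
    """

    true_weights: np.ndarray
    true_params: GlobalParams
    q_grid: np.ndarray
    exp_times: np.ndarray
    bin_width: float = 25.0
    probe: ProbeKind = ProbeKind.xray
    sigma_scale: float = 0.10  # fraction of peak |clean signal|
    sigma_map: np.ndarray | None = None
    noise_seed: int = 1

    def __post_init__(self):
        self.true_weights = np.asarray(self.true_weights, dtype=float)
        if abs(self.true_weights.sum() - 1.0) > 1e-9 or np.any(self.true_weights < 0):
            raise ValueError("true_weights must be a normalized weight vector")
        if not self.sigma_scale >= 0:
            raise ValueError("sigma_scale must be >= 0")


def make_pseudo_experiment(
    ensemble: TrajectoryEnsemble,
    reference: ReferenceSignal,
    spec: PseudoExperimentSpec,
):
    """Forward-model a pseudo-experiment and corrupt it with Gaussian noise.

    Returns ``(signal, sigma, confidence, truth)``: the noisy percent-
    difference signal, the per-point standard deviations, the confidence
    matrix built from them, and a truth record for recovery scoring.  With
    ``sigma_scale = 0`` the output equals the clean forward model exactly.
    """
    clean = forward_model(
        ensemble,
        spec.true_weights,
        spec.true_params,
        reference,
        spec.q_grid,
        spec.exp_times,
        probe=spec.probe,
        bin_width=spec.bin_width,
    )
    peak = np.max(np.abs(clean.values))
    sigma = np.full_like(clean.values, spec.sigma_scale * peak)
    if spec.sigma_map is not None:
        sigma = sigma * np.asarray(spec.sigma_map, dtype=float)
    if spec.sigma_scale == 0:
        noisy = clean.values.copy()
        confidence = ConfidenceMatrix.ones(clean.values.shape)
        sigma_out = sigma
    else:
        rng = np.random.default_rng(spec.noise_seed)
        noisy = clean.values + rng.normal(0.0, 1.0, size=clean.values.shape) * sigma
        confidence = confidence_from_sigma(sigma)
        sigma_out = sigma
    signal = clean.copy_with(values=noisy)
    truth = {
        "weights": spec.true_weights.copy(),
        "params": spec.true_params,
        "trajectory_ids": list(ensemble.ids),
        "labels": list(ensemble.labels),
        "clean_signal": clean,
    }
    return signal, sigma_out, confidence, truth


def reference_fixture(seed: int = 0, noise_seed: int | None = None,
                      sigma_scale: float = 0.10, sigma_map=None):
    """The canonical recovery fixture: ensemble, reference, pseudo-experiment.

    Study conditions, frozen: 40 toy trajectories (10 bound, 30
    dissociative) over 1 ps; 8 active trajectories with a published-fit-like
    sparsity pattern; detector grid of 384 q points on 1.2-10 1/A and 25 fs
    time bins on -50..975 fs; true apparatus parameters t0 = -20 fs,
    tau_c = 50 fs (FWHM), gamma = 4%; Gaussian noise with sigma equal to
    ``sigma_scale`` times the peak |signal| (default 10%).

    Returns ``(ensemble, reference_signal, signal, sigma, confidence,
    truth)``.
    """
    spec = ToyEnsembleSpec(seed=seed)
    ensemble = make_toy_ensemble(spec)
    q = np.linspace(1.2, 10.0, 384)
    exp_times = np.arange(-50.0, 975.01, 25.0)
    reference = ReferenceSignal.from_geometry(reference_geometry(spec), q)
    pe = PseudoExperimentSpec(
        true_weights=reference_fixture_weights(
            spec.n_bound, spec.n_dissociative, seed=seed
        ),
        true_params=GlobalParams(t0=-20.0, tau_c=50.0, gamma=0.04),
        q_grid=q,
        exp_times=exp_times,
        bin_width=25.0,
        sigma_scale=sigma_scale,
        sigma_map=sigma_map,
        noise_seed=seed + 1 if noise_seed is None else noise_seed,
    )
    signal, sigma, confidence, truth = make_pseudo_experiment(ensemble, reference, pe)
    return ensemble, reference, signal, sigma, confidence, truth


def score_recovery(result: OptimizationResult, truth: dict) -> dict:
    """Compare a fit against the ground truth of a pseudo-experiment.

    Reports per-trajectory weight errors (L-infinity and L2), per-class
    fraction errors, and global-parameter errors.  Trajectory IDs must match
    the truth record's ordering.
    """
    if result.trajectory_ids != truth["trajectory_ids"]:
        raise ValueError("trajectory IDs of result and truth do not match")
    w_hat = np.asarray(result.weights, dtype=float)
    w_true = np.asarray(truth["weights"], dtype=float)
    labels = truth["labels"]
    frac_hat = class_totals(w_hat, labels)
    frac_true = class_totals(w_true, labels)
    class_errors = {
        lab: frac_hat.get(lab, 0.0) - frac_true.get(lab, 0.0)
        for lab in sorted(set(labels))
    }
    p_hat, p_true = result.params, truth["params"]
    out = {
        "linf": float(np.max(np.abs(w_hat - w_true))),
        "l2": float(np.linalg.norm(w_hat - w_true)),
        "class_fraction_errors": class_errors,
        "max_class_fraction_error": float(
            max(abs(v) for v in class_errors.values())
        ),
        "t0_error": float(p_hat.t0 - p_true.t0),
        "tau_c_error": float(p_hat.tau_c - p_true.tau_c),
        "gamma_error": float(p_hat.scale - p_true.scale),
        "gamma_rel_error": float(
            abs(p_hat.scale - p_true.scale) / p_true.scale
        ) if p_true.scale else np.inf,
    }
    return out
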