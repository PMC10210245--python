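"""Apparatus mapping: from model intensities to the experimental observable.

The measured quantity is the percent-difference signal

    %dI(q, t) = 100 * gamma_eff(q) * (I_mod(q, t) / I_off(q) - 1),

where ``gamma_eff`` is either a uniform excitation fraction ``gamma`` or a
q-dependent profile ``gamma_q(q)`` scaled by a uniform factor ``x`` (long
interaction regions make the effective excitation vary with q).  The model
signal is then convolved in time with a unit-area Gaussian of FWHM ``tau_c``
(the instrument response: pump-probe cross-correlation plus jitter), shifted
onto the experimental delay axis via ``t' = t + t0``, and box-averaged into
the experimental time bins.

The model is a delta-pulse-excited difference signal: it is identically zero
before excitation, so the leading convolution edge is zero-padded; the
trailing edge holds the last value (late-time dynamics are near-stationary).
Convolution happens on the fine model grid *before* binning, otherwise the
instrument response would be aliased.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import convolve1d

from .ensemble_io import Geometry, SignalMatrix, TrajectoryEnsemble
from .scattering import ProbeKind, elastic_debye, ensemble_signal, inelastic_sum

__all__ = [
    "GlobalParams",
    "ReferenceSignal",
    "percent_difference_model",
    "convolve_time",
    "map_to_experiment",
    "forward_model",
    "FWHM_TO_SIGMA",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class GlobalParams:
    """Global experimental parameters optimized alongside the weights.

    Exactly one of ``gamma`` (uniform excitation fraction) or
    ``(gamma_q, x)`` (sampled q-dependent profile with uniform scale) must be
    active.

    Parameters
    ----------
    t0 : float
        Time-zero shift (fs); experimental axis t' = model t + t0.
    tau_c : float
        FWHM (fs) of the Gaussian instrument response; > 0.
    gamma : float, optional
        Uniform excitation fraction in [0, 1].
    gamma_q : (ndarray, ndarray), optional
        ``(q_nodes, gamma_values)`` sampled profile, linearly interpolated.
    x : float, optional
        Uniform scale applied to ``gamma_q``; > 0.
    """

    t0: float
    tau_c: float
    gamma: float | None = None
    gamma_q: tuple | None = None
    x: float | None = None

    def __post_init__(self):
        if not self.tau_c > 0:
            raise ValueError("tau_c must be > 0")
        uniform = self.gamma is not None
        profile = self.gamma_q is not None
        if uniform == profile:
            raise ValueError("exactly one of gamma or (gamma_q, x) must be set")
        if uniform:
            if not 0.0 <= self.gamma <= 1.0:
                raise ValueError("gamma must lie in [0, 1]")
        else:
            if self.x is None or not self.x > 0:
                raise ValueError("gamma_q mode requires scale x > 0")

    def gamma_eff(self, q) -> np.ndarray:
        """Effective excitation fraction on a q grid."""
        q = np.asarray(q, dtype=float)
        if self.gamma is not None:
            return np.full_like(q, self.gamma)
        qn, gv = self.gamma_q
        return self.x * np.interp(q, np.asarray(qn, float), np.asarray(gv, float))

    @property
    def scale(self) -> float:
        """The scalar amplitude parameter (gamma, or x in profile mode)."""
        return self.gamma if self.gamma is not None else self.x

    def with_scale(self, value: float) -> "GlobalParams":
        if self.gamma is not None:
            return replace(self, gamma=float(value))
        return replace(self, x=float(value))


@dataclass(frozen=True)
class ReferenceSignal:
    """Unpumped ("laser-off") reference intensity I_off(q), strictly positive."""

    q_values: np.ndarray
    i_off: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "q_values", np.asarray(self.q_values, float))
        object.__setattr__(self, "i_off", np.asarray(self.i_off, float))
        if self.i_off.shape != self.q_values.shape:
            raise ValueError("i_off and q_values must have the same shape")
        if np.any(self.i_off <= 0):
            raise ValueError("reference intensity must be strictly positive")

    @classmethod
    def from_geometry(cls, geometry: Geometry, q_grid, probe=ProbeKind.xray):
        """Reference from a single equilibrium geometry (Debye + inelastic)."""
        q = np.asarray(q_grid, float)
        i = elastic_debye(geometry, q, probe) + inelastic_sum(geometry.species, q)
        return cls(q, i)

    @classmethod
    def from_geometries(cls, geometries, q_grid, probe=ProbeKind.xray):
        """Reference from an averaged ground-state ensemble (e.g. Wigner samples)."""
        q = np.asarray(q_grid, float)
        i = np.mean(
            [
                elastic_debye(g, q, probe) + inelastic_sum(g.species, q)
                for g in geometries
            ],
            axis=0,
        )
        return cls(q, i)


def percent_difference_model(
    ensemble_on_signal: SignalMatrix, reference: ReferenceSignal, params: GlobalParams
) -> SignalMatrix:
    """Percent-difference model signal 100 * gamma_eff(q) * (I/I_off - 1)."""
    if not np.allclose(ensemble_on_signal.q_values, reference.q_values):
        raise ValueError("signal and reference q grids differ")
    g = params.gamma_eff(ensemble_on_signal.q_values)
    vals = 100.0 * g[:, None] * (
        ensemble_on_signal.values / reference.i_off[:, None] - 1.0
    )
    return ensemble_on_signal.copy_with(values=vals, units="percent")


def _uniform_step(t: np.ndarray) -> float:
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise ValueError(
            "time grid must be uniform for convolution; resample the model first"
        )
    return float(dt[0])


def convolve_time(signal: SignalMatrix, tau_c: float) -> SignalMatrix:
    """Convolve each q row with a unit-area Gaussian of FWHM ``tau_c`` (fs).

    Edge handling: values before the grid start are zero (no signal before
    the delta-pulse excitation); the trailing edge holds the last value.
    """
    if not tau_c > 0:
        raise ValueError("tau_c must be > 0")
    dt = _uniform_step(signal.t_values)
    sigma = tau_c * FWHM_TO_SIGMA
    radius = int(np.ceil(4.0 * sigma / dt))
    if radius == 0:
        return signal.copy_with()
    x = np.arange(-radius, radius + 1) * dt
    kernel = np.exp(-0.5 * (x / sigma) ** 2)
    kernel /= kernel.sum()  # unit area: constants preserved away from edges
    nq, nt = signal.values.shape
    padded = np.concatenate(
        [
            np.zeros((nq, radius)),  # pre-excitation: zero
            signal.values,
            np.repeat(signal.values[:, -1:], radius, axis=1),  # hold last
        ],
        axis=1,
    )
    out = convolve1d(padded, kernel, axis=1, mode="nearest")[:, radius : radius + nt]
    return signal.copy_with(values=out)


def map_to_experiment(
    signal: SignalMatrix, t0: float, exp_times, bin_width: float
) -> SignalMatrix:
    """Evaluate the model on the experimental delay axis with temporal binning.

    Model time t = t' - t0.  Each experimental point is the exact box average
    of the piecewise-linear model signal over ``[t - bin_width/2,
    t + bin_width/2]`` (bin centered on the experimental stamp);
    ``bin_width = 0`` gives pointwise linear interpolation.
    """
    exp_times = np.asarray(exp_times, dtype=float)
    t = signal.t_values
    centers = exp_times - t0
    lo = centers - bin_width / 2.0
    hi = centers + bin_width / 2.0
    if lo.min() < t[0] - 1e-9 or hi.max() > t[-1] + 1e-9:
        raise ValueError(
            f"model grid [{t[0]}, {t[-1]}] fs does not cover the required span "
            f"[{lo.min():.6g}, {hi.max():.6g}] fs (experimental axis minus t0, "
            f"plus half a bin); extend the model grid"
        )
    v = signal.values  # (Nq, Nt)
    if bin_width == 0:
        out = np.stack([np.interp(centers, t, row) for row in v])
        return SignalMatrix(signal.q_values, exp_times, out, units=signal.units)

    # exact integral of the linear interpolant: piecewise-quadratic antiderivative
    from scipy.integrate import cumulative_trapezoid

    cum = cumulative_trapezoid(v, t, axis=1, initial=0.0)  # (Nq, Nt)

    def antideriv(xs):
        idx = np.clip(np.searchsorted(t, xs, side="right") - 1, 0, len(t) - 2)
        dtl = xs - t[idx]
        h = t[idx + 1] - t[idx]
        slope = (v[:, idx + 1] - v[:, idx]) / h
        return cum[:, idx] + v[:, idx] * dtl + 0.5 * slope * dtl**2

    out = (antideriv(hi) - antideriv(lo)) / bin_width
    return SignalMatrix(signal.q_values, exp_times, out, units=signal.units)


def _extend_for_mapping(
    signal: SignalMatrix, t0: float, exp_times, bin_width: float, tau_c: float
) -> SignalMatrix:
    """Pad the model time axis so convolution + mapping are well-defined.

    Prepends zeros (pre-excitation) and appends held last values so the grid
    covers the experimental span plus the convolution wings.
    """
    t = signal.t_values
    dt = _uniform_step(t)
    wing = 4.0 * tau_c * FWHM_TO_SIGMA
    need_lo = min(np.min(exp_times) - t0 - bin_width / 2.0 - wing, t[0])
    need_hi = max(np.max(exp_times) - t0 + bin_width / 2.0 + wing, t[-1])
    n_pre = max(0, int(np.ceil((t[0] - need_lo) / dt)))
    n_post = max(0, int(np.ceil((need_hi - t[-1]) / dt)))
    if n_pre == 0 and n_post == 0:
        return signal
    new_t = np.concatenate(
        [t[0] + dt * np.arange(-n_pre, 0), t, t[-1] + dt * np.arange(1, n_post + 1)]
    )
    nq = signal.values.shape[0]
    new_v = np.concatenate(
        [
            np.zeros((nq, n_pre)),
            signal.values,
            np.repeat(signal.values[:, -1:], n_post, axis=1),
        ],
        axis=1,
    )
    return SignalMatrix(signal.q_values, new_t, new_v, units=signal.units)


def forward_model(
    ensemble: TrajectoryEnsemble,
    weights,
    params: GlobalParams,
    reference: ReferenceSignal,
    q_grid,
    exp_times,
    probe=ProbeKind.xray,
    bin_width: float = 25.0,
    _per_trajectory=None,
) -> SignalMatrix:
    """Full forward pipeline: weighted intensity -> percent difference ->
    instrument-response convolution -> experimental axis with binning.

    Deterministic, and linear both in the weights and in the effective
    excitation fraction.
    """
    intensity = ensemble_signal(
        ensemble, weights, q_grid, probe, _per_trajectory=_per_trajectory
    )
    pct = percent_difference_model(intensity, reference, params)
    pct = _extend_for_mapping(pct, params.t0, exp_times, bin_width, params.tau_c)
    conv = convolve_time(pct, params.tau_c)
    return map_to_experiment(conv, params.t0, exp_times, bin_width)
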