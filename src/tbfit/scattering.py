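"""Rotationally averaged independent-atom-model (IAM) scattering.

The forward mapping from geometry to observable.  Elastic scattering of a
randomly oriented gas-phase molecule is given by the Debye formula

    I_el(q) = sum_A sum_B f_A(q) f_B(q) sinc(q R_AB),

with ``sinc(x) = sin(x)/x`` and the A = B self terms entering through the
``sinc -> 1`` limit, so that ``I_el(0) = (sum_A Z_A)^2`` for X-rays.  The
inelastic contribution is an incoherent, geometry-independent atomic sum
``S_inel(q) = sum_A S_A(q)``.

Electron diffraction uses the converted form factors
``f^el_A(s) = (Z_A - f_A(s)) / s^2`` (the momentum-transfer axis is
conventionally called *s* for electrons); the ``s -> 0`` singularity is
excluded by a hard cutoff rather than regularized.

Probe prefactors (Thomson / Rutherford cross sections, polarization, s^-4)
are multiplicative in q only and cancel exactly in the percent-difference
observable; they are deliberately not applied here.
"""

from __future__ import annotations

from enum import Enum

import numpy as np

from .elements import AtomicSpecies
from .ensemble_io import Geometry, SignalMatrix, Trajectory, TrajectoryEnsemble

__all__ = [
    "ProbeKind",
    "elastic_form_factor",
    "inelastic_sum",
    "elastic_debye",
    "trajectory_signal",
    "ensemble_signal",
]

Q_MIN_ELECTRON = 1e-3  # 1/A; below this the (Z - f)/q^2 conversion diverges


class ProbeKind(str, Enum):
    """Scattering probe: X-ray photons or (high-energy) electrons."""

    xray = "xray"
    electron = "electron"


def elastic_form_factor(species: AtomicSpecies, q, probe: ProbeKind = ProbeKind.xray):
    """Elastic scattering amplitude of one atom.

    X-ray: the Cromer-Mann f_A(q).  Electron: (Z_A - f_A(q)) / q^2, defined
    only for q >= ``Q_MIN_ELECTRON``.
    """
    q = np.asarray(q, dtype=float)
    probe = ProbeKind(probe)
    if np.any(q < 0):
        raise ValueError("q must be nonnegative")
    if probe is ProbeKind.xray:
        return species.f_elastic(q)
    if np.any(q < Q_MIN_ELECTRON):
        raise ValueError(
            f"electron form factor undefined below q_min_electron={Q_MIN_ELECTRON} 1/A "
            "(the q -> 0 singularity is excluded, not regularized)"
        )
    return (species.Z - species.f_elastic(q)) / q**2


def inelastic_sum(species_list, q):
    """Geometry-independent inelastic intensity: sum_A S_A(q)."""
    q = np.asarray(q, dtype=float)
    out = np.zeros_like(q)
    for sp in species_list:
        out += sp.s_inelastic(q)
    return out


def elastic_debye(geometry: Geometry, q_grid, probe: ProbeKind = ProbeKind.xray):
    """Rotationally averaged elastic intensity of one geometry (Debye formula).

    Returns a vector over ``q_grid``.  Nonnegative by construction (it is the
    orientational average of a modulus squared).
    """
    q = np.asarray(q_grid, dtype=float)
    f = np.stack(
        [elastic_form_factor(sp, q, probe) for sp in geometry.species]
    )  # (Nat, Nq)
    diff = geometry.positions[:, None, :] - geometry.positions[None, :, :]
    rab = np.sqrt(np.sum(diff * diff, axis=-1))  # (Nat, Nat)
    # sinc(q R): np.sinc(x) = sin(pi x)/(pi x); handles R_AB = 0 self terms -> 1
    arg = q[None, None, :] * rab[:, :, None] / np.pi  # (Nat, Nat, Nq)
    sinc = np.sinc(arg)
    return np.einsum("aq,bq,abq->q", f, f, sinc)


def trajectory_signal(
    trajectory: Trajectory, q_grid, probe: ProbeKind = ProbeKind.xray,
    include_inelastic: bool = True,
) -> SignalMatrix:
    """Total IAM intensity I_n(q, t) for a single trajectory.

    Per frame: Debye elastic term plus the (frame-independent) inelastic sum.
    """
    q = np.asarray(q_grid, dtype=float)
    coords = trajectory.coordinates()  # (Nt, Nat, 3)
    f = np.stack(
        [elastic_form_factor(sp, q, probe) for sp in trajectory.species]
    )  # (Nat, Nq)
    ff = np.einsum("aq,bq->abq", f, f)
    diff = coords[:, :, None, :] - coords[:, None, :, :]
    rab = np.sqrt(np.sum(diff * diff, axis=-1))  # (Nt, Nat, Nat)
    sinc = np.sinc(q[None, None, None, :] * rab[..., None] / np.pi)
    vals = np.einsum("abq,tabq->qt", ff, sinc)
    if include_inelastic:
        vals = vals + inelastic_sum(trajectory.species, q)[:, None]
    return SignalMatrix(q, trajectory.times, vals, units="intensity")


def ensemble_signal(
    ensemble: TrajectoryEnsemble, weights, q_grid,
    probe: ProbeKind = ProbeKind.xray, _per_trajectory=None,
) -> SignalMatrix:
    """Weighted ensemble intensity I(q, t) = sum_n w_n I_n(q, t).

    ``weights`` must be a nonnegative vector summing to 1 (tolerance 1e-9).
    ``_per_trajectory`` accepts precomputed per-trajectory SignalMatrix
    objects (a cache used by the optimizer; recomputed if omitted).
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (ensemble.n_tbf,):
        raise ValueError(f"expected {ensemble.n_tbf} weights, got shape {w.shape}")
    if np.any(w < -1e-12):
        raise ValueError("weights must be nonnegative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1 (got {w.sum()!r})")
    if _per_trajectory is None:
        _per_trajectory = [
            trajectory_signal(tr, q_grid, probe) for tr in ensemble.trajectories
        ]
    vals = np.zeros_like(_per_trajectory[0].values)
    for wn, sig in zip(w, _per_trajectory):
        vals += wn * sig.values
    return _per_trajectory[0].copy_with(values=vals)
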