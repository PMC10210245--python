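"""Containers and I/O for trajectory ensembles and (q, t) signal matrices.

Units are fixed package-wide: Angstrom for coordinates, femtoseconds for
time, inverse Angstrom for momentum transfer.  No unit inference is done.

Trajectories come in as multi-frame XYZ files (atom-count line, comment line
carrying a ``t= <fs>`` stamp, then ``symbol x y z`` rows); a plain-text
manifest maps trajectory files to IDs and class labels.  Signal matrices are
delimited text with the time grid as header row and the q grid as first
column.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .elements import AtomicSpecies, get_species

__all__ = [
    "Geometry",
    "Trajectory",
    "TrajectoryEnsemble",
    "SignalMatrix",
    "XYZParseError",
    "read_trajectory_xyz",
    "write_trajectory_xyz",
    "read_manifest",
    "write_manifest",
    "build_ensemble",
    "read_signal_matrix",
    "write_signal_matrix",
]


class XYZParseError(ValueError):
    """Malformed multi-frame XYZ input."""


@dataclass(frozen=True)
class Geometry:
    """A molecular geometry: atomic species plus Cartesian positions (A)."""

    species: tuple  # tuple of AtomicSpecies
    positions: np.ndarray  # (N_at, 3)

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape[0] < 1:
            raise ValueError(f"positions must be (N_at>=1, 3), got {pos.shape}")
        if len(self.species) != pos.shape[0]:
            raise ValueError("species list length must equal position count")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    @property
    def symbols(self) -> tuple:
        return tuple(s.symbol for s in self.species)


@dataclass
class Trajectory:
    """A labelled nuclear trajectory: geometries on a strictly increasing time grid."""

    id: str
    times: np.ndarray  # (N_t,) fs
    frames: list  # list of Geometry, same species ordering
    label: str

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or len(self.times) != len(self.frames):
            raise ValueError("times must be 1-D and match the frame count")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"trajectory {self.id!r}: times must be strictly increasing")
        if not self.label:
            raise ValueError(f"trajectory {self.id!r}: label must be nonempty")
        ref = self.frames[0].symbols
        for i, fr in enumerate(self.frames):
            if fr.symbols != ref:
                raise ValueError(
                    f"trajectory {self.id!r}: frame {i} species differ from frame 0"
                )

    @property
    def species(self) -> tuple:
        return self.frames[0].species

    def coordinates(self) -> np.ndarray:
        """Stacked positions, shape (N_t, N_at, 3)."""
        return np.stack([f.positions for f in self.frames])


@dataclass
class TrajectoryEnsemble:
    """Trajectories resampled onto a common model time grid (the fit basis)."""

    trajectories: list
    model_times: np.ndarray

    def __post_init__(self):
        self.model_times = np.asarray(self.model_times, dtype=float)
        if self.n_tbf < 1:
            raise ValueError("ensemble must contain at least one trajectory")
        sym0 = self.trajectories[0].frames[0].symbols
        for tr in self.trajectories:
            if not np.array_equal(tr.times, self.model_times):
                raise ValueError(f"trajectory {tr.id!r} is not on the model time grid")
            if tr.frames[0].symbols != sym0:
                raise ValueError("all ensemble trajectories must share one species ordering")

    @property
    def n_tbf(self) -> int:
        return len(self.trajectories)

    @property
    def labels(self) -> list:
        return [tr.label for tr in self.trajectories]

    @property
    def ids(self) -> list:
        return [tr.id for tr in self.trajectories]

    @property
    def species(self) -> tuple:
        return self.trajectories[0].species


@dataclass
class SignalMatrix:
    """A real signal on a (q, t) grid with strictly increasing axes.

    ``values`` has shape ``(len(q_values), len(t_values))``.  ``units`` is a
    free tag ("percent" for percent-difference signals, "intensity" for raw
    scattering intensities).
    """

    q_values: np.ndarray
    t_values: np.ndarray
    values: np.ndarray
    units: str = "intensity"

    def __post_init__(self):
        self.q_values = np.asarray(self.q_values, dtype=float)
        self.t_values = np.asarray(self.t_values, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        for name, ax in (("q", self.q_values), ("t", self.t_values)):
            if ax.ndim != 1 or ax.size < 1 or np.any(np.diff(ax) <= 0):
                raise ValueError(f"{name} axis must be 1-D and strictly increasing")
        if self.values.shape != (self.q_values.size, self.t_values.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match grids "
                f"({self.q_values.size}, {self.t_values.size})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signal values must be finite")

    def copy_with(self, **kwargs) -> "SignalMatrix":
        data = dict(
            q_values=self.q_values, t_values=self.t_values, values=self.values,
            units=self.units,
        )
        data.update(kwargs)
        return SignalMatrix(**data)


# ---------------------------------------------------------------------------
# XYZ trajectories

_TIME_RE = re.compile(r"t\s*=\s*([-+0-9.eEdD]+)")


def read_trajectory_xyz(path, label: str, id: str | None = None) -> Trajectory:
    """Read a multi-frame XYZ trajectory.

    Each frame's comment line must carry a ``t= <fs>`` time stamp.  Atom
    counts must agree across frames; unknown elements raise
    :class:`~tbfit.elements.UnsupportedSpeciesError`.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    times, frames = [], []
    i, frame_idx = 0, 0
    n_ref = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        frame_idx += 1
        try:
            nat = int(lines[i].strip())
        except ValueError:
            raise XYZParseError(
                f"{path}: frame {frame_idx}: expected atom count, got {lines[i]!r}"
            ) from None
        if n_ref is None:
            n_ref = nat
        elif nat != n_ref:
            raise XYZParseError(
                f"{path}: frame {frame_idx}: atom count {nat} differs from {n_ref}"
            )
        if i + 1 >= len(lines):
            raise XYZParseError(f"{path}: frame {frame_idx}: truncated (no comment line)")
        m = _TIME_RE.search(lines[i + 1])
        if not m:
            raise XYZParseError(
                f"{path}: frame {frame_idx}: comment line lacks a 't= <fs>' stamp"
            )
        times.append(float(m.group(1).replace("D", "e").replace("d", "e")))
        species, pos = [], []
        for j in range(nat):
            k = i + 2 + j
            if k >= len(lines):
                raise XYZParseError(f"{path}: frame {frame_idx}: truncated atom block")
            parts = lines[k].split()
            if len(parts) < 4:
                raise XYZParseError(
                    f"{path}: frame {frame_idx}: bad atom line {lines[k]!r}"
                )
            species.append(get_species(parts[0]))
            pos.append([float(x) for x in parts[1:4]])
        frames.append(Geometry(tuple(species), np.array(pos)))
        i += 2 + nat
    if not frames:
        raise XYZParseError(f"{path}: no frames found")
    order = np.argsort(times, kind="stable")
    return Trajectory(
        id=id or path.stem,
        times=np.asarray(times)[order],
        frames=[frames[k] for k in order],
        label=label,
    )


def write_trajectory_xyz(traj: Trajectory, path) -> None:
    """Write a trajectory as multi-frame XYZ with ``t=`` time stamps."""
    with open(path, "w") as fh:
        for t, frame in zip(traj.times, traj.frames):
            fh.write(f"{frame.n_atoms}\n")
            fh.write(f"t= {t:.6f} fs  id={traj.id} label={traj.label}\n")
            for sp, xyz in zip(frame.species, frame.positions):
                fh.write(f"{sp.symbol} {xyz[0]:.8f} {xyz[1]:.8f} {xyz[2]:.8f}\n")


def read_manifest(path):
    """Read a trajectory manifest (tab-separated: trajectory_id, path, label).

    Relative trajectory paths are resolved against the manifest's directory.
    Returns a list of ``(id, path, label)`` tuples.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"trajectory_id", "path", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = path.parent / p
        out.append((row["trajectory_id"], p, row["label"]))
    return out


def write_manifest(entries, path) -> None:
    pd.DataFrame(entries, columns=["trajectory_id", "path", "label"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Ensemble assembly


def build_ensemble(trajectories, model_times, edge_policy: str = "hold") -> TrajectoryEnsemble:
    """Resample trajectories onto a common model time grid.

    Linear interpolation per Cartesian coordinate.  ``edge_policy`` governs
    trajectories whose span does not cover ``model_times``:

    - ``"hold"`` (default): clamp to the first/last frame (dissociative
      trajectories reach asymptotes, so holding the last frame is physically
      sensible for late times).
    - ``"strict"``: raise a coverage error.

    Species orderings must match exactly across trajectories; no reordering
    heuristics are applied.
    """
    if edge_policy not in ("hold", "strict"):
        raise ValueError(f"unknown edge policy {edge_policy!r}")
    model_times = np.asarray(model_times, dtype=float)
    if model_times.ndim != 1 or np.any(np.diff(model_times) <= 0):
        raise ValueError("model_times must be 1-D and strictly increasing")
    if not trajectories:
        raise ValueError("no trajectories given")
    sym0 = trajectories[0].frames[0].symbols
    resampled = []
    for tr in trajectories:
        if tr.frames[0].symbols != sym0:
            raise ValueError(
                f"trajectory {tr.id!r}: species ordering {tr.frames[0].symbols} "
                f"differs from {sym0}; no reordering is attempted"
            )
        if edge_policy == "strict" and (
            model_times[0] < tr.times[0] - 1e-9 or model_times[-1] > tr.times[-1] + 1e-9
        ):
            raise ValueError(
                f"trajectory {tr.id!r} spans [{tr.times[0]}, {tr.times[-1]}] fs, "
                f"does not cover model grid [{model_times[0]}, {model_times[-1]}] fs"
            )
        if np.array_equal(tr.times, model_times):
            resampled.append(Trajectory(tr.id, model_times, list(tr.frames), tr.label))
            continue
        coords = tr.coordinates()  # (Nt, Nat, 3)
        flat = coords.reshape(len(tr.times), -1)
        # np.interp clamps outside the data range, i.e. hold-first/hold-last
        interp = np.stack(
            [np.interp(model_times, tr.times, flat[:, k]) for k in range(flat.shape[1])],
            axis=1,
        ).reshape(len(model_times), coords.shape[1], 3)
        frames = [Geometry(tr.species, interp[i]) for i in range(len(model_times))]
        resampled.append(Trajectory(tr.id, model_times, frames, tr.label))
    return TrajectoryEnsemble(resampled, model_times)


# ---------------------------------------------------------------------------
# Signal matrices


def read_signal_matrix(path, sigma_path=None, units: str = "percent"):
    """Read a signal matrix (and optional per-point standard deviations).

    Format: delimited text; first row is the time grid (first cell ignored),
    first column the q grid, body the values.  Returns ``SignalMatrix`` or
    ``(SignalMatrix, sigma_array)`` when ``sigma_path`` is given.
    """

    def _read(p):
        # correctly rounded float parsing so write -> read is an identity
        rows = [
            ln for ln in Path(p).read_text().splitlines()
            if ln.strip() and not ln.lstrip().startswith("#")
        ]
        if len(rows) < 2:
            raise ValueError(f"{p}: no data rows")
        delim = "\t" if "\t" in rows[0] else ("," if "," in rows[0] else None)
        split = (lambda s: s.split(delim)) if delim else str.split
        t = np.array(split(rows[0])[1:], dtype=float)
        body = np.array([split(r) for r in rows[1:]], dtype=float)
        return body[:, 0], t, body[:, 1:]

    q, t, vals = _read(path)
    if np.any(np.diff(q) <= 0) or np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: q and t axes must be strictly increasing")
    sig = SignalMatrix(q, t, vals, units=units)
    if sigma_path is None:
        return sig
    q2, t2, sigma = _read(sigma_path)
    if sigma.shape != vals.shape:
        raise ValueError(
            f"sigma shape {sigma.shape} does not match signal shape {vals.shape}"
        )
    if not (np.allclose(q2, q) and np.allclose(t2, t)):
        raise ValueError("sigma grids differ from signal grids")
    return sig, sigma


def write_signal_matrix(signal: SignalMatrix, path) -> None:
    """Write a signal matrix in the format :func:`read_signal_matrix` reads.

    Full float precision is preserved (round-trip identity).
    """
    with open(path, "w") as fh:
        fh.write("q_t\t" + "\t".join(f"{t:.17g}" for t in signal.t_values) + "\n")
        for qi, row in zip(signal.q_values, signal.values):
            fh.write(f"{qi:.17g}\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")
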