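"""Atomic species and embedded scattering-factor tables.

Elastic X-ray form factors use the standard Cromer-Mann four-Gaussian
parameterization

    f_A(q) = sum_i a_i exp(-b_i (q / 4 pi)^2) + c,

with coefficients shipped as package data (valid to q = 25 1/A).  Inelastic
(incoherent) scattering functions S_A(q) are shipped as sampled tables and
evaluated with shape-preserving (monotone cubic) interpolation; queries
outside the tabulated q range raise rather than extrapolate silently.

All momentum transfers are in inverse Angstrom.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

__all__ = ["AtomicSpecies", "get_species", "supported_elements", "UnsupportedSpeciesError"]

Q_MAX_TABLE = 25.0  # upper validity bound of the embedded parameterizations


class UnsupportedSpeciesError(KeyError):
    """Element has no embedded form-factor data."""


@dataclass(frozen=True)
class AtomicSpecies:
    """One chemical element with its elastic and inelastic scattering factors.

    Attributes
    ----------
    symbol : str
        Element symbol, e.g. ``"C"``.
    Z : int
        Atomic number.
    elastic_coeffs : tuple
        Cromer-Mann ``(a[4], b[4], c)`` parameters of :math:`f_A(q)`.
    inelastic_q : ndarray
        q nodes (1/A) of the sampled incoherent scattering function.
    inelastic_s : ndarray
        Sampled :math:`S_A(q)` values at those nodes.
    """

    symbol: str
    Z: int
    elastic_coeffs: tuple
    inelastic_q: np.ndarray = field(repr=False)
    inelastic_s: np.ndarray = field(repr=False)

    def __post_init__(self):
        if self.Z < 1:
            raise ValueError(f"atomic number must be >= 1, got {self.Z}")

    def f_elastic(self, q):
        """Elastic X-ray form factor f_A(q); f_A(0) = Z to parameterization accuracy."""
        a, b, c = self.elastic_coeffs
        s2 = (np.asarray(q, dtype=float) / (4.0 * np.pi)) ** 2
        out = np.full_like(s2, c, dtype=float)
        for ai, bi in zip(a, b):
            out += ai * np.exp(-bi * s2)
        return out

    @property
    def _inelastic_interp(self):
        # cached per-instance monotone interpolant
        interp = getattr(self, "_interp_cache", None)
        if interp is None:
            interp = PchipInterpolator(self.inelastic_q, self.inelastic_s)
            object.__setattr__(self, "_interp_cache", interp)
        return interp

    def s_inelastic(self, q):
        """Incoherent scattering function S_A(q), interpolated between table nodes.

        Raises
        ------
        ValueError
            If any q lies outside the tabulated range (no silent extrapolation).
        """
        q = np.asarray(q, dtype=float)
        lo, hi = self.inelastic_q[0], self.inelastic_q[-1]
        if np.any(q < lo) or np.any(q > hi):
            raise ValueError(
                f"q outside inelastic table range [{lo}, {hi}] for {self.symbol}"
            )
        return np.clip(self._inelastic_interp(q), 0.0, None)


def _data_text(name: str) -> str:
    return importlib.resources.files("tbfit.data").joinpath(name).read_text()


@lru_cache(maxsize=1)
def _load_tables():
    import io

    cm = pd.read_csv(io.StringIO(_data_text("cromer_mann.tsv")), sep="\t", comment="#")
    inel = pd.read_csv(
        io.StringIO(_data_text("incoherent_scattering.tsv")), sep="\t", comment="#"
    )
    species = {}
    qs = inel["q"].to_numpy(dtype=float)
    for _, row in cm.iterrows():
        sym = row["symbol"]
        coeffs = (
            tuple(row[f"a{i}"] for i in range(1, 5)),
            tuple(row[f"b{i}"] for i in range(1, 5)),
            float(row["c"]),
        )
        species[sym] = AtomicSpecies(
            symbol=sym,
            Z=int(row["Z"]),
            elastic_coeffs=coeffs,
            inelastic_q=qs,
            inelastic_s=inel[sym].to_numpy(dtype=float),
        )
    return species


def supported_elements():
    """Sorted list of element symbols with embedded scattering data."""
    return sorted(_load_tables())


def get_species(symbol: str) -> AtomicSpecies:
    """Look up the :class:`AtomicSpecies` for an element symbol."""
    try:
        return _load_tables()[symbol]
    except KeyError:
        raise UnsupportedSpeciesError(
            f"no embedded form-factor data for element {symbol!r}; "
            f"supported: {supported_elements()}"
        ) from None
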