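"""Confidence weighting, the least-squares target function, and fit-quality
metrics.

The target function is a confidence-weighted sum of squared residuals

    F(w, c) = sum_ij p_ij [ %dI_mod(q_i, t_j; w, c) - %dI_exp(q_i, t_j) ]^2,

with a per-point confidence matrix p in [0, 1] encoding experimental trust
(points with poor statistics get small weight; a threshold p_conf_min zeroes
points below it, excluding them from the fit entirely).

Fit quality is reported through four complementary measures: the relative
absolute error RAE (summed absolute misfit of the optimized model divided by
that of the unweighted model; < 1 means the optimization improved on plain
theory), the RMSE over the (q, t) grid, the variance of the weight vector,
and the Euclidean distance D_b of a solution from the overall best weights.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .ensemble_io import SignalMatrix

__all__ = [
    "ConfidenceMatrix",
    "FitReport",
    "DegenerateObjectiveWarning",
    "normalize_weights",
    "confidence_from_sigma",
    "target_function",
    "integrated_signal",
    "rae",
    "rmse",
    "weight_variance",
    "distance_to_best",
    "class_totals",
    "branching_ratio",
]

WEIGHT_SUM_TOL = 1e-9


class DegenerateObjectiveWarning(UserWarning):
    """The confidence matrix masks every data point."""


def normalize_weights(w, check_only: bool = False) -> np.ndarray:
    """Validate a weight vector (nonnegative, summing to 1 within 1e-9)."""
    w = np.asarray(w, dtype=float)
    if np.any(w < -1e-12):
        raise ValueError("weights must be nonnegative")
    s = w.sum()
    if abs(s - 1.0) > WEIGHT_SUM_TOL:
        raise ValueError(f"weights must sum to 1 within {WEIGHT_SUM_TOL}; got {s!r}")
    return w if check_only else w / s


@dataclass
class ConfidenceMatrix:
    """Per-point confidence weights in [0, 1] on a (q, t) grid.

    Entries below ``p_conf_min`` are set to exactly zero on construction,
    excluding those points from the objective.
    """

    values: np.ndarray
    p_conf_min: float = 0.0

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if np.any(vals < 0) or np.any(vals > 1):
            raise ValueError("confidence entries must lie in [0, 1]")
        if not 0.0 <= self.p_conf_min < 1.0:
            raise ValueError("p_conf_min must lie in [0, 1)")
        vals = vals.copy()
        vals[vals < self.p_conf_min] = 0.0
        self.values = vals
        if not np.any(vals > 0):
            warnings.warn(
                "confidence matrix masks every data point; the objective is "
                "degenerate",
                DegenerateObjectiveWarning,
                stacklevel=2,
            )

    def with_threshold(self, p_conf_min: float) -> "ConfidenceMatrix":
        """Re-threshold the (unmasked) confidence values."""
        return ConfidenceMatrix(self.values, p_conf_min)

    @classmethod
    def ones(cls, shape) -> "ConfidenceMatrix":
        return cls(np.ones(shape))


def confidence_from_sigma(sigma) -> ConfidenceMatrix:
    """Confidence from per-point standard deviations: p proportional to 1/sigma,
    rescaled so the most trusted point has confidence 1.

    Nonpositive or missing (NaN) sigmas mark invalid points and get
    confidence 0.
    """
    sigma = np.asarray(sigma, dtype=float)
    valid = np.isfinite(sigma) & (sigma > 0)
    if not np.any(valid):
        raise ValueError("no valid sigma entries; cannot build a confidence matrix")
    p = np.zeros_like(sigma)
    p[valid] = 1.0 / sigma[valid]
    p /= p.max()
    return ConfidenceMatrix(p)


def _check_grids(a: SignalMatrix, b: SignalMatrix):
    if a.values.shape != b.values.shape or not (
        np.allclose(a.q_values, b.q_values) and np.allclose(a.t_values, b.t_values)
    ):
        raise ValueError("signal matrices are not on identical (q, t) grids")


def target_function(
    model: SignalMatrix, exp: SignalMatrix, confidence: ConfidenceMatrix | None = None
) -> float:
    """Confidence-weighted sum of squared residuals F."""
    _check_grids(model, exp)
    resid = model.values - exp.values
    if confidence is None:
        return float(np.sum(resid**2))
    if confidence.values.shape != resid.shape:
        raise ValueError("confidence shape does not match the signal grids")
    return float(np.sum(confidence.values * resid**2))


def integrated_signal(signal: SignalMatrix, q_lo: float, q_hi: float) -> np.ndarray:
    """Net integrated signal over a q window: per-time trapezoidal integral
    of the signal over [q_lo, q_hi] (window endpoints snapped to the grid)."""
    if not q_lo < q_hi:
        raise ValueError("empty q window")
    mask = (signal.q_values >= q_lo - 1e-12) & (signal.q_values <= q_hi + 1e-12)
    if mask.sum() < 2:
        raise ValueError(
            f"q window [{q_lo}, {q_hi}] contains fewer than two grid points"
        )
    return np.trapezoid(signal.values[mask], signal.q_values[mask], axis=0)


def rae(model: SignalMatrix, theory_unweighted: SignalMatrix, exp: SignalMatrix) -> float:
    """Relative absolute error: summed |model - exp| over summed |theory - exp|.

    Grid-size independent; values below 1 mean the optimized model improves
    on the unweighted theory.
    """
    _check_grids(model, exp)
    _check_grids(theory_unweighted, exp)
    denom = np.sum(np.abs(theory_unweighted.values - exp.values))
    if denom == 0:
        raise ZeroDivisionError(
            "unweighted theory equals the experiment; RAE is undefined"
        )
    return float(np.sum(np.abs(model.values - exp.values)) / denom)


def rmse(model: SignalMatrix, exp: SignalMatrix) -> float:
    """Root mean squared pointwise deviation over the (q, t) grid."""
    _check_grids(model, exp)
    return float(np.sqrt(np.mean((model.values - exp.values) ** 2)))


def weight_variance(w) -> float:
    """Mean squared deviation of the weights from their mean."""
    w = np.asarray(w, dtype=float)
    return float(np.mean((w - w.mean()) ** 2))


def distance_to_best(w_b, w_best) -> float:
    """Euclidean distance between two weight vectors (plots use its square)."""
    w_b = np.asarray(w_b, dtype=float)
    w_best = np.asarray(w_best, dtype=float)
    if w_b.shape != w_best.shape:
        raise ValueError("weight vectors must have equal length")
    return float(np.linalg.norm(w_b - w_best))


def class_totals(weights, labels) -> dict:
    """Sum of weights per class label (bookkeeping of a fitted weight table)."""
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(labels):
        raise ValueError("weights and labels must have equal length")
    out: dict = {}
    for w, lab in zip(weights, labels):
        out[lab] = out.get(lab, 0.0) + float(w)
    return out


def branching_ratio(weights, labels, numerator: str, denominator: str) -> float:
    """Ratio of total weight in one class to another (e.g. triplet : singlet)."""
    totals = class_totals(weights, labels)
    if totals.get(denominator, 0.0) == 0.0:
        raise ZeroDivisionError(f"no weight in class {denominator!r}")
    return totals.get(numerator, 0.0) / totals[denominator]


@dataclass
class FitReport:
    """Fit-quality summary for one optimization."""

    F: float
    rae: float | None = None
    rmse: float | None = None
    var_w: float | None = None
    d_b: float | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.F < 0:
            raise ValueError("target function must be nonnegative")

    def to_dict(self) -> dict:
        d = {"F": self.F, "RAE": self.rae, "RMSE": self.rmse, "Var_w": self.var_w,
             "D_b": self.d_b}
        d.update(self.extras)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    def __str__(self) -> str:
        parts = [f"F = {self.F:.6g}"]
        for name, val in (("RAE", self.rae), ("RMSE", self.rmse),
                          ("Var_w", self.var_w), ("D_b", self.d_b)):
            if val is not None:
                parts.append(f"{name} = {val:.6g}")
        return ", ".join(parts)
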