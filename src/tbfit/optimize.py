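"""Constrained optimization of trajectory weights and global parameters.

One-step mode (good data): for each candidate set of global parameters
``c = (t0, tau_c, gamma-or-x)`` on a scan grid, the trajectory weights are
fitted by bound-constrained trust-region-reflective least squares from a
pool of Monte-Carlo-sampled initial weight vectors; the best converged
minimum over the pool and the scan is the candidate global solution.

Two-step mode (noisy data): step one fixes ``(t0, tau_c, gamma)`` by fitting
the q-integrated signal of an *equally weighted* ensemble (the early-time
wavepacket has dispersed little, so equal weights are a good approximation
near t = t0); step two re-optimizes the weights with gamma freed, and flags
the solution when the re-optimized gamma drifts far from its step-one value
(a self-consistency check on the step-one parameters).

Weights are handled on the box [0, 1]^N and renormalized to the simplex
inside every model evaluation, which enforces sum(w) = 1 exactly and makes
the objective invariant to the overall scale of w.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .apparatus import (
    GlobalParams,
    ReferenceSignal,
    _extend_for_mapping,
    convolve_time,
    map_to_experiment,
    percent_difference_model,
)
from .ensemble_io import SignalMatrix, TrajectoryEnsemble
from .metrics import (
    ConfidenceMatrix,
    FitReport,
    integrated_signal,
    rae,
    rmse,
    weight_variance,
)
from .scattering import ProbeKind, trajectory_signal

__all__ = [
    "OptimizationConfig",
    "OptimizationResult",
    "OptimizationError",
    "ForwardCache",
    "sample_initial_weights",
    "optimize_weights",
    "scan_globals",
    "step1_fit_globals",
    "step2_fit_weights",
    "iterative_resampling",
]


class OptimizationError(RuntimeError):
    """No initial condition converged, or the objective is degenerate."""


@dataclass
class OptimizationConfig:
    """Settings for the weight optimization and global-parameter scans.

    ``n_init`` Monte-Carlo initial weight vectors are drawn per scan cell
    from ``seed``.  Convergence tolerances are passed to the trust-region
    solver.  ``report_threshold`` selects the dominant trajectories listed in
    results (weight above it, default 1%).
    """

    n_init: int = 32
    seed: int = 0
    t0_grid: tuple = (0.0,)
    tau_c_grid: tuple = (100.0,)
    scale_grid: tuple = (0.05,)  # gamma values (uniform mode) or x values (profile)
    p_conf_min: float = 0.0
    ftol: float = 1e-8
    xtol: float = 1e-8
    gtol: float = 1e-8
    max_nfev: int | None = None
    report_threshold: float = 0.01
    bin_width: float = 25.0
    gamma_drift_tol: float = 0.25  # relative drift flagged in step two
    n_step2_candidates: int = 1

    def __post_init__(self):
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")
        for name in ("t0_grid", "tau_c_grid", "scale_grid"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be nonempty")
        for name in ("ftol", "xtol", "gtol"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class OptimizationResult:
    """Outcome of one weight optimization (possibly the best of a scan)."""

    weights: np.ndarray
    params: GlobalParams
    F: float
    report: FitReport
    records: list = field(default_factory=list)  # per-init convergence records
    trajectory_ids: list | None = None
    labels: list | None = None
    report_threshold: float = 0.01

    @property
    def dominant(self) -> list:
        """Trajectories above the report threshold: (id, label, weight), sorted."""
        idx = np.argsort(self.weights)[::-1]
        out = []
        for i in idx:
            if self.weights[i] <= self.report_threshold:
                break
            tid = self.trajectory_ids[i] if self.trajectory_ids else str(i)
            lab = self.labels[i] if self.labels else ""
            out.append((tid, lab, float(self.weights[i])))
        return out


def sample_initial_weights(n_init: int, n_tbf: int, seed) -> np.ndarray:
    """Monte-Carlo pool of initial weight vectors.

    Each component is drawn i.i.d. uniform on [0, 1], then the vector is
    normalized onto the simplex.  Returns an ``(n_init, n_tbf)`` array.
    """
    if n_init < 1 or n_tbf < 1:
        raise ValueError("n_init and n_tbf must be >= 1")
    rng = np.random.default_rng(seed)
    pool = rng.uniform(size=(n_init, n_tbf))
    return pool / pool.sum(axis=1, keepdims=True)


def iterative_resampling(
    previous: OptimizationResult,
    n_init: int,
    seed,
    jitter: float = 0.1,
    fraction_perturbed: float = 0.5,
) -> np.ndarray:
    """Refreshed initial-weight pool biased toward a previous best solution.

    A fraction of the pool is the incumbent best with componentwise uniform
    jitter of amplitude ``jitter`` (clipped at 0, renormalized); the rest are
    fresh uniform simplex draws.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    n_perturb = int(round(fraction_perturbed * n_init))
    base = np.asarray(previous.weights, dtype=float)
    perturbed = base[None, :] + jitter * rng.uniform(-1, 1, size=(n_perturb, base.size))
    perturbed = np.clip(perturbed, 0.0, None)
    # a fully zeroed draw would be unnormalizable; fall back to the incumbent
    dead = perturbed.sum(axis=1) == 0
    perturbed[dead] = base
    perturbed /= perturbed.sum(axis=1, keepdims=True)
    fresh = rng.uniform(size=(n_init - n_perturb, base.size))
    fresh /= fresh.sum(axis=1, keepdims=True)
    return np.concatenate([perturbed, fresh], axis=0)


class ForwardCache:
    """Precomputed per-trajectory building blocks of the forward model.

    The model percent-difference signal is linear in the weights:

        %dI_mod(w, c) = scale * Gamma(q) * sum_n w_n D_n(q, t'; t0, tau_c),

    so per-trajectory processed signals D_n (unit excitation fraction) form
    a design matrix.  This cache stores the per-trajectory percent-difference
    matrices on the model grid (independent of c) and assembles the design
    for any (t0, tau_c) on demand.
    """

    def __init__(
        self,
        ensemble: TrajectoryEnsemble,
        reference: ReferenceSignal,
        q_grid,
        exp_times,
        probe=ProbeKind.xray,
        bin_width: float = 25.0,
    ):
        self.ensemble = ensemble
        self.reference = reference
        self.q_grid = np.asarray(q_grid, dtype=float)
        self.exp_times = np.asarray(exp_times, dtype=float)
        self.probe = ProbeKind(probe)
        self.bin_width = float(bin_width)
        unit = GlobalParams(t0=0.0, tau_c=1.0, gamma=1.0)
        self._pct = [
            percent_difference_model(
                trajectory_signal(tr, self.q_grid, self.probe), reference, unit
            )
            for tr in ensemble.trajectories
        ]
        self._design_cache: dict = {}

    @property
    def n_tbf(self) -> int:
        return self.ensemble.n_tbf

    @property
    def shape(self):
        return (self.q_grid.size, self.exp_times.size)

    def design(self, t0: float, tau_c: float, gamma_profile=None) -> np.ndarray:
        """Design matrix D of shape (Nq * Nt_exp, N_TBF) at unit scale.

        Column n is the per-trajectory percent-difference signal pushed
        through convolution, time-zero shift, and binning, multiplied by the
        gamma(q) profile when one is given (the scalar gamma or x is applied
        by the caller).
        """
        key = (round(float(t0), 9), round(float(tau_c), 9), id(gamma_profile))
        if key in self._design_cache:
            return self._design_cache[key]
        cols = []
        for pct in self._pct:
            ext = _extend_for_mapping(pct, t0, self.exp_times, self.bin_width, tau_c)
            conv = convolve_time(ext, tau_c)
            mapped = map_to_experiment(conv, t0, self.exp_times, self.bin_width)
            vals = mapped.values
            if gamma_profile is not None:
                qn, gv = gamma_profile
                vals = vals * np.interp(self.q_grid, qn, gv)[:, None]
            cols.append(vals.ravel())
        D = np.stack(cols, axis=1)
        self._design_cache[key] = D
        return D

    def model_signal(self, weights, params: GlobalParams) -> SignalMatrix:
        """Model percent-difference signal on the experimental grid."""
        D = self.design(params.t0, params.tau_c, params.gamma_q)
        vals = params.scale * (D @ np.asarray(weights, float)).reshape(self.shape)
        return SignalMatrix(self.q_grid, self.exp_times, vals, units="percent")


def _solve_one(
    D, y, sqrtp, w0, scale0, free_scale, scale_bounds, cfg: OptimizationConfig
):
    """One trust-region-reflective solve from one initial weight vector.

    Variables are the box-constrained weights (renormalized to the simplex
    inside the model) plus, when ``free_scale``, the scalar excitation
    parameter.  Analytic Jacobian.
    """
    n = D.shape[1]
    w0 = np.asarray(w0, dtype=float)
    if np.any(w0 < 0) or w0.sum() <= 0:
        raise ValueError("initial weights must be nonnegative with positive sum")
    w0 = w0 / w0.sum()  # objective is scale-invariant in w; start on the simplex

    if free_scale:
        x0 = np.concatenate([w0, [scale0]])
        lb = np.zeros(n + 1)
        ub = np.ones(n + 1)
        lb[-1], ub[-1] = scale_bounds
        x0[-1] = np.clip(x0[-1], lb[-1] + 1e-12, ub[-1] - 1e-12)
    else:
        x0, lb, ub = w0.copy(), np.zeros(n), np.ones(n)
    # strictly interior start for the reflective solver
    x0[:n] = np.clip(x0[:n], 1e-10, 1.0)

    def unpack(x):
        w = x[:n]
        s = w.sum()
        g = x[n] if free_scale else scale0
        return w, s, g

    def residual(x):
        w, s, g = unpack(x)
        return sqrtp * (g * (D @ (w / s)) - y)

    def jacobian(x):
        w, s, g = unpack(x)
        v = w / s
        Dv = D @ v
        J = np.empty((D.shape[0], x.size))
        J[:, :n] = (sqrtp * g / s)[:, None] * (D - Dv[:, None])
        if free_scale:
            J[:, n] = sqrtp * Dv
        return J

    sol = least_squares(
        residual,
        x0,
        jac=jacobian,
        bounds=(lb, ub),
        method="trf",
        ftol=cfg.ftol,
        xtol=cfg.xtol,
        gtol=cfg.gtol,
        max_nfev=cfg.max_nfev,
    )
    w, s, g = unpack(sol.x)
    return w / s, float(g), 2.0 * float(sol.cost), sol


def optimize_weights(
    exp: SignalMatrix,
    confidence: ConfidenceMatrix | None,
    cache: ForwardCache,
    params: GlobalParams,
    cfg: OptimizationConfig,
    free_gamma: bool = False,
    initial_pool: np.ndarray | None = None,
) -> OptimizationResult:
    """Fit the trajectory weights at fixed (t0, tau_c) from a Monte-Carlo pool.

    Minimizes the confidence-weighted residual between the model and the
    experimental percent-difference signal over the weight simplex, with the
    scalar excitation parameter (gamma, or x in profile mode) optionally
    freed.  Converged candidates are ranked by the target function F, with
    ties broken by lower RAE, then lower weight variance, then init order;
    non-converged inits are recorded, never silently dropped.
    """
    if confidence is not None and not np.any(confidence.values > 0):
        raise OptimizationError(
            "degenerate objective: the confidence matrix masks every point"
        )
    D = cache.design(params.t0, params.tau_c, params.gamma_q)
    y = exp.values.ravel()
    p = np.ones_like(y) if confidence is None else confidence.values.ravel()
    sqrtp = np.sqrt(p)

    if initial_pool is None:
        initial_pool = sample_initial_weights(cfg.n_init, cache.n_tbf, cfg.seed)
    scale_bounds = (0.0, 1.0) if params.gamma is not None else (1e-6, np.inf)

    # unweighted (equal-weight) theory signal for RAE
    n = cache.n_tbf
    theory = cache.model_signal(np.full(n, 1.0 / n), params)

    records, candidates = [], []
    for i, w0 in enumerate(initial_pool):
        try:
            w_hat, g_hat, F, sol = _solve_one(
                D, y, sqrtp, w0, params.scale, free_gamma, scale_bounds, cfg
            )
        except Exception as err:  # pragma: no cover - solver failures are rare
            records.append({"init": i, "converged": False, "status": None,
                            "message": str(err)})
            continue
        converged = sol.status > 0
        records.append(
            {"init": i, "converged": converged, "status": int(sol.status),
             "nfev": int(sol.nfev), "F": F, "gamma": g_hat}
        )
        if converged:
            candidates.append((F, i, w_hat, g_hat))
    if not candidates:
        raise OptimizationError(
            f"no initial condition converged out of {len(initial_pool)}; "
            f"records: {records}"
        )

    def rank_key(cand):
        F, i, w_hat, g_hat = cand
        fitted = cache.model_signal(w_hat, params.with_scale(g_hat))
        return (F, rae(fitted, theory, exp), weight_variance(w_hat), i)

    best_F = min(c[0] for c in candidates)
    near = [c for c in candidates if c[0] <= best_F * (1 + 1e-9) + 1e-15]
    F, i_best, w_best, g_best = min(near, key=rank_key) if len(near) > 1 else near[0]

    final_params = params.with_scale(g_best) if free_gamma else params
    model = cache.model_signal(w_best, final_params)
    theory_final = cache.model_signal(np.full(n, 1.0 / n), final_params)
    report = FitReport(
        F=F,
        rae=rae(model, theory_final, exp),
        rmse=rmse(model, exp),
        var_w=weight_variance(w_best),
        extras={"gamma": g_best if free_gamma else params.scale,
                "n_converged": len(candidates), "n_init": len(initial_pool),
                "best_init": i_best},
    )
    return OptimizationResult(
        weights=w_best,
        params=final_params,
        F=F,
        report=report,
        records=records,
        trajectory_ids=cache.ensemble.ids,
        labels=cache.ensemble.labels,
        report_threshold=cfg.report_threshold,
    )


def scan_globals(
    exp: SignalMatrix,
    confidence: ConfidenceMatrix | None,
    cache: ForwardCache,
    cfg: OptimizationConfig,
    gamma_profile=None,
    free_gamma: bool = False,
) -> tuple:
    """One-step global optimization: full factorial scan over
    (t0, tau_c, gamma-or-x), weight optimization in every cell.

    Returns ``(best_result, cells)`` where ``cells`` is a list of per-cell
    records (parameters, F, RAE, result or error) suitable for
    convergence-versus-parameter tables.  A failed cell is recorded, not
    fatal; the scan fails only if every cell fails.
    """
    cells = []
    best = None
    for t0, tau_c, scale in itertools.product(
        cfg.t0_grid, cfg.tau_c_grid, cfg.scale_grid
    ):
        if gamma_profile is not None:
            params = GlobalParams(t0=t0, tau_c=tau_c, gamma_q=gamma_profile, x=scale)
        else:
            params = GlobalParams(t0=t0, tau_c=tau_c, gamma=scale)
        try:
            res = optimize_weights(exp, confidence, cache, params, cfg, free_gamma)
        except OptimizationError as err:
            cells.append({"t0": t0, "tau_c": tau_c, "scale": scale,
                          "error": str(err)})
            continue
        cells.append(
            {"t0": t0, "tau_c": tau_c, "scale": scale, "F": res.F,
             "RAE": res.report.rae, "RMSE": res.report.rmse, "result": res}
        )
        if best is None or res.F < best.F:
            best = res
    if best is None:
        raise OptimizationError("every scan cell failed")
    return best, cells


def step1_fit_globals(
    exp: SignalMatrix,
    cache: ForwardCache,
    q_window: tuple,
    cfg: OptimizationConfig,
    gamma_profile=None,
) -> list:
    """Step one of the two-step optimization: fix (t0, tau_c, gamma) on the
    q-integrated signal of the equally weighted ensemble.

    For each (t0, tau_c) on the scan grids, the scalar excitation fraction
    is fitted by one-dimensional least squares between the integrated
    experimental signal and the integrated equal-weight model, which is
    linear in gamma (closed form).  Returns records ranked by the sum of
    squared errors, each with the fitted :class:`GlobalParams` plus RAE- and
    RMSE-style consistency measures on the integrated series.
    """
    q_lo, q_hi = q_window
    y = integrated_signal(exp, q_lo, q_hi)
    n = cache.n_tbf
    w_eq = np.full(n, 1.0 / n)
    records = []
    for t0, tau_c in itertools.product(cfg.t0_grid, cfg.tau_c_grid):
        if gamma_profile is not None:
            unit = GlobalParams(t0=t0, tau_c=tau_c, gamma_q=gamma_profile, x=1.0)
        else:
            unit = GlobalParams(t0=t0, tau_c=tau_c, gamma=1.0)
        m = integrated_signal(cache.model_signal(w_eq, unit), q_lo, q_hi)
        mm = float(m @ m)
        if mm <= 0:
            raise OptimizationError(
                "flat equal-weight model in the integration window; the "
                "excitation fraction is unidentifiable"
            )
        g = max(0.0, float(m @ y) / mm)
        resid = g * m - y
        sse = float(resid @ resid)
        denom = float(np.sum(np.abs(y - m))) or np.inf
        records.append(
            {"t0": t0, "tau_c": tau_c, "gamma": g, "sse": sse,
             "rae_int": float(np.sum(np.abs(resid))) / denom,
             "rmse_int": float(np.sqrt(np.mean(resid**2))),
             "params": unit.with_scale(g)}
        )
    records.sort(key=lambda r: r["sse"])
    return records


def _validation_misfit(
    exp: SignalMatrix,
    confidence: ConfidenceMatrix | None,
    cache: ForwardCache,
    params: GlobalParams,
    cfg: OptimizationConfig,
) -> float:
    """Held-out misfit of one global-parameter candidate.

    Weights (with the scalar excitation parameter freed) are fitted on the
    even q rows only and scored on the odd rows.  With gamma free the
    training objective is convex, so a single start suffices.  Ranking
    candidate (t0, tau_c) sets by held-out misfit avoids the bias of raw F:
    refitted weights partially absorb a wrong time zero or instrument
    response by overfitting noise, which held-out rows expose.
    """
    D = cache.design(params.t0, params.tau_c, params.gamma_q)
    y = exp.values.ravel()
    p = (np.ones_like(y) if confidence is None else confidence.values.ravel())
    sqrtp = np.sqrt(p)
    nq, nt = cache.shape
    train = np.zeros((nq, nt), dtype=bool)
    train[::2, :] = True
    tr = train.ravel()
    va = ~tr
    n = cache.n_tbf
    scale_bounds = (0.0, 1.0) if params.gamma is not None else (1e-6, np.inf)
    w_hat, g_hat, _, _ = _solve_one(
        D[tr], y[tr], sqrtp[tr], np.full(n, 1.0 / n), params.scale,
        True, scale_bounds, cfg,
    )
    resid = sqrtp[va] * (g_hat * (D[va] @ w_hat) - y[va])
    return float(resid @ resid)


def step2_fit_weights(
    exp: SignalMatrix,
    confidence: ConfidenceMatrix | None,
    cache: ForwardCache,
    step1_records: list,
    cfg: OptimizationConfig,
) -> OptimizationResult:
    """Step two: weight optimization with gamma freed, seeded from the best
    step-one parameter sets, plus a gamma self-consistency verdict.

    The top ``cfg.n_step2_candidates`` step-one parameter sets are compared
    by held-out validation misfit (the integrated step-one signal
    constrains tau_c only weakly, and raw in-sample F is biased toward
    whatever cell the weights overfit); the winning set gets the full
    Monte-Carlo-initialized weight optimization.  The verdict compares the
    re-optimized gamma with its step-one value: a relative drift above
    ``cfg.gamma_drift_tol`` flags the step-one parameters as suspect.
    """
    if not step1_records:
        raise ValueError("step-one ranking is empty")
    candidates = step1_records[: max(1, cfg.n_step2_candidates)]
    if len(candidates) > 1:
        scored = [
            (_validation_misfit(exp, confidence, cache, rec["params"], cfg), i)
            for i, rec in enumerate(candidates)
        ]
        val_f, i_best = min(scored)
        best_rec = candidates[i_best]
        val_table = [
            {"t0": candidates[i]["t0"], "tau_c": candidates[i]["tau_c"],
             "val_F": v}
            for v, i in sorted(scored)
        ]
    else:
        best_rec = candidates[0]
        val_table = []

    res = optimize_weights(
        exp, confidence, cache, best_rec["params"], cfg, free_gamma=True
    )
    g0, g1 = best_rec["params"].scale, res.params.scale
    drift = abs(g1 - g0) / g0 if g0 > 0 else np.inf
    res.report.extras.update(
        {"gamma_step1": g0, "gamma_step2": g1, "gamma_drift": drift,
         "gamma_drift_flag": bool(drift > cfg.gamma_drift_tol),
         "t0": best_rec["params"].t0, "tau_c": best_rec["params"].tau_c,
         "validation_table": val_table}
    )
    if res.report.extras["gamma_drift_flag"]:
        warnings.warn(
            f"re-optimized excitation fraction drifted {drift:.1%} from its "
            f"step-one value; the step-one global parameters may be "
            f"suboptimal",
            UserWarning,
            stacklevel=2,
        )
    return res
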