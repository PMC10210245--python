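"""Model/Results interface for trajectory-basis inversion.

:class:`TrajectoryBasisModel` bundles the data (an experimental
percent-difference signal with optional per-point uncertainties), the
trajectory basis (a labelled ensemble), the unpumped reference, and the
apparatus configuration.  Its :meth:`~TrajectoryBasisModel.fit` dispatches
the one-step (scan of global parameters, good data) or two-step (global
parameters first, weights second; noisy data) optimization and returns a
:class:`TrajectoryBasisResults` carrying the fitted weights, global
parameters, diagnostics, and a ``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .apparatus import GlobalParams, ReferenceSignal, forward_model
from .ensemble_io import (
    SignalMatrix,
    TrajectoryEnsemble,
    build_ensemble,
    read_manifest,
    read_signal_matrix,
    read_trajectory_xyz,
)
from .metrics import (
    ConfidenceMatrix,
    class_totals,
    confidence_from_sigma,
    distance_to_best,
)
from .optimize import (
    ForwardCache,
    OptimizationConfig,
    OptimizationResult,
    scan_globals,
    step1_fit_globals,
    step2_fit_weights,
)
from .scattering import ProbeKind

__all__ = ["TrajectoryBasisModel", "TrajectoryBasisResults"]


class TrajectoryBasisModel:
    """Weighted trajectory-basis model of a pump-probe scattering signal.

    Parameters
    ----------
    exp_signal : SignalMatrix
        Experimental percent-difference signal on its (q, t') grid.
    ensemble : TrajectoryEnsemble
        Labelled trajectory basis on the model time grid.
    reference : ReferenceSignal
        Unpumped reference intensity I_off(q) on the experimental q grid.
    sigma : ndarray, optional
        Per-point standard deviations; used to build the confidence matrix
        when ``confidence`` is not given.
    confidence : ConfidenceMatrix, optional
        Explicit per-point confidence weights (overrides ``sigma``).
    probe : {"xray", "electron"}
        Scattering probe; decides the form-factor convention.
    bin_width : float
        Experimental time-bin width (fs) for the box average.
    gamma_profile : (ndarray, ndarray), optional
        Sampled q-dependent excitation-fraction profile ``(q, gamma)``; when
        given, the scan's scale parameter is the uniform factor x.
    """

    def __init__(
        self,
        exp_signal: SignalMatrix,
        ensemble: TrajectoryEnsemble,
        reference: ReferenceSignal,
        *,
        sigma=None,
        confidence: ConfidenceMatrix | None = None,
        probe=ProbeKind.xray,
        bin_width: float = 25.0,
        gamma_profile=None,
    ):
        self.exp_signal = exp_signal
        self.ensemble = ensemble
        self.reference = reference
        self.probe = ProbeKind(probe)
        self.bin_width = float(bin_width)
        self.gamma_profile = gamma_profile
        if confidence is not None:
            self.confidence = confidence
        elif sigma is not None:
            self.confidence = confidence_from_sigma(sigma)
        else:
            self.confidence = None
        self._cache = ForwardCache(
            ensemble,
            reference,
            exp_signal.q_values,
            exp_signal.t_values,
            probe=self.probe,
            bin_width=self.bin_width,
        )

    @classmethod
    def from_files(
        cls,
        manifest_path,
        signal_path,
        reference_xyz_path,
        *,
        sigma_path=None,
        model_times=None,
        probe=ProbeKind.xray,
        bin_width: float = 25.0,
        gamma_profile_path=None,
        edge_policy: str = "hold",
    ) -> "TrajectoryBasisModel":
        """Build a model from on-disk inputs (manifest, signal, reference XYZ)."""
        entries = read_manifest(manifest_path)
        trajectories = [
            read_trajectory_xyz(path, label, id=tid) for tid, path, label in entries
        ]
        if model_times is None:
            model_times = trajectories[0].times
        ensemble = build_ensemble(trajectories, model_times, edge_policy=edge_policy)
        out = read_signal_matrix(signal_path, sigma_path=sigma_path)
        sig, sigma = out if sigma_path is not None else (out, None)
        ref_traj = read_trajectory_xyz(reference_xyz_path, label="reference")
        ref = (
            ReferenceSignal.from_geometry(ref_traj.frames[0], sig.q_values, probe)
            if len(ref_traj.frames) == 1
            else ReferenceSignal.from_geometries(ref_traj.frames, sig.q_values, probe)
        )
        gamma_profile = None
        if gamma_profile_path is not None:
            arr = np.loadtxt(gamma_profile_path)
            gamma_profile = (arr[:, 0], arr[:, 1])
        return cls(
            sig, ensemble, ref, sigma=sigma, probe=probe, bin_width=bin_width,
            gamma_profile=gamma_profile,
        )

    # -- forward simulation -------------------------------------------------

    def forward(self, weights, params: GlobalParams) -> SignalMatrix:
        """Model percent-difference signal on the experimental grid."""
        return self._cache.model_signal(np.asarray(weights, float), params)

    def forward_full(self, weights, params: GlobalParams) -> SignalMatrix:
        """Same as :meth:`forward` but through the uncached pipeline."""
        return forward_model(
            self.ensemble, weights, params, self.reference,
            self.exp_signal.q_values, self.exp_signal.t_values,
            probe=self.probe, bin_width=self.bin_width,
        )

    # -- fitting -------------------------------------------------------------

    def fit(
        self,
        method: str = "one_step",
        config: OptimizationConfig | None = None,
        q_window: tuple | None = None,
        free_gamma: bool = False,
    ) -> "TrajectoryBasisResults":
        """Fit the trajectory weights and global parameters.

        ``method="one_step"``: full factorial scan over the config's
        (t0, tau_c, scale) grids with per-cell weight optimization.
        ``method="two_step"``: integrated-signal fit of the globals followed
        by weight optimization with gamma freed; ``q_window`` selects the
        high-confidence integration band (defaults to the q range whose
        confidence-weighted absolute signal is strongest).
        """
        cfg = config or OptimizationConfig()
        conf = self.confidence
        if conf is not None and cfg.p_conf_min > 0:
            conf = conf.with_threshold(cfg.p_conf_min)
        if method == "one_step":
            best, cells = scan_globals(
                self.exp_signal, conf, self._cache, cfg,
                gamma_profile=self.gamma_profile, free_gamma=free_gamma,
            )
            scan_records = [
                {k: v for k, v in c.items() if k != "result"} for c in cells
            ]
            step1 = None
        elif method == "two_step":
            window = q_window or self.default_q_window()
            step1 = step1_fit_globals(
                self.exp_signal, self._cache, window, cfg,
                gamma_profile=self.gamma_profile,
            )
            best = step2_fit_weights(self.exp_signal, conf, self._cache, step1, cfg)
            scan_records = [
                {k: v for k, v in r.items() if k != "params"} for r in step1
            ]
        else:
            raise ValueError(f"unknown method {method!r}")
        return TrajectoryBasisResults(self, best, cfg, method, scan_records)

    def default_q_window(self) -> tuple:
        """Integration band for the step-one fit: the contiguous q range where
        the time-summed confidence-weighted |signal| exceeds half its max."""
        weight = (
            self.confidence.values if self.confidence is not None
            else np.ones_like(self.exp_signal.values)
        )
        strength = np.sum(weight * np.abs(self.exp_signal.values), axis=1)
        strong = strength >= 0.5 * strength.max()
        idx = np.flatnonzero(strong)
        lo, hi = idx.min(), idx.max()
        if hi == lo:  # widen a single-point band to a valid window
            lo, hi = max(0, lo - 1), min(len(strength) - 1, hi + 1)
        q = self.exp_signal.q_values
        return float(q[lo]), float(q[hi])


class TrajectoryBasisResults:
    """Fitted weights, global parameters, and diagnostics of one inversion."""

    def __init__(self, model, best: OptimizationResult, config, method, scan_records):
        self.model = model
        self.best = best
        self.config = config
        self.method = method
        self.scan_records = scan_records

    # -- estimates ----------------------------------------------------------

    @property
    def weights(self) -> pd.Series:
        return pd.Series(
            self.best.weights, index=self.model.ensemble.ids, name="weight"
        )

    @property
    def params(self) -> GlobalParams:
        return self.best.params

    @property
    def fit_report(self):
        return self.best.report

    @property
    def F(self) -> float:
        return self.best.F

    def dominant_trajectories(self) -> pd.DataFrame:
        """Trajectories above the report threshold (default 1%), best first."""
        return pd.DataFrame(
            self.best.dominant, columns=["trajectory_id", "label", "weight"]
        )

    def class_fractions(self) -> dict:
        """Total fitted weight per class label."""
        return class_totals(self.best.weights, self.model.ensemble.labels)

    def distance_from(self, other_weights) -> float:
        """Euclidean distance D_b of another weight vector from this solution."""
        return distance_to_best(other_weights, self.best.weights)

    def fitted_signal(self) -> SignalMatrix:
        return self.model.forward(self.best.weights, self.best.params)

    def resid(self) -> np.ndarray:
        return self.fitted_signal().values - self.model.exp_signal.values

    # -- presentation --------------------------------------------------------

    def summary(self) -> str:
        p = self.best.params
        lines = [
            "Trajectory-basis inversion results",
            "=" * 46,
            f"method:            {self.method}",
            f"trajectories:      {self.model.ensemble.n_tbf}"
            f" ({', '.join(f'{k}: {v}' for k, v in self._label_counts().items())})",
            f"probe:             {self.model.probe.value}",
            f"t0:                {p.t0:.3g} fs",
            f"tau_c (FWHM):      {p.tau_c:.4g} fs",
            (
                f"gamma:             {p.gamma:.4g}" if p.gamma is not None
                else f"gamma(q) scale x:  {p.x:.4g}"
            ),
            f"target function F: {self.best.F:.6g}",
            f"RAE:               {self.best.report.rae:.4g}",
            f"RMSE:              {self.best.report.rmse:.4g}",
            f"Var_w:             {self.best.report.var_w:.4g}",
            "",
            f"dominant trajectories (weight > "
            f"{self.best.report_threshold:.0%}):",
        ]
        for tid, lab, w in self.best.dominant:
            lines.append(f"  {tid:<16s} {lab:<14s} {w:7.2%}")
        fracs = self.class_fractions()
        lines.append("")
        lines.append(
            "class fractions:   "
            + ", ".join(f"{k} {v:.1%}" for k, v in sorted(fracs.items()))
        )
        extras = self.best.report.extras
        if "gamma_drift" in extras:
            lines.append(
                f"gamma drift (step1 -> step2): {extras['gamma_drift']:.1%}"
                + ("  [FLAGGED]" if extras.get("gamma_drift_flag") else "")
            )
        return "\n".join(lines)

    def _label_counts(self) -> dict:
        counts: dict = {}
        for lab in self.model.ensemble.labels:
            counts[lab] = counts.get(lab, 0) + 1
        return counts

    def plot_fit(self, q_indices=None, ax=None):
        """Overlay experimental and fitted time traces at selected q values."""
        import matplotlib.pyplot as plt

        exp = self.model.exp_signal
        fit = self.fitted_signal()
        if q_indices is None:
            q_indices = np.linspace(0, len(exp.q_values) - 1, 4, dtype=int)
        if ax is None:
            _, ax = plt.subplots()
        for qi in q_indices:
            (line,) = ax.plot(
                exp.t_values, exp.values[qi], "o", ms=3,
                label=f"exp q={exp.q_values[qi]:.2f}",
            )
            ax.plot(fit.t_values, fit.values[qi], "-", color=line.get_color())
        ax.set_xlabel("delay (fs)")
        ax.set_ylabel("%ΔI")
        ax.legend(fontsize=7)
        return ax

    def save(self, out_dir) -> None:
        """Write the weight table (TSV), fit report (JSON), and scan table."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {
                "trajectory_id": self.model.ensemble.ids,
                "label": self.model.ensemble.labels,
                "weight": self.best.weights,
            }
        ).to_csv(out / "weights.tsv", sep="\t", index=False)
        report = dict(self.best.report.to_dict())
        p = self.best.params
        report.update(
            {"t0": p.t0, "tau_c": p.tau_c, "scale": p.scale, "method": self.method}
        )
        (out / "fit_report.json").write_text(json.dumps(report, indent=2))
        pd.DataFrame(self.scan_records).to_csv(
            out / "scan_table.tsv", sep="\t", index=False
        )
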