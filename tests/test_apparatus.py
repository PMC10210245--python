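"""Apparatus mapping: percent difference, instrument-response convolution,
experimental-axis binning, and the composed forward model."""

import numpy as np
import pytest
from scipy.special import erf

import tbfit as tb
from tbfit.apparatus import (
    FWHM_TO_SIGMA,
    GlobalParams,
    ReferenceSignal,
    convolve_time,
    forward_model,
    map_to_experiment,
    percent_difference_model,
)
from tbfit.ensemble_io import SignalMatrix


def test_global_params_validation():
    with pytest.raises(ValueError, match="tau_c"):
        GlobalParams(t0=0, tau_c=-5, gamma=0.1)
    with pytest.raises(ValueError, match="exactly one"):
        GlobalParams(t0=0, tau_c=10)
    with pytest.raises(ValueError, match="exactly one"):
        GlobalParams(t0=0, tau_c=10, gamma=0.1, gamma_q=([1, 2], [0.1, 0.2]), x=1.0)
    with pytest.raises(ValueError, match="x > 0"):
        GlobalParams(t0=0, tau_c=10, gamma_q=([1, 2], [0.1, 0.2]))


def test_gamma_profile_interpolation_and_scale():
    p = GlobalParams(t0=0, tau_c=10, gamma_q=([1.0, 3.0], [0.02, 0.06]), x=2.0)
    np.testing.assert_allclose(p.gamma_eff([2.0]), [2.0 * 0.04])
    assert p.scale == 2.0


def test_percent_difference_zero_cases():
    q = np.array([1.0, 2.0, 3.0])
    ref = ReferenceSignal(q, np.array([10.0, 20.0, 30.0]))
    same = SignalMatrix(q, [0.0, 1.0], np.tile(ref.i_off[:, None], 2))
    params = GlobalParams(t0=0, tau_c=10, gamma=0.5)
    assert np.all(percent_difference_model(same, ref, params).values == 0)

    other = SignalMatrix(q, [0.0, 1.0], np.tile((2 * ref.i_off)[:, None], 2))
    zero_gamma = GlobalParams(t0=0, tau_c=10, gamma=0.0)
    assert np.all(percent_difference_model(other, ref, zero_gamma).values == 0)


def test_percent_difference_linear_in_gamma():
    q = np.array([1.0, 2.0])
    ref = ReferenceSignal(q, np.array([5.0, 8.0]))
    sig = SignalMatrix(q, [0.0], np.array([[6.0], [7.0]]))
    v1 = percent_difference_model(sig, ref, GlobalParams(0, 10, gamma=0.1)).values
    v2 = percent_difference_model(sig, ref, GlobalParams(0, 10, gamma=0.2)).values
    np.testing.assert_allclose(v2, 2 * v1)
    # explicit value: 100 * 0.1 * (6/5 - 1) = 2
    assert v1[0, 0] == pytest.approx(2.0)


def test_reference_must_be_positive():
    with pytest.raises(ValueError, match="positive"):
        ReferenceSignal(np.array([1.0, 2.0]), np.array([1.0, 0.0]))


def test_convolution_delta_limit():
    """A kernel narrower than the grid step leaves the signal unchanged."""
    t = np.arange(0.0, 100.0, 4.0)
    sig = SignalMatrix([1.0], t, np.sin(t / 7.0)[None, :])
    out = convolve_time(sig, 1e-4)
    np.testing.assert_allclose(out.values, sig.values)


def test_convolution_preserves_constant_rows_away_from_edges():
    t = np.arange(0.0, 800.0, 4.0)
    sig = SignalMatrix([1.0], t, np.full((1, t.size), 3.7))
    out = convolve_time(sig, 100.0)
    # interior: unit-area kernel reproduces the constant exactly
    interior = out.values[0, 60:-60]
    np.testing.assert_allclose(interior, 3.7, rtol=1e-12)
    # leading edge is depressed by the zero pre-excitation padding
    assert out.values[0, 0] < 3.7 / 1.9


def test_convolution_of_step_matches_error_function():
    """A unit step smoothed by a Gaussian IRF follows the closed-form erf
    profile; at the step the value is half the step height (within 1%)."""
    dt, tau_c = 0.5, 100.0
    t = np.arange(-400.0, 400.0, dt)
    step = (t >= 0).astype(float)
    sig = SignalMatrix([1.0], t, step[None, :])
    out = convolve_time(sig, tau_c)
    sigma = tau_c * FWHM_TO_SIGMA
    expected = 0.5 * (1 + erf(t / (sigma * np.sqrt(2))))
    i0 = np.searchsorted(t, 0.0)
    assert out.values[0, i0] == pytest.approx(0.5, abs=0.005)
    np.testing.assert_allclose(out.values[0, 200:-200], expected[200:-200], atol=5e-3)


def test_convolution_requires_uniform_grid():
    sig = SignalMatrix([1.0], [0.0, 1.0, 3.0], np.zeros((1, 3)))
    with pytest.raises(ValueError, match="uniform"):
        convolve_time(sig, 50.0)


def test_convolution_preserves_integral_of_compact_row():
    t = np.arange(0.0, 1200.0, 4.0)
    bump = np.exp(-0.5 * ((t - 600) / 40.0) ** 2)
    sig = SignalMatrix([1.0], t, bump[None, :])
    out = convolve_time(sig, 80.0)
    assert np.trapezoid(out.values[0], t) == pytest.approx(
        np.trapezoid(bump, t), rel=1e-6
    )


def test_map_to_experiment_pointwise_when_bin_equals_step():
    """With a locally linear signal, bin width = grid step reproduces the
    pointwise samples."""
    t = np.arange(0.0, 100.0, 2.0)
    vals = (0.3 * t + 1.0)[None, :]
    sig = SignalMatrix([1.0], t, vals)
    out = map_to_experiment(sig, t0=0.0, exp_times=t[5:10], bin_width=2.0)
    np.testing.assert_allclose(out.values[0], vals[0, 5:10])


def test_map_to_experiment_shifts_linear_signal_exactly():
    t = np.arange(0.0, 200.0, 2.0)
    sig = SignalMatrix([1.0], t, (0.5 * t - 3.0)[None, :])
    exp_times = np.array([50.0, 75.0, 100.0])
    t0 = -13.0
    out = map_to_experiment(sig, t0=t0, exp_times=exp_times, bin_width=10.0)
    np.testing.assert_allclose(out.values[0], 0.5 * (exp_times - t0) - 3.0)


def test_map_to_experiment_bin_average_of_ramp_is_midpoint():
    t = np.arange(0.0, 100.0, 2.0)
    sig = SignalMatrix([1.0], t, (2.0 * t)[None, :])
    out = map_to_experiment(sig, t0=0.0, exp_times=[50.0], bin_width=24.0)
    assert out.values[0, 0] == pytest.approx(100.0)


def test_map_to_experiment_coverage_error_lists_span():
    t = np.arange(0.0, 100.0, 2.0)
    sig = SignalMatrix([1.0], t, np.zeros((1, t.size)))
    with pytest.raises(ValueError, match="does not cover"):
        map_to_experiment(sig, t0=0.0, exp_times=[120.0], bin_width=10.0)


def test_forward_model_one_hot_matches_single_trajectory(
    tiny_ensemble, tiny_reference, tiny_q, tiny_exp_times, tiny_params
):
    n = tiny_ensemble.n_tbf
    one_hot = np.zeros(n)
    one_hot[3] = 1.0
    full = forward_model(
        tiny_ensemble, one_hot, tiny_params, tiny_reference, tiny_q, tiny_exp_times
    )
    from tbfit.ensemble_io import TrajectoryEnsemble

    single = TrajectoryEnsemble(
        [tiny_ensemble.trajectories[3]], tiny_ensemble.model_times
    )
    direct = forward_model(
        single, np.array([1.0]), tiny_params, tiny_reference, tiny_q, tiny_exp_times
    )
    np.testing.assert_allclose(full.values, direct.values)


def test_forward_model_affine_in_weights(
    tiny_ensemble, tiny_reference, tiny_q, tiny_exp_times, tiny_params
):
    rng = np.random.default_rng(1)
    n = tiny_ensemble.n_tbf
    w1, w2 = rng.dirichlet(np.ones(n)), rng.dirichlet(np.ones(n))
    a = 0.4

    def f(w):
        return forward_model(
            tiny_ensemble, w, tiny_params, tiny_reference, tiny_q, tiny_exp_times
        ).values

    np.testing.assert_allclose(
        f(a * w1 + (1 - a) * w2), a * f(w1) + (1 - a) * f(w2), rtol=1e-10, atol=1e-12
    )


def test_gamma_scaling_commutes_with_convolution(
    tiny_ensemble, tiny_reference, tiny_q, tiny_exp_times, tiny_truth_weights
):
    """Both operations are linear: scaling gamma after the pipeline equals
    running the pipeline at the scaled gamma."""
    p1 = tb.GlobalParams(t0=-10.0, tau_c=50.0, gamma=0.03)
    p2 = tb.GlobalParams(t0=-10.0, tau_c=50.0, gamma=0.06)
    f1 = forward_model(
        tiny_ensemble, tiny_truth_weights, p1, tiny_reference, tiny_q, tiny_exp_times
    )
    f2 = forward_model(
        tiny_ensemble, tiny_truth_weights, p2, tiny_reference, tiny_q, tiny_exp_times
    )
    np.testing.assert_allclose(f2.values, 2 * f1.values, rtol=1e-12, atol=1e-12)


def test_forward_model_reproduces_noiseless_pseudo_experiment(tiny_pseudo,
                                                             tiny_ensemble,
                                                             tiny_reference,
                                                             tiny_q,
                                                             tiny_exp_times,
                                                             tiny_truth_weights,
                                                             tiny_params):
    signal, _sigma, _conf, truth = tiny_pseudo
    again = forward_model(
        tiny_ensemble, tiny_truth_weights, tiny_params, tiny_reference,
        tiny_q, tiny_exp_times,
    )
    np.testing.assert_array_equal(signal.values, again.values)
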