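"""Weight optimization: Monte-Carlo pools, trust-region fits, global scans,
and the two-step procedure, cross-checked against a convex NNLS oracle."""

import numpy as np
import pytest
from scipy.optimize import nnls

import tbfit as tb
from tbfit.metrics import ConfidenceMatrix
from tbfit.optimize import (
    OptimizationConfig,
    OptimizationError,
    iterative_resampling,
    optimize_weights,
    sample_initial_weights,
    scan_globals,
    step1_fit_globals,
    step2_fit_weights,
)


def test_initial_weight_pool_is_deterministic():
    a = sample_initial_weights(8, 5, seed=42)
    b = sample_initial_weights(8, 5, seed=42)
    np.testing.assert_array_equal(a, b)
    c = sample_initial_weights(8, 5, seed=43)
    assert not np.array_equal(a, c)


def test_initial_weight_pool_single_trajectory():
    pool = sample_initial_weights(5, 1, seed=0)
    np.testing.assert_array_equal(pool, np.ones((5, 1)))


def test_initial_weight_pool_symmetry():
    """Normalized uniform draws are exchangeable: each component has mean
    1/n_tbf (checked within 3 standard errors over 10^4 draws)."""
    pool = sample_initial_weights(10_000, 4, seed=7)
    np.testing.assert_allclose(pool.sum(axis=1), 1.0)
    means = pool.mean(axis=0)
    se = pool.std(axis=0, ddof=1) / np.sqrt(pool.shape[0])
    assert np.all(np.abs(means - 0.25) < 3 * se)


def test_iterative_resampling_determinism_and_zero_jitter():
    prev = tb.OptimizationResult(
        weights=np.array([0.7, 0.2, 0.1]),
        params=tb.GlobalParams(0, 10, gamma=0.1),
        F=1.0,
        report=tb.FitReport(F=1.0),
    )
    pool = iterative_resampling(prev, n_init=6, seed=5, jitter=0.0)
    np.testing.assert_allclose(pool[:3], np.tile(prev.weights, (3, 1)))
    again = iterative_resampling(prev, n_init=6, seed=5, jitter=0.0)
    np.testing.assert_array_equal(pool, again)


@pytest.fixture(scope="module")
def tiny_noiseless_fit(tiny_pseudo, tiny_cache, tiny_params):
    signal, _sigma, _conf, truth = tiny_pseudo
    cfg = OptimizationConfig(n_init=8, seed=2)
    res = optimize_weights(signal, None, tiny_cache, tiny_params, cfg,
                           free_gamma=True)
    return res, truth


def test_noiseless_round_trip_recovers_weights(tiny_noiseless_fit):
    res, truth = tiny_noiseless_fit
    assert np.max(np.abs(res.weights - truth["weights"])) <= 1e-3
    assert res.params.gamma == pytest.approx(truth["params"].gamma, rel=1e-2)


def test_fit_agrees_with_nnls_oracle(tiny_pseudo, tiny_cache, tiny_params):
    """Dual route: with gamma free the objective is convex in u = gamma*w,
    so scipy's NNLS solves it exactly; the trust-region fit must match."""
    signal, *_ = tiny_pseudo
    rng = np.random.default_rng(0)
    noisy = signal.copy_with(values=signal.values + rng.normal(0, 0.05,
                                                               signal.values.shape))
    cfg = OptimizationConfig(n_init=8, seed=2)
    res = optimize_weights(noisy, None, tiny_cache, tiny_params, cfg,
                           free_gamma=True)
    D = tiny_cache.design(tiny_params.t0, tiny_params.tau_c)
    u, _ = nnls(D, noisy.values.ravel())
    w_oracle = u / u.sum()
    assert np.max(np.abs(res.weights - w_oracle)) < 5e-3
    assert res.params.gamma == pytest.approx(u.sum(), rel=1e-2)


def test_scale_invariance_of_initial_weights(tiny_pseudo, tiny_cache, tiny_params):
    """Multiplying an initial weight vector by a positive constant changes
    nothing: weights are renormalized inside every model evaluation."""
    signal, *_ = tiny_pseudo
    cfg = OptimizationConfig(n_init=2, seed=2)
    pool = sample_initial_weights(2, tiny_cache.n_tbf, seed=9)
    r1 = optimize_weights(signal, None, tiny_cache, tiny_params, cfg,
                          initial_pool=pool)
    r2 = optimize_weights(signal, None, tiny_cache, tiny_params, cfg,
                          initial_pool=7.3 * pool)
    np.testing.assert_allclose(r1.weights, r2.weights, atol=1e-9)
    assert r1.F == pytest.approx(r2.F, rel=1e-9, abs=1e-12)


def test_best_f_is_minimum_over_converged_inits(tiny_pseudo, tiny_cache,
                                                tiny_params):
    signal, *_ = tiny_pseudo
    cfg = OptimizationConfig(n_init=6, seed=1)
    res = optimize_weights(signal, None, tiny_cache, tiny_params, cfg)
    converged = [r["F"] for r in res.records if r["converged"]]
    assert converged and res.F == pytest.approx(min(converged))
    assert len(res.records) == 6  # nothing silently dropped


def test_duplicate_trajectories_give_equal_f_for_any_split(tiny_cache,
                                                           tiny_params,
                                                           tiny_pseudo):
    """The model is linear in w, so weight splits between identical columns
    are exactly degenerate."""
    signal, *_ = tiny_pseudo
    D = tiny_cache.design(tiny_params.t0, tiny_params.tau_c)
    D2 = np.concatenate([D, D[:, :1]], axis=1)  # duplicate first trajectory
    y = signal.values.ravel()
    w = np.zeros(D2.shape[1])
    for split in (0.0, 0.3, 0.7):
        w[:] = 0
        w[0], w[-1] = 1 - split, split
        f = np.sum((tiny_params.gamma * (D2 @ w) - y) ** 2)
        if split == 0.0:
            f_ref = f
        assert f == pytest.approx(f_ref, rel=1e-12)


def test_fully_masked_objective_raises(tiny_pseudo, tiny_cache, tiny_params):
    signal, *_ = tiny_pseudo
    with pytest.warns(Warning):
        conf = ConfidenceMatrix(np.full(signal.values.shape, 0.4),
                                p_conf_min=0.5)
    with pytest.raises(OptimizationError, match="degenerate"):
        optimize_weights(signal, conf, tiny_cache, tiny_params,
                         OptimizationConfig(n_init=2, seed=0))


def test_scan_single_cell_equals_direct_optimization(tiny_pseudo, tiny_cache,
                                                     tiny_params):
    signal, *_ = tiny_pseudo
    cfg = OptimizationConfig(
        n_init=4, seed=3, t0_grid=(tiny_params.t0,),
        tau_c_grid=(tiny_params.tau_c,), scale_grid=(tiny_params.gamma,),
    )
    best, cells = scan_globals(signal, None, tiny_cache, cfg)
    direct = optimize_weights(signal, None, tiny_cache, tiny_params, cfg)
    assert len(cells) == 1
    np.testing.assert_allclose(best.weights, direct.weights)
    assert best.F == pytest.approx(direct.F)


def test_scan_recovers_interior_t0(tiny_pseudo, tiny_cache, tiny_params):
    """Synthetic truth generated at a t0 interior to the scan grid: the
    argmin cell must sit within one grid step of it."""
    signal, *_ = tiny_pseudo
    cfg = OptimizationConfig(
        n_init=4, seed=3, t0_grid=(-40.0, -30.0, -20.0, -10.0, 0.0),
        tau_c_grid=(tiny_params.tau_c,), scale_grid=(tiny_params.gamma,),
    )
    best, cells = scan_globals(signal, None, tiny_cache, cfg)
    assert abs(best.params.t0 - tiny_params.t0) <= 10.0


def test_step1_round_trip_on_grid(tiny_ensemble, tiny_reference, tiny_q,
                                  tiny_exp_times, tiny_cache):
    """Equal-weight truth with on-grid (t0, tau_c): step one recovers all
    three global parameters (gamma to solver tolerance)."""
    n = tiny_ensemble.n_tbf
    truth = tb.GlobalParams(t0=-20.0, tau_c=60.0, gamma=0.07)
    spec = tb.PseudoExperimentSpec(
        true_weights=np.full(n, 1.0 / n), true_params=truth,
        q_grid=tiny_q, exp_times=tiny_exp_times, sigma_scale=0.0,
    )
    signal, *_ = tb.make_pseudo_experiment(tiny_ensemble, tiny_reference, spec)
    cfg = OptimizationConfig(
        t0_grid=(-40.0, -20.0, 0.0), tau_c_grid=(30.0, 60.0, 90.0),
    )
    ranked = step1_fit_globals(signal, tiny_cache, (2.0, 6.0), cfg)
    top = ranked[0]
    assert top["t0"] == truth.t0
    assert top["tau_c"] == truth.tau_c
    assert top["gamma"] == pytest.approx(truth.gamma, rel=1e-6)
    assert top["sse"] == pytest.approx(0.0, abs=1e-12)


def test_step1_gamma_linearity(tiny_ensemble, tiny_reference, tiny_q,
                               tiny_exp_times, tiny_cache):
    n = tiny_ensemble.n_tbf
    cfg = OptimizationConfig(t0_grid=(-20.0,), tau_c_grid=(60.0,))
    for gamma in (0.0, 0.03, 0.06):
        truth = tb.GlobalParams(t0=-20.0, tau_c=60.0, gamma=gamma)
        spec = tb.PseudoExperimentSpec(
            true_weights=np.full(n, 1.0 / n), true_params=truth,
            q_grid=tiny_q, exp_times=tiny_exp_times, sigma_scale=0.0,
        )
        signal, *_ = tb.make_pseudo_experiment(tiny_ensemble, tiny_reference, spec)
        ranked = step1_fit_globals(signal, tiny_cache, (2.0, 6.0), cfg)
        assert ranked[0]["gamma"] == pytest.approx(gamma, abs=1e-10)


def test_step2_noiseless_gamma_drift_zero(tiny_ensemble, tiny_reference,
                                          tiny_q, tiny_exp_times, tiny_cache):
    n = tiny_ensemble.n_tbf
    truth = tb.GlobalParams(t0=-20.0, tau_c=60.0, gamma=0.05)
    spec = tb.PseudoExperimentSpec(
        true_weights=np.full(n, 1.0 / n), true_params=truth,
        q_grid=tiny_q, exp_times=tiny_exp_times, sigma_scale=0.0,
    )
    signal, *_ = tb.make_pseudo_experiment(tiny_ensemble, tiny_reference, spec)
    cfg = OptimizationConfig(n_init=4, seed=1, t0_grid=(-20.0,),
                             tau_c_grid=(60.0,))
    ranked = step1_fit_globals(signal, tiny_cache, (2.0, 6.0), cfg)
    res = step2_fit_weights(signal, None, tiny_cache, ranked, cfg)
    assert res.report.extras["gamma_drift"] == pytest.approx(0.0, abs=1e-3)
    assert not res.report.extras["gamma_drift_flag"]


def test_step2_flags_wrong_step1_parameters(tiny_pseudo, tiny_cache):
    """Deliberately wrong t0 from step one: the re-optimized gamma drifts
    and the self-consistency flag fires."""
    signal, *_ = tiny_pseudo
    bad = {"params": tb.GlobalParams(t0=60.0, tau_c=60.0, gamma=0.005),
           "sse": 1.0, "t0": 60.0, "tau_c": 60.0, "gamma": 0.005}
    cfg = OptimizationConfig(n_init=4, seed=1)
    with pytest.warns(UserWarning, match="drifted"):
        res = step2_fit_weights(signal, None, tiny_cache, [bad], cfg)
    assert res.report.extras["gamma_drift_flag"]


def test_one_step_scan_with_gamma_profile_recovers_scale(
    tiny_ensemble, tiny_reference, tiny_q, tiny_exp_times, tiny_truth_weights
):
    """q-dependent excitation-fraction mode: the scan over the uniform scale
    factor x recovers the generating scale on noiseless data."""
    from tbfit.optimize import ForwardCache

    profile = (np.array([0.0, 5.0, 10.0]), np.array([0.05, 0.04, 0.03]))
    truth = tb.GlobalParams(t0=-20.0, tau_c=60.0, gamma_q=profile, x=1.1)
    spec = tb.PseudoExperimentSpec(
        true_weights=tiny_truth_weights, true_params=truth,
        q_grid=tiny_q, exp_times=tiny_exp_times, sigma_scale=0.0,
    )
    signal, *_ = tb.make_pseudo_experiment(tiny_ensemble, tiny_reference, spec)
    cache = ForwardCache(tiny_ensemble, tiny_reference, tiny_q, tiny_exp_times)
    cfg = OptimizationConfig(
        n_init=4, seed=1, t0_grid=(-20.0,), tau_c_grid=(60.0,),
        scale_grid=(0.9, 1.0, 1.1, 1.2),
    )
    best, cells = scan_globals(signal, None, cache, cfg, gamma_profile=profile)
    assert best.params.x == pytest.approx(1.1)
    assert np.max(np.abs(best.weights - tiny_truth_weights)) <= 1e-3
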