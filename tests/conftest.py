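"""Shared fixtures: small toy systems kept deliberately tiny so the unit
suite stays fast; the full-size reference fixture is built only where the
recovery properties require it."""

import numpy as np
import pytest

import tbfit as tb
from tbfit.optimize import ForwardCache


@pytest.fixture(scope="session")
def tiny_spec():
    # 8 trajectories over 300 fs: enough structure for round-trip fits
    return tb.ToyEnsembleSpec(
        n_bound=3, n_dissociative=5, t_max=300.0, dt=4.0, seed=11
    )


@pytest.fixture(scope="session")
def tiny_ensemble(tiny_spec):
    return tb.make_toy_ensemble(tiny_spec)


@pytest.fixture(scope="session")
def tiny_reference(tiny_spec, tiny_q):
    geom = tb.reference_geometry(tiny_spec)
    return tb.ReferenceSignal.from_geometry(geom, tiny_q)


@pytest.fixture(scope="session")
def tiny_q():
    return np.linspace(1.0, 8.0, 40)


@pytest.fixture(scope="session")
def tiny_exp_times():
    return np.arange(-50.0, 275.01, 25.0)


@pytest.fixture(scope="session")
def tiny_cache(tiny_ensemble, tiny_reference, tiny_q, tiny_exp_times):
    return ForwardCache(tiny_ensemble, tiny_reference, tiny_q, tiny_exp_times)


@pytest.fixture(scope="session")
def tiny_truth_weights(tiny_ensemble):
    w = np.zeros(tiny_ensemble.n_tbf)
    w[[1, 4, 6]] = [0.5, 0.3, 0.2]
    return w


@pytest.fixture(scope="session")
def tiny_params():
    return tb.GlobalParams(t0=-20.0, tau_c=60.0, gamma=0.05)


@pytest.fixture(scope="session")
def tiny_pseudo(tiny_ensemble, tiny_reference, tiny_q, tiny_exp_times,
                tiny_truth_weights, tiny_params):
    """Noiseless pseudo-experiment for exact round-trip checks."""
    spec = tb.PseudoExperimentSpec(
        true_weights=tiny_truth_weights,
        true_params=tiny_params,
        q_grid=tiny_q,
        exp_times=tiny_exp_times,
        sigma_scale=0.0,
    )
    return tb.make_pseudo_experiment(tiny_ensemble, tiny_reference, spec)
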