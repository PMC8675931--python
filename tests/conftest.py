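"""Shared fixtures.

The full-scale (42-cell, 900-s) simulations are expensive, so each distinct
configuration is integrated once per session and shared by all tests that
assert on it.
"""

import numpy as np
import pytest

from gmnsim import NetworkConfig, compute_metrics, integrate


def _run_and_measure(cfg, duration_s=900.0, **metric_kw):
    res = integrate(cfg, duration_s=duration_s)
    met = compute_metrics(res.time, res.v_sm, length_cm=cfg.length_cm,
                          **metric_kw)
    return res, met


@pytest.fixture(scope="session")
def default_run():
    return _run_and_measure(NetworkConfig())


@pytest.fixture(scope="session")
def electrical_only_run():
    return _run_and_measure(NetworkConfig(enable_ca=False, enable_ip3=False))


@pytest.fixture(scope="session")
def messenger_only_run():
    return _run_and_measure(NetworkConfig(enable_electrical=False))


@pytest.fixture(scope="session")
def g035_run():
    return _run_and_measure(NetworkConfig(g_icc_icc=0.35))


@pytest.fixture(scope="session")
def pip34_run():
    return _run_and_measure(NetworkConfig(p_ip3=4.0))


@pytest.fixture(scope="session")
def pca_extreme_runs():
    out = {}
    for pca in (0.008, 80.0):
        out[pca] = _run_and_measure(NetworkConfig(p_ca=pca))
    return out


@pytest.fixture(scope="session")
def variability_runs():
    out = {}
    for seed in (1, 2, 3):
        cfg = NetworkConfig(variability=0.2, seed=seed)
        out[seed] = _run_and_measure(cfg)
    return out


@pytest.fixture(scope="session")
def intrinsic_frequencies_42():
    from gmnsim.experiments import intrinsic_frequencies

    return intrinsic_frequencies(NetworkConfig(), duration_s=900.0)


@pytest.fixture(scope="session")
def desk_chain():
    """A small chain for fast qualitative checks."""

    cache = {}

    def run(duration_s=400.0, **overrides):
        key = (duration_s, tuple(sorted(overrides.items())))
        if key not in cache:
            cfg = NetworkConfig(n_units=8, length_cm=8 / 7.0, **overrides)
            cache[key] = _run_and_measure(cfg, duration_s=duration_s,
                                          transient_s=150.0, map_k=8)
        return cache[key]

    return run
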