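"""Unit tests of chain assembly and coupling operators."""

import numpy as np
import pytest

from gmnsim import (ICCParams, NetworkConfig, assemble_rhs, beta_gradient,
                    electrical_coupling, icc_sm_current, messenger_exchange,
                    pack_state, sample_variability, unpack_state)
from gmnsim.icc import default_initial_state as icc_init
from gmnsim.network import NS_ICC, NS_OU, NS_SM
from gmnsim.sm import default_initial_state as sm_init


def _random_packed(n, seed=0):
    rng = np.random.default_rng(seed)
    icc_states = np.empty((n, NS_ICC))
    sm_states = np.empty((n, NS_SM))
    cfg = NetworkConfig(n_units=max(n, 2))
    for i in range(n):
        yi = icc_init(cfg.icc_params, V0=-70 + 8 * rng.standard_normal())
        yi[1:6] *= rng.uniform(0.5, 2.0, 5)
        ys = sm_init(cfg.sm_params, V0=-60 + 8 * rng.standard_normal())
        ys[1] *= rng.uniform(0.5, 2.0)
        icc_states[i] = yi
        sm_states[i] = ys
    return icc_states, sm_states


def test_beta_gradient_endpoints_and_linearity():
    cfg = NetworkConfig(n_units=7, beta_rostral=3e-5, beta_caudal=1e-5)
    b = beta_gradient(cfg)
    assert b[0] == pytest.approx(3e-5)
    assert b[-1] == pytest.approx(1e-5)
    assert b[3] == pytest.approx(2e-5)  # midpoint = arithmetic mean
    assert np.all(np.diff(b) < 0)
    assert np.allclose(np.diff(b, 2), 0.0, atol=1e-20)


def test_beta_gradient_requires_two_cells():
    with pytest.raises(ValueError):
        beta_gradient(NetworkConfig(n_units=1, beta_rostral=2e-5))


def test_electrical_coupling_hand_example():
    I = electrical_coupling([-70.0, -60.0, -50.0], [0.7, 0.7])
    assert I == pytest.approx([-7.0, 0.0, 7.0])


def test_electrical_coupling_uniform_voltage_zero():
    I = electrical_coupling([-55.0] * 6, [0.3] * 5)
    assert np.all(I == 0.0)


def test_electrical_coupling_negative_conductance_error():
    with pytest.raises(ValueError):
        electrical_coupling([-70.0, -60.0], [-0.1])


def test_messenger_exchange_hand_example():
    J = messenger_exchange([1.0, 0.5], [8.0])
    assert J == pytest.approx([-4.0, 4.0])


def test_messenger_exchange_validation():
    with pytest.raises(ValueError):
        messenger_exchange([-0.1, 0.5], [8.0])
    with pytest.raises(ValueError):
        messenger_exchange([0.1, 0.5], [-8.0])
    with pytest.raises(ValueError):
        messenger_exchange([0.1, 0.5], [8.0, 8.0])


def test_icc_sm_current_hand_example():
    assert icc_sm_current(-40.0, -60.0, 0.5) == pytest.approx(10.0)
    assert icc_sm_current(-55.0, -55.0, 0.5) == 0.0
    assert icc_sm_current(-40.0, -60.0, 0.0) == 0.0


def test_sample_variability_identity_at_zero():
    cfg = NetworkConfig(variability=0.0, seed=3)
    out = sample_variability(cfg)
    assert out.g_icc_icc == cfg.g_icc_icc
    assert out.p_ip3 == cfg.p_ip3


def test_sample_variability_support():
    cfg = NetworkConfig(n_units=10001, variability=1.0, seed=11)
    out = sample_variability(cfg)
    g = np.asarray(out.g_icc_icc)
    assert g.shape == (10000,)
    assert g.min() >= 0.0 and g.max() <= 1.4
    assert g.min() < 0.05 and g.max() > 1.35  # support actually filled
    p = np.asarray(out.p_ip3)
    assert p.min() >= 0.0 and p.max() <= 16.0


def test_sample_variability_seed_determinism():
    cfg = NetworkConfig(variability=0.5, seed=42)
    a = sample_variability(cfg)
    b = sample_variability(cfg)
    assert np.array_equal(np.asarray(a.g_icc_icc), np.asarray(b.g_icc_icc))
    assert np.array_equal(np.asarray(a.p_ip3), np.asarray(b.p_ip3))
    c = sample_variability(cfg.replace(seed=43))
    assert not np.array_equal(np.asarray(a.g_icc_icc),
                              np.asarray(c.g_icc_icc))


def test_variability_out_of_range_error():
    with pytest.raises(ValueError):
        NetworkConfig(variability=1.5)


def test_assembled_dimension_default():
    cfg = NetworkConfig()
    assert cfg.n_units * NS_OU == 1554
    f = assemble_rhs(cfg)
    icc_states, sm_states = _random_packed(42)
    y = pack_state(icc_states, sm_states)
    assert y.shape == (1554,)
    assert f(0.0, y).shape == (1554,)


def test_decoupled_limit_equals_independent_units():
    """With every coupling off, the chain derivative equals per-unit
    derivatives computed in isolation."""
    from gmnsim.icc import icc_rhs
    from gmnsim.sm import sm_rhs

    n = 4
    cfg = NetworkConfig(n_units=n, g_icc_icc=0.0, p_ip3=0.0, p_ca=0.0,
                        g_sm_sm=0.0, g_coup=0.0)
    icc_states, sm_states = _random_packed(n, seed=5)
    y = pack_state(icc_states, sm_states)
    d = assemble_rhs(cfg)(0.0, y)
    betas = beta_gradient(cfg)
    for i in range(n):
        want_icc = icc_rhs(icc_states[i],
                           cfg.icc_params.replace(beta=float(betas[i])))
        want_sm = sm_rhs(sm_states[i], cfg.sm_params)
        blk = d[i * NS_OU:(i + 1) * NS_OU]
        assert np.allclose(blk[:NS_ICC], want_icc, rtol=1e-12, atol=1e-12)
        assert np.allclose(blk[NS_ICC:], want_sm, rtol=1e-12, atol=1e-12)


def test_two_cell_swap_symmetry():
    """Two identical cells (same beta) with swapped states give swapped
    derivatives."""
    cfg = NetworkConfig(n_units=2, beta_rostral=2e-5, beta_caudal=2e-5 - 1e-12)
    icc_states, sm_states = _random_packed(2, seed=7)
    y = pack_state(icc_states, sm_states)
    y_sw = pack_state(icc_states[::-1], sm_states[::-1])
    f = assemble_rhs(cfg)
    d = f(0.0, y).reshape(2, NS_OU)
    d_sw = f(0.0, y_sw).reshape(2, NS_OU)
    assert np.allclose(d, d_sw[::-1], rtol=1e-9, atol=1e-12)


def test_disabled_mechanisms_contribute_exactly_zero():
    cfg_off = NetworkConfig(n_units=3, enable_electrical=False,
                            enable_ca=False, enable_ip3=False)
    cfg_zero = NetworkConfig(n_units=3, g_icc_icc=0.0, p_ip3=0.0, p_ca=0.0)
    icc_states, sm_states = _random_packed(3, seed=9)
    y = pack_state(icc_states, sm_states)
    d_off = assemble_rhs(cfg_off)(0.0, y)
    d_zero = assemble_rhs(cfg_zero)(0.0, y)
    assert np.array_equal(d_off, d_zero)


def test_rhs_jacobian_structure_block_tridiagonal():
    """Perturbing one unit's state only changes derivatives of that unit
    and its chain neighbors."""
    n = 5
    cfg = NetworkConfig(n_units=n)
    icc_states, sm_states = _random_packed(n, seed=13)
    y = pack_state(icc_states, sm_states)
    f = assemble_rhs(cfg)
    d0 = f(0.0, y)
    j = 2  # interior unit
    for off in range(NS_OU):
        yp = y.copy()
        yp[j * NS_OU + off] += 1e-6 * (1.0 + abs(yp[j * NS_OU + off]))
        delta = f(0.0, yp) - d0
        changed = np.flatnonzero(delta != 0.0) // NS_OU
        assert set(changed) <= {j - 1, j, j + 1}


def test_pack_unpack_roundtrip():
    icc_states, sm_states = _random_packed(6, seed=21)
    y = pack_state(icc_states, sm_states)
    icc2, sm2 = unpack_state(y, 6)
    assert np.array_equal(icc2, icc_states)
    assert np.array_equal(sm2, sm_states)


def test_pack_unpack_errors():
    with pytest.raises(ValueError):
        unpack_state(np.zeros(10), 2)
    with pytest.raises(ValueError):
        pack_state(np.zeros((2, NS_ICC)), np.zeros((3, NS_SM)))
    with pytest.raises(ValueError):
        pack_state(np.zeros((2, 5)), np.zeros((2, NS_SM)))


def test_config_validation():
    with pytest.raises(ValueError):
        NetworkConfig(beta_rostral=1e-5, beta_caudal=2e-5)
    with pytest.raises(ValueError):
        NetworkConfig(g_coup=-0.1)
    with pytest.raises(ValueError):
        NetworkConfig(n_units=5, g_icc_icc=[0.7, 0.7])  # wrong junction count


def test_config_yaml_roundtrip(tmp_path):
    cfg = NetworkConfig(n_units=5, g_icc_icc=[0.5, 0.6, 0.7, 0.8],
                        variability=0.2, seed=9)
    path = tmp_path / "net.yaml"
    cfg.to_yaml(path)
    back = NetworkConfig.from_yaml(path)
    assert back.n_units == 5
    assert np.allclose(np.asarray(back.g_icc_icc), [0.5, 0.6, 0.7, 0.8])
    assert back.seed == 9
    assert back.icc_params == cfg.icc_params


def test_spatial_resolution_default():
    cfg = NetworkConfig()
    assert cfg.n_units / cfg.length_cm == pytest.approx(7.0)


def test_shipped_network_default_file():
    from importlib.resources import files

    import yaml

    text = files("gmnsim.data").joinpath("network_default.yaml").read_text()
    cfg = NetworkConfig.from_dict(yaml.safe_load(text))
    assert cfg == NetworkConfig()
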