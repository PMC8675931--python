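"""Unit tests of the single-ICC model."""

import math

import numpy as np
import pytest

from gmnsim import ICCParams
from gmnsim.icc import (GATE_NAMES, GATING, N_STATES, STATE_NAMES, TAU_F_CA,
                        default_initial_state, gate_steady_state,
                        gate_time_constants, icc_calcium_rhs,
                        icc_ionic_currents, icc_ip3_rhs, icc_rhs)


@pytest.fixture
def params():
    return ICCParams()


@pytest.fixture
def rest(params):
    return default_initial_state(params)


def test_zero_conductance_identity(params, rest):
    p0 = params.replace(g_ltype=0.0, g_vddr=0.0, g_lva=0.0, g_na=0.0,
                        g_kv=0.0, g_kr=0.0, g_ka=0.0, g_erg=0.0, g_bk=0.0,
                        g_cl=0.0, g_kbg=0.0, g_nscc=0.0)
    I = icc_ionic_currents(rest, p0)
    for name, val in I.items():
        assert val == 0.0, name


def test_driving_force_zero(params):
    # at V equal to a current's reversal potential that current vanishes
    for ename, cnames in [("E_ca", ("I_ltype", "I_vddr", "I_lva")),
                          ("E_na", ("I_na",)),
                          ("E_k", ("I_kv", "I_kr", "I_ka", "I_erg", "I_bk",
                                   "I_kbg")),
                          ("E_nscc", ("I_nscc",)),
                          ("E_cl", ("I_cl",))]:
        y = default_initial_state(params)
        y[0] = getattr(params, ename)
        y[7:] = 0.5  # arbitrary gating
        I = icc_ionic_currents(y, params)
        for c in cnames:
            assert I[c] == pytest.approx(0.0, abs=1e-12), c


def test_currents_term_by_term_oracle(params):
    """Each current recomputed independently from its closed form."""
    p = params
    y = default_initial_state(p)
    y[0] = -45.0
    y[1] = 2.0e-4
    y[2] = 3.5e-4
    y[7:] = np.linspace(0.1, 0.9, 16)
    V, Ca_i, Ca_SS = y[0], y[1], y[2]
    g = dict(zip(GATE_NAMES, y[7:]))

    def sig(v, vh, k):
        return 1.0 / (1.0 + math.exp(-(v - vh) / k))

    expected = {
        "I_ltype": p.g_ltype * g["d_ltype"] * g["f_ltype"] * g["f_ca_ltype"]
                   * (V - p.E_ca),
        "I_vddr": p.g_vddr * g["d_vddr"] * g["f_vddr"] * (V - p.E_ca),
        "I_lva": p.g_lva * g["d_lva"] * g["f_lva"] * (V - p.E_ca),
        "I_na": p.g_na * g["m_na"] ** 3 * g["h_na"] * (V - p.E_na),
        "I_kv": p.g_kv * g["x_kv"] * g["y_kv"] * (V - p.E_k),
        "I_kr": p.g_kr * g["p_kr"] * g["q_kr"] * (V - p.E_k),
        "I_ka": p.g_ka * g["a_ka"] * g["b_ka"] * (V - p.E_k),
        "I_erg": p.g_erg * g["e_erg"] * (V - p.E_k),
        "I_bk": p.g_bk * sig(V, -20, 10) * Ca_i / (Ca_i + p.K_bk)
                * (V - p.E_k),
        "I_cl": p.g_cl * sig(V, -40, 8) * (V - p.E_cl),
        "I_nscc": p.g_nscc * Ca_SS ** 6 / (p.K_nscc ** 6 + Ca_SS ** 6)
                  * (V - p.E_nscc),
        "I_kbg": p.g_kbg * (V - p.E_k),
    }
    I = icc_ionic_currents(y, p)
    for name, val in expected.items():
        assert I[name] == pytest.approx(val, rel=1e-12), name
    assert I["total"] == pytest.approx(sum(expected.values()), rel=1e-12)


def test_nonfinite_state_error_names_variable(params, rest):
    bad = rest.copy()
    bad[3] = np.nan
    with pytest.raises(ValueError, match="IP3"):
        icc_ionic_currents(bad, params)


def test_calcium_rhs_zero_fluxes(params, rest):
    p0 = params.replace(g_ltype=0.0, g_vddr=0.0, k_leak=0.0, v_pmca=0.0)
    y = rest.copy()
    dca_i, _ = icc_calcium_rhs(y, p0, J_g_Ca=0.0)
    assert dca_i == 0.0


def test_calcium_rhs_coupling_linearity(params, rest):
    """d[Ca_i]/dt responds to the external flux as f_c * J."""
    x = 3.7e-3
    d0, _ = icc_calcium_rhs(rest, params, J_g_Ca=0.0)
    d1, _ = icc_calcium_rhs(rest, params, J_g_Ca=x)
    assert d1 - d0 == pytest.approx(params.f_c * x, rel=1e-12)


def test_calcium_rhs_term_by_term_oracle(params):
    """Both derivatives recomputed from the individual flux formulas."""
    p = params
    y = default_initial_state(p)
    y[1], y[2], y[3], y[4], y[5], y[6] = (2e-4, 4e-4, 5e-4, 8e-3, 2e-4, 0.6)
    Ca_i, Ca_SS, IP3, Ca_ER, Ca_MT, h = y[1:7]
    I = icc_ionic_currents(y, p)
    m_inf = (IP3 / (IP3 + p.d1)) * (Ca_SS / (Ca_SS + p.d5))
    inh = p.k_inh / (p.k_inh + Ca_SS)
    J_erout = (p.v_ip3r * (m_inf * h) ** 3 * inh + p.v_erleak) * (Ca_ER - Ca_SS)
    J_serca = p.v_serca * Ca_SS ** 2 / (p.k_serca ** 2 + Ca_SS ** 2)
    J_uni = p.v_uni * Ca_SS ** 4 / (p.k_uni ** 4 + Ca_SS ** 4)
    J_naca = p.v_naca * Ca_MT / (p.k_naca + Ca_MT)
    J_leak = p.k_leak * (Ca_SS - Ca_i)
    J_pmca = p.v_pmca * Ca_i ** 2 / (p.k_pmca ** 2 + Ca_i ** 2)
    want_i = p.f_c * (-(I["I_ltype"] + I["I_vddr"]) / (p.F * p.vol_cyto)
                      + J_leak - J_pmca)
    want_ss = p.f_c * ((J_naca - J_uni) * p.vol_mito / p.vol_ss
                       + (J_erout - J_serca) * p.vol_er / p.vol_ss
                       - J_leak * p.vol_cyto / p.vol_ss)
    got_i, got_ss = icc_calcium_rhs(y, p)
    assert got_i == pytest.approx(want_i, rel=1e-12)
    assert got_ss == pytest.approx(want_ss, rel=1e-12)


def test_calcium_rhs_negative_concentration_error(params, rest):
    bad = rest.copy()
    bad[1] = -1e-6
    with pytest.raises(ValueError):
        icc_calcium_rhs(bad, params)


def test_ip3_fixed_point(params, rest):
    """With synthesis and nonlinear degradation off, IP3* = beta / eta."""
    p0 = params.replace(P_MV=0.0, V_m4=0.0)
    y = rest.copy()
    y[3] = p0.beta / p0.eta
    assert icc_ip3_rhs(y, p0) == pytest.approx(0.0, abs=1e-18)


def test_ip3_absorbing_zero(params, rest):
    p0 = params.replace(P_MV=0.0, beta=0.0)
    y = rest.copy()
    y[3] = 0.0
    assert icc_ip3_rhs(y, p0) == 0.0


def test_ip3_voltage_synthesis_vanishes_at_large_V(params, rest):
    """The even-powered Hill term saturates for |V| large of either sign."""
    p0 = params.replace(eta=0.0, V_m4=0.0, beta=0.0)
    for v in (1e4, -1e4):
        y = rest.copy()
        y[0] = v
        assert abs(icc_ip3_rhs(y, p0)) < 1e-12 * p0.P_MV


def test_rhs_linearity_in_coupling_current(params, rest):
    d0 = icc_rhs(rest, params, I_g=0.0)
    d1 = icc_rhs(rest, params, I_g=2.0)
    # only dV/dt changes, by exactly -I_g / C_m (in mV/ms, i.e. x1e3 mV/s)
    assert d1[0] - d0[0] == pytest.approx(-2.0 / params.C_m * 1e3, rel=1e-12)
    assert np.allclose(d1[1:], d0[1:], rtol=0, atol=0)


def test_rhs_dimension_mismatch(params):
    with pytest.raises(ValueError):
        icc_rhs(np.zeros(22), params)


def test_gate_tables_complete():
    assert len(GATE_NAMES) == 16
    assert len(STATE_NAMES) == N_STATES == 23
    assert set(GATING) == set(GATE_NAMES[:-1])
    taus = gate_time_constants()
    assert taus.shape == (16,)
    assert np.all(taus > 0)
    assert taus[-1] == TAU_F_CA


def test_gate_steady_state_bounds(params):
    for v in (-100.0, -60.0, -20.0, 40.0):
        g = gate_steady_state(v, 1e-4, params)
        assert np.all(g >= 0.0) and np.all(g <= 1.0)


def test_params_validation():
    with pytest.raises(ValueError):
        ICCParams(C_m=0.0)
    with pytest.raises(ValueError):
        ICCParams(eta=-0.1)
    with pytest.raises(ValueError):
        ICCParams(vol_ss=0.0)


def test_params_roundtrip(tmp_path, params):
    path = tmp_path / "p.yaml"
    params.to_yaml(path)
    assert ICCParams.from_yaml(path) == params


def test_shipped_default_file_matches_code_defaults():
    assert ICCParams.default_file() == ICCParams()
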