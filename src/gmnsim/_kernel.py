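"""Compiled right-hand side of the assembled network.

This module holds a numba-jitted evaluation of the full 37*N-dimensional
derivative.  It mirrors, operation for operation, the scalar reference
implementations in :mod:`gmnsim.icc` and :mod:`gmnsim.sm`; the equivalence
is enforced by property tests at 1e-12 relative tolerance.  If numba is not
importable the package falls back to the pure-numpy backend in
:mod:`gmnsim.network`.
"""

from __future__ import annotations

from collections import namedtuple
import dataclasses

import numpy as np

from . import icc as _icc
from . import sm as _sm

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def deco(f):
            return f
        return deco if not (a and callable(a[0])) else a[0]


ICC_FIELDS = tuple(f.name for f in dataclasses.fields(_icc.ICCParams))
SM_FIELDS = tuple(f.name for f in dataclasses.fields(_sm.SMParams))
ICCTuple = namedtuple("ICCTuple", ICC_FIELDS)
SMTuple = namedtuple("SMTuple", SM_FIELDS)

# voltage-gate tables (15 ICC gates, 11 SM gates; Ca-dependent gate last)
_IVH = np.array([_icc.GATING[n][0] for n in _icc.GATE_NAMES[:-1]])
_IK = np.array([_icc.GATING[n][1] for n in _icc.GATE_NAMES[:-1]])
_ISGN = np.array([float(_icc.GATING[n][3]) for n in _icc.GATE_NAMES[:-1]])
_ITAU = _icc.gate_time_constants()
_SVH = np.array([_sm.GATING[n][0] for n in _sm.GATE_NAMES[:-1]])
_SK = np.array([_sm.GATING[n][1] for n in _sm.GATE_NAMES[:-1]])
_SSGN = np.array([float(_sm.GATING[n][3]) for n in _sm.GATE_NAMES[:-1]])
_STAU = _sm.sm_gate_time_constants()

NS_ICC = _icc.N_STATES
NS_SM = _sm.N_STATES
NS_OU = NS_ICC + NS_SM


@njit(cache=True)
def _rhs_core(y, dy, n, beta, g_icc, p_ip3, p_ca, g_sm, g_coup, pi, ps,
              ivh, ik, isgn, itau, svh, sk, ssgn, stau):
    # gap-junction coupling terms, accumulated per cell
    i_g = np.zeros(n)
    j_ca = np.zeros(n)
    j_ip3 = np.zeros(n)
    i_g_sm = np.zeros(n)
    for j in range(n - 1):
        b0 = j * NS_OU
        b1 = (j + 1) * NS_OU
        dv = y[b0] - y[b1]
        i_g[j] += g_icc[j] * dv
        i_g[j + 1] += g_icc[j] * (y[b1] - y[b0])
        dca = y[b0 + 1] - y[b1 + 1]
        j_ca[j] -= p_ca[j] * dca
        j_ca[j + 1] += p_ca[j] * dca
        dip = y[b0 + 3] - y[b1 + 3]
        j_ip3[j] -= p_ip3[j] * dip
        j_ip3[j + 1] += p_ip3[j] * dip
        dvs = y[b0 + NS_ICC] - y[b1 + NS_ICC]
        i_g_sm[j] += g_sm[j] * dvs
        i_g_sm[j + 1] += g_sm[j] * (y[b1 + NS_ICC] - y[b0 + NS_ICC])

    for c in range(n):
        b = c * NS_OU
        V = y[b]
        Ca_i = y[b + 1]
        Ca_SS = y[b + 2]
        IP3 = y[b + 3]
        Ca_ER = y[b + 4]
        Ca_MT = y[b + 5]
        h = y[b + 6]
        d_L = y[b + 7]
        f_L = y[b + 8]
        d_v = y[b + 9]
        f_v = y[b + 10]
        m_na = y[b + 11]
        h_na = y[b + 12]
        x_kv = y[b + 13]
        y_kv = y[b + 14]
        p_kr = y[b + 15]
        q_kr = y[b + 16]
        a_ka = y[b + 17]
        b_ka = y[b + 18]
        e_erg = y[b + 19]
        d_t = y[b + 20]
        f_t = y[b + 21]
        f_ca = y[b + 22]

        I_ltype = pi.g_ltype * d_L * f_L * f_ca * (V - pi.E_ca)
        I_vddr = pi.g_vddr * d_v * f_v * (V - pi.E_ca)
        I_lva = pi.g_lva * d_t * f_t * (V - pi.E_ca)
        I_na = pi.g_na * m_na ** 3 * h_na * (V - pi.E_na)
        I_kv = pi.g_kv * x_kv * y_kv * (V - pi.E_k)
        I_kr = pi.g_kr * p_kr * q_kr * (V - pi.E_k)
        I_ka = pi.g_ka * a_ka * b_ka * (V - pi.E_k)
        I_erg = pi.g_erg * e_erg * (V - pi.E_k)
        p_bk = 1.0 / (1.0 + np.exp(-(V - (-20.0)) / 10.0)) * Ca_i / (Ca_i + pi.K_bk)
        I_bk = pi.g_bk * p_bk * (V - pi.E_k)
        I_cl = pi.g_cl * (1.0 / (1.0 + np.exp(-(V - (-40.0)) / 8.0))) * (V - pi.E_cl)
        s = Ca_SS ** pi.n_nscc / (pi.K_nscc ** pi.n_nscc + Ca_SS ** pi.n_nscc)
        I_nscc = pi.g_nscc * s * (V - pi.E_nscc)
        I_kbg = pi.g_kbg * (V - pi.E_k)
        I_total = (I_ltype + I_vddr + I_lva + I_na + I_kv + I_kr + I_ka
                   + I_erg + I_bk + I_cl + I_nscc + I_kbg)

        m_inf = (IP3 / (IP3 + pi.d1)) * (Ca_SS / (Ca_SS + pi.d5))
        inh = pi.k_inh / (pi.k_inh + Ca_SS)
        J_erout = (pi.v_ip3r * (m_inf * h) ** 3 * inh + pi.v_erleak) * (Ca_ER - Ca_SS)
        J_serca = pi.v_serca * Ca_SS ** 2 / (pi.k_serca ** 2 + Ca_SS ** 2)
        J_uni = pi.v_uni * Ca_SS ** 4 / (pi.k_uni ** 4 + Ca_SS ** 4)
        J_naca = pi.v_naca * Ca_MT / (pi.k_naca + Ca_MT)
        J_leak = pi.k_leak * (Ca_SS - Ca_i)
        J_pmca = pi.v_pmca * Ca_i ** 2 / (pi.k_pmca ** 2 + Ca_i ** 2)

        dy[b] = -(I_total + i_g[c]) / pi.C_m * 1e3
        dy[b + 1] = pi.f_c * (-(I_ltype + I_vddr) / (pi.F * pi.vol_cyto)
                              + J_leak - J_pmca + j_ca[c])
        dy[b + 2] = pi.f_c * ((J_naca - J_uni) * pi.vol_mito / pi.vol_ss
                              + (J_erout - J_serca) * pi.vol_er / pi.vol_ss
                              - J_leak * pi.vol_cyto / pi.vol_ss)
        V8 = V ** 8
        synth = pi.P_MV * (1.0 - V8 / (pi.k_V ** 8 + V8))
        degr4 = pi.V_m4 * IP3 ** 4 / (pi.k_4 ** 4 + IP3 ** 4)
        dy[b + 3] = synth - pi.eta * IP3 - degr4 + beta[c] + j_ip3[c]
        dy[b + 4] = pi.f_c * (J_serca - J_erout)
        dy[b + 5] = pi.f_c * (J_uni - J_naca)
        Q2 = pi.d2 * (IP3 + pi.d1) / (IP3 + pi.d3)
        dy[b + 6] = pi.a2 * (Q2 * (1.0 - h) - Ca_SS * h)
        for gidx in range(15):
            sg = 1.0 / (1.0 + np.exp(-(V - ivh[gidx]) / ik[gidx]))
            if isgn[gidx] < 0:
                sg = 1.0 - sg
            dy[b + 7 + gidx] = (sg - y[b + 7 + gidx]) / itau[gidx]
        fca_inf = 1.0 / (1.0 + (Ca_i / pi.K_fca) ** 2)
        dy[b + 22] = (fca_inf - f_ca) / itau[15]

        # --- SM block -------------------------------------------------
        bs = b + NS_ICC
        Vs = y[bs]
        Cas = y[bs + 1]
        d_c = y[bs + 2]
        f_cl = y[bs + 3]
        d_t2 = y[bs + 4]
        f_t2 = y[bs + 5]
        mna = y[bs + 6]
        hna = y[bs + 7]
        x1 = y[bs + 8]
        x2 = y[bs + 9]
        a1 = y[bs + 10]
        a2g = y[bs + 11]
        m_ns = y[bs + 12]
        f_ca2 = y[bs + 13]

        I_cal = ps.g_cal * d_c * f_cl * f_ca2 * (Vs - ps.E_ca)
        I_lva2 = ps.g_lva * d_t2 * f_t2 * (Vs - ps.E_ca)
        I_na2 = ps.g_na * mna ** 3 * hna * (Vs - ps.E_na)
        I_kv2 = ps.g_kv * x1 * x2 * (Vs - ps.E_k)
        I_ka2 = ps.g_ka * a1 * a2g * (Vs - ps.E_k)
        p_bk2 = 1.0 / (1.0 + np.exp(-(Vs - (-20.0)) / 10.0)) * Cas / (Cas + ps.K_bk)
        I_bk2 = ps.g_bk * p_bk2 * (Vs - ps.E_k)
        I_kbg2 = ps.g_kbg * (Vs - ps.E_k)
        I_bgns = ps.g_bgns * (Vs - ps.E_nscc)
        h_ca = 1.0 / (1.0 + (Cas / ps.K_nscc_ca) ** ps.n_ca)
        I_nscc2 = ps.g_nscc * m_ns * ps.r_lig * h_ca * (Vs - ps.E_nscc)
        I_total2 = (I_cal + I_lva2 + I_na2 + I_kv2 + I_ka2 + I_bk2
                    + I_kbg2 + I_bgns + I_nscc2)
        I_coup = g_coup * (V - Vs)

        dy[bs] = -(I_total2 + i_g_sm[c] - I_coup) / ps.C_m * 1e3
        dy[bs + 1] = ps.f_c * (-(I_cal + I_lva2) / (ps.F * ps.vol_cyto)
                               - ps.v_ex * Cas ** 2 / (ps.k_ex ** 2 + Cas ** 2))
        for gidx in range(11):
            sg = 1.0 / (1.0 + np.exp(-(Vs - svh[gidx]) / sk[gidx]))
            if ssgn[gidx] < 0:
                sg = 1.0 - sg
            dy[bs + 2 + gidx] = (sg - y[bs + 2 + gidx]) / stau[gidx]
        fca_inf2 = 1.0 / (1.0 + (Cas / ps.K_fca) ** 2)
        dy[bs + 13] = (fca_inf2 - f_ca2) / stau[11]


def make_compiled_rhs(n, beta, g_icc, p_ip3, p_ca, g_sm, g_coup,
                      icc_params, sm_params):
    """Return ``f(t, y) -> dy`` evaluating the full network derivative."""
    pi = ICCTuple(**icc_params.to_dict())
    ps = SMTuple(**sm_params.to_dict())
    beta = np.ascontiguousarray(beta, dtype=float)
    g_icc = np.ascontiguousarray(g_icc, dtype=float)
    p_ip3 = np.ascontiguousarray(p_ip3, dtype=float)
    p_ca = np.ascontiguousarray(p_ca, dtype=float)
    g_sm = np.ascontiguousarray(g_sm, dtype=float)

    def f(t, y):
        dy = np.empty_like(y)
        _rhs_core(y, dy, n, beta, g_icc, p_ip3, p_ca, g_sm, float(g_coup),
                  pi, ps, _IVH, _IK, _ISGN, _ITAU, _SVH, _SK, _SSGN, _STAU)
        return dy

    return f
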