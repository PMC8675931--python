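"""Single interstitial-cell-of-Cajal (ICC) pacemaker model.

The ICC is a conductance-based cell with a two-compartment intracellular
Ca2+ system (bulk cytosol and a submembrane pacemaker space exchanging Ca2+
with the endoplasmic reticulum and mitochondria) and an IP3 concentration
driven by membrane potential and by a constant innervation input ``beta``.

Units used throughout the package: time s, voltage mV, current pA,
conductance nS, capacitance pF, concentration mM.  With these units
``pA/pF = mV/ms``, so membrane equations carry an explicit factor of 1e3 to
express dV/dt in mV/s.

State vector layout (23 entries per cell)::

    index  0   V        membrane potential (mV)
    index  1   Ca_i     bulk cytosolic Ca2+ (mM)
    index  2   Ca_SS    submembrane-space Ca2+ (mM)
    index  3   IP3      cytosolic IP3 (mM)
    index  4   Ca_ER    endoplasmic-reticulum Ca2+ (mM)
    index  5   Ca_MT    mitochondrial Ca2+ (mM)
    index  6   h_ip3r   IP3-receptor inactivation gate
    index  7+  gates    16 Hodgkin-Huxley gates, order of GATE_NAMES
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ICCParams",
    "N_STATES",
    "N_GATES",
    "STATE_NAMES",
    "GATE_NAMES",
    "CURRENT_NAMES",
    "gate_steady_state",
    "gate_time_constants",
    "icc_ionic_currents",
    "icc_calcium_rhs",
    "icc_ip3_rhs",
    "icc_rhs",
    "default_initial_state",
]

N_STATES = 23
N_GATES = 16

#: Hodgkin-Huxley gates.  The first 15 are purely voltage dependent; the last
#: (f_ca_ltype) is the Ca2+-dependent inactivation gate of the L-type channel.
GATE_NAMES = (
    "d_ltype", "f_ltype",        # L-type Ca2+ activation / V-inactivation
    "d_vddr", "f_vddr",          # voltage-dependent dihydropyridine-resistant Ca2+
    "m_na", "h_na",              # Na+
    "x_kv", "y_kv",              # delayed-rectifier K+
    "p_kr", "q_kr",              # rapidly-activating K+
    "a_ka", "b_ka",              # A-type K+
    "e_erg",                     # ERG K+ activation
    "d_lva", "f_lva",            # low-voltage-activated Ca2+
    "f_ca_ltype",                # Ca2+-dependent L-type inactivation
)

STATE_NAMES = ("V", "Ca_i", "Ca_SS", "IP3", "Ca_ER", "Ca_MT", "h_ip3r") + GATE_NAMES

#: Voltage-gate kinetics: name -> (V_half mV, slope mV, tau s, +1 act / -1 inact)
GATING = {
    "d_ltype": (-30.0, 4.0, 0.05, +1),
    "f_ltype": (-35.0, 6.0, 3.0, -1),
    "d_vddr": (-45.0, 4.0, 0.10, +1),
    "f_vddr": (-65.0, 6.0, 2.5, -1),
    "m_na": (-38.0, 5.0, 0.02, +1),
    "h_na": (-60.0, 5.0, 0.10, -1),
    "x_kv": (-30.0, 6.0, 0.50, +1),
    "y_kv": (-40.0, 10.0, 5.0, -1),
    "p_kr": (-25.0, 5.0, 0.20, +1),
    "q_kr": (-30.0, 10.0, 1.0, -1),
    "a_ka": (-45.0, 6.0, 0.05, +1),
    "b_ka": (-60.0, 6.0, 0.30, -1),
    "e_erg": (-40.0, 5.0, 1.0, +1),
    "d_lva": (-52.0, 4.0, 0.08, +1),
    "f_lva": (-66.0, 5.0, 1.5, -1),
}

#: Time constant (s) of the Ca2+-dependent L-type inactivation gate.
TAU_F_CA = 0.4

#: The intrinsic membrane currents, in the order returned by
#: :func:`icc_ionic_currents`.  The gap-junction current to the paired
#: smooth-muscle cell is a network-level quantity and is not part of this
#: single-cell list.
CURRENT_NAMES = (
    "I_ltype", "I_vddr", "I_lva", "I_na", "I_kv", "I_kr", "I_ka",
    "I_erg", "I_bk", "I_cl", "I_nscc", "I_kbg",
)


@dataclass(frozen=True)
class ICCParams:
    """Constants of the ICC model.  Defaults are the calibrated values."""

    # membrane & physical constants
    C_m: float = 25.0            # capacitance (pF)
    F: float = 96.485            # Faraday constant (C/mmol)
    vol_cyto: float = 0.7        # cytosolic volume fraction
    vol_ss: float = 0.01         # submembrane-space volume fraction
    vol_er: float = 0.00185      # ER volume fraction
    vol_mito: float = 0.05       # mitochondrial volume fraction
    f_c: float = 0.01            # fraction of free (unbuffered) Ca2+

    # reversal potentials (mV)
    E_ca: float = 60.0
    E_k: float = -75.0
    E_na: float = 55.0
    E_nscc: float = 0.0
    E_cl: float = -20.0

    # maximal conductances (nS)
    g_ltype: float = 0.4
    g_vddr: float = 0.25
    g_lva: float = 0.05
    g_na: float = 0.3
    g_kv: float = 1.6
    g_kr: float = 0.6
    g_ka: float = 0.3
    g_erg: float = 0.8
    g_bk: float = 2.0
    g_cl: float = 0.3
    g_kbg: float = 0.40          # background K+
    g_nscc: float = 5.0          # non-selective cation channel

    # current modulation constants (mM unless noted)
    K_nscc: float = 0.4e-3       # Ca_SS half-activation of NSCC
    n_nscc: float = 6.0          # NSCC Hill coefficient
    K_fca: float = 0.3e-3        # Ca_i half-inactivation of L-type
    K_bk: float = 1.0e-3         # Ca_i half-activation of BK

    # IP3 receptor (Li-Rinzel form) and ER/mitochondrial fluxes
    k_inh: float = 5.0e-3        # high-Ca2+ release inhibition constant
    d1: float = 0.13e-3          # IP3R IP3 binding
    d2: float = 1.049e-3         # IP3R Ca2+ inactivation
    d3: float = 0.9434e-3        # IP3R IP3 modulation of inactivation
    d5: float = 0.08234e-3       # IP3R Ca2+ activation
    a2: float = 200.0            # IP3R inactivation rate (1/(mM s))
    v_ip3r: float = 900.0        # max IP3R release rate (1/s)
    v_erleak: float = 11.0       # ER leak rate (1/s)
    v_serca: float = 0.486       # max SERCA uptake (mM/s)
    k_serca: float = 0.1e-3      # SERCA half-activation (mM)
    v_uni: float = 4e-3          # mitochondrial uniporter max (mM/s)
    k_uni: float = 0.8e-3
    v_naca: float = 4e-4         # mitochondrial Na+/Ca2+ exchanger max (mM/s)
    k_naca: float = 0.5e-3
    k_leak: float = 2e-4         # SS -> cytosol leak rate (1/s)
    v_pmca: float = 0.08         # plasma-membrane Ca2+ pump max (mM/s)
    k_pmca: float = 0.3e-3

    # IP3 production / degradation
    P_MV: float = 2e-4           # max voltage-dependent IP3 synthesis (mM/s)
    k_V: float = 35.0            # synthesis half-inactivation voltage (mV)
    eta: float = 0.03            # linear IP3 degradation rate (1/s)
    V_m4: float = 4e-4           # nonlinear IP3 degradation max (mM/s)
    k_4: float = 0.9e-3          # nonlinear degradation half-activation (mM)

    # innervation drive: constant IP3 production rate (mM/s)
    beta: float = 1.993e-5

    def __post_init__(self):
        if self.C_m <= 0:
            raise ValueError("C_m must be positive")
        for name in ("vol_cyto", "vol_ss", "vol_er", "vol_mito"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.eta < 0:
            raise ValueError("eta must be nonnegative")

    def replace(self, **kw) -> "ICCParams":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ICCParams":
        return cls(**d)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ICCParams":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default_file(cls) -> "ICCParams":
        """The canonical shipped parameter file."""
        from importlib.resources import files

        import yaml

        text = files("gmnsim.data").joinpath("icc_default.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text))


def _check_state(state: np.ndarray) -> np.ndarray:
    state = np.asarray(state, dtype=float)
    if state.shape != (N_STATES,):
        raise ValueError(f"ICC state must have length {N_STATES}, got {state.shape}")
    if not np.all(np.isfinite(state)):
        bad = int(np.flatnonzero(~np.isfinite(state))[0])
        raise ValueError(f"non-finite ICC state variable {STATE_NAMES[bad]!r}")
    return state


def _sig(v: float, v_half: float, slope: float) -> float:
    return 1.0 / (1.0 + np.exp(-(v - v_half) / slope))


def gate_steady_state(V: float, Ca_i: float, params: ICCParams) -> np.ndarray:
    """Steady-state values of the 16 gates at voltage ``V`` and Ca2+ ``Ca_i``."""
    out = np.empty(N_GATES)
    for i, name in enumerate(GATE_NAMES[:-1]):
        v_half, slope, _tau, sign = GATING[name]
        s = _sig(V, v_half, slope)
        out[i] = s if sign > 0 else 1.0 - s
    out[-1] = 1.0 / (1.0 + (Ca_i / params.K_fca) ** 2)
    return out


def gate_time_constants() -> np.ndarray:
    """Time constants (s) of the 16 gates, in GATE_NAMES order."""
    taus = [GATING[name][2] for name in GATE_NAMES[:-1]]
    return np.array(taus + [TAU_F_CA])


def icc_ionic_currents(state, params: ICCParams) -> dict:
    """All intrinsic membrane currents (pA) of one ICC plus their sum.

    Returns a dict with one entry per name in :data:`CURRENT_NAMES` and a
    ``"total"`` entry holding their sum.
    """
    y = _check_state(state)
    p = params
    V, Ca_i, Ca_SS = y[0], y[1], y[2]
    g = y[7:]
    (d_L, f_L, d_v, f_v, m_na, h_na, x_kv, y_kv, p_kr, q_kr,
     a_ka, b_ka, e_erg, d_t, f_t, f_ca) = g
    I = {}
    I["I_ltype"] = p.g_ltype * d_L * f_L * f_ca * (V - p.E_ca)
    I["I_vddr"] = p.g_vddr * d_v * f_v * (V - p.E_ca)
    I["I_lva"] = p.g_lva * d_t * f_t * (V - p.E_ca)
    I["I_na"] = p.g_na * m_na ** 3 * h_na * (V - p.E_na)
    I["I_kv"] = p.g_kv * x_kv * y_kv * (V - p.E_k)
    I["I_kr"] = p.g_kr * p_kr * q_kr * (V - p.E_k)
    I["I_ka"] = p.g_ka * a_ka * b_ka * (V - p.E_k)
    I["I_erg"] = p.g_erg * e_erg * (V - p.E_k)
    p_bk = _sig(V, -20.0, 10.0) * Ca_i / (Ca_i + p.K_bk)
    I["I_bk"] = p.g_bk * p_bk * (V - p.E_k)
    I["I_cl"] = p.g_cl * _sig(V, -40.0, 8.0) * (V - p.E_cl)
    s = Ca_SS ** p.n_nscc / (p.K_nscc ** p.n_nscc + Ca_SS ** p.n_nscc)
    I["I_nscc"] = p.g_nscc * s * (V - p.E_nscc)
    I["I_kbg"] = p.g_kbg * (V - p.E_k)
    I["total"] = (I["I_ltype"] + I["I_vddr"] + I["I_lva"] + I["I_na"]
                  + I["I_kv"] + I["I_kr"] + I["I_ka"] + I["I_erg"]
                  + I["I_bk"] + I["I_cl"] + I["I_nscc"] + I["I_kbg"])
    return I


def _ca_fluxes(y: np.ndarray, p: ICCParams) -> dict:
    """Intracellular Ca2+ fluxes (mM/s, referenced to source volume)."""
    Ca_i, Ca_SS, IP3, Ca_ER, Ca_MT, h = y[1], y[2], y[3], y[4], y[5], y[6]
    m_inf = (IP3 / (IP3 + p.d1)) * (Ca_SS / (Ca_SS + p.d5))
    inh = p.k_inh / (p.k_inh + Ca_SS)
    J = {}
    J["J_erout"] = (p.v_ip3r * (m_inf * h) ** 3 * inh + p.v_erleak) * (Ca_ER - Ca_SS)
    J["J_serca"] = p.v_serca * Ca_SS ** 2 / (p.k_serca ** 2 + Ca_SS ** 2)
    J["J_uni"] = p.v_uni * Ca_SS ** 4 / (p.k_uni ** 4 + Ca_SS ** 4)
    J["J_naca"] = p.v_naca * Ca_MT / (p.k_naca + Ca_MT)
    J["J_leak"] = p.k_leak * (Ca_SS - Ca_i)
    J["J_pmca"] = p.v_pmca * Ca_i ** 2 / (p.k_pmca ** 2 + Ca_i ** 2)
    return J


def icc_calcium_rhs(state, params: ICCParams, J_g_Ca: float = 0.0):
    """Time derivatives of bulk and submembrane Ca2+ (mM/s).

    ``J_g_Ca`` is the external gap-junction Ca2+ flux into the bulk
    compartment (0 for an uncoupled cell).
    """
    y = _check_state(state)
    if not np.isfinite(J_g_Ca):
        raise ValueError("J_g_Ca must be finite")
    if y[1] < 0 or y[2] < 0:
        raise ValueError("negative Ca2+ concentration")
    p = params
    I = icc_ionic_currents(y, p)
    J = _ca_fluxes(y, p)
    dCa_i = p.f_c * (-(I["I_ltype"] + I["I_vddr"]) / (p.F * p.vol_cyto)
                     + J["J_leak"] - J["J_pmca"] + J_g_Ca)
    dCa_SS = p.f_c * ((J["J_naca"] - J["J_uni"]) * p.vol_mito / p.vol_ss
                      + (J["J_erout"] - J["J_serca"]) * p.vol_er / p.vol_ss
                      - J["J_leak"] * p.vol_cyto / p.vol_ss)
    return dCa_i, dCa_SS


def icc_ip3_rhs(state, params: ICCParams, J_g_IP3: float = 0.0) -> float:
    """Time derivative of IP3 (mM/s).

    Five terms: voltage-dependent synthesis (suppressed away from the plateau
    range by an eighth-power Hill function of V), linear degradation,
    fourth-power nonlinear degradation, the constant innervation drive
    ``params.beta``, and the external gap-junction flux ``J_g_IP3``.
    """
    y = _check_state(state)
    if y[3] < 0:
        raise ValueError("negative IP3 concentration")
    p = params
    V, IP3 = y[0], y[3]
    V8 = V ** 8
    synth = p.P_MV * (1.0 - V8 / (p.k_V ** 8 + V8))
    degr4 = p.V_m4 * IP3 ** 4 / (p.k_4 ** 4 + IP3 ** 4)
    return synth - p.eta * IP3 - degr4 + p.beta + J_g_IP3


def icc_rhs(state, params: ICCParams, I_g: float = 0.0,
            J_g_Ca: float = 0.0, J_g_IP3: float = 0.0) -> np.ndarray:
    """Full 23-dimensional time derivative of one ICC.

    ``I_g`` is the total gap-junction current (pA) leaving the cell; it
    enters the voltage equation as ``-(I_total + I_g)/C_m``.  With all
    coupling inputs zero this is the isolated pacemaker.
    """
    y = _check_state(state)
    for v, name in ((I_g, "I_g"), (J_g_Ca, "J_g_Ca"), (J_g_IP3, "J_g_IP3")):
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite")
    p = params
    V, Ca_SS, IP3, h = y[0], y[2], y[3], y[6]
    I = icc_ionic_currents(y, p)
    J = _ca_fluxes(y, p)
    dV = -(I["total"] + I_g) / p.C_m * 1e3  # pA/pF = mV/ms -> mV/s
    dCa_i, dCa_SS = icc_calcium_rhs(y, p, J_g_Ca)
    dCa_ER = p.f_c * (J["J_serca"] - J["J_erout"])
    dCa_MT = p.f_c * (J["J_uni"] - J["J_naca"])
    dIP3 = icc_ip3_rhs(y, p, J_g_IP3)
    Q2 = p.d2 * (IP3 + p.d1) / (IP3 + p.d3)
    dh = p.a2 * (Q2 * (1.0 - h) - Ca_SS * h)
    g = y[7:]
    dg = (gate_steady_state(V, y[1], p) - g) / gate_time_constants()
    out = np.empty(N_STATES)
    out[0] = dV
    out[1] = dCa_i
    out[2] = dCa_SS
    out[3] = dIP3
    out[4] = dCa_ER
    out[5] = dCa_MT
    out[6] = dh
    out[7:] = dg
    return out


def default_initial_state(params: ICCParams, V0: float = -70.0) -> np.ndarray:
    """A physiological resting state: hyperpolarized membrane, gates at
    steady state, a loaded ER and low cytosolic Ca2+."""
    y = np.zeros(N_STATES)
    y[0] = V0
    y[1] = 1e-4    # Ca_i
    y[2] = 1.2e-4  # Ca_SS
    y[3] = 3.0e-4  # IP3
    y[4] = 10.0e-3 # Ca_ER
    y[5] = 1e-4    # Ca_MT
    y[6] = 0.8     # h_ip3r
    y[7:] = gate_steady_state(V0, y[1], params)
    return y
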