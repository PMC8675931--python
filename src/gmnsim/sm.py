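"""Single smooth-muscle (SM) cell model.

The SM cell is a conductance-based cell with no intrinsic pacemaker: in
isolation it settles to a stable resting potential, and slow waves appear
only when it is driven by the depolarizing gap-junction current from its
paired ICC.  The muscarinic-modulated non-selective cation current (NSCC)
carries the ligand activity constant ``r_lig`` and an inhibitory Ca2+
facilitation factor ``h_Ca``.

Units as in :mod:`gmnsim.icc`.  State vector layout (14 entries)::

    index 0   V      membrane potential (mV)
    index 1   Ca     intracellular Ca2+ (mM)
    index 2+  gates  12 Hodgkin-Huxley gates, order of GATE_NAMES
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SMParams",
    "N_STATES",
    "N_GATES",
    "STATE_NAMES",
    "GATE_NAMES",
    "CURRENT_NAMES",
    "sm_gate_steady_state",
    "sm_gate_time_constants",
    "sm_nscc_current",
    "sm_ionic_currents",
    "sm_rhs",
    "default_initial_state",
]

N_STATES = 14
N_GATES = 12

GATE_NAMES = (
    "d_cal", "f_cal",      # L-type Ca2+ activation / V-inactivation
    "d_lva", "f_lva",      # low-voltage-activated Ca2+
    "m_na", "h_na",        # Na+
    "x_r1", "x_r2",        # delayed-rectifier K+
    "x_a1", "x_a2",        # A-type K+
    "m_nscc",              # NSCC voltage activation
    "f_ca_cal",            # Ca2+-dependent L-type inactivation
)

STATE_NAMES = ("V", "Ca") + GATE_NAMES

#: Voltage-gate kinetics: name -> (V_half mV, slope mV, tau s, +1 act / -1 inact)
GATING = {
    "d_cal": (-28.0, 4.0, 0.05, +1),
    "f_cal": (-35.0, 6.0, 2.0, -1),
    "d_lva": (-48.0, 4.0, 0.08, +1),
    "f_lva": (-62.0, 5.0, 1.0, -1),
    "m_na": (-40.0, 5.0, 0.02, +1),
    "h_na": (-62.0, 5.0, 0.12, -1),
    "x_r1": (-27.0, 6.0, 0.30, +1),
    "x_r2": (-35.0, 10.0, 4.0, -1),
    "x_a1": (-48.0, 6.0, 0.05, +1),
    "x_a2": (-62.0, 6.0, 0.25, -1),
    "m_nscc": (-30.0, 8.0, 0.30, +1),
}

TAU_F_CA = 0.4

CURRENT_NAMES = (
    "I_cal", "I_lva", "I_na", "I_kv", "I_ka", "I_bk", "I_kbg",
    "I_bgns", "I_nscc",
)


@dataclass(frozen=True)
class SMParams:
    """Constants of the SM cell model.  Defaults are the calibrated values."""

    C_m: float = 50.0            # capacitance (pF)
    F: float = 96.485            # Faraday constant (C/mmol)
    vol_cyto: float = 1.0        # cytosolic volume fraction
    f_c: float = 0.01            # fraction of free (unbuffered) Ca2+

    # reversal potentials (mV)
    E_ca: float = 60.0
    E_k: float = -75.0
    E_na: float = 55.0
    E_nscc: float = 0.0

    # maximal conductances (nS)
    g_cal: float = 0.6
    g_lva: float = 0.05
    g_na: float = 0.25
    g_kv: float = 1.2
    g_ka: float = 0.25
    g_bk: float = 1.5
    g_kbg: float = 0.4           # background K+
    g_bgns: float = 0.156        # background non-selective leak
    g_nscc: float = 2.0          # muscarinic-modulated NSCC

    # NSCC modulation
    r_lig: float = 0.1           # muscarinic ligand activity, uniform
    K_nscc_ca: float = 1.0e-3    # Ca2+ half-inhibition of NSCC (mM)
    n_ca: float = 4.0            # NSCC Ca2+ Hill coefficient

    # other modulation constants
    K_fca: float = 0.5e-3        # Ca half-inactivation of L-type (mM)
    K_bk: float = 1.0e-3         # Ca half-activation of BK (mM)

    # Ca2+ extrusion (sarcolemmal pump / exchanger lump)
    v_ex: float = 0.08           # max extrusion rate (mM/s)
    k_ex: float = 0.3e-3         # half-activation (mM)

    def __post_init__(self):
        if self.C_m <= 0:
            raise ValueError("C_m must be positive")
        if not 0.0 <= self.r_lig <= 1.0:
            raise ValueError("r_lig must be in [0, 1]")
        if self.n_ca <= 0:
            raise ValueError("n_ca must be positive")
        if self.K_nscc_ca == 0:
            raise ValueError("K_nscc_ca must be nonzero")

    def replace(self, **kw) -> "SMParams":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SMParams":
        return cls(**d)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SMParams":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default_file(cls) -> "SMParams":
        """The canonical shipped parameter file."""
        from importlib.resources import files

        import yaml

        text = files("gmnsim.data").joinpath("sm_default.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text))


def _check_state(state: np.ndarray) -> np.ndarray:
    state = np.asarray(state, dtype=float)
    if state.shape != (N_STATES,):
        raise ValueError(f"SM state must have length {N_STATES}, got {state.shape}")
    if not np.all(np.isfinite(state)):
        bad = int(np.flatnonzero(~np.isfinite(state))[0])
        raise ValueError(f"non-finite SM state variable {STATE_NAMES[bad]!r}")
    return state


def _sig(v: float, v_half: float, slope: float) -> float:
    return 1.0 / (1.0 + np.exp(-(v - v_half) / slope))


def sm_gate_steady_state(V: float, Ca: float, params: SMParams) -> np.ndarray:
    out = np.empty(N_GATES)
    for i, name in enumerate(GATE_NAMES[:-1]):
        v_half, slope, _tau, sign = GATING[name]
        s = _sig(V, v_half, slope)
        out[i] = s if sign > 0 else 1.0 - s
    out[-1] = 1.0 / (1.0 + (Ca / params.K_fca) ** 2)
    return out


def sm_gate_time_constants() -> np.ndarray:
    taus = [GATING[name][2] for name in GATE_NAMES[:-1]]
    return np.array(taus + [TAU_F_CA])


def sm_nscc_current(state, params: SMParams) -> float:
    """Muscarinic-modulated NSCC current (pA).

    ``I = g_nscc * m * r_lig * h_Ca * (V - E_nscc)`` with the inhibitory
    Ca2+ facilitation ``h_Ca = 1 / (1 + (Ca/K)^n)``.
    """
    y = _check_state(state)
    p = params
    V, Ca = y[0], y[1]
    m = y[2 + GATE_NAMES.index("m_nscc")]
    h_ca = 1.0 / (1.0 + (Ca / p.K_nscc_ca) ** p.n_ca)
    return p.g_nscc * m * p.r_lig * h_ca * (V - p.E_nscc)


def sm_ionic_currents(state, params: SMParams) -> dict:
    """All intrinsic membrane currents (pA) of one SM cell plus their sum."""
    y = _check_state(state)
    p = params
    V, Ca = y[0], y[1]
    g = y[2:]
    (d_c, f_cl, d_t, f_t, m_na, h_na, x1, x2, a1, a2, m_ns, f_ca) = g
    I = {}
    I["I_cal"] = p.g_cal * d_c * f_cl * f_ca * (V - p.E_ca)
    I["I_lva"] = p.g_lva * d_t * f_t * (V - p.E_ca)
    I["I_na"] = p.g_na * m_na ** 3 * h_na * (V - p.E_na)
    I["I_kv"] = p.g_kv * x1 * x2 * (V - p.E_k)
    I["I_ka"] = p.g_ka * a1 * a2 * (V - p.E_k)
    p_bk = _sig(V, -20.0, 10.0) * Ca / (Ca + p.K_bk)
    I["I_bk"] = p.g_bk * p_bk * (V - p.E_k)
    I["I_kbg"] = p.g_kbg * (V - p.E_k)
    I["I_bgns"] = p.g_bgns * (V - p.E_nscc)
    I["I_nscc"] = sm_nscc_current(y, p)
    I["total"] = (I["I_cal"] + I["I_lva"] + I["I_na"] + I["I_kv"]
                  + I["I_ka"] + I["I_bk"] + I["I_kbg"] + I["I_bgns"]
                  + I["I_nscc"])
    return I


def sm_rhs(state, params: SMParams, I_coup: float = 0.0,
           I_g_SM: float = 0.0) -> np.ndarray:
    """Full 14-dimensional time derivative of one SM cell.

    ``I_coup`` is the unidirectional gap-junction current from the paired
    ICC; it enters with a minus sign, i.e. it depolarizes the SM cell when
    the ICC is more depolarized.  ``I_g_SM`` is the total current leaving
    through SM-SM gap junctions.
    """
    y = _check_state(state)
    for v, name in ((I_coup, "I_coup"), (I_g_SM, "I_g_SM")):
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite")
    p = params
    V, Ca = y[0], y[1]
    I = sm_ionic_currents(y, p)
    dV = -(I["total"] + I_g_SM - I_coup) / p.C_m * 1e3  # pA/pF -> mV/s
    dCa = p.f_c * (-(I["I_cal"] + I["I_lva"]) / (p.F * p.vol_cyto)
                   - p.v_ex * Ca ** 2 / (p.k_ex ** 2 + Ca ** 2))
    dg = (sm_gate_steady_state(V, Ca, p) - y[2:]) / sm_gate_time_constants()
    out = np.empty(N_STATES)
    out[0] = dV
    out[1] = dCa
    out[2:] = dg
    return out


def default_initial_state(params: SMParams, V0: float = -60.0) -> np.ndarray:
    """Resting state: hyperpolarized membrane, gates at steady state."""
    y = np.zeros(N_STATES)
    y[0] = V0
    y[1] = 1e-4
    y[2:] = sm_gate_steady_state(V0, y[1], params)
    return y
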