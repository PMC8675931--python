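"""Chain assembly: coupling operators, innervation gradient, variability.

The network is a linear chain of N oscillatory units (OUs).  Each OU is one
ICC (23 states) electrically coupled to one SM cell (14 states).  Adjacent
ICCs exchange current (gap-junction conductance ``g_icc_icc``), Ca2+
(permeability ``p_ca``) and IP3 (permeability ``p_ip3``); adjacent SM cells
exchange current (``g_sm_sm``); each ICC drives its SM cell through the
unidirectional conductance ``g_coup``.  Boundary cells have exactly one
neighbor.  The innervation parameter beta decreases linearly from the
rostral cell (index 0) to the caudal cell (index N-1).

Packed state layout: one contiguous 37-entry block per OU, ICC states first
(see :mod:`gmnsim.icc`) then SM states (see :mod:`gmnsim.sm`), blocks in
chain order.  This interleaving keeps the Jacobian banded with bandwidth 37.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import icc as _icc
from . import sm as _sm
from ._kernel import HAVE_NUMBA, make_compiled_rhs

__all__ = [
    "NetworkConfig",
    "NS_ICC",
    "NS_SM",
    "NS_OU",
    "beta_gradient",
    "electrical_coupling",
    "messenger_exchange",
    "icc_sm_current",
    "sample_variability",
    "assemble_rhs",
    "pack_state",
    "unpack_state",
]

NS_ICC = _icc.N_STATES  # 23
NS_SM = _sm.N_STATES    # 14
NS_OU = NS_ICC + NS_SM  # 37


def _junction_array(value, n_units: int, name: str) -> np.ndarray:
    """Broadcast a scalar to the n_units-1 junctions, or validate a vector."""
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(max(n_units - 1, 0), float(arr))
    if arr.shape != (max(n_units - 1, 0),):
        raise ValueError(
            f"{name} must be a scalar or a vector of length n_units-1 "
            f"({n_units - 1}), got shape {arr.shape}")
    if np.any(arr < 0):
        raise ValueError(f"{name} must be nonnegative")
    return arr


@dataclass
class NetworkConfig:
    """Topology, coupling, innervation gradient and variability of a chain.

    ``g_icc_icc``, ``p_ip3``, ``p_ca`` and ``g_sm_sm`` may be scalars
    (shared by all junctions) or per-junction vectors of length
    ``n_units - 1``.
    """

    n_units: int = 42
    length_cm: float = 6.0
    g_icc_icc: object = 0.7      # ICC-ICC gap conductance (nS)
    p_ip3: object = 8.0          # ICC-ICC IP3 permeability (1/s)
    p_ca: object = 0.8           # ICC-ICC Ca2+ permeability (1/s)
    g_coup: float = 0.5          # ICC->SM conductance (nS)
    g_sm_sm: object = 0.2        # SM-SM gap conductance (nS)
    beta_rostral: float = 2.650e-5   # innervation drive, cell 1 (mM/s)
    beta_caudal: float = 1.336e-5    # innervation drive, cell N (mM/s)
    enable_electrical: bool = True   # ICC-ICC electrical coupling
    enable_ca: bool = True           # ICC-ICC Ca2+ exchange
    enable_ip3: bool = True          # ICC-ICC IP3 exchange
    variability: float = 0.0         # fractional coupling variability v
    seed: int = 0
    icc_params: _icc.ICCParams = field(default_factory=_icc.ICCParams)
    sm_params: _sm.SMParams = field(default_factory=_sm.SMParams)

    def __post_init__(self):
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.length_cm <= 0:
            raise ValueError("length_cm must be positive")
        if self.g_coup < 0:
            raise ValueError("g_coup must be nonnegative")
        if not 0.0 <= self.variability <= 1.0:
            raise ValueError("variability must be in [0, 1]")
        if self.n_units >= 2 and not self.beta_rostral > self.beta_caudal:
            raise ValueError("beta_rostral must exceed beta_caudal")
        # normalize/validate junction parameters
        for name in ("g_icc_icc", "p_ip3", "p_ca", "g_sm_sm"):
            _junction_array(getattr(self, name), self.n_units, name)

    # -- junction arrays as actually used by the RHS -----------------------
    def junction_arrays(self) -> dict:
        n = self.n_units
        g = _junction_array(self.g_icc_icc, n, "g_icc_icc")
        pip3 = _junction_array(self.p_ip3, n, "p_ip3")
        pca = _junction_array(self.p_ca, n, "p_ca")
        gsm = _junction_array(self.g_sm_sm, n, "g_sm_sm")
        if not self.enable_electrical:
            g = np.zeros_like(g)
        if not self.enable_ip3:
            pip3 = np.zeros_like(pip3)
        if not self.enable_ca:
            pca = np.zeros_like(pca)
        return {"g_icc_icc": g, "p_ip3": pip3, "p_ca": pca, "g_sm_sm": gsm}

    def replace(self, **kw) -> "NetworkConfig":
        return dataclasses.replace(self, **kw)

    # -- round-trip to structured text -------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for name in ("g_icc_icc", "p_ip3", "p_ca", "g_sm_sm"):
            v = d[name]
            if isinstance(v, np.ndarray):
                d[name] = v.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        if "icc_params" in d and isinstance(d["icc_params"], dict):
            d["icc_params"] = _icc.ICCParams.from_dict(d["icc_params"])
        if "sm_params" in d and isinstance(d["sm_params"], dict):
            d["sm_params"] = _sm.SMParams.from_dict(d["sm_params"])
        for name in ("g_icc_icc", "p_ip3", "p_ca", "g_sm_sm"):
            if name in d and isinstance(d[name], list):
                d[name] = np.asarray(d[name], dtype=float)
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "NetworkConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def beta_gradient(config: NetworkConfig) -> np.ndarray:
    """Per-cell innervation drive: linear, strictly decreasing with index."""
    n = config.n_units
    if n < 2:
        raise ValueError("beta_gradient requires n_units >= 2")
    i = np.arange(n, dtype=float)
    return config.beta_rostral + i * (config.beta_caudal - config.beta_rostral) / (n - 1)


def electrical_coupling(V, G) -> np.ndarray:
    """Per-cell gap-junction current I_i = sum_j G_ij (V_i - V_j) (pA).

    ``G`` holds one conductance per junction, shared by both directions, so
    the currents are exactly antisymmetric and sum to zero over the chain.
    """
    V = np.asarray(V, dtype=float)
    G = np.asarray(G, dtype=float)
    if G.shape != (V.size - 1,):
        raise ValueError("G must have one entry per junction (len(V)-1)")
    if np.any(G < 0):
        raise ValueError("conductances must be nonnegative")
    I = np.zeros(V.size)
    d = G * (V[:-1] - V[1:])
    I[:-1] += d
    I[1:] -= d
    return I


def messenger_exchange(C, P) -> np.ndarray:
    """Per-cell diffusive gap-junction flux J_i = -P sum_j (C_i - C_j).

    Used for both Ca2+ and IP3.  Conserves the chain total exactly.
    """
    C = np.asarray(C, dtype=float)
    P = np.asarray(P, dtype=float)
    if np.any(C < 0):
        raise ValueError("concentrations must be nonnegative")
    if P.shape != (C.size - 1,):
        raise ValueError("P must have one entry per junction (len(C)-1)")
    if np.any(P < 0):
        raise ValueError("permeabilities must be nonnegative")
    J = np.zeros(C.size)
    d = P * (C[:-1] - C[1:])
    J[:-1] -= d
    J[1:] += d
    return J


def icc_sm_current(V_icc, V_sm, g_coup: float):
    """Unidirectional ICC->SM coupling current I_coup = g_coup (V_ICC - V_SM).

    Applied only in the SM voltage equation (depolarizing when the ICC is
    more depolarized); there is no retrograde term in the ICC equation.
    """
    return g_coup * (np.asarray(V_icc, dtype=float) - np.asarray(V_sm, dtype=float))


def sample_variability(config: NetworkConfig) -> NetworkConfig:
    """Draw per-junction coupling strengths around their defaults.

    Each junction's ICC-ICC conductance (and, when IP3 exchange is enabled,
    its IP3 permeability) is drawn independently and uniformly from
    ``[d(1-v), d(1+v)]`` where ``d`` is the configured default and
    ``v = config.variability``.  The draw is deterministic in
    ``config.seed``.  With ``v = 0`` the configuration is returned with its
    defaults unchanged.
    """
    v = config.variability
    if not 0.0 <= v <= 1.0:
        raise ValueError("variability must be in [0, 1]")
    if v == 0.0:
        return config.replace()
    n = config.n_units
    rng = np.random.default_rng(config.seed)
    d_g = _junction_array(config.g_icc_icc, n, "g_icc_icc")
    g = rng.uniform(d_g * (1.0 - v), d_g * (1.0 + v))
    out = {"g_icc_icc": g}
    if config.enable_ip3:
        d_p = _junction_array(config.p_ip3, n, "p_ip3")
        out["p_ip3"] = rng.uniform(d_p * (1.0 - v), d_p * (1.0 + v))
    return config.replace(**out)


def pack_state(icc_states, sm_states) -> np.ndarray:
    """Pack per-cell ICC (N x 23) and SM (N x 14) states into a flat vector."""
    icc_states = np.asarray(icc_states, dtype=float)
    sm_states = np.asarray(sm_states, dtype=float)
    if icc_states.ndim != 2 or icc_states.shape[1] != NS_ICC:
        raise ValueError(f"icc_states must be (N, {NS_ICC})")
    if sm_states.shape != (icc_states.shape[0], NS_SM):
        raise ValueError(f"sm_states must be (N, {NS_SM}) matching icc_states")
    return np.hstack([icc_states, sm_states]).ravel()


def unpack_state(y, n_units: int):
    """Inverse of :func:`pack_state`: flat vector -> (N x 23, N x 14)."""
    y = np.asarray(y, dtype=float)
    if y.shape != (n_units * NS_OU,):
        raise ValueError(f"state must have length {n_units * NS_OU}, got {y.shape}")
    Y = y.reshape(n_units, NS_OU)
    return Y[:, :NS_ICC].copy(), Y[:, NS_ICC:].copy()


def _make_numpy_rhs(n, beta, g, pip3, pca, gsm, g_coup, icc_params, sm_params):
    """Reference backend: per-cell scalar evaluations plus coupling ops."""

    def f(t, y):
        Y = y.reshape(n, NS_OU)
        V_icc = Y[:, 0]
        Ca_i = Y[:, 1]
        IP3 = Y[:, 3]
        V_sm = Y[:, NS_ICC]
        I_g = electrical_coupling(V_icc, g) if n > 1 else np.zeros(1)
        J_ca = messenger_exchange(Ca_i, pca) if n > 1 else np.zeros(1)
        J_ip3 = messenger_exchange(IP3, pip3) if n > 1 else np.zeros(1)
        I_g_sm = electrical_coupling(V_sm, gsm) if n > 1 else np.zeros(1)
        I_coup = icc_sm_current(V_icc, V_sm, g_coup)
        dY = np.empty_like(Y)
        for c in range(n):
            p_c = icc_params.replace(beta=float(beta[c]))
            dY[c, :NS_ICC] = _icc.icc_rhs(Y[c, :NS_ICC], p_c, I_g=float(I_g[c]),
                                          J_g_Ca=float(J_ca[c]),
                                          J_g_IP3=float(J_ip3[c]))
            dY[c, NS_ICC:] = _sm.sm_rhs(Y[c, NS_ICC:], sm_params,
                                        I_coup=float(I_coup[c]),
                                        I_g_SM=float(I_g_sm[c]))
        return dY.ravel()

    return f


def assemble_rhs(config: NetworkConfig, backend: str = "auto"):
    """Build the derivative function f(t, y) of the full 37*N system.

    ``backend`` is ``"auto"`` (compiled if numba is available), ``"numba"``
    or ``"numpy"`` (the slow per-cell reference implementation).  Disabled
    coupling mechanisms contribute exactly zero.
    """
    n = config.n_units
    beta = (beta_gradient(config) if n >= 2
            else np.array([config.beta_rostral]))
    arrs = config.junction_arrays()
    args = (n, beta, arrs["g_icc_icc"], arrs["p_ip3"], arrs["p_ca"],
            arrs["g_sm_sm"], config.g_coup, config.icc_params,
            config.sm_params)
    if backend == "auto":
        backend = "numba" if HAVE_NUMBA else "numpy"
    if backend == "numba":
        if not HAVE_NUMBA:
            raise RuntimeError("numba backend requested but numba is unavailable")
        return make_compiled_rhs(*args)
    if backend == "numpy":
        return _make_numpy_rhs(*args)
    raise ValueError(f"unknown backend {backend!r}")
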