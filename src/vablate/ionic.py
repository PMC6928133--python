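"""Human atrial action-potential model with AF electrical remodeling.

Implements the Courtemanche–Ramirez–Nattel (CRN-1998) human atrial myocyte
model: fast Na+, transient-outward, ultrarapid/rapid/slow delayed-rectifier
and inward-rectifier K+ currents, L-type Ca2+ current, pumps and exchangers,
and a two-compartment sarcoplasmic-reticulum Ca2+ subsystem — 21 state
variables per cell.  Persistent-AF electrical remodeling is represented by
four conductance scalings (I_to −80%, I_CaL −40%, I_Kur −50%, I_K1 +50%).

Integration uses the Rush–Larsen update for Hodgkin–Huxley gates and forward
Euler for the membrane potential and concentrations, with a fixed default
time step of 0.02 ms.  Two numba-compiled paths share one physics core: an
analytic path that evaluates every rate expression per step (reference, used
for single cells) and a voltage-lookup-table path that interpolates the
precomputed gate rates (used by the tissue solver; agreement is covered by
tests).

Units: mV, ms, pA/pF, mM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

#: Multiplicative conductance scalings of persistent-AF electrical remodeling.
AF_REMODELING_FACTORS = {"g_to": 0.2, "g_CaL": 0.6, "g_Kur": 0.5, "g_K1": 1.5}

#: Resting potential (mV) at which ablated tissue is clamped.
ABLATION_CLAMP_MV = -80.6

_CURRENT_NAMES = (
    "g_Na",
    "g_to",
    "g_CaL",
    "g_Kur",
    "g_Kr",
    "g_Ks",
    "g_K1",
    "g_bNa",
    "g_bCa",
    "i_NaK_max",
    "i_NaCa_max",
    "i_pCa_max",
    "i_up_max",
)


@dataclass
class CellParams:
    """Maximal conductances (nS/pF) and transporter maxima of the atrial model.

    ``remodeling_factors`` are per-current multiplicative scales; the default
    is the identity (healthy cell).  ``scaled()`` returns the effective
    values used by the integrator.
    """

    g_Na: float = 7.8
    g_to: float = 0.1652
    g_CaL: float = 0.12375
    g_Kur: float = 1.0          # scale on the voltage-dependent g_Kur(V)
    g_Kr: float = 0.029411765
    g_Ks: float = 0.12941176
    g_K1: float = 0.09
    g_bNa: float = 0.0006744375
    g_bCa: float = 0.001131
    i_NaK_max: float = 0.59933874   # pA/pF
    i_NaCa_max: float = 1600.0      # pA/pF
    i_pCa_max: float = 0.275        # pA/pF
    i_up_max: float = 0.005         # mM/ms
    remodeling_factors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in _CURRENT_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def scaled(self) -> np.ndarray:
        """Effective parameter vector (remodeling applied), numba-ready."""
        vals = []
        for name in _CURRENT_NAMES:
            vals.append(getattr(self, name) * self.remodeling_factors.get(name, 1.0))
        return np.asarray(vals, dtype=np.float64)


def apply_af_remodeling(params: CellParams) -> CellParams:
    """Return a copy with persistent-AF conductance remodeling applied.

    I_to x0.2, I_CaL x0.6, I_Kur x0.5, I_K1 x1.5; every other current keeps
    a unit factor.  Composes multiplicatively with any factors already set.
    """
    factors = dict(params.remodeling_factors)
    for k, f in AF_REMODELING_FACTORS.items():
        factors[k] = factors.get(k, 1.0) * f
    return replace(params, remodeling_factors=factors)


# ---------------------------------------------------------------------------
# State layout
# ---------------------------------------------------------------------------

N_STATE = 21
STATE_NAMES = (
    "V", "m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs",
    "d", "f", "f_Ca", "u", "v", "w", "Na_i", "K_i", "Ca_i", "Ca_up", "Ca_rel",
)
_GATE_SLICE = slice(1, 16)
_CONC_SLICE = slice(16, 21)

# Published CRN initial conditions (quiescent, healthy cell).
_INITIAL_STATE = np.array(
    [
        -81.18,      # V (mV)
        2.908e-3,    # m
        9.649e-1,    # h
        9.775e-1,    # j
        3.043e-2,    # oa
        9.992e-1,    # oi
        4.966e-3,    # ua
        9.986e-1,    # ui
        3.296e-5,    # xr
        1.869e-2,    # xs
        1.367e-4,    # d
        9.996e-1,    # f
        7.755e-1,    # f_Ca
        0.0,         # u
        1.0,         # v
        9.992e-1,    # w
        1.117e1,     # Na_i (mM)
        1.390e2,     # K_i (mM)
        1.013e-4,    # Ca_i (mM)
        1.488,       # Ca_up (mM)
        1.488,       # Ca_rel (mM)
    ]
)


@dataclass
class CellState:
    """Full state of one atrial myocyte (membrane potential, gates, concentrations)."""

    values: np.ndarray

    @classmethod
    def initial(cls) -> "CellState":
        return cls(_INITIAL_STATE.copy())

    @property
    def Vm(self) -> float:
        return float(self.values[0])

    def gates(self) -> np.ndarray:
        return self.values[_GATE_SLICE]

    def concentrations(self) -> np.ndarray:
        return self.values[_CONC_SLICE]

    def copy(self) -> "CellState":
        return CellState(self.values.copy())

    def validate(self) -> None:
        if not np.isfinite(self.values).all():
            bad = int(np.flatnonzero(~np.isfinite(self.values))[0])
            raise FloatingPointError(f"non-finite state variable '{STATE_NAMES[bad]}'")
        g = self.gates()
        if (g < -1e-9).any() or (g > 1 + 1e-9).any():
            bad = int(np.flatnonzero((g < -1e-9) | (g > 1 + 1e-9))[0]) + 1
            raise ValueError(f"gate '{STATE_NAMES[bad]}' outside [0, 1]")
        if (self.concentrations() <= 0).any():
            bad = int(np.flatnonzero(self.concentrations() <= 0)[0]) + 16
            raise ValueError(f"non-positive concentration '{STATE_NAMES[bad]}'")


def initial_state_array(n_nodes: int) -> np.ndarray:
    """(n_nodes, 21) state array at published initial conditions."""
    return np.tile(_INITIAL_STATE, (n_nodes, 1))


# ---------------------------------------------------------------------------
# Numba kernels
# ---------------------------------------------------------------------------

# physical constants
_R = 8.3143       # J/(mol K)
_T = 310.0        # K
_F = 96.4867      # C/mmol
_RT_F = _R * _T / _F
_CM = 100.0       # pF
_V_I = 13668.0    # um^3
_V_UP = 1109.52
_V_REL = 96.48
_K_O = 5.4        # mM
_NA_O = 140.0
_CA_O = 1.8
_KQ10 = 3.0
_GAMMA = 0.35
_KM_NAI = 10.0
_KM_KO = 1.5
_KM_NA = 87.5
_KM_CA = 1.38
_K_SAT = 0.1
_K_REL = 30.0
_K_UP = 0.00092
_CA_UP_MAX = 15.0
_CMDN_MAX = 0.05
_TRPN_MAX = 0.07
_CSQN_MAX = 10.0
_KM_CMDN = 0.00238
_KM_TRPN = 0.0005
_KM_CSQN = 0.8
_TAU_TR = 180.0
_TAU_U = 8.0
_TAU_FCA = 2.0
_SIGMA = (np.exp(_NA_O / 67.3) - 1.0) / 7.0

# rate-row layout: 12 voltage gates x (steady state, Rush-Larsen factor
# exp(-dt/tau)), then 6 voltage-dependent current factors
N_RATE = 30
_IDX_IK1F = 24
_IDX_IKRF = 25
_IDX_GKURF = 26
_IDX_FNAK = 27
_IDX_EXPG = 28
_IDX_EXPG1 = 29


@njit(cache=True, fastmath=True)
def _fill_rate_row(V, dt, row):
    """Voltage-dependent gate steady states, Rush-Larsen factors and current factors."""
    # fast sodium m, h, j
    if abs(V + 47.13) < 1e-10:
        am = 3.2
    else:
        am = 0.32 * (V + 47.13) / (1.0 - np.exp(-0.1 * (V + 47.13)))
    bm = 0.08 * np.exp(-V / 11.0)
    if V >= -40.0:
        ah = 0.0
        bh = 1.0 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1)))
        aj = 0.0
        bj = 0.3 * np.exp(-2.535e-7 * V) / (1.0 + np.exp(-0.1 * (V + 32.0)))
    else:
        ah = 0.135 * np.exp(-(V + 80.0) / 6.8)
        bh = 3.56 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.35 * V)
        aj = (
            (-1.2714e5 * np.exp(0.2444 * V) - 3.474e-5 * np.exp(-0.04391 * V))
            * (V + 37.78)
            / (1.0 + np.exp(0.311 * (V + 79.23)))
        )
        bj = 0.1212 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14)))
    row[0] = am / (am + bm)
    row[1] = np.exp(-dt * (am + bm))
    row[2] = ah / (ah + bh)
    row[3] = np.exp(-dt * (ah + bh))
    row[4] = aj / (aj + bj)
    row[5] = np.exp(-dt * (aj + bj))

    # transient outward oa, oi
    a_oa = 0.65 / (np.exp(-(V + 10.0) / 8.5) + np.exp(-(V - 30.0) / 59.0))
    b_oa = 0.65 / (2.5 + np.exp((V + 82.0) / 17.0))
    row[6] = 1.0 / (1.0 + np.exp(-(V + 20.47) / 17.54))
    row[7] = np.exp(-dt * (a_oa + b_oa) * _KQ10)
    a_oi = 1.0 / (18.53 + np.exp((V + 113.7) / 10.95))
    b_oi = 1.0 / (35.56 + np.exp(-(V + 1.26) / 7.44))
    row[8] = 1.0 / (1.0 + np.exp((V + 43.1) / 5.3))
    row[9] = np.exp(-dt * (a_oi + b_oi) * _KQ10)

    # ultrarapid ua, ui
    b_ua = 0.65 / (2.5 + np.exp((V + 82.0) / 17.0))
    row[10] = 1.0 / (1.0 + np.exp(-(V + 30.3) / 9.6))
    row[11] = np.exp(-dt * (a_oa + b_ua) * _KQ10)
    a_ui = 1.0 / (21.0 + np.exp(-(V - 185.0) / 28.0))
    b_ui = np.exp((V - 158.0) / 16.0)
    row[12] = 1.0 / (1.0 + np.exp((V - 99.45) / 27.48))
    row[13] = np.exp(-dt * (a_ui + b_ui) * _KQ10)

    # delayed rectifiers xr, xs
    if abs(V + 14.1) < 1e-10:
        a_xr = 0.0015
    else:
        a_xr = 0.0003 * (V + 14.1) / (1.0 - np.exp(-(V + 14.1) / 5.0))
    if abs(V - 3.3328) < 1e-10:
        b_xr = 3.7836118e-4
    else:
        b_xr = 7.3898e-5 * (V - 3.3328) / (np.exp((V - 3.3328) / 5.1237) - 1.0)
    row[14] = 1.0 / (1.0 + np.exp(-(V + 14.1) / 6.5))
    row[15] = np.exp(-dt * (a_xr + b_xr))
    if abs(V - 19.9) < 1e-10:
        a_xs = 0.00068
        b_xs = 0.000315
    else:
        a_xs = 4e-5 * (V - 19.9) / (1.0 - np.exp(-(V - 19.9) / 17.0))
        b_xs = 3.5e-5 * (V - 19.9) / (np.exp((V - 19.9) / 9.0) - 1.0)
    row[16] = 1.0 / np.sqrt(1.0 + np.exp(-(V - 19.9) / 12.7))
    row[17] = np.exp(-dt * 2.0 * (a_xs + b_xs))

    # L-type calcium d, f
    if abs(V + 10.0) < 1e-10:
        t_d = 1.0 / (0.035 * 6.24 * 2.0)
    else:
        t_d = (1.0 - np.exp(-(V + 10.0) / 6.24)) / (
            0.035 * (V + 10.0) * (1.0 + np.exp(-(V + 10.0) / 6.24))
        )
    row[18] = 1.0 / (1.0 + np.exp(-(V + 10.0) / 8.0))
    row[19] = np.exp(-dt / t_d)
    t_f = 9.0 / (0.0197 * np.exp(-(0.0337 ** 2) * (V + 10.0) ** 2) + 0.02)
    row[20] = 1.0 / (1.0 + np.exp((V + 28.0) / 6.9))
    row[21] = np.exp(-dt / t_f)

    # SR release voltage gate w
    if abs(V - 7.9) < 1e-10:
        t_w = 6.0 * 0.2 / 1.3
    else:
        t_w = (
            6.0
            * (1.0 - np.exp(-(V - 7.9) / 5.0))
            / ((1.0 + 0.3 * np.exp(-(V - 7.9) / 5.0)) * (V - 7.9))
        )
    row[22] = 1.0 - 1.0 / (1.0 + np.exp(-(V - 40.0) / 17.0))
    row[23] = np.exp(-dt / t_w)

    # voltage-dependent current factors
    row[_IDX_IK1F] = 1.0 / (1.0 + np.exp(0.07 * (V + 80.0)))
    row[_IDX_IKRF] = 1.0 / (1.0 + np.exp((V + 15.0) / 22.4))
    row[_IDX_GKURF] = 0.005 + 0.05 / (1.0 + np.exp(-(V - 15.0) / 13.0))
    row[_IDX_FNAK] = 1.0 / (
        1.0 + 0.1245 * np.exp(-0.1 * V / _RT_F) + 0.0365 * _SIGMA * np.exp(-V / _RT_F)
    )
    row[_IDX_EXPG] = np.exp(_GAMMA * V / _RT_F)
    row[_IDX_EXPG1] = np.exp((_GAMMA - 1.0) * V / _RT_F)


@njit(cache=True, fastmath=True, inline="always")
def _cell_core(s, p, dt, istim, row):
    """Physics core: advance one cell given the precomputed rate row."""
    V = s[0]
    m = s[1]; h = s[2]; j = s[3]
    oa = s[4]; oi = s[5]; ua = s[6]; ui = s[7]
    xr = s[8]; xs = s[9]; d = s[10]; f = s[11]; fca = s[12]
    u = s[13]; v = s[14]; w = s[15]
    Nai = s[16]; Ki = s[17]; Cai = s[18]; Caup = s[19]; Carel = s[20]

    gNa = p[0]; gto = p[1]; gCaL = p[2]; gKur_s = p[3]
    gKr = p[4]; gKs = p[5]; gK1 = p[6]; gbNa = p[7]; gbCa = p[8]
    iNaKmax = p[9]; iNaCamax = p[10]; ipCamax = p[11]; iupmax = p[12]

    # reversal potentials
    ENa = _RT_F * np.log(_NA_O / Nai)
    EK = _RT_F * np.log(_K_O / Ki)
    ECa = 0.5 * _RT_F * np.log(_CA_O / Cai)

    # membrane currents (pA/pF)
    INa = gNa * m * m * m * h * j * (V - ENa)
    IK1 = gK1 * (V - EK) * row[_IDX_IK1F]
    Ito = gto * oa * oa * oa * oi * (V - EK)
    IKur = gKur_s * row[_IDX_GKURF] * ua * ua * ua * ui * (V - EK)
    IKr = gKr * xr * (V - EK) * row[_IDX_IKRF]
    IKs = gKs * xs * xs * (V - EK)
    ICaL = gCaL * d * f * fca * (V - 65.0)
    IpCa = ipCamax * Cai / (0.0005 + Cai)
    INaK = (
        iNaKmax * row[_IDX_FNAK] / (1.0 + (_KM_NAI / Nai) ** 1.5) * _K_O / (_K_O + _KM_KO)
    )
    expg1 = row[_IDX_EXPG1]
    INaCa = (
        iNaCamax
        * (row[_IDX_EXPG] * Nai ** 3 * _CA_O - expg1 * _NA_O ** 3 * Cai)
        / ((_KM_NA ** 3 + _NA_O ** 3) * (_KM_CA + _CA_O) * (1.0 + _K_SAT * expg1))
    )
    IbNa = gbNa * (V - ENa)
    IbCa = gbCa * (V - ECa)

    Iion = INa + IK1 + Ito + IKur + IKr + IKs + ICaL + IpCa + INaK + INaCa + IbNa + IbCa

    # SR calcium fluxes
    Irel = _K_REL * u * u * v * w * (Carel - Cai)
    Itr = (Caup - Carel) / _TAU_TR
    Iup = iupmax / (1.0 + _K_UP / Cai)
    Iupleak = iupmax * Caup / _CA_UP_MAX

    # calcium-release gates driven by Fn (pA-scale flux balance)
    Fn = 1e-12 * _V_REL * Irel - 5e-13 / _F * (0.5 * ICaL * _CM - 0.2 * INaCa * _CM)
    arg = (Fn - 3.4175e-13) / 13.67e-16
    e1 = np.exp(-arg)
    uinf = 1.0 / (1.0 + e1)
    t_v = 1.91 + 2.09 / (1.0 + e1)
    vinf = 1.0 - 1.0 / (1.0 + np.exp(-(Fn - 6.835e-14) / 13.67e-16))
    fcainf = 1.0 / (1.0 + Cai / 0.00035)

    # Rush-Larsen gate updates (voltage gates use the precomputed row)
    s[1] = row[0] + (m - row[0]) * row[1]
    s[2] = row[2] + (h - row[2]) * row[3]
    s[3] = row[4] + (j - row[4]) * row[5]
    s[4] = row[6] + (oa - row[6]) * row[7]
    s[5] = row[8] + (oi - row[8]) * row[9]
    s[6] = row[10] + (ua - row[10]) * row[11]
    s[7] = row[12] + (ui - row[12]) * row[13]
    s[8] = row[14] + (xr - row[14]) * row[15]
    s[9] = row[16] + (xs - row[16]) * row[17]
    s[10] = row[18] + (d - row[18]) * row[19]
    s[11] = row[20] + (f - row[20]) * row[21]
    s[12] = fcainf + (fca - fcainf) * np.exp(-dt / _TAU_FCA)
    s[13] = uinf + (u - uinf) * np.exp(-dt / _TAU_U)
    s[14] = vinf + (v - vinf) * np.exp(-dt / t_v)
    s[15] = row[22] + (w - row[22]) * row[23]

    # concentration updates (forward Euler)
    c_f = _CM / (_F * _V_I)
    s[16] = Nai + dt * (-3.0 * INaK - 3.0 * INaCa - IbNa - INa) * c_f
    s[17] = Ki + dt * (2.0 * INaK - IK1 - Ito - IKur - IKr - IKs) * c_f
    b1 = (2.0 * INaCa - IpCa - ICaL - IbCa) * _CM / (2.0 * _F * _V_I) + (
        _V_UP * (Iupleak - Iup) + Irel * _V_REL
    ) / _V_I
    b2 = (
        1.0
        + _TRPN_MAX * _KM_TRPN / ((Cai + _KM_TRPN) ** 2)
        + _CMDN_MAX * _KM_CMDN / ((Cai + _KM_CMDN) ** 2)
    )
    s[18] = Cai + dt * b1 / b2
    s[19] = Caup + dt * (Iup - Iupleak - Itr * _V_REL / _V_UP)
    s[20] = Carel + dt * (Itr - Irel) / (
        1.0 + _CSQN_MAX * _KM_CSQN / ((Carel + _KM_CSQN) ** 2)
    )

    # membrane potential (forward Euler)
    s[0] = V - dt * (Iion + istim)


@njit(cache=True, fastmath=True)
def _cell_kernel(s, p, dt, istim):
    """Analytic single-cell step (rates evaluated exactly at the current Vm)."""
    row = np.empty(N_RATE)
    _fill_rate_row(s[0], dt, row)
    _cell_core(s, p, dt, istim, row)


@njit(cache=True, fastmath=True)
def _build_table(dt, vlo, dv, n):
    table = np.empty((n, N_RATE))
    for i in range(n):
        _fill_rate_row(vlo + i * dv, dt, table[i])
    return table


@njit(cache=True, fastmath=True)
def _step_subset_lut(states, node_idx, p, dt, istim, table, vlo, dv_inv):
    nmax = table.shape[0] - 2
    row = np.empty(N_RATE)
    for k in range(node_idx.size):
        i = node_idx[k]
        s = states[i]
        x = (s[0] - vlo) * dv_inv
        if x < 0.0:
            x = 0.0
        elif x > nmax:
            x = float(nmax)
        i0 = int(x)
        fr = x - i0
        r0 = table[i0]
        r1 = table[i0 + 1]
        for c in range(N_RATE):
            row[c] = r0[c] + (r1[c] - r0[c]) * fr
        _cell_core(s, p, dt, istim[i], row)


class RateTable:
    """Linear-interpolation table of the voltage-dependent rates for one dt."""

    V_LO = -120.0
    V_HI = 80.0
    DV = 0.05

    def __init__(self, dt: float):
        self.dt = float(dt)
        n = int(round((self.V_HI - self.V_LO) / self.DV)) + 1
        self.table = _build_table(self.dt, self.V_LO, self.DV, n)
        self.dv_inv = 1.0 / self.DV


_TABLE_CACHE: dict[float, RateTable] = {}


def get_rate_table(dt: float) -> RateTable:
    key = round(float(dt), 9)
    if key not in _TABLE_CACHE:
        _TABLE_CACHE[key] = RateTable(key)
    return _TABLE_CACHE[key]


def step_states_subset(
    states: np.ndarray,
    node_idx: np.ndarray,
    params: np.ndarray,
    dt: float,
    istim: np.ndarray,
) -> None:
    """Advance the listed rows of an (n, 21) state array by dt (LUT path)."""
    t = get_rate_table(dt)
    _step_subset_lut(states, node_idx, params, dt, istim, t.table, t.V_LO, t.dv_inv)


@njit(cache=True, fastmath=True)
def step_states(states, params, dt, istim):
    """Advance every row of an (n, 21) state array by dt (analytic path)."""
    for i in range(states.shape[0]):
        _cell_kernel(states[i], params, dt, istim[i])


@njit(cache=True, fastmath=True)
def _integrate_single(state, params, dt, n_steps, stim_start, stim_dur, stim_amp, record_every):
    """Integrate one cell with an optional square stimulus; record Vm."""
    n_rec = n_steps // record_every + 1
    vm = np.empty(n_rec)
    times = np.empty(n_rec)
    vm[0] = state[0]
    times[0] = 0.0
    k = 1
    for step in range(1, n_steps + 1):
        t = step * dt
        istim = stim_amp if (stim_start <= t - dt < stim_start + stim_dur) else 0.0
        _cell_kernel(state, params, dt, istim)
        if step % record_every == 0:
            vm[k] = state[0]
            times[k] = t
            k += 1
    return times[:k], vm[:k]


@njit(cache=True, fastmath=True)
def _pace_single(state, params, dt, cl, n_beats, stim_dur, stim_amp, record_every):
    """Pace one cell at fixed cycle length; record the full Vm trace."""
    steps_per_beat = int(round(cl / dt))
    n_steps = steps_per_beat * n_beats
    n_rec = n_steps // record_every + 1
    vm = np.empty(n_rec)
    times = np.empty(n_rec)
    vm[0] = state[0]
    times[0] = 0.0
    k = 1
    stim_steps = int(round(stim_dur / dt))
    for step in range(1, n_steps + 1):
        phase = (step - 1) % steps_per_beat
        istim = stim_amp if phase < stim_steps else 0.0
        _cell_kernel(state, params, dt, istim)
        if step % record_every == 0:
            vm[k] = state[0]
            times[k] = step * dt
            k += 1
    return times[:k], vm[:k]


# ---------------------------------------------------------------------------
# Public single-cell API
# ---------------------------------------------------------------------------

DEFAULT_DT_MS = 0.02
DEFAULT_STIM_DURATION_MS = 2.0


def step_cell(state: CellState, params: CellParams, i_stim: float = 0.0, dt: float = DEFAULT_DT_MS) -> CellState:
    """Advance a single cell one time step (pure: returns a new state)."""
    if dt <= 0 or dt > 0.1:
        raise ValueError("dt must lie in (0, 0.1] ms for the explicit scheme")
    state.validate()
    out = state.copy()
    _cell_kernel(out.values, params.scaled(), dt, i_stim)
    out.validate()
    return out


def simulate_unstimulated(
    state: CellState, params: CellParams, duration_ms: float, dt: float = DEFAULT_DT_MS
) -> tuple[np.ndarray, np.ndarray, CellState]:
    """Integrate without stimulus; returns (times, Vm trace, final state)."""
    s = state.values.copy()
    t, vm = _integrate_single(s, params.scaled(), dt, int(round(duration_ms / dt)),
                              -1.0, 0.0, 0.0, max(1, int(round(1.0 / dt))))
    return t, vm, CellState(s)


def find_resting_state(
    params: CellParams,
    dt: float = DEFAULT_DT_MS,
    max_seconds: float = 60.0,
    tol_mv_per_s: float = 0.01,
) -> CellState:
    """Integrate the unstimulated cell to its quiescent steady state.

    Converged when Vm changes by less than ``tol_mv_per_s`` over one second.
    Raises if no fixed point is reached within ``max_seconds`` of simulated
    time (e.g. an oscillatory parameter regime).
    """
    state = CellState.initial()
    p = params.scaled()
    for _ in range(int(max_seconds)):
        v0 = state.values[0]
        _integrate_single(state.values, p, dt, int(round(1000.0 / dt)), -1.0, 0.0, 0.0, 50000)
        if abs(state.values[0] - v0) < tol_mv_per_s:
            state.validate()
            return state
    raise RuntimeError(
        f"no quiescent steady state within {max_seconds:.0f} s (Vm drift "
        f"{abs(state.values[0] - v0):.3g} mV/s)"
    )


def calibrate_stimulus(
    params: CellParams,
    resting: CellState | None = None,
    duration_ms: float = DEFAULT_STIM_DURATION_MS,
    dt: float = DEFAULT_DT_MS,
    safety_factor: float = 2.0,
) -> float:
    """Diastolic-threshold stimulus amplitude times ``safety_factor`` (pA/pF).

    Bisects the square-pulse amplitude (inward, returned negative) that just
    elicits an action potential (Vm crossing 0 mV within 20 ms) from rest.
    """
    if resting is None:
        resting = find_resting_state(params, dt=dt)
    p = params.scaled()

    def fires(amp: float) -> bool:
        s = resting.values.copy()
        _, vm = _integrate_single(s, p, dt, int(round(20.0 / dt)), 0.0, duration_ms, amp, 5)
        return bool(vm.max() > 0.0)

    lo, hi = 0.0, -4.0
    while not fires(hi):
        hi *= 2.0
        if hi < -2000.0:
            raise RuntimeError("no excitation even at very large stimulus amplitude")
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        if fires(mid):
            hi = mid
        else:
            lo = mid
    return float(safety_factor * hi)


def pace_cell(
    params: CellParams,
    cycle_length_ms: float = 1000.0,
    n_beats: int = 20,
    stim_amplitude: float | None = None,
    stim_duration_ms: float = DEFAULT_STIM_DURATION_MS,
    dt: float = DEFAULT_DT_MS,
    initial: CellState | None = None,
    record_every_ms: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Pace a single cell from rest; returns (times ms, Vm mV) for all beats.

    The default stimulus is auto-calibrated to twice diastolic threshold.
    """
    if initial is None:
        initial = find_resting_state(params, dt=dt)
    if stim_amplitude is None:
        stim_amplitude = calibrate_stimulus(params, resting=initial, dt=dt)
    s = initial.values.copy()
    rec = max(1, int(round(record_every_ms / dt)))
    t, vm = _pace_single(
        s, params.scaled(), dt, cycle_length_ms, n_beats, stim_duration_ms, stim_amplitude, rec
    )
    return t, vm


@njit(cache=True, fastmath=True)
def _record_trajectory(state, params, dt, cl, n_pre_beats, stim_dur, stim_amp, n_rec):
    steps_per_beat = int(round(cl / dt))
    stim_steps = int(round(stim_dur / dt))
    for _ in range(n_pre_beats):
        for step in range(steps_per_beat):
            _cell_kernel(state, params, dt, stim_amp if step < stim_steps else 0.0)
    traj = np.empty((n_rec, state.size))
    per_rec = steps_per_beat // n_rec
    k = 0
    for step in range(steps_per_beat):
        _cell_kernel(state, params, dt, stim_amp if step < stim_steps else 0.0)
        if (step + 1) % per_rec == 0 and k < n_rec:
            traj[k] = state
            k += 1
    return traj


def ap_trajectory(
    params: CellParams,
    cycle_length_ms: float,
    n_pre_beats: int = 6,
    dt: float = DEFAULT_DT_MS,
    resting: CellState | None = None,
    stim_amplitude: float | None = None,
    sample_ms: float = 1.0,
) -> np.ndarray:
    """Full 21-state trajectory over one steady paced cycle, sampled at 1 ms.

    Row k holds the state (k+1)*sample_ms after the stimulus onset of a beat
    at quasi-steady state.  Used to initialize tissue with a phase-distributed
    action-potential pattern.
    """
    if resting is None:
        resting = find_resting_state(params, dt=dt)
    if stim_amplitude is None:
        stim_amplitude = calibrate_stimulus(params, resting=resting, dt=dt)
    n_rec = int(round(cycle_length_ms / sample_ms))
    return _record_trajectory(
        resting.values.copy(), params.scaled(), dt, cycle_length_ms, n_pre_beats,
        DEFAULT_STIM_DURATION_MS, stim_amplitude, n_rec,
    )


# ---------------------------------------------------------------------------
# AP feature measurement
# ---------------------------------------------------------------------------


def measure_apd90(
    vm_trace: np.ndarray, times: np.ndarray, repol_fraction: float = 0.9
) -> float:
    """APD90 (ms) of the last complete action potential in a trace.

    Measured from the instant of maximum upstroke velocity to the point where
    Vm has repolarized by ``repol_fraction`` of the excursion from the action
    potential peak back toward the preceding diastolic level.  Linear
    interpolation between samples at the repolarization crossing.
    """
    vm = np.asarray(vm_trace, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(vm) < 3:
        raise ValueError("trace too short")
    dv = np.diff(vm) / np.maximum(np.diff(times), 1e-12)
    if vm.max() < -30.0 or vm.max() - vm.min() < 30.0:
        raise ValueError("no action potential found in trace")
    threshold_v = vm.min() + 0.25 * (vm.max() - vm.min())
    crossing = np.flatnonzero((vm[:-1] < threshold_v) & (vm[1:] >= threshold_v))
    if len(crossing) == 0:
        raise ValueError("no depolarization found in trace")

    # last complete AP: last upstroke whose repolarization finishes in-trace
    for c in crossing[::-1]:
        lo = max(0, c - 1)
        hi = min(len(vm) - 1, c + 20)
        up = lo + int(np.argmax(dv[lo:hi]))
        prev = crossing[crossing < c]
        dia_start = prev[-1] if len(prev) else 0
        diastolic = vm[dia_start:c + 1].min() if c > dia_start else vm[0]
        peak_idx = up + int(np.argmax(vm[up:]))
        peak = vm[peak_idx]
        v90 = peak - repol_fraction * (peak - diastolic)
        below = np.flatnonzero(vm[peak_idx:] <= v90)
        if len(below) == 0:
            continue  # incomplete AP at end of trace
        k = peak_idx + below[0]
        if k == 0:
            t90 = times[0]
        else:
            frac = (vm[k - 1] - v90) / max(vm[k - 1] - vm[k], 1e-12)
            t90 = times[k - 1] + frac * (times[k] - times[k - 1])
        return float(t90 - times[up])
    raise ValueError("no complete action potential (repolarization not reached)")
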