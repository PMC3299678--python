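"""Endocardial human ventricular action-potential model with a late Na+ current.

The baseline is the Grandi-Pasqualini-Bers human ventricular myocyte model
(endocardial parameter set): Hodgkin-Huxley sarcolemmal currents, a four-state
ryanodine-receptor release scheme, explicit Ca2+/Na+ buffering and four
diffusively coupled compartments (junctional cleft, subsarcolemmal space, bulk
cytosol, SR).  A late Na+ current I_NaL = g_NaL * m^3 * h_L * (V - E_Na) is
added to the membrane current sum; its inactivation gate h_L is an extra state
variable (see :mod:`hfcell.late_sodium`).

The right-hand side is numba-compiled and operates on flat float64 arrays; the
dataclasses here are the user-facing surface.  Units follow the field's
convention: ms, mV, mM, A/F (µA/µF).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp

__all__ = [
    "ModelParameters",
    "SimulationTrace",
    "STATE_NAMES",
    "CURRENT_NAMES",
    "default_initial_state",
    "compute_derivatives",
    "integrate",
    "InvalidStateError",
    "SolverError",
]

# ---------------------------------------------------------------------------
# physical constants and cell geometry (not remodelable)
# ---------------------------------------------------------------------------
R_GAS = 8314.0        # J/(kmol K)
FRDY = 96485.0        # C/mol
TEMP = 310.0          # K
FORT = FRDY / (R_GAS * TEMP)
CMEM = 1.381e-10      # F, whole-cell capacitance

_cell_length = 100.0   # um
_cell_radius = 10.25   # um
VCELL = math.pi * _cell_radius ** 2 * _cell_length * 1e-15   # L
VMYO = 0.65 * VCELL
VSR = 0.035 * VCELL
VSL = 0.02 * VCELL
VJUNC = 0.0539 * 0.01 * VCELL

# inter-compartment diffusion (L/ms)
J_CA_JUNCSL = 1.0 / 1.2134e12
J_CA_SLMYO = 1.0 / 2.68510e11
J_NA_JUNCSL = 1.0 / (1.6382e12 / 3.0 * 100.0)
J_NA_SLMYO = 1.0 / (1.8308e10 / 3.0 * 100.0)

FJUNC = 0.11          # fraction of sarcolemmal current in the junction
FSL = 1.0 - FJUNC
FJUNC_CAL = 0.9       # L-type channels cluster at the junction
FSL_CAL = 1.0 - FJUNC_CAL

# fixed external / internal ion concentrations (mM)
CLI = 15.0
CLO = 150.0
KO = 5.4
NAO = 140.0
CAO = 1.8
MGI = 1.0

# buffering (kon: 1/(mM ms), koff: 1/ms, Bmax: mM)
BMAX_NAJ = 7.561
BMAX_NASL = 1.65
KON_NA = 0.1e-3
KOFF_NA = 1e-3
BMAX_TNCLOW = 70e-3
KON_TNCL = 32.7
KOFF_TNCL = 19.6e-3
BMAX_TNCHIGH = 140e-3
KON_TNCHCA = 2.37
KOFF_TNCHCA = 0.032e-3
KON_TNCHMG = 3e-3
KOFF_TNCHMG = 3.33e-3
BMAX_CAM = 24e-3
KON_CAM = 34.0
KOFF_CAM = 238e-3
BMAX_MYOSIN = 140e-3
KON_MYOCA = 13.8
KOFF_MYOCA = 0.46e-3
KON_MYOMG = 0.0157
KOFF_MYOMG = 0.057e-3
BMAX_SR = 19.0 * 0.9e-3
KON_SR = 100.0
KOFF_SR = 60e-3
BMAX_SLLOWSL = 37.4e-3 * VMYO / VSL
BMAX_SLLOWJ = 4.6e-3 * VMYO / VJUNC * 0.1
KON_SLL = 100.0
KOFF_SLL = 1300e-3
BMAX_SLHIGHSL = 13.4e-3 * VMYO / VSL
BMAX_SLHIGHJ = 1.65e-3 * VMYO / VJUNC * 0.1
KON_SLH = 100.0
KOFF_SLH = 30e-3
BMAX_CSQN = 140e-3 * VMYO / VSR
KON_CSQN = 100.0
KOFF_CSQN = 65.0

# NCX kinetics
KM_CAI = 3.59e-3
KM_CAO = 1.3
KM_NAI = 12.29
KM_NAO = 87.5
KSAT = 0.32
NU = 0.27
KDACT = 0.150e-3

# NaK pump
KM_NAIP = 11.0
KM_KO = 1.5

# SR release / uptake kinetics (non-remodeled part)
KOCA = 10.0     # 1/(mM^2 ms)
KOM = 0.06      # 1/ms
KICA = 0.5      # 1/(mM ms)
KIM = 0.005     # 1/ms
MAX_SR = 15.0
MIN_SR = 1.0
KMF = 0.246e-3  # mM
KMR = 1.7       # mM
HILL_SERCA = 1.787

# sarcolemmal Ca pump
KM_PCA = 0.5e-3
IBAR_SLCAP = 0.0673

GCLCA = 0.5 * 0.109625
GCLB = 9e-3
KD_CLCA = 100e-3
GKP = 2e-3
PNAK = 0.01833

# ---------------------------------------------------------------------------
# state layout
# ---------------------------------------------------------------------------
STATE_NAMES = (
    "m", "h", "j", "d", "f", "fcaBj", "fcaBsl",
    "xtos", "ytos", "xtof", "ytof", "xkr", "xks",
    "RyRr", "RyRo", "RyRi",
    "NaBj", "NaBsl",
    "TnCL", "TnCHc", "TnCHm", "CaM", "Myoc", "Myom", "SRB",
    "SLLj", "SLLsl", "SLHj", "SLHsl",
    "Csqnb", "Ca_sr",
    "Naj", "Nasl", "Nai", "Ki",
    "Caj", "Casl", "Cai",
    "V", "hL",
)
N_STATES = len(STATE_NAMES)
IDX = {name: i for i, name in enumerate(STATE_NAMES)}
IV = IDX["V"]
GATE_IDX = tuple(IDX[n] for n in ("m", "h", "j", "d", "f", "fcaBj", "fcaBsl",
                                  "xtos", "ytos", "xtof", "ytof", "xkr", "xks",
                                  "RyRr", "RyRo", "RyRi", "hL"))
CONC_IDX = tuple(IDX[n] for n in ("Ca_sr", "Naj", "Nasl", "Nai", "Ki",
                                  "Caj", "Casl", "Cai"))
NA_IDX = tuple(IDX[n] for n in ("Naj", "Nasl", "Nai"))

# recorded current decomposition (A/F for membrane currents, mM/ms for fluxes)
CURRENT_NAMES = (
    "I_NaT", "I_NaL", "I_Nab", "I_NaK", "I_to", "I_K1", "I_Kr", "I_Ks",
    "I_Kp", "I_CaL", "I_CaK", "I_CaNa", "I_NCX", "I_pCa", "I_Cab",
    "I_ClCa", "I_Clb", "I_stim", "J_serca", "J_leak", "J_rel",
)
N_CURRENTS = len(CURRENT_NAMES)
ICUR = {name: i for i, name in enumerate(CURRENT_NAMES)}
# membrane currents whose sum is -dV/dt (fluxes excluded)
MEMBRANE_CURRENTS = CURRENT_NAMES[:18]

# ---------------------------------------------------------------------------
# parameter layout (flat array for the compiled RHS)
# ---------------------------------------------------------------------------
_PARAM_FIELDS = (
    ("g_Na", 23.0),              # mS/uF, fast Na+
    ("g_NaL", 0.015),            # mS/uF, late Na+ (clamp-fitted)
    ("tau_hL", 233.0),           # ms, late Na+ inactivation at 37 C
    ("hL_V50", -91.0),           # mV, half-inactivation of h_L
    ("hL_slope", 6.1),           # mV
    ("g_Nab", 0.597e-3),         # mS/uF, background Na+
    ("g_to_slow", 0.13 * 0.3 * 0.964),   # mS/uF, endocardial I_to,slow
    ("g_to_fast", 0.13 * 0.3 * 0.036),   # mS/uF, endocardial I_to,fast
    ("g_Kr", 0.035 * math.sqrt(KO / 5.4)),
    ("g_Ks", 0.0035),
    ("g_K1", 0.35 * math.sqrt(KO / 5.4)),
    ("p_Ca", 0.5 * 5.4e-4),      # cm/s, L-type permeabilities
    ("p_K", 0.5 * 2.7e-7),
    ("p_Na", 0.5 * 1.5e-8),
    ("Ibar_NaK", 1.8),           # A/F
    ("Ibar_NCX", 4.5),           # A/F
    ("g_Cab", 5.513e-4),         # mS/uF
    ("Vmax_SERCA", 5.3114e-3),   # mM/ms
    ("k_rel", 25.0),             # 1/ms, RyR release rate (I_rel scale)
    ("k_leak", 5.348e-6),        # 1/ms, SR leak rate
    ("EC50_SR", 0.45),           # mM, luminal Ca half-activation of release
    ("stim_amplitude", 6.97),    # A/F (1.5x diastolic threshold at baseline)
    ("stim_duration", 5.0),      # ms
)
PARAM_NAMES = tuple(n for n, _ in _PARAM_FIELDS)
N_PARAMS = len(PARAM_NAMES)
PIDX = {n: i for i, n in enumerate(PARAM_NAMES)}


class InvalidStateError(ValueError):
    """State vector violates the model's domain (non-finite entries)."""


class SolverError(RuntimeError):
    """Integration failed; carries the failure time and last valid state."""

    def __init__(self, message: str, t_fail: float, last_state: np.ndarray):
        super().__init__(message)
        self.t_fail = t_fail
        self.last_state = last_state


@dataclass
class ModelParameters:
    """Maximal conductances, transport rates and stimulus definition.

    Defaults are the published endocardial baseline plus the clamp-fitted
    late Na+ parameters (g_NaL = 0.015 mS/uF, tau_hL = 233 ms at 37 C).
    """

    g_Na: float = _PARAM_FIELDS[0][1]
    g_NaL: float = _PARAM_FIELDS[1][1]
    tau_hL: float = _PARAM_FIELDS[2][1]
    hL_V50: float = _PARAM_FIELDS[3][1]
    hL_slope: float = _PARAM_FIELDS[4][1]
    g_Nab: float = _PARAM_FIELDS[5][1]
    g_to_slow: float = _PARAM_FIELDS[6][1]
    g_to_fast: float = _PARAM_FIELDS[7][1]
    g_Kr: float = _PARAM_FIELDS[8][1]
    g_Ks: float = _PARAM_FIELDS[9][1]
    g_K1: float = _PARAM_FIELDS[10][1]
    p_Ca: float = _PARAM_FIELDS[11][1]
    p_K: float = _PARAM_FIELDS[12][1]
    p_Na: float = _PARAM_FIELDS[13][1]
    Ibar_NaK: float = _PARAM_FIELDS[14][1]
    Ibar_NCX: float = _PARAM_FIELDS[15][1]
    g_Cab: float = _PARAM_FIELDS[16][1]
    Vmax_SERCA: float = _PARAM_FIELDS[17][1]
    k_rel: float = _PARAM_FIELDS[18][1]
    k_leak: float = _PARAM_FIELDS[19][1]
    EC50_SR: float = _PARAM_FIELDS[20][1]
    stim_amplitude: float = _PARAM_FIELDS[21][1]
    stim_duration: float = _PARAM_FIELDS[22][1]

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"parameter {f.name} is not finite")
        if self.tau_hL <= 0:
            raise ValueError("tau_hL must be positive")
        if self.EC50_SR <= 0:
            raise ValueError("EC50_SR must be positive")
        if self.hL_slope == 0:
            raise ValueError("hL_slope must be nonzero")
        for name in ("g_Na", "g_NaL", "g_Nab", "g_to_slow", "g_to_fast",
                     "g_Kr", "g_Ks", "g_K1", "p_Ca", "p_K", "p_Na",
                     "Ibar_NaK", "Ibar_NCX", "g_Cab", "Vmax_SERCA",
                     "k_rel", "k_leak"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "ModelParameters":
        return cls(**{n: float(arr[i]) for i, n in enumerate(PARAM_NAMES)})

    def with_updates(self, **kwargs: float) -> "ModelParameters":
        return replace(self, **kwargs)


@dataclass
class SimulationTrace:
    """Sampled time course of a run: state trajectory plus current decomposition."""

    t: np.ndarray                      # ms
    states: np.ndarray                 # (len(t), N_STATES)
    currents: np.ndarray               # (len(t), N_CURRENTS)
    final_state: np.ndarray = field(default=None)  # exact solver end state

    @property
    def V(self) -> np.ndarray:
        return self.states[:, IV]

    def state(self, name: str) -> np.ndarray:
        return self.states[:, IDX[name]]

    def current(self, name: str) -> np.ndarray:
        return self.currents[:, ICUR[name]]

    def concat(self, other: "SimulationTrace") -> "SimulationTrace":
        return SimulationTrace(
            t=np.concatenate([self.t, other.t]),
            states=np.vstack([self.states, other.states]),
            currents=np.vstack([self.currents, other.currents]),
            final_state=other.final_state,
        )


# ---------------------------------------------------------------------------
# compiled right-hand side
# ---------------------------------------------------------------------------
@njit(cache=True, fastmath=False)
def _rhs(y, p, i_app, clamp_v, clamp_na, dy, cur):  # pragma: no cover - compiled
    V = y[38]

    ena_junc = (1.0 / FORT) * math.log(NAO / y[31])
    ena_sl = (1.0 / FORT) * math.log(NAO / y[32])
    ek = (1.0 / FORT) * math.log(KO / y[34])
    eca_junc = (1.0 / (2.0 * FORT)) * math.log(CAO / y[35])
    eca_sl = (1.0 / (2.0 * FORT)) * math.log(CAO / y[36])
    ecl = (1.0 / FORT) * math.log(CLI / CLO)

    # --- fast Na+ gating -------------------------------------------------
    mss = 1.0 / (1.0 + math.exp(-(56.86 + V) / 9.03)) ** 2
    taum = 0.1292 * math.exp(-((V + 45.79) / 15.54) ** 2) \
        + 0.06487 * math.exp(-((V - 4.823) / 51.12) ** 2)
    if V >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + math.exp(-(V + 10.66) / 11.1)))
        aj = 0.0
        bj = 0.6 * math.exp(0.057 * V) / (1.0 + math.exp(-0.1 * (V + 32.0)))
    else:
        ah = 0.057 * math.exp(-(V + 80.0) / 6.8)
        bh = 2.7 * math.exp(0.079 * V) + 3.1e5 * math.exp(0.3485 * V)
        aj = ((-2.5428e4 * math.exp(0.2444 * V) - 6.948e-6 * math.exp(-0.04391 * V))
              * (V + 37.78)) / (1.0 + math.exp(0.311 * (V + 79.23)))
        bj = 0.02424 * math.exp(-0.01052 * V) / (1.0 + math.exp(-0.1378 * (V + 40.14)))
    hss = 1.0 / (1.0 + math.exp((V + 71.55) / 7.43)) ** 2
    jss = hss
    dy[0] = (mss - y[0]) / taum
    dy[1] = (hss - y[1]) * (ah + bh)
    dy[2] = (jss - y[2]) * (aj + bj)

    m3 = y[0] ** 3
    I_Na_junc = FJUNC * p[0] * m3 * y[1] * y[2] * (V - ena_junc)
    I_Na_sl = FSL * p[0] * m3 * y[1] * y[2] * (V - ena_sl)

    # --- late Na+ ---------------------------------------------------------
    hLss = 1.0 / (1.0 + math.exp((V - p[3]) / p[4]))
    dy[39] = (hLss - y[39]) / p[2]
    I_NaL_junc = FJUNC * p[1] * m3 * y[39] * (V - ena_junc)
    I_NaL_sl = FSL * p[1] * m3 * y[39] * (V - ena_sl)

    # --- background Na+ ---------------------------------------------------
    I_nabk_junc = FJUNC * p[5] * (V - ena_junc)
    I_nabk_sl = FSL * p[5] * (V - ena_sl)

    # --- Na+/K+ pump ------------------------------------------------------
    sigma = (math.exp(NAO / 67.3) - 1.0) / 7.0
    fnak = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * V * FORT)
                  + 0.0365 * sigma * math.exp(-V * FORT))
    I_nak_junc = FJUNC * p[14] * fnak * KO / (1.0 + (KM_NAIP / y[31]) ** 4) / (KO + KM_KO)
    I_nak_sl = FSL * p[14] * fnak * KO / (1.0 + (KM_NAIP / y[32]) ** 4) / (KO + KM_KO)
    I_nak = I_nak_junc + I_nak_sl

    # --- rapid delayed rectifier -----------------------------------------
    xrss = 1.0 / (1.0 + math.exp(-(V + 10.0) / 5.0))
    tauxr = 550.0 / (1.0 + math.exp((-22.0 - V) / 9.0)) * 6.0 \
        / (1.0 + math.exp((V + 11.0) / 9.0)) + 230.0 / (1.0 + math.exp((V + 40.0) / 20.0))
    dy[11] = (xrss - y[11]) / tauxr
    rkr = 1.0 / (1.0 + math.exp((V + 74.0) / 24.0))
    I_kr = p[8] * y[11] * rkr * (V - ek)

    # --- slow delayed rectifier ------------------------------------------
    eks = (1.0 / FORT) * math.log((KO + PNAK * NAO) / (y[34] + PNAK * y[33]))
    xsss = 1.0 / (1.0 + math.exp(-(V + 3.8) / 14.25))
    tauxs = 990.1 / (1.0 + math.exp(-(V + 2.436) / 14.12))
    dy[12] = (xsss - y[12]) / tauxs
    I_ks = p[9] * y[12] ** 2 * (V - eks)

    # --- plateau K+ -------------------------------------------------------
    kp_kp = 1.0 / (1.0 + math.exp(7.488 - V / 5.98))
    I_kp = GKP * kp_kp * (V - ek)

    # --- transient outward (endocardial: mostly slow) ---------------------
    xtoss = 1.0 / (1.0 + math.exp(-(V - 19.0) / 13.0))
    ytoss = 1.0 / (1.0 + math.exp((V + 19.5) / 5.0))
    tauxtos = 9.0 / (1.0 + math.exp((V + 3.0) / 15.0)) + 0.5
    tauytos = 800.0 / (1.0 + math.exp((V + 60.0) / 10.0)) + 30.0
    dy[7] = (xtoss - y[7]) / tauxtos
    dy[8] = (ytoss - y[8]) / tauytos
    I_tos = p[6] * y[7] * y[8] * (V - ek)
    tauxtof = 8.5 * math.exp(-((V + 45.0) / 50.0) ** 2) + 0.5
    tauytof = 85.0 * math.exp(-(V + 40.0) ** 2 / 220.0) + 7.0
    dy[9] = (xtoss - y[9]) / tauxtof
    dy[10] = (ytoss - y[10]) / tauytof
    I_tof = p[7] * y[9] * y[10] * (V - ek)
    I_to = I_tos + I_tof

    # --- inward rectifier -------------------------------------------------
    aki = 1.02 / (1.0 + math.exp(0.2385 * (V - ek - 59.215)))
    bki = (0.49124 * math.exp(0.08032 * (V + 5.476 - ek))
           + math.exp(0.06175 * (V - ek - 594.31))) \
        / (1.0 + math.exp(-0.5143 * (V - ek + 4.753)))
    kiss = aki / (aki + bki)
    I_k1 = p[10] * kiss * (V - ek)

    # --- Ca-activated and background Cl- ----------------------------------
    I_ClCa = FJUNC * GCLCA / (1.0 + KD_CLCA / y[35]) * (V - ecl) \
        + FSL * GCLCA / (1.0 + KD_CLCA / y[36]) * (V - ecl)
    I_Clbk = GCLB * (V - ecl)

    # --- L-type Ca2+ current ----------------------------------------------
    dss = 1.0 / (1.0 + math.exp(-(V + 5.0) / 6.0))
    if abs(V + 5.0) < 1e-6:
        taud = dss / 0.21   # limit of dss*(1-exp(-x/6))/(0.035*x) as x->0
    else:
        taud = dss * (1.0 - math.exp(-(V + 5.0) / 6.0)) / (0.035 * (V + 5.0))
    fss = 1.0 / (1.0 + math.exp((V + 35.0) / 9.0)) + 0.6 / (1.0 + math.exp((50.0 - V) / 20.0))
    tauf = 1.0 / (0.0197 * math.exp(-(0.0337 * (V + 14.5)) ** 2) + 0.02)
    dy[3] = (dss - y[3]) / taud
    dy[4] = (fss - y[4]) / tauf
    dy[5] = 1.7 * y[35] * (1.0 - y[5]) - 11.9e-3 * y[5]
    dy[6] = 1.7 * y[36] * (1.0 - y[6]) - 11.9e-3 * y[6]

    vfort = V * FORT
    if abs(vfort) < 1e-7:
        vfort = 1e-7
    e2v = math.exp(2.0 * vfort)
    e1v = math.exp(vfort)
    ibarca_j = p[11] * 4.0 * V * FRDY * FORT * (0.341 * y[35] * e2v - 0.341 * CAO) / (e2v - 1.0)
    ibarca_sl = p[11] * 4.0 * V * FRDY * FORT * (0.341 * y[36] * e2v - 0.341 * CAO) / (e2v - 1.0)
    ibark = p[12] * V * FRDY * FORT * (0.75 * y[34] * e1v - 0.75 * KO) / (e1v - 1.0)
    ibarna_j = p[13] * V * FRDY * FORT * (0.75 * y[31] * e1v - 0.75 * NAO) / (e1v - 1.0)
    ibarna_sl = p[13] * V * FRDY * FORT * (0.75 * y[32] * e1v - 0.75 * NAO) / (e1v - 1.0)
    df = y[3] * y[4]
    I_Ca_junc = FJUNC_CAL * ibarca_j * df * (1.0 - y[5]) * 0.45
    I_Ca_sl = FSL_CAL * ibarca_sl * df * (1.0 - y[6]) * 0.45
    I_Ca = I_Ca_junc + I_Ca_sl
    I_CaK = ibark * df * (FJUNC_CAL * (1.0 - y[5]) + FSL_CAL * (1.0 - y[6])) * 0.45
    I_CaNa_junc = FJUNC_CAL * ibarna_j * df * (1.0 - y[5]) * 0.45
    I_CaNa_sl = FSL_CAL * ibarna_sl * df * (1.0 - y[6]) * 0.45
    I_CaNa = I_CaNa_junc + I_CaNa_sl

    # --- Na+/Ca2+ exchanger -----------------------------------------------
    Ka_junc = 1.0 / (1.0 + (KDACT / y[35]) ** 2)
    Ka_sl = 1.0 / (1.0 + (KDACT / y[36]) ** 2)
    expnu = math.exp(NU * vfort)
    expnum1 = math.exp((NU - 1.0) * vfort)
    s1_junc = expnu * y[31] ** 3 * CAO
    s2_junc = expnum1 * NAO ** 3 * y[35]
    s3_junc = KM_CAI * NAO ** 3 * (1.0 + (y[31] / KM_NAI) ** 3) \
        + KM_NAO ** 3 * y[35] * (1.0 + y[35] / KM_CAI) \
        + KM_CAO * y[31] ** 3 + y[31] ** 3 * CAO + NAO ** 3 * y[35]
    s1_sl = expnu * y[32] ** 3 * CAO
    s2_sl = expnum1 * NAO ** 3 * y[36]
    s3_sl = KM_CAI * NAO ** 3 * (1.0 + (y[32] / KM_NAI) ** 3) \
        + KM_NAO ** 3 * y[36] * (1.0 + y[36] / KM_CAI) \
        + KM_CAO * y[32] ** 3 + y[32] ** 3 * CAO + NAO ** 3 * y[36]
    sat = 1.0 + KSAT * expnum1
    I_ncx_junc = FJUNC * p[15] * Ka_junc * (s1_junc - s2_junc) / s3_junc / sat
    I_ncx_sl = FSL * p[15] * Ka_sl * (s1_sl - s2_sl) / s3_sl / sat
    I_ncx = I_ncx_junc + I_ncx_sl

    # --- sarcolemmal Ca pump and background Ca ----------------------------
    I_pca_junc = FJUNC * IBAR_SLCAP * y[35] ** 1.6 / (KM_PCA ** 1.6 + y[35] ** 1.6)
    I_pca_sl = FSL * IBAR_SLCAP * y[36] ** 1.6 / (KM_PCA ** 1.6 + y[36] ** 1.6)
    I_pca = I_pca_junc + I_pca_sl
    I_cabk_junc = FJUNC * p[16] * (V - eca_junc)
    I_cabk_sl = FSL * p[16] * (V - eca_sl)
    I_cabk = I_cabk_junc + I_cabk_sl

    # --- SR release / uptake / leak ---------------------------------------
    kCaSR = MAX_SR - (MAX_SR - MIN_SR) / (1.0 + (p[20] / y[30]) ** 2.5)
    koSRCa = KOCA / kCaSR
    kiSRCa = KICA * kCaSR
    RI = 1.0 - y[13] - y[14] - y[15]
    dy[13] = (KIM * RI - kiSRCa * y[35] * y[13]) - (koSRCa * y[35] ** 2 * y[13] - KOM * y[14])
    dy[14] = (koSRCa * y[35] ** 2 * y[13] - KOM * y[14]) - (kiSRCa * y[35] * y[14] - KIM * y[15])
    dy[15] = (kiSRCa * y[35] * y[14] - KIM * y[15]) - (KOM * y[15] - koSRCa * y[35] ** 2 * RI)
    J_SRCarel = p[18] * y[14] * (y[30] - y[35])
    rf = (y[37] / KMF) ** HILL_SERCA
    rr = (y[30] / KMR) ** HILL_SERCA
    J_serca = p[17] * (rf - rr) / (1.0 + rf + rr)
    J_SRleak = p[19] * (y[30] - y[35])

    # --- buffering ---------------------------------------------------------
    dy[16] = KON_NA * y[31] * (BMAX_NAJ - y[16]) - KOFF_NA * y[16]
    dy[17] = KON_NA * y[32] * (BMAX_NASL - y[17]) - KOFF_NA * y[17]
    dy[18] = KON_TNCL * y[37] * (BMAX_TNCLOW - y[18]) - KOFF_TNCL * y[18]
    dy[19] = KON_TNCHCA * y[37] * (BMAX_TNCHIGH - y[19] - y[20]) - KOFF_TNCHCA * y[19]
    dy[20] = KON_TNCHMG * MGI * (BMAX_TNCHIGH - y[19] - y[20]) - KOFF_TNCHMG * y[20]
    dy[21] = KON_CAM * y[37] * (BMAX_CAM - y[21]) - KOFF_CAM * y[21]
    dy[22] = KON_MYOCA * y[37] * (BMAX_MYOSIN - y[22] - y[23]) - KOFF_MYOCA * y[22]
    dy[23] = KON_MYOMG * MGI * (BMAX_MYOSIN - y[22] - y[23]) - KOFF_MYOMG * y[23]
    dy[24] = KON_SR * y[37] * (BMAX_SR - y[24]) - KOFF_SR * y[24]
    J_CaB_cytosol = dy[18] + dy[19] + dy[20] + dy[21] + dy[22] + dy[23] + dy[24]
    dy[25] = KON_SLL * y[35] * (BMAX_SLLOWJ - y[25]) - KOFF_SLL * y[25]
    dy[26] = KON_SLL * y[36] * (BMAX_SLLOWSL - y[26]) - KOFF_SLL * y[26]
    dy[27] = KON_SLH * y[35] * (BMAX_SLHIGHJ - y[27]) - KOFF_SLH * y[27]
    dy[28] = KON_SLH * y[36] * (BMAX_SLHIGHSL - y[28]) - KOFF_SLH * y[28]
    J_CaB_junction = dy[25] + dy[27]
    J_CaB_sl = dy[26] + dy[28]

    # --- SR Ca -------------------------------------------------------------
    dy[29] = KON_CSQN * y[30] * (BMAX_CSQN - y[29]) - KOFF_CSQN * y[29]
    dy[30] = J_serca - (J_SRleak * VMYO / VSR + J_SRCarel) - dy[29]

    # --- Na compartments ---------------------------------------------------
    I_Na_tot_junc = I_Na_junc + I_NaL_junc + I_nabk_junc + 3.0 * I_ncx_junc \
        + 3.0 * I_nak_junc + I_CaNa_junc
    I_Na_tot_sl = I_Na_sl + I_NaL_sl + I_nabk_sl + 3.0 * I_ncx_sl \
        + 3.0 * I_nak_sl + I_CaNa_sl
    dy[31] = -I_Na_tot_junc * CMEM / (VJUNC * FRDY) \
        + J_NA_JUNCSL / VJUNC * (y[32] - y[31]) - dy[16]
    dy[32] = -I_Na_tot_sl * CMEM / (VSL * FRDY) \
        + J_NA_JUNCSL / VSL * (y[31] - y[32]) \
        + J_NA_SLMYO / VSL * (y[33] - y[32]) - dy[17]
    dy[33] = J_NA_SLMYO / VMYO * (y[32] - y[33])

    # --- K (held fixed, baseline convention) -------------------------------
    I_K_tot = I_to + I_kr + I_ks + I_k1 - 2.0 * I_nak + I_CaK + I_kp
    dy[34] = 0.0

    # --- Ca compartments ---------------------------------------------------
    I_Ca_tot_junc = I_Ca_junc + I_cabk_junc + I_pca_junc - 2.0 * I_ncx_junc
    I_Ca_tot_sl = I_Ca_sl + I_cabk_sl + I_pca_sl - 2.0 * I_ncx_sl
    dy[35] = -I_Ca_tot_junc * CMEM / (VJUNC * 2.0 * FRDY) \
        + J_CA_JUNCSL / VJUNC * (y[36] - y[35]) - J_CaB_junction \
        + J_SRCarel * VSR / VJUNC + J_SRleak * VMYO / VJUNC
    dy[36] = -I_Ca_tot_sl * CMEM / (VSL * 2.0 * FRDY) \
        + J_CA_JUNCSL / VSL * (y[35] - y[36]) \
        + J_CA_SLMYO / VSL * (y[37] - y[36]) - J_CaB_sl
    dy[37] = -J_serca * VSR / VMYO - J_CaB_cytosol + J_CA_SLMYO / VMYO * (y[36] - y[37])

    # --- membrane potential -------------------------------------------------
    I_Na_tot = I_Na_tot_junc + I_Na_tot_sl
    I_Cl_tot = I_ClCa + I_Clbk
    I_Ca_tot = I_Ca_tot_junc + I_Ca_tot_sl
    I_tot = I_Na_tot + I_Cl_tot + I_Ca_tot + I_K_tot
    dy[38] = -(I_tot - i_app)

    if clamp_v:
        dy[38] = 0.0
    if clamp_na:
        dy[31] = 0.0
        dy[32] = 0.0
        dy[33] = 0.0

    cur[0] = I_Na_junc + I_Na_sl
    cur[1] = I_NaL_junc + I_NaL_sl
    cur[2] = I_nabk_junc + I_nabk_sl
    cur[3] = I_nak
    cur[4] = I_to
    cur[5] = I_k1
    cur[6] = I_kr
    cur[7] = I_ks
    cur[8] = I_kp
    cur[9] = I_Ca
    cur[10] = I_CaK
    cur[11] = I_CaNa
    cur[12] = I_ncx
    cur[13] = I_pca
    cur[14] = I_cabk
    cur[15] = I_ClCa
    cur[16] = I_Clbk
    cur[17] = -i_app
    cur[18] = J_serca
    cur[19] = J_SRleak
    cur[20] = J_SRCarel


@njit(cache=True)
def _rhs_dy(t, y, p, i_app, clamp_v, clamp_na):  # pragma: no cover - compiled
    dy = np.empty(40)
    cur = np.empty(21)
    _rhs(y, p, i_app, clamp_v, clamp_na, dy, cur)
    return dy


def compute_derivatives(state, params, t=0.0, stim=0.0, *, clamp_v=False,
                        clamp_na=False):
    """Evaluate the model right-hand side at one state.

    Parameters
    ----------
    state : array-like of length 40 (see STATE_NAMES)
    params : ModelParameters or flat parameter array
    stim : applied stimulus current (A/F, depolarizing positive)

    Returns
    -------
    (derivatives, currents) : two 1-D arrays; ``currents`` follows
    CURRENT_NAMES, with the stimulus recorded as a membrane current of
    opposite sign so that dV/dt = -(sum of membrane currents).
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (N_STATES,):
        raise InvalidStateError(f"state must have length {N_STATES}")
    if not np.all(np.isfinite(y)):
        raise InvalidStateError("state contains non-finite entries")
    p = params.to_array() if isinstance(params, ModelParameters) else np.asarray(params, float)
    if p.shape != (N_PARAMS,):
        raise ValueError("parameter vector incomplete")
    dy = np.empty(N_STATES)
    cur = np.empty(N_CURRENTS)
    _rhs(y, p, float(stim), clamp_v, clamp_na, dy, cur)
    return dy, cur


def default_initial_state() -> np.ndarray:
    """Near-resting initial state (1-Hz vicinity); pace to steady state before
    measuring."""
    y = np.zeros(N_STATES)
    vals = {
        "m": 1.405627e-3, "h": 0.9867005, "j": 0.991562,
        "d": 7.175662e-6, "f": 1.000681, "fcaBj": 2.421991e-2, "fcaBsl": 1.452605e-2,
        "xtos": 4.051574e-3, "ytos": 0.9945511, "xtof": 4.051574e-3, "ytof": 0.9945511,
        "xkr": 8.641386e-3, "xks": 5.412034e-3,
        "RyRr": 0.8884332, "RyRo": 8.156628e-7, "RyRi": 1.024274e-7,
        "NaBj": 3.539892, "NaBsl": 0.7720854,
        "TnCL": 8.773191e-3, "TnCHc": 0.1078283, "TnCHm": 1.524002e-2,
        "CaM": 2.911916e-4, "Myoc": 1.298754e-3, "Myom": 0.1381982,
        "SRB": 2.143165e-3,
        "SLLj": 9.566355e-3, "SLLsl": 0.1110363,
        "SLHj": 7.347888e-3, "SLHsl": 7.297378e-2,
        "Csqnb": 1.242988, "Ca_sr": 0.5545201,
        "Naj": 9.136, "Nasl": 9.136, "Nai": 9.136, "Ki": 120.0,
        "Caj": 1.737475e-4, "Casl": 1.031812e-4, "Cai": 8.597401e-5,
        "V": -81.0,
    }
    for k, v in vals.items():
        y[IDX[k]] = v
    y[IDX["hL"]] = 1.0 / (1.0 + math.exp((vals["V"] + 91.0) / 6.1))
    return y


@dataclass
class SolverSettings:
    rtol: float = 1e-6
    atol: float = 1e-8
    max_step: float = 1.0     # ms
    output_dt: float = 0.1    # ms sampling interval of the returned trace
    method: str = "LSODA"


def _currents_along(ts, ys, p, stim_fn, clamp_v, clamp_na):
    cur = np.empty((len(ts), N_CURRENTS))
    dy = np.empty(N_STATES)
    for i in range(len(ts)):
        _rhs(ys[i], p, stim_fn(ts[i]), clamp_v, clamp_na, dy, cur[i])
    return cur


def integrate(initial, params, stimulus, duration, settings=None, *,
              t0=0.0, clamp_v=False, clamp_na=False, record=True):
    """Integrate the model over ``duration`` ms.

    ``stimulus`` is a sequence of (onset_ms, duration_ms, amplitude_A_per_F)
    pulses (absolute times).  The integration is split at pulse edges so the
    discontinuous forcing never crosses a solver step.  Returns a
    SimulationTrace sampled every ``settings.output_dt`` ms (empty when
    ``record`` is False or duration == 0; final_state always set).
    """
    settings = settings or SolverSettings()
    y = np.array(initial, dtype=float)
    if not np.all(np.isfinite(y)):
        raise InvalidStateError("initial state contains non-finite entries")
    p = params.to_array() if isinstance(params, ModelParameters) else np.asarray(params, float)
    if duration < 0:
        raise ValueError("duration must be >= 0")
    t_end = t0 + duration

    # build breakpoints at pulse edges
    edges = {t0, t_end}
    for (on, dur, _amp) in stimulus:
        if t0 < on < t_end:
            edges.add(on)
        if t0 < on + dur < t_end:
            edges.add(on + dur)
    edges = sorted(edges)

    def amp_at(t):
        for (on, dur, amp) in stimulus:
            if on <= t < on + dur:
                return amp
        return 0.0

    ts_all, ys_all = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        amp = amp_at(0.5 * (a + b))
        if record:
            n = max(int(round((b - a) / settings.output_dt)), 1)
            t_eval = np.linspace(a, b, n + 1)
        else:
            t_eval = np.array([a, b])
        sol = solve_ivp(
            _rhs_dy, (a, b), y, method=settings.method, t_eval=t_eval,
            args=(p, amp, clamp_v, clamp_na),
            rtol=settings.rtol, atol=settings.atol, max_step=settings.max_step,
        )
        if not sol.success:
            raise SolverError(f"solver failed at t={sol.t[-1]:.3f} ms: {sol.message}",
                              sol.t[-1], sol.y[:, -1].copy())
        y = sol.y[:, -1].copy()
        # drop duplicated segment-start sample
        start = 1 if ts_all else 0
        ts_all.append(sol.t[start:])
        ys_all.append(sol.y.T[start:])

    if not ts_all:
        t_arr = np.array([t0])
        y_arr = y[None, :].copy()
    else:
        t_arr = np.concatenate(ts_all)
        y_arr = np.vstack(ys_all)
    if record:
        cur = _currents_along(t_arr, y_arr, p, amp_at, clamp_v, clamp_na)
    else:
        cur = np.empty((0, N_CURRENTS))
        t_arr = t_arr[:0]
        y_arr = y_arr[:0]
    return SimulationTrace(t=t_arr, states=y_arr, currents=cur, final_state=y)
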