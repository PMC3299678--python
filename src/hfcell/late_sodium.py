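"""Late Na+ current (I_NaL) as an isolated, unit-testable component.

I_NaL is the slowly inactivating component of the Na+ current.  It shares the
fast Na+ activation gate (m, cubed) and the Na+ Nernst potential with the
transient current and adds a single slow inactivation gate h_L:

    I_NaL = g_NaL * m^3 * h_L * (V - E_Na)
    dh_L/dt = (h_L_inf(V) - h_L) / tau_hL
    h_L_inf(V) = 1 / (1 + exp((V - V50) / slope))

Defaults: g_NaL = 0.015 mS/uF (fitted so a -120 -> -20 mV clamp gives an
I_NaL/I_NaT ratio near 0.1%), tau_hL = 233 ms (37 C; a Q10 of 2.2 relates this
to the room-temperature measurement), V50 = -91 mV, slope = 6.1 mV.  Decay
under clamp is single-exponential by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LateSodiumParams", "hL_inf", "hL_derivative", "hL_exact", "compute_INaL"]


@dataclass
class LateSodiumParams:
    g_NaL: float = 0.015    # mS/uF
    tau_hL: float = 233.0   # ms
    V50: float = -91.0      # mV
    slope: float = 6.1      # mV

    def __post_init__(self) -> None:
        if self.g_NaL < 0:
            raise ValueError("g_NaL must be >= 0")
        if self.tau_hL <= 0:
            raise ValueError("tau_hL must be > 0")
        if self.slope == 0:
            raise ValueError("slope must be nonzero")


def hL_inf(V, params: LateSodiumParams = LateSodiumParams()):
    """Steady-state inactivation: decreasing sigmoid, 0.5 at V50, range (0,1)."""
    V = np.asarray(V, dtype=float)
    out = 1.0 / (1.0 + np.exp((V - params.V50) / params.slope))
    return out.item() if out.ndim == 0 else out


def hL_derivative(h_L, V, params: LateSodiumParams = LateSodiumParams()):
    """dh_L/dt (1/ms): first-order relaxation toward hL_inf(V)."""
    return (hL_inf(V, params) - h_L) / params.tau_hL


def hL_exact(h0: float, V: float, t, params: LateSodiumParams = LateSodiumParams()):
    """Closed-form h_L(t) at fixed V: exponential relaxation with rate 1/tau_hL."""
    hinf = hL_inf(V, params)
    t = np.asarray(t, dtype=float)
    out = hinf + (h0 - hinf) * np.exp(-t / params.tau_hL)
    return out.item() if out.ndim == 0 else out


def compute_INaL(V, m, h_L, E_Na, params: LateSodiumParams = LateSodiumParams()):
    """I_NaL (A/F).  Zero at V = E_Na; sign follows (V - E_Na).

    ``m`` is the fast Na+ activation gate (the activation term is m^3, shared
    with the transient current)."""
    return params.g_NaL * np.asarray(m, float) ** 3 * h_L * (np.asarray(V, float) - E_Na)
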