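"""Synthetic fixtures with closed-form biomarker values, plus a small
excitable ODE for integrator tests.

These generators exist so the biomarker extractors and the integration
machinery can be tested against hand-computable answers, independent of the
full myocyte model.
"""

from __future__ import annotations

import numpy as np

__all__ = ["generate_fixtures"]


def _triangular_ap(peak=40.0, rest=-85.0, duration=300.0, dt=0.1, pre=10.0):
    """Linear ramp from peak to rest over ``duration`` ms after an
    instantaneous upstroke at t = pre.  apd(level) = level * duration."""
    t = np.arange(0.0, pre + duration + 50.0 + dt, dt)
    V = np.full_like(t, rest)
    up = t >= pre
    ramp = np.clip((t[up] - pre) / duration, 0.0, 1.0)
    V[up] = peak + (rest - peak) * ramp
    return t, V


def _plateau_ap(peak=35.0, plateau=0.0, rest=-85.0, t_plateau=200.0,
                t_repol=100.0, dt=0.1, pre=10.0):
    """Two-segment repolarization: peak -> plateau over t_plateau, plateau ->
    rest over t_repol.  Crossings are piecewise-linear and hand-computable."""
    t = np.arange(0.0, pre + t_plateau + t_repol + 50.0 + dt, dt)
    V = np.full_like(t, rest)
    seg1 = (t >= pre) & (t < pre + t_plateau)
    V[seg1] = peak + (plateau - peak) * (t[seg1] - pre) / t_plateau
    seg2 = (t >= pre + t_plateau) & (t < pre + t_plateau + t_repol)
    V[seg2] = plateau + (rest - plateau) * (t[seg2] - pre - t_plateau) / t_repol
    return t, V


def _exp_ca(dia=1e-4, amp=4e-4, k=5e-3, dt=0.1, pre=10.0, total=1500.0):
    """Instant rise at t=pre then exponential decay at rate k (1/ms):
    tau_Ca (time to 10% of amplitude) = ln(10)/k."""
    t = np.arange(0.0, total + dt, dt)
    ca = np.full_like(t, dia)
    post = t >= pre
    ca[post] = dia + amp * np.exp(-k * (t[post] - pre))
    return t, ca


def _pl_ca(dia=1e-4, amp=4e-4, t_rise=20.0, t_fall=400.0, dt=0.1, pre=10.0):
    """Piecewise-linear transient; decays to 10% of amplitude at
    pre + t_rise + 0.9 * t_fall."""
    t = np.arange(0.0, pre + t_rise + t_fall + 100.0 + dt, dt)
    ca = np.full_like(t, dia)
    rise = (t >= pre) & (t < pre + t_rise)
    ca[rise] = dia + amp * (t[rise] - pre) / t_rise
    fall = (t >= pre + t_rise) & (t < pre + t_rise + t_fall)
    ca[fall] = dia + amp * (1.0 - (t[fall] - pre - t_rise) / t_fall)
    return t, ca


def _ncx_crossing(t_cross=120.0, dt=0.1, total=600.0, pre=10.0):
    """Current that starts positive after the (synthetic) upstroke and
    crosses zero exactly at t = pre + t_cross."""
    t = np.arange(0.0, total + dt, dt)
    i = 0.5 - 0.5 * (t - pre) / t_cross    # positive after the upstroke,
    i[t < pre] = 0.5                       # crosses zero once at pre + t_cross
    V = np.where(t >= pre, 20.0 - 0.1 * (t - pre), -80.0)  # upstroke marker
    return t, i, V


def _ead_ap(bump_time=400.0, bump_amp=10.0, dt=0.1):
    """Triangular AP with a raised-cosine bump of ``bump_amp`` mV centred at
    ``bump_time``; exactly one EAD event for amplitudes above threshold."""
    t, V = _triangular_ap(duration=600.0, dt=dt)
    w = 60.0
    mask = np.abs(t - bump_time) < w / 2
    V[mask] += bump_amp * 0.5 * (1 + np.cos(2 * np.pi * (t[mask] - bump_time) / w))
    return t, V


def _excitable2d():
    """FitzHugh-Nagumo right-hand side and a known resting point, for
    exercising the integration plumbing on a cheap excitable system."""
    a, b, eps = 0.7, 0.8, 0.08

    def rhs(t, y):
        v, w = y
        return np.array([v - v ** 3 / 3.0 - w, eps * (v + a - b * w)])

    # resting point solves v - v^3/3 - w = 0, v + a - b w = 0
    from scipy.optimize import fsolve
    rest = fsolve(lambda y: rhs(0.0, y), np.array([-1.2, -0.6]))
    return rhs, rest


def generate_fixtures(kind: str, **params):
    """Dispatch: kinds are 'triangular_ap', 'plateau_ap', 'exp_ca', 'pl_ca',
    'ncx_crossing', 'ead_ap', 'excitable2d'."""
    table = {
        "triangular_ap": _triangular_ap,
        "plateau_ap": _plateau_ap,
        "exp_ca": _exp_ca,
        "pl_ca": _pl_ca,
        "ncx_crossing": _ncx_crossing,
        "ead_ap": _ead_ap,
        "excitable2d": _excitable2d,
    }
    if kind not in table:
        raise KeyError(f"unknown fixture kind {kind!r}")
    return table[kind](**params)
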