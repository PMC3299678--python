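"""Scalar electrophysiological characteristics extracted from traces.

All extractors work on one beat: arrays ``t`` (ms) and a signal, with the
stimulus onset time marking the start of the beat.  Crossings are linearly
interpolated between samples, so results are stable under resampling.  The
action-potential-duration clock starts at the maximum upstroke velocity
(max dV/dt), not at stimulus onset.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import List, Optional, Tuple

import numpy as np

__all__ = [
    "BiomarkerSet", "apd", "ca_transient_metrics", "t_ncxrp", "detect_eads",
    "RepolarizationFailure", "FlatTraceError", "NoSignChangeError",
    "beat_biomarkers",
]

CHARACTERISTICS = (
    "APD90", "APD50", "triangulation", "Ca_sys", "Ca_dia", "tau_ca",
    "CaSR_sys", "CaSR_dia", "Nai", "t_NCXRP",
)


class RepolarizationFailure(RuntimeError):
    """The membrane never recrossed the repolarization level within the beat."""


class FlatTraceError(ValueError):
    """No transient present (flat or non-decaying trace)."""


class NoSignChangeError(RuntimeError):
    """The current trace never changes sign after the upstroke."""


@dataclass
class BiomarkerSet:
    """One beat's characteristics (ms, mM); ``eads`` is the per-beat count."""

    APD90: float
    APD50: float
    triangulation: float
    Ca_sys: float
    Ca_dia: float
    tau_ca: float
    CaSR_sys: Optional[float] = None
    CaSR_dia: Optional[float] = None
    Nai: Optional[float] = None
    t_NCXRP: Optional[float] = None
    eads: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


def _interp_crossing(t0, t1, v0, v1, level):
    # linear interpolation of the time where v crosses `level`
    if v1 == v0:
        return t0
    return t0 + (level - v0) * (t1 - t0) / (v1 - v0)


def _upstroke_index(t: np.ndarray, V: np.ndarray) -> int:
    dv = np.diff(V) / np.diff(t)
    return int(np.argmax(dv))


def apd(t, V, level: float, stim_time: Optional[float] = None) -> float:
    """Action potential duration at ``level`` (0.9 -> APD90), in ms.

    Measured from the time of maximum dV/dt to the interpolated crossing of
    V_repol = V_peak - level * (V_peak - V_diastolic).  V_diastolic is the
    value just before the stimulus (``stim_time``; defaults to the start of
    the beat).  Raises RepolarizationFailure if V never recrosses the level.
    """
    t = np.asarray(t, float)
    V = np.asarray(V, float)
    if not 0.0 <= level <= 1.0:
        raise ValueError("level must be in [0, 1]")
    if stim_time is None:
        v_dia = V[0]
    else:
        i_pre = np.searchsorted(t, stim_time, side="right") - 1
        v_dia = V[max(i_pre, 0)]
    i_up = _upstroke_index(t, V)
    t_up = 0.5 * (t[i_up] + t[i_up + 1])  # midpoint of the steepest interval
    i_peak = i_up + int(np.argmax(V[i_up:]))
    v_peak = V[i_peak]
    if v_peak <= 0.0:
        raise RepolarizationFailure("no elicited action potential (peak V <= 0 mV)")
    v_level = v_peak - level * (v_peak - v_dia)
    below = np.nonzero(V[i_peak:] <= v_level)[0]
    if len(below) == 0:
        raise RepolarizationFailure(
            f"V never repolarized to {v_level:.2f} mV within the beat")
    k = i_peak + below[0]
    t_cross = _interp_crossing(t[k - 1], t[k], V[k - 1], V[k], v_level)
    return float(t_cross - t_up)


def ca_transient_metrics(t, ca, stim_time: Optional[float] = None
                         ) -> Tuple[float, float, float]:
    """(systolic, diastolic, tau_Ca) for one Ca2+ transient.

    Diastolic is the pre-stimulus value, systolic the beat maximum, and
    tau_Ca the time from the peak until the transient first decays to 10% of
    its amplitude above diastolic (interpolated).
    """
    t = np.asarray(t, float)
    ca = np.asarray(ca, float)
    if stim_time is None:
        dia = float(ca[0])
    else:
        i_pre = np.searchsorted(t, stim_time, side="right") - 1
        dia = float(ca[max(i_pre, 0)])
    i_peak = int(np.argmax(ca))
    sys = float(ca[i_peak])
    amp = sys - dia
    if amp <= 0 or not np.isfinite(amp):
        raise FlatTraceError("no Ca2+ transient present")
    level = dia + 0.1 * amp
    below = np.nonzero(ca[i_peak:] <= level)[0]
    if len(below) == 0:
        raise FlatTraceError("Ca2+ transient does not decay to 10% of amplitude")
    k = i_peak + below[0]
    t_cross = _interp_crossing(t[k - 1], t[k], ca[k - 1], ca[k], level)
    return sys, dia, float(t_cross - t[i_peak])


def t_ncxrp(t, i_ncx, t_stim: float = None, V=None) -> float:
    """Time (ms, relative to stimulus onset) of the first sign change of the
    Na+/Ca2+ exchanger current after the upstroke."""
    t = np.asarray(t, float)
    i_ncx = np.asarray(i_ncx, float)
    t0 = t[0] if t_stim is None else t_stim
    i_start = _upstroke_index(t, np.asarray(V, float)) if V is not None else \
        np.searchsorted(t, t0)
    neg = np.signbit(i_ncx[i_start:])
    change = np.nonzero(neg[1:] != neg[:-1])[0]
    if len(change) == 0:
        raise NoSignChangeError("I_NCX never changes sign after the upstroke")
    k = i_start + change[0]
    t_cross = _interp_crossing(t[k], t[k + 1], i_ncx[k], i_ncx[k + 1], 0.0)
    return float(t_cross - t0)


def detect_eads(t, V, threshold_mV: float = 1.0, search_start_ms: float = 50.0
                ) -> List[Tuple[float, float]]:
    """Early afterdepolarizations in one beat: (time, amplitude) events.

    An EAD is a local minimum of V followed by a local maximum, after the
    initial upstroke and before 90% repolarization, with an upward deflection
    larger than ``threshold_mV``.  The search window starts
    ``search_start_ms`` after the upstroke; if the beat never reaches 90%
    repolarization the window extends to the end of the beat.
    """
    t = np.asarray(t, float)
    V = np.asarray(V, float)
    i_up = _upstroke_index(t, V)
    if V[i_up:].max() <= 0.0:
        return []
    try:
        end = t[i_up] + apd(t, V, 0.9)
    except RepolarizationFailure:
        end = t[-1]
    mask = (t >= t[i_up] + search_start_ms) & (t <= end)
    idx = np.nonzero(mask)[0]
    if len(idx) < 3:
        return []
    seg = V[idx]
    ts = t[idx]
    events = []
    i = 0
    while i < len(seg) - 1:
        # next local minimum
        while i < len(seg) - 1 and seg[i + 1] <= seg[i]:
            i += 1
        v_min, i_min = seg[i], i
        # following local maximum
        while i < len(seg) - 1 and seg[i + 1] >= seg[i]:
            i += 1
        if i > i_min and seg[i] - v_min > threshold_mV:
            events.append((float(ts[i]), float(seg[i] - v_min)))
        i += 1
    return events


def beat_biomarkers(trace, stim_time: float, *, want_ncxrp: bool = True) -> BiomarkerSet:
    """Extract a full BiomarkerSet from one beat of a SimulationTrace."""
    t, V = trace.t, trace.V
    cai = trace.state("Cai")
    casr = trace.state("Ca_sr")
    apd90 = apd(t, V, 0.9, stim_time)
    apd50 = apd(t, V, 0.5, stim_time)
    ca_sys, ca_dia, tau = ca_transient_metrics(t, cai, stim_time)
    tn = None
    if want_ncxrp:
        try:
            tn = t_ncxrp(t, trace.current("I_NCX"), stim_time, V=V)
        except NoSignChangeError:
            tn = None
    i_pre = max(np.searchsorted(t, stim_time, side="right") - 1, 0)
    return BiomarkerSet(
        APD90=apd90, APD50=apd50, triangulation=apd90 - apd50,
        Ca_sys=ca_sys, Ca_dia=ca_dia, tau_ca=tau,
        CaSR_sys=float(casr.max()), CaSR_dia=float(casr[i_pre]),
        Nai=float(trace.state("Nai")[i_pre]), t_NCXRP=tn,
        eads=len(detect_eads(t, V)),
    )
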