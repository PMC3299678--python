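"""Stimulation protocols: voltage clamp, pacing to steady state, staircase,
rate dependence, Na+ clamp, and the EAD-induction protocol.

All drivers are deterministic functions of (parameters, remodeling spec,
initial state, solver settings).  Pacing uses a rectangular stimulus pulse
(amplitude and duration from ModelParameters; the default is 1.5x the
diastolic threshold determined once at baseline) delivered 10 ms into each
cycle so every beat carries a pre-stimulus diastolic sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .biomarkers import (BiomarkerSet, apd, beat_biomarkers, detect_eads,
                         RepolarizationFailure)
from .model import (IDX, ModelParameters, SimulationTrace, SolverSettings,
                    default_initial_state, integrate)
from .remodeling import RemodelingSpec, overlay as compose_overlay

__all__ = [
    "PacingProtocol", "PacingResult", "NoCaptureError",
    "run_voltage_clamp", "run_to_steady_state", "run_staircase",
    "run_rate_dependence", "run_na_clamp", "run_ead_protocol",
]

STIM_OFFSET = 10.0  # ms into each cycle


class NoCaptureError(RuntimeError):
    """Stimulus failed to elicit an action potential."""

    def __init__(self, message: str, diastolic_V: float):
        super().__init__(message)
        self.diastolic_V = diastolic_V


@dataclass
class PacingProtocol:
    """Pacing configuration: frequency, beat limit and steady-state criterion."""

    frequency: float = 1.0          # Hz
    beat_limit: int = 1000
    apd_tol: float = 0.05           # ms, over 5 consecutive beats
    nai_tol: float = 1e-4           # mM per beat
    record_beats: int = 2

    def __post_init__(self):
        if not 0.1 < self.frequency < 5.0:
            raise ValueError("frequency must be in (0.1, 5) Hz")
        if self.beat_limit < 1:
            raise ValueError("beat_limit must be >= 1")


@dataclass
class PacingResult:
    biomarkers: BiomarkerSet
    trace: SimulationTrace          # last record_beats beats, 0.1-ms sampling
    final_state: np.ndarray
    beats: int
    criterion: str                  # "steady_state" | "beat_limit"
    frequency: float
    apd_history: List[float] = field(default_factory=list)
    nai_history: List[float] = field(default_factory=list)
    stim_times: List[float] = field(default_factory=list)  # within trace


def _apply(params: ModelParameters, spec: Optional[RemodelingSpec]) -> ModelParameters:
    return spec.apply(params) if spec is not None else params


def _one_beat(y, params, cl, settings, *, record=False, output_dt=None,
              clamp_na=False):
    s = settings
    if output_dt is not None:
        s = SolverSettings(rtol=settings.rtol, atol=settings.atol,
                           max_step=settings.max_step, output_dt=output_dt,
                           method=settings.method)
    stim = [(STIM_OFFSET, params.stim_duration, params.stim_amplitude)]
    return integrate(y, params, stim, cl, settings=s, record=record,
                     clamp_na=clamp_na)


def run_to_steady_state(params: ModelParameters,
                        spec: Optional[RemodelingSpec] = None,
                        frequency: float = 1.0,
                        initial: Optional[np.ndarray] = None,
                        settings: Optional[SolverSettings] = None,
                        protocol: Optional[PacingProtocol] = None,
                        clamp_na: bool = False) -> PacingResult:
    """Pace until APD90 and [Na+]i stop drifting, then record the last beats.

    Criterion: |dAPD90| < apd_tol over 5 consecutive beats AND per-beat
    |d[Na+]i| < nai_tol, checked on explicit verification beats once the
    [Na+]i drift (the slow variable) has settled; stops at ``beat_limit``
    otherwise and records which criterion fired.
    """
    protocol = protocol or PacingProtocol(frequency=frequency)
    settings = settings or SolverSettings()
    p = _apply(params, spec)
    cl = 1000.0 / protocol.frequency
    y = default_initial_state() if initial is None else np.array(initial, float)

    beats = 0
    criterion = "beat_limit"
    nai_hist = [y[IDX["Nai"]]]
    apd_hist: List[float] = []
    while beats < protocol.beat_limit:
        # bulk pacing, unrecorded: wait for the slow [Na+]i drift to settle
        tr = _one_beat(y, p, cl, settings, clamp_na=clamp_na)
        y = tr.final_state
        beats += 1
        nai_hist.append(y[IDX["Nai"]])
        nai_ok = len(nai_hist) >= 6 and np.all(
            np.abs(np.diff(nai_hist[-6:])) < protocol.nai_tol)
        if not nai_ok:
            continue
        # verification: recorded beats for the APD criterion
        apds = []
        ok = True
        for _ in range(6):
            if beats >= protocol.beat_limit:
                ok = False
                break
            tr = _one_beat(y, p, cl, settings, record=True, output_dt=1.0,
                           clamp_na=clamp_na)
            y = tr.final_state
            beats += 1
            nai_hist.append(y[IDX["Nai"]])
            if tr.V.max() <= 0.0:
                raise NoCaptureError(
                    f"no AP elicited at {protocol.frequency} Hz "
                    f"(diastolic V = {tr.V[0]:.1f} mV)", float(tr.V[0]))
            try:
                apds.append(apd(tr.t - tr.t[0], tr.V, 0.9, STIM_OFFSET))
            except RepolarizationFailure:
                ok = False
                break
        apd_hist.extend(apds)
        if ok and len(apds) == 6 \
                and np.all(np.abs(np.diff(apds)) < protocol.apd_tol) \
                and np.all(np.abs(np.diff(nai_hist[-6:])) < protocol.nai_tol):
            criterion = "steady_state"
            break

    # final recorded beats at fine sampling for biomarker extraction
    traces = []
    stim_times = []
    t0 = 0.0
    for _ in range(max(protocol.record_beats, 1)):
        tr = _one_beat(y, p, cl, settings, record=True, clamp_na=clamp_na)
        y = tr.final_state
        beats += 1
        tr = SimulationTrace(tr.t + t0, tr.states, tr.currents, tr.final_state)
        stim_times.append(t0 + STIM_OFFSET)
        traces.append(tr)
        t0 += cl
    trace = traces[0]
    for tr in traces[1:]:
        trace = trace.concat(tr)
    last = traces[-1]
    bm = beat_biomarkers(
        SimulationTrace(last.t - last.t[0], last.states, last.currents,
                        last.final_state), STIM_OFFSET)
    return PacingResult(bm, trace, y, beats, criterion, protocol.frequency,
                        apd_hist, nai_hist, stim_times)


# ---------------------------------------------------------------------------
# voltage clamp
# ---------------------------------------------------------------------------

def run_voltage_clamp(params: ModelParameters,
                      spec: Optional[RemodelingSpec] = None,
                      hold_mV: float = -120.0, step_mV: float = -20.0,
                      hold_ms: float = 5000.0, step_ms: float = 2500.0,
                      settings: Optional[SolverSettings] = None):
    """-120 -> -20 mV step clamp; returns (trace, I_NaL/I_NaT ratio in %).

    The ratio is I_NaL measured 40 ms after the step divided by the peak
    transient Na+ current during the step.  The holding period (default 5 s,
    > 20 tau_hL) lets h_L equilibrate.
    """
    if step_ms < 40.0:
        raise ValueError("step must last at least 40 ms to measure I_NaL")
    settings = settings or SolverSettings()
    p = _apply(params, spec)
    y = default_initial_state()
    y[IDX["V"]] = hold_mV
    tr = integrate(y, p, [], hold_ms, settings=settings, clamp_v=True,
                   record=False)
    y = tr.final_state
    y[IDX["V"]] = step_mV
    # fine sampling over the transient peak, coarse afterwards
    s_fine = SolverSettings(rtol=settings.rtol, atol=settings.atol,
                            max_step=0.05, output_dt=0.01, method=settings.method)
    tr1 = integrate(y, p, [], 5.0, settings=s_fine, clamp_v=True)
    s_coarse = SolverSettings(rtol=settings.rtol, atol=settings.atol,
                              max_step=settings.max_step, output_dt=1.0,
                              method=settings.method)
    tr2 = integrate(tr1.final_state, p, [], step_ms - 5.0, settings=s_coarse,
                    t0=5.0, clamp_v=True)
    trace = tr1.concat(tr2)
    i_nat_peak = float(np.abs(trace.current("I_NaT")).max())
    i_nal_40 = float(np.interp(40.0, trace.t, trace.current("I_NaL")))
    ratio = 0.0 if i_nat_peak == 0 else abs(i_nal_40) / i_nat_peak * 100.0
    return trace, ratio


# ---------------------------------------------------------------------------
# staircase
# ---------------------------------------------------------------------------

def run_staircase(params: ModelParameters,
                  spec: Optional[RemodelingSpec] = None,
                  stages: Sequence[float] = (0.5, 1.0, 1.5, 2.0, 2.5),
                  stage_minutes: float = 10.0,
                  initial: Optional[np.ndarray] = None,
                  settings: Optional[SolverSettings] = None):
    """Consecutive pacing stages at increasing rates, state carried over.

    Returns a list of per-stage dicts: frequency, last-beat diastolic and
    systolic [Ca2+]i, and end-stage [Na+]i.
    """
    settings = settings or SolverSettings()
    p = _apply(params, spec)
    y = default_initial_state() if initial is None else np.array(initial, float)
    out = []
    for f in stages:
        cl = 1000.0 / f
        n_beats = int(round(stage_minutes * 60.0 * f))
        for _ in range(max(n_beats - 1, 0)):
            y = _one_beat(y, p, cl, settings).final_state
        tr = _one_beat(y, p, cl, settings, record=True, output_dt=0.5)
        y = tr.final_state
        cai = tr.state("Cai")
        i_pre = max(np.searchsorted(tr.t, STIM_OFFSET, side="right") - 1, 0)
        out.append({
            "frequency": f,
            "Ca_dia": float(cai[i_pre]),
            "Ca_sys": float(cai.max()),
            "Nai": float(y[IDX["Nai"]]),
        })
    return out


# ---------------------------------------------------------------------------
# rate dependence
# ---------------------------------------------------------------------------

def run_rate_dependence(params: ModelParameters,
                        spec: Optional[RemodelingSpec] = None,
                        frequencies: Sequence[float] = (0.5, 1.0, 1.25, 1.6),
                        initial: Optional[np.ndarray] = None,
                        settings: Optional[SolverSettings] = None,
                        protocol: Optional[PacingProtocol] = None):
    """Steady-state APD90 per frequency plus the rate-dependence span.

    delta_APD = APD90 at 0.5 Hz (or the lowest tested rate) minus the minimum
    APD90 at the highest rate.  State is carried between frequencies to speed
    convergence; each frequency still satisfies the steady-state criterion.
    Returns (per-frequency PacingResult dict, delta_APD ms).
    """
    if len(set(frequencies)) < 2 and len(frequencies) < 2:
        raise ValueError("at least two frequencies are required")
    results = {}
    y = initial
    for f in sorted(frequencies):
        proto = PacingProtocol(frequency=f, **{
            k: getattr(protocol, k) for k in
            ("beat_limit", "apd_tol", "nai_tol", "record_beats")
        }) if protocol else PacingProtocol(frequency=f)
        res = run_to_steady_state(params, spec, f, initial=y,
                                  settings=settings, protocol=proto)
        results[f] = res
        y = res.final_state
    f_lo = min(frequencies)
    f_hi = max(frequencies)
    delta = results[f_lo].biomarkers.APD90 - results[f_hi].biomarkers.APD90
    return results, delta


# ---------------------------------------------------------------------------
# Na+ clamp
# ---------------------------------------------------------------------------

def run_na_clamp(params: ModelParameters,
                 spec: Optional[RemodelingSpec] = None,
                 frequency: float = 1.6, clamp_mM: float = 9.0,
                 initial: Optional[np.ndarray] = None,
                 settings: Optional[SolverSettings] = None,
                 protocol: Optional[PacingProtocol] = None) -> PacingResult:
    """Pace with all intracellular Na+ pools held at ``clamp_mM``."""
    if clamp_mM <= 0:
        raise ValueError("clamp value must be positive")
    y = default_initial_state() if initial is None else np.array(initial, float)
    for name in ("Naj", "Nasl", "Nai"):
        y[IDX[name]] = clamp_mM
    return run_to_steady_state(params, spec, frequency, initial=y,
                               settings=settings, protocol=protocol,
                               clamp_na=True)


# ---------------------------------------------------------------------------
# EAD induction
# ---------------------------------------------------------------------------

def run_ead_protocol(params: ModelParameters,
                     spec: RemodelingSpec,
                     overlays: Sequence[RemodelingSpec] = (),
                     beats: int = 20,
                     windowed: Sequence[Tuple[RemodelingSpec, Tuple[int, int]]] = (),
                     initial: Optional[np.ndarray] = None,
                     frequency: float = 1.0,
                     settings: Optional[SolverSettings] = None):
    """Pace under ``spec`` plus overlays; flag EADs on every beat.

    ``windowed`` lists (overlay, (first_beat, last_beat)) pairs applied only
    during the stated beats (0-based, inclusive) — the transitory blocks.
    Returns (trace of all beats at 0.5-ms sampling, list of per-beat EAD
    event lists).
    """
    settings = settings or SolverSettings()
    base = compose_overlay(spec, *overlays) if overlays else spec
    cl = 1000.0 / frequency
    y = default_initial_state() if initial is None else np.array(initial, float)
    traces = []
    ead_events: List[list] = []
    t0 = 0.0
    for b in range(beats):
        spec_b = base
        for ov, (b0, b1) in windowed:
            if b0 <= b <= b1:
                spec_b = compose_overlay(spec_b, ov)
        p = spec_b.apply(params)
        tr = _one_beat(y, p, cl, settings, record=True, output_dt=0.5)
        y = tr.final_state
        ead_events.append(detect_eads(tr.t, tr.V))
        traces.append(SimulationTrace(tr.t + t0, tr.states, tr.currents,
                                      tr.final_state))
        t0 += cl
    trace = traces[0]
    for tr in traces[1:]:
        trace = trace.concat(tr)
    return trace, ead_events
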