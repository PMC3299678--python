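"""Protocol drivers: steady-state detection, clamp machinery, Na+ clamp and
staircase state carry-over."""

import numpy as np
import pytest

from hfcell.model import IDX, ModelParameters
from hfcell.protocols import (PacingProtocol, run_na_clamp, run_staircase,
                              run_rate_dependence, run_to_steady_state,
                              run_voltage_clamp)


def test_pacing_protocol_validation():
    with pytest.raises(ValueError):
        PacingProtocol(frequency=0.05)
    with pytest.raises(ValueError):
        PacingProtocol(frequency=1.0, beat_limit=0)


def test_steady_state_fixed_point(params, control_state):
    """Re-running from a converged state needs only the minimal verification
    beats, and the steady-state criterion (not the beat limit) fires."""
    res = run_to_steady_state(params, frequency=1.0, initial=control_state)
    assert res.criterion == "steady_state"
    # 5 settling + 6 verification + recorded beats is the protocol floor
    assert res.beats <= 20
    res2 = run_to_steady_state(params, frequency=1.0, initial=res.final_state)
    assert res2.beats <= res.beats
    assert res2.biomarkers.APD90 == pytest.approx(res.biomarkers.APD90,
                                                  abs=0.2)


def test_voltage_clamp_ratio_properties(params):
    with pytest.raises(ValueError):
        run_voltage_clamp(params, step_ms=30.0)
    _, r0 = run_voltage_clamp(params.with_updates(g_NaL=0.0), hold_ms=500.0,
                              step_ms=100.0)
    assert r0 == 0.0
    _, r1 = run_voltage_clamp(params, hold_ms=2000.0, step_ms=100.0)
    _, r2 = run_voltage_clamp(params.with_updates(g_NaL=2 * params.g_NaL),
                              hold_ms=2000.0, step_ms=100.0)
    assert r2 / r1 == pytest.approx(2.0, rel=0.01)


def test_na_clamp_self_consistency(params, control_state):
    """Clamping [Na+]i at the run's own steady-state value reproduces the
    unclamped biomarkers within 1%, with Na pools exactly constant."""
    ref = run_to_steady_state(params, frequency=1.0, initial=control_state)
    clamp = float(ref.final_state[IDX["Nai"]])
    res = run_na_clamp(params, frequency=1.0, clamp_mM=clamp,
                       initial=ref.final_state)
    assert res.biomarkers.APD90 == pytest.approx(ref.biomarkers.APD90,
                                                 rel=0.01)
    for name in ("Naj", "Nasl", "Nai"):
        col = res.trace.state(name)
        assert np.ptp(col) < 1e-12
    with pytest.raises(ValueError):
        run_na_clamp(params, clamp_mM=-1.0)


def test_staircase_carries_state(params, control_state):
    """End-stage [Na+]i differs between carried-over and restarted stages."""
    carried = run_staircase(params, stages=(1.0, 2.0), stage_minutes=0.25,
                            initial=control_state)
    restart1 = run_staircase(params, stages=(2.0,), stage_minutes=0.25,
                             initial=control_state)
    assert carried[1]["Nai"] != restart1[0]["Nai"]
    assert [r["frequency"] for r in carried] == [1.0, 2.0]


def test_rate_dependence_requires_two_frequencies(params):
    with pytest.raises(ValueError):
        run_rate_dependence(params, frequencies=[1.0])
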