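"""Structural tests of the myocyte model: current bookkeeping, gate bounds,
stability of the resting state, and solver self-convergence."""

import numpy as np
import pytest

from hfcell.biomarkers import apd
from hfcell.model import (CURRENT_NAMES, GATE_IDX, CONC_IDX, IDX,
                          InvalidStateError, ModelParameters, N_STATES,
                          SolverSettings, compute_derivatives,
                          default_initial_state, integrate)
from hfcell.protocols import STIM_OFFSET, _one_beat


def test_derivative_current_consistency(params, control_beat):
    """dV/dt equals minus the sum of recorded membrane currents everywhere."""
    tr = control_beat
    stim_col = tr.current("I_stim")
    for i in range(0, len(tr.t), 500):
        stim = -stim_col[i]
        dy, cur = compute_derivatives(tr.states[i], params, stim=stim)
        assert abs(dy[IDX["V"]] + cur[:18].sum()) < 1e-6
        np.testing.assert_allclose(cur, tr.currents[i], rtol=0, atol=1e-12)


def test_resting_state_is_stable(params, rested_state):
    """Without stimulus the model sits at a fixed point: < 0.01 mV/s drift."""
    tr = integrate(rested_state, params, [], 10000.0, record=False)
    assert abs(tr.final_state[IDX["V"]] - rested_state[IDX["V"]]) < 0.1  # 10 s
    dy, _ = compute_derivatives(rested_state, params)
    assert abs(dy[IDX["V"]]) < 1e-3


def test_gate_bounds_and_concentration_positivity(control_beat):
    gates = control_beat.states[:, list(GATE_IDX)]
    # bounds hold to within the solver's absolute tolerance
    assert gates.min() >= -1e-8 and gates.max() <= 1.0 + 1e-8
    concs = control_beat.states[:, list(CONC_IDX)]
    assert concs.min() > 0.0


def test_zero_conductance_removes_late_sodium(params, control_state):
    _, cur = compute_derivatives(control_state, params.with_updates(g_NaL=0.0))
    assert cur[CURRENT_NAMES.index("I_NaL")] == 0.0


def test_zero_duration_returns_initial_state(params, control_state):
    tr = integrate(control_state, params, [], 0.0)
    assert tr.t.shape == (1,)
    np.testing.assert_array_equal(tr.final_state, control_state)


def test_invalid_state_and_incomplete_params_signal(params):
    y = default_initial_state()
    y[0] = np.nan
    with pytest.raises(InvalidStateError):
        compute_derivatives(y, params)
    with pytest.raises(ValueError):
        compute_derivatives(default_initial_state(), np.ones(3))
    with pytest.raises(InvalidStateError):
        compute_derivatives(np.ones(5), params)


def test_parameter_validation():
    with pytest.raises(ValueError):
        ModelParameters(tau_hL=0.0)
    with pytest.raises(ValueError):
        ModelParameters(g_NaL=-1.0)
    with pytest.raises(ValueError):
        ModelParameters(EC50_SR=-0.1)


def test_solver_self_convergence(params, control_state, settings):
    """APD90 is insensitive (< 0.1 ms) to a 10x tightening of tolerances."""
    apds = {}
    for name, s in {
        "default": settings,
        "tight": SolverSettings(rtol=settings.rtol / 10,
                                atol=settings.atol / 10),
    }.items():
        tr = _one_beat(control_state, params, 1000.0, s, record=True,
                       output_dt=0.1)
        apds[name] = apd(tr.t, tr.V, 0.9, STIM_OFFSET)
    assert abs(apds["default"] - apds["tight"]) < 0.1


def test_output_sampling_invariance(params, control_state, settings):
    """Halving / doubling the output interval leaves biomarkers unchanged."""
    vals = {}
    for dt in (0.05, 0.1, 0.2):
        tr = _one_beat(control_state, params, 1000.0, settings, record=True,
                       output_dt=dt)
        vals[dt] = apd(tr.t, tr.V, 0.9, STIM_OFFSET)
    assert abs(vals[0.05] - vals[0.1]) < 0.1
    assert abs(vals[0.2] - vals[0.1]) < 0.1


def test_run_determinism(params, control_state, settings):
    """Identical inputs give bit-identical trajectories."""
    a = _one_beat(control_state, params, 1000.0, settings, record=True,
                  output_dt=0.5)
    b = _one_beat(control_state, params, 1000.0, settings, record=True,
                  output_dt=0.5)
    np.testing.assert_array_equal(a.states, b.states)
    np.testing.assert_array_equal(a.currents, b.currents)
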