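"""Unit tests of the late Na+ current component: steady-state inactivation,
exponential gate relaxation, and the current equation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from hfcell.late_sodium import (LateSodiumParams, compute_INaL, hL_exact,
                                hL_derivative, hL_inf)
from hfcell.model import (FORT, FJUNC, FSL, IDX, NAO, SolverSettings,
                          compute_derivatives, integrate)


def test_hL_inf_midpoint_and_limits():
    p = LateSodiumParams()
    assert hL_inf(p.V50, p) == pytest.approx(0.5)
    assert hL_inf(-1e3, p) == pytest.approx(1.0, abs=1e-9)
    assert hL_inf(1e3, p) == pytest.approx(0.0, abs=1e-9)


@pytest.mark.parametrize("V", [-100.0, -80.0, -60.0])
def test_hL_inf_matches_sigmoid(V):
    # direct closed-form evaluation with the configured half-voltage / slope
    expected = 1.0 / (1.0 + math.exp((V + 91.0) / 6.1))
    assert hL_inf(V) == pytest.approx(expected, rel=1e-12)


@given(v1=st.floats(-120, 40), dv=st.floats(0.1, 50))
@hyp_settings(max_examples=50, deadline=None, derandomize=True)
def test_hL_inf_monotone_decreasing(v1, dv):
    assert hL_inf(v1 + dv) < hL_inf(v1)


def test_gate_relaxation_properties():
    p = LateSodiumParams()
    V = -60.0
    hinf = hL_inf(V, p)
    assert hL_derivative(hinf, V, p) == 0.0
    # after one time constant the gap to equilibrium shrinks by a factor e
    h0 = 0.9
    gap0 = h0 - hinf
    gap_tau = hL_exact(h0, V, p.tau_hL, p) - hinf
    assert gap_tau == pytest.approx(gap0 / math.e, rel=1e-12)


def test_clamped_integration_matches_closed_form(params, control_state):
    """h_L integrated in the full model under voltage clamp follows the
    single-exponential closed form to < 1e-6."""
    y = control_state.copy()
    V = -40.0
    y[IDX["V"]] = V
    y[IDX["hL"]] = 0.2
    tr = integrate(y, params, [], 500.0, settings=SolverSettings(rtol=1e-10,
                   atol=1e-12), clamp_v=True)
    lsp = LateSodiumParams(g_NaL=params.g_NaL, tau_hL=params.tau_hL,
                           V50=params.hL_V50, slope=params.hL_slope)
    expected = hL_exact(0.2, V, tr.t, lsp)
    assert np.abs(tr.state("hL") - expected).max() < 1e-6


def test_current_zero_at_reversal_and_sign():
    p = LateSodiumParams()
    e_na = 65.0
    assert compute_INaL(e_na, 0.9, 0.5, e_na, p) == 0.0
    assert compute_INaL(e_na + 10, 0.9, 0.5, e_na, p) > 0
    assert compute_INaL(e_na - 10, 0.9, 0.5, e_na, p) < 0
    assert compute_INaL(-20.0, 0.9, 0.5, e_na,
                        LateSodiumParams(g_NaL=0.0)) == 0.0


def test_model_embeds_same_formulation(params, control_state):
    """The in-model I_NaL equals the standalone component evaluated with the
    compartmental Nernst potentials and the shared m gate."""
    y = control_state.copy()
    y[IDX["V"]] = -20.0
    y[IDX["m"]] = 0.8
    y[IDX["hL"]] = 0.4
    _, cur = compute_derivatives(y, params)
    lsp = LateSodiumParams(g_NaL=params.g_NaL, tau_hL=params.tau_hL)
    ena_j = math.log(NAO / y[IDX["Naj"]]) / FORT
    ena_sl = math.log(NAO / y[IDX["Nasl"]]) / FORT
    expected = (FJUNC * compute_INaL(-20.0, 0.8, 0.4, ena_j, lsp)
                + FSL * compute_INaL(-20.0, 0.8, 0.4, ena_sl, lsp))
    from hfcell.model import ICUR
    assert cur[ICUR["I_NaL"]] == pytest.approx(expected, rel=1e-12)


def test_late_sodium_param_validation():
    with pytest.raises(ValueError):
        LateSodiumParams(tau_hL=-1.0)
    with pytest.raises(ValueError):
        LateSodiumParams(slope=0.0)
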