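"""Biomarker extractors against closed-form synthetic fixtures."""

import math

import numpy as np
import pytest

from hfcell.biomarkers import (FlatTraceError, NoSignChangeError,
                               RepolarizationFailure, apd,
                               ca_transient_metrics, detect_eads, t_ncxrp)
from hfcell.fixtures import generate_fixtures


def test_apd_on_triangular_ramp():
    t, V = generate_fixtures("triangular_ap")  # 300-ms ramp, upstroke at 10 ms
    assert apd(t, V, 0.9) == pytest.approx(270.0, abs=0.5)
    assert apd(t, V, 0.5) == pytest.approx(150.0, abs=0.5)
    assert apd(t, V, 0.0) == pytest.approx(0.0, abs=0.5)


def test_apd_on_two_segment_plateau():
    # peak 35 -> plateau 0 over 200 ms, plateau -> -85 over 100 ms
    t, V = generate_fixtures("plateau_ap")
    v90 = 35 - 0.9 * (35 + 85)          # = -73: in the second segment
    expected = 200.0 + (0.0 - v90) / 85.0 * 100.0
    assert apd(t, V, 0.9) == pytest.approx(expected, abs=0.5)
    v50 = 35 - 0.5 * 120                # = -25: also second segment
    expected50 = 200.0 + 25.0 / 85.0 * 100.0
    assert apd(t, V, 0.5) == pytest.approx(expected50, abs=0.5)


@pytest.mark.parametrize("l1,l2", [(0.3, 0.5), (0.5, 0.9), (0.2, 0.95)])
def test_apd_monotone_in_level(control_beat, l1, l2):
    t, V = control_beat.t, control_beat.V
    assert apd(t, V, l1, 10.0) <= apd(t, V, l2, 10.0)


def test_apd_repolarization_failure_signalled():
    t = np.linspace(0, 500, 5001)
    V = np.where(t < 10, -85.0, 20.0)   # never repolarizes
    with pytest.raises(RepolarizationFailure):
        apd(t, V, 0.9)


def test_ca_metrics_exponential_decay():
    k = 5e-3
    t, ca = generate_fixtures("exp_ca", k=k)
    sys_, dia, tau = ca_transient_metrics(t, ca)
    assert dia == pytest.approx(1e-4)
    assert sys_ == pytest.approx(5e-4, rel=1e-3)
    assert tau == pytest.approx(math.log(10) / k, rel=1e-3)


def test_ca_metrics_piecewise_linear():
    t, ca = generate_fixtures("pl_ca")  # rise 20 ms, fall 400 ms
    sys_, dia, tau = ca_transient_metrics(t, ca)
    assert tau == pytest.approx(0.9 * 400.0, abs=0.5)


def test_ca_metrics_errors():
    t = np.linspace(0, 100, 1001)
    with pytest.raises(FlatTraceError):
        ca_transient_metrics(t, np.full_like(t, 1e-4))
    with pytest.raises(FlatTraceError):
        ca_transient_metrics(t, 1e-4 + 1e-6 * t)  # monotone rise, no decay


def test_ncx_reversal_point():
    t, i, V = generate_fixtures("ncx_crossing", t_cross=120.0)
    assert t_ncxrp(t, i, 10.0, V=V) == pytest.approx(120.0, abs=0.5)
    with pytest.raises(NoSignChangeError):
        t_ncxrp(t, -np.abs(i) - 0.01, 10.0, V=V)


def test_ead_detection():
    t, V = generate_fixtures("triangular_ap", duration=600.0)
    assert detect_eads(t, V) == []
    t, V = generate_fixtures("ead_ap", bump_time=400.0, bump_amp=10.0)
    events = detect_eads(t, V)
    assert len(events) == 1
    assert events[0][0] == pytest.approx(400.0, abs=40.0)
    assert events[0][1] > 1.0  # net deflection, reduced by the underlying ramp
    t, V = generate_fixtures("ead_ap", bump_amp=0.5)  # sub-threshold ripple
    assert detect_eads(t, V) == []


def test_extractors_invariant_to_shift_and_resampling(control_beat):
    t, V = control_beat.t, control_beat.V
    ref = apd(t, V, 0.9, 10.0)
    shifted = apd(t + 137.0, V, 0.9, 147.0)
    assert shifted == pytest.approx(ref, abs=1e-9)
    coarse = apd(t[::2], V[::2], 0.9, 10.0)  # 0.2-ms resampling
    assert coarse == pytest.approx(ref, abs=0.1)
    cai = control_beat.state("Cai")
    _, _, tau = ca_transient_metrics(t, cai, 10.0)
    _, _, tau2 = ca_transient_metrics(t[::2], cai[::2], 10.0)
    assert tau2 == pytest.approx(tau, rel=0.001)
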