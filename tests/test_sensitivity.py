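"""Sensitivity indices and matrix assembly on synthetic inputs."""

import numpy as np
import pytest

from hfcell.sensitivity import (build_matrix, percent_change,
                                sensitivity_index)


@pytest.mark.parametrize("c,base,expected", [
    (300.0, 250.0, 20.0),
    (250.0, 250.0, 0.0),
    (225.0, 250.0, -10.0),
])
def test_percent_change(c, base, expected):
    assert percent_change(c, base) == pytest.approx(expected)


def test_percent_change_zero_baseline():
    with pytest.raises(ZeroDivisionError):
        percent_change(1.0, 0.0)


def test_sensitivity_index_properties():
    assert sensitivity_index(-10.0, -10.0, 2.0) == 0.0
    assert sensitivity_index(-10.0, 22.0, 2.0) == pytest.approx(16.0)
    assert sensitivity_index(22.0, -10.0, 2.0) == pytest.approx(-16.0)
    with pytest.raises(ZeroDivisionError):
        sensitivity_index(0.0, 1.0, 0.0)


def _mat(baseline, variants, spans):
    return build_matrix(baseline, variants, spans, characteristics=("c1",))


def test_single_cell_matrix_normalizes_to_unit():
    m = _mat({"c1": 100.0}, {"p": {1: {"c1": 90.0}, 2: {"c1": 120.0}}},
             {"p": 3.0})
    assert m.normalized[0, 0] == pytest.approx(1.0)
    m = _mat({"c1": 100.0}, {"p": {1: {"c1": 120.0}, 2: {"c1": 90.0}}},
             {"p": 3.0})
    assert m.normalized[0, 0] == pytest.approx(-1.0)


def test_matrix_missing_run_signals_gap():
    with pytest.raises(KeyError, match="x=2"):
        _mat({"c1": 1.0}, {"p": {1: {"c1": 1.0}}}, {"p": 1.0})


def test_row_normalization_invariant_to_span_rescaling():
    baseline = {"c1": 100.0}
    variants = {"a": {1: {"c1": 90.0}, 2: {"c1": 130.0}},
                "b": {1: {"c1": 95.0}, 2: {"c1": 110.0}}}
    m1 = build_matrix(baseline, variants, {"a": 1.0, "b": 1.0}, ("c1",))
    m2 = build_matrix(baseline, variants, {"a": 2.0, "b": 2.0}, ("c1",))
    np.testing.assert_allclose(m1.normalized, m2.normalized)
    assert m1.dominant("c1") == ["a"]


def test_row_max_abs_reports_percent():
    m = _mat({"c1": 100.0}, {"p": {1: {"c1": 90.0}, 2: {"c1": 122.0}}},
             {"p": 1.0})
    assert m.row_max_abs[0] == pytest.approx(22.0)
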