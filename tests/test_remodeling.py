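"""Remodeling-spec algebra: HF factors, inversion, sensitivity variants,
perturbations and overlay composition."""

import pytest

from hfcell.model import ModelParameters
from hfcell.remodeling import (RemodelingSpec, basic_hf_spec, ical_increase,
                               ikr_block, inal_scale, incx_block, irel_block,
                               overlay, perturb, sensitivity_variant,
                               variant_factor)

GPB = ModelParameters()


def test_empty_spec_is_identity():
    assert RemodelingSpec().apply(GPB) == GPB


def test_basic_hf_factors():
    p = basic_hf_spec().apply(GPB)
    assert p.g_to_slow == pytest.approx(GPB.g_to_slow * 0.4)
    assert p.g_to_fast == pytest.approx(GPB.g_to_fast * 0.4)
    assert p.EC50_SR == pytest.approx(0.4)
    assert p.g_Nab == 0.0
    assert p.g_NaL == pytest.approx(2 * GPB.g_NaL)
    assert p.tau_hL == pytest.approx(2 * GPB.tau_hL)
    assert p.g_K1 == pytest.approx(0.68 * GPB.g_K1)
    assert p.Ibar_NaK == pytest.approx(0.9 * GPB.Ibar_NaK)
    assert p.Ibar_NCX == pytest.approx(1.75 * GPB.Ibar_NCX)
    assert p.Vmax_SERCA == pytest.approx(0.5 * GPB.Vmax_SERCA)


def test_no_change_on_everything_restores_baseline_bitwise():
    spec = basic_hf_spec()
    for name in list(spec.transforms):
        spec = sensitivity_variant(spec, name, "no_change")
    assert spec.apply(GPB) == GPB


def test_double_application_guard():
    spec = basic_hf_spec()
    applied = set()
    spec.apply(GPB, applied)
    with pytest.raises(ValueError):
        spec.apply(GPB, applied)


@pytest.mark.parametrize("param,mode,factor", [
    ("I_NaK", "no_change", 1.0),
    ("I_NaK", "double_change", 0.45),
    ("I_NCX", "double_change", 3.5),
    ("I_NaL", "double_change", 4.0),
    ("I_to", "double_change", 0.2),
])
def test_sensitivity_variant_factors(param, mode, factor):
    assert variant_factor(param, mode) == pytest.approx(factor)


def test_sensitivity_variant_assignments():
    hf = basic_hf_spec()
    # EC50_SR: 0.45 -> 0.4 in HF; doubling the remodeling multiplicatively
    v = sensitivity_variant(hf, "EC_50SR", "double_change")
    assert v.apply(GPB).EC50_SR == pytest.approx(0.45 * (0.4 / 0.45) / 2)
    # a removed current stays removed
    v = sensitivity_variant(hf, "I_Nab", "double_change")
    assert v.apply(GPB).g_Nab == 0.0
    v = sensitivity_variant(hf, "I_Nab", "no_change")
    assert v.apply(GPB).g_Nab == GPB.g_Nab


def test_sensitivity_variant_errors():
    hf = basic_hf_spec()
    with pytest.raises(KeyError):
        sensitivity_variant(hf, "I_Kr", "no_change")
    with pytest.raises(ValueError):
        sensitivity_variant(hf, "I_NaK", "triple_change")


def test_perturb():
    hf = basic_hf_spec()
    p = perturb(hf, ["I_SERCA"], +0.15).apply(GPB)
    assert p.Vmax_SERCA == pytest.approx(GPB.Vmax_SERCA * 0.575)
    assert perturb(hf, [], 0.15).apply(GPB) == hf.apply(GPB)
    pm = perturb(hf, "all", -0.15).apply(GPB)
    assert pm.Ibar_NCX == pytest.approx(GPB.Ibar_NCX * 1.75 * 0.85)
    assert pm.EC50_SR == pytest.approx(0.4 * 0.85)
    with pytest.raises(ValueError):
        perturb(hf, "all", 1.5)


def test_overlays_compose_multiplicatively():
    hf = basic_hf_spec()
    spec = overlay(hf, ikr_block(0.5), ical_increase(0.3))
    p = spec.apply(GPB)
    assert p.g_Kr == pytest.approx(0.5 * GPB.g_Kr)
    assert p.p_Ca == pytest.approx(1.3 * GPB.p_Ca)
    # doubling I_NaL on top of HF (already x2) gives x4 vs baseline
    p = overlay(hf, inal_scale(2.0)).apply(GPB)
    assert p.g_NaL == pytest.approx(4 * GPB.g_NaL)
    p = overlay(hf, irel_block(0.5), incx_block(0.5)).apply(GPB)
    assert p.k_rel == pytest.approx(0.5 * GPB.k_rel)
    assert p.Ibar_NCX == pytest.approx(0.875 * GPB.Ibar_NCX)


def test_conflicting_assignments_error_names_sources():
    a = RemodelingSpec({"EC_50SR": __import__("hfcell.remodeling",
                        fromlist=["Transform"]).Transform("assign", 0.4)},
                       label="specA")
    b = RemodelingSpec({"EC_50SR": a.transforms["EC_50SR"]}, label="specB")
    with pytest.raises(ValueError, match="specA.*specB"):
        a.composed_with(b)


def test_unknown_parameter_rejected():
    spec = RemodelingSpec({"I_bogus": __import__("hfcell.remodeling",
                           fromlist=["Transform"]).Transform("scale", 2.0)})
    with pytest.raises(KeyError):
        spec.apply(GPB)
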