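"""Named, composable parameter transforms: heart-failure remodeling and overlays.

A RemodelingSpec is an ordered mapping from a remodelable quantity (named as
in the field: "I_to", "I_NaK", ...) to a transform, either scale-by-factor or
assign-value.  The basic heart-failure (HF) spec doubles the late Na+ current
density and its inactivation time constant, downregulates I_to, I_K1 and the
Na+/K+ pump, removes the background Na+ current, upregulates the Na+/Ca2+
exchanger, SR leak and background Ca2+ current, halves SERCA, and sensitises
RyR release (EC50_SR 0.45 -> 0.4 mM).

Sensitivity variants restore a quantity to its baseline value ("no change")
or double its remodeling in its own direction ("double change": x2 -> x4,
x0.9 -> x0.45; a removed current stays removed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from .model import ModelParameters

__all__ = [
    "Transform", "RemodelingSpec", "basic_hf_spec", "sensitivity_variant",
    "perturb", "overlay", "ikr_block", "ical_increase", "inal_scale",
    "irel_block", "incx_block", "REMODEL_TARGETS", "HF_FACTORS",
]

# remodelable quantity -> ModelParameters fields it scales
REMODEL_TARGETS = {
    "I_NaL": ("g_NaL",),
    "tau_hL": ("tau_hL",),
    "I_to": ("g_to_slow", "g_to_fast"),
    "I_K1": ("g_K1",),
    "I_NaK": ("Ibar_NaK",),
    "I_Nab": ("g_Nab",),
    "I_Cab": ("g_Cab",),
    "I_NCX": ("Ibar_NCX",),
    "I_SERCA": ("Vmax_SERCA",),
    "I_leak": ("k_leak",),
    "EC_50SR": ("EC50_SR",),
    "I_Kr": ("g_Kr",),
    "I_CaL": ("p_Ca", "p_K", "p_Na"),
    "I_rel": ("k_rel",),
}


@dataclass(frozen=True)
class Transform:
    """scale-by-factor (kind='scale') or assign-value (kind='assign')."""
    kind: str
    value: float

    def __post_init__(self):
        if self.kind not in ("scale", "assign"):
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.kind == "scale" and self.value < 0:
            raise ValueError("scale factor must be >= 0")


def _scale(v: float) -> Transform:
    return Transform("scale", v)


def _assign(v: float) -> Transform:
    return Transform("assign", v)


@dataclass
class RemodelingSpec:
    """Ordered parameter-name -> Transform mapping with a provenance label.

    Transitory (beat-windowed) I_rel / I_NCX blocks are not part of the
    RemodelingSpec itself: the protocol driver swaps between variants with
    and without the block for the stated beats (see run_ead_protocol).
    """

    transforms: dict = field(default_factory=dict)
    label: str = "custom"

    def apply(self, params: ModelParameters, applied_labels=None) -> ModelParameters:
        """Return transformed parameters.  If ``applied_labels`` (a set) is
        given, re-applying a spec with a label already in it raises — a guard
        against accidental double application; the label is added in place."""
        if applied_labels is not None:
            if self.label in applied_labels:
                raise ValueError(f"remodeling {self.label!r} already applied")
            applied_labels.add(self.label)
        updates = {}
        for name, tr in self.transforms.items():
            if name not in REMODEL_TARGETS:
                raise KeyError(f"unknown remodelable parameter {name!r}")
            for fld in REMODEL_TARGETS[name]:
                base = updates.get(fld, getattr(params, fld))
                updates[fld] = tr.value if tr.kind == "assign" else base * tr.value
        return params.with_updates(**updates) if updates else params

    def composed_with(self, other: "RemodelingSpec") -> "RemodelingSpec":
        """Compose: scales multiply; assign in ``other`` overrides a scale;
        two assignments to the same parameter conflict."""
        merged = dict(self.transforms)
        for name, tr in other.transforms.items():
            if name in merged:
                prev = merged[name]
                if prev.kind == "assign" and tr.kind == "assign":
                    raise ValueError(
                        f"conflicting assignments to {name!r} from "
                        f"{self.label!r} and {other.label!r}")
                if tr.kind == "assign":
                    merged[name] = tr
                elif prev.kind == "assign":
                    merged[name] = _assign(prev.value * tr.value)
                else:
                    merged[name] = _scale(prev.value * tr.value)
            else:
                merged[name] = tr
        return RemodelingSpec(merged, f"{self.label}+{other.label}")


# basic HF factors vs the baseline model.  The I_Cab and I_leak readings are
# ambiguous in the source literature (x1.53 vs x2.53 and x3/x4/x5); the
# defaults below reproduced the published HF phenotype best and both are
# exposed as arguments.
HF_FACTORS = {
    "I_NaL": 2.0, "tau_hL": 2.0, "I_to": 0.4, "I_K1": 0.68, "I_NaK": 0.9,
    "I_NCX": 1.75, "I_SERCA": 0.5, "I_Cab": 2.53, "I_leak": 4.0,
}
HF_ASSIGNMENTS = {"I_Nab": 0.0, "EC_50SR": 0.4}


def basic_hf_spec(i_cab_factor: float = HF_FACTORS["I_Cab"],
                  i_leak_factor: float = HF_FACTORS["I_leak"]) -> RemodelingSpec:
    """The basic HF remodeling (all eleven quantities)."""
    tr = {
        "I_NaL": _scale(HF_FACTORS["I_NaL"]),
        "tau_hL": _scale(HF_FACTORS["tau_hL"]),
        "I_to": _scale(HF_FACTORS["I_to"]),
        "I_K1": _scale(HF_FACTORS["I_K1"]),
        "I_NaK": _scale(HF_FACTORS["I_NaK"]),
        "I_Nab": _assign(HF_ASSIGNMENTS["I_Nab"]),
        "I_Cab": _scale(i_cab_factor),
        "I_NCX": _scale(HF_FACTORS["I_NCX"]),
        "I_SERCA": _scale(HF_FACTORS["I_SERCA"]),
        "I_leak": _scale(i_leak_factor),
        "EC_50SR": _assign(HF_ASSIGNMENTS["EC_50SR"]),
    }
    return RemodelingSpec(tr, "basic_HF")


_GPB_VALUES = {"I_Nab": ModelParameters().g_Nab, "EC_50SR": ModelParameters().EC50_SR}


def _double_factor(f: float) -> float:
    """Double the remodeling in its own direction: an up-regulation x f
    becomes x 2f, a down-regulation x f becomes x f/2 (a quantity already
    removed, f = 0, stays removed)."""
    if f >= 1.0:
        return 2.0 * f
    return f / 2.0


def sensitivity_variant(base: RemodelingSpec, parameter: str, mode: str) -> RemodelingSpec:
    """Variant of ``base`` with one remodeled quantity restored to baseline
    ("no_change") or its remodeling doubled ("double_change").

    Doubling is multiplicative and direction-aware (x2 -> x4, x0.9 -> x0.45);
    assigned values are handled through their equivalent factor vs baseline.
    This reproduces the published responses (APD90 +22% when the late-Na+
    density is doubled beyond its HF value; strong shortening when the pump
    is further suppressed), which the additive deviation-doubling reading
    does not."""
    if parameter not in base.transforms:
        raise KeyError(f"{parameter!r} is not remodeled in {base.label!r}")
    if mode not in ("no_change", "double_change"):
        raise ValueError(f"unknown mode {mode!r}")
    tr = dict(base.transforms)
    old = tr[parameter]
    if mode == "no_change":
        del tr[parameter]
    elif old.kind == "scale":
        tr[parameter] = _scale(_double_factor(old.value))
    else:
        g = _GPB_VALUES[parameter]
        tr[parameter] = _assign(g * _double_factor(old.value / g) if g > 0 else old.value)
    return RemodelingSpec(tr, f"{base.label}[{parameter}:{mode}]")


def variant_factor(parameter: str, mode: str, base: RemodelingSpec = None) -> float:
    """Effective multiplier vs baseline for a sensitivity variant (1.0 for
    no_change); used for the Delta_a span of the sensitivity index."""
    base = base or basic_hf_spec()
    tr = base.transforms[parameter]
    if mode == "no_change":
        return 1.0
    if mode == "hf":
        return tr.value if tr.kind == "scale" else tr.value / _GPB_VALUES[parameter]
    v = sensitivity_variant(base, parameter, mode).transforms[parameter]
    return v.value if v.kind == "scale" else v.value / _GPB_VALUES[parameter]


def perturb(base: RemodelingSpec, parameters, fraction: float) -> RemodelingSpec:
    """Scale selected remodeled quantities' HF values by (1 + fraction).

    ``parameters`` may be an iterable of names or "all"."""
    if not -1.0 < fraction < 1.0:
        raise ValueError("fraction must be in (-1, 1)")
    names = list(base.transforms) if parameters == "all" else list(parameters)
    tr = dict(base.transforms)
    for name in names:
        if name not in tr:
            raise KeyError(f"{name!r} is not remodeled in {base.label!r}")
        old = tr[name]
        cls = _scale if old.kind == "scale" else _assign
        tr[name] = cls(old.value * (1.0 + fraction))
    return RemodelingSpec(tr, f"{base.label}±{fraction:+.0%}")


# --- arrhythmia overlays ----------------------------------------------------

def ikr_block(fraction: float) -> RemodelingSpec:
    """Block I_Kr by ``fraction`` (0.5 -> factor 0.5)."""
    return RemodelingSpec({"I_Kr": _scale(1.0 - fraction)}, f"IKr-block-{fraction:.0%}")


def ical_increase(fraction: float = 0.3) -> RemodelingSpec:
    return RemodelingSpec({"I_CaL": _scale(1.0 + fraction)}, f"ICaL+{fraction:.0%}")


def inal_scale(k: float) -> RemodelingSpec:
    """Scale I_NaL by k relative to the current spec (multiplicative)."""
    return RemodelingSpec({"I_NaL": _scale(k)}, f"INaL-x{k:g}")


def irel_block(fraction: float = 0.5) -> RemodelingSpec:
    return RemodelingSpec({"I_rel": _scale(1.0 - fraction)},
                          f"Irel-block-{fraction:.0%}")


def incx_block(fraction: float = 0.5) -> RemodelingSpec:
    return RemodelingSpec({"I_NCX": _scale(1.0 - fraction)},
                          f"INCX-block-{fraction:.0%}")


def overlay(base: RemodelingSpec, *overlays: RemodelingSpec) -> RemodelingSpec:
    """Compose overlays onto ``base`` (scales multiply; assignment conflicts
    raise, naming both sources)."""
    out = base
    for ov in overlays:
        out = out.composed_with(ov)
    return out
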