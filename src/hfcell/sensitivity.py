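"""Two-point finite-difference sensitivity analysis of the HF model.

For every remodeled quantity p, the model is re-run at steady state with p
restored to its baseline value (x = 1, "no change") and with its remodeling
doubled (x = 2, "double change").  For each electrophysiological
characteristic c the percent change vs the basic HF model is

    D_c,p,x = 100 * (C_p,x - C_HFbasic) / C_HFbasic

and the sensitivity is the slope across the two variants,

    S_c,p = (D_c,p,2 - D_c,p,1) / Delta_a .

Delta_a, the total interval of change of parameter p, is by default the
variant interval itself (x = 1 to x = 2, one remodeling doubling for every
parameter, so Delta_a = 1 and S is the response span in percent); this
convention reproduces the published dominance patterns (APD driven by I_NaL
and the Na+/K+ pump; [Na+]i by the pump, background Ca2+ current and I_K1;
the NCX reversal time by SERCA).  ``span_convention="gpb"`` instead measures
the multiplier span in units of the baseline value (e.g. I_NaK:
|0.45 - 1.0| = 0.55), which weights columns differently and therefore
changes rankings.  Rows of the final matrix are normalized by their maximum
|S|; the per-row maximum absolute response is reported alongside in percent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .biomarkers import CHARACTERISTICS
from .model import ModelParameters, SolverSettings
from .protocols import run_to_steady_state
from .remodeling import RemodelingSpec, basic_hf_spec, sensitivity_variant, variant_factor

__all__ = [
    "percent_change", "sensitivity_index", "build_matrix", "run_sensitivity",
    "SensitivityMatrix", "HF_SENSITIVITY_PARAMETERS",
]

# the remodeled quantities of the basic HF model, in presentation order
HF_SENSITIVITY_PARAMETERS = (
    "I_NaL", "tau_hL", "I_to", "I_K1", "I_NaK", "I_Nab", "I_Cab",
    "I_NCX", "I_SERCA", "I_leak", "EC_50SR",
)


def percent_change(c_px: float, c_hfbasic: float) -> float:
    """D index: percent change of a characteristic vs its basic-HF value."""
    if c_hfbasic == 0:
        raise ZeroDivisionError("characteristic is zero in the basic HF model")
    return 100.0 * (c_px - c_hfbasic) / c_hfbasic


def sensitivity_index(d_p1: float, d_p2: float, delta_a: float) -> float:
    """S index: slope of D between the two variants per unit parameter span."""
    if delta_a == 0:
        raise ZeroDivisionError("parameter-change span is zero")
    return (d_p2 - d_p1) / delta_a


@dataclass
class SensitivityMatrix:
    characteristics: tuple        # rows
    parameters: tuple             # columns
    D1: np.ndarray                # percent, no-change variant
    D2: np.ndarray                # percent, double-change variant
    S: np.ndarray
    normalized: np.ndarray        # in [-1, 1], rows scaled by max |S|
    row_max_abs: np.ndarray       # percent: max |D| over the row

    def to_frame(self, which: str = "normalized") -> pd.DataFrame:
        return pd.DataFrame(getattr(self, which),
                            index=list(self.characteristics),
                            columns=list(self.parameters))

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.characteristics):
            for j, p in enumerate(self.parameters):
                rows.append({"characteristic": c, "parameter": p,
                             "D_no_change": self.D1[i, j],
                             "D_double_change": self.D2[i, j],
                             "S": self.S[i, j],
                             "normalized": self.normalized[i, j],
                             "row_max_abs_percent": self.row_max_abs[i]})
        return pd.DataFrame(rows)

    def dominant(self, characteristic: str, n: int = 1):
        """Parameters with the n largest |normalized| entries of a row."""
        i = list(self.characteristics).index(characteristic)
        order = np.argsort(-np.abs(self.normalized[i]))
        return [self.parameters[j] for j in order[:n]]

    def save_heatmap(self, path) -> None:
        """Signed normalized-sensitivity heatmap with per-row max % labels."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(1 + 0.8 * len(self.parameters),
                                        1 + 0.5 * len(self.characteristics)))
        im = ax.imshow(self.normalized, cmap="RdBu_r", vmin=-1, vmax=1)
        ax.set_xticks(range(len(self.parameters)), self.parameters,
                      rotation=45, ha="right")
        labels = [f"{c}  ({m:.0f}%)" for c, m in
                  zip(self.characteristics, self.row_max_abs)]
        ax.set_yticks(range(len(self.characteristics)), labels)
        fig.colorbar(im, ax=ax, label="normalized sensitivity")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def build_matrix(baseline: Dict[str, float],
                 variants: Dict[str, Dict[int, Dict[str, float]]],
                 spans: Dict[str, float],
                 characteristics: Sequence[str] = CHARACTERISTICS,
                 ) -> SensitivityMatrix:
    """Assemble the sensitivity matrix from per-run characteristic values.

    ``baseline`` maps characteristic -> basic-HF value; ``variants`` maps
    parameter -> {1: {...}, 2: {...}} with the same characteristic keys;
    ``spans`` maps parameter -> Delta_a.  A missing (parameter, variant) run
    raises, naming the gap.  A characteristic that is undefined in some run
    (None) yields NaN cells which are ignored in the row normalization.
    """
    params = tuple(variants.keys())
    nc, npar = len(characteristics), len(params)
    D1 = np.full((nc, npar), np.nan)
    D2 = np.full((nc, npar), np.nan)
    S = np.full((nc, npar), np.nan)
    for j, p in enumerate(params):
        for x in (1, 2):
            if x not in variants[p]:
                raise KeyError(f"missing run: parameter {p!r}, variant x={x}")
        for i, c in enumerate(characteristics):
            base = baseline.get(c)
            v1 = variants[p][1].get(c)
            v2 = variants[p][2].get(c)
            if base in (None, 0) or v1 is None or v2 is None:
                continue
            D1[i, j] = percent_change(v1, base)
            D2[i, j] = percent_change(v2, base)
            S[i, j] = sensitivity_index(D1[i, j], D2[i, j], spans[p])
    norm = np.full_like(S, np.nan)
    row_max = np.zeros(nc)
    for i in range(nc):
        with np.errstate(invalid="ignore"):
            m = np.nanmax(np.abs(S[i])) if not np.all(np.isnan(S[i])) else np.nan
        if np.isnan(m) or m == 0:
            continue
        norm[i] = S[i] / m
        row_max[i] = np.nanmax(np.abs(np.concatenate([D1[i], D2[i]])))
    return SensitivityMatrix(tuple(characteristics), params, D1, D2, S, norm, row_max)


def _characteristics_of(bm) -> Dict[str, float]:
    d = bm.as_dict()
    return {c: d[c] for c in CHARACTERISTICS}


def run_sensitivity(params: ModelParameters,
                    base_spec: Optional[RemodelingSpec] = None,
                    parameters: Sequence[str] = HF_SENSITIVITY_PARAMETERS,
                    frequency: float = 1.0,
                    initial=None,
                    settings: Optional[SolverSettings] = None,
                    protocol=None,
                    join_tau_hL: bool = False,
                    span_convention: str = "variant") -> SensitivityMatrix:
    """Run the full sweep: basic HF plus (no-change, double-change) per
    parameter, all at 1-Hz steady state.

    ``join_tau_hL``: vary tau_hL together with I_NaL as a single parameter
    (and drop the separate tau_hL column).
    """
    base_spec = base_spec or basic_hf_spec()
    if join_tau_hL:
        parameters = tuple(p for p in parameters if p != "tau_hL")
    base_res = run_to_steady_state(params, base_spec, frequency, initial=initial,
                                   settings=settings, protocol=protocol)
    baseline = _characteristics_of(base_res.biomarkers)
    warm = base_res.final_state
    variants: Dict[str, Dict[int, Dict[str, float]]] = {}
    spans: Dict[str, float] = {}
    for p in parameters:
        variants[p] = {}
        for x, mode in ((1, "no_change"), (2, "double_change")):
            spec = sensitivity_variant(base_spec, p, mode)
            if join_tau_hL and p == "I_NaL":
                spec = sensitivity_variant(spec, "tau_hL", mode)
            res = run_to_steady_state(params, spec, frequency, initial=warm,
                                      settings=settings, protocol=protocol)
            variants[p][x] = _characteristics_of(res.biomarkers)
        if span_convention == "gpb":
            spans[p] = abs(variant_factor(p, "double_change", base_spec) - 1.0)
        elif span_convention == "variant":
            spans[p] = 1.0
        else:
            raise ValueError(f"unknown span convention {span_convention!r}")
    return build_matrix(baseline, variants, spans)
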