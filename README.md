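# hfcell — late sodium current and heart-failure electrophysiology in a human ventricular myocyte

`hfcell` simulates the action potential (AP) and Ca²⁺/Na⁺ handling of a
single human endocardial ventricular myocyte, for electrophysiologists and
modellers studying how the **late Na⁺ current (I_NaL)** shapes the phenotype
of the failing heart: AP prolongation and triangulation, blunted and slowed
Ca²⁺ transients, Na⁺ accumulation, reverse rate-dependence of APD, and early
afterdepolarizations (EADs).

## The model

The baseline is the Grandi–Pasqualini–Bers (GPB) human ventricular AP model
(endocardial parameter set): Hodgkin–Huxley sarcolemmal currents (I_Na, I_to,
I_Kr, I_Ks, I_K1, I_Kp, I_CaL, Cl⁻ and background currents), Na⁺/K⁺ pump,
Na⁺/Ca²⁺ exchanger (NCX), a four-state ryanodine-receptor release scheme with
SERCA uptake and passive SR leak, explicit buffering, and four diffusively
coupled compartments (junctional cleft, subsarcolemmal space, bulk cytosol,
SR) — 40 ODE states in all.

A late Na⁺ current is added to the membrane current sum:

    I_NaL = g_NaL · m³ · h_L · (V − E_Na)
    dh_L/dt = (h_L∞(V) − h_L) / τ_hL,   h_L∞(V) = 1 / (1 + exp((V + 91)/6.1))

with g_NaL = 0.015 mS/µF (fitted so a −120 → −20 mV voltage clamp gives an
I_NaL/I_NaT ratio near 0.1%) and τ_hL = 233 ms at 37 °C. The activation gate
and Nernst potential are shared with the fast Na⁺ current.

**Heart failure** is a named set of parameter transforms: g_NaL ×2, τ_hL ×2,
I_to ×0.4, I_K1 ×0.68, I_NaK ×0.9, I_Nab = 0, I_Cab ×2.53, I_NCX ×1.75,
I_SERCA ×0.5, I_leak ×4, EC50_SR = 0.4 mM. Overlays (I_Kr block, I_CaL
increase, I_NaL scaling, transitory I_rel/I_NCX blocks) compose
multiplicatively on top.

A two-point **sensitivity analysis** re-runs the HF model with each remodeled
quantity restored to baseline or doubled, and summarises percent responses
D_c,p,x and sensitivities S_c,p of ten electrophysiological characteristics
(APD₉₀, APD₅₀, triangulation, systolic/diastolic [Ca²⁺]ᵢ, Ca²⁺-decay time,
systolic/diastolic [Ca²⁺]_SR, [Na⁺]ᵢ, NCX reversal time) in a row-normalized
matrix.

## Worked example

```bash
$ hfcell clamp
I_NaL/I_NaT ratio: 0.0904%

$ hfcell pace --config ctrl.yaml       # baseline, warm-started snapshot
beats: 13 (steady_state); APD90 = 326.4 ms

$ hfcell pace --config hf.yaml         # remodeling: hf_basic
beats: 13 (steady_state); APD90 = 412.2 ms
```

with `hf.yaml`:

```yaml
remodeling:
  name: hf_basic
protocol:
  type: pace
  initial_snapshot: hf_1hz
```

The clamp ratio is the late current 40 ms after the depolarizing step divided
by the peak transient Na⁺ current — ~0.1% as measured in human myocytes.
The two pacing runs show the HF phenotype: APD₉₀ prolonged 26% (412 vs
326 ms), and the biomarker table written alongside
(`out_hf/biomarkers.csv`) records the slowed Ca²⁺ transient decay (606 vs
379 ms) and raised [Na⁺]ᵢ. Runs stop when APD₉₀ drifts < 0.05 ms over five
consecutive beats *and* [Na⁺]ᵢ drifts < 10⁻⁴ mM per beat; each command also
writes the trace (CSV/HDF5) and a JSON manifest echoing the configuration.

Other subcommands: `staircase` (0.5→2.5 Hz Na⁺/Ca²⁺ accumulation), `rate`
(APD₉₀ rate-dependence and its span ΔAPD), `naclamp` (pacing with [Na⁺]ᵢ
held fixed), `ead` (reduced-repolarization-reserve protocol with per-beat EAD
counts), `sensitivity` (the full matrix as CSV), `validate` (derivative
comparison against an external reference table).

## Layout

- `hfcell.model` — the ODE right-hand side (numba-compiled), parameters,
  integration (LSODA, adaptive).
- `hfcell.late_sodium` — the I_NaL formulation as an isolated component.
- `hfcell.remodeling` — HF remodeling, sensitivity variants, ±15%
  perturbations, arrhythmia overlays.
- `hfcell.protocols` — voltage clamp, steady-state pacing, staircase, rate
  dependence, Na⁺ clamp, EAD induction.
- `hfcell.biomarkers` — APD, Ca²⁺-transient metrics, NCX reversal time, EAD
  detection.
- `hfcell.sensitivity` — D/S indices and the normalized matrix.
- `hfcell.config`, `hfcell.io`, `hfcell.cli` — YAML configs, trace/state
  serialization, command line.
- `docs/methods.md` — model equations' provenance, numerical choices, and
  known limitations.
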