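# Methods

## Model

The cell is a human endocardial ventricular myocyte of the
Grandi–Pasqualini–Bers (GPB) family. The 40 state variables comprise the
membrane potential; Hodgkin–Huxley gates for the fast Na⁺ current (m, h, j),
L-type Ca²⁺ current (d, f, plus Ca²⁺-dependent inactivation fractions in the
junctional and subsarcolemmal compartments), transient-outward current (fast
and slow pairs), rapid and slow delayed rectifiers; a four-state
ryanodine-receptor scheme (resting/open/inactivated tracked, the fourth state
by conservation); Na⁺ and Ca²⁺ buffer occupancies (sarcolemmal, troponin,
calmodulin, myosin, SR membrane, calsequestrin); and ion concentrations in
the junctional cleft, subsarcolemmal space and bulk cytosol for Na⁺ and
Ca²⁺, plus SR Ca²⁺. Intracellular K⁺ is held fixed at 120 mM, following the
baseline model's convention. Geometry, buffering constants, and current
kinetics are transcribed from the published baseline; the endocardial
transient-outward parameter set is used. All Q10 temperature factors are
evaluated at 37 °C (their exponent is zero), matching the baseline.

One current is added: the late Na⁺ current

    I_NaL = g_NaL · m³ · h_L · (V − E_Na),
    dh_L/dt = (h_L∞(V) − h_L)/τ_hL,
    h_L∞(V) = 1/(1 + exp((V + 91)/6.1)),

split across the junctional/subsarcolemmal membrane fractions with the
compartmental Na⁺ Nernst potentials, exactly like the fast Na⁺ current whose
activation gate it reuses. Its Na⁺ flux enters the compartmental Na⁺ mass
balances. Inactivation is deliberately single-exponential: a single gate with
voltage-independent τ_hL, so decay under clamp is exactly exponential (a
property the tests exploit as a closed-form oracle).

### Late-Na⁺ parameters

| parameter | default | units | meaning |
|---|---|---|---|
| g_NaL | 0.015 | mS/µF | maximal conductance, clamp-fitted |
| τ_hL | 233 | ms | inactivation time constant at 37 °C |
| V₅₀ | −91 | mV | half-inactivation of h_L∞ |
| slope | 6.1 | mV | sigmoid slope |

With these defaults the −120 → −20 mV clamp protocol measures an
I_NaL/I_NaT ratio of 0.090% (current at 40 ms after the step over the peak
transient current), against a measured value of "approximately 0.1%". The
reported ratio is computed at model temperature (τ_hL = 233 ms); the original
fit was done against room-temperature recordings (a Q10 of 2.2 relates the
time constants), which plausibly explains why the ratio quoted for the model
in its source (0.12%) sits slightly above the clamp measurement here. g_NaL
is not retuned to split that difference.

## Heart-failure remodeling

The basic HF model multiplies or assigns eleven quantities: g_NaL ×2,
τ_hL ×2, I_to ×0.4, I_K1 ×0.68, I_NaK ×0.9, I_Nab = 0, I_Cab ×2.53,
I_NCX ×1.75, I_SERCA ×0.5, I_leak ×4, EC50_SR = 0.4 mM. The literature
reports the background-Ca²⁺ and SR-leak factors ambiguously (readings of
×1.53 vs ×2.53 and ×3/×4/×5 are all defensible); both are exposed as
arguments of `basic_hf_spec`, and the defaults are the combination that best
reproduced the published HF phenotype when all candidate readings were run
(see Limitations). Remodeling specs are pure transforms on the parameter set:
composable (scales multiply; conflicting assignments raise), invertible
(restoring every quantity reproduces the baseline bit-for-bit), and guarded
against accidental double application.

**Sensitivity variants.** "No change" removes one quantity's transform;
"double change" doubles its remodeling in its own direction, multiplicatively
(×2 → ×4, ×0.9 → ×0.45; assigned values through their equivalent factor).
The multiplicative reading was adopted because it reproduces the published
responses — APD₉₀ +22% when the late-Na⁺ density is doubled beyond its HF
value (measured here: +22.8% with g_NaL ×4, τ_hL kept at its HF value), and
strong APD shortening when the pump is further suppressed — whereas doubling
the *deviation* from baseline (×0.9 → ×0.8 for the pump) gives only −5%
against a reported −22%. τ_hL is treated as its own sensitivity parameter;
`join_tau_hL=True` varies it together with g_NaL instead.

**Overlays** for the arrhythmia experiments: I_Kr ×(1−block), I_CaL ×1.3
(all three L-type permeabilities), I_NaL ×k composed multiplicatively on the
current spec (so "doubled" on top of HF means ×4 vs baseline), and 50%
I_rel or I_NCX blocks, either continuous or restricted to a 5-beat window
(the window is handled by the protocol driver, which swaps parameter sets
between beats).

## Protocols

* **Stimulus**: rectangular, 5 ms, 6.97 A/F — 1.5× the diastolic threshold
  determined once by bisection at baseline and held fixed across all
  conditions, so biomarker differences between conditions are attributable to
  remodeling, not to stimulus adaptation. Delivered 10 ms into each cycle so
  every beat has a pre-stimulus diastolic sample.
* **Steady state**: pacing stops when |ΔAPD₉₀| < 0.05 ms over five
  consecutive beats *and* per-beat |Δ[Na⁺]ᵢ| < 10⁻⁴ mM, or at a 1000-beat
  limit; which criterion fired is recorded. [Na⁺]ᵢ is the binding (slow)
  criterion, so it is tracked every beat and the APD criterion is verified on
  explicitly recorded beats once Na⁺ has settled.
* **Voltage clamp**: 5 s hold at −120 mV (> 20 τ_hL, letting h_L reach 1),
  step to −20 mV for 2.5 s; gating and concentration ODEs are integrated with
  dV/dt forced to zero. The first 5 ms of the step are sampled at 0.01 ms to
  resolve the transient Na⁺ peak.
* **Staircase**: consecutive stages at 0.5, 1, 1.5, 2, 2.5 Hz, 10 simulated
  minutes each, state carried over; a 2-minute fast mode exists for the
  test suite's ordinal checks.
* **Rate dependence**: steady state at 0.5, 1, 1.25, 1.6 Hz;
  ΔAPD = APD₉₀(0.5 Hz) − APD₉₀(highest rate). State is carried between
  frequencies to speed convergence; the criterion is still enforced per
  frequency.
* **Na⁺ clamp**: all three intracellular Na⁺ compartments held at a set
  value (their derivatives zeroed) while pacing.
* **EAD protocol**: 1-Hz pacing under HF plus overlays, per-beat EAD flags.

## Biomarkers

APDs are measured from the maximum-upstroke-velocity time (midpoint of the
steepest sampling interval) to the linearly interpolated crossing of
V_peak − level·(V_peak − V_diastolic), with V_diastolic taken just before the
stimulus. The Ca²⁺ decay time τ_Ca is the time from the transient peak to 10%
of its amplitude above diastolic. The NCX reversal time t_NCXRP is the first
interpolated sign change of I_NCX after the upstroke. An EAD is a local
minimum followed by a local maximum of V between 50 ms after the upstroke and
the 90% repolarization crossing (or the end of the beat if repolarization
fails), with an upward deflection above a configurable 1 mV threshold. All
crossings are interpolated, so extractors are invariant to uniform time
shifts and stable under resampling at ≤ 0.2 ms.

## Sensitivity indices

D_c,p,x = 100·(C_p,x − C_HFbasic)/C_HFbasic for variants x = 1 (no change)
and x = 2 (double change); S_c,p = (D_c,p,2 − D_c,p,1)/Δₐ. Δₐ is by default
the variant interval itself (one remodeling doubling per parameter, Δₐ = 1),
under which the dominance patterns match the published matrix: APD₉₀ driven
by I_NaL and I_NaK, [Na⁺]ᵢ by I_NaK then I_Cab and I_K1, t_NCXRP by SERCA.
A convention measuring the multiplier span in baseline units
(`span_convention="gpb"`) is also available; note rankings across parameters
are *not* invariant to this choice, only the within-row normalization is.
Rows are normalized by their maximum |S| to [−1, 1]; the per-row maximum
absolute response (percent) is reported alongside, and cells whose
characteristic is undefined in a variant (e.g. no NCX sign change) propagate
as NaN rather than poisoning the row.

## Numerics

LSODA (adaptive stiff/non-stiff switching) with rtol 10⁻⁶, atol 10⁻⁸, max
step 1 ms; output sampled at 0.1 ms on recorded beats (0.5–1 ms where only
convergence or event flags are needed). The right-hand side is
numba-compiled; integration is split at stimulus edges so the discontinuous
forcing never crosses a solver step. These tolerances were chosen because the
mandated self-convergence gates pass at them: APD₉₀ moves < 0.1 ms under a
10× tolerance tightening and < 0.1 ms under output-interval halving/doubling,
while a 100× tighter setting triples run time without changing biomarkers at
the reported precision. Degenerate inputs are guarded: the L-type driving
term and d-gate time constant use their analytic limits near V = 0 and
V = −5 mV; gate bounds hold to within atol.

Two packaged steady-state snapshots (control and basic HF at 1 Hz) warm-start
long protocols. They change run time only: every measured run still enforces
the full steady-state criterion, and the tests verify cold starts reach the
same state.

## What the simulations do and do not show

All inputs are model-generated; there is no external data. The simulated
conditions emulate isolated-myocyte experiments (fixed extracellular bath,
constant pacing, no mechanical feedback, no β-adrenergic or CaMKII
signalling, no cell-to-cell coupling). Reproduction of the published
quantitative surface is therefore a statement about the fidelity of the model
transcription and protocols, not about biological variability: real failing
myocytes vary widely in remodeling degree and stage, which the ±15%
perturbation machinery only caricatures.

## Known limitations

* No independent reference encoding of the baseline model was available to
  diff against, so fidelity rests on the printed quantitative surface. Most
  of it reproduces closely (control τ_Ca 379 vs 380 ms, HF τ_Ca 606 vs
  630 ms, APD₉₀ +11.2/+41.2% for g_NaL ×2/×5 vs +11/+44%, HF APD₉₀ +26 vs
  +24%, rate-dependence span 110.3 vs 110 ms, I_NaL double-change +22.8 vs
  +22%). A residual plateau offset of a few mV remains: triangulation rises
  +58% vs +43%, HF systolic Ca²⁺ is 71% of normal vs 41%, the NCX reversal
  shift is +12.5 vs +20 ms, and the g_NaL ×10 prolongation is +72% vs +78%.
* The asymptotic [Na⁺]ᵢ at 1 Hz settles ~0.8 mM below the baseline model's
  published initial conditions, suggesting the original working state was a
  shorter pacing run; with the strict steady-state criterion used here this
  gap is irreducible and feeds the residuals above.
* Under HF + 50% I_Kr block + 30% I_CaL increase the model crosses from
  discrete EADs directly into sustained failed repolarization (for both
  normal-HF and doubled I_NaL), rather than showing EADs only in the doubled
  arm. The EAD regime is a delicate balance; the offset above is enough to
  move its boundary. I_Kr block alone produces graded, finite prolongation
  (479/502/529 ms at 40/50/60% block on HF), so the failure is quantitative,
  not structural.
* Steady-state APD₉₀ at low pacing rates inherits the baseline model's known
  inaccuracy below 0.5 Hz; no abrupt-rate-change (dynamic restitution)
  protocols are provided.
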