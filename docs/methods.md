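# Methods

## Cell model

The baseline is the ventricular-like spontaneous hiPSC-CM action-potential
model of Paci, Hyttinen, Aalto-Setälä and Severi (Ann Biomed Eng
41:2334–2348, 2013), transcribed into `cardiopop.cell_model` with its
published constants: membrane capacitance `Cm = 9.87109e-11 F`, cytosol
8800 μm³, SR 583.73 μm³, T = 310 K, fixed extracellular (Na⁺ 151, K⁺ 5.4,
Ca²⁺ 1.8 mM) and intracellular K⁺ (150 mM) concentrations, and eleven
sarcolemmal currents (I_Na, I_CaL, I_Kr, I_Ks, I_K1, I_f, I_to, NCX, NaK
pump, sarcolemmal Ca pump, plus Na⁺/Ca²⁺ backgrounds). State: Vm, 16 gates,
Na_i, Ca_i, Ca_SR (20 ODEs). There is no stimulus current; beating is
intrinsic. One transcription detail worth flagging: the SR-release flux
carries a 0.0411 prefactor (present in later model revisions of the same
family); with it the model produces a stable Ca²⁺ transient
(~2×10⁻⁵–3×10⁻⁴ mM) and plausible APs, and it is kept.

Voltage is integrated in **volts** (the source model's convention); traces
and biomarkers use mV and V/s at the `Trace` boundary. Currents are in A/F.

Behavioural validation of the transcription (baseline parameters): rate
36.9 bpm, MDP −76.8 mV, Peak +28 mV, V_max 25 V/s, APD₉₀ 512 ms — inside
the experimentally reported hiPSC-CM ranges and within one SD of published
control APD₉₀ statistics for spontaneously beating hiPSC-CMs.

## Late Na⁺ current and the V1763M genotype

I_NaL is Hodgkin–Huxley: `I_NaL = g_NaL · mL · hL · (Vm − E_Na)`, with the
O'Hara–Rudy (endocardial) activation steady state/time constant for `mL`
and inactivation `hL_inf = 1/(1+exp((V+87.61)/7.488))`, τ_hL = 200 ms.

The mutant variant must satisfy two experimental observables: the persistent
I_NaL sampled 200 ms after the upstroke of the steady-state spontaneous AP
is **4.86×** control, and the baseline mutant APD₉₀ is **+43%** vs baseline
control. The V1763M parameterization is exposed as three named constants and
was calibrated numerically against those observables (240-s runs, LSODA
rtol 1e-7, then confirmed at the 800-s production protocol):

| constant | value | meaning |
|---|---|---|
| `BASELINE_MAXIMA["g_NaL"]` | 46.4 S/F | control late-Na conductance |
| `MUTANT_HL_SHIFT_MV` | +12.5 mV | depolarizing shift of hL steady-state inactivation |
| `MUTANT_TAU_HL_SCALE` | 2.0 | slowed inactivation |
| `MUTANT_GNAL_SCALE` | 0.766 | conductance scale of the mutant channel |

This yields +43.0% APD₉₀ prolongation and a 4.86 persistent-current ratio.
The gain of function is carried by impaired inactivation (shift + slowing),
not by a larger conductance — consistent with the biophysics of
inactivation-deficient SCN5A mutants. Fast I_Na is unchanged by the
genotype.

Persistent-I_NaL protocols: the default samples I_NaL 200 ms after the
instant of maximum upstroke velocity of the steady-state spontaneous AP
(the cells are unpaced, so the upstroke stands in for a stimulus); a
voltage-clamp variant (`voltage_clamp_persistent`, hold −80 mV → step
−20 mV, read at 200 ms, closed-form gate relaxation) is provided for
comparison with clamp assays. The offset is configurable.

## Simulation protocol

`solve_ivp`/LSODA (BDF selectable), rtol 1e-7, atol 1e-9, max step 1 s.
Default protocol: **800 s** simulated from the published diastolic starting
point, final **30 s** sampled every 0.5 ms as the analysis window. dV/dt on
the trace is evaluated from the model right-hand side at each sample (not
finite-differenced). Outcomes are a strict trichotomy:

- *spontaneous*: ≥ 2 APs detected in the window (upward crossing of 0 mV
  with ≥ 40 mV excursion; both thresholds configurable);
- *quiescent*: fewer than 2 such APs (includes sub-threshold oscillations,
  rejected by the amplitude floor);
- *failed*: solver breakdown or non-finite state, kept distinct from
  quiescence so drug trials can report exclusions.

Steady state is declared when beat-to-beat APD₉₀ drift over the last 3
beats is < 5 ms; the production protocol reaches < 0.5 ms for the baseline
models. Self-convergence was verified by tolerance halving (< 1 ms APD₉₀
change) and the limit cycle by state recurrence between consecutive beats
(< 2% per component). Integration is deterministic: identical inputs give
bit-identical traces on one machine.

Where the tests and examples need many simulations they use 60-s runs with
a 20-s window — long enough that the slow drift left relative to the 800-s
protocol (≲ 2 ms in APD₉₀) is irrelevant for directional population
statistics; the two baseline-mutation headline numbers are always computed
with the full 800-s protocol.

## Biomarkers

Per beat: MDP (min Vm), Peak (max Vm), APA = Peak − MDP, V_max (max dV/dt),
rate = 60/mean cycle length (0 if < 2 cycles), APD_x = time from the V_max
instant to the downward crossing of `Peak − x/100·APA`, with linear
interpolation between samples (grid-refinement stable to < 0.5%). The APD
reference point is the upstroke, not a threshold crossing, because the
cells are unpaced; the level is relative to the per-beat APA, matching the
MDP/Peak/APA definitions. Per-model summaries are means over the last 3
beats (configurable) to smooth residual drift. Absent beats raise an
explicit undefined-biomarkers signal rather than returning zeros.

## Population method

Scale factors on the 11 maximal conductances/permeabilities are sampled
uniformly (or Latin-hypercube) on **[0.5, 2.0]**, the conventional range
for this method when the source interval is not otherwise specified.
Calibration accepts a model iff it beats spontaneously and every biomarker
named in the range table lies within its **inclusive** [min, max] window
(inclusive so boundary models cannot flip under round-off). When several
per-dataset tables are supplied, the default combined window is the union
(min of lower, max of upper) per biomarker.

The shipped `configs/ranges_synthetic.yaml` is a synthetic stand-in with
literature-scale bounds for spontaneously beating hiPSC-CMs; with it, a
[0.5, 2] uniform sample accepts roughly 20–25% of models at small n. Real
calibration requires transcribed experimental tables in the same YAML
format.

Transfection switches the genotype of every accepted control model with no
further filtering; ids and scale factors are preserved (injective mapping),
and members that stop beating as mutants are excluded but logged, so
`|control| = |mutant| + |quiescent log|` always holds.

Classification: symptomatic iff APD₉₀ exceeds the upper APD₉₀ calibration
bound of the control population (rationale: a mutant AP longer than
anything the control calibration would have accepted is pathologically
prolonged). An explicit ms threshold can be given instead; the main-text
description of the reference split ("shortest APDs") does not pin down the
rule, so this declared rule is a documented design choice.

## Drug model

Single pore block: each targeted channel's conductance is multiplied by
`1/(1+(dose/IC50)^h)`, constant in time (no state- or use-dependent
binding). Targets are I_Na, I_NaL, I_Kr, I_CaL; Hill defaults to 1 when a
table gives only IC50; IC50/h may differ per genotype (used for the
Na⁺-channel blockers, whose affinity for mutant channels differs from
wild-type). Trials re-simulate every model × dose from the published
initial conditions, compare APD₉₀ to the model's drug-free value, and
aggregate mean ± SD ΔAPD₉₀, stopped counts and paradoxical-prolongation
counts per dose and per phenotype label.

The shipped mexiletine/ranolazine YAMLs are synthetic stand-ins assembled
from typical assay magnitudes (mexiletine: strong I_NaL block, moderate
I_Na block stronger on mutant channels; ranolazine: strong I_NaL block,
weak I_Na block, moderate hERG block). The ranolazine I_Kr value was set to
60 μM because at literature-style 12 μM the stand-in inverted the drug's
documented net effect in LQT3 (APD shortening); with the shipped values the
stand-ins reproduce the documented qualitative profile: strong mutant APD
shortening for both drugs, near-neutral/slightly prolonged controls under
mexiletine, and more silenced cells under mexiletine than ranolazine.

## Analysis conventions

Group contrasts are **medians of absolute maxima** (scale × baseline, in
S/F, cm³/(F·s) or A/F), percent difference `100·(A−B)/B`; ΔAPD₉₀
aggregates are means ± SD. A rank-based test (Mann–Whitney) is available
but not part of any headline number.

## Synthetic-data generator

`make_waveform` produces AP-like waveforms with closed-form biomarkers
(linear or exponential repolarization; APD_x = x%·repol duration, or
τ·ln(100/(100−x))); `make_range_table` builds ±tightness windows around a
reference; `make_toy_population` plants exact group-median conductance
differences (central elements pinned to the median) recoverable to
round-off by `compare_groups`; `make_test_drug` is a fictitious blocker
whose 20 μM dose exactly halves I_NaL. These fixtures emulate input
*shapes* with known ground truth, not electrophysiology: tests passing on
them demonstrate the machinery (detection, extraction, filtering,
bookkeeping, contrast arithmetic) is correct, and tests on the real model
at reduced scale demonstrate directions and orderings — neither substitutes
for calibration against real experimental tables at full scale
(10⁴ sampled models), which the same code performs given those tables and
proportionally more compute.

## Problem sizes used by the shipped tests

Baseline mutation effect: full 800-s protocol, control + mutant. Population
checks: 48 sampled models, 60-s runs, synthetic ranges (≈ 12 accepted,
5 symptomatic / 7 asymptomatic at the fixed seed). Drug checks: the mutant
population at 10/20 μM plus two-model contrast fixtures. At this scale the
dominant contrasts (late-Na, L-type Ca, rapid-rectifier, ancestor APD₉₀)
reproduce with the published signs; small contrasts (I_K1, ancestor rate
and V_max) need the full-scale calibrated population and are not asserted.

## Known limitations

Hodgkin–Huxley I_Na/I_NaL (no Markov state dependence); pore block without
use-dependence; variability restricted to maximal conductances (kinetics
shared); single-cell only (no tissue coupling or stochastic gating);
synthetic stand-in ranges and drug tables unless replaced; the baseline
transcription is validated against the published behaviour of the model
family (spontaneous rate, AP morphology, biomarker ranges) rather than
line-by-line against later revisions of the equation set.
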