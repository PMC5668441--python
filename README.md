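# cardiopop

Experimentally calibrated **populations of in-silico hiPSC-cardiomyocyte
models** for studying phenotypic variability in long QT syndrome type 3
(LQT3) and its response to late-sodium-current blockers.

Human induced pluripotent stem cell-derived cardiomyocytes (hiPSC-CMs) beat
spontaneously and vary strongly from cell to cell and lab to lab. A single
"average" model cannot explain why some carriers of the same Na+-channel
mutation show a severe phenotype while others look normal, or why the same
drug shortens the action potential (AP) in one cell, silences a second and
paradoxically prolongs a third. `cardiopop` addresses this with the
population-of-models method: sample many variants of one mechanistic cell
model, keep those consistent with experimental biomarker ranges, express a
mutation in every accepted model, and run in-silico drug trials on the whole
ensemble.

The package is aimed at computational electrophysiologists and
safety-pharmacology modellers; it is primarily a Python library (see
`examples/`), with a thin `cardiopop` command-line wrapper for the pipeline.

## What is inside

- **Cell model** (`cardiopop.cell_model`) — the spontaneous ventricular-like
  hiPSC-CM membrane model of Paci et al. (Ann Biomed Eng 2013): 11
  sarcolemmal currents, dynamic intracellular Na+/Ca2+, no stimulus; membrane
  equation `dVm/dt = −ΣI/Cm`. Extended with a Hodgkin–Huxley late Na+ current
  `I_NaL = g_NaL · mL · hL · (Vm − E_Na)` (O'Hara–Rudy gate shapes). The LQT3
  **V1763M** genotype shifts and slows `hL` inactivation so that the
  persistent I_NaL measured 200 ms after the upstroke is 4.86× control.
- **Simulation** (`cardiopop.simulation`) — stiff-capable adaptive
  integration (LSODA) to a steady spontaneous-beating regime, with explicit
  spontaneous / quiescent / failed outcomes and AP cycle detection.
- **Biomarkers** (`cardiopop.biomarkers`) — rate, MDP, Peak, APA, V_max and
  APD₃₀/₅₀/₉₀ per beat (APD measured from the instant of maximum upstroke
  velocity to x% repolarization of the per-beat amplitude).
- **Population** (`cardiopop.population`) — conductance sampling (uniform or
  Latin hypercube on [0.5, 2]×baseline), calibration against per-biomarker
  `[min, max]` windows, in-silico transfection of the mutation (1:1 id
  mapping, no re-calibration), symptomatic/asymptomatic classification.
- **Drugs** (`cardiopop.drugs`) — single pore-block model
  `factor = 1/(1 + (dose/IC50)^h)` on I_Na, I_NaL, I_Kr, I_CaL with
  per-genotype IC50 overrides; population dose sweeps with ΔAPD₉₀, stopped
  and paradoxical-prolongation bookkeeping.
- **Analysis** (`cardiopop.analysis`) — median conductance contrasts between
  groups (symptomatic vs asymptomatic, stopped vs beating, ancestors by
  descendant fate), reported on absolute maxima (S/F, cm³/(F·s), A/F).
- **Synthetic data** (`cardiopop.synthetic`) — analytic AP waveforms with
  closed-form biomarkers, toy range tables, planted-truth populations and a
  fictitious test drug, so every stage is testable with no experimental
  input. The shipped `configs/*_synthetic.yaml` calibration ranges and
  mexiletine/ranolazine tables are clearly-labelled synthetic stand-ins for
  assay data.

## Worked example

```python
import cardiopop as cp

settings = cp.SolverSettings(duration=240.0, analysis_window=30.0)
for tag, params in (("control", cp.CellParameters()),
                    ("mutant", cp.apply_mutation(cp.CellParameters()))):
    res = cp.run_to_steady_state(params, settings=settings)
    bio = cp.extract_biomarkers(cp.detect_cycles(res.trace), res.trace)
    inal = cp.persistent_late_sodium(res, params)
    print(tag, round(bio["APD90"], 1), "ms", round(inal, 4), "A/F")
```

prints

```
control 511.8 ms -0.0752 A/F
mutant  732.1 ms -0.3654 A/F
```

i.e. the mutation prolongs APD₉₀ by **+43.0%** and enlarges the persistent
late Na+ current **4.86-fold** — the gain-of-function signature of LQT3: a
small inward Na+ leak that outlasts the upstroke and delays repolarization.
`examples/` contains one short script per capability (baseline mutation
effect, population building, transfection and classification, drug trials,
group contrasts), each printing and explaining its numbers.

The same pipeline is scriptable from the shell:

```bash
cardiopop run --n 100 --seed 1 --outdir myrun     # full pipeline
cardiopop make-fixtures toyws                     # toy workspace
cardiopop drug-trial --population pop.csv --drug mexiletine.yaml --doses 5,10,20
```

## Limitations

Hodgkin–Huxley (not Markov) Na+-channel kinetics; time-independent pore
block (no use-dependence); conductance variability only (kinetics shared by
all models); synthetic stand-in calibration ranges and drug tables unless
you supply transcribed experimental ones. See `docs/methods.md` for the full
model description and every numerical choice.
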