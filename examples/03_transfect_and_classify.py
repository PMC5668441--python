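"""In-silico transfection of the LQT3 mutation and phenotype classification.

Takes a small calibrated control population, expresses the V1763M late-Na
mutation in every member (no re-calibration — the control-to-mutant id
mapping stays 1:1), and splits the mutants into symptomatic (APD90 beyond
the control calibration window) and asymptomatic groups.
"""

import cardiopop as cp
from cardiopop.config import packaged_config

ranges = cp.BiomarkerRanges.from_yaml(packaged_config("ranges_synthetic.yaml"))
settings = cp.SolverSettings(duration=60.0, analysis_window=20.0)

control = cp.build_population(n=30, ranges=ranges, seed=1, settings=settings, progress=True)
mutant = cp.transfect(control, settings=settings, progress=True)
labels = cp.classify(mutant)

ctrl_apd = control.table.set_index("id")["APD90"]
mut_apd = mutant.table.set_index("id")["APD90"]
pct = 100 * (mut_apd.median() / ctrl_apd.loc[mut_apd.index].median() - 1)

print(f"\ncontrol models: {len(control)}   mutant survivors: {len(mutant)}   "
      f"stopped by the mutation: {len(mutant.provenance['quiescent_ids'])}")
print(f"median APD90: control {ctrl_apd.median():.0f} ms -> mutant {mut_apd.median():.0f} ms "
      f"(+{pct:.0f}%)")
print(f"phenotypes: { {k: int(v) for k, v in labels.value_counts().items()} } "
      f"(threshold {mutant.provenance['classification_threshold_ms']:.0f} ms)")
print("\nSymptomatic models are those whose mutant AP is longer than anything the")
print("control calibration would accept — the in-silico long-QT phenotype.")
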