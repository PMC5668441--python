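"""Multichannel pore-block drug trial on a mutant population.

Applies the packaged (synthetic) mexiletine and ranolazine parameter sets
to a small LQT3 mutant population at 10 and 20 μM and reports the mean
ΔAPD90 and the number of models whose spontaneous beating stops.
"""

import cardiopop as cp
from cardiopop.config import packaged_config

ranges = cp.BiomarkerRanges.from_yaml(packaged_config("ranges_synthetic.yaml"))
settings = cp.SolverSettings(duration=60.0, analysis_window=20.0)

control = cp.build_population(n=30, ranges=ranges, seed=1, settings=settings, progress=True)
mutant = cp.transfect(control, settings=settings, progress=True)
cp.classify(mutant)

for spec in ("mexiletine_synthetic.yaml", "ranolazine_synthetic.yaml"):
    drug = cp.DrugSpec.from_yaml(packaged_config(spec))
    trial = cp.drug_trial(mutant, drug, [10.0, 20.0], settings=settings, progress=True)
    agg = trial.aggregates
    overall = agg[agg["label"].isna()] if "label" in agg.columns else agg
    print(f"\n{drug.name} on the mutant population:")
    for _, row in overall.iterrows():
        print(f"  {row['dose_uM']:4.0f} uM: mean dAPD90 {row['mean_dAPD90_ms']:7.1f} ms "
              f"({row['mean_dAPD90_pct']:+5.1f}%), stopped {int(row['n_stopped'])}, "
              f"paradoxically prolonged {int(row['n_prolonged'])}")

print("\nBoth late-Na blockers shorten the pathologically long mutant APs; the")
print("stronger fast-Na block of mexiletine silences more cells than ranolazine.")
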