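# SYNTHETIC ranolazine multichannel pore-block parameters.
#
# Stand-in built from typical literature-scale assay values (ranolazine blocks
# late Na+ current at single-digit micromolar, fast Na+ current only weakly —
# the key difference from mexiletine — and hERG at low tens of micromolar).
# Not transcribed from any specific assay table.
name: ranolazine
doses_uM: [5.0, 10.0, 20.0]
channels:
  I_NaL:
    ic50_uM: 6.2
    hill: 1.0
  I_Na:
    ic50_uM: 294.0
    hill: 1.0
    genotype_overrides:
      V1763M:
        ic50_uM: 194.0
  I_Kr:
    ic50_uM: 60.0
    hill: 1.0
  I_CaL:
    ic50_uM: 296.0
    hill: 1.0
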