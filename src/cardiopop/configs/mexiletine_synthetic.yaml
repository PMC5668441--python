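# SYNTHETIC mexiletine multichannel pore-block parameters.
#
# Stand-in built from typical literature-scale ion-channel assay values
# (mexiletine is a strong late-Na blocker, a moderate fast-Na blocker with
# higher affinity for gain-of-function mutant channels, and a weak hERG /
# L-type blocker).  Not transcribed from any specific assay table; replace
# with measured IC50/Hill values for quantitative work.
name: mexiletine
doses_uM: [5.0, 10.0, 20.0]
channels:
  I_NaL:
    ic50_uM: 8.4
    hill: 1.0
  I_Na:
    ic50_uM: 110.0
    hill: 1.0
    genotype_overrides:
      V1763M:
        ic50_uM: 38.0
  I_Kr:
    ic50_uM: 50.0
    hill: 1.0
  I_CaL:
    ic50_uM: 125.0
    hill: 1.0
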