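# SYNTHETIC calibration ranges.
#
# Stand-in for the experimental per-biomarker acceptance windows that a real
# calibration would take from published hiPSC-CM datasets (union of per-dataset
# min/max).  The numbers below are plausible literature-scale bounds for
# spontaneously beating hiPSC-CMs, chosen once when this file was written; they
# are NOT transcribed from any specific dataset.  Replace this file with a
# transcription of real dataset tables to calibrate against experiments.
source: synthetic union-of-datasets stand-in
biomarkers:
  rate:
    lower: 15.0      # beats/min
    upper: 95.0
  MDP:
    lower: -85.0     # mV
    upper: -50.0
  Peak:
    lower: 10.0      # mV
    upper: 55.0
  APA:
    lower: 75.0      # mV
    upper: 125.0
  Vmax:
    lower: 5.0       # V/s
    upper: 60.0
  APD50:
    lower: 150.0     # ms
    upper: 450.0
  APD90:
    lower: 230.0     # ms
    upper: 630.0
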