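# Default exposure model for the baby-food ingestion pathway.
#
# BW (70 kg) and SF (7.3 per mg/kg/day, oral slope factor for BaP) are the
# study's stated values.  IR, EF, ED and AT are not printed in the study and
# are calibrated so that the combined ingestion factor
#     IR * EF * ED / (BW * AT)  =  1.86e-4 per day
# matches the study's published median-EDI-to-concentration ratio, which is
# constant across congeners.  Uncertainty is carried on IR as a lognormal
# with a 95th/50th percentile ratio of 1.5, reproducing the published
# EDI dispersion; every entry is overridable.
parameters:
  IR: {family: lognormal, median: 0.01302, p95_over_p50: 1.5}   # kg/day
  EF: {family: point, value: 365.0}                             # days/year
  ED: {family: point, value: 1.0}                               # years
  BW: {family: point, value: 70.0}                              # kg
  AT: {family: point, value: 365.0}                             # days
  SF: {family: point, value: 7.3}                               # per mg/kg/day
monte_carlo:
  iterations: 10000
  seed: 20220217
  percentiles: [5, 50, 75, 95]
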