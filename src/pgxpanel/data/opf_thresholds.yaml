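# Default per-algorithm binarization thresholds for the optimized prediction
# framework (OPF) composite pathogenicity score.  A score on the deleterious
# side of its threshold (the threshold itself counts as deleterious) is
# binarized to 1, otherwise 0.  Values follow dbNSFP conventions and are
# meant to be overridden from study-specific calibration when available.
algorithms:
  LRT:
    threshold: 0.0025
    direction: lower_is_deleterious
  MutationAssessor:
    threshold: 1.935
    direction: higher_is_deleterious
  PROVEAN:
    threshold: -2.5
    direction: lower_is_deleterious
  VEST3:
    threshold: 0.45
    direction: higher_is_deleterious
  CADD:
    threshold: 15.0
    direction: higher_is_deleterious
min_available: 3
classification_cutoff: 0.6
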