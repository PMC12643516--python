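# Fickett TESTCODE lookup tables, version 1.
#
# For each base, the position parameter is max(count in the three codon
# positions) / (min(count) + 1), and the content parameter is the base's
# overall fraction.  Each parameter value is converted into a probability
# of coding by finding the first threshold in *_para that the value
# reaches (thresholds scanned in decreasing order; the final entry is a
# catch-all) and taking the probability at that rank.  The eight
# probabilities are combined with the published weights into the TESTCODE
# score.  Classification bands: < 0.74 noncoding-like, > 0.95
# coding-like, otherwise borderline.
version: 1
position_para: [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]
content_para: [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0]
position_prob:
  A: [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22]
  C: [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23]
  G: [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08]
  U: [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09]
position_weight:
  A: 0.26
  C: 0.18
  G: 0.31
  U: 0.33
content_prob:
  A: [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21]
  C: [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31]
  G: [0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29]
  U: [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58]
content_weight:
  A: 0.11
  C: 0.12
  G: 0.15
  U: 0.14
noncoding_below: 0.74
coding_above: 0.95
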