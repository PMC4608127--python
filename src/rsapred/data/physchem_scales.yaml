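# Six per-residue physicochemical propensity scales, min-max normalised to
# [0, 1] at load time. The unknown residue X receives each scale's mean.
# Sources (classical epitope/structure-prediction scales):
#   hydrophilicity  - Parker, Guo & Hodges (1986)
#   flexibility     - Karplus & Schulz (1985)
#   accessibility   - Janin (1979) transfer free energy (positive = buried;
#                     monotone in burial, which is all the regressor needs)
#   polarity        - Grantham (1974)
#   exposed_surface - Emini et al. (1985) surface probability
#   turns           - Chou & Fasman (1978) beta-turn propensity
# Any replacement file with the same structure is accepted.
hydrophilicity:
  A: 2.1
  R: 4.2
  N: 7.0
  D: 10.0
  C: 1.4
  Q: 6.0
  E: 7.8
  G: 5.7
  H: 2.1
  I: -8.0
  L: -9.2
  K: 5.7
  M: -4.2
  F: -9.2
  P: 2.1
  S: 6.5
  T: 5.2
  W: -10.0
  Y: -1.9
  V: -3.7
flexibility:
  A: 0.984
  R: 1.008
  N: 1.048
  D: 1.068
  C: 0.906
  Q: 1.037
  E: 1.094
  G: 1.031
  H: 0.950
  I: 0.927
  L: 0.935
  K: 1.102
  M: 0.952
  F: 0.915
  P: 1.049
  S: 1.046
  T: 0.997
  W: 0.904
  Y: 0.929
  V: 0.931
accessibility:
  A: 0.3
  R: -1.4
  N: -0.5
  D: -0.6
  C: 0.9
  Q: -0.7
  E: -0.7
  G: 0.3
  H: -0.1
  I: 0.7
  L: 0.5
  K: -1.8
  M: 0.4
  F: 0.5
  P: -0.3
  S: -0.1
  T: -0.2
  W: 0.3
  Y: -0.4
  V: 0.6
polarity:
  A: 8.1
  R: 10.5
  N: 11.6
  D: 13.0
  C: 5.5
  Q: 10.5
  E: 12.3
  G: 9.0
  H: 10.4
  I: 5.2
  L: 4.9
  K: 11.3
  M: 5.7
  F: 5.2
  P: 8.0
  S: 9.2
  T: 8.6
  W: 5.4
  Y: 6.2
  V: 5.9
exposed_surface:
  A: 0.815
  R: 1.475
  N: 1.296
  D: 1.283
  C: 0.394
  Q: 1.348
  E: 1.445
  G: 0.714
  H: 1.180
  I: 0.603
  L: 0.603
  K: 1.545
  M: 0.714
  F: 0.695
  P: 1.236
  S: 1.115
  T: 1.184
  W: 0.808
  Y: 1.089
  V: 0.606
turns:
  A: 0.66
  R: 0.95
  N: 1.56
  D: 1.46
  C: 1.19
  Q: 0.98
  E: 0.74
  G: 1.56
  H: 0.95
  I: 0.47
  L: 0.59
  K: 1.01
  M: 0.60
  F: 0.60
  P: 1.52
  S: 1.43
  T: 0.96
  W: 0.96
  Y: 1.14
  V: 0.50
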