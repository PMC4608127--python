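# rsapred

Sequence-based prediction of the **relative solvent accessibility (RSA)** of
protein residues. RSA is a residue's accessible surface area (ASA, Å²)
divided by the maximum ASA of its amino-acid type in an extended Ala-X-Ala
tri-peptide, expressed as a fraction or percent. Because exposure drives
folding, binding and epitope accessibility, real-valued RSA prediction from
sequence alone is a standard first step when no structure is available.

The package is aimed at structural-bioinformatics practitioners who have the
usual upstream profiles for a chain — a PSI-BLAST PSSM, PSIPRED 3-state
secondary-structure probabilities, DISOPRED disorder probabilities — and
want a trained regressor plus honest chain-level cross-validated scores.

## Method

Each residue *i* is encoded from five sources over a sliding window of
*N* positions (default *N* = 9):

| block       | width | content |
|-------------|-------|---------|
| pssm_window | 21N   | logistic-normalised PSSM scores `x' = 1/(1+e^(−x))` + a terminal flag per position |
| ss_local    | 3N    | (C,H,E) probabilities per position |
| ss_global   | 6     | chain-level SS content and segment fractions (H-runs ≤ 2 recoded as coil for segment counting) |
| disorder    | 3N    | (p_disorder, p_order, state) per position |
| seq_len     | 1     | L / 1000 |
| seq_pos     | 1     | `1 − |i − (L+1)/2| / (L/2)` |
| physchem    | 6N    | six normalised propensity scales per position |

Positions beyond the chain ends are pseudo residues (all-zero features,
terminal flag 1). A **weighted sliding window** rescales each window
position's sub-block by multipliers derived from an ordinary-least-squares
fit of `RSA_i ~ b + Σ_k w_k · RSA_{i+k}` — the fitted neighbour influences
decrease symmetrically with distance from the centre, so near neighbours
keep almost full weight and far ones are damped.

The regressor is a Gaussian-kernel ε-SVR. Its hyperparameters (C, γ, ε) are
tuned by inertia-weight **particle swarm optimisation** (PSO) minimising
chain-level 3-fold cross-validated mean absolute error, with an exhaustive
grid search available as a baseline. Scores are MAE (percent RSA), Pearson
correlation, and two-state buried/exposed accuracy for thresholds 5–90%.

A first-class synthetic-data module generates chains with realistic profile
statistics and RSA tracks from two known processes (a symmetric
neighbour-autoregression for parameter-recovery tests and a feature-linked
logistic signal for learnability tests), so the whole pipeline is testable
without any downloads.

## Worked example

```sh
rsapred simulate --n-chains 12 --min-len 60 --max-len 90 --seed 11 --out data
rsapred fit-weights --in data --window 9 --out weights.json
rsapred tune  --in data --folds 3 --swarm 4 --iters 3 --seed 11 --subset 4 --out params.json
rsapred train --in data --params params.json --out model.joblib
rsapred simulate --n-chains 6 --min-len 60 --max-len 90 --seed 12 --out test_data
rsapred predict --in test_data --model model.joblib --out preds
rsapred evaluate --truth test_data --pred preds --out report.json
```

The tune step prints the selected hyperparameters and their subset CV error:

```
INFO best params C=0.97729 gamma=0.011995 epsilon=0.10682 (CV MAE 0.0888)
```

and the final evaluation on the six held-out chains prints

```
INFO MAE 7.78%  PCC 0.950 over 468 residues
```

i.e. predictions deviate from the true track by 7.8 RSA percentage points
on average and correlate at r = 0.95 — strong because the synthetic signal
is, by construction, a function of the encoded features. `report.json`
additionally holds two-state accuracies per threshold (94.0% at 25%),
per-residue-type means/errors, and the absolute-error histogram.

Everything is also available as a library (`rsapred.assemble_features`,
`rsapred.fit_window_weights`, `rsapred.pso_optimize`,
`rsapred.train_pipeline`, `rsapred.evaluate`, ...).

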