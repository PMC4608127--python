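# Methods

## Problem and model

The package predicts per-residue relative solvent accessibility (RSA) from
sequence-derived inputs. RSA is ASA normalised by the residue type's maximum
ASA in an extended Ala-X-Ala tri-peptide; internally all tracks are
fractions in [0, 1] and evaluation reports percent. The predictor is a
Gaussian-kernel ε-SVR over a windowed feature encoding; its assumptions are
the usual ones for this family of methods: exposure is largely determined by
local sequence context (window of N residues) plus a few global descriptors
(chain length, position in the chain, overall secondary-structure content),
and the mapping is smooth enough for an RBF kernel.

## Feature encoding

Five blocks per residue (widths for window N): PSSM window 21N, local
secondary structure 3N, global secondary structure 6, disorder 3N, sequence
descriptors 2, physicochemical 6N — 33N + 8 columns in total, 305 at the
default N = 9. Details that required decisions:

- **Pseudo-terminal padding.** Window positions outside the chain contribute
  literal zeros (not logistic(0) = 0.5) for the 20 PSSM values and a
  terminal flag of 1. Real first/last residues carry flag 0 by default; a
  `flag_real_terminals` switch marks them too, since usage varies between
  implementations of this encoding.
- **Global segment counting.** Content fractions use the raw C/H/E string;
  for segment fractions, maximal H-runs of length ≤ 2 are first recoded to
  coil (too short to be a helix). E and C runs are never recoded. Both
  (H,E,C) triples sum to 1 for any non-empty chain.
- **Physicochemical scales.** Six classical propensity scales (Parker
  hydrophilicity, Karplus–Schulz flexibility, Janin accessibility, Grantham
  polarity, Emini surface probability, Chou–Fasman turns) ship as a YAML
  file, min-max normalised to [0, 1] at load; X maps to each scale's mean.
  The file is user-replaceable — any 20-letter table with the same six keys
  works. The same applies to the max-ASA table (Ahmad Ala-X-Ala values).
- **Weighted window.** The neighbour-influence model (below) supplies
  per-offset multipliers. Mode `max` (default) uses m_k = w_k / max_j w_j
  with the centre fixed at 1, preserving the fitted ordering of
  contributions while keeping feature magnitudes bounded; `raw` uses the
  coefficients directly; `none` disables weighting. How fitted regression
  weights should enter the encoding is genuinely open; the normalised form
  was chosen so that switching weighting on never shrinks the most
  informative neighbours, and the intercept plays no role.

## Neighbour-weight regression

`fit_window_weights` solves ordinary least squares for
RSA_i = b + Σ_k w_k RSA_{i+k} over every residue whose window lies fully
inside a chain; incomplete windows are excluded rather than padded, to avoid
biasing coefficients with artificial zeros. Degenerate designs (constant
RSA) raise a singular-fit error. Diagnostics report the symmetry
(max |w_k − w_{−k}|) and centre-ward monotonicity of the fitted profile.
Coefficients are invariant to the RSA unit; the intercept scales with it.

## Hyperparameter search

PSO uses the standard inertia-weight update (ω = 0.729, c1 = c2 = 1.49445,
Clerc–Kennedy constriction values), velocities clamped to 20% of each
dimension's range, positions clipped to the box with the velocity zeroed in
clipped dimensions, and non-finite fitness treated as +inf. C and γ are
searched in log10 space (1e-4..1e3 and 1e-5..1e1), ε linearly (0..0.5 on
fraction RSA). The fitness is the pooled residue-weighted chain-level CV
MAE, computed on features encoded once and reused across evaluations. The
swarm can be warm-started with incumbent parameters
(`init_positions` / `seed_default`); warm-starting with the defaults
guarantees tuning never does worse than the defaults under the same folds.
Untuned defaults follow the LIBSVM convention: C = 1, γ = 1/(D·Var(X)),
ε = 0.1. For large corpora `tune_on_subset` mirrors the common reduced-set
strategy: a fixed number of chains is sampled from each fold and tuning runs
on that subset only.

Cross-validation is always chain-level: `make_folds` partitions chain ids
(sizes differing by at most 1), so no residue of a test chain ever enters
its own training set.

## Evaluation

- MAE default is mean |x − y| on percent RSA — the deviation measure whose
  reported magnitudes (≈ 8–15%) this field quotes. A `relative` mode,
  mean |x − y|/x with zero-truth positions skipped and counted, is provided
  because some formulations normalise by the true value; it diverges at
  buried residues and is not the default.
- PCC is Pearson correlation (scipy); constant inputs raise an explicit
  undefined-correlation error. Tests verify it against the textbook formula
  written independently.
- Two-state accuracy binarises truth and prediction with the same
  "exposed if RSA ≥ threshold" rule.
- Per-type summaries (mean true/predicted RSA, error, RSA standard
  deviation per amino acid) use the true residue identity; the correlation
  between per-type error and per-type RSA spread is reported, and is NaN in
  degenerate cases (single type, zero error).
- Error-band histograms use left-closed 10-point bins with the last bin
  closed, so counts always sum to the residue count.

## Synthetic data

The generator emulates the statistical shape of real inputs, not their
biophysics: sequences from a Swiss-Prot-like composition; PSSM rows with the
emitted residue's own column elevated by +6 log-odds; secondary structure
from a 3-state Markov chain (self-transitions 0.85/0.80/0.75 for H/E/C,
giving realistic geometric run lengths); disorder as a low background with a
few contiguous high-probability segments. Generated probabilities are
quantised to the precision of their on-disk dialects so every fixture
round-trips bit-exactly.

Two RSA processes:

- **neighbor_linear** — the stationary law of the symmetric update
  RSA_i ← b + Σ w_k RSA_{i±k} + N(0, σ²): a Gaussian conditional
  autoregression with banded precision (I − W)/σ², sampled exactly by
  banded Cholesky. This construction was chosen deliberately over a
  simultaneous-autoregression draw x = (I − W)⁻¹(b + u): for the CAR the
  conditional mean given the window neighbours is exactly b + Σ w_k x_{i±k},
  so OLS recovery of (w, b) is unbiased, whereas OLS on an SAR draw is
  inconsistent (simultaneity bias of the same order as the weights).
  Validity requires Σ|w| < 1; defaults are ±(0.22, 0.12, 0.05, 0.01) with
  b = 0.07 (stationary mean 0.35) and σ = 0.02. Optional observation noise
  is a separate parameter defaulting to 0, because errors-in-variables
  attenuation would otherwise bias recovery; with the defaults fewer than 1%
  of values hit the [0, 1] clamp.
- **feature_linked** — RSA = logistic(linear signal) + N(0, 0.05), clamped.
  The signal combines the residue's normalised physicochemical values
  (hydrophilic, flexible, polar, turn-prone and surface-prone residues more
  exposed), helix/strand probabilities (negative coefficients: structured
  residues more buried), and chain position (termini more exposed), with
  the intercept set so the population mean RSA is ≈ 0.3 and spread ≈ 0.15 —
  typical of real chains.

What passing tests on this data does and does not show: recovery and
learnability results validate the estimators and the protocol (no leakage,
correct arithmetic, a learnable signal is learned), but synthetic chains
carry no homology, no real evolutionary profiles and no contact-driven
exposure patterns, so accuracy numbers here say nothing quantitative about
accuracy on real proteins.

## Problem sizes and numerical choices

- Neighbour-weight recovery experiments use 200 chains × length 300
  (≈ 58k complete windows); at that size the OLS sampling s.d. per
  coefficient is ≈ 0.004, so the ±0.01 recovery check is ≈ 2.5 s.d.
- The tuned-vs-default comparison uses 20 paired runs on 30 chains of
  length 30–45 with a swarm of 5 × 5 iterations, warm-started at the
  defaults and evaluated on identical folds — a paired design in which
  tuning can only match or improve.
- End-to-end learnability uses 20 training + 10 held-out chains of length
  50–80.
- OLS uses `numpy.linalg.lstsq` with a rank check; residual orthogonality
  holds to 1e-8 in tests. Ss3 argmax ties break C > H > E (coil as the
  unstructured default). The DISOPRED decision threshold is 0.5 with the ≥
  rule, applied identically in parsing and encoding.
- All randomness flows from explicit seeds (numpy `default_rng`); identical
  configuration and seeds give byte-identical outputs, including prediction
  TSVs.

## Known limitations

- The ε-SVR is scikit-learn's; training is O(n²)–O(n³) in residues, so
  corpus-scale fitting needs subset tuning and patience.
- Window weighting modes other than the shipped three, per-type neighbour
  models, and regularised variants of the neighbour regression are out of
  scope.
- DSSP parsing is limited to a minimal (position, residue, ACC) TSV; full
  DSSP files must be reduced upstream.
- The physicochemical defaults are classical scales chosen for availability
  and documentation; swapping in other six-scale sets is supported but
  untested beyond shape checks.
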