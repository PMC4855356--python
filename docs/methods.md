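# Methods

## Model

The correction model predicts the benchmark-quality interaction energy of a
molecular complex directly from a small set of descriptors, of which the
cheap DFT interaction energy (`dft_nci`, kcal/mol) is the primary one. The
predictor is a general regression neural network (GRNN): Nadaraya–Watson
kernel regression in which every training complex is stored as a pattern
neuron and a query is scored as the Gaussian-weighted average of the
training targets,

    y(X) = Σᵢ yᵢ pᵢ(X) / Σᵢ pᵢ(X),   pᵢ(X) = exp(−‖X − Xᵢ‖²/2σ²).

There is no iterative optimization: fitting stores the normalized patterns
and targets verbatim, and the only tunable parameter is the smoothing
factor σ. Predictions are convex combinations of training targets, so they
are bounded by the training-target range; σ → 0 interpolates the training
targets and σ → ∞ returns their mean. The learned correction is the
difference between the GRNN output and the raw DFT value, so
`corrected = dft + correction` holds exactly by construction.

Assumptions: the DFT error is a smooth function of the chosen descriptors;
the descriptor table covers the query region (kernel regression does not
extrapolate — distant queries fall back to the nearest pattern's target);
reference energies are trustworthy (they are the regression targets).

## Workflow and parameters

| Parameter | Default | Meaning |
|---|---|---|
| train fraction | 91/121 ≈ 0.752 | SPXY training share; `n_train = round(f·N)` |
| K (CV folds) | 10 | seeded shuffle, round-robin folds, sizes differ ≤ 1 |
| σ grid | 0.1 : 2 : 0.1 | smoothing-factor loop test (normalized units) |
| shortlist k | 10 | descriptors kept after PLS ranking |
| max subset | 6 | largest GRNN input subset searched |
| PLS components | 2 | screening rank; coefficients on centered, scaled data |
| fallback σ | 0.2 | used only when no reference data allow optimization |

Stage order: SPXY split → normalization (fitted on the training set) → PLS
ranking → exhaustive CV subset search (every candidate contains the
primary descriptor; σ optimized per candidate; ties prefer the smaller
subset, then lexicographic names, and the larger σ) → final fit on the full
training set → validation.

Design choices where the design was genuinely open:

- **Normalization.** All variables are min–max scaled to [−1, 1].
  Constant variables map to 0 and are flagged rather than dropped, keeping
  column indices stable. Query values outside the fitted range are *not*
  clipped; kernel distances remain meaningful for mild extrapolation.
  Inside cross-validation the map is refitted on each fold's training part
  only, so no information leaks from held-out samples.
- **SPXY metric.** Euclidean distance on the normalized descriptor block,
  absolute difference on the normalized response, each block scaled by its
  own maximum. A degenerate block (zero maximum) contributes 0; both
  blocks degenerate is an error. The split uses *all* available
  descriptors (splitting precedes screening). Ties in the greedy max–min
  selection break toward the lowest row index for determinism.
- **σ selection** uses CV RMSE in kcal/mol (denormalized); exact ties go to
  the larger, smoother σ. σ selection never sees the SPXY test set.
- **Subset search** is exhaustive over shortlist subsets containing the
  primary descriptor up to size 6 (≤ 382 candidates), so the reported
  winner is the true CV argmin, not a greedy approximation. The
  single-descriptor baseline is always in the pool, so the winner never
  scores worse than the DFT-only model.
- **R²** is the squared Pearson correlation (goodness-of-fit); the
  coefficient-of-determination variant is available as
  `validation.r2_determination`. q² and q²cv use the external-validation
  form 1 − PRESS/SS(ȳ_train) with the *training-set* mean in the
  denominator; both may be negative. The over-fit flag fires iff
  R² − q²cv > 0.3.
- **Numerical stability.** Kernel weights are computed with the maximum
  exponent shifted out, so the denominator is ≥ 1 and a query far from all
  patterns returns the nearest pattern's target instead of 0/0.
- **Valence table.** Constitutional descriptors use main-group valence
  counts (H=1, C=4, N=5, O=6, S=6, P=5, halogens=7, …, H–Xe); a benzene
  dimer C12H12 therefore counts 24 atoms and 60 valence electrons.
- The "arrangement of monomers" style descriptors have no canonical
  encoding; any user-supplied numeric column is accepted as a descriptor.

## Synthetic benchmark

The generator emulates the statistical shape of the S22/S66/X40
compilation so every stage is testable without quantum-chemistry runs:

- Four interaction classes with counts (29, 30, 26, 36) and mean reference
  energies (−10.33, −3.94, −3.70, −3.43) kcal/mol; within-class spreads
  3.0 kcal/mol (H-bonded) and 2.0 kcal/mol (others), truncated at 0
  (binding energies are negative).
- The simulated DFT energy is
  `ref + bias_c·ref + g(descriptors) + N(0, 0.4)` with class-dependent
  multiplicative biases (0.45, −0.38, 0.22, −0.15) — small-basis DFT
  over/under-binds different interaction motifs differently — and a smooth
  linear term `g` in three planted informative descriptors (analogues of
  the valence-electron count, dipole moment and E_LUMO+1).
- Each planted descriptor follows a smooth per-class trend in the
  reference with small Gaussian jitter, plus a crisp two-level sub-motif
  split inside one class (Cl vs Br/I-type halogen bonds for `nve`, π- vs
  aliphatic-type dispersion for `dipole`, a sub-motif of the mixed class
  for `e_lumo1`) that carries ~2.6–3 kcal/mol of that class's systematic
  error through `g`. The split makes each descriptor individually
  necessary for the correction while keeping it nearly deterministic
  elsewhere, which preserves kernel locality after min–max scaling. This
  mirrors a property of real quantum descriptors: they are strongly
  collinear with the interaction energy, with discrete chemical sub-motifs
  rather than independent continuous scatter.
- 39 additional descriptors are pure standard-normal noise, for 43 columns
  in total.

Raw DFT-vs-reference RMSE lands at ≈ 2.5–3.0 kcal/mol (within the
1.4–4.0 kcal/mol span of uncorrected small-basis methods), with the
0.4 kcal/mol noise floor at ~15% of it, so a correct pipeline can remove
≥ 70% of the error. Everything is a pure function of the seed.

What passing tests on this generator do **not** show about real data: real
descriptor–error relationships need not be linear in the descriptors; real
sub-motif structure is richer than one binary split per class; descriptor
noise is not Gaussian; and reference energies carry their own (small)
uncertainty. The generator validates the machinery and the headline error
reduction under a faithful error *scale and structure*, not the chemistry
of any particular complex.

## Problem sizes

Default analyses use the 121-complex benchmark size with 10-fold CV and a
20-point σ grid; the exhaustive subset search evaluates ≤ 382 candidates,
each at all 20 σ values, which completes in roughly two seconds per seed.
The repeated-seed analyses (subset recovery, median error reduction)
aggregate ten consecutive seeds.

## Limitations

- Kernel regression degrades with genuinely high-dimensional informative
  input; the subset search caps inputs at 6 for this reason.
- The model cannot correct error components invisible to its descriptors
  (e.g. the irreducible noise floor in the simulation).
- Quantum-chemistry computation is entirely out of scope: descriptors and
  reference energies arrive as table columns; no program output is parsed.
- The fallback σ = 0.2 is a sensible default for small-basis descriptor
  sets but is always overridden by the CV loop test when reference data
  are present.
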