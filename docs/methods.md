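# Methods

## Problem setting

Fluoroquinolone antibiotics largely pass through wastewater treatment
unchanged and accumulate in sewage sludge. During the thermophilic stage of
sludge composting, heat-tolerant bacteria (here represented by the degrading
enzymes 1GKQ, 1OB0 and 5M0K) can break them down. The package quantifies
that degradability and the levers that improve it, starting from
ligand-receptor docking scores and MD binding energies as inputs — it never
performs docking or MD itself.

## Composite biodegradability (scoring)

The score matrix must be strictly positive and finite with at least two
compounds; each receptor column is treated as a criterion in a
multi-criteria evaluation.

- Proportions `P_ij = v_ij / sum_i v_ij` make every column a probability
  distribution over compounds.
- Column entropy `e_j = -(1/ln m) * sum_i P_ij ln P_ij` (natural log,
  `0 ln 0 = 0`) lies in [0, 1]; a uniform column carries no discriminating
  information (`e = 1`), a one-hot column the most (`e = 0`).
- Entropy weights `w_j = (1 - e_j) / sum_k (1 - e_k)` require at least one
  column with `e_j < 1`; all-uniform input is a hard error, not a silent
  fallback.
- Range normalisation maps each column affinely onto [1, 9] with the column
  minimum at 1 and maximum at 9. (A verbal description elsewhere of the
  anchors being "9 and 1" is superseded by the formula itself, whose
  midpoint lands at 5 on the 1-9 scale.) Constant columns are errors that
  name the offending receptor.
- Composite value `b_i = sum_j w_j a_ij` inherits the [1, 9] bounds.

All intermediates (proportions, entropies, weights, normalised matrix) are
retained on the result object for audit. Invariants asserted on every fit:
weights sum to 1, proportion columns sum to 1, all normalised and composite
values within the scale.

**Known discrepancy.** Applying this pipeline to the packaged 49 x 3 score
table does not reproduce the packaged composite reference values
(mean |dev| ~ 0.67, max ~ 0.90 on the 1-9 scale, recomputed at run time by
`datasets.composite_deviation_report()`). Cross-checking individual
compounds implies mutually inconsistent weights, so the reference table
cannot have been produced from the score table by these formulas as printed.
The reference is therefore shipped as a diagnostic comparison only; no test
gates on it and no alternative formula is guessed.

## PLS QSAR and its validation battery (qsar)

PLS1 is implemented by NIPALS on column-centred X and centred y, unscaled by
default (the CoMFA convention; unit-variance scaling is available via
`scale_blocks`). Extraction stops early, without error, when the residual X
block is numerically rank-deficient; the actual component count is recorded.
The fit is deterministic — no randomness anywhere in the chain.

- `loo_q2`: leave-one-out `q2 = 1 - PRESS/SS` with the denominator anchored
  at the full-training-set mean (held fixed across folds). The per-fold
  component count is capped at `s - 2`.
- `select_components`: argmax of LOO q2 over `1..max_n`, capped at
  `min(s_train - 2, p, 10)`; ties resolve toward fewer components.
- `r2pred = 1 - sum(y - yhat)^2 / sum(y - ybar)^2` on the external test
  set. The reference mean defaults to the training mean (the standard
  external-validation convention); `ref_mean="test"` gives the literal
  test-mean reading. The convention used is recorded in every report.
- Overfit index `(r2 - q2)/r2`, defined only for `r2 > 0`.
- Acceptance flags use strict inequalities: `q2 > 0.5`, `r2 > 0.8`,
  overfit `< 0.30`, `r2pred > 0.6`.

The published q2/r2 values of the original CoMFA models are not recomputable
without the original field matrices and train/test membership; they enter
only through the overfit-index arithmetic, which reproduces the four
published percentages exactly from the printed (r2, q2) pairs.

## Lattice field descriptors (fields)

Molecules must arrive pre-aligned with partial charges attached; neither
alignment nor charge assignment is computed here. The grid is the smallest
lattice (default spacing 2.0 A) enclosing all conformers with a 4.0 A
margin.

- Steric: Lennard-Jones 6-12 against an sp3-carbon probe (radius 1.70 A,
  well depth 0.457 kJ/mol), `rmin = R_i + R_probe`,
  `eps = sqrt(e_i * e_probe)`.
- Electrostatic: Coulomb with a +1 e probe and linear distance-dependent
  dielectric, so the pair energy is `k q_i q_p / r^2` with
  `k = 1389.35458 kJ A / (mol e^2)`.
- Both fields are clamped to ±125.4 kJ/mol (30 kcal/mol) after summation; a
  small distance floor keeps grid points coincident with atoms finite before
  the clamp. Values below the clamp are unaffected by raising it.
- Assembly stacks the steric block then the electrostatic block in grid
  raster order; electrostatic values at sterically excluded points are
  replaced by the column mean over non-excluded molecules (toggleable to
  plain clamping); near-constant columns (sd < 1e-6) are dropped with a
  reported count.

The probe identity, functional forms and grid geometry are the de-facto
CoMFA standards; the module is validated by scalar-formula oracles and
geometric invariants (translation equivariance, clamp bounds), not by
published numbers, which do not exist at this granularity.

## Derivative screening (screening)

Percent changes are raw signed values `100 (new - ref)/ref`, rounded
half-up to 2 decimals — the printed-table convention (note a "reduction of
129.47%" in prose corresponds to the signed table value −129.47). The
bioconcentration red line is strict: a compound fails only for
`logKow > 5` (Stockholm-Convention persistence definition), so 5.0 exactly
passes. Ranking sorts by composite-value change descending with the name as
tie-break and is a pure permutation of the derivative records. Survey
summaries are arithmetic means rounded half-up (the N column mean 0.605
prints as 0.61 only under half-up); the nutrient addition levels (2/1/2
g/kg C/N/P) are downstream simulation configuration, never derived from the
means.

## Factorial analysis (factorial)

Binding energies are negative for bound states, so improvements are
percentages of magnitude: `100 (|E_g| - |E_b|)/|E_b|` with a negative blank
required. Scenario reports flag groups with positive improvement and report
the min-max range among them. The packaged scenario fixture contains only
the group energies that were published (scenario 3 published only its blank,
which is exactly why its beneficial set is empty).

Effects require a complete 2^k design (replicates averaged per cell first)
and use the Yates ±1 coding: `effect(T) = (1/2^(k-1)) sum signs * cellmean`.
This equals the marginal-mean difference for main effects and twice the
±1-coded least-squares coefficient for every term — both identities are
regression-tested.

Significance at p = 0.05:

- `lenth` (default for unreplicated designs): pseudo standard error
  `PSE = 1.5 * median{|effect| : |effect| < 2.5 * (1.5 * median|effect|)}`,
  individual margin `t(0.975, d/3) * PSE` with d effects. Simulation shows
  type-I control at ~5% per effect and near-certain detection of 10-sigma
  effects.
- `pool-high-order`: highest-order interactions pooled as pure error,
  t-tests for the rest.
- `replicated-anova`: ordinary least squares on ±1 regressors (via
  statsmodels) when every cell has >= 2 replicates; infeasible shapes raise.

Group-to-amendment mapping follows the published design table (G1 = OM,
G2 = POS, ..., G8 = MS). The published amendment-scenario effect estimates
themselves (e.g. 10.929 for apple pomace) are not recomputable because the
underlying per-run responses were never published; they are discussed here
only as context.

## MM/PBSA bookkeeping (energetics)

`G_bind = G_complex - G_protein - G_ligand`; per species
`G = E_gas - T S_gas + G_polar + G_nonpolar` with energies in kJ/mol and
entropies in kJ/mol/K. `validate_record` reports residuals of every identity
without raising. The composting simulation temperatures 308 K and 328 K are
accepted presets. Component-level values were never published, so component
checks are property-based (generated records satisfy the identities exactly;
injected perturbations are detected at their known magnitude).

## Synthetic data (synthetic)

One `numpy.random.Generator` per call, seeded explicitly; no global state.

- Score matrices: truncated-normal positive scores with per-receptor means
  (100, 73, 116) and sds (10, 8, 13), mirroring the spread of the packaged
  49 x 3 docking table.
- QSAR datasets: `X = T C P' + noise`, `y = T q + noise` with orthonormal
  loadings, geometrically decreasing component strengths `C = (1, 1/2, 1/4,
  ...)` and *inverse* response loadings `q = reverse(C)`. The inverse
  loading is what makes a PLS model genuinely need all k components (each
  component corrects the mismatch between covariance and regression
  directions), giving a sharply peaked LOO-q2 curve. Defaults mirror the
  study scale: 30 samples, 8 of them held out, descriptor noise and response
  noise 0.05. Ground truth (k, beta = P C^-1 q, scores, loadings) is
  returned alongside.
- Factorial responses: complete 2^k enumeration, response
  `intercept + sum_T (effect_T / 2) * prod(x_T) + N(0, sigma)` in ±1 coding,
  so estimation recovers the injected map exactly at sigma = 0.
- Energy records: protein/ligand components drawn freely; the complex
  non-polar term is solved so both identities close exactly while the
  binding energy realises a drawn `N(mean, sd)` value.

**What the generators do not emulate:** docking physics (scores are
statistical stand-ins), structured descriptor correlation beyond the
low-rank-plus-noise model, heteroscedastic or systematic MD noise, and
non-binary amendment dosing. Passing tests demonstrate the statistical
machinery, not the chemistry.

## Numerical and design choices

- Rounding everywhere follows the printed-table convention: half-up, 2
  decimals for percentages, 3 for energies; tests compare at ±0.01.
- Typographic minus signs (U+2212) are normalised on CSV read; writers emit
  ASCII. Data outputs are written atomically and are byte-identical across
  reruns.
- Problem sizes in the test suite and the acceptance script are desk-scale
  (seconds): 200 permutation seeds, 50 recovery seeds, 100 factorial-recovery
  seeds, 500 energy records.

## Known limitations

- The argmax-LOO-q2 component selection rule is noisy at small sample sizes:
  at the study-scale default (30 samples) it overshoots the true latent
  count in roughly 15% of seeds, selecting one extra component on q2 margins
  of ~1e-3. The latent-count recovery property is therefore demonstrated at
  100 samples (49/50 seeds); at 30 samples users should treat `n_opt` as an
  upper bound and inspect the full q2 curve.
- The composite reference table and the published CoMFA q2/r2 values are not
  reproducible from published inputs (see above); both are handled as
  diagnostics or fixed-input arithmetic, never as fit targets.
- The field module reconstructs a CoMFA-family descriptor engine; absolute
  energy values depend on probe/dielectric conventions and should only be
  compared within a consistent configuration.
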