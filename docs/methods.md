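# Methods

## The problem

Two lines divergently selected from one base population for intramuscular
fat (IMF, g/100 g fresh muscle) are profiled by untargeted LC-MS/MS in
four acquisition blocks (positive-early, positive-late, negative, polar).
The goal is to identify metabolites whose plasma abundance differs
between the lines — i.e. a correlated metabolomic response to selection —
and to quantify each difference with a posterior distribution. Because
both line membership (categorical) and IMF (continuous) carry the
selection signal, the design uses two parallel multivariate analyses and
keeps only metabolites confirmed by both.

## Synthetic panel generator

The generator (`synth`) emulates the statistical structure the analysis
assumes, not mass spectra: no retention times, adducts or batch drift are
simulated, and metabolites are independent by default (an optional
low-rank latent-factor knob induces correlation; it is an assumption, as
real acquisition data carry unknown correlation structure).

* Log-abundances are Gaussian per metabolite, log-mean ~ N(12, 2) and
  log-SD ~ U(0.2, 0.8) — arbitrary intensity units spanning the dynamic
  range typical of area-under-curve peak quantification.
* A fraction `frac_affected` (default 0.35, matching the observed ~322 of
  920) of metabolites receives a between-line log-mean shift of
  `effect × σ_j` with |effect| ~ U(0.23, 6.04) SD and random sign, split
  ±effect/2 around the grand mean. Effects are planted on the log scale
  because the alr operates there, making SD-unit recovery well defined.
* Zeros (non-detections) are Bernoulli per cell with a per-metabolite,
  per-line rate ~ U(0, 0.15); this is missingness-mechanism-agnostic
  (random, not intensity-dependent), a deliberate simplification — the
  true mechanism in LC-MS data is partly left-censoring. The default
  range removes roughly 5–10% of metabolites at the 10% filter,
  mirroring the observed 997 → 920 attrition.
* IMF = `imf_base + 1{H}·imf_line_gap + N(0, imf_noise_sd)` with defaults
  0.84 + 0.45 and noise SD 0.145 g/100 g (a 0.45 gap ≈ 3.1 trait SD).
  The IMF–metabolite coupling arises through the shared line effect, as
  in the real design; no direct metabolite→IMF term is added.
* Block sizes default to 242/168/399/111. Sample IDs are sex-balanced
  (12 M + 12 F per line at the default n=24).
* One master seed is split via `numpy.random.SeedSequence.spawn` into
  independent streams (structure, abundances, zeros, IMF), so stages are
  individually re-runnable and generation is bit-reproducible.

Consequently, passing tests demonstrate correctness of the statistical
machinery under the assumed generative model; they do not certify
behaviour under correlated metabolites, intensity-dependent missingness
or batch effects.

## Preprocessing

Filtering keeps a metabolite iff its zero fraction is **strictly** below
10% in at least one line ("less than 10%" read as `<`; at 24/line this
admits up to 2 zeros). Zeros in kept metabolites are treated as missing —
not as true zeros — and imputed by iterative random-forest regression
(missForest): column-median initialization, columns cycled in
increasing-missingness order, 100 trees per forest by default, stopping
when the normalized squared change of the imputed cells increases
(returning the previous iterate) or after `max_iter = 10` sweeps (with a
warning). Imputed values are floored at half the column's minimum
observed value: the log-ratio step requires strict positivity, and half
the minimum is the conventional detection-limit surrogate.

## alr reference selection

The reference-choice criteria are (1) reproduce the geometry of the full
set of pairwise log-ratios, and (2) have low log variance. They are
combined as: screen candidates at the panel's median log variance
(quantile configurable), then maximize the Procrustes correlation among
survivors; ties break toward lower variance, then lexicographic ID. This
combination rule is the package's own deterministic choice — the two
criteria admit other weightings.

The full-geometry configuration is realized as the clr configuration:
the complete pairwise-log-ratio matrix spans the same sample geometry up
to rotation and a √J scale, to which the Procrustes correlation is
invariant (the equivalence is asserted against an explicit J(J−1)/2
brute force in the tests). The Procrustes correlation itself is computed
as the nuclear norm of the cross-product of the two column-centred
principal-coordinate score matrices, normalized by the geometric mean of
total variances — the standard statistic of Procrustes-rotation tests.
Selection runs per acquisition block (one reference consumed per block).

## PLS core

NIPALS PLS1 with X-deflation (chosen over SIMPLS for transparency; for
PLS1 they coincide in the fitted subspace). The coefficient path `B_a`
for every truncation a = 1..A comes from one fit, which the inner CV
exploits. PLS-DA codes the two classes 0/1 in sorted label order and
classifies at ŷ ≥ 0.5 → code 1; all reported quantities are invariant to
the coding direction. VIP uses the standard weight formulation with
per-component explained y-variance; mean(VIP²) = 1 identically.
Coefficient CIs are Martens-jackknife: segment-wise refits on the inner-CV
partition, variance `(m−1)/m Σ(b_(i) − b)²`, symmetric t-interval with
m−1 df. Q² = 1 − PRESS/TSS with TSS around the *training* mean.

Numerical notes: component extraction stops early (without error) if the
X-residual becomes orthogonal to y; zero-variance response raises;
requested components beyond the rank bound raise.

## CMV

Defaults: 8 outer folds × 20 iterations (160 models/mode), 7-fold inner
CV, VIP ≥ 0.8, 95% CI excluding 0, consensus at tally **strictly**
greater than 0.8 × 160 = 128 in both modes independently.

* Outer folds are stratified by line (3 H + 3 L per fold of 6 at n=48),
  dealing shuffled line members round-robin; in regression mode a
  `strata` vector (typically line) may be supplied.
* The component count (capped at 10) is the smallest whose inner-CV mean
  error (MSEP or misclassification rate) is within one standard error of
  the best — the component-selection rule is the package's choice.
* After variable selection the reduced model re-runs the inner CV to
  re-pick its component count before predicting the test fold.
* Empty selections are retained as models (counting toward n_models) but
  contribute nothing to the tally; such a model predicts the training
  mean (≡ majority/tie in discriminant mode).
* The Q² < 0.4 exclusion applies to regression (PLS) models only; excluded
  models still count toward the 160, so the consensus cut stays at 128.
* Standardization is one global pass over the joined dataset by default
  (matching the modelling convention of standardizing once before CMV); a
  leakage-safe per-training-fold option (`fold_standardize`) exists but
  is off by default for fidelity to that convention.
* The permutation test draws a fresh uniform permutation of the response
  and reruns the identical CMV. `n_permutations` defaults to 1; ≥ 20 is
  recommended (and used by the acceptance script) for a calibrated null,
  since a single permutation's pooled misclassification has an SD of
  roughly 7 percentage points at the reduced problem size.

## Bayesian stage

Per selected metabolite, the alr value (un-standardized, so effects stay
on the interpretable log-ratio scale) is modelled as y = Xb + e with
intercept, line and sex fixed effects and e ~ N(0, Iσ²). Line is coded
H = +1/2, L = −1/2 (sex M/F likewise), so the line coefficient *is* the
phenotypic H−L difference. Flat priors are implemented as improper flat
priors (posterior proper for n > p); the conjugate full conditionals are
b | σ² ~ N(b_OLS, σ²(XᵀX)⁻¹) and σ² | b ~ SSR(b)/χ²_n.

Chain defaults: 50,000 draws, 10,000 burn-in, no thinning; a Geweke
first-10%-vs-last-50% z-check warns (never fails) at |z| > 3. This
conditional sampler mixes essentially immediately, so the reduced chains
used in tests and examples (2,000–4,000 draws) are adequate there.

Summaries: posterior median D_H-L; shortest-interval HPD95% (never wider
than the equal-tailed interval); P0 = posterior mass on the median's side
of zero (≥ 0.5 by construction); SD-unit difference = median divided by
the pooled across-line sample SD of the same trait (the "metabolite SD"
standardization is the pooled within-line SD — a deliberate choice, as a
total SD would be inflated by the line difference itself).

## Problem sizes in the shipped checks

The test suite and acceptance script use reduced problem sizes chosen as
the smallest that leave the statistical conclusions stable: 160-model
structural checks run on 12-metabolite panels; the permutation-null
calibration uses a 200-metabolite panel (block sizes 52/36/87/25 scaled
from the defaults), 5 CMV iterations, and averages 10–20 permutations;
HPD coverage uses 100 replicates of 5 planted effects at n = 24/line
with 3,000-draw chains. Full-scale runs (920 metabolites, 20 iterations,
50,000 draws) use the same code paths via the defaults.

## Known limitations

* Independent-metabolite default in the generator; real panels are
  strongly correlated within lipid classes.
* Random (not intensity-dependent) missingness; imputation quality under
  left-censoring is not benchmarked.
* Jackknife CIs are approximate; under pure noise the realized
  false-exclusion rate is near, but slightly below, the nominal 5%.
* The consensus rule inherits the discreteness of the 160-model tally;
  with few iterations the 80% cut is coarse.
* Single-response PLS only; multi-trait extensions are out of scope, as
  are pathway annotation and anything upstream of the intensity table
  (peak picking, QC, identification).
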