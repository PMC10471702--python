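# metabodiverge

Detecting genetically driven differential metabolite abundance between two
divergently selected lines, from raw untargeted LC-MS intensity tables to
per-metabolite Bayesian effect estimates.

The motivating design is a divergent selection experiment: two lines bred
from one base population for high (H) and low (L) intramuscular fat (IMF)
content, reared and fed identically, so between-line differences in the
plasma metabolome reflect genetic change. The package implements the full
statistical chain for such an experiment and ships a synthetic-data module
that emulates its structure (4 acquisition blocks, ~900–1000 metabolites,
24 + 24 sex-balanced samples, zero inflation, planted effects of
0.23–6.04 SD), so every stage is testable without any proprietary data.

## The method

1. **Zero filtering** — a metabolite is kept iff it has strictly fewer
   than 10% zeros (non-detections) in at least one line.
2. **Random-forest imputation** — remaining zeros are treated as missing
   and imputed missForest-style: columns cycled in increasing-missingness
   order, each regressed on all others with a random forest, stopping when
   the change in imputed values rises.
3. **Compositional transformation** — untargeted intensities are relative,
   so each block is additive-log-ratio transformed,
   `alr_j = ln(x_j) − ln(x_ref)`, with the reference chosen per block as
   the low-variance metabolite whose alr geometry best reproduces the full
   pairwise-log-ratio geometry (Procrustes correlation). Blocks are then
   joined and standardized once.
4. **Cross model validation (CMV)** — nested CV around PLS-DA (line as the
   response) and PLS (IMF as the response): 8-fold outer CV × 20
   iterations = 160 models per mode; a 7-fold inner CV inside each training
   partition picks the component count and supplies Martens-jackknife
   segments; variables with VIP ≥ 0.8 **and** a 95% coefficient CI
   excluding 0 are selected, the reduced model refit and scored on the
   held-out fold (pooled misclassification for PLS-DA, Q² = 1 − PRESS/TSS
   for PLS; PLS models with test Q² < 0.4 are dropped from the tally). A
   permutation of the response through the identical CMV calibrates the
   null.
5. **Consensus** — metabolites selected in more than 80% of the models of
   *both* analyses (tally > 128 of 160 in each) form the consensus set:
   differential between lines *and* linearly related to the phenotype.
6. **Bayesian estimation** — each consensus metabolite's alr value is
   modelled as `y = Xb + e` with line and sex fixed effects and flat
   priors; Gibbs sampling yields the posterior of the H−L difference
   D_H-L, its shortest 95% HPD interval, the sign-consistency probability
   P0 ∈ [0.5, 1], and the difference in units of the metabolite's pooled
   within-line SD.

The PLS/PLS-DA core (NIPALS, VIP, jackknife CIs, Q²) and the Gibbs sampler
are implemented from scratch and verified against closed-form oracles
(OLS at full rank, the analytic flat-prior Student-t posterior, literal
formula reimplementations) in the test suite.

## Worked example

```python
import numpy as np
from metabodiverge import (SynthConfig, generate_panel, PipelineConfig,
                           CmvConfig, run_pipeline, misclassification_table)

panel = generate_panel(SynthConfig(
    n_per_line=24, n_metabolites_per_block=(16, 12, 18, 10),
    frac_affected=0.30, effect_size_range=(1.5, 6.04), seed=99))
config = PipelineConfig(cmv=CmvConfig(iterations=5, max_components=3),
                        impute_trees=20, mcmc_draws=4000,
                        mcmc_burn_in=500, seed=17)
run = run_pipeline(panel, config)
print(misclassification_table(run.cmv_da).round(1))
print(run.posterior.round(3).head())
```

Output:

```
       H      L
H  100.0    0.0
L    0.0  100.0
               d_hl_median  hpd95_low  hpd95_high   p0     sd  d_sd_units
metabolite_id
PE_0003             -3.639     -4.119      -3.194  1.0  0.797      -4.564
PE_0011             -2.481     -2.887      -2.048  1.0  0.740      -3.351
PE_0012             -1.083     -1.363      -0.818  1.0  0.458      -2.366
PE_0014              0.921      0.648       1.175  1.0  0.445       2.069
PE_0016              3.182      2.829       3.553  1.0  0.635       5.010
```

The misclassification table pools the held-out predictions of all 40
PLS-DA models (rows = true line, %, rows sum to 100): the planted signal
separates the lines perfectly, while the same CMV on permuted labels
classifies near chance (53/56% correct) and the permuted-label PLS mean
Q² drops to −0.02 against 0.75 with true labels. The posterior table
lists, per consensus metabolite, the median H−L difference on the
log-ratio scale, its 95% HPD interval, the probability the difference
has the sign of its median, and the difference in SD units — here the
recovered effects (2.1–5.0 SD) match the planted range.

The same stages are scriptable from the shell:

```bash
metabodiverge synth --seed 3 --out panel/
metabodiverge run --panel panel/ --config config.yaml --out results/
```

(`metabodiverge preprocess / cmv / bayes` run individual stages.)

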