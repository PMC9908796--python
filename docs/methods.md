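# Methods

## Data model

The unit of analysis is the *cell*: one line in one environment, where an
environment is a location × year × season combination. Adjusted phenotypes
(stage-1 BLUPs, or raw values for unreplicated trials) populate a sparse
line × environment grid; unobserved cells are prediction targets. Cells are
ordered environment-major throughout, so every kernel is a Kronecker
product and its block structure is directly inspectable:
`K_g = J_E ⊗ G`, `K_e = I_E ⊗ J_L`, `K_w = Ω ⊗ J_L`, `K_ge = I_E ⊗ G`,
`K_gw = Ω ⊗ G` (J = all-ones). The two interaction kernels are the
Hadamard products of their main-effect parents and are PSD by the Schur
product theorem (checked numerically on every build).

## Stage-1 trial model

Each trial is analysed as `y = Xb + Zu + e` with replicates fixed,
genotypes random `u ~ N(0, σ²g I)` and i.i.d. residuals. REML profiles the
ratio γ = σ²g/σ²e: the restricted log-likelihood at fixed γ has a closed
form, maximised on a log-γ grid (33 points on [−8, 8]) and refined with
bounded scalar minimisation (xatol 1e−8). Spatial (AR1 ⊗ AR1) residual
models are deliberately out of scope: the downstream analysis consumes only
adjusted phenotypes, which may also be loaded directly from file.
Unreplicated trials cannot separate σ²g from σ²e; their centred raw values
pass through and H² is reported undefined — the standard practice for such
designs. A balanced-RCBD closed-form shrinkage oracle and a brute-force
grid maximisation back the implementation in the tests.

## Environmental covariates

Daily weather (TMIN, TMAX, TM, DPT, RH, PP, APAR, CPAR) is augmented with
TR = TMAX − TMIN; VPD = (es(TMIN)+es(TMAX))/2 − es(DPT) with the Tetens
curve es(T) = 0.61078·exp(17.27 T/(T+237.3)) kPa, floored at 0; and
Hargreaves–Samani PET = 0.0023 (TM+17.8) √TR · Ra/λ with FAO-56
extraterrestrial radiation Ra(latitude, day of year) and λ = 2.45 MJ kg⁻¹,
floored at 0. These formulas are fixed in-package so no external download
or weather service is needed; they follow the conventions of the standard
agro-meteorological toolchains, so results can be cross-checked against
them.

Phenology windows per environment derive from flowering data: vegetative =
transplanting → earliest flowering, reproductive = earliest → latest
flowering (inclusive), ripening = after latest flowering → harvest.
Days-to-flowering counts from seeding. Degenerate zero-length windows are
widened to one day with a warning. Each of the 8 covariates is averaged
(not summed — window lengths differ between environments and columns are
standardised afterwards, so sums would only rescale) within each window:
24 ECs per environment. The whole-season window spans transplanting →
harvest; whether a seeding-based span would be preferable is ambiguous in
practice, and transplanting → harvest is adopted because that is the span
the daily record covers.

Columns are z-scored across environments (n−1 denominator; constant
columns dropped with a warning) giving W, and the environmental kernel is
Ω = WW′/q. Dividing the "proportional to WW′" kernel by the number of
covariate columns q keeps diag(Ω) near 1, on the same scale as the GRM, so
variance components of w/gw terms are comparable with g/e terms.

## Genotypes

Markers are filtered jointly on statistics computed once (missingness
> 0.20, MAF < 0.05, heterozygosity > 0.10, strict inequalities): a single
pass is reproducible, whereas sequential filtering would let earlier
removals shift later statistics. The panel-major allele defines the 0
state; orientation cannot leak downstream because the GRM of the centred
standardised matrix is invariant to it (tested algebraically). Missing
genotypes are mean-imputed per marker before centring; standardisation
uses the sample (n−1) standard deviation for bit-reproducibility.
G = XX′/p.

## The multi-kernel sampler

The model over cells is `y = μ1 + Σ_k u_k + ε`, `u_k ~ N(0, σ²_k K_k)`,
`ε ~ N(0, σ²_ε I)`. Each kernel is eigendecomposed once (eigenvalues below
1e−8 of the largest truncated — K_e and Ω are low-rank by construction)
and u_k is sampled in its eigenbasis, where the full conditional is
Gaussian with diagonal precision: O(n·rank) per kernel per iteration.
Masked cells are treated as missing data and sampled each iteration
(data augmentation), so a fully unobserved environment receives
predictions through exactly those kernels that link it to training cells
(K_g always; K_w/K_gw through Ω; K_e/K_ge contribute zero — see below).

Priors: scaled-inverse-χ² on every variance, default df 5, scale set so
the prior *mode* splits the sample phenotypic variance equally between the
random terms and the residual. This mirrors the documented defaults of the
standard Bayesian whole-genome regression software for this model class,
keeping results comparable with analyses run there. μ has a flat prior.
Default chain: 25,000 iterations, 5,000 burn-in, thinning 10 — common
practice for this model family. Doubling the chain length moves posterior
mean predictions by well under 1 % of the phenotype scale (tested), so the
test suite runs chains of 1,000–6,000 iterations. Seeds are explicit
inputs recorded in the results object; effective sample sizes
(initial-positive-sequence estimator) are reported per variance and an ESS
below 50 raises a diagnostic warning.

A closed-form companion, `mme_predict`, solves the mixed-model (GLS)
equations for known variance components and returns per-term
contributions. It is the deterministic oracle for the sampler (with all
variances fixed, the sampler's posterior-mean prediction converges to it;
verified to ±0.02 over three seed-averaged 20,000-iteration chains on a
20-cell instance) and makes structural arguments exact: for a fully
unobserved environment the K_ge (and K_e) conditional-mean contribution is
*identically zero*, because those kernels connect only same-environment
cells. This is the mechanism behind the empirical finding that interaction
models do not beat main-effect models for untested environments: whatever
σ²_ge is estimated, none of it transfers.

## Cross-validation designs

All four designs audit against leakage by construction: the target's cells
are masked before the fit, and each result row records the training
environments. Per-run seeds derive deterministically from the master seed
and the target/replicate/model labels, so any single run can be reproduced
in isolation. CV-RAN samples 4 training environments per target (50
replicates by default); CV-SEL takes the 4 nearest by Euclidean distance
on standardised ECs (ties broken lexicographically), one run per target as
there is nothing to replicate; CV-LOEO trains on all remaining
environments. Leave-one-line-out masks one fully observed line everywhere;
per-environment ability is computed across the assembled left-out
predictions of all lines, not per fit. Predictive ability is the Pearson
correlation in the validation set, sign preserved; fewer than 3 pairs or a
constant vector yields NaN with a warning. Model comparison operates on
Fisher-z transformed abilities (|r| ≥ 1 clamped at 1 − 1e−6): one-way
ANOVA, Tukey HSD at α = 0.05, and an insert-and-absorb compact letter
display; means are back-transformed to r.

## Synthetic data: what it emulates and what it does not

The generator draws biallelic genotypes for an inbred panel (MAF uniform
on a configurable band, 2 % heterozygosity, monomorphic columns redrawn),
ECs from a multivariate normal with exchangeable correlation (default
0.3), an unbalanced allocation mask (per-environment counts uniform on a
range, default 35–100 % of the panel, with a 30 % core observed
everywhere), and phenotypes from
`y_ij = μ + g_i + e_j + w_ij + ge_ij + gw_ij + ε_ij` with:

* g from marker effects on the centred standardised genotypes;
* e linear in the ECs plus noise (configurable noise share; share 1 means
  pure i.i.d. effects) — so EC distance predicts environmental similarity,
  the assumption EC-guided training-set selection exploits;
* w = Wγ, environment-level with covariance exactly Ω;
* ge i.i.d. line × environment — deliberately *non-transferable*, matching
  the K_ge model class;
* gw = X A W′/√(pq), marker × EC interaction with cell covariance exactly
  G ⊗ Ω — transferable through Ω.

Each component is rescaled so its realised variance over observed cells
hits the target exactly, which pins the ground truth for recovery tests.
Default variance targets (g 1.0, e 2.0, w 0.5, ge 0.3, gw 0.3, ε 0.5) put
the environment main effect above the genetic variance, as multi-
environment yield trials typically show. Default sizes (150 lines, 500
markers, 10 environments, 8 ECs) keep full-suite runs to minutes on one
CPU. The generator does not emulate linkage disequilibrium, pedigree
structure, population stratification, selection over cycles, or spatial
field trends — so passing tests demonstrate correctness of the estimators
under the model's own assumptions, not robustness to those real-data
features.

## Reference computations and their problem sizes

`envgblup.benchmarks` fixes the study conditions for the quantitative
checks shared by the tests and `scripts/acceptance.py`:

* *Sampler vs closed form*: 20-cell instance, GE-GxE kernels, known
  variances, three 20,000-iteration chains averaged.
* *Variance recovery*: GEW regime (g/e/w/ε all 1.0, e i.i.d., interactions
  off), 200 lines × 300 markers × 10 environments, fully observed, five
  seeds, 3,000-iteration chains. σ²_g and σ²_ε recover within a few
  percent. σ²_e and σ²_w do **not** recover within 30 %: each rests on
  only 10 environment-level observations, and the df-5 equal-split prior —
  whose mean is 2.33× its mode — dominates such a weak likelihood, pulling
  posterior means up by roughly 40–90 %. This is a property of the
  estimator under its documented prior at this design size (it persists on
  data drawn exactly from the model and with 5× longer chains), not a
  sampler defect; with more environments, or reported as posterior
  medians, the inflation shrinks. Users comparing environment-level
  variance components across traits should read them as prior-regularised
  quantities, not unbiased point estimates.
* *CV scheme comparison*: 60 lines × 10 environments, sparse mask,
  environment variance 3× genetic, transferable gw 0.8, GW-GxW model for
  the scheme contrast (training-set composition can only matter through
  Ω), 8 CV-RAN replicates, 2,000-iteration chains. Reproduces the expected
  ordering LOEO ≥ SEL ≥ RAN and GE > G under dominant environment
  variance.

## Known limitations

* Single-trait analysis only; no factor-analytic or multi-trait G×E
  models, no alternative (Gaussian/deep) kernels.
* Stage 1 ignores spatial field structure; heritabilities from
  row-column-designed trials will differ from a spatial analysis.
* Bootstrap support values for dendrograms are not computed; cluster trees
  are topology-and-height only.
* The Fisher-z ANOVA requires replicated abilities; single-run schemes
  (CV-SEL, CV-LOEO) can be summarised but not letter-grouped.
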