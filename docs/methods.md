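# Methods

`ancestrx` estimates each subject's genome-wide ancestral background from SNP
genotypes and asks how much of the variation in drug response that background
predicts — both in absolute terms and relative to self-reported ethnicity —
and finally compresses each ancestral dimension into a small weighted SNP
panel that could run on an inexpensive array. This note records the models,
the defaults and why they were chosen, what the synthetic data do and do not
emulate, and the numerical conventions that make results reproducible.

## Ancestry estimation

**Subject QC.** Subjects are dropped when their genotype call rate falls
below `min_call_rate` (default 0.99) or their heterozygosity rate (fraction
of non-missing calls that are heterozygous) lies outside the sample mean
± `het_sd` standard deviations (default 3, the conventional GWAS screen).
The heterozygosity statistics are computed over all subjects before any
removal; both filters are applied jointly in one pass.

**IBS similarity.** For subjects *i, j* and SNP *m* with minor-allele
dosages *g ∈ {0,1,2}*, the shared fraction is (2 − |g_im − g_jm|)/2; the
similarity s_ij is its mean over SNPs non-missing in both subjects
(pairwise-complete, no imputation). The computation is expressed as three
indicator-matrix products, so a 1000×10000 panel takes seconds. s_ij is
invariant to recoding any SNP as g → 2−g for all subjects, which is why the
choice of counted allele (sample minor allele, frequency ties broken to the
alphabetically first allele) affects only serialization, not inference.

**Classical MDS.** The squared-distance matrix is taken as D²_ij = 1 − s_ij
and double-centered, B = −½ J D² J. Because D² is affine in S, B = ½ J S J,
so the scores (top-d eigenvectors of B scaled by √eigenvalue) coincide up to
scale with principal components of the centered similarity matrix — the
standard equivalence between IBS-based MDS and PCA of genotype similarity.
`d` defaults to 5 dimensions, mirroring the convention that the first five
axes capture the vast majority of ancestral variation in large cohorts;
the fraction of positive eigenvalue mass per dimension is reported so users
can judge this for their data. Eigenvector signs are arbitrary; each
dimension is deterministically flipped so the subject with the largest
absolute score is positive, which makes loadings and proxy weights
reproducible run-to-run.

**Loadings.** The loading of SNP *m* on dimension *k* is the Pearson
correlation between dosage and score over pairwise-complete cases.
Monomorphic SNPs get loading 0 with a logged warning rather than an error,
since genome-wide panels routinely contain them.

## Treatment-effect extraction

Per drug–outcome combination, outcomes over time are modelled as

    y_it = α + f(t)·β + b_0i + b_1i·f(t) + Σ_c γ_c x_ic + ε_it,

with subject random intercept b_0i and random slope b_1i (full 2×2
covariance Ψ), residual variance σ²_e, and f(t) one of t, t², log(1+t) —
three shapes spanning the monotone-accelerating, monotone-decelerating and
straight-line response profiles typical of symptom scores. Selection among
forms and forward selection of covariates both minimize BIC from maximum-
likelihood fits (REML likelihoods are not comparable across different
fixed-effect designs); the final model is refit by REML. Ties in form
selection resolve to linear, and data with no within-subject variation
return linear outright, since every transform then fits identically.
Subjects with fewer than two observations are excluded and logged.

The per-subject treatment effect is f(T_end)·(β̂ + b̂_1i), the modelled
outcome change from baseline to the last scheduled visit T_end, where b̂_1i
is the empirical-Bayes conditional mean

    b̂_i = Ψ Zᵢ' (Zᵢ Ψ Zᵢ' + σ²_e I)⁻¹ (y_i − X_i β̂),

computed explicitly from the REML variance components (statsmodels MixedLM
supplies the components; its own `random_effects` output is used as an
independent cross-check in the tests, not as the implementation). In the
random-intercept-only case this reduces to the familiar scalar shrinkage
σ²_b/(σ²_b + σ²_e/n_i) of the subject's raw mean deviation, and with no
residual noise the BLUP slope equals the subject's own least-squares slope.
Condensing whole trajectories this way is more precise than post-minus-pre
differencing and shrinks poorly observed subjects toward the population
mean instead of letting them dominate.

## Association and model comparison

Treatment effects are regressed (OLS with intercept, listwise-complete
cases) on four predictor sets: M1 = 5 MDS + 3 ethnicity indicators,
M2 = 5 MDS, M3 = 3 ethnicity, M4 = the 3 MDS dimensions most aligned with
ethnicity + 3 ethnicity. Ethnicity enters as three 0/1 indicators with the
intercept retained, leaving an implicit "other" reference category.
"Aligned" means the dimensions with the highest R² when regressed on the
ethnicity indicators, so the two dimensions M4 drops are the cryptic axes
that self-report does not capture. All four models for a combination are
fit on the identical (maximal common) complete-case set — without this the
Δ-correlation comparisons would mix case sets and be incoherent. Model fit
is summarized by the multiple correlation R and the overall F-test; nested
comparisons use the partial F on ΔR². Combinations with fewer than `min_n`
(default 20) complete cases, or with a degenerate predictor column in the
case subset, are marked skipped in the output rather than silently dropped.

## Family-wise inference

Given the model-fit p-values of a family of combinations:

- **λ** maps each p back to a χ²₁ statistic by its upper-tail quantile and
  divides the median by the null χ²₁ median (≈0.45494). The χ²₁ scale makes
  medians comparable when the underlying F statistics carry heterogeneous
  degrees of freedom across combinations. Non-positive p-values are clamped
  to the smallest positive float with a warning.
- **QQ bands** use the Beta(i, m−i+1) distribution of uniform order
  statistics (pointwise 95%), reported on the −log10 scale. Note that the
  fraction of points inside pointwise bands is heavy-tailed downward for a
  single family — order statistics leave the band in stretches — so only
  its mean across families sits at ~95%.
- **Wilcoxon** is the one-sample signed-rank test that p-values sit below
  0.5 (one-sided), exact for m ≤ 25 without ties, normal approximation with
  tie correction otherwise; a −log10-scale variant is available by flag.
- **FDR**: Benjamini–Hochberg step-up q-values, and Storey q-values with
  π̂₀ = #{p > 0.5}/(m/2) capped at 1 (tuning constant fixed at 0.5), so
  Storey q ≤ BH q always.
- **Proportion test**: z = (x/n − p₀)/√(p₀(1−p₀)/n) without continuity
  correction, statistic z², one-sided upper p — the convention that exactly
  reproduces published marginal-effect worked examples to three decimals.

## Proxy panels

Markers are LD-pruned by a greedy sliding window (defaults: window 50 SNPs,
step 5, r²_max 0.1; correlations on mean-imputed dosages): within a window,
while any retained pair exceeds r²_max, the later-positioned SNP of the
worst pair is removed. The rule is deterministic and idempotent. Per
dimension, the `k_panel` (default 700) pruned SNPs with the largest
|loading| enter a single multiple regression of the dimension's scores on
their dosages; the coefficients are the scoring weights. Missing calls are
mean-imputed from training means both in fitting and scoring, which keeps
scores linear and lets an entirely missing subject score at the training
centroid. Scoring new genotypes requires ≥80% marker overlap per dimension.
Training R² is reported per dimension; because SNP selection and weighting
reuse the same subjects the training figure overstates held-out accuracy —
overfitting is reported (train vs held-out), not corrected, and penalized
selection is deliberately out of scope.

## Synthetic data

The generator exists so the full pipeline is testable without
controlled-access trial data. Genotypes: per SNP an ancestral frequency
p ~ Uniform(0.1, 0.9) and Balding–Nichols population frequencies
p_j ~ Beta(p(1−F)/F, (1−p)(1−F)/F) (mean p, variance F·p(1−p)); subjects
mix K populations with Dirichlet(α) proportions Q_i and draw dosages
Binomial(2, Q_i·p). Defaults: K = 3, F = 0.1 (continental-scale
divergence), symmetric α = 1. SNPs are independent given population
frequencies — no linkage disequilibrium along chromosomes — so LD pruning
on synthetic data mostly verifies the pruning rule itself rather than
realistic LD structure.

Trials: y_i(t) = α + t(β_drug + γ'Q_i + b_i) + a_i + c'x_i + ε, with random
slope SD σ_b = 0.3, random intercept SD σ_a = 0.5, residual SD σ_e = 1,
five scheduled visits (baseline + 4) and MCAR dropout of follow-ups at rate
0.15 — yielding ~4.4 observations per subject, in the range reported for
the large psychiatric effectiveness trials this emulates. γ is the
ancestry effect on the response slope; γ = 0 gives exact nulls.
Self-reported ethnicity is the arg-max of Q_i with a misclassification
knob, plus a 5% "other/unreported" rate. The "other" group is what keeps
the three indicators linearly independent of the intercept; it also plays
the role of the reference category real questionnaires have. Dropout is
missing-completely-at-random by design: the sequential switch-on-nonresponse
logic of real effectiveness trials is out of scope and would confound the
desk-scale calibration experiments.

What passing tests therefore show: the estimators are correct and calibrated
under an admixed, linear-response, MCAR world. What they do not show:
robustness to LD, to informative dropout, to treatment switching, or to
non-Gaussian outcomes.

## Calibration experiments and problem sizes

The null-calibration suite simulates one 40-subject genotyped cohort and
2400 independent γ = 0 drug–outcome families (4 balanced visits each), runs
the full BLUP → regression pipeline per family, and checks λ ∈ [0.9, 1.1],
~95% mean QQ-band coverage, and KS-uniformity of the model-fit and
signed-rank p-values. Balanced (no-dropout) families are used because that
is the setting in which the OLS F-test null is exact: under MCAR dropout the
BLUP effects become a variance mixture across subjects, and at 40 subjects
per family this heavier-tailed null measurably inflates λ (≈1.12 in a
2400-family experiment) even though the implementation is correct — the
effect shrinks with subjects per family and is negligible at the hundreds-
of-subjects scale of real trials. A separate test keeps λ under default
dropout within the looser [0.8, 1.25] band. Signal-recovery tests use
200-subject cohorts over 12 seeds. The proxy-compression experiment uses
1000 subjects × 10000 SNPs with k_panel = 700; with K = 3 the admixture
carries only K−1 = 2 degrees of freedom, so dimensions 3–5 there are
eigen-noise axes that plateau near 96–97% training R² while the
ancestry-bearing dimensions exceed 99% — reconstructing all five dimensions
above 99% requires data in which all five axes carry genuine structure.

## Numerical conventions

- Missing dosage sentinel −1; dosages int8; similarity accumulations exact
  in float32 (integer counts below 2²⁴), symmetrized and diagonal pinned
  to 1.
- MDS refuses d beyond the count of positive eigenvalues (tolerance
  n·ε·max(|λ|, 1)).
- BIC tie tolerance 1e−6; candidate forms are tried in the canonical order
  linear, quadratic, log so ties resolve deterministically.
- Forward selection skips candidates whose design condition number exceeds
  1e8; rank-deficient proxy designs drop collinear SNPs lowest-|loading|
  first.
- All generators are seeded `numpy.random.default_rng`; fixing the seed
  fixes every output bit-for-bit.
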