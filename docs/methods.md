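# Methods

This note documents the statistical models implemented in `dxmeta`, the
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerical details a user re-deriving results will need.

## Study rows and 2×2 reconstruction

The analysis unit is one *study row*: one lncRNA evaluated in one sample
type within one publication.  A publication may contribute several rows, so
row identifiers are row-unique (author + year + gene + specimen).

Source tables print SEN, SPE and the two arm sizes but not the cells, so the
2×2 table is reconstructed as TP = round(SEN·n₁) (nearest integer, ties away
from zero), FN = n₁ − TP, TN = round(SPE·n₀), FP = n₀ − TN.  The round-trip
invariant |TP/n₁ − SEN| ≤ 0.5/n₁ (and the SPE analogue) is enforced on every
reconstruction.  When SEN or SPE is printed to four decimals this pins the
cells uniquely; at two decimals several integer tables are compatible with
the printed value, so statistics that depend on the exact cells (Cochran's Q,
meta-regression coefficients) carry an irreducible transcription uncertainty
of a few tenths of a percent.  Tables containing a zero cell receive the
Haldane–Anscombe correction (+0.5 to all four cells) before any log or logit
transform.

## Univariate pooling and heterogeneity

Each index is pooled by inverse-variance weighting on its natural modelling
scale — logit for SEN/SPE (variance 1/TP + 1/FN, resp. 1/TN + 1/FP), log for
PLR/NLR (delta-method variances) and for DOR (variance = sum of reciprocal
cells).  Cochran's Q is computed under the fixed-effect model;
I² = max(0, (Q − df)/Q)·100.  Random effects (DerSimonian–Laird τ²) are used
whenever I² ≥ 50% or the Q-test p ≤ 0.05, the conventional switch rule; the
caller can force either model.  The univariate engine exists because the
bivariate model has no per-index Q; both engines run on every analysis.

## Bivariate random-effects model

The headline pooled values come from the bivariate logit model

  TPᵢ ~ Bin(n₁ᵢ, senᵢ), TNᵢ ~ Bin(n₀ᵢ, speᵢ),
  (logit senᵢ, logit speᵢ) ~ N(μ, Σ),

fitted by maximum likelihood.  The per-study integral over the bivariate
random effect uses **adaptive Gauss–Hermite quadrature**: the integrand is
re-centred at the posterior mode of the study's random effect (found by a
2-D Newton iteration, vectorised across studies) and scaled by the local
curvature; 7 nodes per dimension leave the packaged-data estimates stable to
< 1e-4 (checked against 21 nodes).  Optimisation is Nelder–Mead on
(μ₁, μ₂, Cholesky(Σ)) with log-likelihood tolerance 1e-8 and up to three
jittered restarts; a 1e-6 ridge on Σ keeps the deviance smooth as the
between-study variance approaches zero.  The covariance of μ̂ is the
corresponding block of the inverse numerical Hessian.

A **normal-approximation engine** (per-study logit proportions with plug-in
variances, REML or ML, μ profiled out by GLS) is provided for speed and for
cross-checking; it reproduces `metafor::rma.mv(struct="UN", method="REML")`
to ~6 decimals on test data.  The exact-binomial likelihood is the default
because the plug-in logit variances are biased for small or extreme studies;
on real data this shows up as a visibly lower pooled specificity and DOR
from the normal engine.  REML applies only to the normal engine — the
binomial GLMM has no residual-likelihood analogue here, so it is fitted by
ML.

Derived indices are plug-in values at μ̂ (PLR = sen/(1−spe) etc.) with
delta-method CIs on the log scale; the ln DOR gradient with respect to μ is
exactly (1, 1).  A seeded Monte-Carlo CI alternative is available for
comparison (`monte_carlo_summary`).

## Summary ROC and AUC

The bivariate fit implies a hierarchical summary ROC through the summary
point with logit-scale slope √(σ₁₁/σ₂₂) — the standard conversion between
the bivariate and hierarchical (accuracy/threshold) parameterisations, using
the between-study variance ratio.  If the specificity variance is zero the
slope is undefined and the symmetric (unit-slope) curve is used with a
warning.  AUC is the trapezoidal integral of TPR over the **full** FPR range
[0, 1] on a 2001-point logit-spaced grid closed with the exact endpoint
limits; restricting to the observed FPR range is deliberately not done, to
match how summary AUCs are conventionally reported for this model.

No closed form exists for SE(AUC) here, so it is estimated by seeded
parametric resampling: μ is redrawn from N(μ̂, V̂(μ̂)) (Σ, hence the slope,
held fixed; 2000 draws by default) and the AUC standard deviation across
draws is reported.

The classical linear-model SROC (D = a + bS, back-transformed to
TPR = expit(a/(1−b) + (1+b)/(1−b)·logit FPR)) is also implemented, with
inverse-variance weights on var(ln DOR) by default and an unweighted option.
On the packaged table the unweighted fit integrates to 0.79 and the weighted
one to 0.775, bracketing the bivariate value 0.791.  |b| ≥ 1 yields a
non-monotone back-transform; the curve is then integrated over its valid
range with a warning.

Subgroup AUC differences use the independent-samples Z-test with the
resampled SEs; the correlation induced by shared model structure is ignored,
matching the conventional report.

## Threshold effect, subgroups, meta-regression

The threshold test is Spearman's rank correlation between logit TPR and
logit FPR (average ranks for ties, two-sided p from the t approximation).
Positive correlation means studies trade sensitivity for specificity along a
common ROC — a cut-off artefact rather than real heterogeneity.

Subgroups (intergenic vs antisense location, circulating vs tissue sample,
total ≤200 vs >200, NOS quality <7 vs ≥7) re-run the full bivariate + SROC
pipeline per stratum.  "Circulating" means serum or plasma.  Rows outside a
binary contrast — gastric-juice rows for sample type; intronic, bidirectional
or unknown locations — are excluded from that subgroup analysis and counted.

Meta-regression follows the extended linear SROC model: weighted least
squares of D = ln DOR on [1, S, covariates] with weights 1/(varᵢ + τ²),
varᵢ the ln-DOR variance and τ² estimated by REML (method-of-moments
available).  Standard errors come from the weighted information matrix;
two-sided t-tests with k − p degrees of freedom; RDOR = e^coeff with t-based
95% CIs.  Covariates are coded **ordinally** — reference category 1, index
category 2, and 0 where the covariate has no value for a row (the
missing-to-zero rule): tissue=1/circulating=2/gastric juice=0;
antisense=1/intergenic=2/other locations=0; ≤200=1/>200=2; NOS<7=1/≥7=2.
This keeps missing rows in the regression as a distinct level while the
contrast of interest stays one unit; with plain 0/1 coding the missing rows
collapse into the reference class and the coefficient pattern of the
4-covariate model changes materially.  An inverse-sample-size weighting
variant is available.  Backward elimination drops the covariate with the
largest p ≥ 0.05, refits until all survivors are significant, and appends
the single-covariate model of each survivor.

On the packaged table the trajectory is: quality out first (p = 0.85), then
location (p = 0.60), leaving sample type (RDOR 1.82, p = 0.006) and sample
size (RDOR 1.67, p = 0.018); singly, sample type gives RDOR 1.82 and sample
size 1.64.  τ² sits between 0.41 and 0.49 across models.

## Publication bias, clinical utility, influence

Deeks' test regresses ln DOR on 1/√ESS with weights ESS, where
ESS = 4n₁n₀/(n₁+n₀); the slope's two-sided t-test (k − 2 df) is the
asymmetry p-value.  This is the appropriate funnel test for DTA data;
Egger/Begg are intentionally not provided.  Degenerate inputs (identical
sizes or identical effects) return slope 0, p 1.  Below 10 studies the test
warns about power.

Fagan updating is Bayes' rule on the odds scale:
post-odds = pre-odds × LR.

Leave-one-out refits the bivariate model k times, warm-started at the
full-data solution; a study is flagged when its omission moves pooled SEN or
SPE outside the baseline 95% CI.  Note an intrinsic property of this rule:
a single mean-level outlier inflates the between-study variance — and hence
the baseline CI — faster than its omission shifts the mean, so lone outliers
widen intervals rather than trigger flags.  The influence table therefore
also reports each omission's estimates so the largest displacements can be
ranked directly.

## Expression stage

TPM: count/length rates scaled to one million per sample.  Differential
expression: per-gene two-sided Mann–Whitney U (exact for small untied
samples, tie-corrected normal approximation otherwise), Benjamini–Hochberg
FDR, direction called at FDR < 0.05; log₂ fold change uses group means with
a pseudo-expression of 1 to guard zero means.  ROC: empirical, AUC equal to
the Mann–Whitney probability with ties counted one half (verified against
O(n²) pair counting), Hanley–McNeil SE and normal CIs, Youden-optimal
cut-off with ties broken toward higher specificity, scores oriented so
higher = more case-like.  Combination models: maximum-likelihood logistic
regression with all listed genes entered simultaneously; perfect separation
is flagged, not hidden.  Stage-stratified AUCs score each stage's cases
against the shared control pool (plus a pooled late-stage row) and compare
to stage I with the independent-samples Z-test; the correlation from shared
controls is ignored by design, and a stage reaching AUC exactly 1 (zero
Hanley–McNeil SE) yields no Z-test rather than a fabricated one.  The
case/control design for validation data is accepted as given (unpaired
tumour-vs-normal or paired subsets both work); direction concordance with
literature calls is produced as a report, not a gate.

## Synthetic generators

`simulate_meta_dataset` draws per-study (logit sen, logit spe) from N(μ, Σ),
optionally shifted along the ln-DOR axis by covariate effects (half the
shift on each logit so the full effect lands on ln DOR) or perturbed by a
latent threshold component whose variance is r/(1−r) times the base
variance, giving an induced logit-TPR/logit-FPR correlation of r before
binomial noise.  Cells are then **binomially realised**, so within-study
sampling variation matches the pooling model's assumption.  Default arm
sizes are uniform on 20–200, typical of the case–control studies in this
literature; a "paper-like" preset mirrors the packaged table's structure
(k = 54, μ = (0.89, 1.13), Σ = [[0.32, −0.14], [−0.14, 0.55]], arm sizes
20–280, a 0.6 ln-DOR circulating effect).

`simulate_expression` draws lognormal expression (log-scale spread 0.5 by
default) and multiplies case samples by 2^(planted log₂FC) with optional
per-stage multipliers.

What the generators do **not** emulate: correlated genes, library-size and
batch effects, paired tumour/normal designs, non-lognormal dropout, or the
selective-reporting processes that create real publication bias.  Passing
tests on synthetic data therefore certify the estimators (bias, coverage,
type-I error under the stated model), not robustness to those real-data
features.

## Problem sizes used in the shipped checks

The statistical property checks run at desk scale by choice: parameter
recovery and CI coverage use 60 generator replicates at k = 200 studies;
type-I calibration uses 400 null genes at 30 vs 30 samples; the
leave-one-out sweep covers all 54 packaged rows.  Each full-table bivariate
fit takes well under a second on one CPU.

## Known limitations

* The packaged table is a transcription of printed values; rows the source
  printed inconsistently (a spaced decimal in one AUC; one NOS score at odds
  with the prose) are kept as printed, with the parser repairing only
  whitespace, loudly.  Exact-cell statistics inherit the rounding ambiguity
  described above — observed as ~0.1% on Q and a few percent on
  meta-regression coefficients.
* The full hierarchical Bayesian summary-ROC estimation is out of scope; the
  bivariate-implied curve is used.
* No multiple-testing correction is applied across subgroup contrasts,
  matching the conventional report shape.
* Monte-Carlo and resampling SEs are seeded and reproducible, but are still
  simulation estimates; report them with their draw counts.
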