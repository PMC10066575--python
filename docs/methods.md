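# Methods

## The network failure quotient

The package quantifies default-mode-network (DMN) dysfunction with the
network failure quotient (NFQ). The DMN is decomposed into four
subsystems — posterior (pDMN), ventral (vDMN), anterior ventral (avDMN)
and anterior dorsal (adDMN) — each represented by one or more spatial
components of a connectivity atlas. For a pair of subsystems (A, B) the
*pair connectivity* m(A, B) is the median Pearson correlation over all
cross component pairs, computed on nuisance-cleaned, band-passed component
time courses. The NFQ is

    NFQ = [ m(pDMN, avDMN) + m(pDMN, adDMN) ] / m(pDMN, vDMN)

Higher values indicate a connectivity shift away from the posterior hub
toward anterior subsystems — the signature of DMN failure in aging that is
accelerated in Alzheimer's disease. A `literal` variant replacing
m(pDMN, avDMN) by m(pDMN, vDMN) in the numerator is selectable because the
formula has circulated in both forms; the numerator/denominator pair sets
are configurable. A denominator below 1e-6 marks the session's NFQ
undefined (NaN) instead of producing an unstable ratio; undefined sessions
are dropped from the within-subject average.

## Time-course extraction and cleaning

Volume-mode sessions pass through: removal of the first 10 frames;
construction of a white-matter/CSF noise ROI (probability maps binarized
at 0.9, inclusive, then eroded by two voxels with a 6-connected element);
extraction of the top 6 principal components of the noise-ROI voxel time
series (aCompCor); assembly of a nuisance design from the 6 motion
parameters, their backward-difference derivatives and the noise
components; *simultaneous* band-pass filtering (0.009–0.08 Hz) and
nuisance regression — both data and regressors are passed through the
identical zero-phase 4th-order Butterworth (forward–backward) operator
before the least-squares projection, so motion artefact cannot be
reintroduced through spectral mismatch; per-column variance
normalization; optional 8 mm FWHM Gaussian smoothing; and dual
(spatial–temporal) regression, i.e. a joint multivariate regression of
every frame on all column-centred atlas maps. Time-course-mode input
(frames × components tables) bypasses the volumetric steps. Upstream
steps (despiking, slice timing, realignment, template normalization) are
assumed done by the acquisition pipeline and are out of scope.

The filter realization is a contract, not a fixed tool: the tests pin the
pass band (a 0.04 Hz sinusoid retains > 95% variance), the stop band
(0.2 Hz retains < 10%), exact removal of nuisance columns, and the
orthogonality of residuals to every filtered regressor.

## Motion quality control

Frame-wise displacement is Power-style: FD_t = |Δx|+|Δy|+|Δz| +
r·(|Δpitch|+|Δyaw|+|Δroll|) with r = 50 mm. Two exclusion rules: scans
with mean FD ≥ 0.25 mm are dropped (strict "lower than" retention), and
scans in which any translation exceeds a 2 mm peak-to-peak range or any
rotation exceeds 2° peak-to-peak are dropped as gross motion. The FD
summary statistic (mean/median/max) is configurable; mean is the default.

## Structural biomarkers

From Desikan-Killiany regional statistics: (1) the thickness meta-ROI, an
unweighted mean of bilateral entorhinal, inferior temporal, middle
temporal, inferior parietal, fusiform and precuneus thickness (12
values; "middle temporal" stands in for the ambiguous "medial temporal"
phrasing sometimes attached to this composite — Desikan-Killiany has no
medial temporal parcel; the parcel set is configurable); (2) left/right
hippocampal volumes adjusted for intracranial volume by the residual
method (volume − β̂·(ICV − mean ICV), β̂ from an OLS fit *in the normative
reference only*; ratio adjustment available); (3) inferior parietal
thickness summed across hemispheres.

## Normative modelling

Each biomarker is modelled on the normative cohort as
value | age ~ N(μ(age), σ(age)) with μ and log σ penalized cubic
B-splines of age (P-splines: uniform extended knots, second-order
difference penalty, so the penalty null space is exactly the linear
functions and the infinite-smoothing limit reproduces the OLS line).
Fitting is penalized maximum likelihood, alternating a weighted
penalized least-squares step for μ (weights 1/σ²) and Fisher-scoring
steps for log σ (score r²/σ² − 1, information 2), to a relative deviance
tolerance of 1e-6. Smoothness is parameterized by effective degrees of
freedom (EDF); λ is solved from the EDF target by bisection on the
generalized-eigenvalue form of the hat-matrix trace. A candidate grid of
(EDF_μ, EDF_σ) pairs — by default {2..8} × {2..4} — is scanned and the
winner chosen by the Schwarz Bayesian criterion, with global deviance and
AIC reported alongside (the selection criterion is configurable; the
three scores are always attached). The family is normal; the
location-scale scaffolding is extensible but skew/kurtosis families are
out of scope.

Scoring an external subject gives z = (value − μ̂(age))/σ̂(age) and the
centile rank Φ(z), stored unrounded and rounded to two decimals. The
two-decimal rounding is load-bearing: centile-threshold counts ("above
the 90th centile" ⇒ rounded rank ≥ 0.90; "second centile or lower" ⇒
rounded rank ≤ 0.02) operate on the rounded rank, so a rank printing as
0.90 counts as above the 90th centile. Ages outside the fit support are
scored at the boundary and flagged extrapolated. Diagnostics are
normalized quantile residuals (equal to the Z-scores under the normal
family): mean, SD, skewness, kurtosis, and detrended Q-Q (worm)
coordinates with a pointwise 95% band.

Recovery protocol: on simulated linear truth (n = 1000, σ = 2) the
sampling spread of the max-over-grid error of *any* unbiased curve
estimate is itself ≈ 0.13, i.e. at the scale of the recovery tolerance;
the package therefore checks (a) agreement of the fitted curve with the
brute-force OLS oracle on the same data (max deviation < 0.05) and
(b) mean absolute error against the planted truth < 0.15 for μ and < 10%
for σ, on the 2nd–98th percentile age grid.

## Group statistics

Standardized simple regressions (Pearson) per covariate with
Benjamini-Hochberg FDR across the family; Spearman's ρ with a Fisher-z CI
for heavily skewed scores (completion-time tasks such as the TMT-B);
multivariate OLS with rank-deficiency detection; one-way ANOVA with
Tukey-Kramer post hoc tests; Cohen's D (pooled SD) with a noncentral-t or
bootstrap CI and the 0.3/0.5/0.8 magnitude conventions; AUC by the
rank/Mann-Whitney statistic with ties at half credit and a DeLong
(default) or stratified-bootstrap CI; centile-threshold counts as above;
and amyloid/tau positivity at SUVR > 1.42 / > 1.23 (strict).

## Mediation

Quasi-Bayesian Monte Carlo for linear no-interaction models: OLS fits of
M ~ X (+covariates) and Y ~ X + M (+covariates); n_sims (default 10,000)
parameter vectors drawn from each fit's asymptotic multivariate normal;
per draw ACME = a·b, ADE = c′, total = ACME + ADE, proportion =
ACME/total (draws with |total| ≈ 0 are flagged and the flagged fraction
reported). Point estimates are medians of draws (mean optional), CIs are
percentile intervals, p-values two-sided tail probabilities. The
case-resampling bootstrap wording sometimes used for this estimator is
interpreted as the parametric Monte Carlo algorithm; the identity
total = ACME + ADE holds per draw by construction.

## Synthetic cohorts: what they emulate, and what they do not

The generator produces a normative aging cohort (default n = 500, ages
uniform on 36–90) plus small dysexecutive (dAD, n = 10) and amnestic
(AD, n = 8) patient groups and scanned controls (n = 5), with four
488-frame sessions at TR = 0.8 s per subject. Five biomarkers follow
linear age-dependent normal location/scale laws; defaults (units, per
year): NFQ 0.55 + 0.011·age, σ 0.30; meta-ROI 3.15 − 0.004·age mm,
σ 0.10; hippocampal volumes 5200/5300 − 16·age mm³, σ 420/430; inferior
parietal sum 5.90 − 0.008·age mm, σ 0.28. Patient shifts are expressed
in normative-SD units at the subject's age; the defaults are the
published patient-group mean Z-scores per biomarker, so planted effects
match the magnitudes the analysis is expected to detect. Patient age
windows mirror the reported group medians. Left/right hippocampal
residuals share a factor (r ≈ 0.7).

Each subject carries a true component correlation matrix (4 components
per subsystem; within-subsystem r = 0.7, pDMN–vDMN 0.6, background 0.25)
whose pDMN–avDMN and pDMN–adDMN entries encode the subject's NFQ; the
matrix is projected to the nearest correlation matrix and the realized
NFQ recomputed from it, so table-driven and scan-driven analyses agree in
expectation. Scan synthesis filters white noise with the *same* band-pass
operator the analysis uses, standardizes, and mixes by the symmetric
square root of the target matrix — band-limited synthesis and band-pass
cleaning therefore commute and the analysis filter cannot distort the
planted structure. Volume mode mixes courses through Gaussian-blob atlas
maps on a 30×36×30 grid, adds voxel noise, injects nuisance signals into
the white-matter/CSF slab and a motion-locked artefact pattern. Motion
traces have bounded baseline drift (spike-free FD provably below the
baseline amplitude) plus exponential-magnitude spike steps; the default
spike rate is calibrated so ≈ 2% of scans trip the exclusion rules, the
removal rate of the emulated study.

Memory scores carry a planted mediation chain on the standardized
age-residual scale: hippocampal residual → NFQ residual (a = −0.28) →
recall residual (b = −0.25) with direct slope c′ = 0.50, giving a
proportion mediated a·b/(a·b + c′) ≈ 12.3%, the order reported for the
corresponding recall model. Because all three variables also depend on
age, recovery analyses must include age as a covariate.

Known gaps between synthetic and real data: haemodynamics, scanner
artefact physics and non-Gaussian BOLD structure are absent; the age
density is uniform rather than cohort-specific; and the session-to-session
consistency of the measured NFQ tops out near ICC ≈ 0.5–0.6, below the
≈ 0.85 reported on real data — band-limited Gaussian courses at 478
frames carry only ≈ 55 effective samples, which bounds the stability of
correlation medians and hence of a ratio statistic. Passing tests
demonstrate correctness of the pipeline's operations and recoverability
of planted structure at realistic effect sizes; they do not certify
real-data reliability.

## Problem sizes and numerics

Default analysis runs use 500 normative subjects × 4 sessions × 488
frames in time-course mode, a 21-candidate EDF grid per biomarker, and
2,000–10,000 mediation draws; the end-to-end synthetic pipeline completes
in well under a minute on one core, and the recovery studies use
n = 1,000–10,000 as stated per check. Tie-breaking and degeneracy
policies: inclusive (≥) probability thresholds; strict (<) FD retention
and strict (>) SUVR positivity; zero-variance courses excluded from
medians with a warning; rank-deficient nuisance designs pruned with a
warning; rank-deficient regression designs are errors naming the aliased
columns; NFQ denominators under 1e-6 are flagged undefined; ICC is
ICC(2,1) with listwise deletion.
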