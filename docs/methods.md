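# Methods

This note records the model, the estimation choices, the synthetic-data
design and the known limitations of `msstratify`, at the level of detail a
maintainer or reviewer needs to judge what the tests do and do not show.

## Normalization and feature selection

Raw volumes x are mapped to z = flip · (x − μ_ref)/σ_ref with sample
mean/SD (n−1 denominator) of the reference population's baseline visits.
Gray-matter regions use the healthy-control (HC) reference with flip = −1
(volume loss is pathological); total lesion volume uses an external
patient reference with flip = +1 (healthy controls carry almost no lesion
load, so their lesion SD would be degenerate as a norm).  The mapping of
biomarker → reference is configurable.

Selection keeps biomarkers whose group effect in a patient-vs-control
linear model has Cohen's f = sqrt(η²_p/(1 − η²_p)) strictly above 0.25
(a moderate effect; for equal-n two-group designs f = |d|/2).  Covariate
adjustment (age/sex/TIV-style ANCOVA) is available but off by default:
which variant an applied study uses should be an explicit choice, so both
are exposed and neither hard-wired.  Lesion volume is always retained:
lesion load is a core MS feature regardless of its effect size against
controls, who essentially lack lesions.

## The subtype-and-stage model

*Events and grid.*  Candidate events are biomarkers crossing z ∈ {1, 2, 3}
("mild / moderate / severe").  A level is retained only if at least 5% of
baseline subjects reach it (strictly fewer than 5% → excluded); biomarkers
retaining no level are dropped with a warning.  N is the total event
count; stages run 0..N, event positions 1..N (stage k = the first k events
have occurred).

*Trajectories.*  The expected z of biomarker i at stage k is the
piecewise-linear interpolant through (0, 0), (position of each of i's
events, its level) and (N, z_max).  z_max defaults to 5 per biomarker
(it only needs to exceed the last level; the exact ceiling mildly shapes
the tail of the trajectory after the last observed event).  If a
biomarker's last event lands exactly at position N the event anchor takes
precedence over the ceiling anchor, so "stage = event position ⇒ expected
value = event level" holds without exception.

*Likelihood.*  Observed z-scores are independent Gaussians around the
trajectory with per-biomarker SD σ (default 1 z-unit — the natural scale
for z-scored data; configurable).  The stage is marginalized with a
uniform prior over 0..N.  Missing biomarker values contribute a factor of
one, so visits with partial coverage remain usable.  Subtypes form a
mixture with fractions f_c on the simplex.

*Fitting.*  The single-subtype ML sequence is found by greedy single-event
reinsertion (remove an event, try every position that keeps its
biomarker's levels ordered, keep the best; ties go to the lowest
position) iterated to a fixed point, from 25 uniform-random valid
start sequences by default.  C-subtype models are seeded by splitting each
cluster of the (C−1)-subtype solution: its ML-assigned subjects are
randomly bipartitioned (3 tries per cluster by default), each half refit
by greedy search from the parent sequence, then the full model is refined
by alternating (i) soft fraction updates from subtype responsibilities and
(ii) greedy sequence refits on hard-assigned subjects, until the total
log-likelihood improves by < 1e−6 or 100 iterations.  The best split wins.
All stochastic steps draw from a generator seeded by the caller.

*Positional uncertainty.*  A Metropolis-Hastings chain proposes swapping
two event positions within a randomly chosen subtype's sequence; proposals
violating within-biomarker level order are rejected outright (the chain
stays put, keeping the kernel symmetric), others are accepted by the data
likelihood ratio with fractions held fixed.  The first 10% of samples are
discarded; empirical event-by-position frequencies give the positional
variance diagram (PVD).  With a single subtype the stationary law is
exactly the sequence posterior under a uniform prior over valid sequences,
which is what the enumeration test checks.  The chain is intended for
uncertainty display, not for point estimation.

*Assignment.*  A visit's subtype posterior is f_c times its
stage-marginalized likelihood, normalized; the stage posterior is
conditional on the ML subtype; both the ML stage and the expected stage
are reported.  Visits are assigned even when the subtype posterior is
flat (e.g. stage 0, which is subtype-uninformative); downstream analyses
re-filter by assignment probability instead.

*Labelling.*  With two subtypes, the one whose deep-gray-matter events
have the earlier mean position is "DGM-first", the other "cortex-first";
exact ties fall back to the lesion-event position with a warning; a
single-subtype model is "undifferentiated".

## Model selection

Subject-level K-fold cross-validation (10 folds on a full-size cohort;
the shipped analyses use 3 folds at their reduced sizes) refits the whole
hierarchy per fold and scores the held-out mixture log-likelihood,
per-subject normalized because folds can differ in size; the C with the
best fold-mean wins.  The event grid is built once on the full training
data and reused across folds — the 5% exclusion rule is part of the
problem definition, and per-fold grids would make likelihoods
non-comparable.  Fold subtypes are matched to full-model subtypes by
optimal assignment (Hungarian) on total event-wise Bhattacharyya
similarity before computing CVS — the mean over events of the
Bhattacharyya coefficient between fold and full positional distributions —
so arbitrary fold-side label order cannot depress the score.  CVS averages
over events only (not over any additional MCMC dimension).

## Longitudinal validation

*Stability.*  Krippendorff's nominal α over subjects' per-visit subtype
labels, via the coincidence-matrix formulation; subjects contribute only
if they have ≥ 2 visits, and all within-subject visits are used.  CIs are
percentile bootstrap over subjects (1000 resamples by default) — the
resampling unit must be the subject, since visits within a subject are the
agreement being measured.  α is undefined (explicit error) when only one
label occurs overall; the acceptance pipeline reports that limit as
perfect agreement when it arises from thresholding to a single-subtype
subset.  The 95%/99% sensitivity analyses re-threshold on the *baseline*
assignment probability.

*Stage change.*  A linear mixed model with random intercepts and slopes
per subject, estimated by maximum likelihood.  The fitter is an
in-package profiled-GLS optimizer specialized to the 2-dimensional
random-effect structure (marginal covariance Z G Z' + σ²I with G
parameterized by its Cholesky factor; subjects bucketed by visit count so
all per-subject inverses are batched): the replicate-heavy calibration
analyses need fits in tens of milliseconds, and it agrees with
statsmodels' MixedLM to ~1e−4 on shared fixtures (tested).  Wald CIs and
p-values use the GLS covariance of the fixed effects.  Stage is treated
as continuous despite being an integer — a deliberate simplification
matching standard practice for staging scores.  Moderation (subtype ×
time, baseline-stage × time) enters as main effect + interaction; the
subtype analysis is restricted to subjects whose ML subtype is identical
at every visit ("retained the initial subtype", read literally).
Noise-free data make the mixed likelihood singular; if per-subject lines
reproduce the outcome exactly the fitter returns that exact solution with
zero variances instead of a NaN fit.  Subjects with a single visit are
retained (they inform intercepts).  Per-biomarker trajectory models reuse
the same machinery with each z-score as outcome.

## Outcome models

Ordinal outcomes (baseline EDSS on its observed 0.5-step categories;
long-term motor and cognitive disability on 0–3) use proportional-odds
(cumulative logit) models; the secondary-progressive transition (SP = 1,
RR = 0) uses binary logistic regression.  Predictors: baseline subtype
(DGM-first = 0, cortex-first = 1), baseline ML stage (expected stage via a
flag), their product, age, sex (F = 0, M = 1); long-term models add
follow-up time and the therapy code (0 none, 1 interferon, 2 glatiramer
acetate, 3 natalizumab).  A baseline-EDSS covariate for long-term models
is supported but off by default.  Headline coefficients, Wald tests,
−2LL, likelihood-ratio χ² and McFadden/Nagelkerke pseudo-R² come from
statsmodels; confidence intervals are percentile bootstrap over subjects
(5000 resamples by default; the calibration tests use 500), refit by an
in-package warm-started L-BFGS maximizer of the same cumulative-logit
likelihood (columns standardized internally for conditioning; checked
against statsmodels to 1e−4) because tens of thousands of statsmodels
refits would dominate the runtime.  The intercept-only cumulative-logit
null likelihood is the empirical category distribution, computed in closed
form.  Percentile (not BCa) intervals are the simplest defensible
bootstrap reading.  Quasi-complete separation or non-convergence raises.

## Synthetic cohorts

The generator mirrors the model's own generative assumptions — by design,
since its purpose is ground-truth recovery testing.  Defaults: 425
patients, 148 HC, 80 external patients; 11 biomarkers (bilateral thalami
and right putamen as DGM; insulae, cunei and cingulate regions as cortex;
TLV as lesion volume) with HC norms in plausible mL ranges and the
external lesion norm at 3.4 ± 5.3 mL; two subtypes with 60/40 fractions
whose sequences are tier-mirrored (DGM → lesion → cortex within each
z-level tier vs the reverse); baseline stages uniform on 0..N (maximizing
sequence identifiability; configurable to skewed distributions for
realism); observation noise σ_gen = 0.25 z-units; visit counts
1 + Poisson(1.7) (~2.7 visits/patient) at ~yearly spacing; latent stage
advancing as k(t) = clip(k₀ + (0.2 − 0.05·k₀ + subject slope)·t, 0, N)
with random-slope SD 0.1/year; ordinal/binary outcomes drawn from
latent-logistic blocks whose default coefficients sit in the ranges such
prognostic models typically report (stage coefficients 0.03–0.08, age
0.015–0.095, therapy 0.09–0.57), with thresholds chosen to give realistic
category occupancies.

What the generator does **not** emulate: scanner/site effects,
non-Gaussian or heteroscedastic measurement noise, informative dropout,
biomarker correlations beyond the shared stage, negative-volume
truncation (raw values are the exact affine inverse of the z-scores, so a
large lesion SD can produce negative raw volumes), or subtype-dependent
demographics.  Passing recovery tests therefore certifies the inference
machinery under the model's own assumptions — not robustness to real-data
violations of them.

## Problem sizes

The default test-suite and acceptance-script runs are scaled to a desktop
budget, as the package's own choice of demonstration size: the acceptance
pipeline uses 300 patients and the full 11 biomarkers at a single z-level
(N = 11 events), 3-fold CV, 2000/1000-sample MCMC chains and 500-resample
bootstraps; the calibration tests use the replicate counts stated in
their docstrings (200 for the mixed-model and ordinal-recovery checks).
The single-level grid is also a deliberate modelling condition for the
two-subtype demonstrations: with multiple z-levels per biomarker a
sequence cannot be fully reversed (levels must stay ordered), tier-
mirrored orderings share many stage profiles, and the two subtypes are
then only weakly identified — chimeric orderings can match or beat the
generating pair in likelihood.  With one level per biomarker the reversal
is a valid ordering and the subtypes are well separated.  The generator's
full defaults (11 biomarkers × 3 levels, N = 33, 425 patients, 10-fold
CV, 5000 bootstrap resamples) run the same code unchanged in a few
hours.

## Numerical choices

Likelihoods are accumulated in log space with log-sum-exp; greedy ties
break to the lowest position (determinism); mixture fractions are floored
at 1e−9 before renormalizing so empty subtypes cannot produce log(0);
MCMC burn-in is 10% of the chain; bootstrap resamples whose outcome
collapses to a single level are redrawn (up to a bounded number of
attempts); model artifacts serialize with canonical JSON (sorted keys,
fixed separators) so write → read → write is byte-identical, and MCMC
samples are stored in full so positional diagrams are exactly
reconstructable.
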