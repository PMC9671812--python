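# Methods

## Overview

`metastate` implements a multidisease risk-modelling workflow for circulating
NMR metabolomics. A single multitask neural survival model maps 168 marker
concentrations to one scalar *metabolomic state* per endpoint — a relative
log-hazard — and those states are then integrated into ordinary Cox
proportional-hazards (CPH) models alongside standardized clinical predictor
sets. Discrimination, calibration, clinical utility and per-marker
attributions are evaluated on test predictions pooled across spatially
separated cross-validation folds. Because real biobank cohorts are
access-restricted, the package ships a synthetic-cohort generator that
reproduces the statistical structure the analysis assumes and retains its
ground truth, so every stage can be benchmarked against an oracle.

## The state model

The network is a residual multitask architecture. A shared trunk of three
fully connected layers (defaults 256, 256, 512 units), each with batch
normalization, dropout 0.3 and SiLU activations, produces a representation
shared by all endpoints. Each endpoint head receives two inputs: the shared
representation, transformed by an MLP (256, 128, 32; dropout 0.6), and the
raw 168 markers, transformed by a skip network (128, 128, 32). The two
32-dimensional outputs are added, passed through a further 128, 128 block,
and reduced to a scalar by a final linear layer with identity activation.

Training minimizes an adapted Cox partial-likelihood loss: within each
minibatch and endpoint, the negative log partial likelihood (Breslow ties)
is averaged over the eligible in-batch events, with risk sets formed among
eligible in-batch rows; per-endpoint means are then summed across endpoints.
Endpoint eligibility (prevalent-case exclusion, sex restriction, medication
exclusion for cardiovascular endpoints) enters as a mask, so one forward
pass serves all endpoint losses. Risk sets are batch-local, the standard
choice for stochastic Cox training; a full-batch mode exists and is used by
the exactness tests, which verify that the batch loss equals the classical
full-data negative log partial likelihood.

Optimization uses Adam (defaults), batch size 1,024, learning rate 0.001
with multistep decay (factor 0.1 at epochs 20/30/40), at most 100 epochs,
stochastic weight averaging from epoch 20, and early stopping on the
validation multitask loss (patience 10, a package choice). The returned
checkpoint is the best-validation one, or the SWA average when it validates
better. Marker z-scoring statistics are fitted on training rows and stored
with the model; exported bundles (npz weights + JSON sidecar) carry them so
states are reproducible from raw marker input.

The engine is a compact numpy implementation with hand-written backprop for
exactly this layer family; its gradients are verified against finite
differences and the Cox gradient against an enumerated oracle.

### Desk-scale training

The defaults above describe the biobank-scale protocol (hundreds of
thousands of person-years, thousands of events per endpoint). The synthetic
studies in this package run at n ≈ 2×10⁴ with a few hundred events per
endpoint, where a full-width network sees roughly two orders of magnitude
fewer optimizer steps and far fewer events per parameter. The desk-scale
recipe therefore shrinks widths (trunk 24/24/24, heads 12/8/8, skip 8/8/8,
post-merge 8/8), lowers dropout to 0.05, raises the learning rate to 5e-3,
and adds L2 weight decay (`weight_decay`, default 0; 0.1 in the recipe) to
substitute for the implicit regularization that data volume provides at
full scale. Two further trainer facilities matter at this scale. First,
weight-averaged (SWA) candidates get their batch-norm running statistics
re-estimated with a full training-set pass before validation — averaged
running statistics do not describe averaged weights. Second,
`checkpoint_selection="per_endpoint"` snapshots, for each endpoint, the
epoch at which *its* validation partial likelihood is lowest: in a
multitask run on small data, endpoints reach their optima at very
different epochs, and a single global checkpoint forces a compromise. The
default remains the single global best-validation checkpoint, the sensible
policy when every endpoint has ample events. With a few hundred events and
168 correlated features, any dense estimator — including a ridge-penalized
linear Cox fit — sits measurably below the oracle ceiling; the recovery
studies therefore assert the network's mean concordance gap across
strong-signal endpoints and training seeds, the statistically stable
version of the per-endpoint claim (per-seed, per-endpoint values carry
several points of evaluation noise at a few hundred test events each).

## Synthetic cohorts

Participants carry: demographics (age uniform-like around 56 ± 8 years, sex
54% female), correlated clinical covariates built from latent adiposity and
lipid factors (so BMI/waist/SBP and the lipid labs inter-correlate, which
the chained-equation imputer needs), three-level smoking and education,
medication flags whose propensities depend on the relevant covariates, and
168 markers drawn as block-correlated Gaussians — 14 lipoprotein-like
blocks of 10 markers (within-block r = 0.5 by default) plus 28 independent
small molecules. The first block loads on the lipid factor so markers and
laboratory lipids correlate, as in real assays. Each of 22 centers adds a
mild mean shift (s.d. 0.08) to markers and continuous covariates — centers
differ in covariate distribution but share the outcome model, which is what
spatial validation is meant to exercise.

Outcomes per endpoint follow proportional hazards exactly: a constant
baseline hazard (calibrated by root-finding so the population 10-year
cumulative incidence hits a target) times exp(eta), with eta a linear
combination of standardized clinical covariates and markers plus optional
quadratic/interaction terms. Event times are inverse-transform sampled;
censoring is the minimum of an exponential dropout time and an
administrative horizon (10 years plus up to 5 years of uniform slack, so
median follow-up lands near 12 years). Prevalent flags are independent
Bernoulli draws; sex-restricted endpoints have no events or prevalent cases
in the excluded sex. Missingness is injected MCAR (optionally MAR-on-age)
into designated clinical columns only.

The default endpoint suite has eight endpoints spanning the observed
spectrum: three strong-metabolomic (type-2-diabetes-, renal- and
liver-disease-like; oracle C ≈ 0.78–0.81, with the signal deliberately
placed almost entirely in the markers so a marker-only model can in
principle reach the oracle), three mixed clinical/metabolomic (heart
failure, MACE, dementia analogues), and two metabolomic-null endpoints
(breast-cancer-like, female-restricted; Parkinson's-like at a 0.6% event
rate). Ten-year rates span 0.6%–8.7%. What the generator does *not*
emulate: unit-faithful Nightingale concentrations, non-proportional
hazards, informative censoring, competing risks, and real marker-marker
biochemistry; passing recovery tests therefore shows the pipeline recovers
the model class it assumes, not that the assay behaves this way.

## Preprocessing and predictor sets

Seven covariate sets are fitted per endpoint: MET (the state alone),
Age+Sex, ASCVD (age, sex, smoking, systolic blood pressure, total and HDL
cholesterol, diabetes, antihypertensives), PANEL (ASCVD plus lifestyle,
physical measurements, laboratory values and lipid-lowering medication),
and the three clinical sets each combined with MET. PANELnoLaboratory
(PANEL minus laboratory columns) is available for the utility analyses.
Continuous predictors are imputed with chained equations (sklearn's
iterative imputer; regression conditionals by default, random-forest
optional; at most 10 sweeps or relative change < 1e-3), then standardized;
categoricals are one-hot encoded against training-level maps with the first
level dropped; unseen levels map to all-zeros with a logged warning. All
statistics come from training rows only — a per-fold audit refits on
identical training rows and asserts bit-identical statistics. A single
completed imputation is used per fold (m = 1); the pooling rules for
multiple imputations add complexity without changing the pipeline's
contracts, so m is configurable but defaults to 1. Imputation happens on
the raw scale, before standardization. The state column is never
re-standardized: it is already on a log-hazard-like scale.

## Partitioning and pooling

One fold per center: the center's participants are the test set, a uniform
10% of the pooled remainder (floor rounding) is validation, the rest
training. Disjointness and coverage are asserted programmatically on every
run. Test predictions are pooled across folds with a duplicate-id tripwire
— any participant appearing twice is a leakage indicator and raises.

## Survival integration and evaluation

CPH fits use lifelines' `CoxPHFitter` (Breslow ties and baseline) behind
the package's interface, with a deterministic step-size retry ladder
(1.0 → 0.5 → 0.1) for hard instances and no penalization by default (a
ridge option exists for degenerate synthetic designs). Ten-year risk is
1 − S₀(10)^exp(lp) with the linear predictor centered at training means.
Hazard ratios per s.d. use the training standard deviation of the column.
Partial effects fix other predictors at training medians/modes and sweep
the state over its 0.1/0.5/0.9 quantiles.

Harrell's C is implemented to its pairwise contract (comparable iff the
earlier time is an event; event-censored ties in time comparable; tied
scores half credit) and verified against O(n²) enumeration and lifelines.
Uncertainty comes from percentile bootstrap (≥1,000 resamples at full
scale; reports record the count used). Model comparisons resample
participants once per iteration and evaluate both models on the same draw
(paired bootstrap); a difference is significant when the 95% CI excludes
zero. Stratification reports 100 equal-count state-percentile bins and the
top-vs-bottom-decile event-rate ratio — both the plain rate ratio and the
odds ratio are emitted under explicit labels, because printed decile rates
in the field are sometimes labelled OR while matching the rate ratio.
Calibration bins are equal-count in predicted risk with Kaplan–Meier
observed incidence and Greenwood 95% CIs. Decision curves use
NB(p) = TP/n − FP/n · p/(1−p) against 10-year outcome status and are
standardized by prevalence; participants censored before the horizon
without an event are excluded from classification metrics (their count is
reported), so with zero censoring the computation reduces exactly to the
naive binary one; an IPCW option is left to future work. Sensitivity, PPV
and LR+ are reported at target false-positive rates via quantile thresholds
on non-event scores, with the achieved FPR reported when ties bite.

## Attributions

Per-sample, per-marker attributions use the DeepLIFT rescale rule
propagated through the exact layer graph (linear and inference-mode
batch-norm layers pass multipliers through their weights; SiLU uses the
Δout/Δin ratio with a derivative fallback for tiny Δin; the residual
addition fans multipliers to both branches), evaluated against each row of
a background sample (default 256 training rows) and averaged — the same
estimand DeepSHAP's DeepExplainer targets for this layer family. For every
background row the rule is exactly additive, so the averaged attributions
satisfy Σᵢ φᵢ(x) = f(x) − E_b f(b) to numerical precision; the test-suite
tolerance (5% relative for ≥99% of samples) is deliberately loose relative
to the implementation. For a linear model the rule reduces to
φᵢ = wᵢ(xᵢ − mean background). Global importance is the sum of |φ| per
marker and endpoint; percentile profiles rank participants per marker by
attribution and report per-bin mean attribution and mean raw marker value;
high-impact flags mark attributions outside the empirical 1%/99%
percentiles of the pooled per-endpoint distribution (a fixed-interval
variant exists — the percentile definition is primary since the interval
printed in the literature is a realized percentile, not a constant). The
attribution space is embedded in 2-D with UMAP at fixed seed.

## Pipeline determinism

Every stage derives its seed by SHA-256 hashing of (master seed, stage
name, fold id), truncated below 2³¹. With a fixed master seed, two runs
produce byte-identical evaluation reports (JSON with sorted keys); this is
asserted in the test suite. Model exports, pooled predictions, curve tables
and a line-delimited JSON log are written per run.

## Problem sizes used by the shipped studies

The recovery study runs at n = 20,000 participants, 22 centers, 8
endpoints, with the desk-scale model recipe; the smoke pipeline profile
uses n = 3,000, 2 folds, 4 endpoints and reduced bootstrap counts. The
coverage studies use 100 replicates at n = 2,000. These sizes are the
package's chosen trade-off between statistical resolution and the cost of
rerunning every study from scratch on a single CPU.

## Known limitations

- The numpy engine is single-threaded BLAS-bound; biobank-scale training is
  out of its intended envelope.
- Competing risks, time-varying covariates and IPCW-based utility metrics
  are not implemented.
- The hyperparameter-search space is illustrative; the original search
  campaign is not re-run.
- Model export uses an npz/JSON bundle rather than an interchange graph
  format; the bundle is complete (weights, normalization, config) but
  consumers must use this package to load it.
- With a few hundred events per endpoint, unpenalized dense estimators sit
  below the oracle by more than evaluation noise; recovery results should
  be read against the ridge-linear reference floor, not against an
  expectation of exact oracle attainment.
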