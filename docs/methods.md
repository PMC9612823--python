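# Methods

This note documents the models, the synthetic-data generators, the numerical
choices, and the known limitations of the package. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Task structure and schedules

Each session's hierarchy is seven wall textures A>B>...>G. The six adjacent
pairs are premise discriminations (transitive distance 1); the six untrained
pairs among B-F at distances 2-4 (B>D, C>E, D>F, B>E, C>F, B>F) are the
inferred discriminations. Pairs involving A or G are never inferred, because
"always pick A / never pick G" is a featural policy that requires no
relational knowledge.

**Interleaved schedule.** The task is described by two constraints: a
uniform 1/6 marginal probability of each pair at any trial, and exactly 60
presentations of each pair in 360 trials. Both hold simultaneously only
under balanced randomisation, so the generator seeds a shuffle of the
exactly-balanced multiset. Left/right placement is balanced 30/30 per pair.

**Progressive schedule.** Six epochs introduce pairs one-by-one. The printed
constraints fix epoch 1 (17 trials of A>B) and epoch 2 (14 x A>B + 20 x B>C),
and require each pair to total 60 presentations, appear in every epoch from
its introduction, and decline strictly across epochs. These constraints
under-determine the full epoch-count matrix; the default

```
A>B: 17 14 11  8  6  4
B>C:  - 20 14 11  8  7
C>D:  -  - 20 16 13 11
D>E:  -  -  - 22 20 18
E>F:  -  -  -  - 31 29
F>G:  -  -  -  -  - 60
```

satisfies all of them and is configurable; any matrix violating a constraint
is rejected with a validation error.

**In-scanner list.** 24 discriminations x 8 repetitions + 16 null events,
every event occupying 6.5 s (3 s response window + 3.5 s fixation; nulls
6.5 s), for 1352 s and 537 volumes at TR = 2.52 s. The higher-valued texture
appears on the left in exactly 4 of each discrimination's 8 trials. The
original in-scanner order came from a design-efficiency optimiser; this
package substitutes a constrained seeded shuffle, which is sufficient for
synthetic analyses and keeps the generator self-contained.

**Chain counting** (overlapping pairs presented back-to-back, e.g. B>C then
C>D) is defined only by example in the literature this follows; the default
counts non-directional maximal runs of texture-sharing trials, with a
directional mode (each successor one step lower) available.

## AND/OR models

Premise memory is a retrieval probability r_p. A premise test trial is
correct if retrieval succeeds (probability r) or a fair guess lands
(probability 1/2), so k of n correct follows
Pr(k|n,r) = C(n,k)((1+r)/2)^k ((1-r)/2)^(n-k); the module also carries the
explicit two-stage sum over the number of retrieved trials, and a test
verifies the two agree to 1e-10. Normalising Pr over r in [0,1] (trapezoid
quadrature on a 2001-point grid, normalisation checked to 1e-6) gives a
likelihood whose cumulative is inverted by linear interpolation for
inverse-transform sampling.

For an inferred pair i with mediating chain A_i (the adjacent premises
spanning it; |A_i| = distance) and end premises O_i = {first, last of A_i}:

- AND (retrieval-based): g_i = kappa * prod(r_p in A_i)
- OR (encoding-based):  g_i = kappa * (1 - prod(1 - r_p in O_i))

kappa in [0,1] is the probability of engaging memory-guided generalisation
rather than guessing, shared across a participant/condition's inferences and
fitted independently per model. Observed inference counts follow the same
two-stage law with g in place of r.

**Fitting.** Retrieval probabilities are drawn once per iteration (default
10,000 in the library; 1,000 in recovery tests, 500 at pipeline CI scale)
from the premise likelihoods using common random numbers, so g is linear in
kappa through a fixed per-iteration factor. The probability of each observed
inference count is averaged across iterations first, then logged, and kappa
minimises H = -(1/I) sum_i log(mean_iter Pr) by bounded scalar minimisation
with three sub-interval starts plus explicit endpoint checks (the objective
can be flat near the boundary). Whether the original analysis fitted kappa
per iteration and averaged afterwards is not documented; averaging
probabilities first makes the objective smooth and is the package's default.
Missing responses are resampled as fair guesses before counting, mirroring
the accuracy analysis.

**Comparison.** Per participant/condition the package reports H for both
models, expected counts n(1+g)/2 averaged over iterations, Spearman
correlations between observed and expected counts (rows with constant
expectations are flagged and excluded), and a seeded bootstrap (default
10,000 resamples) of the paired rho(OR) - rho(AND) difference, summarised as
mean difference / bootstrap SE.

**Known limitation — asymmetric model recovery.** On synthetic cohorts the
OR model is recovered cleanly (the OR fit wins H for the large majority of
OR-generated participants, and median fitted kappa lands within 0.1 of
truth), but AND-generated cohorts are *not* reliably attributed to AND. The
premise likelihood is built from 8 trials with a flat prior, so sampled r_p
sit systematically below the true near-ceiling values that generated the
counts; the AND model multiplies two to four such draws, placing its
predictions below the data with no way to compensate (kappa cannot exceed
1), while the OR model freely re-tunes its overall level through kappa. The
cross-entropy comparison is therefore structurally biased toward OR whenever
premise performance is near ceiling — a property of the method itself that
anyone interpreting AND-vs-OR comparisons should keep in mind. The
acceptance suite asserts recovery for both regimes and the AND half fails by
design rather than being weakened.

## Behavioural regressions

Accuracy is the count of correct responses out of 8 per discrimination,
binomial with a logit link; latency (correct trials only) is gamma with a
log link. Both designs have 12 fixed-effect columns: intercept; trial type,
training method and session coded +-0.5 (the coding scheme is not specified
upstream; contrast coding keeps main effects at the grand mean); their
three two-way and one three-way interactions; and transitive distance,
mean-centred over inference rows, zero on premise rows (distance "applies to
inference trials only"; coding premise rows at the centred baseline keeps
the design estimable), interacted with method, session and method x session.

Estimation is delegated to statsmodels. For binomial outcomes the mixed
path uses the variational-Bayes binomial mixed GLM with participant random
intercepts; statsmodels has no gamma GLMM, so latency models — and any
binomial model whose mixed fit fails — downgrade to a fixed-effects GLM with
cluster-robust (by participant) standard errors, flagged in the result.
Clustered p-values use a t reference with (clusters - 1) degrees of freedom.
Exact replication of any particular pseudo-likelihood solver's output is a
non-goal; recovery and type-I calibration of this estimation path are part
of the test suite (30 and 200 simulation replicates respectively, sizes
chosen to keep the default run brief while leaving Monte-Carlo error well
inside the asserted bands).

## Synthetic fMRI

Ground-truth texture patterns are Gaussian across voxels; optionally the
seven same-session textures are drawn with covariance exp(-distance/lambda)
(default lambda = 2) so that pattern correlation decays with hierarchical
distance — the structure an encoding-based representation predicts.
Sessions are independent. Each trial evokes the sum of its two textures'
patterns; events are 3 s boxcars convolved with a canonical double-gamma
HRF (peak 6 s, undershoot 16 s, ratio 1/6 — the upstream analysis used a
standard package HRF without printing parameters); noise is AR(1) with
rho = 0.3 and unit SD by default (the upstream simulation's noise spectrum
is undocumented; both knobs are config).

Repetition suppression follows exponential recovery a*exp(-dt/tau),
calibrated exactly to the two published anchors (23% attenuation at a 0.1 s
repeat delay, 10% at 1 s), giving tau = 0.9/ln(2.3) ~ 1.0805 s and
a ~ 0.2523. Suppression keys on each *texture's* previous presentation, since
it is stimulus repetition that adapts. At this task's >= 6.5 s inter-trial
intervals the calibrated attenuation is numerically negligible
(a*exp(-6.5/tau) ~ 6e-4); it is implemented as specified anyway, with a
scale multiplier for stress tests.

Betas are estimated least-squares-separate: per discrimination, one GLM with
the summed regressor of its 8 trials, one regressor for all other trials, a
discrete-cosine drift basis implementing a 1/128 Hz high-pass filter, and an
intercept. Motion and physiological nuisance regressors are not simulated.

## Decomposition and RSA

The 24 x 15 occurrence matrix has a unit entry per presented texture (7
recent + 7 remote columns) and a +-0.5 premise/inferred contrast (the
upstream description says only that the final component "encodes overall
BOLD differences" between trial types; the sign convention is a config).
The matrix has full column rank, and multiplying betas by its pseudoinverse
returns 14 texture patterns plus the trial-type nuisance row, which is
dropped. Decomposing X @ P returns P exactly (tested to 1e-10, and against
a per-voxel least-squares oracle).

Similarities are Pearson correlations across voxels between interior
textures (B-F; A and G appear only in premise trials and are excluded),
Fisher-transformed with clipping at atanh(1 - 1e-12). Within-hierarchy:
10 pairs per session, distances 1-4. Across-hierarchy: 25 recent x remote
pairs, distances 0-4.

Two nuisance predictors accompany the similarities. (1) Co-presentation:
the Fisher-z phi correlation between the textures' presence vectors over the
24 discriminations (equal repetition counts make this identical to the
192-trial computation; whether the original used session-restricted vectors
is ambiguous, so the span is a config switch). (2) Simulation-derived: the
mean Fisher-z correlation, across iterations, of patterns recovered by the
full simulate -> LSS -> decompose route from *independent* ground-truth
patterns — capturing correlations induced by trial timing, repetition
suppression and the decomposition itself. AR noise inclusion and SNR are
config; fewer than 50 iterations triggers an instability warning. In the
orchestrated pipeline this predictor is optional (disabled by default at CI
scale) because it multiplies run time by the iteration count.

The RSA mixed model predicts Fisher z from mean-centred distance, +-0.5
method (and session, within-scope), mean-centred inference accuracy and
transitive slope (the per-participant, per-session Pearson correlation
between distance and inference accuracy), all interactions among these
excluding any joining accuracy with slope, plus the nuisance predictors
(constant nuisance columns are dropped). Across-scope rows carry participant-
mean accuracy and slope, since session is undefined for cross-hierarchy
pairs. Random effects are participant intercepts and distance slopes — the
fully parameterised covariance used upstream is unidentifiable at small
voxel counts — with an OLS + clustered-errors fallback flagged on solver
failure. Outliers are excluded in a single pass: rows with absolute
standardised residual above |Phi^-1((1 - 2^(-1/n))/2)| (the bound containing
all n normal points half the time; ~2.7 at n = 100, ~3.4 at n = 1000) are
dropped and the model refitted once. A sensitivity refit excluding
distance-1 pairs (8 rows per participant) checks that distance effects are
not driven by textures co-presented within a premise pair.

## Synthetic cohorts: what they do and do not emulate

Profiles draw per-premise retrieval probabilities from Beta(8,2) (mean 0.8;
premise accuracy (1+r)/2 ~ 0.9, matching near-ceiling performance — the
population distribution is a modelling choice, flagged in config), assign
training method alternately between participants, and generate premise and
inference counts from the exact two-stage laws above under a chosen regime
and kappa (optionally kappa per method, for cohorts with a real
method-by-trial-type effect). Missing responses are independent at 1.81%;
latencies are gamma draws whose mean is multiplicative in trial type
(matching the log link), truncated at the 3 s response window — the analysis
model ignores truncation, as the original did.

The generators reproduce the statistical structure the analyses assume, not
the phenomena themselves: there is no trial-by-trial learning dynamics, no
refresher task, no 3-D brain geometry, motion or physiological noise, and
behavioural and neural ground truth are independent unless explicitly
coupled. Passing tests therefore demonstrate that the pipeline recovers
known structure under its own assumptions, not that those assumptions hold
of real data.

## Problem sizes

Default library scales follow the study (34 participants, 10,000 model
iterations); the test suite and pipeline CI scale use reduced sizes chosen
as the smallest that leave Monte-Carlo error comfortably inside the
asserted tolerances: 1,000 model iterations and 34 participants for
recovery, 10 replicates of 10-participant cohorts at 50 voxels for RSA sign
recovery, 200 null replicates for regression calibration, 2,000 seeds for
the schedule-marginal check.
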