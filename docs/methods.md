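# Methods

This note documents the models, numerical choices and limitations of the
simulation and analysis pipeline. It is written for a reader who wants to
know exactly what the synthetic data contain, what each analysis assumes,
and what a passing test suite does and does not establish about real data.

## Synthetic recognition data

**Templates.** Each of the four objects has a voxel-length template built
from six orthonormal components: one shared component per pair and one
unique component per object. Components are seeded standard-normal vectors
orthonormalized by QR decomposition with the sign convention fixed to match
classical Gram–Schmidt, so the ground truth is exactly recoverable and
bit-reproducible. A template is `shared_scale · shared(pair) +
unique_scale · unique(object)`; both scales default to 1.

**Implanted integration.** Post-training templates multiply the trained
pair's unique components by `unique_shrink` (default 0.5) and its shared
component by `shared_gain` (default 1, i.e. the implanted effect is purely
a loss of unique features). The untrained pair is untouched. This yields
the exact ground-truth ordering: trained-pair template similarity rises
from pre to post while untrained similarity is constant.

**Trials.** Each recognition run has 48 trials (12 per object, 3 per
quarter, no back-to-back repetitions), generated by per-quarter constrained
shuffles with rejection sampling (cap 10,000 draws; in practice a handful
suffice). A trial's pattern is its template plus i.i.d. Gaussian voxel
noise. `noise_sd` defaults to 0.75, which places baseline pairwise
decoding at a cross-validated AUC of ≈0.79 with 200 voxels — decodable but
imperfect, the regime the analyses are designed for. Temporal
autocorrelation and hemodynamic convolution are deliberately absent: the
real-time system reads single-TR patterns 4 s (2 TRs) after onset, so
trials are generated directly at the lagged TR; the 2-TR lag is carried in
the configuration for the timeseries-extraction path.

**Sessions.** Defaults follow the multi-session protocol: 8 recognition
runs in sessions 1 and 5; 3 feedback sessions of 10 runs.

## The simulated participant

The feedback agent emits per-TR competitor evidence from a clipped Gaussian
whose mean rises linearly across sessions (`baseline` 0.45, `gain` 0.10 per
session, within-run SD 0.15) and stationary presented evidence (mean 0.75).
These are classifier-probability units in [0, 1]. The values were chosen
once as a plausible regime — competitor evidence near chance initially,
clearly above it by session 3, presented evidence high because that object
is on screen — and produce the qualitative signatures the protocol expects
(rising staircase threshold, rising coactivation product).

**Learning strength.** Each simulated participant draws a latent strength
λ ~ U(0.2, 1) that interpolates all three implanted effects (unique shrink,
agent gain, psychometric slope change). This is the simplest mechanism that
makes neural and behavioural integration covary across participants, which
a brain–behaviour correlation requires; it asserts nothing about the
physiology of individual differences.

## The closed loop

Per TR, the running average of the competitor evidence collected so far in
the trial is compared with the threshold; *strictly greater than* counts as
above (any fixed convention works; this one is documented for
reproducibility). The lead-in TRs 1–3 are classified and contribute to the
count but display the maximal wobble level regardless. Count-to-level,
level-to-morph-range and count-to-reward maps are the printed protocol
constants.

The staircase is a criterion-based up/down rule: once per run, the
threshold rises by 0.05 if the run's mean above-threshold count is ≥ 3,
falls by 0.05 if ≤ 1, clamped to [0, 1]. The published protocol staircased
adaptively but its exact step table is not available, so the rule here is
the simplest one reproducing the stated qualitative behaviour (threshold
tracks competence, rises across sessions for a learning participant); all
constants are configuration. For a fixed-competence agent the loop
converges to a neighbourhood of the agent's sustainable evidence level
(verified within two step sizes in tests).

## Decoding

Pairwise classifiers are L2-regularized logistic regressions. The
regularization is quoted as a penalty of 1; whether that denotes the weight
on the squared-norm term or its inverse is convention-dependent, so both
readings are exposed (`l2_weight`, `weight_is_c`) — they coincide at the
default of 1, and the setting is held fixed across all analyses so
contrasts are unaffected. Evidence for an object is the mean probability
from its two against-control classifiers (a bounded score, as thresholding
requires); coactivation is the product of presented and competitor
evidence. Real-time normalization is strictly causal per-voxel z-scoring
(sample variance over TRs 1..t−1; the first two TRs and zero-variance
voxels emit 0); offline analyses use full-run z-scoring.

## ROI selection

Parcels are abstract voxel-index sets. Each parcel is scored by
leave-one-run-out four-way accuracy, realized as one-vs-rest logistic
models with an argmax over probabilities (composing the same binary
machinery used everywhere else; accuracy rather than AUC is used for the
4-way score, with the metric isolated behind one function). Greedy backward
elimination evaluates every single-parcel removal per step, keeps the best
(ties remove the lowest id, for determinism), and returns the best subset
over all visited sizes with its score re-evaluated rather than cached.

## ROC/AUC and the neural integration index

AUC is computed by the rank/concordance method with midranks for ties
(equivalently the trapezoidal area under the empirical ROC), checked in
tests against an exhaustive pair-counting oracle and against scikit-learn.
Session-1 AUC is the mean over leave-one-run-out folds; session-5 AUC tests
fold model *i* on run *i* (the model→run pairing is not specified by the
protocol; index pairing is deterministic and exchangeable under the null)
and averages per-run AUCs. The integration index is session-1 minus
session-5 AUC; the headline statistic is the trained-minus-untrained
contrast.

## Geometric decomposition

Mean patterns are computed per object after per-run mean-centering of each
voxel's trial series. Directions come from the session-1 means of the same
axis — necessarily so, since shared features must be estimated from the
initial representations; the bias this induces is common to both axes and
cancels in the trained-minus-untrained contrast.

Two conventions required a decision:

- **Signed unique projections.** The unique direction û ∝ v̂_a − v̂_b
  points *towards* object a; object b expresses its unique features along
  −û. Each object's unique projection is therefore taken along its own
  sense (a on +û, b on −û) so that "expression of unique features" is
  positive for both and a symmetric shrink registers as a negative change
  instead of cancelling. Shared projections need no such alignment.
- **Pooling.** The two objects' projection changes are summed (not
  averaged) per axis; this scales the index but not its sign or tests.

A noteworthy property, verified noise-free in development: with
independent per-object unique components, a symmetric unique shrink leaks
into the *shared* projection (the shared direction is the bisector of the
full patterns, which contains the symmetric part of the unique content),
and per-run centering couples the untrained means to the trained pair's
change through the grand mean — but both distortions are identical for the
two axes, so the trained-minus-untrained contrasts are exact: pure unique
shrinkage yields a negative unique contrast and a shared contrast of
exactly zero in the noise-free limit.

The geometric integration index is the shared contrast minus the unique
contrast (shared gain plus unique loss), positive for integration.

## Psychometrics

The categorical-perception model is p(x) = 1/(1 + e^−β(x−μ)) on the 0–100
morph scale, sampled at the 13 printed steps with 12 repetitions each.
"Slope" throughout is the steepness β = 1/s, so a shallower curve gives a
smaller slope and the integration index β₁ − β₅ is positive for
integration; the s-parameterization is exposed for conversion. Fits are
penalized maximum likelihood (ridge 10⁻⁶ on β, L-BFGS-B with three μ
starts; the fixed-μ refit is a bounded scalar minimization), with β capped
at ±10 and flagged under complete separation (every morph level answered
unanimously). Fits accept fractional success counts, so noise-free
expected-value data can be fitted exactly.

Two small systematic effects of the estimator are worth knowing: the free
fit's β is slightly biased away from zero (≈ +5% at the default design
size, the usual ML logistic bias), and fixing μ at a noisy session-1
estimate slightly attenuates the session-5 slope. Together they give the
*untrained* behavioural index a small positive offset (≈ +0.01 at β = 0.2)
that is shared by the trained axis and removed by the trained-minus-
untrained contrast. Generating slopes default to β₁ = 0.2 (s = 5 morph
units, a transition spanning roughly the central five steps) and
β₅ = 0.12 on the trained axis at full learning strength; much steeper
generating slopes make the 13-step design nearly separable and the free
fit unstable.

## Group statistics

The bootstrap resamples participants with replacement (1000 iterations by
default), reports the percentile 2.5/97.5 interval, and defines the sign
p as the fraction of iteration means whose sign opposes the observed mean
(1 by convention for a zero mean). A doubling flag provides the two-sided
variant. The p is used directionally: the pipeline's hypotheses predict a
positive effect, and a claim requires the predicted sign together with a
small sign p.

Calibration, measured on null cohorts of 20: the *directional* claim at
the 0.05 level occurs in ≈7% of null cohorts — slightly anticonservative,
as expected for a percentile-bootstrap test at n = 20 (the implicit
normal-quantile threshold understates the t quantile); the literal
one-sided `p_sign < 0.05` alone, ignoring direction, occurs in ≈14% and
should not be read as a 5% test. The test-suite calibration check uses the
full-scale design: reducing runs and voxels coarsens the fold AUCs and
visibly inflates these rates, so calibration must be assessed at the
design size actually analysed. The brain–behaviour Pearson correlation is
reported as a point estimate, with a participant-level bootstrap interval
available as an extension (the core procedure prescribes none).

## Problem sizes used by the test suite

Unit tests run on reduced designs (typically 30–60 voxels, 2–4 runs of
16–32 trials) chosen so each property is measured where it is informative.
The cohort-level recovery check runs 50 cohorts of 20 participants at the
full design; the null calibration check runs 200 null cohorts of 20 at the
full design with 1000-iteration bootstraps; closed-loop and psychometric
checks use 100 seeds at protocol sizes.

## Limitations

The generator omits hemodynamic convolution, temporal autocorrelation,
motion, physiological noise, viewpoint variability and anatomical
structure (parcels and ROIs are abstract index sets); classifier
performance on real BOLD data will differ, so passing recovery tests
demonstrates correctness of the analysis chain and adequacy of its power
under the stated noise model — not expected effect sizes in vivo. The
staircase is a plausible reconstruction, not the original step table. The
agent model bypasses the brain entirely: it emits classifier evidence
directly, so the closed-loop results validate the protocol logic, not any
claim about learnability of real neurofeedback.
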