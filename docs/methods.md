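# Methods

## The analysis problem

A behavioral session alternates between active task engagement and
passive listening to identical stimuli. Each trial is a sequence of
0.3 s narrowband noise distractors (0.2 s ISI) optionally ending in a
target tone at one of four SNRs (−10, −5, 0, Inf dB relative to 60 dB
SPL masking noise) or an explicit catch noise burst matched to the
target's masker. Spike counts are binned at 20 ms around each stimulus
event (100 ms baseline + 300 ms evoked window). The pipeline measures
how engagement changes (a) behavioral sensitivity, (b) single-neuron and
population discriminability of stimulus pairs, and (c) the structure of
stimulus-independent covariability, and then attributes population-level
changes to specific single-trial statistics via ablation simulations.

## Evoked responses and normalization

Single-trial responses are each neuron's mean z-scored rate over the
300 ms evoked window. Z-parameters (mean and SD of the binned rate) are
pooled across both behavioral states per neuron: active and passive d′
must share a scale for their difference to be meaningful, and pooling is
the only convention that guarantees this. Bins from both the baseline
and evoked windows enter the pooled moments; since z-scoring is affine
per neuron, downstream d′ values are unaffected by this choice. Active
trials ending in a false alarm are excluded, as are the pure-tone
reminder targets appended to catch trials (their responses are
confounded by reward delivery); hit, correct-reject and miss trials are
retained. Neurons with zero pooled SD are dropped and logged.

## Behavioral d′

d′ = Φ⁻¹(hit rate) − Φ⁻¹(catch response rate) per target SNR, with
rates estimated from n trials clipped to [1/(2n), 1 − 1/(2n)] — the
standard signal-detection convention for extreme rates; this bounds
|d′| by 2·Φ⁻¹(1 − 1/(2n)).

## Population decoding (dDR)

The optimal linear decoder's sensitivity is d′² = ΔμᵀΣ⁻¹Δμ with Δμ the
class-mean difference and Σ the stimulus-independent (within-class)
covariance. The full-space plug-in estimate of this quantity is
unusable at realistic trial counts: when trials are of the order of the
neuron count, the pooled covariance is near-singular and its inversion
explodes (the package's `plugin_dprime` demonstrates overestimation by
factors of ~70 at 100 neurons, 20 trials/class). Decoding therefore
projects onto the two-dimensional dDR plane spanned by:

* the signal axis: Δμ normalized;
* the noise axis: the leading eigenvector e₁ of the pooled within-class
  covariance, Gram–Schmidt orthogonalized against the signal axis and
  renormalized. If e₁ is numerically parallel to the signal axis the
  next eigenvector is used; if all are, a 1-D space is returned with a
  warning. Eigenvector sign is fixed (largest-magnitude element
  positive) for determinism.

Within the plane, Σ is the within-class covariance averaged over the
two stimuli, ridged by 1e−6 × trace for conditioning. Because the
plug-in Mahalanobis estimate still inflates as trial counts shrink —
and active trial counts (correct trials only) are systematically
smaller than passive ones, which would otherwise masquerade as an
engagement effect concentrated in target-vs-target pairs — the standard
small-sample correction is applied by default:

    D²_corrected = (ν − p − 1)/ν · D̂² − p(1/n_a + 1/n_b),  ν = n_a + n_b − 2

with p = 2 the plane dimension, clipped at zero. With isotropic private
noise plus rank-1 shared covariability the optimal discriminant lies
exactly in the dDR plane, so the validation suite uses that structure
to compare the pipeline against the closed form; with anisotropic
private noise the plane is strictly suboptimal and the pipeline's d′
correctly stays at or below the full-space analytic value.

Decoding runs per stimulus pair (re-fitting the plane each time, to
avoid bias from response-magnitude differences between pairs) and per
state, on correct trials only, with a ≥5-trial inclusion rule per
stimulus and state. Pairs are grouped as target-vs-catch
(task-relevant), target-vs-target and distractor-vs-distractor
(task-irrelevant). The engagement change is Δd′ = d′_active −
d′_passive, reported raw and normalized by the sum; category summaries
average over pairs within a session, and all cross-session tests
operate on those session means only. In-sample (debiased) d′ is the
default rather than cross-validated d′, keeping one d′ per pair/state
at small trial counts.

## Single neurons

Neural d′ per neuron is |Z[target] − Z[catch]|. Discrimination
significance: stimulus labels are permuted (100 resamples, one-sided,
actual > 95th percentile of the null, order-statistic percentiles).
Engagement change: active/passive labels are permuted within each
stimulus; significant if the observed Δd′ falls outside the central 95%
of the null. The realized level of these permutation tests is slightly
conservative (~4% at typical trial counts) because the null is
conditioned on the pooled sample; the calibration suite verifies both
stay within 2 points of nominal.

## Factor analysis of covariability

Catch-stimulus responses (the condition common to all task-relevant
comparisons) are fit per state with maximum-likelihood factor analysis,
Σ = LLᵀ + Ψ. In-sample likelihood never decreases with rank, so the
shared dimensionality is chosen by k-fold cross-validated log-likelihood
(default 10-fold; 5-fold where trials are few), scanning R = 1..R_max
with ties toward the smaller rank; R = 0 (pure diagonal) is available as
a closed form. Metrics:

* **Percent shared variance**: mean over neurons of
  100 · diag(LLᵀ)/(diag(LLᵀ) + Ψ).
* **Loading similarity**: 1 − N·Var(w) ∈ [0, 1] for the unit-norm
  dominant loading vector w (factor space rotated to its SVD basis so
  factors are ordered by explained shared variance); 1 means identical
  weights, 0 maximally dissimilar. Invariant to the sign of w.
* **Alignment**: |cos| between the dominant covariability axis and the
  discrimination axis (Δμ of a target vs the catch), per state.

## Ablation simulations

For each target and catch stimulus and each state, n = 2000 responses
are drawn from N(μ, LLᵀ + Ψ) using the per-condition factor fits (rank
selected once per condition and reused across models; the mean is the
condition's measured mean response). Four models tie progressively
fewer parameters to the active-state estimates:

| model      | passive mean | passive Ψ | passive Σ_shared |
|------------|--------------|-----------|------------------|
| null       | active       | active    | active           |
| gain_only  | passive      | active    | active           |
| indep_var  | passive      | passive   | active           |
| shared_var | passive      | passive   | passive          |

(The active side always uses active estimates.) Simulated responses
feed the identical dDR decoding, so differences in model performance
isolate the ablated parameters. Selective enhancement is the difference
of category-mean Δd′ (target-vs-catch minus target-vs-target); the
normalized Δd′ is used by default, matching the category statistics.
Model performance is the Pearson correlation between simulated and
measured selective enhancement across sessions; each model is compared
to the full (shared_var) model via 1000 bootstrap resamples of sessions
— a model is significantly worse if the 97.5th percentile of its
bootstrap correlation distribution falls below the full model's
observed correlation.

## Pupil control

Pupil size is aligned to spikes with a 750 ms lag and summarized per
event as the mean over the (lagged) evoked window. Per neuron and
stimulus (states pooled), r = αp + β is fit by OLS and the centered
term α(p − p̄) subtracted, which removes pupil-correlated variability
while preserving the per-stimulus mean exactly; the correction is
idempotent and skipped (with a log message) for groups under 3 events.
Pre-trial pupil (1 s before trial onset, configurable) is compared
between correct/hit/miss outcome classes with two-sided rank-sum tests.

## Choice probability

Hit vs miss trials per target stimulus are decoded with leave-one-out
cross-validation: within each fold the dDR plane, the discriminant
Σ⁻¹Δμ and the midpoint threshold are fit on training trials only.
Reported as percent correct. Under the null, LOO percent correct is
mildly conservative (mean ~49.5% rather than 50% at 20 trials/class)
because train and test sets are negatively coupled; fully separated
classes decode at exactly 100%.

## Session-level statistics

Category comparisons use two-sided Wilcoxon signed-rank tests on
session means (α = 0.05; fewer than 5 pairs is flagged underpowered).
The neural–behavioral analysis correlates the raw target-vs-catch Δd′
with behavioral d′ over (session, target) pairs; significance is
one-sided, observed r above the 97.5th percentile of a null built by
shuffling the pairing (1000 resamples), with a percentile bootstrap 95%
CI. All resampling is seed-deterministic.

## Synthetic data generator

The generator emulates the study structure, not its biology. Trials:
flat-hazard distractor counts (constant per-position stop probability
0.35, max 5 — both unspecified in the task description and
configurable), catch trials concluded by a reminder pure tone, outcomes
drawn independently per trial from configured psychometric rates
(defaults rise from 0.35 at −10 dB to 0.95 at Inf dB against a 0.15
catch false-alarm rate, giving behavioral d′ ≈ 0.7–2.6). Populations:
60 neurons, 25 trials per stimulus and state by default — the scale at
which the ≥5-trial inclusion rule starts to bind; baseline rates 10–30
Hz; target means are the catch mean plus an SNR-scaled tone-response
vector (nonzero in half the neurons); private variance is Poisson-like
(Ψ = 1.2 × mean count) and the shared component is rank-2 with ~25%
shared variance, cortex-like values. Latent Gaussian draws are rounded,
clipped at zero and spread across the 15 evoked bins with an
onset-weighted profile (the analysis consumes window sums and z-scores,
so exact count marginals are not constrained). The pupil trace is an
Ornstein–Uhlenbeck walk rescaled to [0, 1] with an upward offset during
the active block; coupled neurons (30%) receive α·p added to their
evoked counts, with the same lag convention the analysis uses.

Two region modes define the engagement effect:

* **dPEG_like** (non-primary): engagement adds a common boost δ along
  the tone direction to every target mean — targets move away from the
  catch mean and toward each other (a categorical enhancement);
  target-vs-target and distractor contrasts are analytically unchanged,
  so ground-truth selective enhancement is positive.
* **A1_like** (primary): engagement multiplies every stimulus's evoked
  component by one gain g ∈ [1.2, 1.6], scaling all contrasts equally;
  ground-truth selective enhancement is exactly zero.

Optional switches rotate the dominant active-state loading toward the
discrimination axis and rescale active private variance, for exercising
the ablation ladder with covariance-dependent effects.

Validation ensembles use 12 sessions with the gain boost δ on a fixed
grid from 0.3 to 2.4: a correlation-based model comparison is only
interpretable when across-session variance in the true effect dominates
per-session estimation noise, so the ensemble is designed to span weak
to strong effects (as the real sessions' spread does). For ensembles
whose defining property is "gain is the only state change", pupil
coupling is disabled — an engagement-correlated pupil offset is itself
a state change.

## What the generator does not emulate

No spiking point process (counts are rounded Gaussians), no receptive
fields or tuning curves, no reaction times, no learning or satiation,
no coupling between behavioral outcomes and neural effect size, and no
outcome-dependent pupil dynamics by default. Consequently passing tests
demonstrate the estimators and the attribution logic, not biological
claims; in particular the neural–behavioral correlation on default
synthetic ensembles is near zero by construction (behavioral rates are
configured, not driven by the neural gain change), and the reported
value for it should be read as a calibration of the machinery.

## Numerical choices and known limitations

* Ridge 1e−6 × trace on every 2×2 decoder covariance; the summary-stat
  primitive `dprime_from_stats` applies no ridge by default.
* FA private variances floored at 1e−12; EM non-convergence raises.
* Small-sample d′ correction removes most, not all, trial-count
  artifacts: the dDR axes are themselves estimated in-sample, leaving a
  residual inflation of order tr(Σ)/(n‖Δμ‖²) that is largest for pairs
  where both classes are hit-limited. On primary-like null ensembles
  this can surface as small spurious differences between the two
  *irrelevant* categories (distractor pairs have many more trials than
  target pairs); the task-relevance contrast (target-vs-catch vs
  target-vs-target) compares pairs with matched trial statistics and is
  unaffected.
* Permutation tests at 100 resamples have attainable levels of ~4–5.9%
  and run slightly conservative (see above).
* Problem sizes for the validation suite and acceptance script — 12
  sessions per ensemble, 2000 simulation samples, 5000 trials/class for
  closed-form comparisons, 100–1500 Monte-Carlo replicates per
  calibration — were chosen so every check resolves its tolerance with
  margin while the whole suite stays desk-scale.
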