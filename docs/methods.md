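# Methods

## Model and procedure

The pipeline estimates, for every token of a timed narrative transcript
and six sliding context windows (15–90 s in 15 s steps), two
language-model quantities, and tests them as fMRI encoding predictors.

**Context windows.** For target token *i* with onset *t<sub>i</sub>*,
the context at window size *W* is the set of earlier tokens with onset
in the half-open interval [*t<sub>i</sub>* − *W*, *t<sub>i</sub>*).
Membership is anchored on token *onsets* (not offsets) and the target
is excluded; both are deliberate conventions, since only the interval's
duration is substantively constrained. Contexts are nested across
window sizes, and context size is non-decreasing in *W* (both
property-tested). Targets earlier than *W* seconds into the narrative
keep their truncated context and are flagged `is_full = False`; the
very first token has no context and its surprisal is null (a
configurable policy can make this an error instead).

**Surprisal.** `-log10 P(token | context)`, with the probability taken
from the LM's next-token distribution after feeding it the context
tokens. Probabilities are clamped at 1e−12 before the log; softmax
outputs are strictly positive, so the clamp only guards pathological
adapters.

**Saliency (GradientXInput).** For each prediction event, the weight of
context token *j* is the L2 norm of the elementwise product of its
embedding with the gradient of the predicted token's score with respect
to that embedding; the vector is then normalized by its sum. The
"score" is the pre-softmax logit of the target class by default
(configurable to the log-probability): logit gradients are the common
GradientXInput convention, and the per-context-token reading of the
norm is the standard one. An all-zero raw vector (degenerate gradient)
maps to uniform weights by default, or raises.

**From per-prediction vectors to a per-token predictor.** The exact
construction of a single fMRI regressor from the per-prediction
saliency vectors is a genuine configuration point; the default,
`mean_received`, gives each token the mean weight it received across
all *full-window* predictions whose context contains it
(`sum_received` and `last_prediction` are exposed as alternatives, and
`sum_received` conserves mass: the series total equals the number of
contributing predictions). Predictions with truncated windows are
excluded, which is what makes the saliency analysis use fewer fMRI time
points at larger windows. Tokens covered by no full-window context are
null and contribute nothing downstream.

**The toy decay LM.** The built-in adapter pools context embeddings
with an exponential recency decay, g = Σ<sub>j</sub> γ<sup>n−j</sup>
X<sub>j</sub>, and scores classes linearly, logits = U·g. It is
deterministic given (E, U, γ), differentiable in closed form (the logit
gradient w.r.t. row *j* is exactly γ<sup>n−j</sup>·U<sub>c</sub>), and
exposes recency weighting analogous to attention. A central
finite-difference routine serves as an independent gradient oracle in
the tests (agreement to relative error < 1e−4 at step 1e−5). Real
pretrained transformers can implement the same three-method protocol;
nothing in the test suite requires one.

**Predictor construction.** Token metrics become impulses at token
onsets on a fine grid (dt = 0.1 s), amplitude-modulated by the metric
value; events sharing a bin sum. Events are impulses rather than
duration boxcars because word duration enters separately as a nuisance
regressor, so duration is not double-encoded. The HRF is the canonical
double-gamma difference (response peak 6 s, undershoot peak 16 s,
dispersions 1 s, undershoot ratio 1/6, kernel length 32 s; all
configurable), sampled at dt and normalized to unit peak; the gamma
shape is delay/dispersion + 1 so the mode sits exactly at the stated
delay. The convolved series is sampled at t = k·TR for k = 0…T−1
(TR = 1 s, T = 709 by default) with zero-padding if the scan outlasts
the stimulus.

**Validity mask.** The saliency analysis drops the first
⌈(W + buffer)/TR⌉ volumes; with buffer = 11 s, TR = 1 s, T = 709 this
yields 683, 668, 653, 638, 623, 608 valid points for W = 15…90 s. The
11 s buffer is a calibration that reproduces that bookkeeping, not an
independently specified constant, and it is exposed in the
configuration. The surprisal analysis uses all T points.

**Design and GLM.** The design per (metric, window) is intercept +
interest + word duration (WD) + log10 lexical frequency (LF) + word
sound (WS, a supplied audio-envelope series interpolated onto the fMRI
grid). WD and LF pass through the same event→HRF path as the interest
regressor; non-intercept columns are z-scored within the valid mask;
rank deficiency raises `collinear-design`. First level: per subject and
condition, OLS of every ROI column on the masked design (exact
normal-equations solution; residual orthogonality is asserted to
1e−8). The forward and backward runs are fitted separately with the
same forward-text-derived regressors — the control condition shares the
acoustics, not the language, so the contrast of interest is the FW−BW
difference of the interest beta. Second level: one-sample t across
subjects on the per-ROI contrasts (dof = S−1), one-sided positive
(FW > BW) by default, Bonferroni-corrected over the number of ROIs
tested (overridable to a fixed atlas size such as 1000). ROIs with
zero contrast variance get a ±∞ t sentinel. Whether the two conditions
should enter one combined model or two run-level fits is not
substantively determined; separate fits with a second-level contrast is
the implemented choice. Optional per-ROI AR(1) prewhitening was
considered and left out of the default path; the group-level t on
subject contrasts is robust to first-level autocorrelation because the
subject betas, not their first-level SEs, carry the inference.

## Synthetic data: what it emulates, and what it does not

`synthetic_data` reproduces the study's scale: 2,512 tokens over a
~12-min narrative (≈3.54 tokens/s, giving ≈53 context tokens per 15 s
window), 63% full words (1589/2512), 27 subjects, 709 volumes at
TR = 1 s, two conditions, and 100 ROIs by default (1000 behind the
`paper-scale` profile; 100 keeps desk-scale runtimes while exercising
the same multiple-testing arithmetic). Token onsets follow a gamma
renewal process whose interval coefficient of variation defaults to 1,
which matches the study's reported dispersion of per-window token
counts (sd ≈ √mean); the onset axis is rescaled so the narrative fits
its stated duration. Token identities are Zipf(1.1) draws and lexical
frequency is the Zipf probability per million, so LF is consistent with
the token statistics by construction.

BOLD is Gaussian AR(1) per ROI (lag-1 coefficient 0.3, stationary sd 1
by default), independent across ROIs. The forward run adds the planted
betas times the z-scored predictor in the designated effect ROIs; the
backward run carries only the word-sound effect plus independent noise.
Not emulated: spatial correlation between ROIs, scanner drift and
motion artifacts, real linguistic structure (the toy LM's surprisal
saturates once contexts exceed its effective memory ~1/(1−γ) tokens,
so, unlike a real LM, its mean surprisal barely varies across windows),
and subject-level HRF variability. Passing tests therefore demonstrate
the statistical machinery — calibration of the Bonferroni contrast,
exact OLS recovery, mask/dof bookkeeping — on data meeting the model's
assumptions, not performance on real fMRI.

## Numerical choices

- Natural-log softmax internally (scipy), base-10 only at the surprisal
  formula.
- Probability floor 1e−12; saliency normalization tolerance 1e−9;
  gradient-vs-FD tolerance 1e−4 at step 1e−5; OLS orthogonality 1e−8.
- Double-gamma kernel normalized to unit peak (beta scaling is absorbed
  by the z-scoring of design columns anyway).
- Resampling takes the nearest fine-grid bin of each TR tick
  (dt = 0.1 s, so within 50 ms).
- Ties in a bin: amplitudes sum (additivity of the linear model).
- Determinism: every simulated artifact is a pure function of
  `SimConfig` including its seed; the run manifest records a config
  hash and per-file checksums.

## Monte-Carlo studies and problem sizes

`studies.fwer_study` runs 200 null replicates (no planted effect,
S = 27, R = 100, T = 709), reusing one stimulus and redrawing only the
noise — the quantity under study — and counts replicates with any
Bonferroni-flagged ROI; the check allows the nominal 0.05 plus two
Monte-Carlo standard errors. `studies.power_study` plants β = 1 (on the
z-scored surprisal predictor, noise sd 1, AR1 0.3) in 5 of 100 ROIs and
scores the fraction recovered over 10 replicates; at this scale the
per-subject contrast SE is ≈0.05, so the group t on the planted ROIs is
enormous and sensitivity is expected (and observed) to be 1.0. These
sizes were chosen so the whole suite runs in about a minute on one CPU.

## Known limitations

- The `mean_received` saliency aggregation is an explicit stand-in for
  a construction that is underdetermined; conclusions that depend on
  the exact aggregation should vary the `saliency_aggregation` setting.
- The 11 s mask buffer is reverse-engineered from the valid-time-point
  bookkeeping, as is TR = 1 s.
- The toy LM is a linear pooler: it validates gradients, normalization,
  and plumbing exactly, but its surprisal series lacks the long-range
  context sensitivity of a real transformer.
- Headline ROI counts from the original study (e.g. 144/40/17
  significant ROIs) depend on real fMRI data and are out of reach of
  the synthetic generator by design.
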