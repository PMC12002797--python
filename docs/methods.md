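# Methods

`socialddm` models how people *perceive* other people's merit (deservingness)
and need, and how those perceptions translate into *altruistic action*. It
implements two multi-attribute drift-diffusion models (DDMs), the model-free
generosity metrics of a modified dictator game, the individual-differences
statistics that link the two tasks, and seeded generators that produce both
task designs with the statistical structure the analysis assumes.

## 1. Diffusion engine (`socialddm.ddm`)

Both behavioral models reduce each trial to a two-boundary constant-drift
Wiener process: evidence `x(t)` starts at `z = w·a` between a lower boundary
at 0 and an upper boundary at `a`, drifts at rate `v`, and diffuses with
noise scale `σ`. The first boundary reached determines the choice; observed
response time is the first-passage time plus a non-decision time `ndt`.

* **Scaling convention.** `σ` is fixed at 1 (drift-side parameters are
  identified only relative to the noise scale); the engine accepts other
  values of `σ` and renormalizes internally (`v/σ`, `a/σ`).
* **Choice probability.** Closed form
  `P(upper) = (1 − e^{−2vz/σ²}) / (1 − e^{−2va/σ²})`, computed with `expm1`
  and continuous at `v = 0` where it equals `w`.
* **Likelihood.** The first-passage density at the lower boundary uses the
  standard small-time / large-time series expansions, switching by the
  usual required-number-of-terms criterion at a truncation error target of
  1e-7. The upper boundary follows by reflection,
  `f_upper(t|v,a,w) = f_lower(t|−v,a,1−w)`. The per-trial log-likelihood is
  floored (default −1e10, configurable) for observations with `rt ≤ ndt` so
  optimizers never see −inf; fitting bounds keep `ndt` below the minimum
  observed RT, so the floor is an off-path guard.
* **Simulator.** Euler–Maruyama with step `dt` (default 1e-3 for data
  generation), augmented with the standard Brownian-bridge within-step
  crossing test and midpoint crossing-time assignment. Plain EM has an
  O(√dt) first-passage bias of the same order as the oracle tolerances used
  in the tests; the bridge correction plus midpoint assignment reduce the
  bias to O(dt). Both corrections are toggleable (`bridge=False` gives plain
  EM). Paths that do not absorb within `max_time` (default 20 s) are
  returned flagged, never dropped. The inner loop is numba-compiled;
  simulation is deterministic given the integer seed.

## 2. Social-perception model (`socialddm.perception`)

On each trial of the speeded yes/no judgment task the drift is

    v = Bias_c + S[c][merit]·Merit + S[c][need]·Need + S[c][control]·Control

where `c` is the judgment condition (merit / need / control block), the
evidence values are the *mean-centered* normative "yes" proportions of the
displayed image (centering over the full 64-stimulus set, stored with the
dataset), "yes" maps to the upper boundary, and each condition carries its
own threshold, non-decision time and start fraction. A subject has 18
parameters: a 3×3 sensitivity matrix (task-relevant diagonal, task-irrelevant
off-diagonal), 3 evidence biases, 3 thresholds, 3 ndts, 3 start fractions.

**Estimation.** The three conditions share no parameters, so the subject fit
factorizes into three 7-parameter maximum-likelihood problems. Each is
solved with L-BFGS-B from a choice-informed start (a logistic approximation:
at `w = ½`, `P(yes) ≈ logistic(v·a)`) plus seeded random restarts (default
8; the test harness uses 3 for budget). Bounds: `S ∈ [−10,10]`,
`Bias ∈ [−5,5]`, `a ∈ [0.3,5]`, `w ∈ [0.05,0.95]`,
`ndt ∈ [0.05, min RT − 0.01]`. Responses outside the 2-s display window are
treated as missing and excluded from the likelihood. An optional *shrinkage*
mode refits every subject under normal priors whose hyper-mean/SD are the
first-stage MLE moments across subjects — an explicit, documented stand-in
for full hierarchical pooling, not a replication of it.

**What a fit can and cannot recover.** With 64 trials per condition the
per-subject sampling SD of a task-relevant sensitivity is ≈0.6–0.7 (measured
by refitting replicate datasets of one subject). With between-subject true
SDs of 0.69–1.02 this caps the attainable true-vs-recovered Pearson
correlation at roughly 0.7–0.83; bias parameters (sampling SD 0.2–0.3) are
recovered much better (r ≈ 0.76–0.85 at n=30). Shrinkage reduces RMSE but,
being approximately a linear rescaling toward the mean, does not raise the
correlation. This ceiling is a property of the design size, not of the
optimizer: the likelihood-identity and profile tests confirm the objective
is computed and maximized correctly.

## 3. Altruistic-choice model (`socialddm.altruism`)

Each accept/reject decision over a proposed allocation (vs. the constant
$20/$20 default) accumulates value evidence with drift

    v = w0 + w_self·Self + w_other·Other + w_fairness·Fairness

with `Self = (offer_self − 20)/10`, `Other = (offer_other − 20)/10`,
`Fairness = −|Other − Self|` (computed on the rescaled values; a raw-dollar
convention would only rescale `w_fairness` by 10). Accept maps to the upper
boundary. Each of the four weights has a baseline (reference condition:
unknown merit, low need) plus three additive change parameters — high merit,
low merit, high need — with no merit×need interaction; threshold,
non-decision time and start fraction are shared across the six conditions.
That gives 19 parameters, estimated jointly by multi-start L-BFGS-B with a
least-squares choice-informed start. Change scores are
`Δw(merit) = δ_merit_high − δ_merit_low` and `Δw(need) = δ_need_high`
(identical to differencing the condition-resolved weights); the *overall*
weight is the unweighted mean over the six cells.

The four-point response scale of the original task ("strong no" … "strong
yes") is collapsed to binary accept/reject; the deltas are weight-specific
(12 of them) rather than shared across weights — the shared-3 alternative
is strictly nested and can be imposed by bounding the extra parameters.

**Recovery precision.** At 300 trials the baseline weights recover very
well (r ≈ 0.85–0.96 across a 20-subject cohort; w0 ≈ 0.70). Change
parameters are estimated from the ~100–150 trials of their condition, so
their sampling SD (0.15–0.26, unbiased, worse for subjects with high
thresholds or extreme accept rates) is comparable to a between-subject
delta spread of 0.18; individual delta correlations therefore range
roughly 0.3–0.9 depending on the attribute, while the *sign* of a
generated need effect on other-regard is recovered in ≥ 85% of subjects.

## 4. Behavioral metrics (`socialddm.metrics`)

A choice is *generous* if it accepts a proposal with `$Self < $Other` or
rejects one with `$Self > $Other`; equal-payoff proposals involve no
trade-off, are unclassifiable, and are excluded from fractions but counted.
The buy-out rule converts dollars to cold-pressor (CPT) probability at 10
percentage points per dollar, clamped at 0%. Quality control drops subjects
whose modal response exceeds 90% of trials (strictly greater, as printed:
exactly 90% is kept) or who have too few trials.

## 5. Linking statistics (`socialddm.stats`, `socialddm.glmm`)

* **Mixed logistic model of generous choice.**
  `generous ~ 1 + Need + Merit + Need×Merit + (1|subject)`, dummy-coded with
  low need / low merit reference levels. The marginal likelihood of the
  random intercept is maximized with adaptive Gauss–Hermite quadrature
  (default 15 nodes; 1 node recovers the Laplace approximation), each
  subject's node set centered on the posterior mode found by Newton steps.
  Verified during development to agree with lme4's `glmer` (nAGQ=15) to four
  decimals in coefficients, random-effect SD and log-likelihood; the test
  suite checks the σ→0 limit against a plain statsmodels GLM. LRT
  chi-squares compare full vs. random-intercept-only null (5 df) and
  interaction vs. main effects (2 df). The reported pseudo-R² is the
  latent-scale marginal/conditional pair (fixed-effect variance over
  fixed + random + π²/3). Quasi-separation (|β| > 10) triggers a flagged
  ridge-penalized refit.
* **Condition contrasts.** Paired Wilcoxon signed-rank tests per attribute
  and manipulation (six tests, one BH family); exact distribution for
  n ≤ 25 without ties, normal approximation otherwise; degenerate all-zero
  differences reported as p = 1 with a flag.
* **Correlations.** Spearman with midranks; two-tailed p by exact
  permutation enumeration for n ≤ 8 and the t-approximation above (full
  enumeration beyond 8! is not desk-scale). Batteries are BH-adjusted
  within the declared family; each variable is screened by the single-pass
  3-SD rule (mean/SD from the full vector, no iteration) before
  correlation, and a subject removed from either member of a pair is
  removed from that pair.
* **Partial correlation** controlling for the inter-task delay: Spearman of
  the residuals of the rank-transformed variables after linear regression
  on the rank-transformed control (agrees with pingouin's
  `partial_corr(method="spearman")`).
* **Linking regression.** OLS `Δw ~ 1 + S_merit + rTPJ` with Wald CIs, the
  F test against the intercept-only model, and a collinearity flag at
  |r| > 0.99 between predictors.

## 6. Synthetic world (`socialddm.synth`)

The generators state one concrete world and keep it in an editable config:

* **Normative stimuli.** 64 images; per-dimension "yes" proportions drawn
  from Beta marginals through a Gaussian copula. Means are the reported
  mean response rates (merit 56.7%, need 48.7%, control 54.9%); the
  concentration is 2.0, spanning roughly 0.1–0.9 — a stimulus set built to
  contain clear exemplars at both ends of each judgment dimension.
  Merit–need evidence correlation defaults to 0.3.
* **Perception task.** 64 stimuli × 3 conditions = 192 trials per subject,
  2-s response window (overtime trials marked missing, not dropped).
* **Altruism task.** 300 trials = 5 runs × 3 partner blocks × 20 trials,
  100 per partner, 50 high-need + 50 low-need each in random order; need
  cues 80 or 20 plus a symmetric integer jitter on [−4, +4] (honoring the
  "±4" band over the ambiguous one-sided reading; toggleable via
  `jitter_band`); base proposals from a $5–$35 grid with 75% of trials in
  the trade-off quadrants, then a $0–$4 jitter; partner-block order rotated
  across subjects.
* **Cohort.** Subject-level parameters are normal draws centered on the
  reported group statistics (sensitivities 2.84/3.28/4.40 ± 1.02/0.75/0.69;
  biases 0.33/−0.17/0.09 ± 0.47/0.39/0.36; overall attribute weights
  0.97/0.22/0.35, back-computed into baselines given the delta means).
  Unreported nuisance parameters use field-typical values: perception
  a = 1.5 ± 0.25, ndt = 0.35 ± 0.05 s, w = 0.5 ± 0.05; altruism
  a = 1.8 ± 0.3, ndt = 0.5 ± 0.1 s. Delta means follow the directions of
  the reported contrasts (high merit and high need raise other-regard and
  lower self-regard; high need lowers the fairness weight) with SD 0.18.
  Couplings give the linking stage something to find: merit-bias/need-bias
  correlation 0.73; a merit-responsiveness latent correlates merit
  sensitivity with the merit deltas (0.7); merit bias couples to baseline
  other-regard (0.6); the rTPJ-like covariate is standardized merit
  sensitivity plus N(0, 0.8) noise. Inter-task delays are uniform on
  27–663 days.
* **What the generator does not emulate:** real image content, sequential
  or learning effects, RT contaminants (fast guesses, lapses),
  within-subject parameter drift over the ~10-month delay, and fMRI noise
  structure (the neural covariate is a one-number stand-in). A green
  recovery or sign test therefore establishes correctness of the estimators
  under the model's own assumptions, not robustness to their violation.

## 7. Numerical choices and degenerate inputs

* Series truncation error 1e-7; quadrature tolerances 1e-4 for
  conservation checks; reference CDFs for simulation oracles use a grid
  log-dense near zero because the density can peak within milliseconds
  when a boundary is close.
* Optimizer: L-BFGS-B with numerical gradients; restarts are seeded and
  the best solution is kept; non-convergence of every restart is flagged,
  never silent.
* Degenerate data: too few trials or missing design cells raise
  immediately with the offending cells listed; constant vectors raise in
  correlation routines; zero-variance outlier screening removes nothing;
  empty generosity cells warn and report NaN.

## 8. Known limitations

* Per-subject maximum likelihood at the printed design sizes cannot match
  the individual-level precision of the original hierarchical Bayesian
  fits; the measured consequences for recovery correlations are given in
  §2, and the shrinkage mode is an approximation, not a replication.
* No across-trial variability parameters (sv, st, sz), collapsing bounds,
  or attention-weighted variants.
* The mixed model supports a single random intercept (the design the
  analysis needs), not arbitrary random-effect structures.
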