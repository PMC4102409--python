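# Methods

## The task and the generative model

`audcat` models a two-alternative auditory categorization experiment. On
each trial a tone burst is drawn from one of two categories of frequencies,
**A** (low) and **B** (high). The stimulus range 500–5550 Hz is divided, in
log units, into two equal but overlapping piecewise-uniform category
distributions: A occupies the lower two-thirds of the range (500–2488 Hz),
B the upper two-thirds (1115–5550 Hz), so the middle third (1115–2488 Hz)
is ambiguous. Block by block, the prior probability π that a trial comes
from A is 0.25, 0.5 or 0.75.

The observer is modeled generatively. A tone of log-frequency *x* produces
a noisy sensory measurement *m* ~ Normal(*x*, σ_s). Given *m*, the observer
computes category likelihoods by marginalizing over frequency,

    L_C(m) = ∫ N(m; x, σ_s) p(x | C) dx,

which for a box (optionally Gaussian-smoothed) category has the closed form
of a difference of two normal CDFs at the box edges with effective SD
√(σ_s² + σ_cat²), divided by the box width. The posterior for A is
π·L_A / (π·L_A + (1−π)·L_B). Two decision rules are implemented:

* **MAP** — choose the category with the larger posterior (optimal for
  accuracy). For monotone posteriors this reduces to a single criterion
  m\*, and the psychometric function ψ(f) = P(choose A | f) is the normal
  CDF Φ((m\* − x(f))/σ_s).
* **MATCH** — probability matching: choose A with probability equal to the
  posterior. ψ(f) is the posterior averaged over the measurement
  distribution, computed with a fixed 129-node Gauss–Hermite rule.

Category distributions come in two families. *Objective* categories are
the experiment's true boxes. *Subjective* categories describe what an
observer may actually have learned: boxes with free centers μ_A, μ_B, a
shared width w and a shared Gaussian smoothing SD σ_cat.

## Units and scale

All internal computation uses log2 frequency (octaves); σ_s, σ_cat, w and
μ are in octaves and Hz appears only at interfaces. The model's math is
invariant to the log base as long as every σ is expressed on the same
scale; octaves are the auditory convention and are used throughout.

## Sensory noise from the discrimination task

σ_s is not a free parameter of the core analyses: it is measured by a
separate two-interval 2AFC discrimination task. The psychometric function
(probability of judging the comparison higher vs. the log-frequency offset
Δ) is fit by maximum likelihood with a cumulative Gaussian Φ((Δ − μ)/σ_fit)
on raw trials; the bias μ is left free. Under the equal-variance
difference model, two independent measurements subtract, so the
single-interval threshold is σ_d = σ_fit/√2. A subject's σ_s is the mean
σ_d over the eight standard frequencies (794–4976 Hz). Bootstrap CIs use
1000 nonparametric trial resamples (percentile intervals), refit from the
point estimate.

## Synthetic data

No behavioral data ship with the package; the `synthetic_data` module
generates the full experiment with the design's statistical structure:

* **Categorization** — sessions contain one block per prior condition
  (order shuffled per session); within a block the true category is
  Bernoulli(π) and the frequency is uniform in log units on the category's
  support. Defaults are 3 sessions × 234 trials/block (≈700 trials per
  condition, within the experiment's 600–1000 range). Responses are
  simulated from any observer model; an optional lapse fraction (default
  0) marks trials `choice = none` to exercise the responded-trials-only
  filter, without modeling human lapse mechanisms.
* **Discrimination** — 2-up-1-down adaptive staircases (40 trials per
  track, 4 tracks per standard by default). The schedule is a
  Levitt-style convention (the design does not pin it down): initial
  offset 0.5 octaves, multiplicative steps with factor 0.5 until four
  reversals and 0.75 after, floor 0.005 octaves, comparison placed above
  or below the standard at random. Simulated responses are correct with
  probability Φ(|Δ|/(σ_d√2)), so tracks converge near the 70.7%-correct
  offset (≈0.0154 octaves at σ_d = 0.02).

Randomness flows from one root seed through deterministic child streams
per (subject, session, block), so any part regenerates independently and
byte-identically.

What the generator deliberately does *not* emulate: learning or
non-stationarity within a subject (the generative observer is stationary;
history effects are studied separately in the noise simulations), reaction
times, sequential dependencies, or any audio-level detail. Passing tests
therefore demonstrate that the analysis pipeline is correct and well
calibrated for a stationary Bayesian observer — not that real listeners
satisfy those assumptions.

## Descriptive psychometrics

Choice data are summarized per condition in nine equidistant log-frequency
bins anchored at the category edges (three bins per exclusive region,
three in the overlap; membership is half-open with the last bin closed).
Fits are *decreasing* cumulative Gaussians P(A|x) = 1 − Φ((x − μ)/σ) by
maximum likelihood on raw trials (bins serve display and the empirical
reference model only); the PSE is the frequency at μ. No lapse parameter
is used, matching the model (which has none). Per-session fits provide a
learning table; degenerate sessions are skipped with a warning.

## Model comparison

Three variants per decision rule:

| variant | categories | priors | σ_s | free parameters |
|---|---|---|---|---|
| prediction | objective | objective | measured, fixed | 0 |
| subjective-7 | subjective | π̂ per condition | measured, fixed | 7 |
| subjective-8 | subjective | π̂ per condition | free | 8 |

Fit quality is the total Bernoulli log-likelihood over responded trials,
with choice probabilities clamped to [1e−9, 1−1e−9]. It is rescaled
between a random-guessing reference, n·log(1/2), and an empirical
reference — a binomial model using each bin's observed choice probability
(0·log 0 := 0). Zero marks random guessing, one marks the data explaining
themselves; negative values mean worse than a random guess. The model
likelihood is trial-level while the empirical reference is bin-level (as
each is defined), so normalized values can marginally exceed 1; they are
reported untruncated.

Optimization is bounded L-BFGS-B from 20 Latin-hypercube starts (the first
start replaced by the objective-geometry guess), deterministic for a fixed
seed. Bounds: μ_A, μ_B within ±2 octaves of the objective centers, w ∈
[0.1, 6], σ_cat ∈ [1e−3, 3], π̂ ∈ [1e−3, 1−1e−3], σ_s ∈ [1e−3, 3] octaves.
A soft penalty keeps μ_A below μ_B, where the shared-width geometry
guarantees a monotone likelihood ratio and hence a single MAP criterion.
Whether the original analysis maximized trial-level or bin-level
likelihood is not documented; trial-level is used here.

Known identifiability limits, visible in the recovery experiments: with
MATCH data the overlap's plateau heights pin the π̂ parameters tightly,
but (μ, w) trade off against each other outside the stimulus range — the
*category edges* are identified, not the box centers — and σ_s trades off
against σ_cat (the choice curves constrain mainly σ_eff = √(σ_s²+σ_cat²)),
so the subjective-8 σ_s point estimate is loosely pinned at realistic
trial counts. The diagnostic contrast is robust: MATCH fits keep σ_s at
the measured scale while MAP fits to matching behavior inflate it by an
order of magnitude or more.

## Categorical-prior noise simulations

To ask whether an *optimal* rule with *non-stationary* priors can mimic
probability matching, the `prior_noise_sims` module perturbs the MAP
observer trial by trial and averages the resulting psychometric curves
(600 iterations by default):

* **mean noise** — each category center is displaced independently by
  Normal(0, σ_μ) each iteration (a common-shift option exists); averaging
  flattens the slope, and the net curve differs measurably from a single
  MAP observer with statically widened distributions of matched variance;
* **prior noise** — π′ = clip(π + Normal(0, σ_π), 0, 1); clipping (not
  resampling) matches the constraint that probabilities stay in [0, 1].
  At π = 0.5 any noise level produces a plateau at 0.5; at asymmetric π a
  plateau emerges above a noise threshold and its height moves with σ_π
  (over-, under- or true matching).

The eight default noise levels are geometric ladders, σ_μ ∈ [0.01, 1.28]
octaves and σ_π ∈ [0.01, 0.64] — the source analysis color-codes but does
not print its levels, so these are configurable conventions. Because mean
perturbations can reorder the categories, MAP curves in these simulations
are computed by locating every posterior 0.5-crossing rather than assuming
a single criterion.

The companion history analysis computes running estimates of π over
windows of consecutive trials (non-overlapping tiling by default; sliding
optional). Window fractions are binomial, with SD √(π(1−π)/L); for short
windows (≤16 trials) this variability sits in the same 0.1–0.25 range as
the σ_π levels that plateau the psychometric function, which is the
quantitative link between short-history prior estimation and apparent
probability matching.

## Numerical choices

* Gauss–Hermite order 129 for the MATCH measurement marginalization;
  validated against adaptive quadrature and Monte-Carlo simulation.
* With sharp boxes and small σ_s the posterior equals 0.5 to machine
  precision across the overlap interior. Criterion finding treats
  |posterior − 0.5| < 1e−12 as undecided and returns the midpoint of the
  undecided band (refined by predicate bisection) — the exact crossing of
  the symmetric design. For the same reason the observer simulator applies
  MAP through the criterion, not by comparing posteriors at machine
  precision.
* If both likelihoods underflow (unreachable within ±10σ of the stimulus
  range) the posterior falls back to the prior.
* MAP ties (posterior exactly 0.5) in `decide` are broken by a fair coin.
* Probit MLEs restart from five jittered method-of-moments starts with σ
  bounded in [1e−4, 2] octaves to avoid boundary collapse on sparse
  staircase data.
* Frequencies outside 500–5550 Hz are accepted by prediction (subjective
  supports may extend past the range) but flagged with a warning.

## Problem sizes used in the shipped tests

The test suite and acceptance script regenerate everything at run time.
Recovery experiments use one synthetic subject with 700 trials per
condition (the experiment's per-condition scale) and 160 staircase trials
per standard; unit-level property checks use smaller blocks (120–4000
trials) and Monte-Carlo checks 4×10⁴–10⁵ draws. Multi-start counts are 20
for the headline recovery fits and 2–12 in unit tests.
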