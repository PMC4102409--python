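# audcat

Bayesian-observer analysis of human auditory categorization under
overlapping categories.

## The problem

In a two-alternative categorization task, listeners judge whether a tone
burst (500–5550 Hz) belongs to a low-frequency category **A** or a
high-frequency category **B**. The categories are equal-width,
piecewise-uniform distributions in log frequency that overlap in the
middle third of the range (1115–2488 Hz), and the prior probability π of
category A varies by block (0.25, 0.5, 0.75). Because the overlap makes
the stimulus genuinely ambiguous, performance there reveals how listeners
combine sensory evidence with learned category distributions and priors —
and whether they decide *optimally* (maximum a posteriori, MAP) or by
*probability matching* (MATCH), sampling choices from the posterior.

`audcat` is for psychophysicists and computational modelers who want to
simulate this experiment, fit the generative observer to trial data, and
reproduce the associated model-comparison and noise analyses.

## The model

A tone of log2-frequency *x* yields a measurement *m* ~ N(*x*, σ_s), with
σ_s measured independently by a 2AFC frequency-discrimination task
(2-up-1-down staircases; threshold σ_d = σ_fit/√2, averaged over eight
standards). The observer computes L_C(m) = ∫ N(m; x, σ_s) p(x|C) dx and
the posterior p(A|m) = πL_A / (πL_A + (1−π)L_B), then decides by MAP or
MATCH. Category distributions are either the objective boxes or
*subjective* ones — boxes with free centers μ_A, μ_B, shared width w, and
Gaussian smoothing σ_cat. Model variants: a zero-free-parameter
*prediction* (objective priors, measured σ_s), a 7-parameter subjective
fit (σ_s fixed) and an 8-parameter fit (σ_s free). Fits are scored by the
normalized log-likelihood, scaled between a random-guessing model (0) and
the binned empirical model (1). See `docs/methods.md` for details.

## Worked example

Simulate a probability-matching subject (the default generative observer:
subjective categories smoothed by 0.1 octaves, σ_s = 0.02, MATCH rule),
estimate its discrimination threshold, and compare MAP vs MATCH fits.
With a config file `demo.yaml` containing `{seed: 1, out_dir: demo,
n_starts: 8, n_boot: 200}`:

```bash
audcat simulate -c demo.yaml
audcat discrim --trials demo/discrimination_S1.csv -c demo.yaml
audcat fit --trials demo/categorization_S1.csv --sigma-s 0.01677 -c demo.yaml
audcat report --dir demo
```

which prints (threshold stage, then report):

```
sigma_s = 0.01677 octaves (S1)
normalized log-likelihood by rule and variant:
  match prediction   norm_loglik=+0.896
  match subjective7  norm_loglik=+1.023
  match subjective8  norm_loglik=+1.023
    map prediction   norm_loglik=-6.985
    map subjective7  norm_loglik=-6.637
    map subjective8  norm_loglik=+0.896
best account: match subjective8
```

Reading the numbers: the discrimination stage recovers the generative
sensory noise (0.0168 vs 0.02 octaves). The MATCH prediction — with
*zero* free parameters — already explains the choices nearly as well as
the data explain themselves, and the subjective-priors MATCH fits reach
the empirical ceiling (values slightly above 1 reflect the trial-level
model vs bin-level reference, see methods); the 7-parameter MATCH fit
recovers the block priors as π̂ = (0.269, 0.498, 0.776). The MAP
prediction and 7-parameter fit at measured noise are far *worse than
random guessing*; freeing σ_s rescues MAP only by inflating it to 0.685
octaves — ~41× the measured threshold — and it still does not beat MATCH.

The library mirrors the CLI: `audcat.generate_trial_sequence`,
`simulate_observer`, `fit_discrimination_psychometric`,
`fit_choice_psychometric`, `fit_model`, `simulate_prior_noise`,
`running_prior_estimates`, etc.

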