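# Methods note

## Model

Whole report is modelled as an exponential race (TVA). With `n` letters
displayed, each letter is encoded independently with rate `C/n`
(elements/s divided over the display). The effective exposure is

```
tau = max(0, exposure − t0) + (µ if unmasked and exposure > t0 else 0)
```

so nothing is encoded below the perceptual threshold `t0`, and unmasked
displays gain the iconic-buffer persistence `µ`. Each letter finishes in
time with probability `p = 1 − exp(−(C/n)·tau)`; the number finished is
Binomial(n, p). VSTM capacity `K` truncates the score: for integer `k`,
`P(S = j) = P(F = j)` for `j < k` and `P(S = k) = P(F ≥ k)`. Fractional
`K` is a Bernoulli mixture of the caps `⌊K⌋` and `⌈K⌉` with weight
`K − ⌊K⌋` on the upper cap, drawn per trial.

All durations are seconds internally and milliseconds in files and CLI
flags.

## Parameters and defaults

| parameter | meaning | bounds used in fitting |
|---|---|---|
| C | processing speed, elements/s | [1, 200] |
| K | VSTM capacity, letters (may be fractional) | [0.5, max display size] |
| t0 | perceptual threshold, s | [0, min exposure] |
| µ | iconic-buffer duration, s | [0, 1] |

Fitting is maximum likelihood on the score counts, grouped per condition
(the cost is independent of trial count). The optimizer is Nelder–Mead
from a fixed 3×3×2×2 start grid (C ∈ {10, 25, 60}, K ∈ {2, 3.5, 5.5}
clipped to stay feasible given the highest observed score, t0 ∈ {1, 20}
ms, µ ∈ {100, 250} ms); the best of the 36 local fits is returned. Fit
quality is the Pearson correlation between empirical and fitted mean
scores per condition; cohort averages of fit quality go through a Fisher
z-transform. Bootstrap parameter uncertainty uses within-condition
resampling (default B = 500) with refits warm-started at the parent
estimate (a standard resampling economy; the full start grid is available
with `warm_start=False`).

The experimental design mirrors the study: {3, 6} letters ×
{D_min masked, D_min unmasked, D_min+70 ms masked, 200 ms masked,
200 ms unmasked}, 15 trials per condition, with the per-child minimum
exposure at the analytic 50% single-letter threshold
`D_min = t0 + ln 2 / C`. VA span is measured as the mean score over 20
trials of an unmasked 5-letter, 200 ms display.

## Synthetic cohorts

Two generators:

**Structural.** Children draw latent parameters (C truncated-normal
around 24.6 el/s, K clipped-normal around 3.6, t0 half-normal, µ normal
around 184 ms) with a shared latent factor inducing the C–K correlation.
VA span is simulated trial-by-trial from the race model; reading speed is
a linear function of age and VA span plus noise. One deliberate
departure from the bare race model: the VA-span task grants a capacity
bonus of +1 element. A capped score can never average above E[K] ≈ 3.6,
yet measured VA spans in this population centre near 4.1 — the
horizontal-string format confers a familiarity advantage over the
circular arrays used for TVA estimation, and the bonus encodes that gap.
Without it no parameterization of the capped model can reach the observed
VA-span mean. The structural generator is calibrated only loosely
(anchor means within wide bands); it exists for recovery studies and
end-to-end pipeline tests, not for reproducing the published table.

**Moment-exact.** Given target means, SDs, and a correlation matrix, a
Gaussian basis is orthonormalized by QR, scaled by √(n−1), and colored by
the Cholesky factor of the target correlation, making the *sample*
moments match the targets to machine precision. The seed only rotates
rows. Because published descriptives describe an already-screened cohort,
the generator optionally rejects draws containing any |z| > 2.5 row so
the emulated cohort passes the outlier screen untouched. Non-positive-
semidefinite targets are rejected with a pointer to the nearest-PSD
remedy.

## Statistical pipeline

Screening: one pass of univariate z-scores (threshold 2.5) over reading
speed, VA span, C, and K, with moments computed on the candidate set;
fit-quality screening removes children with empirical/fitted correlation
not above 0.75. Associations: Pearson correlations with t-distribution
p-values, age-controlled partial correlations by residualization, OLS via
statsmodels with standardized coefficients and added-variable
(partial-regression) data exported for plotting. Mediation: causal steps
(three regressions, verdict "total" when a, b, c are significant and c′
is not at α = .05); case-resampling bootstrap of a·b with a hand-rolled
BCa interval (bias correction from the bootstrap distribution's position
relative to the point estimate, acceleration from jackknife skewness);
κ² as the observed indirect effect over the maximum admissible indirect
effect (Preacher–Kelley), computed on covariate-residualized variables.
Sample-size conversions from published 95% CIs use the normal quantile:
`sd = half_width·√n / 1.96`.

## Numerical choices

- Grouped-count likelihood: per-condition score histograms make the NLL
  cost independent of trial count.
- `expm1` for encoding probabilities; direct binomial PMF evaluation (the
  display sizes are ≤ 6, so no log-gamma machinery is needed).
- Infeasible K starts (below the highest observed score) are clipped into
  the feasible region rather than discarded, keeping the start-grid size
  fixed.
- A single pipeline seed is fanned into per-stage streams by fixed
  offsets; the mediation workup further splits its stream so the a·b and
  κ² bootstraps are independent.

## Known limitations

- **Finite-sample ML bias at the study design.** With 15 trials per
  condition, Ĉ is biased upward by ≈ 0.6–0.9 el/s (≈ 3%) and K̂ downward
  by ≈ 0.05 across 50-child simulations — both larger than the
  between-child simulation SE at that scale. The estimator is consistent:
  at 150 trials per condition the biases fall to ≈ 0.1 el/s and ≈ 0.0005
  respectively, inside their simulation SEs. Interpret small group
  differences in C and K at desk-scale trial counts with this in mind.
- The structural generator's reading-speed equation is linear and its
  capacity bonus is a fixed offset; both are conveniences, not claims.
- κ² is used as published, but it does not reach 1 even for a noiseless
  mediation chain and is not monotone in all path configurations; the
  test suite asserts only the properties that hold.
- Problem sizes throughout (50 recovery children, B = 500–1000
  bootstraps, 10⁶-draw Monte-Carlo checks) are this package's own
  choices, balancing precision against desk-scale runtime.
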