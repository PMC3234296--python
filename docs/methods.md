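# Methods

This note documents the models and numerical choices behind `ampeff`, what
the synthetic-data generator does and does not emulate, and the known
limitations. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`.

## Efficiency from amplification curves

A qPCR trace is modelled as a 4-parameter logistic
F(c) = F0 + a/(1 + exp(−(c − m)/b)) on the baseline-corrected fluorescence.
The logistic has closed forms for every landmark the estimator needs:

- the second-derivative maximum (the take-off landmark) is at
  cpD2 = m − b·ln(2+√3), where the sigmoid has reached the fixed fraction
  1/(3+√3) ≈ 0.2113 of its amplitude;
- the quantification point *n* is where the amplified (baseline-free)
  component reaches 20% of its value at cpD2 — on a logistic this is the
  fixed fraction 0.2·0.2113 ≈ 0.0423 of the amplitude, so
  n = m + b·ln(u\*) with u\* = 0.0423/(1−0.0423) ≈ 0.04413 a shape constant;
- the efficiency is the per-cycle ratio of amplified product at that point,
  E = (F(n) − F0)/(F(n−1) − F0).

*n* is kept real-valued. Rounding it to an integer cycle would add a bias
that depends on the fractional part of the fitted midpoint (up to ±0.02 in
E) while buying nothing: E is evaluated on the fitted curve, which is
already smooth in noise. Likewise E is taken net of the fitted residual
baseline F0: after correction F0 is ≈ 0, but a shallow curve whose early
cycles leak into the correction window leaves |F0| up to ~2% of the
amplitude, and a ratio of totals rather than of amplified components would
be biased by up to +0.024 at low E.

### Baseline correction

- `standard`: subtract the mean of cycles 1–5.
- `dynamic_tube`: locate the take-off as the maximum of the smoothed
  (window-3 moving average) finite-difference second derivative and subtract
  the mean of all cycles before it; a flat trace falls back to `standard`
  with a warning. On simulated sigmoids the recovered baseline is within a
  few percent of the amplitude — the residual comes from early exponential
  signal inside the pre-take-off window.
- `adaptive`: subtract the median of the lowest quartile of values.

A curve is called non-amplified (E = 1) when the raw-scale max/median
fluorescence ratio is below 1.2; the baseline subtracted by this module is
added back for that check. The rule implies that amplification smaller than
roughly 20% of the background level is indistinguishable from a flat trace —
acceptable for typical instruments, where plateau signal is a multiple of
background. A curve corrected elsewhere (unknown baseline) is only called
flat when it is numerically constant.

### Fitting

Nonlinear least squares (Levenberg-Marquardt) initialised at
F0 = min F, a = range, m = the cycle of the largest first difference, with a
deterministic restart ladder over slope starts b ∈ {1, 2, 4, 8, 16}; the
best converged fit with a > 0, b > 0 wins. Tight tolerances (1e-12) matter
for shallow curves (E ≲ 1.2, b ≳ 5) where 40 cycles cover only part of the
sigmoid and the likelihood has a shallow ridge.

Estimator accuracy, measured by the closed loop against the generator: a
noise-free perfect-doubling curve returns E = 2.000 ± 0.01; across 200
curves with E ~ U(1.05, 2) and 1% multiplicative noise the median absolute
error is ≈ 0.011 (< 0.02). Errors concentrate at the low-E end, where the
curve barely rises in 40 cycles.

## The additive efficiency model

A Gaussian GAM on the efficiency scale (no link: the response lives in
[1, 2] and the intercept is directly interpretable):

efficiency ~ β₀ + s(lengthSequence, gcSequence)
+ s(primersLength, gcPrimers) + s(gcImbalance, primerDimers)

Each bivariate smooth is a tensor product of marginal cubic B-spline bases
(6 × 5 = 30 coefficients) on uniform open knots spanning the training range,
penalized by second-order difference matrices on both margins with a single
smoothing parameter per term. Penalties are trace-normalized against the
term's design so one λ unit means the same thing for every term. Smooth
design columns are centred, which makes every fitted smooth average zero
over the training rows and leaves the intercept equal to the mean response
(an exact identity, tested at 1e-4). Note that centring does *not* make the
prediction at the covariate means equal the mean response — that gap is
smooth curvature and can reach the signal SD.

Smoothing parameters minimize GCV = n·RSS/(n − edf)², searched by
Nelder-Mead over the three log-λ from three fixed starts, so the fit is
deterministic. Effective degrees of freedom are traces of the penalized hat
matrix (per-term: the corresponding diagonal block). A small jitter
(1e-7 · tr(XᵀX)/p) keeps the normal matrix positive definite even when the
number of distinct covariate points is close to the number of coefficients,
as happens with replicate-heavy designs. The final RSS is recomputed from
actual residuals; the quadratic-form shortcut used inside the λ search
cancels catastrophically for near-perfect fits. Model comparison uses
AIC = −2·loglik + 2·edf with the Gaussian profile likelihood; models are
only comparable when fitted to the same response vector (checked by a
content fingerprint, so row order does not matter).

Predictions clamp to [1, 2] with a flag; covariates outside the training
hull are clipped to it for basis evaluation and flagged as extrapolation.
Models serialize to versioned JSON (knots, coefficients, centring offsets,
ranges); load(save(m)) predicts bit-identically.

Covariates screened as individually informative but excluded from the model
(species, operator, melting temperatures, 3′ nucleotides, palindromes,
repeat flags) remain in the feature schema for user-defined refits; in
multi-assay panels they largely covary with the pair identity.

## Rank statistics

Efficiency data are heavily tied, so the battery uses asymptotic rank tests:

- Spearman: ρ is the Pearson correlation of ranks, Z = ρ√(n−1), two-sided
  normal p. Ties by midranks (default) or seeded random assignment of
  distinct ranks within tie groups ("random rank averaging").
- Kruskal-Wallis: tie-corrected H, χ² with k−1 df (via scipy).
- Wilcoxon-Mann-Whitney: U standardized with the tie-corrected variance and
  a 0.5 continuity correction. The null is discrete; the correction places
  the normal tail near the middle of the observed atom and measurably
  halves the distance to sampled-permutation p-values.

Approximation quality degrades with tie severity at small n: with only 4
distinct values in two samples of 7 and 8, two-sided p atoms are ~0.05 wide
and no continuous approximation can sit closer than ~0.025 in the worst
case; with moderate ties and 15 observations per sample, agreement with
1e5-sample permutation oracles is within 0.02 across seeds (tested). At the
study scales the battery targets (thousands of reactions) the asymptotics
are exact for practical purposes.

Effect sizes are carried along every Z-type test via the conversion chain
d = 2ρ/√(1−ρ²), logOdds = d·π/√3, Hedges g = d·(1 − 3/(4n−9)). No
multiplicity adjustment is applied by default (raw p against 0.05); Holm
step-down is available as an option.

## Success classification

Success ⇔ measured efficiency ≥ threshold; exactly at the threshold counts
as success (only values *below* it fail). Default threshold 1.65 (65%
efficiency), with {1.60, 1.65, 1.80} swept — 1.80 being the boundary often
quoted for optimized reactions. ROC points are taken at every distinct
score with ties grouped (trapezoid AUC, which equals the Mann-Whitney
U/(n₁n₀) identity and makes the curve invariant under monotone score
transforms). PR points sweep thresholds from the top score until full
recall is first reached — lower thresholds only dilute precision at the
same recall — with precision defined as 1 at recall 0.

## The synthetic study generator

`generate_dataset` emulates a multi-assay efficiency study: 90
amplicon/primer-pair combinations (amplicons 74–907 bp, primers 18–25 nt,
per-sequence GC drawn from Beta(10, 10)), 44 replicate reactions each
(≈3,960 rows). Features are computed from the actual random sequences by
the feature module, not resampled marginally, so covariate correlations
(e.g. Tm with primer GC) are realistic. The ground truth is a fixed smooth
surface over the six model covariates (two Gaussian-bump terms and one
separable sine-cosine ripple, one per covariate pair — representable by the
model family), standardized across pairs and scaled so that

- residual noise SD = √0.0092293 ≈ 0.0961 (the study-scale residual
  variance the defaults target), and
- signal SD = 0.0961·√(0.41/0.59) ≈ 0.0801, making the true
  signal-to-total-variance ratio 0.41.

Observed efficiency = truth + Gaussian noise, truncated (clipped, not
resampled) to [1, 2] — a minor distributional distortion at the top end.
Under these defaults the fitted deviance explained lands in roughly
0.39–0.43 across seeds (tested against the band 0.31–0.51 over 20 seeds).

`simulate_curve` produces logistic traces with additive baseline, optional
multiplicative Gaussian noise, and a plateau shortly after cycle 30. Its
`true_e` is defined as the per-cycle fluorescence ratio **at the
quantification point** (20% of the fluorescence at cpD2) — the operating
point the estimator reads. A logistic's per-cycle ratio declines
continuously along the curve, so "the" exponential-phase ratio has to be
anchored somewhere; anchoring it at the measurement point makes the
simulate→estimate loop exactly identifiable (the low-copy limit ratio is
E + u\*(E−1), about 4% above E at E = 2). Alternative anchorings are not
innocuous: a hard-clamped pure exponential or a discrete logistic-map
mechanism put the 4PL fit's effective slope far from 1/ln E and misestimate
by 0.05–1.3.

What the generator does **not** emulate: species/operator/machine batch
effects (metadata are sampled independently of the response), primer-template
annealing or mispriming, plate position effects, and non-Gaussian
heteroscedastic noise. Passing tests therefore demonstrate correctness of
the algorithms under the stated statistical structure, not performance on
any particular instrument's data.

## Degenerate inputs and tie-breaks

- Sequences are uppercased; any non-ACGT character (including IUPAC
  ambiguity codes) is rejected with the offending character named.
- Palindromes: minimum length 6 (even, matching the N6 repeat convention),
  perfect reverse-complement matches only, each start position counted once
  at its maximal extent.
- Constant response: deviance explained and adjusted R² are reported as 0
  (the total sum of squares is below numerical resolution).
- Constant covariate in a smooth: rejected with the covariate named.
- AIC ties (|Δ| < 1e-9): the model with fewer effective df wins.
- Curves must have ≥ 10 cycles; re-correcting a corrected curve is an
  error; a threshold sweep skips (with a warning) thresholds that yield a
  single class.

## Known limitations

- The 4-parameter logistic cannot represent asymmetric plateaus; a
  5-parameter generalisation is deliberately out of scope.
- Efficiencies below ≈1.1 are weakly identified from 40 cycles (the curve
  never plateaus); estimates there carry most of the sweep error.
- The GAM's GCV search is local (three fixed starts); pathological designs
  could in principle find different optima, though the fit is deterministic
  for any given input.
- Triplet hybridization scores are position-blind counts — a cheap k-mer
  proxy, not a thermodynamic duplex model; raw counts (default) or
  length-normalized variants are available.
- Primer-template annealing is never checked: features describe the
  amplicon and primers as given.
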