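# Methods

## The model

All analyses operate on per-participant cell means of reaction times (ms),
aggregated by trial type (visuo-tactile VT / tactile-only TO), distance
(D1–D5), light location and tactile location after filtering.  The working
model is a Gaussian hierarchical linear model

    y = X β + Z ξ + ε

* `X` — sum-to-zero contrast matrix of the fixed factors (Distance as a
  5-level categorical, Light and Tactile Location 3-level; interactions as
  products of margin columns, so the full three-way expansion has 45
  columns).
* `β_i ~ N(0, σ_i)` — independent normal priors per coefficient.  Default
  scales: 50 ms for effects (RT effects in this paradigm are 5–80 ms, so
  this is weakly informative without inviting Lindley-type dilution of the
  selection engines), 1000 ms for the intercept (RT levels are far from
  zero).
* `ξ_s ~ MN(0, Ω)` — one random-effect vector per participant (intercept
  plus Light and Tactile offsets, q = 5).  `Ω ~ Inverse-Wishart(q + 2,
  diag(20² ms²))`, so the prior expectation of each random sd is 20 ms.
* `ε ~ N(0, σ²)`, `σ² ~ Inverse-Gamma(0.01, 0.01)`; σ² can be pinned for
  conjugate cross-checks.

Every full conditional is conjugate and the model is fitted by a blocked
Gibbs sampler (coefficient blocks → per-subject random effects, batched →
Ω → σ²).  Trial-level likelihoods are deliberately out of scope: the
pipeline models cell means, matching how this paradigm is analysed.

Chains are seeded independently from the user seed; defaults in the
pipeline are 2 chains × (500 warmup + 1000 draws), enough for the
selection proportions and summaries used here (typical bulk ESS well above
1000 for fixed effects).  Split-R̂ > 1.01 on any monitored estimand is
reported, and aborts the analysis when the strict convergence gate is
enabled.

## Posterior summaries

Estimands are reported as the posterior **mode** (Gaussian-KDE argmax with
Silverman bandwidth on the pooled draws, histogram fallback for degenerate
samples, clipped into the interval below) and the **95% highest-density
interval** (narrowest interval containing 0.95 mass, computed from sorted
draws; for unimodal posteriors this is never wider than the equal-tailed
interval).  ESS, split-R̂ and MCSE come from arviz.

## Product Space Method

Three candidate structures for the TO baseline are compared while the VT
sub-model stays fixed:

* **H0** — TO rows share the VT linear predictor (same β, ξ).
* **H1** — TO is a single constant `τ ~ N(0, 1000 ms)` plus noise.
* **H2** — TO has its own coefficient vector on the same design (and, by
  default, shares the random effects with the VT equation; a
  duplicated-random-effects mode exists behind
  `HypothesisSet(shared_random=False)`).

A categorical index with prior 1/3 each is sampled jointly with all
parameters.  β, ξ, Ω and σ² appear in every candidate with identical
priors, so they are treated as *common* parameters and need no
pseudo-priors; only H1's τ and H2's τ-vector get normal pseudo-priors
fitted from short pilot runs (posterior mean, sd inflated ×1.5 for
mixing).  The index conditional multiplies each candidate's TO likelihood
by the active block's prior/pseudo-prior ratio.  `P(H_id|D)` is the exact
empirical visit frequency over post-warmup draws; a run in which the index
never switches *and* chains disagree on the resident model raises a
pseudo-prior mismatch warning instead of silently reporting proportions.

## Indicator Variable Selection

Each fixed-effect term's whole coefficient block is multiplied by a
Bernoulli indicator `γ_t` (prior 0.5, configurable), one indicator per
term — factor or interaction — with no heredity constraint.  The indicator
is drawn with the coefficient block integrated out analytically (the
conjugate marginal-likelihood ratio `½b'A⁻¹b − ½log|A| − ½log|S|`), after
which the block is refreshed from its conditional (posterior when active,
prior when inactive).  This collapsed update keeps the sampler exact and
removes the poor block-flip mixing of the naive scheme.  The inclusion
proportion is the posterior mean of `γ_t`.

Evidence categories use strict thresholds: > 0.99 / > 0.95 / > 0.75 very
strong / strong / positive support for the alternative; < 0.01 / < 0.05 /
< 0.25 the same for the null; [0.25, 0.75] inconclusive.  Following
Occam's razor, inconclusive terms are reported but excluded from the
pipeline's "considered" list for downstream interpretation.

## Boundary localization

For one light location, each adjacent distance pair is fitted as its own
two-level indicator-selection model on the normalized RTs (random
intercept by participant; tactile locations as replicate rows).  The
declared boundary is the pair with the largest inclusion proportion above
0.75, mapped to its cm interval.  When the runner-up is within `tie_tol`
(default 0.05) of the top contrast a tie flag raises and the pair nearer
the body is preferred.  A joint four-contrast model was considered and
rejected for v1: per-pair models keep the evidence for each candidate
boundary independent and are what the reported per-boundary IVS values
imply.

## Preprocessing

Non-responses and catch trials are dropped first (catch trials never enter
RT analyses).  The outlier fence is `[Q1 − ⅔·IQR, Q3 + ⅔·IQR]`, bounds
inclusive, quartiles by linear interpolation of order statistics (the
common default; the rule is a named constant, not hard-coded).  The fence
is computed per participant on RTs pooled over conditions and trial types
— the stated granularity is per participant, and pooling is the default
with a per-stratum mode behind a flag.  On clean Gaussian data this fence
removes a predictable ≈ 11.6% of trials (fence at ±1.574σ), which the
tests check against the closed form.  Cells emptied by filtering stay
absent; normalization (VT − TO per cell) skips and reports keys lacking a
counterpart rather than imputing.

## Synthetic data

The generator emulates the study conditions: 40 participants, 3 × 3
light × tactile conditions, per condition 30 VT trials (6 per distance),
15 TO trials (3 per distance) and 3 catch trials, randomized within
condition.  Distances D1–D5 sit at 1/49/98/147/196 cm; the TO delays use
the apparatus' canonical lookup (6.125/4.564/3.063/1.531/0 s).  The lookup
is kept verbatim even though the D1 and D2 entries differ slightly from
the nominal kinematics `(196 − d)/32 cm·s⁻¹` (6.094/4.594 s) — the
kinematic formula is exposed separately as `distance_to_delay` and the two
are not silently reconciled.

Generative defaults: grand mean 355 ms; TO delay effect a Gaussian bump
peaking at D3 with 25 ms amplitude (the magnitude of the mid-trial slowing
this paradigm produces: alerting-sound facilitation covers the short
delays, accumulated expectancy the long ones); VT distance effect a
−25 ms facilitation step inside a configurable boundary (default after
D3); subject intercept sd 60 ms; by-subject light/tactile effect sd 8 ms
(diagonal covariance unless a full matrix is supplied); residual sd 40 ms;
2% additive outliers of +600 ms; 1% missing responses; 1% catch false
alarms.  Under H1 the TO mean is the grand mean + 20 ms (the constant
TO-vs-VT offset observed in this paradigm).  Residuals are normal on the
ms scale to match the fitted likelihood; an optional lognormal mode adds
right skew for robustness exercises but is off by default.

What the generator does **not** emulate: sequential/serial dependence
between trials, fatigue or practice drift, lapse-generated heavy tails
beyond the additive outliers, and any light-by-tactile interaction
structure.  Passing recovery tests therefore demonstrates that the
pipeline identifies the structures it models under realistic noise — not
that real data are free of the unmodelled effects.

## Numerical choices and problem sizes

* All randomness flows from one root seed; pipeline stages derive their
  seeds deterministically (`seed·1000003 + offset mod 2³¹`), so identical
  configuration + seed reproduces reports byte-for-byte.
* Recovery suites run at the study's n = 40 with 2 chains × (400–500
  warmup + 500–800 draws) and 5–20 replicates per scenario — sizes chosen
  so the whole suite documents calibration, hypothesis recovery and
  boundary localization in a few minutes on one CPU.
* Degenerate inputs: empty RT sets filter to empty with a zero-count
  report; zero-spread samples keep everything (IQR = 0); constant
  posterior draws summarize to a degenerate mode/HDI; designs with a
  single observed factor level are rejected as rank-deficient.

## Known limitations

* Priors for the original JAGS implementations of these analyses are not
  public; the defaults here are declared (weakly-informative normal/IW/IG)
  and surfaced in configuration, and selection proportions do depend on
  the coefficient prior scale, as all marginal-likelihood-based methods
  do.
* Only sum-to-zero contrasts are implemented; the likelihood, not the
  coding, is what the selection engines compare.
* The Inverse-Wishart prior on Ω is conjugate but mildly informative for
  small random-effect variances; an LKJ-style alternative would require a
  non-conjugate update and is left out of v1.
* No trial-level likelihood and no heavy-tailed residual options.
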