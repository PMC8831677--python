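# Methods

## Model

An ego allocates links among choices whose cost per link lies in a bounded
range `[s_min, s_max]`. In the discrete version the range is split into
`r` uniform layers, `s_k = s_max − (s_max − s_min)(k − 1)/(r − 1)`, with
layer 1 the most costly; maximizing entropy subject to fixed mean cost per
link σ gives a multinomial over layer occupancies with geometric cell
probabilities ∝ e^{μk}, where μ solves the softmin-mean relation
σ = Σ s_k e^{−μ̂s_k} / Σ e^{−μ̂s_k} (μ = μ̂(s_max − s_min)/(r − 1)).
Expected layer fractions are ε_k = (e^{kμ} − e^{(k−1)μ})/(e^{rμ} − 1) and
circles χ_k = (e^{kμ} − 1)/(e^{rμ} − 1).

Letting r → ∞ at fixed η = μ(r − 1) turns the layer index into a
normalized distance t = (k − 1)/(r − 1) ∈ [0, 1] and the allocation into
the truncated-exponential density ε(t) = ηe^{ηt}/(e^η − 1) with CDF
χ(t) = (e^{ηt} − 1)/(e^η − 1). The mean distance and η are linked by the
implicit cost equation t̄ = g(η) ≡ e^η/(e^η − 1) − 1/η, strictly
increasing with g(0) = 1/2; equivalently g(η) = ½ + ½·L(η/2) with the
Langevin function L(x) = coth x − 1/x, an identity the tests use as an
independent oracle. The discrete and continuum scalings correspond through
η ≈ (r − 1)(e^μ − 1); four circles with ratio e^μ = 3 give η = 6, the
reference value for human ego-networks.

## Estimation

Each alter contributes tᵢ = (s_max − sᵢ)/(s_max − s_min); the likelihood
depends on the data only through L̃ (count) and L̃₁ = Σtᵢ. With a flat
(improper) prior on η over ℝ, the posterior
P(η|L̃, L̃₁) ∝ (η/(e^η − 1))^L̃ e^{ηL̃₁} is proper exactly when
0 < L̃₁ < L̃; this is validated eagerly and violations surface as explicit
improper-posterior failures rather than numeric garbage. The MAP/ML
estimate is the root of g(η) = t̄, found by bracket doubling from [−1, 1]
plus Brent's method (monotonicity guarantees a sign change); t̄ within
1e−12 of ½ returns η = 0 exactly, avoiding root-finder churn at the
symmetric point.

Equal-tail intervals solve Γ(η₋) = δ and Γ(η₊) = 1 − δ (default
δ = 0.025, i.e. a 95% interval) where the posterior CDF Γ is assembled
from the one-sided integrals Φ_u(R) = ∫₀ᵘ (η/(1 − e^{−η}))^L̃ e^{−Rη} dη
via the substitution η → −η on the negative axis:

    Γ(u) = [Φ_∞(L̃₁) − Φ_{−u}(L̃₁)] / D            for u < 0,
    Γ(u) = [Φ_∞(L̃₁) + Φ_u(L̃ − L̃₁)] / D          for u ≥ 0,
    D = Φ_∞(L̃₁) + Φ_∞(L̃ − L̃₁).

Φ_∞(R) diverges iff R ≤ 0 (the integrand grows like η^L̃ e^{−Rη}), which
is again exactly the propriety condition.

## Numerics

Everything is computed on the log scale. The recurring factor
log[η/(e^η − 1)] is evaluated as log|η| − log|e^η − 1| through `expm1`,
which is exact near the removable singularity at η = 0 and switches to the
linear branch log(e^x − 1) ≈ x above x = 34; no special-casing beyond
η = 0 itself is needed. g uses its odd series ½ + η/12 − η³/720 for
|η| ≤ 1e−4 (coefficients validated against 40-digit arithmetic in the
tests, not asserted); χ and ε use the quadratic expansion
χ ≈ t + (η/2)t(t − 1) for |e^η − 1| ≤ 1e−6, and the discrete χ_k the
analogous form k/r + (k/2r)(e^μ − 1)(k − r).

Finite Φ_u integrals use adaptive quadrature on exp(log-integrand − shift)
with the shift set to the grid maximum of the log-integrand (absolute
target 1e−13 after shifting). Φ_∞ splits at η = 40: below, the adaptive
rule; above, (1 − e^{−η})^{−L̃} equals 1 to double precision, so the tail
is the upper incomplete gamma Γ(L̃ + 1, 40R)/R^{L̃+1}, added in log space.
A fixed 150-point Gauss–Laguerre evaluator (log-integrand, max-shifted,
nodes rescaled by R) is retained as `_log_phi_inf_laguerre`; it agrees
with the hybrid to ~5e−4 in the log and with a 30-digit quadrature oracle
to ~1e−14 at moderate R, but its worst-case accuracy is limited by the
integrand's complex poles at 2πikR, so the hybrid is the default. Both
Φ_∞ values are cached per summary; CDF evaluations inside the interval
search then cost one finite quadrature each. Interval roots are bracketed
outward from the MLE by doubling steps and solved with Brent at
xtol = 1e−8, comfortably inside the 1e−6 contract on the tail masses.

## Cost-scale heuristics and filtering

The continuum model needs `s_min`/`s_max` as inputs, and real datasets do
not observe them. Two standard heuristics are implemented:

* **global-extrema** — per ego, the smallest and largest per-alter weight
  totals over the whole observation period (used for face-to-face and
  message data); by construction at least one tie sits at each end, so
  t̄ ∈ (0, 1) strictly and fits are always proper when ≥ 2 distinct
  weights exist.
* **windowed-sum** — when interactions carry month-like sub-window labels,
  `s_max` (`s_min`) is the sum over sub-windows of the per-window maximum
  (minimum) single-tie weight: the cost the extreme alter would have
  accrued had it been the same alter all along. Minima are taken over
  observed interactions only — months in which an alter was not contacted
  simply do not contribute — and empty windows are dropped with a warning.

Ties strictly below `s_min` are discarded (an alter cheaper than the
least admissible relationship is not a relationship); a weight equal to
`s_min` is kept, since under the global heuristic the boundary alter
defines the scale itself. Egos with fewer than `min_alters` survivors
(default 5, configurable; 0 disables) are excluded, and exclusion — like
a degenerate all-equal-weights scale or a boundary t̄ — is reported as a
per-ego status in the fit table, never as an exception that aborts a
population run.

A consequence worth knowing: with the global-extrema heuristic the
estimated scale is the *sample* range of the tie weights, which undercovers
the population range. Renormalizing by sample extrema compresses t̄ toward
½ and therefore shrinks |η̂|, increasingly so at large |η| where the
smallest t is typically far from 0 (at η = 6 and L̃ = 100 the median
shrinkage is ≈ −1.9). This is a property of the heuristic, not of the
estimator: in known-scale mode the estimator's median error at L̃ = 100 is
below 0.1 across η ∈ [−2, 12]. The recovery experiment exposes both modes
(`known_scale` isolates the estimator; `pipeline` exercises the full
heuristic), and the end-to-end pipeline test is run at η = 3, where the
heuristic's shrinkage stays within a ±0.5 median band at L̃ = 100.

## Signature persistence

To ask whether η is an individual trait, per-ego fits across W ≥ 2 time
windows are compared through relative distances: self-distances
|η_a − η_{a+1}|/|η_a| over consecutive windows, and reference distances
the mean of |η_a(i) − η_a(j)|/|η_a(i)| over all other egos j in the same
(later) window — N egos × (W − 1) points per distribution. The two
samples are compared with a two-sided Mann–Whitney U test (scipy). Egos
whose η changes sign between windows are kept (the formula applies
literally; the distance may exceed 1); an anchor η exactly 0 makes the
distance undefined and skips that ego with a logged count. Reference
denominators use only egos with valid fits in that window.

## Synthetic data and what passing tests mean

The generator draws t i.i.d. by exact inverse-CDF sampling
(t = log(1 + u(e^η − 1))/η, uniform branch below |η| = 1e−9), so χ(·, η)
is the true distribution function of the draws — the KS identity checked
at n = 10⁵ is a property of the construction, not a fit. Alter counts are
fixed (default 30, a typical retained-network size in communication data)
or binomial over a finite pool; weights map linearly onto the configured
scale (default (0, 1)). For windowed data each alter's integer-rounded
total is split multinomially across months, optionally skewed by a
Dirichlet with concentration 1/window_noise. One seeded generator drives a
whole experiment; recovery cells derive child seeds via
`SeedSequence.spawn`, making runs bit-reproducible within a library
version.

Because alters are exchangeable and windows independent given η, these
populations contain no turnover, reciprocity, topology or burstiness.
Passing recovery and persistence tests therefore demonstrates that the
estimator, interval machinery and distance analysis behave correctly under
the model's own assumptions — not that any real population satisfies
those assumptions.

Default experiment sizes (recovery grid 200 replicates per cell, coverage
cell 500 replicates at η = 6, L̃ = 30, persistence 40 replicates of 24
egos × 3 windows with cross-ego std 4 about mean 7.5, |η| ≥ 0.5 by
redraw) were chosen to keep Monte-Carlo error small relative to the
effects tested; the persistence construction fits with the known (0, 1)
scale so that the comparison isolates the distance machinery from
scale-heuristic noise.

## Known limitations

* The cost scale must come from outside the likelihood; the heuristics are
  biased in data-dependent ways (global extrema shrink |η̂|; the
  windowed-sum range is wider and yields systematically higher estimates
  than global extrema on the same windowed data). Fits from differently
  scaled datasets are comparable only qualitatively.
* The flat prior makes the posterior improper at t̄ ∈ {0, 1}; such egos
  (e.g. two alters with equal weights after filtering) are reported, not
  estimated.
* `Φ` caching keys on (R, L̃) exactly; extremely long-running processes
  fitting millions of distinct egos will simply see cache misses, not
  wrong answers.
* The discrete pmf normalization is verified by enumeration only up to
  r ≤ 4, L ≤ 5 (the count of compositions explodes combinatorially); the
  closed form is exact for all sizes.
* The CLI's mode statistic is the midpoint of the fullest fixed-width
  histogram bin (default width 1.0, logged); other mode estimators will
  differ on long-tailed populations.
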