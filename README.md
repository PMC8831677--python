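# egocircles

Continuum maximum-entropy modelling of how people allocate a limited budget
of social effort across their personal relationships.

## The problem

Personal ("ego") networks are classically described by nested Dunbar
circles of roughly 5, 15, 50 and 150 alters — each successive circle about
3× the size of the previous one. That picture presumes a handful of
discrete closeness layers, but most observable measures of tie strength
(calls made, seconds of face-to-face contact, messages exchanged) are
continuous. `egocircles` implements the continuum counterpart: an ego
spreads a fixed resource budget over its alters, each tie carries a cost
`s` in `[s_min, s_max]`, and the maximum-entropy allocation of links over
normalized "distance" `t = (s_max − s)/(s_max − s_min) ∈ [0, 1]` is the
truncated exponential

    ε(t) = η e^{ηt} / (e^η − 1),        χ(t) = (e^{ηt} − 1)/(e^η − 1),

where χ(t) is the circle function (fraction of alters within distance t)
and η is the single scaling parameter. η > 0 is the ordinary regime (outer
circles progressively larger); η < 0 the inverse regime (overpopulated
innermost circle). The discrete r-layer model maps onto this limit through
η ≈ (r − 1)(e^μ − 1); with r = 4 circles and the empirical layer ratio
e^μ ≈ 3, the predicted human value is **η ≈ 6**.

Estimation is exact and one-dimensional. The data enter only through the
sufficient statistics L̃ (retained alters) and L̃₁ = Σᵢ tᵢ; under a flat
prior the posterior is

    P(η | L̃, L̃₁) ∝ (η / (e^η − 1))^L̃ · e^{η L̃₁},

the maximum-likelihood estimate solves the implicit cost equation
g(η) = L̃₁/L̃ with g(η) = e^η/(e^η − 1) − 1/η, and equal-tail 95% credible
intervals come from quadrature of the posterior CDF (tail mass δ = 0.025
per side).

The package is aimed at quantitative social scientists and network
researchers who want to fit η to per-ego weighted tie lists, test whether
η is a persistent individual trait across time windows, and validate the
whole pipeline on synthetic data.

## Worked example

Simulate a 24-ego population with true η = 6 and 100 alters per ego, then
fit every ego (scale set per ego from its extreme tie weights, 95% CIs):

```sh
$ cat population.yaml
n_egos: 24
eta: 6.0
n_alters: 100
s_min: 0.0
s_max: 1.0
seed: 7

$ egocircles simulate --config population.yaml --out data
wrote 2400 ties for 24 egos to data/edges.csv

$ egocircles fit --input data/edges.csv --out fits
n_total: 24
n_ok: 24
bin_width: 1.0
mean: 4.329396763852048
median: 4.324882027835738
std: 0.6847033623311588
mode: 4.5
frac_inverse: 0.0
```

All 24 egos fit cleanly in the ordinary regime (`frac_inverse: 0.0`); the
per-ego estimates and intervals are in `fits/fits.csv`. The population
median sits near 4.3 rather than 6 because the cost scale was *estimated*
from each ego's extreme weights — that heuristic compresses the admissible
range and systematically shrinks |η̂| (see `docs/methods.md`). When the
scale is known, the estimator is consistent: feeding the same draws to the
estimator directly recovers η ≈ 6 (the recovery experiments in the test
suite quantify this).

The same objects are available as a library:

```python
import egocircles as ec

print(f"g(6) = {ec.g(6.0):.4f}")            # mean normalized distance at eta = 6
print(f"solve_eta(0.8) = {ec.solve_eta(0.8):.4f}")

ego = ec.generate_ego(ec.SyntheticConfig(eta_true=6.0, n_alters=200, seed=42))
fit = ec.fit_ego(ego)                        # global-extrema scale, 95% CI
print(f"eta_hat = {fit.eta_hat:.2f}, CI = ({fit.ci_low:.2f}, {fit.ci_high:.2f}), "
      f"L_tilde = {fit.summary.L_tilde}, regime = {fit.regime}")
```

prints

```
g(6) = 0.8358
solve_eta(0.8) = 4.8010
eta_hat = 4.57, CI = (3.88, 5.32), L_tilde = 200, regime = ordinary
```

`g(6) = 0.8358` says an η = 6 ego holds 83.6% of its mean normalized
distance budget; the fitted synthetic ego lands in the ordinary regime with
a tight interval at L̃ = 200.

A third subcommand, `egocircles signatures`, takes per-window fit tables
and tests whether each ego's η is persistent: it pools relative
self-distances |η₁ − η₂|/|η₁| against same-window reference distances to
the rest of the population and reports a two-sided Mann–Whitney p-value.

## Layout

| module | contents |
| --- | --- |
| `egocircles.discrete` | r-layer model: cost grid, σ↔μ relation, layer fractions, pmf |
| `egocircles.continuum` | g(η), its inverse, ε(t), χ(t), discrete↔continuum map |
| `egocircles.inference` | sufficient statistics, MLE, Φ/Γ integrals, credible intervals |
| `egocircles.data_io` | edge-list / contact-triplet readers, scale heuristics, per-ego fits |
| `egocircles.signatures` | self vs reference η-distances, rank test, η–size correlation |
| `egocircles.synthetic` | inverse-CDF generator, populations, recovery experiments |
| `egocircles.cli` | `egocircles fit | signatures | simulate` |

Methodological details, parameter defaults and known limitations are in
`docs/methods.md`.
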