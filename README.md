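# occuwatch

Occupancy and detection-probability analysis for annual camera-trap
monitoring of cryptic ground-dwelling marsupials — bandicoots (*Isoodon*,
*Perameles*) and potoroos (*Potorous*) — across a fox-baited and an unbaited
reserve, and for any monitoring design with the same structure: many sites,
daily binary detections over 30–40 day deployments, repeated annually.

Camera traps detect these species imperfectly: a site can be occupied yet
yield an all-zero detection history. `occuwatch` implements the standard
correction chain for that problem, end to end:

* **Single-season occupancy.** Site-level MLE of occupancy ψ and daily
  detection probability p under the two candidate models ψ(.)p(.) and
  ψ(area)p(.); for a history with m surveyed days and d detections the site
  likelihood is ψ·p^d(1−p)^(m−d) when d > 0 and ψ(1−p)^m + (1−ψ) when d = 0.
* **Multi-season (dynamic) occupancy.** A hidden two-state Markov chain with
  per-transition colonization γ and extinction ε, fitted by the forward
  recursion; four variants (constant, area on ψ₁, year on γ/ε, both).
  Derived occupancy follows ψ_{t+1} = ψ_t(1−ε_t) + (1−ψ_t)γ_t, with 95%
  intervals from a 1000-draw parametric bootstrap of the MLE.
* **Model selection.** ΔAIC/ΔDIC, Akaike weights
  w_i = exp(−Δ_i/2)/Σ exp(−Δ_k/2), degree-of-support categories
  (0–2 substantial, 4–7 considerably less, >10 essentially none), and
  weighted model averaging with unconditional variances.
* **Bayesian daily detection.** Conditional on occupancy,
  d_ij ~ Bernoulli(δ_j) with logit(δ_j) = β₀ + β₁·bait + β₂·ground +
  β₃·shrub + year effects, vague N(0, precision 10⁻⁶) priors, an in-house
  adaptive random-walk Metropolis sampler (2 chains, half burn-in),
  Gelman–Rubin diagnostics (< 1.05) and DIC comparison of five variants.
* **Survey effort.** The days needed to be α-certain an undetected species is
  absent, n = log(1−α)/log(1−δ), propagated through the posterior for
  best-case and worst-case detection environments.
* **Synthetic data.** A generator producing datasets with exactly this
  statistical structure (latent occupancy dynamics, logit-linear daily
  detection, camera malfunction/theft missingness), so the whole chain is
  testable without field data.

## Worked example

```python
import occuwatch as ow

data, sites, _ = ow.simulate_dataset(ow.SimulationConfig(seed=7))
season = ow.truncate_histories(data.subset(seasons=["2015"]), 30)
fits = [ow.fit_single_season(season, sites, m) for m in ow.SingleSeasonModel]
print(ow.comparison_table(fits, criterion="AIC").round(3).to_string(index=False))
```

prints

```
        model  K      AIC  delta  weight     support
   psi(.)p(.)  2 2182.931  0.000   0.523 Substantial
psi(area)p(.)  3 2183.119  0.188   0.477 Substantial
```

Both models sit within 2 AIC units (both "Substantial"), so neither is
decisively better; the weights 0.52/0.48 quantify that near-tie, and the top
model's occupancy estimate is

```
BB: occupancy 0.355 (95% CI 0.286-0.431)
```

i.e. roughly one in three sites is used by the species once imperfect daily
detection is accounted for. The `examples/` directory walks through each
capability the same way: data summaries (`01`), single-season fits (`02`),
dynamic occupancy and bootstrap trajectories (`03`), model-selection
arithmetic (`04`), the Bayesian detection model (`05`) and survey effort
(`06`). A thin CLI mirrors the main workflows
(`occuwatch simulate|summarize|fit-single|fit-multi|compare|fit-bayes|effort`).

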