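# Methods

This note documents the statistical models implemented in `occuwatch`, the
assumptions they carry, the defaults and numerical choices, and what the
synthetic-data generator does and does not emulate.

## The monitoring design being modelled

The package targets annual camera-trap monitoring of ground-dwelling
marsupials across two managed areas: a fox-baited reserve (coded `BB`) and an
unbaited one (`NAD`), with 84 camera sites in each (168 total). Cameras run
for 30–40 consecutive days per site per year; each day is collapsed to a
binary outcome (species detected at least once that day, or not), and days a
camera was inoperative are *missing*, not zero. Each site carries a
habitat-complexity profile: seven structural attributes (tree, shrub and
ground cover, woody debris, rocks, leaf litter, moisture) scored ordinally
0–3, of which ground and shrub cover enter the detection model.

## Single-season occupancy

Each site is occupied with probability ψ (constant, or logit-linear in area);
conditional on occupancy, each surveyed day is an independent Bernoulli(p)
detection. Marginalising the latent state gives the site likelihood

    L = ψ p^d (1−p)^(m−d)        if d > 0
    L = ψ (1−p)^m + (1−ψ)        if d = 0

with m surveyed days and d detections. Assumptions: closure (the occupancy
state does not change within the season), no false positives, independence
across sites and days, and missing days that are uninformative about
occupancy (missing-at-random given the state).

Fitting maximises the summed log likelihood on the logit (working) scale with
L-BFGS-B (objective tolerance 1e-12, gradient tolerance 1e-8), from a
naive-occupancy starting point plus five random restarts — these likelihoods
are flat and boundary-prone at small sample sizes, and restarts are cheap.
Working parameters are box-bounded at ±15 on the logit scale; an estimate
pinned there (e.g. every site detected, so ψ̂ → 1) is reported but flagged
`boundary` and the fit is marked non-converged rather than silently trusted.
The covariance of the working parameters is the inverse numerical Hessian at
the optimum (central differences); 95% confidence intervals are Wald
intervals on the logit scale back-transformed to probabilities, which keeps
the bounds inside [0, 1]. Records with no surveyed days carry likelihood 1
and are dropped with a warning before fitting.

## Multi-season (dynamic) occupancy

Between seasons the latent state evolves as a Markov chain: an occupied site
goes extinct with probability ε_t and an empty one is colonized with
probability γ_t. The site likelihood is computed by the forward recursion
over the hidden chain with per-season binomial emissions; a season with no
record at a site contributes emission 1 under both states, keeping the chain
intact. The recursion renormalises the state vector each season and
accumulates the log normaliser, so long histories cannot underflow. Four
variants are fitted: constant everything; area on initial occupancy;
year-specific γ/ε with and without the area effect. With four seasons these
have 4, 5, 9 and 8 parameters respectively (year-specific rates are indexed
by transition: three transitions for four seasons). Fitting, covariance and
flags are as in the single-season case.

Derived occupancy is projected by ψ_{t+1} = ψ_t(1−ε_t) + (1−ψ_t)γ_t, whose
fixed point for constant rates is γ/(γ+ε). Trajectory uncertainty uses a
parametric bootstrap with 1000 draws by default: parameter vectors are
sampled from the multivariate normal with the MLE's working-scale covariance,
back-transformed and iterated through the projection, and 2.5/97.5 percentile
bounds are taken per season and area. This propagates *parameter* uncertainty
(the asymptotic-normal interpretation of a parametric bootstrap) rather than
refitting to re-simulated data; the point trajectory always comes from the
MLE itself, so the season-1 value equals the fitted ψ₁ exactly. The
covariance is eigendecomposed and tiny negative eigenvalues (numerical noise)
clipped to zero; genuinely indefinite covariances are an error instructing a
refit. Percentile intervals were chosen over normal-theory intervals because
the projection is nonlinear in the parameters.

## Model selection

Akaike weights are computed after min-subtraction, w_i = exp(−Δ_i/2) / Σ_k
exp(−Δ_k/2), so arbitrarily large criterion values cannot overflow. The
degree-of-support convention maps Δ 0–2 to "Substantial", 4–7 to
"Considerably Less" and >10 to "Essentially None"; the convention is silent
on (2, 4) and (7, 10], and those deltas are labelled "Intermediate"
explicitly rather than absorbed into a neighbouring bin — misreporting
support strength is worse than admitting the convention has gaps. Comparison
tables sort ascending by delta with ties broken toward fewer parameters, and
carry weights for AIC only (the DIC convention reports deltas without
weights).

Model averaging weights the per-model point estimates directly on the
probability scale and builds the interval from the unconditional variance on
the logit scale: each model's Wald standard error (recovered from its CI) is
inflated by its squared deviation from the weighted mean before averaging.
The averaging variance method is a package choice; it follows the standard
multimodel-inference formulation.

## Bayesian daily detection

Detection probability is modelled conditional on use: only (site, season)
records with at least one detection enter, since a season with no detections
at a site is uninformative about daily detectability *given presence* (it
confounds absence with non-detection). Each retained non-missing day is a
Bernoulli trial with logit(δ) linear in an intercept and, per variant,
baiting (0/1), ground- and shrub-cover scores, and categorical year
indicators with the first season as baseline. Habitat scores enter as numeric
0–3 — a monotone dose interpretation of the ordinal cover classes — not as
dummies. Five variants are compared: Null, Baiting, Habitat, Baiting +
Habitat, Baiting + Habitat + Year. Coefficients carry independent normal
priors parameterised by mean and precision (inverse variance); the default
(0, 10⁻⁶) is a vague prior with sd 1000.

The sampler is random-walk Metropolis updating one coefficient at a time.
Internally the day-level design is aggregated to unique covariate profiles
with binomial counts, which is likelihood-equivalent and makes each
evaluation a small matrix-vector product. Proposal scales start at 0.5 and
are multiplied by 1.5 or 0.7 every 50 iterations during burn-in to keep
acceptance inside 0.2–0.4, then frozen for the second half of the run so the
retained draws come from a fixed, detailed-balance-preserving kernel. Two
chains run by default from dispersed N(0, 1) starts; the first half of every
chain is burn-in and no thinning is applied. 2500 iterations suffice for the
smaller variants; run length should be raised until the Gelman–Rubin
statistic is below 1.05 for every coefficient (the fully specified variant on
a full-size dataset typically needs ~6000).

The Gelman–Rubin potential scale reduction factor is computed from the
post-burn-in between- and within-chain variances. The plain finite-sample
PSRF equals sqrt((n−1)/n) < 1 when chains agree perfectly; values are clamped
at 1 from below so that zero between-chain variance reports exactly 1, and
anything ≥ 1.05 is flagged. Autocorrelation-at-lag tables are provided as the
non-interactive counterpart of visual autocorrelation checks.

DIC is D̄ + pD with pD = D̄ − D(posterior mean of β) and deviance −2 log
likelihood (likelihood only, priors excluded, the standard convention). A
point-mass posterior gives pD = 0; an irrelevant extra covariate raises pD by
about one, which the tests verify.

## Survey effort

If δ is the daily detection probability at an occupied site, the probability
of at least one detection in n days is 1 − (1−δ)^n; setting this to α and
solving gives n = log(1−α)/log(1−δ). The default α is 0.95. δ = 1 returns one
day; δ = 0 can never resolve absence and is an error, and posterior draws
whose δ underflows to zero contribute +∞ (surfacing in the upper percentile
and an `n_infinite` count rather than being dropped silently).

"Best case" and "worst case" are taken per posterior draw as the maximum and
minimum δ over a supplied set of covariate profiles — the most and least
favourable detection environments — defaulting to all covariate combinations
the fitted variant distinguishes. Each scenario reports the posterior mean of
continuous n, its ceiling as an operational day count, 2.5/97.5 percentiles,
and an adequacy flag: adequate when the upper percentile fits inside the
stated deployment length (default 40 days). Alternatives (extremes over
sites, or posterior quantiles of a single profile) would answer slightly
different questions; the profile-extremes reading matches the
favourable/unfavourable-environment framing and is the one implemented.

## Synthetic data

The generator produces data with exactly the structure the models assume:
sites split between the two areas (area-level baiting), i.i.d. ordinal
habitat scores per attribute, first-season occupancy Bernoulli(ψ₁) with
Markov γ/ε dynamics, and daily Bernoulli detections whose logit is linear in
baiting, ground cover, shrub cover and additive per-year offsets (first year
baseline). Missingness has two mechanisms: each day is independently
unrecorded with probability `missing_day_rate` (camera malfunction), and each
(site, season) deployment is lost entirely with probability
`whole_deployment_loss_rate` (theft/total failure). Both are
missing-completely-at-random. One seed drives everything, with independent
sub-streams spawned per stage (sites, occupancy, detections) so each stage is
individually reproducible.

Defaults: 168 sites, even split, 4 years, 40 days, ψ₁ = 0.3, γ = 0.1,
ε = 0.15, detection coefficients (−2.2 intercept, +0.4 bait, +0.35 ground,
+0.25 shrub, year offsets +0.1/+0.2/+0.3), habitat-score distribution
(0.15, 0.35, 0.35, 0.15), 2% missing days, 3% lost deployments. The design
numbers mirror the monitoring program; the rates and effect sizes are fixture
choices — no published generating values exist for a field study — picked so
daily detection spans roughly 0.1–0.4, the range typical of these species at
baited cameras, with the slow occupancy turnover and year-on-year detection
increase the monitoring context suggests.

What the generator deliberately omits: spatial autocorrelation between
neighbouring sites, animal movement and home-range structure, misidentified
(false-positive) detections, informative missingness (e.g. cameras failing
where animals chew cables), and within-season occupancy change. Passing
parameter-recovery tests therefore shows the estimators are correct *under
the models' own assumptions*; it does not certify robustness to violations of
closure, independence or the no-false-positive assumption in real field data.

## Degenerate inputs and edge conventions

All-missing records: likelihood 1, dropped from fits with a warning. No
detections anywhere: fitting raises (ψ and p are not jointly identifiable).
Every site detected: ψ̂ pinned at the working-scale bound and flagged.
Empty design (no data rows): the sampler runs prior-only, which the tests use
to verify prior recovery. Empty frequency strata: zero counts, rate reported
as NaN. Criterion ties in comparison tables: fewer parameters first. Weights
are kept at full precision internally and rounded to two decimals only for
display, matching the print convention of published tables.

## Problem sizes used by the test suite

The parameter-recovery harness runs 100 replicates of the full design
(168 sites × 4 seasons × 40 days); likelihood oracle checks use 500 random
instances against exhaustive latent-state enumeration at T ≤ 4; sampler
correctness uses a 20-trial/7-success intercept-only posterior against a
120,001-point quadrature oracle and a 30,000-iteration prior-only run. These
sizes give Monte-Carlo error comfortably below the tolerances asserted while
keeping the whole suite under a minute of compute for the statistical tests.
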