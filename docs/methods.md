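# Methods

`cyclesem` implements a three-stage analysis of how climate along a migratory
bird's annual cycle shapes its breeding-population dynamics, together with a
forward simulator that generates every input the pipeline consumes. This note
documents the models, the estimation machinery, the simulator, and the design
choices that were genuinely open.

## Annual variables

The density index is the percentage of *available* nest boxes occupied by the
focal species in year *t*:

    N_t = 100 * (boxes occupied by the focal species)
              / (boxes surveyed - boxes occupied by Parids),

since boxes taken by tits are not available to a flycatcher. Annual
population growth rate is the log-difference

    R_t = ln(N_t) - ln(N_{t-1}),

defined only when both years are observed and consecutive; gap years in a
merged two-area series propagate missingness into R_t rather than silently
bridging the gap. Natural logarithms are used throughout (the standard
convention for log-difference growth rates). Hatching dates are integer day
offsets with day 1 = April 1 by default (configurable); an intercept near 69
on this scale is early–mid June.

A widely quoted relative reading of density dependence ("a 10 % increase in
density lowers growth by x %") is not derivable from a per-index-unit slope
without fixing a baseline; `data_prep.density_dependence_interpretations`
reports both the absolute (per 10 index points) and relative (per 10 % of a
stated baseline) readings and endorses neither.

## Climate-window scan

For each site and variable, every contiguous run of months with lags
0..`max_lag` before a reference month (default June of the breeding year,
`max_lag = 12`, hence 13 anchors and 91 windows) is aggregated (mean by
default, sum by flag) into an annual covariate. Each covariate is compared
to an intercept-only null by AICc with a Gaussian likelihood, counting the
error variance as a parameter (k = 3 vs 2). AICc rather than AIC because the
series is short (n ≈ 77); plain AIC is available by editing the criterion.
Ties are broken toward shorter and more recent windows. The scan is
deterministic and *exploratory*: sliding-window selection over 91 correlated
candidates overfits easily, so the pipeline refuses to feed the winner into
the structural models unless the user names the windows or explicitly opts
in to automatic selection.

Window-year convention: with the June anchor, lags 5–6 are December–January
of the winter preceding breeding and lags 8–9 are September–October of the
previous calendar year — a window "in year t−1" is reached by lag, never by
additionally shifting the aggregate.

## Growth model (AR-residual path model)

Two endogenous annual variables with autoregressive residuals:

    R_t     = a + b1 N_{t-1} + b2 F_{t-1} + b3 F_{t-2}
                + b4 MedWinterTemp_t + b5 EurSpringPrecip_t
                + b6 AfrAutumnPrecip_{t-1} + e_t
    N_{t-1} = c + d F_{t-2} + f_t

where F is the annual mean fledgling number (exogenous, with free mean and
variance) and each residual follows an AR process, candidates at lags 1–3.
Residual serial correlation is thus separated from the structural paths.
Because the two residual processes are independent and every mediator is
observed, the joint posterior factorises over the equation blocks; the
implementation samples them as independent conjugate-Gibbs blocks, which is
exactly the joint posterior.

AR pruning: starting from lags {1,2,3} on both residuals, the retained AR
term whose posterior places the most mass across zero is dropped and the
model refit, until every retained AR 95 % interval excludes zero. Terms are
only ever dropped (no re-entry), and structural paths are never pruned.
Note a mild selection effect inherent to this procedure: conditional on
retention, AR magnitudes are biased slightly away from zero (about +0.04 for
a true coefficient of 0.415 at n = 77 in our replicate experiments, i.e.
roughly a third of a posterior SD).

The mean fledgling number two years back is the one variable with both a
direct path to growth and an indirect path via the next year's density; its
indirect effect is the *per-draw* product of the two paths and the total the
per-draw sum. Medians of products deliberately differ from products of
medians, which is why a reported indirect effect need not equal the product
of the reported path medians.

## Nest model (two-level SEM with latent-mean centering)

Nests i within years j. Each within-year response has a random intercept —
its latent year mean — and within predictors are centered at latent year
means, cleanly separating within-year from between-year associations
(observed-mean centering is available as a fallback in the generic
`TwoLevelRegression`). Within a year, hatching date predicts clutch size and
clutch size predicts fledgling number; nestling-period temperature and
precipitation (14 days from hatching, inclusive) predict fledglings with a
temperature × precipitation interaction formed from the centered deviations;
the two weather variables have a free within covariance. Between years, the
latent means of hatching date, clutch size and fledgling number form a
mediation chain with two winter-temperature windows (Europe/February,
Africa/November) as exogenous between-level predictors, and the latent year
means of the nestling weather enter the between-level fledgling equation.
Hatching date reaches fledglings only through clutch size; a direct
between-level hatch → fledglings path is off by default and available as a
sensitivity flag (`direct_hatch_path`). Fledgling counts are modelled as
Gaussian at both levels; no count likelihood is used.

Effect decompositions (total = direct + indirect; indirect split into the
hatch route and the clutch route) are evaluated draw by draw, so additivity
holds exactly at every draw while the reported medians need not add.
Interaction simple slopes are β_temp + β_int · q_p at percentile q_p of the
within-year precipitation deviations (centering offset 0 on the latent
scale); the matching raw-scale percentiles are reported alongside.

## Estimation machinery

All models are fit by conjugate-block Gibbs sampling written on numpy:

* regression/AR blocks and variances use Normal(0, 10⁶) coefficient priors
  and InverseGamma(0.001, 0.001) variance priors (all configurable);
* the 2×2 weather covariance blocks use an InverseWishart(df = 3,
  scale = 10⁻³ I) prior, the matrix analogue of the diffuse scalar choice;
* AR coefficients are not truncated to the stationary region; the fraction
  of stationary draws is reported as a diagnostic instead;
* the AR likelihood conditions on the first max-lag observations; missing
  responses are latent and re-imputed from their Gaussian full conditional
  each sweep, with a weak N(0, 100 σ²) prior on latent residuals so that a
  residual connected to the data only through a near-zero AR weight cannot
  wander numerically; missing covariates are disallowed at the engine level,
  and the growth-model layer converts rows with missing covariates into
  latent-response rows (their likelihood contribution is removed while the
  AR chain over the remaining years stays intact);
* two chains by default, the first half of each chain discarded as warm-up,
  convergence declared when every split-R̂ < 1.05; seeded runs are
  bit-reproducible;
* in the two-level sampler the latent year means are updated one variable at
  a time — the bilinear interaction makes each weather mean conditionally
  Gaussian given the other — and all per-cluster updates are vectorised.

Correctness is established by oracle tests rather than by trusting the
algebra: with flat priors and no AR terms the posterior matches OLS; AR
coefficients are recovered on long simulated series; nominal 95 % intervals
cover planted truths at near-nominal rates; and the full generate → fit
round trips below.

## The synthetic-data generator

The reference coefficient estimates come from a 77-year field survey that
is not publicly deposited, so the generator is the package's study system. Its
defaults are the study conditions: 77 years, Poisson(85) nests per year
(minimum 10), ~113 nest boxes with a 12 % Parid share, and the structural
truth values set to the fitted posterior medians of both models, making
recovery targets the reference values themselves.

Monthly climate is a seasonal sinusoid per site plus independent annual
anomalies; five sites span breeding grounds, European and Mediterranean
migration staging, a Sahel stopover and the African non-breeding grounds,
with anomaly SDs chosen so that, e.g., African winter temperature varies
within about 2 °C across years. Designated true windows (Mediterranean
Dec–Jan temperature, European Jan–Apr precipitation and Feb temperature,
African Sep–Oct precipitation and Nov temperature) feed the structural
equations. Structural climate covariates enter as anomalies relative to the
study-period window mean: the fitted intercepts are only coherent with
near-zero-mean climate covariates, and with this convention the simulated
series have realistic levels (mean growth ≈ 0, ~4–5 fledglings per nest,
density mostly between 10 and 90 index points).

The annual block iterates the two growth-model equations forward with a
30-year burn-in so the AR residual processes are effectively stationary;
occupancy counts are back-computed from the density index so the data-prep
round trip reproduces it (up to integer rounding of box counts). The
emitted table carries the lagged covariates from the burn-in, so all 77
emitted growth observations are usable; a raw field series without
pre-period history loses the first two years to lagging. The table's
"residual variances" are innovation variances of the AR processes by
default (`residual_variance_convention = "innovation"`); the marginal
convention is available by flag and the manifest records which was used.
Note one deliberate simplification inherited from the model itself: growth
rate and density are simulated from their respective structural equations,
so the identity R_t = ln N_t − ln N_{t−1} does *not* bind in the synthetic
world — the models treat density as a predictor, not as the integral of
growth, and the simulator is faithful to the models.

The nest block draws latent year means from the between-level equations and
nests from the within-level equations. `realism_mode="gaussian"` (default)
matches the fitted likelihood exactly — fledgling "counts" are continuous
and may stray outside [0, clutch]; `realism_mode="clamped"` rounds
fledglings into [0, clutch], reflects density into (0, 100] and truncates
precipitation at zero, which makes the files look like field data at the
cost of a small, documented likelihood mismatch. Passing tests in gaussian
mode therefore demonstrate estimator correctness under the model's own
assumptions, not robustness to the discreteness, truncation, observation
error and non-stationarity of real field data.

## Replicate experiments and problem sizes

The recovery experiments (`cyclesem.recovery`) regenerate data at truth and
refit: 20+ replicates of the 77-year growth system and 10+ replicates of the
77-cluster nest system, scored by the cross-replicate mean and SD of
posterior medians. The default MCMC sizes (2 chains × 800 retained draws
for the growth model, 2 × 600 for the nest model, equal warm-up) were chosen
as the smallest runs at which split-R̂ < 1.05 is consistently met and
doubling the draws does not change the reported medians at the precision we
report; the reproduction script averages 40/20 replicates for tighter
Monte-Carlo error on the same unbiased quantities.

## Known limitations

* Gaussian likelihoods everywhere — no Poisson/binomial treatment of counts
  and no overdispersion modelling.
* The scan ranks windows by ΔAICc only; the randomisation and
  weighted-window diagnostics of dedicated window-scan software are out of
  scope.
* Interior gap years are handled by latent imputation, which assumes the AR
  process persists unchanged across the gap.
* The two structural models are estimated separately (an annually measured
  outcome cannot receive within-year indirect effects), so cross-model
  uncertainty is not propagated.
* AR pruning is a discrete model-selection step; its retention-conditioning
  bias is documented above rather than corrected.
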