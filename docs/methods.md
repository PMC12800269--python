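# Methods

This note documents the statistical machinery, the synthetic-data model
behind the tests, the numerical choices, and the known limitations.

## Climate-window detection

Daily climate is aggregated to weekly resolution by backward-counting from
a study-specific reference day: week *w* covers the seven days with
backward-day indices 7(w−1)…7w−1, where index 0 is the day immediately
before (and excluding) the reference day. A window (open, close) spans
weeks close…open inclusive; all pairs with 1 ≤ close ≤ open ≤ 104 (two
years) are candidates, so a full scan fits k(k+1)/2 = 5460 models.
Temperature windows are summarized by their mean, precipitation windows by
their sum. The reference day is fixed across years ("absolute" windows)
and must be supplied in the study metadata; day 366 clamps to the last day
of non-leap years.

Each candidate is scored by the weighted Gaussian regression
`trait ~ 1 + window + year` with weights 1/SE². The per-observation
variance is σ²·SEᵢ² with σ² profiled out, and
AICc = −2logL + 2k + 2k(k+1)/(n−k−1) with k = 4 (three mean parameters
plus the residual scale; the null model has k = 3). Years with missing
trait or SE are dropped; a scan needs more than five usable years. Ties in
AICc break toward the shorter window, then the smaller close week.

The scan is computed by orthogonalizing the base design (intercept + year)
once and adding each window column by the Frisch–Waugh identity; the scalar
`fit_window_model` is the reference implementation and the tests assert the
two routes agree to 1e-8 (and both agree with an independent
statsmodels-based oracle).

**Randomization null.** The spuriousness probability permutes the mapping
of study years to climate years — trait, SE and the year covariate travel
together — re-runs the full scan, and reports the add-one percentile

    p = (1 + #{Δrand ≤ Δobs}) / (1 + n_rand),   n_rand = 200 by default,

so p is floored at 1/(n_rand+1). The permutation null assumes the climate
aggregates are exchangeable across years *conditional on the study's
climate series*. Two practical consequences: (i) a trend in the climate
makes the observed (time-ordered) assignment special, which is why the
windowed climate's year trend is also controlled by the year covariate;
(ii) when a single climate realization is shared by many studies whose
traits are autocorrelated, the p-values are mildly conservative in
aggregate — calibration checks therefore give each null study its own
climate realization, matching the one-climate-per-location layout of real
collections.

Detrending regresses the selected window's per-year values on year by OLS;
the residuals (mean 0, orthogonal to year) are the climate variable C of
the path models.

## Per-study path analysis

Variables are z-transformed over the years entering each model (the growth
model re-standardizes its n−1-year slices); trait SEs are divided by the
temporal trait SD. Growth is G_t = ln(P_{t+1}/P_t), standardized over its
n−1 values, with G_t aligned to the year-t values of C, Z and P.

Both regressions are GLS with residual covariance σ²·D·R(ρ)·D, where
D = diag(SE-derived scales or 1) and R(ρ)ᵢⱼ = ρ^|tᵢ−tⱼ| (calendar-year
gaps enter the exponent, the continuous-time analogue). ρ is estimated by
profile maximum likelihood on (−0.95, 0.95) with a bounded scalar
optimizer (tolerance 1e-6); coefficients are GLS at ρ̂, standard errors use
the (n−p)-corrected σ̂², and R² is 1 − RSS/TSS on the standardized
response. The declared order of scaling — D·R(ρ)·D, i.e. heteroscedastic
scales applied outside the AR(1) correlation — is this package's
convention.

Fisher's C uses the single omitted directed claim P→Z given C: the claim's
p-value is the two-sided Wald p of P in the auxiliary weighted AR(1)
regression Z ~ C + P, then C = −2·ln(p) with df = 2, so the model p-value
equals the claim p-value exactly (an identity the tests assert).

The bootstrap draws each path coefficient independently from
Normal(estimate, SE²) — 10,000 draws by default — and summarizes
CZG* = CZ*·ZG* and TotalCG* = CZG* + CG* by the median and the
0.025/0.975 quantiles. ZG and CG share a model and are correlated; a
joint draw from the growth model's coefficient covariance is available
(`joint_growth_draw=True`) but off by default, keeping the simple
independent-draw contract.

## Across-study meta-analysis

For effect vector y with known sampling variances se², the marginal
covariance is

    V = diag(se²) + τ²_study·Z_s Z_sᵀ + τ²_loc·Z_l Z_lᵀ
        + σ²_n·Z_sp Z_spᵀ + σ²_p·Z_sp A Z_spᵀ,

the last term only in the phylogenetic variant. A is the shared-path-length
correlation of an ultrametric tree (A_ij = depth of the most recent common
ancestor divided by tree depth), which is the Brownian-motion correlation;
non-ultrametric trees are rejected rather than silently rescaled, and
polytomies are accepted as-is. Components are estimated by REML with fixed
effects profiled out, optimizing log-variances by L-BFGS-B from three fixed
starts with a Nelder–Mead polish; a single free component instead uses
bounded Brent refined by root-finding on the analytic REML gradient, which
reproduces the equal-variance closed form (τ̂² = s² − v̄) to 1e-8. A
component whose grouping has one group per record is confounded with the
study component and is pinned to 0 with a warning. The implementation is
cross-checked against metafor's `rma.mv` in the test suite.

Derived statistics: Pagel's λ = σ²_p/(σ²_n+σ²_p) (0 when both vanish);
multilevel Higgins I² = (sum of between-study components)/(that sum + s̃²)
with the typical sampling variance s̃² = (k−1)Σw/((Σw)²−Σw²), w = 1/se²;
Cochran's Q from the fixed-effects-only weighted fit with df = k − p.
Model choice between the phylogenetic and non-phylogenetic variants uses
marginal AIC = −2·REML loglik + 2·(#variance components); both variants
share identical fixed effects (the only setting in which REML likelihoods
are comparable), and ties go to the model without phylogeny.

Models for climate-dependent effects (CZ, CG, CZG, TotalCG) always include
P_ΔAICc and climate quality as covariates. Quantitative covariates are
grand-mean centred so the intercept is the across-study mean; factor
moderators enter as dummies (first level by alphabet as reference). The
moderator block Wald test reports the df actually fitted (latitude 1 +
generation time 1 + diet 2 + migratory mode 1 = 5 when all levels are
present) rather than assuming a count. The multiple-comparison threshold
is α divided by the number of moderator models per family (0.05/5 = 0.01
by default). The binomial sign test counts bootstrap-median CZG ≥ 0 and
reports the exact one-sided upper tail at p₀ = 0.5.

## Synthetic data

The generator deliberately mirrors the fitted analysis — linear, Gaussian,
AR(1) — so that parameter recovery is well posed. Per study:

- climate: seasonal sinusoid in day-of-year + per-year linear trend +
  AR(1) daily noise (defaults: mean 8 °C, amplitude 9 °C, noise SD 3 °C,
  daily autocorrelation 0.6, trend 0.03 °C/yr; precipitation clamped at 0);
- trait: latent z_t = cz·C̃_t + AR(1) noise, with C̃ the standardized
  true-window aggregate; observed trait = baseline + SD·z_t + SE_t·noise,
  with per-year SEs log-normal around `se_scale` (heteroscedastic and
  strictly positive) and measurement noise at exactly the drawn SE;
- growth: g_t = cg·C̃_t + zg·z_t + pg·x_t/s_ref + noise, with
  x = ln(P/P₀) and P_{t+1} = P_t·exp(scale·g_t), so populations are
  positive by construction; s_ref is the closed-form stationary SD of x
  under the linearized dynamics (a random-walk heuristic when pg ≥ 0);
  trajectories that overflow are regenerated with halved growth scale and
  a warning, never clipped.

Residual SDs default to "auto": they are set so the standardized trait and
the growth composite have unit marginal variance, which puts the generative
cz/zg/cg/pg on exactly the standardized scale the SEM estimates. The trait
has no independent year trend by default (the fitted SEM has no year term
for the trait), and growth innovations are serially independent by
default: with a dynamically fed-back population regressor, autocorrelated
growth noise makes the growth regression endogenous, so the fitted model
would no longer mirror the generator. Both AR(1) coefficients remain fully
settable.

Between-study heterogeneity applies to the climate–trait path: per-study
cz = cz_base + study + location + species effects, the species effects
multivariate normal with covariance σ²_species·(λ·A + (1−λ)·I). Trees come
from a hand-rolled Yule sampler (started from a single ancestor so even a
two-tip tree shares a positive stem; depth scaled to 1). The default
parameter values — cz −0.37, zg +0.05, cg −0.07, pg −0.4, λ 0.65,
τ²_study 0.05, τ²_location 0.02, σ²_species 0.04, 25-year series — are the
magnitudes reported for phenology–temperature systems in wild vertebrates.

What the generator does **not** emulate: non-linear climate–trait
relations, observation error in population counts, missing years,
age structure, multi-trait mediation, and real spatial correlation between
nearby locations. Passing recovery tests therefore demonstrate the
correctness of the estimation chain under its own assumptions, not
robustness to the full messiness of field data.

## Problem sizes and numerical choices

The test suite runs recovery simulations at 25–40 year series, 50–300
seeds, scans up to 26 weeks, randomizations at n_rand = 100–200, and
meta-analyses at k = 150 effects over 60 species with 100 replicates —
sizes at which all Monte-Carlo tolerances used in the tests are several
times the Monte-Carlo error. The acceptance script uses a 60-study
collection, max_weeks 26, n_rand 100 and n_boot 2000.

Numerical conventions worth knowing: z-scores use the ddof = 1 sample SD;
bootstrap quantiles use numpy's default (linear) interpolation; REML
variance components below 1e-9 are reported as exactly 0; the ρ search is
bounded at ±0.95; the scan declares a window degenerate (no AICc gain)
when its partialled-out sum of squares is below 1e-12 of the column scale.

## Known limitations

- **Density-dependence bias.** The growth model regresses G_t on P_t, and
  P_t integrates all past growth shocks. At series lengths around 40 years
  this produces the classic Hurwicz/Nickell small-sample bias — roughly
  −(1+3φ)/n in the implied mean-reversion coefficient, ≈ −0.07 on the PG
  path at n = 40 — which no faithful implementation of this estimator
  avoids and which is independent of the growth scale. Estimates of PG
  from short series are systematically too negative, and their nominal 95%
  intervals undercover (≈ 0.85 at n = 40). CZ, ZG and CG are unaffected.
- λ estimates from single collections are noisy and boundary-prone
  (SD ≈ 0.3 at 150 effects / 60 species); ensemble reporting over trees
  (`lambda_over_trees`) gives the honest spread.
- P_ΔAICc is exactly calibrated only under year-exchangeable climate; see
  the randomization-null paragraph above.
- The scan conditions on a single best window; selection uncertainty is
  summarized only through P_ΔAICc, not propagated into the SEM.
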