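# Methods

This note documents the models, the estimation machinery, the synthetic
data generator, and the numerical choices behind `fishgrowth`, with the
rationale for every default.

## 1. Growth functions

Two three-parameter size-at-age curves are supported.

**von Bertalanffy (vBGF)**
$L(t) = L_\infty (1 - e^{-k(t-t_0)})$ with asymptotic length
$L_\infty > 0$ (mm), Brody growth coefficient $k > 0$ (1/yr), and
location $t_0$ (yr), the hypothetical age of zero length. An
equivalent parametrization anchors the curve at the length at age zero,
$L(t) = L_\infty(1 - e^{-kt}) + L_0 e^{-kt}$; the two are connected by
$t_0 = \log(1 - L_0/L_\infty)/k$, and `vbgf_t0_from_L0` implements the
bridge. The package deliberately does not clamp negative lengths below
$t_0$: the curve is a model, and truncating it would silently change
likelihood values.

**Gompertz**
$L(t) = A \exp(-e^{-k_G(t - T_i)})$ with asymptote $A$, rate $k_G$, and
inflection age $T_i$. At $t = T_i$ the curve attains exactly
$A e^{-1}$, i.e. an integer 37% of the asymptote regardless of
parameters — a parameter-free analytic anchor used as a sanity check
throughout.

Internally both curves are parametrized as (log asymptote, log rate,
location): the log links keep asymptote and rate positive without
constrained optimization and make multiplicative individual variation
additive.

## 2. Mixed-effects structure

For fish $i$, the three curve parameters are

- $\log(\text{asymptote}_i) = \beta_a^\top x_{a,i} + \sigma_a u_{a,i}$
- $\log(\text{rate}_i) = \beta_r^\top x_{r,i} + \sigma_r u_{r,i}$
- $\text{location}_i = \beta_l^\top x_{l,i} + \sigma_l u_{l,i}$

with standardized effects $u_{\cdot,i} \sim N(0,1)$, independent across
parameters and fish. Observed lengths are conditionally Gaussian with a
single time-invariant error sd $\sigma_\varepsilon$ (mm). Each of the
three linear predictors takes its own design: constant, categorical
factors (population, species, cohort), numeric covariates, or `a:b`
interactions, coded by treatment contrasts with the reference level the
first one encountered in the data. Any subset of the three random
effects can be switched off per model.

The priors on the effects are deliberately independent even though real
fish plausibly have correlated asymptote and rate deviations: an
individual-level correlation should *emerge* in the empirical-Bayes
estimates when the data carry it, and the synthetic generator can
create exactly that situation (§5) to verify the pipeline detects it.

## 3. Estimation

**Marginal likelihood.** The per-fish random effects (dimension
$q \in \{0,\dots,3\}$) are integrated out with a Laplace
approximation: for each fish, a damped Newton iteration with analytic
gradients and Hessians of the joint negative log-likelihood finds the
empirical-Bayes mode $\hat e_i$; the marginal NLL is
$\sum_i f_i(\hat e_i) + \tfrac12 \sum_i \log\det H_i - \tfrac{qn}{2}\log 2\pi$.
The curve's first and second derivatives with respect to (log asymptote,
log rate, location) are closed-form for both growth functions and are
verified against finite differences in the tests.

Inner Newton safeguards: a Levenberg-style ridge when the Hessian's
smallest eigenvalue drops below 1e-6, a step-norm cap of 4.0 (effects
are standardized, so modes beyond ±4 are already extreme), backtracking
with up to 30 halvings, convergence at gradient norm 1e-8, at most 50
iterations. Inner failures are reported, and outer convergence requires
all fish to have converged.

**Quadrature oracle.** `gh_quadrature_nll` recomputes the same integral
with adaptive (mode- and curvature-centred) tensor Gauss–Hermite
quadrature, stabilized by log-sum-exp. It shares no code with the
Laplace path beyond the joint likelihood itself, so agreement between
the two (relative error < 1e-3 at $q=1$, < 5e-3 at $q=3$ on randomized
instances) validates both.

**Outer optimization.** L-BFGS-B on the packed vector (coefficients,
active log effect sds, log $\sigma_\varepsilon$) with finite-difference
gradients and warm-started inner modes, followed by up to five damped
Newton polishing steps on central-difference derivatives. A fit is
declared converged only when the relative gradient is below 1e-4, the
outer Hessian is positive definite, and every inner problem converged.
Standard errors come from the inverse central-difference Hessian of the
marginal NLL; natural-scale quantities get first-order delta-method
SEs. AIC is $2\,\text{NLL} + 2p$ with $p$ the number of estimated
outer parameters (random effects are integrated out, not counted).

Start values: log asymptote at $\log(1.1 \max y)$ (the asymptote must
exceed the largest observed fish), log rate at $\log 0.3$ (a typical
salmonid growth coefficient), location 0, effect sds 0.1 (small but
away from the boundary), and $\sigma_\varepsilon$ at one tenth of the
overall length sd — most length variation in a growth study comes from
age and individual differences, not measurement error.

## 4. Prediction and validation

Per-fish predictions evaluate the curve at the fish's empirical-Bayes
parameters; prediction SEs combine the fixed-effect covariance (delta
method through the curve) with the conditional spread of the fish's
effects from the inner Hessian. Unknown fish fall back to the
group-mean curve when group labels are supplied.

The hold-out protocol mirrors a field-realistic question — predict a
tagged fish's later sizes from its first measurement: fish captured at
least `min_captures = 4` times are eligible (strictly "more than three
records"), a seeded third of them (`floor(fraction · n_eligible)`) are
drawn as test fish, all but their earliest observation is masked, the
model is refitted on the masked data, and the held-out lengths are
scored by $R^2$ against the 1:1 line,
$1 - \sum(\text{obs}-\text{pred})^2 / \sum(\text{obs}-\bar{\text{obs}})^2$,
plus the maximum absolute error. Replicate splits are shared across all
candidate model specs so comparisons are paired; a model is
rank-eligible only if its full-data fit and every replicate refit
converged. Five replicates is the default: hold-out $R^2$ varies by a
few hundredths between splits, and five paired replicates separate
model specs clearly at a fifth of the cost of a full cross-validation.

## 5. Synthetic data generator

`generate(SimulationConfig)` emulates a multi-year tagging study:

- **Structure**: four populations mapped to three species
  (`LIdri_MT`, `UIdri_MT` → MT; `LIdri_RT` → RT; `UVol_BT` → BT),
  birth cohorts 2004–2011, September sampling at integer ages 1–8.
- **Sparsity**: annual survival 0.6 and capture probability 0.7.
  These rates are not published for the real study; the values are
  plausible placeholders for stream salmonids and produce the
  characteristic 1–3 records for most fish with a minority of long
  trajectories. They are configuration, not constants.
- **Tagging threshold**: fish enter the record at their first capture
  above 115 mm (small fish cannot carry a tag); earlier captures are
  discarded. This creates the realistic left-truncation where fast
  growers are observed earlier. `None` disables it.
- **Truth**: per-population natural-scale parameters themed on stream
  salmonids, e.g. vBGF (330 mm, 0.35/yr, −0.30 yr) for `LIdri_MT` and
  (222 mm, 0.60/yr, −0.20 yr) for the brown trout population; effect
  sds 0.15 (log asymptote), 0.15 (log rate), 0.3 (location);
  measurement error 5 mm — roughly the repeatability of a field length
  measurement.
- **Emergent correlation**: optionally the asymptote and rate effects
  are drawn from a correlated bivariate normal
  (`rho_asym_rate`); the fitted model keeps independent priors, so any
  recovered individual-level correlation is data-driven.
- Every run returns the dataset plus a ground-truth table (drawn
  effects and natural-scale parameters per recorded fish) and is
  deterministic given `seed`.

**Limitations**: lengths are exactly on-curve plus Gaussian error (no
seasonal growth, no size-selective mortality beyond the tag threshold,
no measurement-error dependence on size); capture is independent across
years; ages are known exactly. These are the same idealizations the
fitted model makes, which is what a recovery study requires — the
generator is a realism-themed oracle, not a stream ecosystem model.

## 6. Problem sizes and budgets

Defaults are desk-scale by design: 150 fish per population (≈ 400–500
recorded fish study-wide), which fits in well under a second per
Laplace fit for constant models and a few seconds for fully
population-structured ones. Recovery studies in the test suite use
400-fish datasets with 50 replicate refits, and the complete test suite
(including the end-to-end acceptance properties) runs in a few minutes
on one CPU. Quadrature checks use up to 31 nodes in one dimension and
15 per dimension in three (3 375 tensor nodes per fish), far past the
point where the integral has converged for these likelihoods.
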