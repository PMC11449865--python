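# Methods

## Model and assumptions

The structural model is a one-compartment disposition model with
first-order absorption and first-order elimination, parameterized as
CL/F (L/h), V/F (L), Ka (h⁻¹).  All doses are oral; bioavailability F is
inseparable and never appears as its own symbol.  Concentrations are in
ng/mL (≡ µg/L with doses converted mg → µg; that factor lives in one place,
the structural prediction).  Multiple dosing — including mid-course dose
reductions 400 → 320 → 240 mg — is handled by superposition of the
analytic single-dose solution over the explicit dosing history; no
steady-state shortcut is used, so irregular histories are exact.  The
removable singularity at Ka = k is replaced by its analytic limit
`C = 1000·D·k·Δt·e^(−k·Δt)/V` when |Ka − k| < 1e−8·k; the closed form is
verified against numerical integration of the two-state ODE system at
rtol 1e−6 across Ka/k ratios from 1.001 to 100.

Between-subject variability (BSV) is lognormal on CL and V
(`P_i = P_pop·e^η`, η ~ N(0, ω²), diagonal Ω); Ka carries no random effect
(the data contain almost no absorption-phase samples).  Residual error is
proportional by default (`Y = IPRED·(1+ε)`), with additive and combined
forms available.  Reporting conventions: BSV %CV = 100·ω (SD scale) and
proportional residual %CV = 100·σ_p.

Covariate submodels on a typical value θ₁: linear `θ₁ + θ₂·(cov/med)`,
power `θ₁·(cov/med)^θ₂`, exponential `θ₁·exp(θ₂·cov/med)`, and categorical
`θ₁·θ₂^cov` (cov ∈ {0,1}, no centering).  The centering constant is the
dataset median, recomputed per dataset.  The final pyrotinib model uses the
exponential form for TP on CL with θ₂ = 0.376 centered at 67.2 g/L: at the
median TP this gives CL/F = 88.8·e^0.376 ≈ 129 L/h, consistent with the
base model's 127 L/h.  Note this form is **not** normalized to 1 at the
median — θ₁ and θ₂ ride a near-collinear ridge (see Identifiability).

## Estimation: FOCE with interaction

The marginal likelihood is approximated by first-order conditional
estimation with η–ε interaction.  Per subject, the empirical Bayes mode η̂
minimizes

```
l(η) = Σ_j [ (y_j − f_j(η))² / w_j(η) + log w_j(η) ] + ηᵀΩ⁻¹η ,
```

with the residual variance w evaluated at the η-dependent individual
prediction (the interaction).  With G = ∂f/∂η at η̂, R = diag(w(η̂)),
V = GΩGᵀ + R and r = y − f(η̂) + Gη̂, the objective is

```
OFV = Σ_i [ log det V_i + r_iᵀ V_i⁻¹ r_i ]          (no n·log 2π term),
```

so OFV values can be negative and nested-model differences are
χ²-distributed under the null.  On 1-η problems the OFV agrees with a
41-node Gauss–Hermite quadrature of the true marginal likelihood within
0.5 units at ω = 0.3 (tested).

Numerical design of the inner problem: subjects are padded into arrays and
solved independently in compiled (numba) loops with analytic ∂f/∂η.  The
conditional objective can be bimodal when ω approaches 1 (the study's
ω_V ≈ 0.97 ≈ 100 %CV), so the solver evaluates a small start grid
(0, ±1.6ω per dimension), refines the two best starts with damped
Gauss–Newton (step clipping at ±2, backtracking line search, tolerance
1e−10), and keeps the better mode.  Everything is cold-started, making the
OFV a deterministic, reproducible function of the population parameters;
following a single basin instead makes the outer surface discontinuous
wherever a subject's preferred mode flips, which stalls or misleads the
outer optimizer.

Outer optimization: θ, ω and σ are log-transformed (positivity); covariate
coefficients stay on the natural scale.  A coarse adaptive Nelder–Mead
(explicit start simplex: 10 % steps on log-scale entries, 0.3 on covariate
coefficients, whose natural start of 0 would otherwise get a microscopic
default step) is followed by a restarted small-simplex polish (2 % steps,
xatol 1e−4, relative fatol 1e−6).  Gradient-based polishing was
deliberately avoided: near the optimum the surface is flat in ΔOFV units
and finite-difference line searches stall.  Generous box bounds (±4
log-units around the initial values, ±10 on covariate coefficients)
guard against a pathology of the linearized objective: at extreme ω
(≳ 2, i.e. several hundred %CV) spurious basins exist whose FOCE OFV is
far below the sane region while the true (quadrature) likelihood rejects
them.  Fixed parameters (Ka = 0.357 h⁻¹ in the final model) are never
perturbed.

Diagnostics: CWRES uses the same linearization with a symmetric
(eigendecomposition) matrix square root, and is ~N(0,1) under a correct
model; η-shrinkage = 100·(1 − SD(η̂)/ω), ε-shrinkage = 100·(1 − SD(IWRES)).
Standard errors use the sandwich estimator (numerical Hessian of OFV/2 and
per-subject score cross-products, h = 1e−4 on the transformed scale,
delta-method back), cross-checked against a Monte-Carlo replicate SD; the
bootstrap is the recommended fallback whenever the Hessian is ill-behaved.

## Covariate search

Pre-screening drops covariates missing in > 20 % of subjects and
dichotomous covariates with minority prevalence < 10 %, and keeps exactly
one member of each |r| > 0.7 Pearson-correlation cluster (priority TP, WT,
TBIL, AST over their partners, configurable).  The formal search is
forward inclusion (accept the largest drop if ΔOFV > 3.84, χ²₁ at p<0.05,
strict) to exhaustion, then backward elimination (retain only if deletion
raises OFV by > 10.83, p<0.001, strict); a full-model strategy (fit all
screened candidates, backward-eliminate only) is available by flag.
Decisions depend only on ΔOFV.  When a term is deleted, its mean multiplier
over the dataset is folded back into the typical value before refitting —
without this the non-normalized exponential form strands the reduced model
far along the θ₁/θ₂ ridge.  Clinical relevance evaluates each term at the
observed covariate extremes against the median; changes above 20 % are
flagged.  For the published TP effect the change is −9.7 %/+7.8 % over
49.0–80.7 g/L — not clinically relevant, hence no dose adjustment.

## Synthetic cohorts

The generator emulates the study design: 50 subjects, exactly 158 samples
(per-subject counts allocated around the mean 3.16), once-daily oral
dosing at 240/320/400 mg (default mixing 20/30/50 %, 15 % of subjects with
a mid-course reduction — the study reports dynamic dosing but not the
proportions; these are fixed, realistic choices), 20 dosing days with
opportunistic sampling uniform (0.5, 24] h after a dose on or after day 14
(steady state; the terminal half-life is ~31 h, so ≥14 daily doses are
simulated explicitly).  Continuous covariates use truncated-normal margins
parameterized by the published median (location) and range (±3 SD
truncation); the right-skewed laboratory values (AST, TBIL, SCR, and their
correlated partners ALT, DBIL, IBIL, whose ranges span more than a decade)
are log-normal on the same median/range rule.  Correlated blocks
(WT/BMI/HT at r = 0.85/0.75, AST/ALT and the bilirubins at r = 0.8) are
induced through a Gaussian copula; dichotomous covariates are Bernoulli at
the published prevalences (diarrhea 48 %, montmorillonite 18 %, loperamide
30 %, ER 56 %, PR 50 %).  Simulated concentrations apply lognormal BSV and
the residual-error model; proportional-error draws below −1 (which would
flip the concentration sign) are resampled and counted; values below the
1 ng/mL LLOQ are flagged BLQ.  All generators are pure functions of
(design, seed).

What the generator does **not** emulate: time-varying covariates,
absorption lag or food effects (dosing was 30 min after meals; no lag term
is published and none is implemented), enterohepatic recirculation,
metabolite kinetics, dropout, and any dependence of dose reduction on
observed toxicity.  Passing recovery tests therefore demonstrates
correctness of the estimation machinery under the model's own assumptions,
not robustness to real-data violations of them.

Data-handling rules mirror the study: BLQ observations omitted;
observations with |CWRES| > 6 under a supplied fit flagged and removed
(self-simulated clean data produce none; a 50× inflated observation is
caught — note that proportional error absorbs smaller multiplicative
distortions because the variance scales with the prediction); covariates
missing in > 20 % of subjects dropped.  Every exclusion is logged with a
reason.

## Qualification tools

Bootstrap: subjects resampled with replacement (cohort size preserved,
optional dose-stratification), each replicate refit from the original
estimates; converged replicates summarized by median and 2.5/97.5
percentiles plus relative bias.  VPC: the dataset's exact design is
simulated n_sim times from the model, the BLQ rule applied, and observed
5/50/95th percentiles compared with across-replicate medians and
nonparametric 95 % CIs in quantile-based time-after-dose bins (8 by
default; quantile bins because opportunistic sampling makes fixed-width
bins fragile; plain, not prediction-corrected).  GOF tables are long-format
(DV, PRED, IPRED, CWRES, time, TAD, subject).  The Ka sensitivity grid
refits with Ka fixed at each of 0.10–0.50 h⁻¹; on sparse data the OFV is
flat (< 3.84 spread over 0.30–0.50), reproducing the insensitivity that
justified fixing Ka.

## Identifiability and approximation properties (read before interpreting)

Two quantitative caveats are intrinsic to this study design and model
form, and the package's own tests measure both:

- **The TP coefficient is weakly identified.**  Because TP/67.2 has mean
  ≈ 1 but SD ≈ 0.08 across patients, θ₂'s information comes only from the
  narrow covariate spread: SE(θ₂) ≈ ω_CL/(√n·SD(TP/med)) ≈ 0.46 even at a
  rich 200-subject design (and ≈ 0.9 at the study's n = 50).  Single-fit
  estimates of θ₂ — and, through the ridge, of θ₁ alone — scatter widely
  while CL at the median TP stays stable.  Recovery experiments therefore
  compare medians across seeds, and intervals for θ₂ should come from the
  bootstrap, not the curvature.
- **FOCE bias at ~100 %CV BSV.**  With ω_V ≈ 0.97 the linearization is
  exercised far from its comfort zone: against a 2-D Gauss–Hermite
  quadrature oracle, the FOCE surface's optimum is shifted (median
  recovered V/F ~8–13 % low, CL/F ~5–10 % high at the rich design) even
  though per-subject approximation errors are only ~0.2 OFV units.  This
  is a property of the method, not of the optimizer (quadrature prefers
  the truth; profiling confirms the fits sit at the FOCE optimum).
  Similarly, the FOCE likelihood-ratio test shows its documented
  small-sample inflation at very sparse designs (type-I ≈ 11–13 % at
  3 samples/subject vs 5.0 % measured at 4 samples/subject with 40
  subjects, 200 null replicates).

## Problem sizes and defaults

Default experiment sizes used by the test-suite and the acceptance script:
recovery at 200 subjects × 6 samples with medians over 5 (tests) or 9
(script) seeds; null calibration at 200 replicates of 40 × 4; bootstrap
self-checks at 20 replicates; VPC self-checks at 100 simulations.  The
outer optimizer caps (per-stage simplex iteration limits) are part of each
experiment's stated protocol.  Seeds are explicit everywhere; identical
(design, seed) pairs reproduce results bit-for-bit.

## Known limitations

Diagonal Ω only (no CL–V correlation); no inter-occasion variability; BLQ
data are excluded rather than integrated (no M3-type likelihood); no
SAEM/Bayesian estimation; one- (and comparator two-) compartment
disposition only; the assay module computes validation statistics from
replicate tables and calibration responses, not from chromatograms (LLOQ
S/N ≥ 10 and LOD S/N = 3 are carried as metadata definitions).
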