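# Methods

## The model

`htr3mix` fits raw (non-normalized) peak-current amplitudes from
two-electrode voltage-clamp recordings of 5-HT3 receptors expressed in
*Xenopus* oocytes.  The structural model for a single observation is a
chain of four components:

1. **Agonist response** — a four-parameter logistic (Hill) curve,
   `PRED = Min0 + (Max - Min0)·[A]^nH / ([A]^nH + EC50^nH)` with
   `EC50 = 10^(-pEC50)`.  `Min0` is representable but fixed to 0 by
   default: the preparations show no basal current.
2. **Time drift** — the maximal response drifts linearly with hours
   since the start of that oocyte's experiment,
   `MaxT = Max0·(1 + nT·T)`, floored at 0 (the floor only matters under
   out-of-design extrapolation).  `nT = -0.1` means a 10 %/h decline.
3. **Insurmountable inhibition** — an inhibitor at concentration `[D]`
   depresses the maximum, `MaxD = MaxT / (1 + ([D]/IC50)^nH(D))`, with
   complete block in the `[D] → ∞` limit.
4. **Generalized Schild shift** — the same drug may shift agonist
   potency, `pEC50(D) = pEC50,0 - nG·log10(1 + ([D]·10^pA2)^nS)`.
   At `nS = nG = 1` this is the classical Schild relation (EC50 ratio
   `1 + [D]/KB`); `nG = 0` removes the effect entirely.  The two
   exponents let a likelihood-ratio test distinguish competitive-like,
   absent, and steeper-than-competitive shifts.

Between-oocyte variability enters through Gaussian random effects
(`eta`) applied additively (pEC50, pIC50s, pA2, nT) or multiplicatively
(`Max0·exp(eta)`, which keeps the maximum positive), with joint
covariance OMEGA.  The default configuration carries seven etas with a
single free covariance between the pEC50 and Max0 effects — the
parsimonious structure that captures the strong empirical correlation
between expression level and apparent agonist sensitivity.  Residual
variance follows a power law, `RUV = alpha²·PRED^gamma`, spanning
constant (`gamma = 0`), proportional-variance (`gamma = 1`) and
constant-CV (`gamma = 2`) error models.

## Estimation

The marginal -2 log-likelihood is approximated per oocyte with the
Laplace method.  The inner objective

`g(eta) = Σ_obs [(y - PRED)²/V + ln V] + eta' Ω_a^{-1} eta + ln det Ω_a`

is minimized over the oocyte's *active* eta subset (random effects on a
drug the oocyte never received are integrated out exactly — their
Gaussian factors integrate to one — keeping the inner problem at most
four-dimensional).  The contribution is `g(η̂) + ln det(H(η̂)/2)` with
`H` the Hessian of `g` at the mode; the `(2π)^{k/2}` Laplace factor
cancels the eta-prior normalization, so the expression is exact for any
linear-in-eta, constant-variance configuration (the test suite asserts
this against the closed-form Gaussian marginal, and against 64-node
adaptive Gauss–Hermite quadrature on nonlinear toys).

Numerical details that matter:

- **Inner solver.**  Damped Newton with analytic eta-gradients (chain
  rule through the four structural components and the variance model);
  the Hessian is central finite differences of that gradient.  Armijo
  backtracking plus per-instance Levenberg damping; gradient tolerance
  `1e-8` scaled by `(1 + |g|)`.  Everything is vectorized so that all
  oocytes at all outer finite-difference points are solved in one batch.
- **Bimodal inner problems.**  A weakly expressing oocyte admits two
  conditional modes — "low expression, normal sensitivity" and "normal
  expression, low sensitivity".  A single cold start can hop basins as
  the outer parameters move, making the marginal objective
  discontinuous.  The solver therefore always starts from `eta = 0` and
  additionally, for instances whose summed observed current differs
  from the `eta = 0` prediction by more than a factor `e^0.3`, from a
  start with the multiplicative Max0 eta set to the log
  observed/predicted ratio; the lower mode wins.  Both starts are
  deterministic functions of the data, so refits are bit-reproducible.
- **Variance floor.**  `RUV` is evaluated at
  `sqrt(PRED² + eps²)`, `eps = 1e-4 µA`.  A floor is needed because a
  zero prediction would give zero variance and an unbounded likelihood;
  the *smooth* form matters because a hard `max(PRED, eps)` puts a
  gradient crease exactly where near-silent oocytes' modes sit, which
  corrupts the Laplace curvature term.
- **Hessian safeguards.**  The log-determinant uses absolute
  eigenvalues (PSD repair).  Flooring small/negative eigenvalues
  instead would *reward* the outer optimizer for driving inner problems
  indefinite (each floored eigenvalue contributes about -23 to the
  objective), a failure mode observed during development.
- **Outer problem.**  L-BFGS-B on transformed parameters (log scale for
  positivity-bounded quantities; OMEGA as log-SDs plus
  atanh-correlations for disjoint 2×2 blocks, guaranteeing positive
  definiteness; a full Cholesky parametrization is available).
  Gradients are central finite differences with relative step `1e-5`,
  evaluated in a single vectorized pass over all `2p + 1` points.
  Failed optimizations restart from up to three deterministically
  perturbed starts.
- **Objective conventions.**  `ofv` drops the `n·ln 2π` data constant;
  `ofv_full = ofv + n·ln 2π`.  `AIC = ofv_full + 2p` and
  `BIC = ofv_full + p·ln n`, with `p` counting free fixed effects, free
  OMEGA entries and free RUV parameters.  The full default model has
  p = 22 (12 fixed effects + 7 SDs + 1 correlation + alpha + gamma);
  with that count the published AIC/BIC values are internally
  consistent with the published objective value under exactly this
  convention.
- **Standard errors.**  Inverse of the central-finite-difference
  Hessian of half the objective at the optimum, delta-method-mapped to
  the natural scale; withheld whenever the curvature matrix is not
  positive definite (e.g. a parameter with no influence on the fit).

## Hypothesis testing

Nested variants are refit and compared by likelihood-ratio test;
degrees of freedom are the difference in free-parameter counts, which
makes block tests such as freeing `{nG, pA2, nS}` for one drug df = 3
automatically.  Variance-component nulls sit on the boundary of the
parameter space where the naive chi-squared reference is conservative;
the battery reports the naive p-value as primary (matching standard
practice in the field's software) with the 50:50 mixture p-value as a
secondary column for df = 1 boundary rows.  No multiplicity correction
is applied by default; a Bonferroni column is available behind a flag.
For derived quantities (variant-shifted potencies) standard errors
combine by independent Gaussian propagation, `sqrt(Σ se_i²)`.

## Synthetic data

The generator emulates the oocyte study design: 55 wild-type oocytes /
532 peak currents, in three experiment classes —

- 8 oocytes with 9-point drug-free 5-HT curves (0.3–300 µM),
- 28 oocytes with a 3-point drug-free curve followed by an 8-point 5-HT
  curve in the presence of one inhibitor concentration (citral 11,
  eucalyptol 9, linalool 8 oocytes, concentrations drawn from the
  declared grids: citral 10–1000 µM, eucalyptol 100–2000 µM, linalool
  100–500 µM),
- 19 oocytes with fixed-agonist (1.7 µM) concentration-inhibition runs
  bracketed by drug-free controls (8 applications each),

for 8·9 + 28·11 + 19·8 = 532 exactly.  Successive applications are
0.07 h apart (a ~1-minute application plus a 3-minute wash), so each
experiment spans up to ~0.8 h and exercises the time-drift term.  The
within-oocyte control applications in the second class are essential:
without them a drug-induced potency shift is confounded with that
oocyte's own pEC50 random effect, and the shift parameters (pA2, nS)
and the Max0–pEC50 correlation are recovered with far less precision
than the original study reports — so the allocation with internal
controls is the faithful reading of the protocol.  An optional T6'S
block adds 11 oocytes / 113 observations (control curves plus 2 µM 5-HT
inhibition runs) with covariate shifts on pEC50, the pIC50s and Max0.

Per oocyte, `eta ~ MVN(0, OMEGA)`; each record gets an additive
Gaussian residual with the power variance.  Negative simulated currents
are floored at 0 (well under 1 % of records at the default noise
level) and counted in the log.  The default generative truth is the
published best-fit estimate set (Max0 4.94 µA, pEC50 5.65, nH(A) 2.94,
nT -0.13/h; citral pIC50 3.92 / nH 1.34; eucalyptol pIC50 3.59 /
nH 1.04 / pA2 3.09 / nS 1.70 / nG 1; linalool pIC50 3.85 / nH 2.19;
eta SDs 0.18, 0.95, 0.18, 0.32, 0.16, 0.05, 0.19 with correlation 0.87;
alpha 0.30, gamma 1.30).

What the generator does *not* emulate: current time-courses,
desensitization and rebound kinetics, use-dependence, series-resistance
artifacts, or day/batch effects.  Passing recovery tests therefore
shows that the estimator inverts its own generative assumptions at the
study's design size — not that those assumptions hold for any
particular recording.

Two headline parameters are intrinsically noisy at this design size:
the Schild exponent nS (reported ± 0.24) and the eta correlation
(reported ± 0.05).  Single-replicate estimates scatter accordingly;
the recovery checks use ±3 reported SEs.

## Dual application

Two blockers applied together discriminate shared-site (syntopic) from
independent-site (allotopic) binding.  With single-drug fractional
inhibitions `ia`, `ib`, the allotopic prediction multiplies unblocked
fractions, `1 - (1-ia)(1-ib)`; the syntopic prediction adds occupancy
ratios, `(a+b)/(1+a+b)` with `a = ia/(1-ia)`.  Syntopic never exceeds
allotopic, so measured inhibition above the allotopic prediction
indicates positive interaction.  Measured inhibitions are quantified
against drug-free control responses linearly interpolated to the
application time (no extrapolation), absorbing within-experiment drift.
The original analysis used a mixed two-way ANOVA with Dunnett post-hoc
comparisons; this package instead performs paired within-oocyte
t-tests of measured minus predicted inhibition with a Šidák correction
for the two planned comparisons — the same inferential target without
depending on a specific ANOVA implementation.  The occupancy-ratio form
assumes unit Hill coefficients; a Hill-generalized variant is available
but has no single canonical closed form and is off by default.

## Problem sizes and runtimes

The full recovery fit (55 oocytes, 532 observations, 22 free
parameters) takes on the order of one to four minutes on a single CPU.
The likelihood-ratio calibration study uses a deliberately scaled-down
design — 15 oocytes × 8 observations, two random effects, gamma fixed
at its generating value — so that 200 simulated replicates (a reduced
and a full fit each) complete in minutes.  The chi-squared shape check
for interior nulls uses a random-effect-free logistic model at 6
oocytes × 7 observations over 500 replicates.

## Known limitations

- The Laplace approximation is least accurate for oocytes with few
  observations and large random-effect variance; the quadrature
  cross-checks bound the error at ~0.1 objective units on such toys,
  but no adaptive-quadrature estimation mode is provided.
- The block test for a drug's pEC50-shift parameters evaluates a null
  under which pA2 and nS are unidentified nuisance parameters; its
  chi-squared reference is approximate (the calibration test measures
  the realized size empirically).
- `fit_model` supports random effects on pEC50, Max0, nT and per-drug
  pIC50/pA2; etas on Hill coefficients are not implemented (none are
  used by the default model).
- OMEGA structures with overlapping correlated pairs require the full
  Cholesky parametrization.
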