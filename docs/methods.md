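# Methods

`pdsmeq` implements a three-stage measurement-equivalence analysis for a 7-item
perceived-discrimination scale answered on a 5-point Likert scale by youth in
six intersectional cells (Black/Latinx/White × female/male), together with a
synthetic-data generator that stands in for the access-restricted cohort data.

## Covariate coding

Sex, race/ethnicity, and their interaction enter every model through five
orthogonal Helmert contrast codes: sex (female = 1, male = −1), race1
(Black = −1/3, Latinx = −1/3, White = 2/3), race2 (Black = −1/2, Latinx = 1/2,
White = 0), and the two products sex×race1, sex×race2.  The codes are stored as
exact rationals and converted to floats only when a model matrix is built, so
the thirds never accumulate rounding.  They are fixed constants of the scheme:
the design is *not* re-centred at observed cell proportions, which means the
columns are exactly orthogonal only under balanced cells; `verify_orthogonality`
reports (never enforces) departures.  Two consequences worth keeping in mind:

* a race effect on the factor mean moves the *population* mean away from zero
  (the x = 0 reference point is not any observed cell), so posterior factor
  scores average to the sample mean of the fitted α(x), not to 0;
* the race pair and the interaction pair are treated as retention units
  everywhere: a unit is significant when any member is, and units are kept or
  dropped whole.

## The MNLFA model

For person *i* with covariates x<sub>i</sub> and responses y<sub>i</sub> ∈ R⁷:

    eta_i ~ N(alpha(x_i), psi(x_i)),   y_ij = nu_j(x_i) + lambda_j(x_i) eta_i + e_ij,
    e_ij ~ N(0, theta_j)

with alpha(x) = βᵀx, psi(x) = exp(δᵀx), nu_j(x) = nu_j0 + κ_jᵀx, and
lambda_j(x) = lambda_j0 + ω_jᵀx.  Identification fixes the baseline factor mean
at 0 and variance at 1 with all seven loadings free; moderation is interpreted
relative to the x = 0 reference.  The log-linear variance link keeps psi(x)
positive by construction.

Indicators are treated as continuous (linear-normal links), so the marginal
distribution of y at x is multivariate normal with mean ν(x) + λ(x)α(x) and
covariance ψ(x)λ(x)λ(x)ᵀ + diag(θ), and the marginal likelihood is closed-form.
An ordinal (graded) link is out of scope.  This choice follows the reported
analysis surface (item "intercepts" rather than thresholds; unadjusted scores
built as item means) and makes every downstream quantity (likelihood, Wald
tests, posterior scores) exact rather than quadrature-based.

**Computation.**  The covariates take at most six distinct values, so the
likelihood is evaluated from per-cell sufficient statistics (n, mean vector,
covariance); the rank-one structure of Σ(x) gives log-determinants and inverses
via the matrix-determinant lemma and Sherman–Morrison.  A full fit at
n ≈ 10,000 costs well under a second.  Optimisation is L-BFGS-B on the packed
free-parameter vector (θ log-parameterised) with finite-difference gradients,
gradient tolerance 1e−6, at most 500 iterations; starting values are item means
for ν₀, 1 for λ₀, half the item variances for θ, 0 for all moderation.
Standard errors come from the numerically differentiated observed information
(central differences with a relative step of 1e−4 — the default step is small
enough that roundoff can make the estimated Hessian indefinite); a singular
information matrix falls back to the pseudo-inverse with the affected
parameters excluded from Wald reports.  Robust (sandwich) standard errors are
not implemented.

**Factor scores.**  The posterior of eta given y is normal with mean
α + ψλᵀΣ⁻¹(y − μ) and variance ψ − ψ²λᵀΣ⁻¹λ; the posterior mean is the
bias-adjusted score.  Under the default generator parameters the within-group
SD of these scores is √(l/(1+l)) ≈ 0.813 with l = Σ λ_j²/θ_j ≈ 1.95.

**Reliability.**  Coefficient omega at the baseline,
ω = (Σλ_j)² / ((Σλ_j)² + Σθ_j), is 0.660 under the default parameters.

## Stage 1: multiple-group CFA

Configural, metric, and scalar one-factor models are fitted jointly to the six
cells by plain ML on per-group sufficient statistics.  Identification:
configural fixes every group's factor mean at 0 and variance at 1; metric and
scalar free the variance (and, for scalar, the mean) in all non-reference
groups.  Fit is summarised by the ML chi-square against the saturated model,
CFI against an independence baseline (free means and variances, zero
covariances per group), and RMSEA using total n (the √G convention is a switch,
default off), with a 90% CI from inverting the noncentral chi-square CDF.
Nested levels are compared with three criteria reported separately — ΔCFI >
0.01, chi-square-difference p < .05, disjoint RMSEA CIs — and "decrement" is
declared if any fires.  Satorra–Bentler scaling is deliberately not
implemented: all validation here runs on synthetic normal-kernel data, and the
robust corrections would need fourth-moment machinery without changing any
decision in that regime.  Degrees of freedom for 7 items × 6 groups are 84 /
114 / 144 (checked against hand counts).

## Stage 2: staged DIF selection

1. **Impact screen** — all five covariates moderate the factor mean and
   log-variance with an invariant measurement model; a (target × unit) is
   carried if any member has p < .10 (strict).
2. **Item screens** — for each item in turn, all five covariates moderate that
   item's intercept and loading (other items invariant, carried impact effects
   included); carried at p ≤ .05 (inclusive).
3. **Conditional model** — one simultaneous fit of all carried effects.
   Structural units must re-qualify at p < .05; measurement units proceed to
   trimming.
4. **FDR trimming** — Benjamini–Hochberg at q = .05 over loading units, refit,
   then over intercept units, refit (block trimming with two refits, not
   per-effect iteration).

Two design choices in step 4 were genuinely open and deserve explanation:

* **The BH family is all tested units of the class** (21 = 7 items × 3 covariate
  units; units screened out earlier enter with p = 1), not only the carried
  ones.  Screening guarantees every carried p-value is below .05 = q, so BH over
  the carried set alone would reject essentially everything that survived the
  screens and the trimming step would control nothing; against the full family
  the step actually guards against the Type-I inflation it exists for.  The
  carried-only variant remains available (`trim_family="carried"`).
* **A unit's p-value is the Šidák-corrected minimum of its member p-values**,
  1 − (1 − min p)^k: the raw minimum of k tests is not a valid p-value for the
  union hypothesis "any member nonzero", and using it would make pair units
  systematically easier to keep than singleton sex units.

A consequence worth stating plainly: the procedure's specificity under a fully
invariant population is intrinsically about 0.90 at n = 9,360 — each of the two
BH passes carries roughly a 5% chance of a false retention, and replicate
simulations of the full pipeline (the selection-pattern study in
`pdsmeq.experiments`) measure the fully-invariant rate at ≈ 0.90, fluctuating
either side of that value run to run.  A user wanting stricter control should
lower `fdr_q` rather than expect the two-pass q = .05 design to deliver more.

One structural hazard of the staged design is handled explicitly: when a
factor-mean unit *and* the matching intercept unit of every single item are
carried (a common outcome when intercept DIF leaks into the impact screen),
the model is exactly unidentified — adding c to β_k and subtracting λ_j c from
every κ_jk leaves the likelihood unchanged.  The conditional step then anchors
the item with the weakest screening evidence (largest screen p), removing its
intercept unit so the remaining DIF is interpreted relative to the anchor.
The anchoring is recorded in the selection trace.

Every decision (stage, effect, estimate, SE, p, threshold, kept, reason) is
appended to a `SelectionTrace`; replaying the trace reproduces the final active
set, and the same seed and config give an identical trace.

## Stage 3: scoring and group comparisons

Unadjusted scores are the mean of the seven raw items (persons with a missing
item are listwise-excluded, with a logged count).  Adjusted scores are the
posterior factor scores under the final trimmed model.  Comparisons are run in
three families — sex (1 pair), race/ethnicity (3), intersectional (15) — each
corrected by BH at q = .05 separately (a global-family switch exists).  The
test is a Welch-type z on weighted means with variances from the weighted SDs
and raw counts; weights enter means and SDs with frequency-weight
normalisation, while raw group counts are used in the pooling degrees of
freedom and in the Hedges correction J = 1 − 3/(4N − 9), keeping the
small-sample correction well defined under arbitrary positive weights.  Effect
sizes are binned at |g| ≥ 0.2 / 0.5 / 0.8 (half-open bins); pairs not surviving
FDR are labelled "ns".  No multilevel/site-clustered standard errors are
computed.

## Synthetic-data generator

The generator emulates the cohort the analysis was designed for, and its
defaults are the study conditions:

| quantity | default | source/rationale |
|---|---|---|
| n | 9,360 | analytic sample size |
| cell counts | 747/741/1007/1092/2695/3078 | reproduce 47.53% female, 15.90% B, 22.42% L, 61.68% W |
| ν₀ | 0 (all items) | latent response scale origin |
| λ₀ | 0.60, 0.55, 0.60, 0.55, 0.50, 0.50, 0.55 | calibrated once so closed-form ω = 0.66 ∈ [0.60, 0.72] |
| θ | 1.15, 1.05, 1.15, 1.10, 1.00, 1.00, 1.18 | same calibration; no data provenance |
| thresholds | 1.05, 2.10, 3.20, 4.30 (all items) | right-skewed Likert output, category 1 modal |
| κ (sex) | −0.21 on item 1, −0.15 on item 3 | the two reported DIF effects ("final_model" scenario) |
| β (race) | −0.5551 on race1, −0.2731 on race2 | latent mean gaps = reported adjusted g (0.851 B–W, 0.515 L–W) × 0.813 (model-implied score SD) |
| weights | none, or mean-1 lognormal (σ = 0.3) | stand-in for ascertainment weights |

DIF is injected on the continuous latent response before discretisation, which
matches the linear-indicator model the pipeline fits.  Missing data are off by
default (an MCAR rate is available for robustness checks).

**What the Likert output does and does not emulate.**  Discretising through
four thresholds reproduces the coarse, heavily right-skewed response
distributions of the real scale (≈ 80% "Almost never").  But the linear-normal
model is then only an approximation: the threshold map is nonlinear, so the
large race differences in the latent mean turn into small spurious race
moderation of intercepts and loadings on the Likert scale, which n = 9,360 can
detect (an n = 4,000 Likert run retains spurious loading/variance units
alongside the true sex effects), and the injected DIF coefficients are
attenuated (≈ −0.064 recovered for the −0.21 truth).  For this reason the
validation experiments — parameter recovery and selection-pattern rates — run
on the generator's continuous output, where the fitted model class coincides
with the generating process and "recovering the configured truth" is well
defined.  Passing those experiments shows the estimator and the staged
selection work as designed; it does not show that a linear-indicator analysis
of real 5-point data is free of discretisation bias (with ordinal data of this
skewness it demonstrably is not — a known limitation shared with any
continuous-indicator treatment of coarse Likert items, and the reason an
ordinal-link variant would be the natural next extension).

Similarly, two structural facts about the synthetic world differ from the
tables the generator emulates: the uncentred Helmert codes put the adjusted
scores' grand mean at the weighted mean of α(x) (≈ −0.17) rather than ≈ 0, and
the injected sex intercept DIF produces a small real sex gap in *unadjusted*
scores that a 9,360-person comparison can flag — which the bias-adjusted
scores then correctly remove.  Both are consequences of the generating design,
not bugs; the tests assert the structural pattern (level sex groups after
adjustment, positive Black–White and Latinx–White gaps under both scorings).

## Monte-Carlo experiment sizes

The recovery study uses 50 replicates at n = 9,360; the selection-pattern
studies use 20 replicates per scenario at n = 9,360.  Per-replicate seeds are
spawned from one base seed via a seeded generator, so every experiment is
reproducible end to end.  These sizes put Monte-Carlo error well below the
assertion tolerances (recovery MC SE ≈ 0.002 against a 3-SE band) while keeping
a full validation run in minutes on one core.

## Known limitations

* Continuous-indicator likelihood only; no ordinal/graded link.
* Plain ML chi-square in the CFA stage; no robust scaling, so real-data (non-
  normal) fit statistics would be anti-conservative.
* No site/cluster structure in either the generator or the comparison SEs.
* The weighted z-test is a pragmatic choice; the analysis it emulates does not
  name its test statistic, and with extreme weight variability a replication-
  based variance estimator would be preferable.
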