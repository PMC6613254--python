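# Methods

## The model

Two bounded integer total scores `X1` (maximum `m1`) and `X2` (maximum
`m2`) — typically the raw totals of two self-report instruments intended to
measure the same construct — are modelled as conditionally independent
power-series variables sharing one person parameter `ξ ≥ 0`
(`θ = log ξ` on the additive scale):

    P(X_i = x | ξ) = ξ^x γ_ix / Σ_h ξ^h γ_ih ,   x = 0..m_i .

The non-negative score parameters `γ_ix` play the role Rasch item
parameters play for a polytomous "super item"; indeed the total of any set
of partial-credit Rasch items has exactly this distribution, with `γ` the
convolution of the per-item category weights (`gamma_from_thresholds`).
The total `R = X1 + X2` is again power-series with parameters
`ω_r = Σ_x γ_1x γ_2,r−x`, and the split of `R` into `(x, r−x)` satisfies

    P(X1 = x | R = r) = γ_1x γ_2,r−x / ω_r ,

free of `ξ`: the total score is sufficient for the person parameter.  This
is what permits conditional inference — estimation and testing that require
no assumption about how persons are distributed or sampled.

All probability computations run on the log scale with a running-maximum
subtraction, so score ranges up to ~108 and extreme `ξ` cannot overflow.
`ξ = 0` and `ξ = ∞` are honoured as explicit limits (point masses at the
boundary of the γ-support), which makes the equating endpoints total.

## Estimation

**Score parameters (CML via IPF).**  Persons enter only through the
two-way score table.  Conditional on the diagonal totals, the model is a
quasi-independence loglinear model (row effects × column effects × one free
factor per total-score diagonal), whose MLE is computed by iterative
proportional fitting over the three margins.  At convergence the fitted
conditional expected counts reproduce the observed row and column margins
within every diagonal.  Stopping rule: maximum absolute change of the
fitted conditional split probabilities over one cycle ≤ 1e-9 (configurable;
up to 200,000 cycles — IPF converges linearly, and sparse tables of
realistic size can need several tens of thousands of cheap cycles).  The
inner loop is compiled with numba when available; a pure-numpy
implementation with identical semantics is the fallback and is tested for
agreement.

The conditional likelihood identifies `γ` only up to one constant per scale
and a common geometric tilt `a^x` (any person distribution can absorb the
diagonal factors).  Every inferential output — conditional splits, the
conditional log likelihood, fit tests, equating tables — is invariant to the
convention (tested to 1e-9).  Reported parameters set the first supported
`γ` of each scale to 1 and, by default, centre the tilt so that the mean
person estimate over observed interior total scores is 0, which keeps `θ`
numerically small.

Scores never observed in the data have inestimable `γ` (the conditional
likelihood drives them to 0); fits and equating tables are restricted to
the observed score ranges, and conversion values for never-taken raw scores
are deliberately not interpolated.

**Person parameters.**  The MLE of `θ` given a single score solves
"expected score = observed score" on the test characteristic curve; it is
found by Newton–Raphson on `θ` (the derivative is the score variance) with
bisection fallback inside a sign-changing bracket, to |expected − target| ≤
1e-10.  Scores at the support boundary have no finite MLE and are handled
by the endpoint convention (lowest score ↔ `θ = −∞`, highest observed score
↔ `θ = +∞`).

## Tests of fit

Score tables are large and sparse, so no asymptotic reference distribution
is trusted; all three table-level tests are referred to a parametric
bootstrap that *conditions on the observed total-score counts `n_r`*: each
pseudo-table redistributes the `n_r` persons over the splits of diagonal
`r` according to the fitted conditional distribution, and the model is
refitted on every pseudo-table so the null distributions include the
estimation step.  Bootstrap p-values use the `(1 + #extreme)/(S + 1)`
convention (never exactly 0); S defaults to 1000, with S = 199 adequate for
screening.

1. **Conditional LRT.**  `G² = 2 Σ obs·ln(obs/exp)` over occupied cells,
   with `exp = n_r · P(x | r)` under the fit; upper-tail bootstrap p.
2. **Gamma discrepancy.**  The observed Goodman–Kruskal gamma of the table
   minus the gamma of the fitted expected table, two-sided against its
   bootstrap distribution.  The discrepancy form matters: the fitted model
   reproduces the margins that pin gamma, so the raw observed gamma barely
   varies around its expected value and a test based on it alone has
   essentially no size or power.
3. **Person-misfit count.**  Each person's split `x` of their total `r` is
   tested with a two-sided conditional exact test ordered by probability;
   the default *mid-p* tail (half weight on splits exactly as probable as
   the observed one) keeps the per-person flag rate near the nominal 5% on
   discrete supports, where the strict tail (available as
   `method="exact"`) is conservative.  The flagged count is referred to its
   bootstrap null distribution; the standalone operation also reports an
   asymptotic chi-square p against the *model-implied* flag probability
   (computable exactly from the fitted conditional pmfs), since the flags
   of a model fitted to the same data are less variable than binomial and a
   fixed-5%-null chi-square would have size near zero.

Verdict convention: p ≤ 0.01 on any test — or at least two tests
significant at 5% — is strong evidence against the model; exactly one p in
(0.01, 0.05] is moderate evidence; otherwise the model is taken to fit.

Calibration, measured on 500 tables simulated from the model (0–24 × 0–12
scales, n = 722, S = 199), puts each test's rejection rate at the 5% level
within 5% ± 3 percentage points (the conditional LRT runs mildly hot, ~7%,
because the bootstrap cannot propose splits outside the observed support).

**What these tests cannot see.**  They are purely conditional: any joint
distribution of the form `a_x b_y c_{x+y}` fits perfectly, whatever the
persons do.  With bivariate-normal latent traits, divergence between the
two scales' traits (correlation < 1, or different logit units) produces
joints of essentially that form — the Gaussian moment structure
`exp(σ²(x² + y² + 2ρxy)/2)` factorizes into row × column × diagonal terms —
so even nearly unrelated traits go undetected.  What the tests do detect is
*local dependence* between the scores themselves (shared or near-duplicate
items, copied responses, careless responding), which distorts the
within-diagonal split law.  Construct equivalence therefore needs content
arguments in addition to fit statistics; the simulation module exposes
both families of violation so users can see the distinction.

## Equating

**Direct (common persons).**  For each observed source score: estimate the
person parameter, evaluate the expected target score at it, round to the
nearest integer with halves away from zero (the rounding dialect is a
declared convention; only non-half cases occur in practice).  Endpoints map
lowest→lowest and highest-observed→highest-observed.  Produced tables are
non-decreasing by construction of the monotone test characteristic curves.

**SEE.**  The Standard Error of Equating of a source score is the standard
deviation (S−1 denominator around the bootstrap mean) of its equated score
over S nonparametric bootstrap resamples of the table (multinomial over
cells — equivalent to resampling person records for collapsed data), each
refitted and re-equated.  Replicates whose fit fails are dropped and
counted (> 5% triggers a warning).  The per-score bootstrap error
distributions are retained; the SEE recomputed from a stored distribution
equals the stored SEE (internal consistency, tested).  A weighted SEE mean
(weights = observed source-score frequencies, so sparse score groups do not
inflate the summary) below **0.91** is regarded acceptable: 0.91 is the SEE
of the worst error distribution still considered tolerable (roughly a third
of replicates each at −1, 0, +1 plus 2.5% at ±2).

**Indirect (common scale).**  B → C through a scale A present in both
samples chains the B → A and A → C direct tables: the (generally
fractional) expected A score is carried through the expected-C curve by
linear interpolation on the grid of observed A scores (the midpoint rule at
half-integers is the special case; the grid form also covers holes in the
observed range).  Expected A scores outside sample 2's observed range are
clamped with a warning.  Its SEE resamples both tables independently and
replays the whole chain; with two estimated equatings in series the
indirect weighted SEE mean exceeds the direct one at equal sample sizes
(verified in the acceptance suite).  Equating from a wide scale onto a
narrow one is more precise than the reverse — each narrow-scale score fans
out over several wide-scale scores.

## Synthetic data

The generator emulates two cross-sectional self-report samples: bounded
integer totals (ranges like 0–24, 0–12, up to 0–108) driven by a shared
latent trait with `θ ~ N(μ, σ²)`, defaulting to `N(0, 1)` and n = 722 (a
realistic cohort size for a single-centre clinical study).  The normal
person distribution is a generator convention, not a model assumption —
conditional estimation is distribution-free — and is stated as such.
Scales are specified either by γ vectors or by partial-credit item
thresholds; the two pathways are distributionally equivalent (tested).
Controlled violations: trait correlation < 1 and per-trait logit rescaling
(the near-invisible family, see above), plus `copy_rate` and
`careless_rate` local-dependence contaminations (the detectable family).
All generators are pure functions of (scenario, seed).

What passing tests on these data do *not* show: robustness to item-level
DIF, non-normal trait distributions, missing-data mechanisms beyond
pairwise-complete deletion, or instrument-specific floor/ceiling artefacts
— none of which the generator emulates.

## Numerical and design notes

- Parameter recovery is verified as a *bias* check: the fitted conditional
  splits averaged over 10 independent replicates of n = 20,000 match the
  generating values within 0.01 total variation per well-populated total
  score.  A single replicate at that size has sampling error of the same
  order as the tolerance (near-extreme diagonals carry only about `n_r`
  observations' worth of information), so a one-draw comparison would
  measure noise, not the estimator.
- Correctness of the IPF estimator is established against brute-force
  numerical maximization of the conditional likelihood on small
  all-positive tables (agreement to 1e-6 in the maximum and 1e-5 in the
  conditional splits).
- Problem sizes in the test-suite simulations (scale ranges 0–4 … 0–24,
  n = 500 … 50,000, S = 199, 500 calibration replicates) were chosen so
  each check has the statistical resolution its tolerance requires.
- Degenerate inputs: empty tables raise; tables in which every observed
  total admits a single split carry no conditional information and are
  flagged non-identifiable (their γ is reported but arbitrary); all-tie
  tables give an undefined (NaN) Goodman–Kruskal gamma.
- Missing scores are handled pairwise-complete per scale pair; no
  imputation is attempted (documented limitation).

## Known limitations

- Only total scores enter; item-level Rasch estimation, DIF analysis and
  loglinear extensions with modelled local dependence are out of scope.
- Conversion values for raw scores absent from the sample are not
  interpolated.
- The conditional fit tests cannot reject person-level multidimensionality
  with (approximately) Gaussian trait structure; see above.
- The SEE reflects sampling error of the equating only, not model
  misspecification.
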