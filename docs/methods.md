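# Methods

## The problem and the measures

`equicost` quantifies how the costs of *accessing* primary health care —
not the price of treatment alone, but the whole visit — are distributed
across household wealth and place of residence. The cost of one visit is
split into time costs (minutes travelling to the facility, waiting, and
in consultation) and direct costs (transport fares and out-of-pocket
medical payments). Travel time and transport cost are recorded for the
one-way journey; an optional round-trip convention doubles exactly those
two components and nothing else. Currency amounts are recorded in
Tanzanian shillings and converted to USD at the survey-period rate
(1 USD = 1600 TZS by default); conversion keeps full precision
internally and rounds only at reporting time (USD to 2 decimals, minutes
to 1, shares to 0.1 percentage points).

Three equity measures are computed per outcome:

- **equity gap** — difference of group means, disadvantaged group first
  (poorest quintile − least-poor quintile, or rural − urban), with a
  Welch two-sample t-test;
- **equity ratio** — quotient of the same means; reported as an explicit
  *undefined* value (not infinity, not an exception) when the comparison
  mean is zero;
- **concentration index (CI)** —

  CI = (2/μ) · cov(y_i, R_i),

  where y_i is the outcome, R_i the fractional wealth rank and μ the
  mean. CI < 0 means the burden is concentrated among the poorest.

## Wealth index and fractional ranks

Household wealth is proxied by the first principal component of the
standardised asset/housing indicator matrix (correlation-scale PCA, the
standard choice for mixed binary/ordinal items; categorical items must
be one-hot-expanded upstream — the concrete item list is survey
configuration, not code). Constant indicators are dropped with a
warning; missing indicator values are a hard error instructing upstream
mode-imputation or row exclusion, so the imputation policy stays an
explicit caller decision. Because eigenvectors are sign-ambiguous, the
score is oriented to correlate positively with the row sum of
standardised indicators: higher score = wealthier, always.

Fractional ranks are midpoint ranks on the cumulative (weight) share:
an untied unit-weight observation at sort position i gets
R_i = (i − ½)/n; ties receive the average of the ranks their positions
would occupy (equivalently: cumulative weight of strictly poorer
observations plus half the tie group's own weight, over total weight).
This tie rule is what keeps the weighted mean of ranks at exactly ½ —
the identity that makes the covariance form of the CI, the sum form
2·Σy_iR_i/(nμ) − 1, and the regression slope below coincide. Quintiles
are cut on the fractional rank, `min(floor(5R) + 1, 5)`, so tied scores
can never straddle a quintile boundary and untied samples split into
fifths differing by at most one record.

## Numerical conventions for the CI

All covariances use the **population convention** (divide by total
weight, not n − 1). With the midpoint ranks this makes the sum-formula
identity exact rather than exact-up-to-(n−1)/n; the three formulations
agree to ~1e−15 in the test suite. Degenerate inputs: an all-zero
outcome has no defined CI (error); a constant positive outcome has
CI = 0 with p = 1; |CI| is bounded by (n−1)/n, attained when the entire
outcome mass sits on the top-ranked individual.

Inference uses the *convenient regression*: OLS of
z_i = 2·var(R)·y_i/μ on R_i. Its slope equals the CI to machine
precision (the sample/population covariance factors cancel between
numerator and denominator), which doubles as a second, independent
implementation of the point estimate; the heteroskedasticity-robust
(HC1) standard error of the slope with a two-sided normal p-value tests
CI = 0. At n = 500 the robust SE agrees with a 2000-resample bootstrap
within a few percent. Weighted samples go through WLS with the same
algebra.

Binary outcomes (probability of paying, travel-mode shares) run through
the same machinery as 0/100 indicators. The plain CI of a bounded
variable does not span (−1, 1); no Wagstaff or Erreygers normalisation
is applied, matching common reporting practice for such tables, and the
caveat travels with the output rather than being silently corrected.

Significance stars use strict inequalities — *** p < 0.01, ** p < 0.05,
* p < 0.10 — so a boundary p-value maps to the weaker star. A p exactly
0.05 is therefore one star, not two; the convention is stated because
"significant at 5%" is ambiguous at the boundary.

## Stratified analysis

Each outcome is analysed on its own complete-case subset (no
imputation), so per-outcome n differs; counts are recomputed after every
restriction and never cached. Wealth scores are computed once on the
full sample handed to the analysis; within each outcome's subset the
fractional ranks and quintiles are recomputed from those scores, so the
mean-rank-½ identity holds in every analysis sample. For wealth and
residence the output is the full equity triple (gap, ratio, CI); for
facility ownership, facility level, and service type it is group means
with Welch tests against the reference group (public facility, hospital,
ANC). Mode-specific rows (travel time on foot / by car / by motorbike
or bicycle) filter on travel mode before summarising; "for all" rows
pool modes. Transport cost is reported both over all clients and
conditional on payers, because a self-reported zero conflates "did not
pay" with "no fare existed"; both rows are labelled. A public-only
robustness restriction reruns everything on the ~82% of records from
publicly owned facilities (where ownership then has a single level, the
facility table stratifies by level alone).

No survey weights and no facility-clustered variance estimation are
supported: the target analysis is unweighted, and adding design-based
variance machinery would change what the stars mean. No outlier trimming
is applied to self-reported times or costs.

## The synthetic survey generator

The generator exists so that every pipeline stage can be validated
against known ground truth, at the scale of the survey it emulates:
1400 patients, ≤ 10 per facility across 150 facilities, 82% public
facilities, 12/32/106 hospital/health-centre/dispensary split, 82.8%
rural residents, service mix ≈ 24/27/10/40% (ANC/PNC/vaccination/
check-up), 8.9% insured.

Structure, all driven by one `numpy` generator seeded from the mandatory
config seed:

- latent wealth w ~ N(0, 1) per patient-household; the true fractional
  rank R is computed from w and stored in the ground-truth sidecar;
- 42 binary asset indicators with P(item j = 1) = logistic(α_j + λ_j w),
  α_j spread over [−1.5, 1.5], λ_j = 1 — informative enough that the
  recovered PCA score attains Spearman ρ ≈ 0.93 with w, which is the
  reliability the pipeline realistically has to work with;
- travel mode by multinomial logit in w (slopes −0.8 / +1.0 / +0.5 for
  foot / car / motorbike-bicycle — walking pro-poor, vehicles pro-rich);
  intercepts are calibrated deterministically (Gauss–Hermite fixed
  point) so the *marginal* shares hit the configured 71.1/8.5/20.5%
  targets; residence uses the same device for the 82.8% rural marginal
  with slope −0.7;
- each outcome has E[y | R] = a + bR with gamma noise for times
  (shape 2 — visibly right-skewed) and lognormal for cost amounts
  (σ = 0.8): travel a = 40, b = −20 min; waiting a = 56.2, b = −19;
  consultation a = 12.9, b = 0; medical amount-among-payers a = 280,
  b = 3560 TZS; transport amount a = 800, b = 4560 TZS. These reproduce
  the emulation targets: means 30.1/46.7/12.9 min, overall 0.41/0.23
  USD, extreme-quintile gaps ≈ 16/15 min;
- zero inflation: medical cost is paid with rank-independent probability
  0.178; transport cost is zero for all foot travellers, and the
  remaining travellers pay with the conditional probability that makes
  the marginal payment share 0.213;
- per-outcome missingness (18.8/0.9/2.3/7.7/0.6%) reproduces the
  differing complete-case n of the emulated survey.

**Closed-form oracle.** A linear-in-rank mean gives a large-sample CI of
CI_∞ = 2·b·var(R)/μ → b/(6a + 3b) (var(R) → 1/12, μ = a + b/2), and an
extreme-quintile gap of −0.8b (E[R | q1] = 0.1, E[R | q5] = 0.9). The
closed form is invariant to rank-independent thinning (the mean scales,
the CI does not change), so it also holds for the zero-inflated medical
cost. It deliberately does *not* hold for transport cost, whose zeros
are wealth-dependent through mode choice: its realised CI exceeds the
amount-process value, as in real data, and the sidecar marks it as
having no closed form. With the travel-time defaults,
CI_∞ = −20/(240 − 60) = −1/9 ≈ −0.111, a pro-poor time burden of the
magnitude the pipeline is designed to detect.

**Recovery behaviour.** Through the full pipeline (PCA ranks, not true
ranks) the three time outcomes recover CI_∞ within ±0.02 at n = 10,000
across 20 seeds; rank-proxy attenuation is roughly proportional to |CI|
(≈ 0.007 at CI = −0.11 for ρ ≈ 0.93). The heavy-tailed zero-inflated
medical cost is a different regime: even scored with the generator's
*true* ranks its CI at n = 10,000 has a sampling spread of several
hundredths (lognormal σ = 0.8, 17.8% payers), so for it the tests check
unbiasedness over seeds and sign/magnitude rather than a per-seed
±0.02 band. That spread is a property of skewed zero-inflated
expenditure data generally and is one reason published CIs for payment
variables carry wide stars.

**What the generator does not emulate** — and therefore what passing
tests do not demonstrate about real surveys: facility-level clustering
of unobservables, any mode–residence–wealth joint structure beyond the
separate logits, informal payments, recall error, and care-seeking
selection (only attenders are observed; a real poorest-of-the-poor
never reaches the facility and no simulated record represents them).
Distributional fidelity beyond the headline magnitudes is not claimed.

## Problem sizes in the checked runs

The test suite and the acceptance script run the generator at the
emulated survey scale (n = 1400) for descriptive checks, and at
n = 10,000 × 20 seeds (tests) / 10 seeds (acceptance script) for CI
parameter recovery — large enough that the ±0.02 recovery band is
dominated by genuine estimator behaviour rather than seed luck, while a
full run stays within a coffee break on one core.

## Known limitations

- The CI standard error is the HC1 convenient-regression SE; analytic
  delta-method and bootstrap variants can differ in the third decimal,
  so star patterns near thresholds should not be over-read.
- PCA on the correlation matrix of binary items is standard but not
  polychoric; wealth indices built with different item recodings will
  rank a few households differently near quintile boundaries.
- Ratios of near-zero means are numerically legal but scientifically
  meaningless; the tables carry them without suppression.
- The replication driver (`equicost.replicate`) assumes the deposited
  study table has been converted to the canonical CSV schema; it ships
  with no data.
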