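# Methods

`ruraldce` models the question facing a health ministry that wants more
physicians in rural postings: which bundle of non-wage incentives (housing,
transport, accelerated promotion, continuing education, facility upgrades)
buys the most health per dollar?  The pipeline has three linked parts:
preference estimation from a discrete choice experiment (DCE), a workforce
and costing projection, and a cost-effectiveness ranking.

## Choice model

Respondent *n* choosing between two hypothetical job postings *A* and *B*
derives utility difference

    ΔU_nt = (x_A − x_B)' β_n + ε_nt,

with logistic ε.  Attributes are the six job characteristics of the Lao PDR
instrument (salary with 4 levels, housing 3, transport 3, career promotion
3, continuing education 3, facility quality 2).  Non-salary attributes are
dummy coded against their most basic level; the salary attribute is coded by
its numeric proportional increase (0, 0.3, 0.4, 0.5), so the salary
coefficient β_S is "utility per 100% of annual salary".  In the mixed logit
each non-salary coefficient is normal across respondents,
β_nk ~ N(b_k, s_k²), independent between components; salary is fixed in the
base specification.

Estimation is maximum simulated likelihood: the respondent likelihood
averages the product of task probabilities over R draws of β_n.  Draws are
scrambled Halton sequences in per-respondent blocks (seed-reproducible);
the default is 500 draws, and the packaged simulation studies use 128,
which keeps each n = 2000 fit under half a minute while leaving simulation
bias an order of magnitude below the sampling SEs.  The optimizer is
L-BFGS-B on an analytic gradient, started from conditional-logit estimates
(means) and 0.1 (SDs), capped at 500 iterations.  Standard errors come from
the inverse observed Hessian of the simulated log-likelihood (centered
finite differences of the analytic gradient); mixing SDs are reported as
absolute values, with the covariance sign-adjusted accordingly.  With all
SDs forced to zero the simulated likelihood reduces exactly to the analytic
conditional logit, which is used as an oracle in the tests, alongside a
64-node Gauss–Hermite quadrature oracle for low-dimensional mixing.

Separation (a coded column whose sign never varies against the observed
choices) is detected before fitting and flagged rather than silently
producing divergent estimates.

## Design generation and synthetic survey

The original instrument came from commercial conjoint software.  Here a
design is the best of N (default 200) random level-balanced candidates
scored by D-efficiency — the determinant of the within-task-centered coded
information matrix, normalized per parameter — with duplicate alternatives
within a task repaired by perturbation.  This is transparent, reproducible,
and adequate because the estimation stage is design-agnostic.

The synthetic survey emulates the study conditions: 329 respondents, 12
binary forced-choice tasks, one shared design block, coefficients drawn
from the published mean/SD table, and Bernoulli choices at the implied
logit probabilities (329 × 12 × 2 = 7896 evaluation rows).  What the
generator does **not** emulate: real respondents' attribute non-attendance,
fatigue or ordering effects, blocked designs, and any correlation between
random coefficients.  Passing parameter-recovery tests therefore show the
estimator is consistent for this data-generating process, not that the
published survey data would be recovered.

## Valuation and uncertainty

Component valuation is (b_c / b_S) × annual salary ($1128/year; the source
reports 751,450 LAK per month alongside US$1128 per year, and the yearly
dollar figure is the operative number because the published valuation table
uses it).  SEs use the first-order delta method on (b_c, b_S) with the
estimated covariance; tests check agreement with a 50,000-draw parametric
bootstrap within 5%.  Valuation/cost ratios divide the valuation CI bounds
by the annualized component cost.

## Preference impact and uptake

A package's utility is the sum of its component coefficients (mean = sum of
means, variance = sum of variances).  The predicted preference impact (PPI)
is the probability of preferring the package over a salary-only posting:
plug-in = logistic(mean), simulated (default, 100,000 seeded draws) =
average logistic over the normal package utility.  PPI 0.5 is indifference;
the rural-uptake relative risk is 2 × PPI, capped at 2.  Where the package
table lists career promotion without a level, immediate promotion is
assumed (configurable).

## Workforce projection

Strata: private (urban), public urban, public rural; baseline stocks from
the 2011 public-system counts (1187 public physicians, 273 rural) and a 70%
public share.  Each year the stock attrites at 2.5%, then 180 graduates
enter: 30% private, and the rural share of public entrants is the baseline
0.23 multiplied by the package's relative risk (capped at 100% of public
entrants).  Timing convention: attrition first, entrants at year end,
entrants attrite from the following year.  These conventions are package
choices — the source's printed no-program rural count for 2016 (300) is not
derivable from its stated parameters under any obvious timing, so absolute
counts are treated as order-of-magnitude context, not targets.

Demography is a geometric stand-in for UN urbanization tables: total
population grows at 1.4%/year from 6.275 M (2011) and the rural share
(0.658) declines 0.5%/year relative.  Densities are physicians per 10,000
by location.

## Costing

Unit costs are the published 2011–12 figures (housing $12,500 construction
/ $360 allowance, transport $625/year, promotion $1500 one-time, training
$5600 at 18% annual uptake = $1008 expected, facility upgrades $100k/$25k
district and $25k/$4.25k local at 10 and 100 per year until the 120/836
totals run out).  Capital follows cash or straight-line depreciation (30
years buildings, 7 equipment).  Variable benefits accrue per retained
rural recruit (attrition-adjusted) for the remainder of the horizon;
promotion is billed once at entry plus its lag; housing construction is
accepted by 50% of recruits.  Facility programs are uptake-independent and
attributed to the incentive program at 1/10.

Deferred nominal-fixed fees are deflated by the inflation path (6.7%,
5.3%, then interpolating to the 3% discount rate after year 5):
$1500 one year out is 1500/1.067 ≈ $1406.  The engine's net deferral
factor is Π(1+d)/(1+i), so deferral and discounting cancel once inflation
equals the discount rate.  The engine's own per-physician facility cost
(year-1 depreciated total $213,095 × 0.1 / 21 ≈ $1015) differs slightly
from the published $1030; the fixture carries the published figure for the
valuation ratio column and the engine computes its own elsewhere.

## Health effects

Per year, location and outcome (infant, under-5 excl. infant, maternal
mortality): %Δ density → %Δ outcome via a log-log elasticity → cases
averted against baseline incidence split rural/urban by population share →
QALYs per case from remaining life expectancy at the event age (0, 2.5, 25
years; configurable life table) weighted by age-specific QALY/life-year
ratios (default 1.0) and discounted at 3%; yearly totals are further
discounted to program start.  National net effects subtract urban losses
from rural gains.

The elasticities are **placeholders** (−0.24, −0.26, −0.39): the source
regression is external and unpublished here, and the source's own QALY
totals are two orders of magnitude smaller than these literature-scale
elasticities imply, so absolute QALY and ACER levels from the default
configuration are not comparable to the published table.  Orderings —
QALYs monotone in rural density gains, densities monotone in PPI — are the
meaningful outputs and are what the tests assert.  The published
per-package cost/QALY figures are packaged separately and drive the
ranking logic (frontier {4, 1}; 7 of 15 packages under the $3786/QALY
threshold at 5 years, 3 at 30 years) without re-deriving absolute levels.

## CEA ranking

Comparator: no program at (0 cost, 0 QALYs).  Strong dominance removes
options at least as costly and no more effective than another; extended
dominance prunes iteratively until frontier ICERs strictly increase.  With
exactly tied ICERs a strictly increasing chain keeps only the most
effective of the tied points (verified against a greedy lower-hull oracle
on random instances).  The under-threshold count uses strict "<" on ACERs;
the optimal package is the highest-QALY frontier point with ICER ≤
threshold.  ICERs are computed from unrounded values; rounding happens only
at reporting.  Univariate sensitivity scenarios (accounting method,
horizon, discount, attrition, sector shares, ±1 SD utility shifts, salary
scaling) re-run the pipeline as pure re-parameterizations.

## Numerical choices and limitations

- All randomness flows from one seed per run via spawned seed sequences;
  outputs are byte-identical across identical runs.
- Estimation supports binary forced-choice tasks (the instrument's format);
  multinomial tasks are simulated but not estimable.
- Random coefficients are independent normals; correlated or non-normal
  mixing, latent classes and hierarchical Bayes are out of scope.
- PPI assumes "most basic incentive level" means zero non-salary components
  at equal salary, anchoring indifference at 0.5.
- Problem sizes in the test-suite simulation studies (n = 2000
  respondents, 20 replicate seeds, 128 draws) are package choices that
  keep each study to a few minutes while leaving Monte Carlo error well
  below the tolerances asserted.
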