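# Methods

## Measurement model

`dscorekit` measures a single latent developmental trait. A PASS/FAIL
response x_ni of child n on milestone i follows the Rasch model

    P(x_ni = 1) = logistic(beta_n - delta_i),

with local independence across milestones given beta. The model yields an
interval scale: differences in ability mean the same thing wherever they
occur on the scale, which is what licenses comparisons across ages,
visits and milestone subsets.

Ability and difficulty are expressed in **D units**. The metric is fixed
by anchoring two milestones at 20 D and 40 D; under this convention ~0 D
corresponds to newborn ability and ~50 D to the median 1-year-old. The
package plugs D-unit values of beta and delta into the logistic directly
(one D treated as one logit). This convention exactly reproduces the
five-milestone worked example shipped as a fixture (55.7 D for the
all-pass child) and is applied consistently in scoring, diagnostics and
simulation; no separate slope parameter relates the D metric to the
logit metric anywhere in the package.

## Item calibration

Difficulties are estimated by pairwise conditional estimation. For items
i and j administered at the same measurement occasion, conditional on
exactly one of the two being passed, the probability that it was i is
free of beta:

    P(pass i, fail j | discordant) = exp(delta_j) / (exp(delta_i) + exp(delta_j)),

with larger delta meaning harder. The pseudo-likelihood over all
discordant pair counts n_ij is maximised by a fixed-point iteration on
eps_i = exp(delta_i),

    eps_i <- sum_j n_ji / sum_j (n_ij + n_ji) / (eps_i + eps_j),

with log-scale over-relaxation (factor 1.6), geometric-mean normalization
per sweep, tolerance 1e-6 on the max log change, and at most 1000 sweeps
(the defaults of `RaschCalibrator`). If the iteration has not converged
an L-BFGS pass on the same objective (analytic gradient) finishes the
job; the two routes agree because the objective is concave in delta up
to translation. Pairs never observed discordant contribute nothing.
Mean-zero normalization identifies the logit solution; the anchoring
transform D = a + b·logit then sends the two anchor items exactly to
their fixed values.

Pairs are formed **within a visit** by default — a child's repeated
answers across visits come from different abilities, so pooling them
(available via `pool_waves=True`) would violate the conditioning
argument. Because only discordant pairs enter, perfect scores drop out
of the likelihood automatically and no records are deleted.

Properties worth knowing:

- Estimates are invariant to translations of the ability distribution
  (specific objectivity); tested by simulation.
- The item-pair graph must be connected for a common metric; the
  calibrator warns and reports components otherwise.
- When co-administered items sit many logits apart (as happens between
  the easy "standard" and hard "additional" sets of a surveillance
  design under the D-as-logit convention), discordance becomes
  near-deterministic and carries little information; relative
  difficulties across such gaps are then weakly identified and the
  recovered metric can stretch at the extremes. Dense co-administration
  designs do not have this problem; see the simulation notes below.

## Scoring

The D-score of one measurement occasion is the mean of the posterior
ability distribution (EAP), computed on a fixed quadrature grid of
integers from −10 to 80 D (91 points; extend `grid_hi` for children
older than ~2.5 years). The reported measurement error (sem) is the
posterior SD.

The starting prior is normal with SD 5 D — wide enough to be dominated
by four or more informative responses, tight enough to keep scores for
perfect response patterns finite — centred on the reference median at
the child's age. The centre is taken from the *nearest row* of the
reference table rather than by interpolation: the table mesh is roughly
weekly, the discrepancy is hundredths of a D against a 5 D prior SD, and
the convention keeps every number reproducible from the printed table
rows alone.

Updating is Bayes' rule with the Rasch likelihood, computed in log space
for stability. Item order cannot matter (the posterior is a product);
batch and sequential updating agree to 1e-12 and both are tested.
Missing responses are skipped entirely: the posterior equals the prior
when nothing was observed. Flipping any single response moves the score
in the expected direction (tested). All-PASS patterns on easy items
produce a ceiling: the score exceeds the prior mean but stays within the
grid; widen the grid rather than trusting scores near its edge.

When no reference exists yet, `DScorer(reference=None)` bootstraps a
provisional median curve: score everything under a flat-wide prior
(mid-grid mean, SD a quarter of the grid span), re-centre the prior on a
binned running median of score against age, and repeat; two passes are
used, after which the scores change negligibly.

For children born very preterm, `AgeCorrectionSpec(f)` applies

    corrected age (days) = postnatal age − f · (280 − gestational age),

with f between 0 (no correction) and 1 (full correction). The corrected
age feeds both the prior and the DAZ lookup. Negative corrected ages are
passed through with a warning; reference lookups clamp to the first row.

## Age-conditional references

The reference distribution of D at age t is Box-Cox normal with median
M_t, spread S_t and skewness power L_t. The conversion to an
age-standardized score is

    DAZ = ((D / M_t)^{L_t} − 1) / (L_t · S_t),      |L_t| > 1e-4
    DAZ = ln(D / M_t) / S_t                          otherwise,

and the 100·alpha centile is the inverse at the standard-normal quantile
z_alpha. The 1e-4 threshold selects the logarithmic branch where the
power formula loses precision. L, M and S are interpolated linearly in
age on the table mesh; the shipped Dutch table (144 rows, 2 weeks to
2.8 years) is the normative reference of this package.

`fit_lms` re-estimates a reference from scored data and is deliberately
simplified: ages are cut into quantile bins (default 12, bins under 20
observations merged), each bin fitted by Box-Cox-normal maximum
likelihood (Nelder-Mead on (mu, log sigma, nu)), and the three parameter
tracks smoothed by count-weighted polynomials in log-age with degrees
2 (M), 2 (S) and 1 (L). It recovers median curves to well under 1 D at
n = 5000 in simulation. It is *not* a penalized-spline reference fitter:
boundary behaviour is polynomial, and the Box-Cox power L is weakly
identified (ML standard error ≈0.12 at n = 5000 even for a single
homogeneous sample), so fitted L tracks should be read as smoothed
central tendencies only.

## Diagnostics

All fit statistics start from the standardized residual
z_ni = (x_ni − P_ni)/√W_ni with W_ni = P_ni(1 − P_ni):

- item/person **infit** = Σ(x − P)² / ΣW (information-weighted, sensitive
  mid-scale), **outfit** = mean z² (sensitive in the tails); expectation
  1 under the model. Items are flagged *underfit* above 1.3; persons
  (occasions) flagged above 3.0. Overfit (values < 1) is not flagged —
  it is harmless and can even raise reliability.
- **DIF**: per item, three nested logistic regressions of the response on
  (ability), (ability + group), (ability + group + interaction);
  likelihood-ratio chi-square tests give uniform (group main effect, its
  size reported in logits) and non-uniform (interaction) DIF. The
  matching ability is the D-score estimated from all items including the
  one under test (a purification pass would change little for 50+ item
  banks and is out of scope). `dif_scan` optionally applies
  Benjamini-Hochberg across items. Separation is reported as an
  unbounded effect with a warning, not an exception.
- **Information**: I = P(1 − P), maximal 0.25 where ability equals
  difficulty; `information_by_age` evaluates it along the reference
  median path and reports the age window with I ≥ 0.05 (the default
  usefulness threshold), which is the practical guide for when to
  administer an item.
- **Reliability**: R̂ = (σ̂²_ability − σ̂²_error)/σ̂²_ability, with
  σ̂²_ability the variance of estimated abilities and σ̂²_error obtained
  by parametric bootstrap: regenerate responses from the fitted
  abilities/difficulties with the exact missing-data pattern, re-score,
  and take the variance of the re-estimate minus the original. One
  replicate by default (`replicates` to average). The statistic is
  computed in whatever metric the abilities are supplied in. In
  surveillance-type cohorts R is dominated by the enormous age-driven
  ability variance; the sem is the more interpretable precision measure.

## Synthetic cohorts

`simulate_cohort` emulates the structure of a national nine-visit
surveillance study (~2000 children, visits at 1, 2, 3, 6, 9, 12, 15, 18
and 24 months). Each visit administers a *standard* set of easy
milestones (the items debuting at that visit; ~90% pass) plus an
*additional* set borrowed from the next visit (~50% pass); the realized
per-visit standard-set sizes are 5/2/5/6/7/6/6/6/7. Ability follows

    beta_n(t) = median_curve(t) + b_n + e_nt,

with the packaged reference median as the default curve, child-level
intercepts b_n ~ N(0, 3²) D (matching the 2.6–3.0 D cross-sectional
spread the reference prior is built on, and making simulated DAZ roughly
standard normal), and occasion noise e_nt ~ N(0, 0²) by default — the
references are cross-sectional and provide no within-child correlation
model, so the random-intercept form is a modelling choice of this
package, not an empirical claim. Visit ages jitter around the nominal
schedule (normal, SD 7 days, truncated at ±21 days) to avoid degenerate
age bins. An optional preterm fraction draws gestational ages
(N(210, 14²) days, clipped) and makes development follow fully corrected
age by construction, so that full-correction scoring recentres their DAZ
near zero — a designed property used as a test, not a finding.

Synthetic item difficulties (`synthetic_itembank`) place each item at
the median ability of the visit *before* its debut (≈50% pass as an
additional item, easy at its own visit); first-visit items sit ln 9
below the 1-month median (≈90% pass). The generating difficulties of
the real instrument are not public; these stand-ins reproduce the
design's pass-rate structure, and truth tables (abilities, difficulties,
gestational ages) accompany every simulated cohort.

What passing simulations do and do not show: the generator draws exactly
Rasch-conform responses with a known growth curve, so recovery results
validate the estimation machinery, not the behavioural realism of any
instrument — examiner effects, caregiver-report bias and local item
dependence are all absent by construction.

## Problem sizes and numerical conventions

The test suite exercises the full pipeline at the study scale it
emulates: reliability on 2000 children × 9 visits (≈200k responses,
seconds on one CPU), calibration recovery on 1000 children × 20 items,
DIF error rates over 200 null replicates. EAP scoring is vectorized over
occasions; likelihoods are accumulated in log space; the pairwise
objective is evaluated with `logaddexp`. Quadrature is plain summation
on the uniform grid (91 points suffice for ages to 2.5 years). Ties and
degenerate inputs fail loudly: non-binary scores, duplicate
(child, visit, item) rows, non-increasing reference ages, empty grids
and out-of-range gestational ages all raise typed errors.

## Known limitations

- The printed worked-example difficulties are rounded to one decimal;
  with them, the two-fail child's score computes to 47.76 D (the
  unrounded difficulties behind the published 47.7 are not recoverable).
- The pairwise metric is weakly identified across wide co-administration
  gaps (see calibration notes); calibrating a real standard/additional
  design benefits from pooling with denser linking data.
- `fit_lms` is a smoothed-bin estimator, not a penalized-spline fitter;
  its L curve is imprecise at cohort sizes below ~10⁵.
- No sex-specific references; no velocity/change-score references; no
  multi-instrument linking or adaptive administration.
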