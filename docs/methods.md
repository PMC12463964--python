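# Methods

## The POR model

The endpoint is poor ovarian response (POR): fewer than five oocytes
retrieved after controlled ovarian stimulation in a GnRH-antagonist cycle.
Risk is modelled as a Bernoulli outcome with logistic link on age (years)
and serum AMH (ng/mL). Fitting maximizes the log-likelihood
`Σ[y·log p + (1−p)-terms]` by Newton iteration (statsmodels' IRLS), with a
quasi-Newton (BFGS) fallback when the Hessian becomes singular on tiny or
near-separated cohorts. Convergence tolerance is 1e-8 on the
log-likelihood, at most 100 Newton iterations.

Design choices:

- **model2 is hierarchical.** "Quadratic age, cubic AMH" is implemented
  with all lower-order terms (age, age², AMH, AMH², AMH³), the standard
  convention for polynomial regression; dropping lower orders would make
  the fit depend on the origin of the predictor scales.
- **Centering** (optional, default off; reference point age 35 y, AMH
  2 ng/mL) conditions the cubic design. Fitted probabilities are invariant
  to centering on well-conditioned data (tested to 1e-6); only the
  coefficient parametrization changes.
- **model0 bins.** The legacy categorical model's original cut-points are
  not public; by default quintile bins are computed on the training cohort
  and stored in the fitted model, and explicit cut-points may be supplied.
  Values outside the bin range fall into the outermost bins.
- **Separation handling.** A fit is flagged (`converged=False`, warning)
  rather than rejected when the fitted linear predictor classifies the
  sample perfectly — the defining condition of complete/quasi-complete
  separation, under which the MLE is unbounded. Earlier drafts used a
  threshold on the standardized coefficient norm; that heuristic misfires
  on collinear polynomial columns (healthy fits can carry per-column
  standardized norms in the hundreds) and was replaced by the exact
  condition.
- AMH = 0 is a legitimate value (exhausted reserve) and is never excluded;
  no log transform is applied to model predictors.
- Cohorts below 50 outcome-labelled records fit with a warning instead of
  an error, since tiny cohorts are legitimate in testing and teaching.

## Evaluation

AUC is the Mann–Whitney concordance probability computed from midranks
(ties between a case and a control count ½). Confidence intervals are
percentile bootstrap, B = 2000 by default, resampling cases and controls
separately so every resample has both classes; the bootstrap generator is
seeded (default 20170101) and reproducible.

Calibration uses 10 equal-frequency bins of predicted probability by
default (equal-width optional); each row carries the bin bounds, count,
mean predicted probability and observed event proportion, and a sub-table
restricted to predicted p ≤ 0.25 is always emitted because the bulk of a
screening population sits in that range.

The net reclassification improvement is category-free by default (no risk
categories are imposed): signed movement of predicted risk between a
reference and a new model, summed over events and non-events, giving a
value in [−2, 2]; ties contribute zero. A categorical variant taking
user-supplied thresholds is provided. Percentiles and quartiles throughout
use linear interpolation between order statistics (numpy's default).

## Aging curve and endocrine age

A record is "predicted DOR" when its predicted POR probability is at least
τ = 0.15, the cohort POR incidence. Ages are floored to integer years;
rows with fewer than 20 records are excluded (and reported), because the
age extremes of an ART cohort are thin and noisy. The two-parameter
logistic (asymptotes fixed at 0 and 1) is fitted by least squares on the
proportion scale — unweighted by default so r² matches a plain proportion-
scale readout, with an optional by-n weighting. The optimizer start is
deterministic (k = 0.25/yr; x₀ at the interpolated 0.5 crossing;
tolerances 1e-10), so refits are bit-for-bit reproducible. Flat input
(k → 0) is returned with a warning rather than an error, since the
midpoint is then unidentified.

Inversion clamps probabilities to [1e-6, 1 − 1e-6] before the logit
(logged): young high-reserve women sit on the flat plateau of the curve
where the inverse is unbounded, and their reports carry a `plateau` flag
whenever their probability lies below the curve's value at the youngest
fitted age.

## Milestones

The fixed-interval hypothesis treats individual trajectories as horizontal
translations of the population curve, so milestone ages are
`age_now + curve⁻¹(p_target) − curve⁻¹(p_now)`. The score-50 milestone is
p = 0.5 by definition. The perimenopause milestone is conceptually the
lowest reserve score observed in an ART population; that number is not
public, so `p_peri` is a configuration parameter defaulting to 0.95, and
`estimate_p_peri` recovers it from a training cohort as the maximum
predicted probability. Milestones already behind the subject's age are
returned with a flag, not an error — a counselling tool must answer for
low-reserve users too. Reported ages are rounded to 0.1 year; internal
arithmetic is unrounded.

## Synthetic cohorts

No patient data are distributed; generators reproduce published summary
structure, and all draws go through a seeded `numpy` Generator.

**Class-conditional generator.** POR ~ Bernoulli(0.146 = 2224/15241);
given the label, AMH is lognormal and age truncated normal on [20, 45],
with parameters matched to the published per-class median/IQR blocks
(POR-negative: AMH 3.14 [1.7–5.4] ng/mL, age 32 [29–35]; POR-positive:
AMH 0.67 [0.34–1.31], age 36 [32–40]) through the percentile identities
μ = ln median, σ = (ln q75 − ln q25)/(2·0.6745). This generator matches the
marginal class structure but, by construction, carries no within-class
age–AMH dependence beyond what the class labels induce.

**Mechanistic generator.** Ages are uniform on [20, 45] — chosen for
balanced per-age counts so every integer-year row of the aging-curve table
is well populated, not as a portrait of a clinic's age mix. ln(AMH) is
normal around ln m(age), where m interpolates the anchor points
(26 y, 3.65 ng/mL), (35, 2.26), (42, 0.98) log-linearly and is flat outside
— anchors taken from published age-stratum medians. The within-age
log-scale sd defaults to 0.5, a realistic within-age spread (the pooled
class sd ≈ 0.86 includes the age gradient). POR follows a true logistic
model in age and ln(AMH + 0.01) (the offset tolerates AMH = 0) with
coefficients a_age = +0.12/yr and a_lnAMH = −1.7 — tunables placing the
generator in a realistic discrimination regime (held-out AUC ≈ 0.9), not
published values — and the intercept solved by root-finding so the
sample-expected prevalence equals the target. The generating parameters
are returned, including the closed-form true DOR-by-age curve (a probit in
the age-dependent ln-AMH threshold) and its midpoint, enabling end-to-end
parameter-recovery tests.

One calibration caveat: because m(age) declines from age 26 to 30 inside
the ≤30 stratum, the stratum's empirical median sits systematically ~4 %
below the 3.65 anchor (typically 3.43–3.55 at n = 10,000). This is a
property of summarizing a declining median curve by a stratum median, not
a sampling artifact.

**What passing tests do and do not show.** The generators reproduce
marginal medians/IQRs, prevalence, and a sigmoidal DOR-age trend; they do
not emulate assay batch effects, repeat cycles per woman, informative
missingness, or the true joint age–AMH distribution of any clinic.
Discrimination and recovery results on these cohorts demonstrate that the
pipeline is correct and well-calibrated under its stated assumptions, not
that it attains the same performance on real populations.

**Stimulation-day decline.** During stimulation, AMH falls as estradiol
rises: mean declines relative to day 2 are 17.4 % by day 6 and 49.7 % by
the hCG trigger day. Mean mode applies the factor exactly. Stochastic mode
draws a per-subject decline fraction from Beta(f·ν, (1−f)·ν) with mean f
preserved and concentration ν = 8 by default; the published means carry no
variance information, so ν is a tunable. Heterogeneity — not the mean
shift — is what degrades discrimination: a uniform rescaling of an
AMH-monotone score is rank-preserving and leaves AUC exactly invariant
(tested), while heterogeneous declines scramble ranks and strictly lower
AUC. The published magnitude of that degradation depends on the unpublished
variance structure and is checked directionally, not numerically.

## Problem sizes and numerics

Tests and the acceptance script use cohorts of 4,000–30,000 records and
aging-curve tables of 31 integer ages at 1,000 subjects per age — sizes at
which binomial noise on per-age proportions is ≤ 0.016 and curve r²
routinely exceeds 0.998. Bootstrap B is reduced (0–200) inside loops where
only point estimates matter. All tolerances asserted in tests (1e-3 against
the MLE search oracle, 1e-9 round-trip inversion, ±5 % parameter recovery,
±1 year midpoint recovery) are stated in the tests themselves.

## Known limitations

- Antral follicle count and FSH, used by richer reserve models, are out of
  scope; the clock is AMH+age only.
- No uncertainty intervals accompany milestone ages; the fixed-interval
  projection is a point estimate.
- Cross-assay AMH conversion is not handled; inputs are ng/mL, and pmol/L
  values must be converted explicitly at the CLI boundary.
- The aging curve is cross-sectional: it describes population proportions,
  and its use for individual projection rests entirely on the
  fixed-interval hypothesis.
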