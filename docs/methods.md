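# Methods

This note documents the models implemented in `pehsurv`, the assumptions they
rest on, the design choices that were genuinely open, and what the synthetic
data generator does and does not emulate.

## The exposure: parental educational homogamy (PEH)

Each child's exposure is the joint classification of the parents' educational
attainment, split at "at most primary" (none or primary) versus "at least
secondary" (secondary or higher):

| code | definition |
|------|------------|
| 1 | both spouses at most primary |
| 2 | husband at most primary, wife at least secondary |
| 3 | husband at least secondary, wife at most primary |
| 4 | both at least secondary (reference) |

None and primary are merged because under-five mortality differs little
between them.  Eligibility mirrors standard survey practice: multiple births
are excluded, as are children of mothers not currently in a cohabiting union
and records missing survival status or either parent's education
(complete-case analysis; no imputation).  Exclusions are applied in a fixed
precedence order (multiple birth → non-cohabiting → missing survival →
missing education) so the per-reason tally is deterministic.  Whether union
status should be evaluated at the child's birth rather than at interview is
ambiguous in retrospective data; it is evaluated at interview here.

## Survival outcome and Cox workflow

The outcome is survival over the first 59 months of life.  Deaths at reported
age ≤ 59 months are events at that age; surviving children are right-censored
at `min(current age, 59)` months.  Deaths reported at age 0 are lifted to 0.5
months (half-interval convention) so the partial likelihood is defined.
Children younger than 59 months contribute censored exposure at their current
age by default; a `drop_incomplete_exposure` flag offers the stricter
completed-cohort alternative.

The hazard model is the semi-parametric proportional-hazards model
`h_i(t) = h_0(t) exp(x_i'β)` with categorical covariates expanded to
indicator contrasts against fixed reference levels (PEH reference is
category 4).  The workflow is two-stage: single-covariate screening keeps
candidates with any-level Wald p < 0.10 (minimum-p rule; a covariate-level
likelihood-ratio screen would also be defensible, but the per-level rule is
transparent and is the default), with the PEH exposure always retained; the
adjusted model then includes the screened covariates.  Fitting is by
`statsmodels` `PHReg` (Newton-type maximization of the partial likelihood).
Confidence intervals are Wald on the log-HR scale.  The multivariate stage is
unweighted; sampling weights enter only the descriptive layer.

**Ties.**  Ages at death come in whole months, so event times are heavily
tied.  Tie handling defaults to Breslow, with Efron available, and the chosen
method is recorded in every fit and output header.  On untied data the two
coincide (tested).

**Diagnostics.**  Proportionality is checked two ways.  (1) Scaled Schoenfeld
residuals: residuals `x_k − x̄(t_k)` are computed at each event over the
Breslow risk set, scaled by `d·V⁻¹` with `V` the observed information and `d`
the event count, and tested for a linear trend in a transform of event time
(identity by default, rank optional) with the Grambsch–Therneau score
statistics, per covariate (χ²₁) and globally (χ²_p).  The implementation is
cross-checked against R `survival::cox.zph(transform="identity")` in the test
suite.  (2) Kaplan–Meier `log(−log S)` versus `log t` curves per exposure
group, which are parallel under proportional hazards; the package emits the
plot coordinates rather than rendered figures.

**Descriptive layer.**  Weighted cross-tabulations report percent dead per
factor level; Pearson chi-square tests of association run on the *unweighted*
counts (a deliberate simplification — scalar weights only are modelled, and no
Rao–Scott design correction is attempted).  Zero rows/columns are dropped
before testing; no continuity correction by default.  Significance markers
reproduce the convention `* p<0.001, ** p<0.01, *** p<0.005` verbatim,
including its unusual ordering.

## Brass indirect estimation of 5q0

From each woman: children ever born (CEB) and children dead (CD), classified
by 5-year age group i = 1..7 (15–19 … 45–49).  With D(i) the proportion dead
among CEB of group i and P(i) the mean parity,

    q(x(i)) = k(i) · D(i),        k(i) = a(i) + b(i)·(P1/P2) + c(i)·(P2/P3),

with the standard correspondence i → x of 1, 2, 3, 5, 10, 15, 20 and the
Trussell (West-family) regression coefficients shipped as package data.  Each
q(x) converts to the level parameter of a one-parameter relational logit
life-table system over a standard `l_s(x)`:

    Y(l) = ½ ln((1−l)/l),   α = ½ ln(q/(1−q)) − Y_s(x),
    5q0  = e^{2(α+Y_s(5))} / (1 + e^{2(α+Y_s(5))}),

i.e. `logit l(x) = α + β·logit l_s(x)` with β fixed at 1 (the two-parameter
extension is deliberately absent).  The α's of the retained indices are
combined by arithmetic mean (median optional) and 5q0 is read back from the
combined level, reported per 1000 live births.

Open choices fixed here:

- **Indices combined:** i ∈ {2, 3, 4} by default — q(2), q(3), q(5) from
  women 20–34.  The 15–19 group is conventionally unstable (few, selected
  births) and older groups reflect increasingly distant mortality.  The
  indices used are logged in every estimate.
- **Standard:** the shipped default `west_pattern_synthetic` follows the
  Coale–Demeny West family's child-mortality age shape (infant-heavy) but is
  a constructed table, clearly labelled synthetic, not a transcription of the
  printed West tables; users can supply any `x,l` CSV.  Because α absorbs
  level shifts, estimates are insensitive to the particular reasonable
  standard, but the name travels in all output metadata.  Standards are
  checksummed; the test suite relies only on a closed-form exponential
  standard so correctness never hinges on transcription.
- No time-location (reference date) of estimates is computed.

## The synthetic survey generator

The generator emulates a DHS-style child recode with known ground truth:

- **Women** aged 15–49 (exact age uniform), with education sampled from the
  4-cell PEH joint distribution, household covariates from fixed marginal
  distributions, gamma sampling weights, and a configurable fraction flagged
  non-cohabiting.
- **Fertility**: a piecewise age-dependent birth process driven by
  age-specific fertility rates per 5-year group (default
  0.09/0.23/0.25/0.22/0.16/0.08/0.025 births·woman⁻¹·yr⁻¹, TFR ≈ 5.1,
  typical of high-fertility settings), with a shifted-gamma minimum spacing
  (9 + Gamma(2, 6) months) so all preceding-birth-interval categories are
  populated.  Because birth intensity depends only on age, fertility is
  constant in calendar time — the stationarity the indirect method assumes.
- **Mortality**: piecewise-constant baseline hazard on [0, 60) months scaled
  per child by `exp(linear predictor)` of PEH and any configured covariate
  effects — proportional hazards hold by construction.
  `baseline_segments_from_standard` builds segments whose survivorship
  matches an α-shift of a chosen standard at ages 1, 2, 3, 5, so simulated
  mortality has exactly the standard's age pattern at any target 5q0.  Death
  ages are drawn in continuous time by piecewise-exponential inversion,
  floored to whole months for reporting (exact times retained internally for
  oracle checks).  An optional heaping perturbation rounds reported death
  ages to multiples of 6; it is off by default and no claim is made that it
  matches any particular survey's heaping.
- **Censoring**: children are observed only up to the interview date;
  a child "dies" in the data only if the drawn death age precedes its age at
  interview.
- **Determinism**: one root seed; woman-level sub-streams are derived from
  (seed, woman id) so a woman's records do not depend on iteration order;
  child-level draws use dedicated streams in the deterministic child order.
  Same config ⇒ byte-identical output.
- **Ground truth**: `true_q5(config, peh, profile)` returns
  `1 − exp(−Σ λ_s Δ_s e^{lp})` in closed form, the oracle against which all
  recovery studies measure.
- An optional `TimeVaryingEffect` deliberately violates proportionality (a
  covariate's log-HR switches value at a configurable age) to exercise the
  diagnostics' power.

**What it does not emulate** — and hence what passing tests do not show about
real surveys: cluster/stratum sampling and design effects (weights are
i.i.d. scalars), HIV-era or crisis mortality age patterns, mortality above
age five (children surviving 60 months never die, which biases the i = 4
index very slightly downward since some children of women 30–34 are past age
five; the effect is well under the recovery tolerance), recall and
displacement errors, country-specific fertility calendars, and parental
frailty/sibling correlation beyond shared covariates.

## Numerical choices and degenerate inputs

- Logit transforms require probabilities strictly inside (0,1); boundary
  values raise domain errors.  `q5_from_alpha` uses the numerically stable
  logistic form and is exact to 1e−12 as the inverse of `alpha_from_q`.
- Trussell multipliers that go nonpositive (possible only far outside the
  fitted fertility domain) are clipped positive with a warning; q(x) ≥ 1 is
  truncated just below 1 with a warning.
- Cox fits raise with the optimizer trace on non-convergence and name the
  offending term when coefficients diverge (|β| > 15, monotone likelihood).
- Empty strata: descriptive tables keep zero rows (flagged); chi-square drops
  them; Brass strata without positive P1–P3 are omitted with a warning; a
  pipeline dataset that fails aborts alone and is reported as failed.

## Validation studies and problem sizes

`pehsurv.studies` packages the recovery/calibration experiments run by
`scripts/acceptance.py` and `tests/test_acceptance.py`.  The reference sizes,
chosen once as the package's study conditions: indirect-method recovery and
stratum-ordering recovery at 50,000 women (programmed 5q0 = 0.150, mortality
pattern equal to the standard); hazard-ratio recovery over 200 replicates of
~5,000 children with a programmed ln(1.6) effect; Schoenfeld calibration over
500 replicates (~1,800 children each) and power against a male log-HR
doubling from 0.47 to 0.94 at month 12 over 40 replicates of ~10,000
children; chi-square exactness on 1,000 random 2×2 tables and type-I
calibration over 1,000 replicates of ~450 women; Cox-versus-oracle agreement
on 25 no-ties fixtures of n ≤ 10.  Expected behaviour when the indirect
method's assumptions are *violated* (simulated mortality pattern differing
from the standard) is a nonzero bias; that is a property of the method, not a
defect of the implementation.

## Known limitations

- The Brass chain inherits the method's assumptions (constant recent
  fertility and mortality, mortality age pattern close to the standard);
  violations bias the estimates, by design.
- Screening by minimum Wald p across levels mildly over-selects
  multi-level covariates relative to a joint test.
- No frailty / random effects, no time-varying covariates in the fitted
  models, no weighted partial likelihood, no survey-design variance
  estimation.
- The shipped Trussell coefficients and the West-pattern standard are
  reference constants / a labelled synthetic table respectively; production
  estimates for a real survey should plug in values verified against the
  printed sources (the loaders accept user CSVs).
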