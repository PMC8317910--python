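# pehsurv

Does the *joint* education of both parents — their educational homogamy —
track the survival chances of their under-five children?  `pehsurv` is a
tested pipeline for that question on DHS-style child birth-history records,
for demographers and epidemiologists working on child survival in
high-mortality settings.  It implements, end to end:

- derivation of the four-level **parental educational homogamy (PEH)**
  exposure (split at "at most primary" vs "at least secondary", with none and
  primary merged) and the standard eligibility exclusions (multiple births,
  mothers not in a cohabiting union, incomplete records);
- **weighted descriptive tables** of under-five deaths with Pearson
  chi-square association tests;
- a two-stage **Cox proportional-hazards workflow** — unadjusted screening at
  α = 0.10, adjusted model for PEH with h_i(t) = h_0(t)·exp(x_i'β), censoring
  at 59 months — with scaled-Schoenfeld-residual and log(−log S) diagnostics;
- **Brass indirect estimation of 5q0** from children-ever-born /
  children-dead summaries: q(x) = k(x)·D(x) with Trussell multipliers
  k = a + b·(P1/P2) + c·(P2/P3), converted through the one-parameter
  relational logit life-table system logit l(x) = α + logit l_s(x) and read
  back as 5q0 per 1000 live births;
- a **synthetic DHS-like generator** with piecewise-constant under-five
  hazards, covariate-dependent proportional effects, interview censoring and
  survey weights, whose ground truth (`true_q5`) is available in closed form
  — so every stage of the pipeline is testable against a known answer.

Real DHS microdata are restricted-access; the package ships no survey data
and instead exercises everything on the generator, which is first-class,
tested code.  See `docs/methods.md` for models, assumptions and design
choices.

## Worked example

The numbered drivers under `analysis/` run a small two-country study
(country A with programmed PEH hazard ratios 1.6 / 1.2 / 1.4 versus the
both-at-least-secondary reference, country B null; 2,500 women each,
reference 5q0 = 150/1000):

```sh
python analysis/01_simulate.py
python analysis/02_descriptives.py
python analysis/03_cox_models.py
python analysis/04_brass_estimates.py
```

which prints, among other lines:

```
country_a: excluded 469/7575 children ({'multiple_birth': 278, 'non_cohabiting': 191, ...}); 7106 analyzed, 17.8% died; factors flagged by the chi-square screen: ['peh', 'wealth']
country_a: screened in ['peh', 'wealth', 'sex', 'm_age_group'] (tie method breslow); adjusted HR cat1 vs cat4 = 1.51 (1.32-1.73); PH global p = 0.21 (no evidence against proportionality)
country_a (n eligible women = 2431):
peh  alpha  q5_per_1000  true_q5_per_1000 indices_used               standard
  1 0.4118        209.2             229.0        2,3,4 west_pattern_synthetic
  4 0.1777        142.1             150.0        2,3,4 west_pattern_synthetic
```

Reading: in country A the eligibility filter removed 469 of 7,575 children
(twins and children of non-cohabiting mothers); both-parents-at-most-primary
children die at 1.51 times the adjusted hazard of the doubly-educated
reference (truth 1.60, inside the CI); the Schoenfeld check finds no evidence
against proportional hazards (which hold by construction); and the indirect
Brass estimates recover the programmed mortality gradient — 209 vs the true
229 per 1000 in category 1, 142 vs 150 in the reference — at this modest
sample size.  Tables land under `results/`.

The same machinery is scriptable (`pehsurv simulate|all|report` on a YAML run
config) or callable as a library:

```python
from pehsurv import brass, cox, recode
from pehsurv.lifetable import load_standard
from pehsurv.simulate import SimulationConfig, generate_population

cfg = SimulationConfig(n_women=2000, seed=1)
women, children = generate_population(cfg)
obs = recode.build_survival_data(women, children, cfg.interview_cmc)
fit = cox.fit_cox(obs, ["peh", "sex"])          # adjusted hazard ratios
check = cox.schoenfeld_test(fit)                 # PH diagnostic
est = brass.estimate_u5m_by_stratum(             # 5q0 per 1000 by stratum
    women.assign(peh=recode.derive_peh_series(women.wife_edu, women.husband_edu)),
    load_standard(), stratifier="peh")
```

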