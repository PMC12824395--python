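# medseq

State sequence analysis of longitudinal medication use after an incident
psychiatric diagnosis, built for dispensing-register data.

## The problem

After a first diagnosis of bipolar disorder, guideline-concordant care
means timely initiation and maintenance of a mood-stabilizing medication
(anticonvulsant mood-stabilizers, lithium, or antipsychotics; concomitant
antidepressants are acceptable, antidepressant *monotherapy* is not).
Registers record pharmacy dispensations, hospital stays and deaths at
the person-day level; the analytic challenge is turning that stream into
interpretable longitudinal treatment patterns and relating them to
population groups and covariates.

`medseq` implements that pipeline end to end:

1. **Exposure** — dispensations (ATC-coded, with days of supply) become
   continuous per-class use periods via a sliding-mean supply estimate
   (window *w* = 3 dispensations) and a 30-day grace period for gaps.
2. **Cohort** — incidence filters: prior diagnosis lookback (3 years),
   medication washout (15 until 3 months pre-diagnosis), psychosis /
   dementia exclusions, continuous residency, age 16–65.
3. **Sequences** — follow-up is cut into twelve 91-day periods
   (1092 days). Per period, each class gets a binary indicator (use on
   ≥ 50 % of non-hospital days; periods ≥ 50 % in hospital borrow the
   next period's state), and a decision tree maps the four indicators to
   one of seven mutually exclusive states — lack of treatment,
   antidepressant monotherapy, mood-stabilizers, antipsychotics,
   lithium, augmentation, lithium with augmentation — plus an absorbing
   censoring symbol after death.
4. **Sequence analysis** — transition matrices, transversal and
   longitudinal entropy, mean time in state with log-linear (Poisson)
   group contrasts, and optimal-matching (OM) distances

   $$d(x, y) = \min_{\text{edit scripts}} \sum \text{cost},\qquad
     \text{sub}(i,j) = c - p(i{\to}j) - p(j{\to}i),\ \text{indel} = c/2$$

   with transition-rate (TRATE) substitution costs, `c = 2` by default.
5. **Typologies** — weighted Ward, PAM (partitioning around medoids) and
   Ward-initialised PAM on the dissimilarity matrix of unique sequences;
   the number of clusters is chosen by maximising the weighted average
   silhouette width (ASW) over k = 2…15.
6. **Trajectories** — sequences dichotomised to treatment vs lack;
   initiation (early ≤ 3 months vs delayed) and discontinuation (first
   treatment→lack transition, binned at 6 months / 1 / 2 / >2 years).
7. **Association** — multinomial logistic regression of typology
   membership on population group and covariates (largest typology and
   Swedish-born as references), Wald 95 % CIs, and marginally
   standardized fitted probabilities.

Because the registers such analyses run on are confidential, the package
ships a **synthetic register generator**: persons in four population
groups draw a latent typology from a multinomial logit over their
covariates, and dispensing / hospital / death records are emitted so the
pipeline can be validated against the known latent structure.

## Worked example

```bash
medseq run --out demo --seed 1 -n 6000
```

generates a 6,000-person synthetic register, runs every stage and prints

```
analyzed 5998 persons; best pam k=8 asw=0.901; artifacts in demo
```

Eight clusters are found: the seven latent treatment typologies plus a
small cluster of censored (deceased) follow-ups. `demo/table_one.csv`
holds the per-group summary; the typology section for the two extreme
groups reads

```
typology  treatment failure            swedish_born  1616  4966  32.5
typology  persistent mood-stabilizers  swedish_born  1003  4966  20.2
...
typology  treatment failure            refugee        120   206  58.3
typology  persistent mood-stabilizers  refugee         24   206  11.7
```

i.e. 32.5 % of Swedish-born but 58.3 % of refugees fall into the
*treatment failure* typology (a short trial followed by lack of
treatment), while persistent mood-stabilizer use is roughly halved —
exactly the covariate-dependent structure the generator planted.
`demo/effects_adjusted.csv` quantifies it as covariate-adjusted odds
ratios vs the *treatment failure* reference:

```
typology                      odds_ratio  ci_low  ci_high   (refugee vs swedish_born)
persistent mood-stabilizers         0.32    0.21     0.50
persistent lithium                  0.28    0.14     0.56
...
```

All stages are also available as individual commands
(`medseq simulate | cohort | sequences | ssa | cluster | trajectories |
associate | report`) operating on CSV directories, and as plain library
functions (`medseq.run_pipeline`, `medseq.om_distance`, …).

## Layout

```
src/medseq/
  states.py              state alphabet + indicator decision tree
  exposure_model.py      ATC classification, use-period construction
  cohort_builder.py      eligibility filters + exclusion log
  sequence_builder.py    period grid, binarization, censoring rules
  ssa_core.py            transitions, TRATE costs, OM, entropies
  typology.py            weighted Ward / PAM / silhouette / selection
  trajectory_stats.py    initiation, discontinuation, trajectories
  association.py         multinomial models, ORs, standardization
  synthetic_registry.py  generator + CSV round-trip
  pipeline.py, cli.py    orchestration and the `medseq` CLI
docs/methods.md          modelling choices, parameters, limitations
```
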