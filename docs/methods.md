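# Methods

This note records the modelling choices behind `medseq`: what each stage
assumes, which knobs matter, what the synthetic register does and does
not emulate, and the numerical conventions used where the published
methodology of register-based sequence analyses leaves room.

## Time conventions

All computation is at day resolution on proleptic-Gregorian ordinal
days; dates in CSVs are ISO-8601. The diagnosis day is day 0 of
follow-up. Follow-up is twelve half-open 91-day periods
`[91·(k−1), 91·k)`, 1092 days total. "Three years" of lookback is
rendered as 1092 days and the medication washout window of 15-until-3
months as `[−455, −91]` days so that every rule is commensurate with
the 91-day grid (a month is treated as 91/3 days). Whether a
month-based or day-based convention was used in the source analyses is
not stated anywhere we could check; the day convention is declared
here once and used everywhere.

## Exposure model

Register dispensations carry an ATC code, a date and a days-of-supply
estimate. The exposure model is deliberately simple and fully
documented rather than a reimplementation of any proprietary
drug-use-period algorithm:

* the run covered by the i-th dispensation of a class starts on its
  date and lasts `round(mean(days_supply of the last w dispensations))`
  days, with **w = 3**. The sliding mean damps stockpiling: a burst
  purchase stretches future estimates instead of tripling instantaneous
  coverage.
* runs separated by at most **grace_days = 30** days merge into one use
  period (short refill gaps are not treatment interruptions).
* ATC prefixes map to the four classes by longest-prefix match; the
  default table (N06A antidepressants, N03A anticonvulsant
  mood-stabilizers, N05AN lithium — shadowing — N05A antipsychotics) is
  a configurable placeholder, not an authoritative code list.

Hospital stays do **not** extend use periods; inpatient days are
handled at binarization (below), where they are subtracted from the
denominator, because in-hospital medication does not appear in
dispensing registers.

## Cohort rules

Exclusions are evaluated in a fixed order and *all* triggered reasons
are recorded: prior bipolar code (F30/F31 in the 1092-day lookback,
index day exclusive); washout use of antipsychotics or mood-stabilizers
/ lithium overlapping `[−455, −91]`; any F2*, F00–F03 or G30 code from
lookback through end of follow-up; residency not covering lookback
through follow-up (or death, whichever is earlier); age at diagnosis
outside 16–65. Antidepressant-only use in the washout window does not
exclude.

## Sequence construction

Per period, each class indicator is 1 iff covered non-hospital days are
≥ 50 % of the non-hospital denominator `91 − inpatient days`. With ≥ 46
inpatient days (≥ 50 % of 91) the period is unassessable and borrows
the state of the following period; substitution resolves right-to-left
so alternating valid/invalid chains are well defined; an unassessable
final period borrows period 11 (the only available neighbour — the
mirror image of forward substitution, logged when it occurs). Two
consecutive unassessable periods exclude the person. Death censors the
containing period and everything after it; censoring from period 1
excludes. If substitution pulls censoring back into period 1 the person
is likewise excluded. The indicator → state decision tree gives lithium
plus any other adequate class lithium-with-augmentation, lithium alone
lithium, mood-stabilizer + antipsychotic augmentation, single adequate
classes their own state, antidepressants alone antidepressant
monotherapy, nothing lack — antidepressant flags are ignored whenever
an adequate class is present.

## Sequence analysis kernel

* **Transitions**: lag-1 counts pooled over sequences and positions,
  weighted by sequence multiplicity; rows for never-observed origins
  are zero and flagged rather than NaN.
* **Substitution costs**: the transition-rate convention
  `cost(i,j) = cval − p(i→j) − p(j→i)`, `cval = 2`, floored at 0, zero
  diagonal; indel `cval/2 = 1`. The censoring symbol is a real
  absorbing state of the data, so it participates in the alphabet, the
  transition estimates and the cost matrix; this and the entropy
  normalisation are switches, not silent defaults.
* **Optimal matching**: Needleman–Wunsch dynamic programming;
  all-pairs distances are computed on unique sequences only (identical
  sequences pool into one row with a multiplicity weight, rows ordered
  lexicographically so results are independent of input order).
* **Entropies**: Shannon entropy of the state distribution per period
  (transversal) or within a sequence (longitudinal), natural logs,
  normalised by `log(8)` — the full alphabet including censoring — by
  default (`norm_states` overrides). The complexity index is
  `sqrt(transition density × normalised longitudinal entropy)`.
* **Time in state**: shares of the seven treatment states are computed
  over non-censored periods (they sum to 1 per group); the censored
  share is reported against the full grid separately. Group contrasts
  use Poisson regression with a log link and an offset for observed
  periods — the standard reading of "log-linear regression" for period
  counts — with an HC1 robust-variance option.

## Clustering

Clustering operates on weighted unique sequences, which is exactly
equivalent to clustering every person separately:

* **Ward**: Lance–Williams recurrence on squared dissimilarities
  ("ward.D2" convention), with inter-cluster costs initialised to
  `2 w_i w_j/(w_i+w_j) · d²` so that multiplicity weights reproduce the
  expanded multiset exactly. Ties break toward the lowest index pair.
* **PAM**: greedy deterministic BUILD seeding, then steepest-descent
  single-swap refinement of the weighted objective (no random seed
  anywhere). The hybrid variant replaces BUILD with the weighted
  medoids of the Ward partition.
* **Silhouette**: weighted, with the within-cluster mean dividing by
  (cluster weight − 1) so duplicates at distance zero are counted as in
  the expanded data; singletons and degenerate a = b = 0 cases score 0.
* **Selection**: every (method, k) for k = 2…15 is fitted; the highest
  weighted ASW wins, ties toward smaller k then PAM over hybrid over
  Ward. ASW ≈ 0.3 is conventionally "reasonable", ≈ 0.5 "good"; a
  best ASW below 0.25 triggers a no-structure warning.
* **Naming**: clusters are labelled by the modal state of their medoid
  (lack-dominated → *treatment failure*, etc.); censoring-dominated or
  tied medoids stay "unclassified" with a warning.

*Known limitation*: PAM is a local search. On cluster-structured data
fitted at the true k the steepest-descent swap reliably attains the
global optimum of the weighted objective (the test suite verifies
equality with exhaustive medoid enumeration on such instances), but on
unstructured dissimilarities, or when k disagrees with the structure,
single-swap local optima exist — as they do for any canonical PAM
implementation.

## Trajectories

The seven states dichotomise to lack (0) vs any treatment (1);
censoring ends the evaluable window. Initiation is the first treatment
period: period 1 ≙ months 0–3 ("early"; antidepressant monotherapy
carried over the diagnosis into period 1 also counts as early), periods
2–4 ≙ months 4–12, periods 5–12 ≙ ≥ 12 months. Discontinuation is the
first 1→0 transition after initiation (later re-initiations are
ignored); the gap in periods maps to ≤ 2 within 6 months, 3–4 within a
year, 5–8 within two, ≥ 9 after two — the unique 91-day-commensurate
reading of the calendar bins. Summary tables restrict the
discontinuation denominator to persons initiating within a year
(periods 1–4), and persons censored before any event count as
non-events within their evaluable window (no survival weighting — a
documented simplification). Percentages are rounded half-up to one
decimal, and every printed percentage is re-derived from its count and
denominator by an automatic self-check.

## Association models

Typology membership is modelled with maximum-likelihood multinomial
(softmax) regression: Newton iterations from a zero start, with a
deterministic BFGS fallback when Newton stalls under quasi-separation;
a diverged coefficient (|β| > 10) or a singular information matrix
raises a separation error naming the offending term rather than
returning garbage. The largest typology is the reference outcome,
Swedish-born the reference group, all predictors dummy-coded against
their (configurable) reference levels, no interactions — group-specific
effects come from stratified refits. Effects are odds ratios with Wald
95 % intervals. Fitted probabilities use marginal standardization
(g-computation): set everyone's factor to each level, average predicted
probabilities, optionally within strata; whether published "fitted
probabilities" in comparable analyses are standardized or
at-reference predictions is typically unstated — standardization is the
choice here because it averages over the observed covariate
distribution. Clusters left "unclassified" (censoring-dominated) are
excluded from the regression outcome: they are an artefact of mortality,
not a treatment typology, and at moderate cohort sizes their empty
group cells would otherwise make the saturated univariate model
inestimable.

## Synthetic register

The generator emulates the *structure* of a national incident-cohort
register, not its clinical microdynamics:

* four population groups at the exact count fractions of a published
  cohort (0.8284 / 0.0760 / 0.0595 / 0.0361);
* ten categorical covariates with plausible, fully configurable
  marginals (they are illustrative — no claim of fidelity to any
  unavailable supplementary table);
* a latent typology per person drawn from a multinomial logit: baseline
  shares (34.1 / 18.7 / 19.7 / 8.9 / 8.3 / 5.0 / 5.2 %) shifted by
  covariate coefficients (reference typology fixed at 0). Defaults push
  refugees (−0.9 on all non-failure typologies, i.e. OR ≈ 0.4), other
  immigrant groups (−0.45 … −0.55) and low education (−0.3) toward
  treatment failure;
* archetype sequences: *treatment failure* is two mood-stabilizer
  periods then lack; the six others are constant in their namesake
  state. Per-period noise (default 0.05) replaces a state with a
  uniformly drawn different treatment state — register sequences are
  far from noise-free, and 0.05 keeps archetypes dominant while
  producing realistic sequence diversity;
* each "use" period emits one dispensation per active class covering
  all 91 days, so at zero noise and without hospitalizations the
  pipeline reconstructs the latent sequence exactly (the round-trip
  property the tests assert);
* hospital stays (rate 0.05, 3–60 days) exercise the denominator and
  substitution rules; deaths (rate 0.01, uniform over follow-up)
  exercise censoring; optional rates inject prior-diagnosis, washout
  and psychosis histories to exercise every eligibility rule.

What the generator does **not** emulate: dose tapering, partial
adherence, within-class switching, seasonal dispensing patterns,
covariate correlation structure, or informative censoring. Passing
tests therefore demonstrate that the pipeline recovers known structure
of this generative family — they do not certify behaviour on real
registers, whose exposure misclassification and cluster geometry can
differ.

## Problem sizes

The shipped experiments use cohorts of 400–6,000 persons (unique
sequences after pooling: a few hundred to ~2,000), a scale at which
the full method grid (3 clustering methods × k = 2…15) runs in seconds
to a couple of minutes on one CPU. The confidence-interval calibration
study uses 200 replicates of n = 5,000. Cohorts of register scale
(tens of thousands) are supported by the same code path; the
all-pairs OM step is quadratic in the number of *unique* sequences.

## Degenerate inputs and tie-breaking

Empty dispensing tables give all-lack sequences; a state never observed
as a transition origin gets a zero (flagged) probability row and
maximal substitution costs; all-identical sequences give a 1×1
dissimilarity matrix and a no-structure warning at selection;
deterministic lowest-index tie-breaking is used in Ward merges, PAM
BUILD/SWAP and ASW selection, making every stage reproducible without
random seeds (the only randomness in the package is the generator's,
governed by its single integer seed).
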