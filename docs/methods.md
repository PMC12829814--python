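# Methods

## Model structure

The natural history of ductal carcinoma in situ (DCIS) is a discrete
annual-cycle Markov chain simulated per woman from birth to age 100.
States: healthy; DCIS of grade 1, 2 or 3; and the absorbing end states
death, clinically detected DCIS, and DCIS progressed to invasive breast
cancer (IBC). There is no direct healthy→IBC route (IBC matters here
only as a way a DCIS surfaces) and no IBC→DCIS regression.

Per cycle at age *a*:

- **healthy**: death with probability *d(a)*; otherwise onset of a
  grade-*g* episode with probability *o_g(a)* (one uniform partitioned
  by the grade-specific probabilities decides grade);
- **DCIS(g)**: death *d(a)*; then progression to IBC *p(a)·m_g*; then
  clinical detection *c*; then regression *r* — sequential Bernoulli
  draws in that fixed order, probabilities used as given (validation
  enforces *d + p·m_g + c + r ≤ 1* at every age and grade, and
  *d + Σ_g o_g ≤ 1* in the healthy state).

Regression returns the woman to the healthy state; later onsets are
allowed by default (`allow_reonset=False` disables them — the field's
literature does not settle whether a regressed lesion's host remains at
risk, so both readings are testable). Clinical detection and progression
are absorbing: post-diagnosis survival is out of scope.

Death probability is identical in the healthy and DCIS states, so death
never differs between the arms of the paired design.

## Screening overlay and timing conventions

Screening never alters the latent chain; it is a pure observation
process. A policy defines rounds at start, start+interval, …, ≤ stop
(or a single round). Attendance is an independent Bernoulli(compliance)
per round by default; an all-or-none variant (one draw decides every
round) brackets the realistic correlation structure. An attended screen
detects a prevalent, not-yet-detected episode with probability 0.86,
independently per round.

Same-cycle ties need a convention, fixed once and mirrored exactly by
the enumeration oracle:

- a screen at age *a* happens after the onset event of cycle *a* and
  before the DCIS-state events of cycle *a*: it observes episodes with
  onset ≤ *a* that have not resolved strictly before *a*, and wins a
  same-age tie against clinical detection, progression, or regression;
- a woman in the DCIS state at cycle start therefore dies *after* the
  age-*a* screen (death ≥ *a* means alive at the screen), while a
  healthy woman's death resolves before it.

A failed screen has no effect on later rounds.

## Overdiagnosis estimand

Both arms derive from one latent trajectory per woman (common random
numbers, CRN), so the estimator needs no population matching: a woman is
**overdiagnosed** if her screened arm has a DCIS diagnosis inside the
observation window and her unscreened arm has none. The window runs from
the first scheduled round age to min(last round age + follow-up,
age 100); diagnoses before the window (young-age clinical detections)
are excluded from both arms symmetrically. Short windows misclassify
lead time as overdiagnosis; because lengthening the window can only turn
overdiagnosed women into not-overdiagnosed ones, the overdiagnosed count
and proportion are non-increasing in follow-up *seed by seed*, not just
in expectation — the follow-up experiment re-windows one simulation
rather than re-simulating.

Statistics:

- **proportion** = overdiagnosed / all diagnosed in the screened arm
  (undefined — reported as NaN, never 0 — when nothing is diagnosed);
- **rate** = 100,000 × overdiagnosed / (population_scale × denominator).

The default rate denominator is **screens actually performed** (rounds
attended while alive and not yet diagnosed in the screened arm). This is
a deliberate design choice: it is the only denominator under which more
screening (shorter interval, higher compliance) *lowers* the per-unit
risk of overdiagnosis while *raising* the proportion — the opposing
directions that make reporting both statistics informative. Any
per-woman denominator (attendees, cohort) moves almost nothing across
policies, so the rate would simply track the overdiagnosed count and
fall with longer intervals. Both per-woman denominators remain available
via `ScenarioConfig.rate_denominator`.

`population_scale` (default 1.0; 0.82 in the sensitivity analysis)
rescales only the rate denominator. The model omits direct-to-invasive
cancer, which leaves the healthy pool larger than in a real population;
scaling the denominator to the DCIS-precursor share bounds that bias.
The proportion, a ratio of diagnosed counts, cancels the scale exactly.

Grade stratification uses the grade of the screened-arm diagnosis.
Every run asserts the excess identity
`n_overdiagnosed = n_diagnosed_screened − n_diagnosed_unscreened +
n_unscreened_only`; with the shared-trajectory design the
unscreened-only class is structurally empty (a screen detection is
always inside the window and death is shared), which the oracle
confirms exactly.

## Random streams

One Philox counter-based engine per (cohort seed, purpose), with
purposes natural-history / attendance / screen-test keyed through
`numpy.random.SeedSequence`. Each woman owns a disjoint fixed-width
counter block (404 words = 101 ages × 4 event slots for natural history;
32 words, indexed by round number, for each screening purpose), so:

- woman *i*'s trajectory depends only on (cohort seed, *i*) — not on
  cohort size, chunking, or policy;
- a whole cohort's deviates are one vectorised draw, bit-identical to
  the per-woman view (asserted in tests);
- deviates are consumed positionally (age × event slot, or round index),
  so CRN coupling across arms and across sweep cells is exact: cells of
  a sweep share trajectories outright, and round *j* of any policy uses
  the same attendance and sensitivity deviates.

Cohort seeds derive from (master seed, cohort index) via SeedSequence
and stay below 2³².

## The enumeration oracle

Because screening never perturbs the latent chain, the coupled pair
process is the latent chain augmented with an observation flag (which
grade, if any, a screen has detected). `markov_oracle` propagates the
joint mass through the same intra-cycle event order as the simulator and
returns exact probabilities of each pair classification, the proportion,
the rate (via the expected number of screens performed), and per-cycle
mass-conservation errors (tolerance 10⁻¹²). It is restricted to
per-round attendance and horizons ≤ 60 cycles, and it starts
healthy-and-alive at `start_age` — exact versus the birth-start
simulator whenever death and onset carry no mass below that age, as in
the constant-hazard fixtures built by
`synthetic_params.constant_hazard_parameters`. A private argument
permuting the DCIS event order exists solely so a regression test can
pin the convention.

Monte-Carlo agreement is tested at n = 200,000 women within 4 binomial
standard errors on every outcome class for five fixtures spanning single
and multi-round policies, partial compliance, mortality, and
progression-only disease.

## Stylized parameter generator

`SyntheticSpec` → `generate_parameter_set` builds the study conditions
that the withheld registry calibrations would otherwise provide:

| quantity | form | default | why |
|---|---|---|---|
| mortality | level·e^(slope·age) | 1.2e−5, 0.10/y (→ ~0.2% at 50, ~30% at 100) | monotone Gompertz-like adult mortality |
| onset (total) | Gaussian bell over age | peak 2e−3/y at 62, sd 12 y | screening-age incidence peaking in the 60s; sd is a free scale choice |
| grade mix | fixed split of onset | 0.20 / 0.45 / 0.35 | intermediate grade most common at diagnosis |
| progression base | level·(0.3 + age/100) | 0.03/y at the age-70 reference | mildly age-increasing |
| grade multipliers | m₁ ≤ m₂ ≤ m₃ | 0.5 / 1.0 / 2.0 | grade 3 most progressive |
| clinical detection, regression, sensitivity | scalars | 0.05/y, 0.05/y, 0.86 | the model's fixed rates |

The seed drives only a ±5% jitter on the three levels, so distinct seeds
give structurally identical but numerically distinct sets; every
generated set passes full validation, and the generator refuses specs
that violate the cycle probability-mass bounds.

What the stylized set does **not** emulate: calibrated Dutch incidence
and mortality levels, cohort (birth-year) effects, age-dependence of
clinical detection or regression, and detection-mode-specific grade
mixes. Passing tests therefore certify the estimator's mechanics and
the *directions* of the determinant effects, not Dutch point estimates;
absolute proportions and rates on these inputs are higher than
registry-calibrated values.

## Scales and numerical choices

- Reporting scale in the analysis drivers and acceptance script:
  5 cohorts × 20,000 women (the package's chosen reduced scale;
  `--full` switches the drivers to 10 × 100,000). Across-cohort means
  and standard errors accompany every estimate.
- Oracle mass tolerance 10⁻¹²; parameter-mass validation slack 10⁻⁹;
  probabilities compared in standard-error units in stochastic tests.
- Ages are integers; all rates are annual discrete-cycle probabilities.
  No continuous-time hazards anywhere, which keeps the oracle exact.
- Degenerate inputs: zero-compliance or zero-sensitivity policies give
  woman-identical arms (asserted exactly); empty diagnosis sets report
  NaN statistics rather than 0.

## Known limitations

- No IBC-related overdiagnosis, no post-diagnosis survival, no
  treatment or overtreatment modelling, no false positives or recall
  cascades, no breast density or modality effects, no high-risk
  subgroups.
- The attendance correlation structure (per-round vs all-or-none) is a
  bracket, not an estimate; real programmes lie between.
- Conclusions about magnitudes transfer to calibrated settings only in
  direction and ordering; the stylized levels are not Dutch estimates.
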