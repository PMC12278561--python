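# Methods

This note documents the models, algorithms and design choices behind
`clabsi_forest`: a package that compares random-forest risk models for
7-day CLABSI (central line-associated bloodstream infection) prediction
built against four different operationalizations of the same outcome --
binary, multinomial, survival, and competing risks -- on catheter-episode
data with complete follow-up.

## The prediction problem

The unit of risk is the *catheter episode*: a maximal period of
central-line exposure within a hospital admission, ending in exactly one
of three mutually exclusive terminal events: CLABSI, death (including
transfer to palliative care), or discharge (hospital discharge or 48 h
after catheter removal, whichever comes first).  Catheters overlapping or
separated by less than 48 h belong to one episode.  Follow-up is complete:
there is no loss to follow-up, so "censoring" only ever arises from
deliberate analytic choices, never from the data.

Episodes are expanded into daily *landmarks* LM0..LM30 (LM0 at the first
catheter observation, LMk at k x 24 h).  At each landmark the target is the
risk of CLABSI within the next 7 days.  Static models use only LM0 rows;
dynamic models treat each landmark row as an observation and include the
landmark index as a feature.

## Outcome operationalizations

With residual time to event `T` (days from the landmark) and cause
`D in {CLABSI, death, discharge}`, each landmark row is encoded as:

* **binary** -- `y = 1{D = CLABSI, ceil(T) <= 7}`;
* **multinomial** -- the cause if `ceil(T) <= 7`, else "none";
* **survival** -- `(min(ceil(T), c), 1{D = CLABSI, ceil(T) <= c})` with
  administrative censoring day `c in {7, 30}`.  Competing events are
  censored either at their event time (naive) or at day 7, the prediction
  horizon, which keeps subjects with competing events in the risk set in
  the spirit of Fine-Gray subdistribution censoring;
* **competing risks** -- `(min(ceil(T), c), cause)`, cause 0 (censored) if
  the event falls after `c`.

Event times are discretized by `ceil`: an event at day 6.1 is recorded at
day 7.  Rounding up moves events into the future, never the past, so the
encoding can never leak post-landmark information; it also reduces split
statistics to sums over at most `c` distinct days, which is what makes
survival forests affordable on landmark datasets.  An event exactly on the
administrative-censoring day counts as an event (only events strictly
after `c` are censored).

The model grid pairs these encodings with split rules into 14 static and
8 dynamic configurations (day-30 administrative censoring is fit
statically only; its dynamic counterparts are disproportionately expensive
and add no information at the 7-day horizon).

## The forest engine

The forest is written from scratch because the comparison needs one engine
that supports all four outcome types, admission-clustered resampling, and
a Gray-type split rule; no installed library offers that combination, and
using different libraries per outcome would confound the comparison with
implementation differences.

**Split statistics.**  Classification trees (binary, multinomial) maximize
the Gini impurity decrease.  Survival-type trees maximize `|U|/sqrt(V)`
where, over distinct event days `t_k` with `d_k` events, `Y_k` at risk and
(`d_kL`, `Y_kL`) in the left child,

    U = sum_k (d_kL - d_k Y_kL / Y_k)
    V = sum_{k: Y_k>1} d_k (Y_kL/Y_k)(1 - Y_kL/Y_k)(Y_k - d_k)/(Y_k - 1),

the hypergeometric two-sample log-rank form.  The cause-specific rule
("logrank") computes `(U_j, V_j)` per cause, treating other causes as
censored at their times, and combines them with nonnegative cause weights
as `|sum_j w_j U_j| / sqrt(sum_j w_j^2 V_j)`; weights (1,0,0) restrict
splitting to CLABSI differences.  The cumulative-incidence rule
("logrankCR") is Gray-type: cause `j`'s risk set is modified so that a
subject with a prior competing event remains at risk until its
administrative-censoring day.  With complete follow-up that day is known
deterministically, so the modified risk set needs no censoring-distribution
weighting; the variance keeps the same hypergeometric form with the
modified risk set substituted.  Both brute-force oracles in the test suite
implement these formulas independently of the engine.

**Terminal estimates.**  Every leaf stores the 7-day CLABSI risk in the
estimator its scheme implies: the class fraction (binary, multinomial, no
renormalization of the multinomial CLABSI probability), `1 - KM(7)`
(survival), or the Aalen-Johansen `CIF_CLABSI(7)` together with the other
causes' CIFs (competing risks).  Two identities anchor the comparison and
are asserted in the tests: on any node, `1 - KM(7)` under horizon
censoring equals the binary CLABSI-within-7 fraction exactly, and on
complete (uncensored) node data the Aalen-Johansen CIF at day 7 equals the
empirical cause fraction.  The naive survival encoding is the one
configuration that breaks this equivalence: subjects discharged before day
7 leave its risk set, inflating `1 - KM(7)` above the true cumulative
incidence.  Under the generator's default hazards the population version
of this inflation is 1 - (1-h_C)^7 ~ 0.0139 against a true 7-day CIF of
~0.0092, an E:O ratio of roughly 1.5.

**Aggregation.**  A forest prediction is the mean of leaf estimates over
trees (rather than an aggregated ensemble hazard curve); only the day-7
functional is consumed downstream, and averaging the functional keeps the
binary/survival identity exact at forest level.

**Clustered resampling.**  In-bags are sampled by whole admission:
bootstrap (with replacement, size = number of admissions) for static
models, subsampling without replacement (fraction tunable in 0.30-0.80)
for dynamic models.  An admission is never partly in-bag: out-of-bag (OOB)
predictions are honest at admission level.  An optional `equalize_inbag`
mode trims all in-bags to the smallest in-bag size by randomly dropping
rows (mirroring the equal-in-bag-size constraint of reference survival
forest software); the dropped rows fall out-of-bag, which is knowingly a
mild information leak, so the mode is off by default.

**Candidate splits.**  At each node `mtry` variables are drawn (default
`ceil(sqrt(p))`); per variable at most `nsplit = 10` random observed
values serve as thresholds (`nsplit = 0` gives exhaustive splits, used in
tests).  Ties between equal scores resolve to the first candidate in
(variable draw order, ascending threshold), making trees deterministic
given the seed.  Nodes stop splitting when the best score is zero or
undefined (e.g. no weighted events for survival rules) or when a child
would fall below `nodesize`.

**Hyperparameters.**  `n_trees` defaults to 100 at desk scale (the
reference analysis fixes 1000; predictions stabilize well before that at
our cohort sizes).  `nodesize` defaults to 60: with a ~1.3% 7-day event
rate a leaf needs tens of rows before its risk estimate carries signal on
the 1% scale, and 60 balances discrimination against leaf-level noise.
Random-search tuning on OOB binary logloss of the 7-day CLABSI indicator
(the one objective shared by all schemes) is available with bounds on
`mtry`, `nodesize` and, for dynamic models, `sample_fraction`; ties break
toward smaller nodesize then smaller mtry.  At desk scale (tens of
training events) the OOB logloss is itself noisy, so tuning mainly adds
variance; desk experiments therefore run on the fixed defaults, and tuning
is exercised at small scale in the tests.

**Minimal depth.**  Variable importance is reported as minimal depth: per
tree, the depth of the shallowest node split on the variable (0 = root),
averaged over the trees where the variable appears; unused variables are
reported as absent.

## Metrics

AUROC (Mann-Whitney with ties counted 1/2), AUPRC (average precision),
Brier skill score against a constant training-prevalence predictor
(`1 - BS/BS_ref`; the pure ratio form is also exposed because the
convention is stated ambiguously in parts of the applied literature), E:O
ratio (mean predicted / mean observed), calibration slope (maximum
likelihood logistic regression of the outcome on the logit of predictions,
clipped to [1e-6, 1-1e-6]), and ECI (100 x mean squared difference between
predictions and a loess-smoothed calibration curve; local quadratic
regression, tricube weights, span 0.75, smoother output clipped to [0,1]).
Undefined cells (single-class strata, zero events, non-convergence) are
reported as missing, with per-landmark strata additionally requiring at
least 5 events.  Repeated-split summaries report median and IQR with
linear-interpolation quartiles.

## The synthetic cohort generator

Real CLABSI surveillance data cannot be shared, so all experiments run on
a generator that emulates the cohort structure the analysis assumes.

* **Admissions and episodes.**  8.2% of admissions carry more than one
  episode: episode count is `1 + Bernoulli(0.082) * Geometric(0.5)`,
  truncated at 4.  Episodes are sequential with at least 48 h between the
  end of one and the start of the next; an episode ending in death
  terminates the admission.
* **Covariates.**  Five binary baseline covariates (catheter type, TPN,
  antibiotics, chemotherapy, ICU; marginals from a realistic catheter
  cohort) shared by all episodes of an admission, and three AR(1) daily
  series (temperature, white-cell count, CRP) with stationary marginals
  anchored at clinically plausible means.
* **Events.**  Discrete-time competition: on each day an at-risk episode
  experiences cause `j` with hazard `h_j(d, x)` from a multinomial logit
  on the standardized covariates *at episode onset*, with separate
  intercepts for days 1-7 and later days; otherwise it continues.  The
  continuous event time is `day - U`, `U ~ Uniform(0,1)`, so `ceil`
  recovers the generating day exactly.  The rare episode still event-free
  at day 60 is discharged then.
* **Calibration.**  The default coefficients make TPN and CRP predictive
  of CLABSI while death and discharge are driven by distinct covariates
  (ICU, CRP, antibiotics, chemotherapy), so that multi-event models can
  plausibly prefer different early splits.  The two intercept sets were
  calibrated once, by simulation at 200,000 admissions, so that marginal
  episode-level event fractions match the emulation targets: 3.1% CLABSI /
  4.7% death / 92.1% discharge overall and 1.3% / 2.7% / 63.4% within 7
  days of onset (the piecewise intercepts are what lets both sets of
  targets hold simultaneously: discharges concentrate early, CLABSI late).
* **Ground truth.**  Because hazards depend on covariates at onset,
  `true_cif` -- the discrete-time cumulative incidence
  `sum_d h_j(d,x) prod_{d'<d}(1 - sum_l h_l(d',x))` -- is the exact
  generating risk for every episode, enabling parameter-recovery tests.
* **Missingness** is optional and strictly MCAR; terminal events are never
  masked.  Imputation is mean/mode/fixed-normal-value learned on training
  rows only.

What the generator does *not* emulate: within-admission correlation of
episode outcomes beyond shared baseline covariates (episodes are
conditionally independent), informative missingness, sub-daily timing,
feedback from evolving covariates onto hazards (trajectories fluctuate
around the onset value that drives risk), and the full 302-feature space
of a real EHR extraction.  Passing tests therefore demonstrate the
*mechanisms* -- censoring-scheme bias, identity of encodings, estimator
consistency -- not clinical-scale performance numbers.

## Desk-scale experiment design

Default experiments use 3,000 admissions (~3,300 episodes, ~40
CLABSI-within-7 events), 100 trees, admission-level 2/3-1/3 splits.  At
this event count, single-split metrics are dominated by Monte-Carlo noise
(an E:O ratio from one test set of ~14 events has a ~25% relative
standard deviation), so headline quantities are computed by pooling
predictions and outcomes over many repeated splits: the pooled E:O ratio
over 100 splits has a standard deviation of about 0.035, against ~0.3 for
a single split.  Consistency of the competing-risks forest is checked on
nested training subsets (1,000 / 2,000 / 4,000 admissions drawn from one
cohort) against `true_cif` on a fixed evaluation cohort, averaging the
mean absolute error over replicate subsets; nesting shares the
cohort-level noise across sizes so the expected monotone decrease is not
drowned by cohort sampling variation.

## Known limitations

* The Gray-type split rule fixes its own variance convention (the
  hypergeometric form with the modified risk set); reference
  implementations may weight differently, so scores are validated against
  this package's stated formula, not against external software internals.
* Multi-event models (multinomial, competing risks) hold a genuine
  small-sample efficiency advantage on the synthetic cohort: they place
  splits using thousands of discharge/death events, whereas the binary and
  survival models see only the few dozen CLABSI events.  At desk scale
  this separates their discrimination visibly; the gap narrows as the
  cohort grows.
* Calibration slope and ECI are unstable below a few dozen events and are
  reported as missing rather than extrapolated.
* Forest training is pure NumPy; it is fast enough for desk-scale cohorts
  (seconds per forest) but is not engineered for the multi-million-row
  landmark datasets of a production EHR pipeline.
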