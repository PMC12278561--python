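# clabsi-forest

Static and dynamic random forests for predicting the 7-day risk of
central line-associated bloodstream infection (CLABSI), built against four
operationalizations of the same outcome — binary, multinomial, survival
and competing risks — on catheter-episode data with complete follow-up.

Hospital admissions are split into *catheter episodes* (maximal periods of
central-line exposure; catheters overlapping or separated by less than
48 h are grouped) that end in exactly one of CLABSI, death or discharge.
Episodes are expanded into daily *landmarks* LM0–LM30, and at each
landmark the question is: what is the probability of CLABSI within the
next 7 days?  Because in-hospital follow-up is complete, the outcome can be
encoded categorically or as a (discretized) time-to-event, and the choice
of encoding — in particular how competing events are censored in a
survival model — changes the fitted risks:

* a survival forest that censors death/discharge **at their event times**
  removes those subjects from the risk set and overestimates 7-day risk
  (E:O ratio well above 1);
* censoring competing events **at day 7, the prediction horizon**
  (Fine–Gray-style subdistribution censoring) keeps them in the risk set;
  the leaf estimate `1 − KM(7)` then equals the plain CLABSI-within-7
  fraction, and the model is calibrated (E:O ≈ 1).

The package implements the full comparison pipeline: a synthetic cohort
generator with known ground-truth hazards, episode/landmark data
engineering, the four outcome encodings, a from-scratch forest engine
(Gini, log-rank, cause-weighted log-rank and Gray-type "logrankCR" split
rules; Kaplan–Meier and Aalen–Johansen leaf estimators; in-bag sampling
clustered by admission), an evaluation suite (AUROC, AUPRC, Brier skill
score, E:O, calibration slope, ECI), and an experiment runner with a CLI.
See `docs/methods.md` for the statistical details.

## Worked example

```python
import numpy as np
from clabsi_forest import (CohortConfig, ForestHyperparams, fit_forest,
                           generate_cohort, model_by_name, split_admissions)
from clabsi_forest.landmarks import (ID_COLS, OUTCOME_COLS, build_landmark_table,
                                     filter_baseline, impute)
from clabsi_forest.outcomes import encode_frame
from clabsi_forest.synthetic import cohort_frames

cohort = generate_cohort(CohortConfig(n_admissions=3000, seed=42))
episodes, daily = cohort_frames(cohort)
baseline = filter_baseline(build_landmark_table(episodes, daily))
feats = [c for c in baseline.columns if c not in ID_COLS + OUTCOME_COLS]

rng = np.random.default_rng(7)
train_ids, _ = split_admissions(episodes["admission_id"], 2 / 3, rng)
mask = baseline["admission_id"].isin(train_ids)
train, test, _ = impute(baseline[mask], baseline[~mask])

for name in ("surv7d", "surv7d_cens7"):
    model = model_by_name(name)
    forest = fit_forest(train, feats, model, ForestHyperparams(n_trees=100),
                        np.random.default_rng(5))
    pred = forest.predict_risk7(test)
    obs = encode_frame(test, model.spec)["y_bin7"]
    print(f"{name:13s} E:O = {pred.mean() / obs.mean():.2f}")
```

Output:

```
surv7d        E:O = 1.57
surv7d_cens7  E:O = 1.06
```

The naive event-time-censoring model (`surv7d`) predicts a mean risk some
50–60% above the observed 7-day CLABSI rate, while the horizon-censored
variant (`surv7d_cens7`) sits near 1.  A single test set of a
3,000-admission cohort holds only ~14 CLABSI events, so individual E:O
values carry substantial Monte-Carlo noise; pooling over repeated splits
(as the acceptance script does) stabilizes them near 1.4 and 1.0.

The full 14-model static grid (plus 8 dynamic models) can be run with the
CLI:

```bash
clabsi-forest generate --n-admissions 3000 --seed 1 --outdir cohort/
clabsi-forest run --config run.yaml --outdir results/
clabsi-forest report results/
```

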