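# Methods

## The validation problem

A verbal-autopsy (VA) classification algorithm maps a vector of ternary
symptom indicators (yes / no / don't-know) to one of N causes of death.
Its performance must be assessed at two levels:

* **individual**: does it diagnose single deaths correctly?
* **population**: does it recover the cause-specific mortality fraction
  (CSMF) vector of a population whose composition it has never seen?

Both assessments are run against gold-standard data and corrected for chance,
and the test data's cause composition is randomised independently of the
training data. This package implements that protocol as a reusable pipeline
and ships a synthetic data generator so the pipeline can be exercised and
tested end-to-end with a known ground truth.

## Metrics

**Chance-corrected concordance (CCC).** For cause j out of N,

    CCC_j = (sens_j - 1/N) / (1 - 1/N),   sens_j = TP_j / (TP_j + FN_j).

CCC_j is 1 for perfect detection, 0 for uniform random guessing, and bounded
below by -1/(N-1) (sensitivity 0). Causes with no true cases in an
evaluation set have undefined CCC; they are carried as NaN and excluded from
overall aggregation. The overall individual-level summary can be the mean or
the median of the per-cause values; both are computed in every report, and
the mean is the default in exported tables. (The validation literature uses
both formulations; nothing downstream depends on the choice, and it is a
config switch.)

**CSMF accuracy.**

    CSMFAccuracy = 1 - Σ_j |CSMF_j^true - CSMF_j^pred| / (2 (1 - min_j CSMF_j^true)).

The denominator is the largest possible L1 error given the true composition,
so the statistic lies in [0, 1]. The true CSMF of a resampled test set is its
*realised* cause composition, not the Dirichlet target it was drawn toward.

**Chance-corrected CSMF accuracy (CCCSMF).**

    CCCSMF = (CSMFAccuracy - (1 - e^-1)) / (1 - (1 - e^-1)).

When true fractions are drawn from an uninformative Dirichlet and causes are
allocated at random, CSMF accuracy concentrates near 1 - e^-1 ≈ 0.632 as N
grows; CCCSMF rescales so that this chance level maps to 0 and perfect
prediction to 1. Negative values mean *worse than guessing* — the regime a
badly mis-specified expert probbase produces. At finite N the chance level
differs slightly from the asymptote (for N = 34 the exact mean of
Σ|t_j - 1/N| under Dirichlet(1) is 2(1-1/N)^N ≈ 0.725, not 2/e ≈ 0.736, and
multinomial noise in realised compositions pushes the other way); the
package's chance-calibration checks therefore assert closeness to 0.632 with
a tolerance rather than equality.

**Sensitivity/specificity** are one-vs-rest per cause, summarised by their
median over defined causes; the full N×N misclassification matrix (rows =
true cause, columns = predicted) is kept per split and pooled in exports.

## Split design

Each repetition partitions the data uniformly at random into a 75% train and
25% test fold (simple random, not cause-stratified), draws a target CSMF from
a flat symmetric Dirichlet (alpha = 1 on every cause; configurable), and
resamples the test fold with replacement to that target: realised cause
counts are multinomial with probabilities equal to the target renormalised
over causes actually present in the fold (renormalisation events are
logged), and records are drawn uniformly with replacement within cause. The
resampled test-set size equals the test-fold size (the whole dataset in
no-training mode) so per-split metric variance is comparable across modes.
The default number of repetitions is 500.

This design makes train-fold and test-set cause compositions uncorrelated —
a classifier that simply echoes the training composition gains nothing — and
exposes the algorithm to a wide range of compositions. The decorrelation is
asserted empirically (per-cause |r| < 0.15 across 200 splits).

Per-split RNG seeds are `(master_seed * 1_000_003 + split_index) mod 2^31`,
so any single split can be reproduced in isolation.

## Probbase estimation and classifiers

The *probbase* P[j, s] = P(symptom s endorsed | cause j) is estimated from a
training fold as

    P[j, s] = (#yes + c) / (#observed + 2c),   c = 0.5 by default,

with don't-know responses excluded from both counts. The Jeffreys-style
pseudo-count keeps every entry strictly inside (0, 1) so log-likelihoods are
finite; causes with zero training records receive the uninformative 0.5 row
and are flagged. Training-fold cause counts (plus the same pseudo-count)
give the default classifier prior; a uniform prior is available.

Two deterministic naive-Bayes scorers consume a probbase:

* `bayes_full`: log-score(j) = log prior_j + Σ_{s observed}
  [x_s log P(j,s) + (1 - x_s) log(1 - P(j,s))] — uses endorsed *and*
  not-endorsed symptoms;
* `bayes_endorsed_only`: drops the absence term (the InterVA-style
  restriction). When one cause's symptom profile nests another's, only the
  full likelihood can separate them; the test suite asserts this.

Missing symptoms are skipped by default (don't-know is not evidence);
`as_absent` treats them as "no" for sensitivity analysis. Posteriors are
softmax of the log-scores; ties break to the lowest cause index. Records
with no observed symptoms fall back to the prior argmax and are flagged.
Probabilities entering log space are clipped to [1e-12, 1 - 1e-12] so that
user-supplied fixed probbases containing exact 0/1 entries cannot produce
non-finite scores; trained (smoothed) probbases are unaffected.

A uniform `random` classifier provides the chance baseline, and externally
produced predictions can be scored through a `record_id,predicted_cause` CSV
(the plug-in contract) — this is how MCMC-based probbase samplers, which are
deliberately not re-implemented here, would be evaluated.

## Experiment modes

* **trained**: per split, estimate the probbase on the train fold, resample
  the test fold, predict, score.
* **fixed_probbase**: no training — a supplied probbase predicts for test
  sets resampled from the *complete* dataset (there is no held-out fold to
  protect), once per repetition.

HCE (health-care-experience) symptoms can be excluded from data and probbase
consistently to emulate community deaths without prior medical contact.
Split-level failures (e.g. an infeasible resample) are logged and skipped;
more than 50% failures aborts the run. Aggregation reports the median and
the 2.5th/97.5th percentiles (linear interpolation) across completed splits,
per scalar metric and per-cause CCC; exported tables are on the percent
scale with one decimal. `compare_runs` gives difference-in-medians in
percentage points and per-cause sensitivity/specificity win counts.

## Synthetic data generator

Each cause owns `signature_size` dedicated symptoms endorsed with probability
`signature_strength`; all other symptoms are endorsed at `background_rate`.
Records draw a cause from `csmf_true`, symptoms Bernoulli from the probbase
row, then a symmetric flip with probability `noise_eps` (respondent
misreport), then missingness completely at random at `missing_rate`. Sites
are uniform labels with no distributional effect by default (an optional
per-site endorsement offset exists, default 0). HCE flags are a seeded random
subset of symptoms so that informative and background items are both
affected by HCE exclusion.

Defaults: `signature_strength 0.8`, `background_rate 0.05`,
`signature_size 3`, `noise_eps 0.05`, `missing_rate 0.05`,
`hce_fraction 0.2`, `n_sites 6`, uniform `csmf_true` — a moderately noisy,
clearly learnable regime in which the trained classifier is far from both
ceiling and chance. Module presets mirror the gold-standard validation
database's structure: 34 adult / 21 child / 6 neonate causes; 171 / 86 / 110
symptoms; ~7,800 / 2,100 / 2,600 records.

What the generator does **not** emulate: real marginal endorsement rates,
symptom-symptom correlation beyond the common cause, instrument skip logic,
informative missingness, site-specific cause compositions, or graded
cause-symptom propensities shared across causes. Passing tests therefore
demonstrate that the *protocol and metrics* behave correctly and that the
classifiers recover a known truth under the stated noise model — not that
any classifier achieves a particular accuracy on real VA data.

## Numerical and design choices

* Cause and symptom order is construction/file order and is authoritative
  for all matrices; nothing is sorted, so tie-breaks are reproducible.
* Symptom encoding on disk: 1 / 0 / empty-cell for yes / no / missing.
* Probbase CSVs are written with 17 significant digits and round-trip to
  better than 1e-12.
* CCC/sensitivity for causes absent from an evaluation set are NaN and
  excluded from aggregates (avoids 0/0; one-vs-rest convention).
* The 95% uncertainty interval is the 2.5/97.5 percentile pair of the
  per-split values with linear interpolation.
* The scaled problem sizes used by `scripts/acceptance.py` (3,000 records,
  100-500 repetitions) were chosen as the smallest sizes at which the
  medians are stable to well under a percentage point across seeds.

## Known limitations

* The reference classifiers assume conditional independence of symptoms
  given cause; they are transparent plug-in stand-ins, not re-implementations
  of any published MCMC sampler, and their absolute accuracies are not
  comparable to published algorithm benchmarks.
* Only top-cause predictions feed the CSMF (no partial/ranked assignment).
* The generator's independence assumptions make classification easier than
  on real data at matched noise levels; comparisons across configurations
  (trained vs fixed, with vs without HCE, full vs endorsed-only) are the
  meaningful outputs, not absolute levels.
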