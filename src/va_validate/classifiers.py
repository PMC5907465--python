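"""Empirical probbase estimation and plug-in reference classifiers.

``estimate_probbase`` computes, per training fold, the empirical probability
of each symptom being endorsed conditional on the gold cause — the "trained
probbase" — with Jeffreys-style pseudo-count smoothing so no propensity is
exactly 0 or 1.

The reference classifiers are deterministic naive-Bayes scorers over the
probbase:

* ``bayes_full`` uses information about symptoms that are endorsed *and*
  symptoms that are not: log-score(j) = log prior_j +
  sum over observed symptoms of x*log P(j,s) + (1-x)*log(1-P(j,s));
* ``bayes_endorsed_only`` drops the (1-x) absence term, using endorsements
  only (the InterVA-style restriction);
* ``random`` assigns causes uniformly at random — the chance-calibration
  baseline against which CCC = 0 and CCCSMF = 0 are defined.

These are transparent stand-ins that consume the same probbase input as
MCMC-based probbase samplers; such samplers are deliberately not
re-implemented here, and their predictions can instead be brought in through
the external predictions-CSV contract (``datamodel.read_predictions``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import (
    MISSING,
    YES,
    CauseList,
    PredictionSet,
    Probbase,
    SymptomDictionary,
    VADataset,
)

__all__ = [
    "ClassifierConfig",
    "estimate_probbase",
    "train_csmf_prior",
    "BayesClassifier",
    "RandomClassifier",
    "make_classifier",
    "classify",
    "random_classifier",
    "predict_all",
]

_KINDS = ("bayes_full", "bayes_endorsed_only", "random", "external_plugin")
_PRIORS = ("uniform", "train_csmf")
_MISSING_POLICIES = ("skip", "as_absent")

# floor/ceiling for probabilities entering log space; protects fixed
# probbases containing exact 0/1 entries from non-finite scores
_P_CLIP = 1e-12


@dataclass
class ClassifierConfig:
    """Configuration of a reference classifier.

    missing_policy: "skip" drops missing symptoms from the likelihood
    (don't-know is not evidence); "as_absent" treats them as not endorsed.
    Ties are broken to the lowest cause index, deterministically.
    """

    kind: str = "bayes_full"
    prior: str = "train_csmf"
    smoothing: float = 0.5
    missing_policy: str = "skip"
    tie_break: str = "lowest_index"

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}; expected {_KINDS}")
        if self.prior not in _PRIORS:
            raise ValueError(f"unknown prior {self.prior!r}; expected {_PRIORS}")
        if not (np.isfinite(self.smoothing) and self.smoothing >= 0):
            raise ValueError("smoothing must be a finite non-negative pseudo-count")
        if self.missing_policy not in _MISSING_POLICIES:
            raise ValueError(f"unknown missing_policy {self.missing_policy!r}")
        if self.tie_break != "lowest_index":
            raise ValueError("only lowest_index tie-breaking is supported")


def estimate_probbase(train: VADataset, smoothing: float = 0.5) -> Probbase:
    """Empirical cause-conditional endorsement probabilities from a train fold.

    P[j, s] = (#(yes | cause j, s observed) + smoothing)
              / (#(s observed | cause j) + 2 * smoothing).

    Missing responses are excluded from both numerator and denominator.
    Causes with zero training records get the uninformative row 0.5 and are
    flagged in ``zero_train_causes``.
    """
    if train.n_records == 0:
        raise ValueError("training dataset is empty")
    N = train.cause_list.N
    cause_idx = train.gold_cause_indices()
    onehot = np.zeros((train.n_records, N))
    onehot[np.arange(train.n_records), cause_idx] = 1.0
    yes = (train.symptoms == YES).astype(np.float64)
    observed = (train.symptoms != MISSING).astype(np.float64)
    yes_counts = onehot.T @ yes          # (N, S)
    obs_counts = onehot.T @ observed     # (N, S)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = (yes_counts + smoothing) / (obs_counts + 2.0 * smoothing)
    cause_counts = np.bincount(cause_idx, minlength=N)
    zero = cause_counts == 0
    P[zero] = 0.5
    P = np.where(np.isfinite(P), P, 0.5)  # smoothing=0 with a fully-missing cell
    flagged = tuple(c for c, z in zip(train.cause_list.causes, zero) if z)
    return Probbase(P, train.cause_list, train.symptom_dict,
                    provenance="trained", zero_train_causes=flagged)


def train_csmf_prior(train: VADataset) -> np.ndarray:
    """Training-fold cause composition, floored so every cause is reachable."""
    counts = np.bincount(train.gold_cause_indices(), minlength=train.cause_list.N)
    weights = counts + 0.5  # pseudo-count keeps log prior finite for unseen causes
    return weights / weights.sum()


class BayesClassifier:
    """Deterministic probbase scorer (full or endorsed-only likelihood)."""

    def __init__(self, probbase: Probbase, config: ClassifierConfig,
                 prior: np.ndarray | None = None):
        if config.kind not in ("bayes_full", "bayes_endorsed_only"):
            raise ValueError(f"BayesClassifier cannot run kind {config.kind!r}")
        self.probbase = probbase
        self.config = config
        N = probbase.cause_list.N
        if prior is None:
            prior = np.full(N, 1.0 / N)
        prior = np.asarray(prior, dtype=np.float64)
        if prior.shape != (N,) or (prior < 0).any() or abs(prior.sum() - 1.0) > 1e-9:
            raise ValueError("prior must be a probability vector over the causes")
        self.prior = prior

    def predict(self, dataset: VADataset) -> PredictionSet:
        if dataset.n_records == 0:
            raise ValueError("cannot predict on an empty dataset")
        if dataset.symptom_dict.ids != self.probbase.symptom_dict.ids:
            raise ValueError("dataset symptoms do not match the classifier's probbase")
        X = dataset.symptoms
        if self.config.missing_policy == "as_absent":
            endorsed = X == YES
            observed = np.ones_like(endorsed, dtype=bool)
        else:
            endorsed = X == YES
            observed = X != MISSING
        P = np.clip(self.probbase.values, _P_CLIP, 1.0 - _P_CLIP)
        logP = np.log(P)
        log1mP = np.log1p(-P)
        log_prior = np.log(np.clip(self.prior, _P_CLIP, 1.0))
        scores = endorsed.astype(np.float64) @ logP.T
        if self.config.kind == "bayes_full":
            scores = scores + (observed & ~endorsed).astype(np.float64) @ log1mP.T
        scores = scores + log_prior

        # records with no observed symptom carry no evidence: flag them; their
        # score row is the prior alone, so argmax falls back to the prior
        no_evidence = ~observed.any(axis=1)
        flagged = tuple(dataset.record_ids[no_evidence].tolist())

        shifted = scores - scores.max(axis=1, keepdims=True)
        post = np.exp(shifted)
        post /= post.sum(axis=1, keepdims=True)
        pred_idx = np.argmax(scores, axis=1)  # argmax takes the lowest index on ties
        causes = np.array([self.probbase.cause_list.causes[j] for j in pred_idx],
                          dtype=object)
        return PredictionSet(
            record_ids=dataset.record_ids,
            predicted_causes=causes,
            cause_list=self.probbase.cause_list,
            posteriors=post,
            flagged_ids=flagged,
        )


class RandomClassifier:
    """Uniform-at-random cause assignment; the chance baseline."""

    def __init__(self, cause_list: CauseList, rng: np.random.Generator | int = 0):
        if cause_list.N < 2:
            raise ValueError("need at least 2 causes")
        self.cause_list = cause_list
        self.rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    def predict(self, dataset: VADataset) -> PredictionSet:
        if dataset.n_records == 0:
            raise ValueError("cannot predict on an empty dataset")
        idx = self.rng.integers(self.cause_list.N, size=dataset.n_records)
        causes = np.array([self.cause_list.causes[j] for j in idx], dtype=object)
        return PredictionSet(dataset.record_ids, causes, self.cause_list)

    def predict_labels(self, n: int) -> np.ndarray:
        """Draw n uniform cause labels without needing a dataset."""
        idx = self.rng.integers(self.cause_list.N, size=n)
        return np.array([self.cause_list.causes[j] for j in idx], dtype=object)


def make_classifier(config: ClassifierConfig, probbase: Probbase | None = None,
                    prior: np.ndarray | None = None,
                    rng: np.random.Generator | int = 0):
    """Instantiate the classifier described by ``config``."""
    if config.kind in ("bayes_full", "bayes_endorsed_only"):
        if probbase is None:
            raise ValueError(f"kind {config.kind!r} requires a probbase")
        return BayesClassifier(probbase, config, prior=prior)
    if config.kind == "random":
        if probbase is None:
            raise ValueError("random classifier needs a probbase or cause list context")
        return RandomClassifier(probbase.cause_list, rng=rng)
    raise ValueError(
        "external_plugin predictions are scored from a predictions CSV"
        " (datamodel.read_predictions / `va-validate score`), not run in-process"
    )


def classify(probbase: Probbase, prior: np.ndarray | None, record: np.ndarray,
             config: ClassifierConfig) -> tuple[str, np.ndarray]:
    """Score a single symptom vector; returns (top cause, posterior vector)."""
    record = np.asarray(record, dtype=np.int8).reshape(1, -1)
    ds = VADataset(
        record_ids=np.array(["_single"], dtype=object),
        module=probbase.cause_list.module,
        sites=np.array(["_"], dtype=object),
        gold_causes=np.array([probbase.cause_list.causes[0]], dtype=object),
        symptoms=record,
        cause_list=probbase.cause_list,
        symptom_dict=probbase.symptom_dict,
    )
    pred = BayesClassifier(probbase, config, prior=prior).predict(ds)
    return str(pred.predicted_causes[0]), pred.posteriors[0]


def random_classifier(cause_list: CauseList, rng: np.random.Generator | int = 0) -> RandomClassifier:
    return RandomClassifier(cause_list, rng=rng)


def predict_all(classifier, dataset: VADataset) -> PredictionSet:
    """Predict a top cause for every record in ``dataset``."""
    return classifier.predict(dataset)
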