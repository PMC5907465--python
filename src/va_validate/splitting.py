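"""Test-train splits with Dirichlet resampling of the test cause composition.

The validation design: partition the gold-standard data uniformly at random
into a 75% train fold and a 25% test fold, then resample the test fold (with
replacement, within cause) to a cause composition drawn from an uninformative
(flat) Dirichlet on the simplex.  Repeating this many times yields test sets
whose cause compositions are uncorrelated with the training data, so a
classifier cannot score well at the population level merely by echoing the
training composition.  In the no-training (fixed-probbase) mode the resample
is drawn from the complete dataset instead of a held-out fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import VADataset

__all__ = [
    "SplitPlan",
    "ResampledTestSet",
    "make_splits",
    "draw_dirichlet_csmf",
    "resample_to_csmf",
    "split_seed",
]


def split_seed(master_seed: int, index: int) -> int:
    """Deterministic per-split seed; reproducible in isolation, < 2^31."""
    return (int(master_seed) * 1_000_003 + int(index)) % (2**31)


@dataclass
class SplitPlan:
    """One train/test repetition and its Dirichlet target composition."""

    index: int
    seed: int
    train_indices: np.ndarray
    test_indices: np.ndarray
    target_csmf: np.ndarray

    def __post_init__(self) -> None:
        self.train_indices = np.asarray(self.train_indices, dtype=np.int64)
        self.test_indices = np.asarray(self.test_indices, dtype=np.int64)
        self.target_csmf = np.asarray(self.target_csmf, dtype=np.float64)
        if len(self.train_indices) == 0 or len(self.test_indices) == 0:
            raise ValueError("train and test folds must both be non-empty")
        if np.intersect1d(self.train_indices, self.test_indices).size:
            raise ValueError("train and test folds overlap")
        if abs(self.target_csmf.sum() - 1.0) > 1e-9 or (self.target_csmf < 0).any():
            raise ValueError("target_csmf must be a probability vector (sum 1 within 1e-9)")


@dataclass
class ResampledTestSet:
    """A with-replacement resample of a test fold to a target composition.

    ``record_indices`` index into the parent dataset (payloads are referenced,
    never copied), so repeated draws of the same record share identity.
    """

    parent_index: int
    record_indices: np.ndarray
    realized_counts: np.ndarray
    renormalized: bool = False  # True if some target causes had no records

    def __post_init__(self) -> None:
        self.record_indices = np.asarray(self.record_indices, dtype=np.int64)
        if len(self.record_indices) == 0:
            raise ValueError("resampled test set is empty")

    @property
    def size(self) -> int:
        return len(self.record_indices)


def make_splits(dataset: VADataset, n_splits: int = 500, train_frac: float = 0.75,
                master_seed: int = 0, alpha: float = 1.0) -> list[SplitPlan]:
    """Draw ``n_splits`` independent uniform train/test partitions.

    Each split gets its own RNG stream derived from ``master_seed`` and the
    split index, plus a flat-Dirichlet target CSMF for test resampling.
    """
    n = dataset.n_records
    if n < 8:
        raise ValueError("need at least 8 records to split")
    if not (0.0 < train_frac < 1.0):
        raise ValueError("train_frac must be in (0, 1)")
    n_train = int(round(train_frac * n))
    if n_train == 0 or n_train == n:
        raise ValueError("train or test fold would be empty")
    N = dataset.cause_list.N
    plans = []
    for i in range(n_splits):
        seed = split_seed(master_seed, i)
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        target = draw_dirichlet_csmf(N, alpha=alpha, rng=rng)
        plans.append(SplitPlan(
            index=i,
            seed=seed,
            train_indices=np.sort(perm[:n_train]),
            test_indices=np.sort(perm[n_train:]),
            target_csmf=target,
        ))
    return plans


def draw_dirichlet_csmf(N: int, alpha: float = 1.0,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """One draw from the symmetric Dirichlet(alpha, ..., alpha) on N causes."""
    if N < 2:
        raise ValueError("need at least 2 causes")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if rng is None:
        rng = np.random.default_rng()
    draw = rng.dirichlet(np.full(N, float(alpha)))
    return draw / draw.sum()  # guard against float drift off the simplex


def resample_to_csmf(dataset: VADataset, record_indices: np.ndarray,
                     target_csmf: np.ndarray, size: int,
                     rng: np.random.Generator, parent_index: int = -1) -> ResampledTestSet:
    """Resample ``record_indices`` with replacement to ``target_csmf``.

    Realised cause counts are multinomial with probabilities equal to the
    target renormalised over causes that have at least one available record;
    within each cause, records are drawn uniformly with replacement.
    """
    record_indices = np.asarray(record_indices, dtype=np.int64)
    if record_indices.size == 0:
        raise ValueError("no records to resample from")
    if size < 1:
        raise ValueError("size must be >= 1")
    target = np.asarray(target_csmf, dtype=np.float64)
    N = dataset.cause_list.N
    if target.shape != (N,):
        raise ValueError("target_csmf length must equal the number of causes")

    cause_idx = dataset.gold_cause_indices()[record_indices]
    available = np.bincount(cause_idx, minlength=N) > 0
    probs = np.where(available, target, 0.0)
    total = probs.sum()
    if total <= 0.0:
        raise ValueError("no cause with positive target weight has any available record")
    renormalized = bool((~available & (target > 0)).any())
    probs = probs / total

    counts = rng.multinomial(size, probs)
    by_cause = [record_indices[cause_idx == j] for j in range(N)]
    chunks = []
    for j in range(N):
        if counts[j] > 0:
            chunks.append(rng.choice(by_cause[j], size=counts[j], replace=True))
    out = np.concatenate(chunks)
    rng.shuffle(out)
    return ResampledTestSet(
        parent_index=parent_index,
        record_indices=out,
        realized_counts=counts,
        renormalized=renormalized,
    )
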