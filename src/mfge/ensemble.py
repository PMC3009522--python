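"""Five-classifier ensemble fitness machinery.

A candidate gene subset is scored by fitting every classifier in the bank on
the training slice restricted to the subset and measuring balanced
classification accuracy (mean per-class sensitivity) on the test slice.  Two
terms are combined:

* *blocking* — the mean balanced accuracy over the individual classifiers,
  so a subset must work for the whole ensemble rather than exploit the
  quirks of one inducer;
* *majority voting* — the balanced accuracy of the per-sample modal class
  over the first k classifiers, rewarding subsets that induce a strong
  consensus.

combined = w1 * blocking + w2 * voting, with w1 = w2 = 0.5 by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import sklearn
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from .data import ExpressionDataset

log = logging.getLogger(__name__)

__all__ = [
    "ClassifierBank",
    "FitnessValue",
    "make_bank",
    "balanced_accuracy",
    "majority_vote",
    "bank_fitness",
    "evaluate_subset",
    "CLASSIFIER_NAMES",
]

CLASSIFIER_NAMES = ("dt", "rf", "3nn", "7nn", "nb")

_PRETTY = {
    "dt": "Decision Tree",
    "rf": "Random Forest (7)",
    "3nn": "3-Nearest Neighbor",
    "7nn": "7-Nearest Neighbor",
    "nb": "Naive Bayes",
}


def _build(name: str, seed: int):
    if name == "dt":
        return DecisionTreeClassifier(random_state=seed)
    if name == "rf":
        # forest size 7; other hyperparameters at library defaults
        return RandomForestClassifier(n_estimators=7, random_state=seed)
    if name == "3nn":
        return KNeighborsClassifier(n_neighbors=3, algorithm="brute")
    if name == "7nn":
        return KNeighborsClassifier(n_neighbors=7, algorithm="brute")
    if name == "nb":
        return GaussianNB()
    raise ValueError(f"unknown classifier name {name!r}")


@dataclass
class ClassifierBank:
    """Ordered bank of classifier specifications.

    Members are re-instantiated and re-fit from scratch for every evaluated
    subset; stochastic members (tree, forest) draw their random state from
    the bank seed, so evaluation is deterministic for fixed inputs.
    """

    names: tuple[str, ...] = CLASSIFIER_NAMES
    seed: int = 0
    vote_k: int | None = None  # None -> all members vote

    def __post_init__(self) -> None:
        if not self.names:
            raise ValueError("empty classifier bank")
        unknown = set(self.names) - set(CLASSIFIER_NAMES)
        if unknown:
            raise ValueError(f"unknown classifier(s): {sorted(unknown)}")
        if self.vote_k is not None and not 1 <= self.vote_k <= len(self.names):
            raise ValueError("vote_k must be in 1..L")

    @property
    def size(self) -> int:
        return len(self.names)

    @property
    def k(self) -> int:
        return self.vote_k if self.vote_k is not None else self.size

    def estimators(self):
        return [_build(n, self.seed) for n in self.names]

    def pretty_names(self) -> list[str]:
        return [_PRETTY[n] for n in self.names]


def make_bank(names: tuple[str, ...] = CLASSIFIER_NAMES, seed: int = 0,
              vote_k: int | None = None) -> ClassifierBank:
    return ClassifierBank(tuple(names), seed, vote_k)


@dataclass
class FitnessValue:
    """Fitness of one gene subset under the ensemble."""

    blocking: float
    voting: float
    combined: float
    per_classifier: np.ndarray = field(default_factory=lambda: np.array([]))

    def __iter__(self):
        yield from (self.blocking, self.voting, self.combined)


def balanced_accuracy(
    predicted: np.ndarray, actual: np.ndarray, class_set: np.ndarray | None = None
) -> float:
    """Mean per-class sensitivity over ``class_set``.

    ``Se_j`` is the fraction of class-j samples predicted as class j.  A
    class from ``class_set`` absent from ``actual`` contributes sensitivity
    0 (with a warning), so degenerate folds penalize rather than inflate
    the score.
    """
    predicted = np.asarray(predicted)
    actual = np.asarray(actual)
    if len(predicted) != len(actual):
        raise ValueError(
            f"length mismatch: {len(predicted)} predictions, {len(actual)} labels"
        )
    classes = np.unique(actual) if class_set is None else np.asarray(class_set)
    se = []
    for c in classes:
        mask = actual == c
        if not mask.any():
            log.warning("balanced_accuracy: class %r absent from actual; Se=0", c)
            se.append(0.0)
        else:
            se.append(float((predicted[mask] == c).mean()))
    return float(np.mean(se))


def majority_vote(hypotheses: list[np.ndarray] | np.ndarray, k: int) -> np.ndarray:
    """Per-sample modal class among the first k prediction vectors.

    Ties are broken by the earliest classifier in bank order whose
    prediction belongs to the tied class set.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    H = np.asarray(hypotheses)
    if k > H.shape[0]:
        raise ValueError(f"k={k} exceeds number of hypotheses {H.shape[0]}")
    H = H[:k]
    out = np.empty(H.shape[1], dtype=H.dtype)
    for j in range(H.shape[1]):
        votes = H[:, j]
        vals, counts = np.unique(votes, return_counts=True)
        tied = set(vals[counts == counts.max()])
        if len(tied) == 1:
            out[j] = tied.pop()
        else:
            out[j] = next(v for v in votes if v in tied)
    return out


def bank_fitness(
    Xtr: np.ndarray,
    ytr: np.ndarray,
    Xte: np.ndarray,
    yte: np.ndarray,
    class_set: np.ndarray,
    bank: ClassifierBank,
    w1: float = 0.5,
    w2: float = 0.5,
) -> FitnessValue:
    """Fitness of pre-restricted train/test design matrices (samples x
    genes): blocking = mean BC over members, voting = BC of the k-vote,
    combined = w1*blocking + w2*voting."""
    hyps = []
    accs = []
    with sklearn.config_context(assume_finite=True):
        for est in bank.estimators():
            if (isinstance(est, KNeighborsClassifier)
                    and est.n_neighbors > Xtr.shape[0]):
                # degenerate tiny training slice: clamp k to what exists
                est.set_params(n_neighbors=Xtr.shape[0])
            est.fit(Xtr, ytr)
            h = est.predict(Xte)
            hyps.append(h)
            accs.append(balanced_accuracy(h, yte, class_set))
    blocking = float(np.mean(accs))
    voting = balanced_accuracy(majority_vote(hyps, bank.k), yte, class_set)
    combined = w1 * blocking + w2 * voting
    return FitnessValue(blocking, voting, combined, np.asarray(accs))


def evaluate_subset(
    subset,
    train: ExpressionDataset,
    test: ExpressionDataset,
    bank: ClassifierBank,
    w1: float = 0.5,
    w2: float = 0.5,
) -> FitnessValue:
    """Fit every bank member on ``train`` restricted to ``subset`` and score
    on ``test``; see :func:`bank_fitness` for the combination rule.

    ``subset`` is a collection of gene ids (or integer row indices).  An
    empty subset is never fitted and scores 0.
    """
    subset = list(subset)
    if not subset:
        log.warning("evaluate_subset: empty subset; fitness 0")
        return FitnessValue(0.0, 0.0, 0.0, np.zeros(bank.size))
    if isinstance(subset[0], str):
        pos = {g: i for i, g in enumerate(train.gene_ids)}
        rows = [pos[g] for g in subset]
    else:
        rows = [int(g) for g in subset]

    Xtr = np.ascontiguousarray(train.values[rows].T)
    Xte = np.ascontiguousarray(test.values[rows].T)
    class_set = np.unique(np.concatenate([train.labels, test.labels]))
    return bank_fitness(Xtr, train.labels, Xte, test.labels, class_set, bank, w1, w2)
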