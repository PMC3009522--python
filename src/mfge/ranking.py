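"""Gene ranking by selection frequency and the evaluation protocol.

After the genetic-ensemble loop, each gene is ranked by the number of
collected iterations whose best subset contains it.  The top-N genes
(default N in {5, 10, 15, 20}) are then assessed on the *external* test
fold — data never touched by pre-filtering, scoring or subset search —
reporting per-classifier balanced accuracy, their mean, and the
majority-voting accuracy, aggregated over folds and repeated runs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .data import ExpressionDataset
from .ensemble import ClassifierBank, balanced_accuracy, majority_vote
from .ga import SubsetCollection

log = logging.getLogger(__name__)

__all__ = [
    "selection_frequency",
    "evaluate_top_genes",
    "convergence_summary",
]


def selection_frequency(
    coll: SubsetCollection,
    tie_scores: pd.Series | None = None,
    all_genes: list[str] | None = None,
) -> pd.DataFrame:
    """Rank genes by how many collected subsets contain them.

    Returns a DataFrame indexed by gene id with a ``count`` column, sorted
    descending; ties break by fused integer score (``tie_scores``, if
    given) and then by original gene order, so the ranking is
    deterministic.  ``all_genes`` appends never-selected genes with count 0
    so the ranking is a permutation of the candidate set.
    """
    if not coll.records:
        raise ValueError("empty subset collection")
    counts: dict[str, int] = {}
    for rec in coll.records:
        for g in rec.genes:
            counts[g] = counts.get(g, 0) + 1
    if all_genes is not None:
        for g in all_genes:
            counts.setdefault(g, 0)
        order_ref = {g: i for i, g in enumerate(all_genes)}
    else:
        order_ref = {g: i for i, g in enumerate(sorted(counts))}
    genes = list(counts)

    def sort_key(g: str):
        tie = float(tie_scores.get(g, 0)) if tie_scores is not None else 0.0
        return (-counts[g], -tie, order_ref.get(g, len(order_ref)))

    genes.sort(key=sort_key)
    return pd.DataFrame({"count": [counts[g] for g in genes]}, index=pd.Index(genes, name="gene_id"))


def evaluate_top_genes(
    ranking: pd.DataFrame,
    n_list: tuple[int, ...],
    train: ExpressionDataset,
    test: ExpressionDataset,
    bank: ClassifierBank,
) -> pd.DataFrame:
    """Balanced accuracy of the top-N ranked genes on one external fold.

    Rows: one per bank classifier plus ``Mean`` and ``Majority Voting``;
    columns: one per N.  Accuracies are fractions in [0, 1].
    """
    if max(n_list) > len(ranking):
        raise ValueError(
            f"top-{max(n_list)} requested but ranking has {len(ranking)} genes"
        )
    class_set = np.unique(np.concatenate([train.labels, test.labels]))
    rows = {name: [] for name in bank.pretty_names()}
    rows["Mean"] = []
    rows["Majority Voting"] = []
    gene_pos = {g: i for i, g in enumerate(train.gene_ids)}
    for n in n_list:
        top = [g for g in ranking.index[:n]]
        idx = [gene_pos[g] for g in top]
        Xtr, Xte = train.values[idx].T, test.values[idx].T
        hyps, accs = [], []
        for name, est in zip(bank.pretty_names(), bank.estimators()):
            est.fit(Xtr, train.labels)
            h = est.predict(Xte)
            hyps.append(h)
            acc = balanced_accuracy(h, test.labels, class_set)
            accs.append(acc)
            rows[name].append(acc)
        rows["Mean"].append(float(np.mean(accs)))
        rows["Majority Voting"].append(
            balanced_accuracy(majority_vote(hyps, bank.k), test.labels, class_set)
        )
    return pd.DataFrame(rows, index=[f"top{n}" for n in n_list]).T


def _paired_one_tailed(a: np.ndarray, b: np.ndarray) -> float:
    """One-tailed paired t-test p-value for mean(a) < mean(b).

    All-zero differences carry no evidence either way; the p-value is
    defined as 0.5 (non-significant) in that degenerate case.
    """
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if np.allclose(d, 0):
        return 0.5
    if np.allclose(d, d[0]):
        # constant non-zero difference: direction decides
        return 0.0 if d[0] < 0 else 1.0
    t, p = stats.ttest_rel(a, b, alternative="less")
    return float(p)


def convergence_summary(
    collections: dict[str, list[SubsetCollection]],
    reference: str | None = None,
) -> pd.DataFrame:
    """Mean termination generation and subset size per method, with the
    one-tailed paired t-test that the first (or ``reference``) method
    converges faster / selects smaller subsets than each other method.

    Each method maps to a list of collections (one per run); all methods
    must have the same run count, runs paired by position.
    """
    methods = list(collections)
    if len(methods) < 2:
        raise ValueError("need >= 2 methods to compare")
    n_runs = {m: len(collections[m]) for m in methods}
    if len(set(n_runs.values())) != 1:
        raise ValueError(f"unequal repeat counts: {n_runs}")
    ref = reference or methods[0]

    gens = {m: np.array([c.mean_termination_generation() for c in collections[m]])
            for m in methods}
    sizes = {m: np.array([c.mean_subset_size() for c in collections[m]])
             for m in methods}

    rows = []
    for m in methods:
        p_gen = p_size = np.nan
        if m != ref:
            p_gen = _paired_one_tailed(gens[ref], gens[m])
            p_size = _paired_one_tailed(sizes[ref], sizes[m])
        rows.append({
            "method": m,
            "mean_termination_generation": float(gens[m].mean()),
            "mean_subset_size": float(sizes[m].mean()),
            "p_generation_ref_less": p_gen,
            "p_size_ref_less": p_size,
        })
    return pd.DataFrame(rows).set_index("method")
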