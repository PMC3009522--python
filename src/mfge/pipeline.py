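"""End-to-end orchestration of the MF-GE protocol.

Per external fold: BSS/WSS pre-filter on the training samples, filter
scoring and frequency-map construction on the same training samples, the
genetic-ensemble search with fitness averaged over the internal folds, and
finally top-N evaluation on the held-out external test samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (
    CVPlan,
    ExpressionDataset,
    bss_wss_scores,
    build_cv_plan,
    normalize_genes,
    prefilter_top_k,
    standardize_genes,
)
from .ensemble import ClassifierBank, FitnessValue, bank_fitness, make_bank
from .filters import FILTER_NAMES, score_all_filters
from .ga import GAConfig, SubsetCollection, run_ge
from .mapping import (
    FilterScoreTable,
    GeneFrequencyMap,
    build_frequency_map,
    combine_scores,
    uniform_frequency_map,
)
from .ranking import evaluate_top_genes, selection_frequency

log = logging.getLogger(__name__)

__all__ = ["FoldResult", "PipelineResult", "preprocess", "run_fold", "run_pipeline"]

DEFAULT_N_LIST = (5, 10, 15, 20)


@dataclass
class FoldResult:
    fold_id: int
    score_table: FilterScoreTable
    collection: SubsetCollection
    ranking: pd.DataFrame
    report: pd.DataFrame  # classifiers x top-N balanced accuracies
    gene_ids: list[str]  # pre-filtered candidate genes of this fold


@dataclass
class PipelineResult:
    folds: list[FoldResult] = field(default_factory=list)

    def mean_report(self) -> pd.DataFrame:
        """Grand mean of the per-fold top-N reports."""
        return sum(f.report for f in self.folds) / len(self.folds)

    def collections(self) -> list[SubsetCollection]:
        return [f.collection for f in self.folds]


def preprocess(ds: ExpressionDataset) -> ExpressionDataset:
    """Standardize then min-max normalize every gene row."""
    return normalize_genes(standardize_genes(ds))


class CachedFitness:
    """Memoized subset fitness: mean combined fitness over internal folds.

    A chromosome's fitness is the mean of :func:`evaluate_subset` over the
    internal train/test splits; identical decoded subsets are evaluated
    once.  The cache may be shared between engines run on the same fold
    (e.g. a frequency-map engine and its uniform-map baseline).
    """

    def __init__(
        self,
        ds: ExpressionDataset,
        internal_folds: list[tuple[np.ndarray, np.ndarray]],
        bank: ClassifierBank,
        w1: float = 0.5,
        w2: float = 0.5,
    ) -> None:
        # integer-encoded labels and samples x genes matrices, sliced by
        # column per subset: keeps the (very hot) evaluation path lean
        classes, y = np.unique(ds.labels, return_inverse=True)
        X = np.ascontiguousarray(ds.values.T)
        self.class_set = np.arange(len(classes))
        self.slices = [
            (X[tr], y[tr], X[te], y[te]) for tr, te in internal_folds
        ]
        self.bank = bank
        self.w1, self.w2 = w1, w2
        self.cache: dict[frozenset[int], FitnessValue] = {}
        self.evaluations = 0

    def __call__(self, subset: frozenset[int]) -> FitnessValue:
        hit = self.cache.get(subset)
        if hit is not None:
            return hit
        if not subset:
            return FitnessValue(0.0, 0.0, 0.0, np.zeros(self.bank.size))
        self.evaluations += 1
        cols = [code - 1 for code in subset]  # codes are 1-based gene rows
        vals = [
            bank_fitness(
                np.ascontiguousarray(Xtr[:, cols]), ytr,
                np.ascontiguousarray(Xte[:, cols]), yte,
                self.class_set, self.bank, self.w1, self.w2,
            )
            for Xtr, ytr, Xte, yte in self.slices
        ]
        fv = FitnessValue(
            float(np.mean([v.blocking for v in vals])),
            float(np.mean([v.voting for v in vals])),
            float(np.mean([v.combined for v in vals])),
            np.mean([v.per_classifier for v in vals], axis=0),
        )
        self.cache[subset] = fv
        return fv


def run_fold(
    ds: ExpressionDataset,
    plan: CVPlan,
    fold_id: int,
    cfg: GAConfig,
    bank: ClassifierBank,
    prefilter_size: int = 200,
    filter_set: tuple[str, ...] = FILTER_NAMES,
    n_list: tuple[int, ...] = DEFAULT_N_LIST,
    uniform_map: bool = False,
    fitness: CachedFitness | None = None,
    seed: int | None = None,
) -> FoldResult:
    """Run the full protocol on one external fold of a preprocessed dataset.

    ``uniform_map=True`` swaps the fused frequency map for the multiplicity-1
    baseline (the unenhanced genetic-ensemble engine); everything else is
    identical, so paired comparisons isolate the effect of the map.
    """
    ext_train_idx, ext_test_idx = plan.external_folds[fold_id]
    train_all = ds.subset_samples(ext_train_idx)

    ranks = bss_wss_scores(train_all)
    k = min(prefilter_size, train_all.n_genes)
    train_pf = prefilter_top_k(train_all, ranks, k)
    pos = {g: i for i, g in enumerate(ds.gene_ids)}
    keep = [pos[g] for g in train_pf.gene_ids]
    ds_pf = ds.subset_genes(keep)

    seed = cfg.seed if seed is None else seed
    table = score_all_filters(train_pf, filter_set, seed=seed)
    combine_scores(table)
    if uniform_map:
        fmap: GeneFrequencyMap = uniform_frequency_map(train_pf.gene_ids, seed=seed)
    else:
        fmap = build_frequency_map(table, seed=seed)

    if fitness is None:
        fitness = CachedFitness(
            ds_pf, plan.internal_folds[fold_id], bank, cfg.w1, cfg.w2
        )
    coll = run_ge(fitness, fmap, cfg, seed=seed)
    coll.fold_id = fold_id

    ranking = selection_frequency(coll, tie_scores=table.integer,
                                  all_genes=train_pf.gene_ids)
    report = evaluate_top_genes(
        ranking, n_list, ds_pf.subset_samples(ext_train_idx),
        ds_pf.subset_samples(ext_test_idx), bank,
    )
    log.info("fold %d: %d unique subsets evaluated", fold_id, fitness.evaluations)
    return FoldResult(fold_id, table, coll, ranking, report, train_pf.gene_ids)


def run_pipeline(
    ds: ExpressionDataset,
    cfg: GAConfig | None = None,
    bank: ClassifierBank | None = None,
    k_external: int = 3,
    k_internal: int = 3,
    prefilter_size: int = 200,
    filter_set: tuple[str, ...] = FILTER_NAMES,
    n_list: tuple[int, ...] = DEFAULT_N_LIST,
    uniform_map: bool = False,
    seed: int = 0,
    preprocessed: bool = False,
) -> PipelineResult:
    """Preprocess, build the nested CV plan, and run every external fold."""
    cfg = cfg if cfg is not None else GAConfig(seed=seed)
    bank = bank if bank is not None else make_bank(seed=seed)
    if not preprocessed:
        ds = preprocess(ds)
    plan = build_cv_plan(ds, k_external, k_internal, seed)
    result = PipelineResult()
    for fold_id in range(len(plan.external_folds)):
        result.folds.append(
            run_fold(
                ds, plan, fold_id, cfg, bank,
                prefilter_size=prefilter_size,
                filter_set=filter_set,
                n_list=n_list,
                uniform_map=uniform_map,
                seed=seed + 7919 * (fold_id + 1),
            )
        )
    return result
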