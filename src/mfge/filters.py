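"""Filter scoring algorithms: chi-square statistic, ReliefF, Symmetrical
Uncertainty, Information Gain and Gain Ratio.

The four contingency-table filters operate on a discretized version of each
gene, produced by Fayyad-Irani MDL-stopped recursive binary splitting on
class entropy; a gene for which no split passes the MDL test keeps a single
bin and receives the minimum score (0) from all four.  ReliefF works on the
continuous [0, 1]-normalized values directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ExpressionDataset
from .mapping import FilterScoreTable

log = logging.getLogger(__name__)

__all__ = [
    "DiscretizedGene",
    "ContingencyTable",
    "discretize_supervised",
    "contingency_table",
    "entropy",
    "chi2_score",
    "info_gain",
    "gain_ratio",
    "symmetrical_uncertainty",
    "relieff_score",
    "relieff_scores_all",
    "score_all_filters",
    "FILTER_NAMES",
]

FILTER_NAMES = ("chi2", "relieff", "su", "infogain", "gainratio")


@dataclass
class DiscretizedGene:
    """Per-sample bin assignment of one gene under supervised discretization.

    ``bins[i]`` equals the number of cut points strictly below the value of
    sample i, so ``n_bins == len(cut_points) + 1``.
    """

    bins: np.ndarray
    cut_points: list[float]

    @property
    def n_bins(self) -> int:
        return len(self.cut_points) + 1


@dataclass
class ContingencyTable:
    """Bin x class co-occurrence counts with marginals."""

    counts: np.ndarray  # shape (n_bins, n_classes)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (bins x classes)")
        if (self.counts < 0).any():
            raise ValueError("negative count")

    @property
    def bin_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def class_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> float:
        return float(self.counts.sum())


# ---------------------------------------------------------------------------
# Supervised discretization (Fayyad-Irani MDL)
# ---------------------------------------------------------------------------

def _class_entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _mdl_split(values: np.ndarray, y: np.ndarray, classes: np.ndarray,
               cuts: list[float]) -> None:
    """Recursively add accepted MDL cut points for one (sub)interval."""
    order = np.argsort(values, kind="stable")
    v, yy = values[order], y[order]
    n = len(v)
    # suffix/prefix class counts at every possible split position
    onehot = (yy[:, None] == classes[None, :]).astype(float)
    prefix = np.cumsum(onehot, axis=0)
    total = prefix[-1]
    ent_s = _class_entropy(total)
    k = int((total > 0).sum())
    if n < 2 or ent_s == 0:
        return

    best = None  # (weighted_entropy, cut, pos)
    for pos in range(1, n):
        if v[pos] == v[pos - 1]:
            continue  # identical values cannot be separated
        left, right = prefix[pos - 1], total - prefix[pos - 1]
        e = (pos * _class_entropy(left) + (n - pos) * _class_entropy(right)) / n
        if best is None or e < best[0]:
            best = (e, (v[pos - 1] + v[pos]) / 2.0, pos)
    if best is None:
        return
    e_split, cut, pos = best
    gain = ent_s - e_split
    left, right = prefix[pos - 1], total - prefix[pos - 1]
    k1, k2 = int((left > 0).sum()), int((right > 0).sum())
    delta = np.log2(3.0**k - 2.0) - (
        k * ent_s - k1 * _class_entropy(left) - k2 * _class_entropy(right)
    )
    if gain <= (np.log2(n - 1.0) + delta) / n:
        return
    cuts.append(cut)
    _mdl_split(v[:pos], yy[:pos], classes, cuts)
    _mdl_split(v[pos:], yy[pos:], classes, cuts)


def discretize_supervised(values: np.ndarray, labels: np.ndarray) -> DiscretizedGene:
    """Fayyad-Irani MDL discretization of one gene's expression values.

    Recursive binary splitting minimizing class entropy, with each split
    accepted only if its information gain beats the MDL coding cost; if no
    split is accepted the gene collapses to a single bin.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if len(values) < 2:
        raise ValueError("need at least 2 samples to discretize")
    classes = np.unique(labels)
    cuts: list[float] = []
    _mdl_split(values, labels, classes, cuts)
    cuts.sort()
    bins = np.searchsorted(cuts, values, side="left")
    return DiscretizedGene(bins, cuts)


def contingency_table(disc: DiscretizedGene, labels: np.ndarray) -> ContingencyTable:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    counts = np.zeros((disc.n_bins, len(classes)))
    for j, c in enumerate(classes):
        counts[:, j] = np.bincount(disc.bins[labels == c], minlength=disc.n_bins)
    return ContingencyTable(counts)


# ---------------------------------------------------------------------------
# Table-based filters
# ---------------------------------------------------------------------------

def entropy(probabilities: np.ndarray) -> float:
    """Shannon entropy in bits of a probability vector (0 log 0 = 0)."""
    p = np.asarray(probabilities, dtype=float)
    if (p < 0).any():
        raise ValueError("negative probability")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities sum to {p.sum()}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def chi2_score(table: ContingencyTable) -> float:
    """Pearson chi-square statistic of the bin x class table.

    Cells with expected count 0 (structural zeros) contribute nothing.
    """
    n = table.total
    if n < 1:
        raise ValueError("empty table")
    expected = np.outer(table.bin_marginals, table.class_marginals) / n
    mask = expected > 0
    obs = table.counts[mask]
    exp = expected[mask]
    return float(((obs - exp) ** 2 / exp).sum())


def info_gain(table: ContingencyTable) -> float:
    """Mutual information between bin and class in bits:
    ``H(class) - sum_v P(g=v) H(class | g=v)``."""
    n = table.total
    if n < 1:
        raise ValueError("empty table")
    h_class = _class_entropy(table.class_marginals)
    cond = 0.0
    for v in range(table.counts.shape[0]):
        nv = table.bin_marginals[v]
        if nv > 0:
            cond += (nv / n) * _class_entropy(table.counts[v])
    return max(0.0, h_class - cond)


def gain_ratio(table: ContingencyTable) -> float:
    """Information gain normalized by the split information
    ``-sum_v (|S_v|/|S|) log2(|S_v|/|S|)``; defined as 0 for a single bin."""
    split_info = _class_entropy(table.bin_marginals)
    if split_info == 0:
        return 0.0
    return info_gain(table) / split_info


def symmetrical_uncertainty(table: ContingencyTable) -> float:
    """``2 (H(class) - H(class|g)) / (H(class) + H(g))`` in [0, 1];
    0 when both marginal entropies vanish."""
    h_class = _class_entropy(table.class_marginals)
    h_gene = _class_entropy(table.bin_marginals)
    if h_class + h_gene == 0:
        return 0.0
    return 2.0 * info_gain(table) / (h_class + h_gene)


# ---------------------------------------------------------------------------
# ReliefF
# ---------------------------------------------------------------------------

def _relieff_neighbors(
    ds: ExpressionDataset, k_neighbors: int
) -> tuple[list[tuple[int, np.ndarray, list[tuple[float, np.ndarray]]]], set]:
    """Per sample: (index, k nearest hits, [(class weight, k nearest misses)]).

    Neighbours are found once by Euclidean distance over all genes (self
    excluded, ties broken by lowest sample index) — the search does not
    depend on which gene is being scored.
    """
    X = ds.values.T
    y = ds.labels
    n = len(y)
    classes, counts = np.unique(y, return_counts=True)
    priors = dict(zip(classes, counts / n))
    small = {c for c, cnt in zip(classes, counts) if cnt < 2}
    if small:
        log.warning("relieff: classes %s have a single member; skipped", small)

    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)

    out = []
    for i in range(n):
        if y[i] in small:
            continue
        same = np.where(y == y[i])[0]
        same = same[same != i]
        hits = same[np.argsort(d2[i, same], kind="stable")][:k_neighbors]
        denom = 1.0 - priors[y[i]]
        misses = []
        for c in classes:
            if c == y[i] or c in small:
                continue
            others = np.where(y == c)[0]
            mk = others[np.argsort(d2[i, others], kind="stable")][:k_neighbors]
            misses.append((priors[c] / denom, mk))
        out.append((i, hits, misses))
    return out, small


def relieff_scores_all(
    ds: ExpressionDataset,
    sample_count: int | None = None,
    seed: int = 0,
    k_neighbors: int = 1,
) -> np.ndarray:
    """ReliefF weight of every gene over [0, 1]-normalized expression.

    For each probed sample the nearest same-class hit and nearest
    different-class miss are found by Euclidean distance over all genes;
    each gene's weight accumulates ``diff(miss) - diff(hit)`` where ``diff``
    is the absolute value difference on that gene, and is divided by the
    number of probes, which bounds W in [-1, 1] for [0, 1]-scaled data.
    With more than two classes the miss term is averaged over the opposing
    classes weighted by their priors ``P(c) / (1 - P(class of probe))``; the
    two-class case reduces to the plain miss-minus-hit form.

    ``sample_count=None`` probes every sample (deterministic);
    ``k_neighbors > 1`` averages over the k nearest hits/misses.
    """
    neighbors, _small = _relieff_neighbors(ds, k_neighbors)
    X = ds.values.T
    n = len(ds.labels)
    if sample_count is None or sample_count >= len(neighbors):
        probes = {i for i, _, _ in neighbors}
    else:
        rng = np.random.default_rng(seed)
        eligible = np.array([i for i, _, _ in neighbors])
        probes = set(rng.choice(eligible, size=sample_count, replace=False))

    w = np.zeros(ds.n_genes)
    used = 0
    for i, hits, misses in neighbors:
        if i not in probes:
            continue
        hit_diff = np.abs(X[hits] - X[i]).mean(axis=0)
        miss_diff = np.zeros(ds.n_genes)
        for weight, mk in misses:
            miss_diff += weight * np.abs(X[mk] - X[i]).mean(axis=0)
        w += miss_diff - hit_diff
        used += 1
    return w / used if used else w


def relieff_score(
    ds: ExpressionDataset,
    gene: int,
    sample_count: int | None = None,
    seed: int = 0,
    k_neighbors: int = 1,
) -> float:
    """ReliefF weight of a single gene; see :func:`relieff_scores_all`."""
    return float(
        relieff_scores_all(ds, sample_count=sample_count, seed=seed,
                           k_neighbors=k_neighbors)[gene]
    )


# ---------------------------------------------------------------------------
# Batch scoring
# ---------------------------------------------------------------------------

def score_all_filters(
    ds: ExpressionDataset,
    filter_set: tuple[str, ...] = FILTER_NAMES,
    seed: int = 0,
    relieff_sample_count: int | None = None,
) -> FilterScoreTable:
    """Raw score per (gene, filter).

    The four discrete-valued filters share one MDL discretization per gene;
    ReliefF runs on the continuous matrix with all samples probed by
    default (deterministic).
    """
    if not filter_set:
        raise ValueError("empty filter set")
    unknown = set(filter_set) - set(FILTER_NAMES)
    if unknown:
        raise ValueError(f"unknown filter(s): {sorted(unknown)}")

    cols: dict[str, np.ndarray] = {name: np.zeros(ds.n_genes) for name in filter_set}
    discrete = [f for f in filter_set if f != "relieff"]
    if discrete:
        fns = {
            "chi2": chi2_score,
            "su": symmetrical_uncertainty,
            "infogain": info_gain,
            "gainratio": gain_ratio,
        }
        for g in range(ds.n_genes):
            disc = discretize_supervised(ds.values[g], ds.labels)
            table = contingency_table(disc, ds.labels)
            for f in discrete:
                cols[f][g] = fns[f](table)
    if "relieff" in filter_set:
        cols["relieff"] = relieff_scores_all(
            ds, sample_count=relieff_sample_count, seed=seed
        )
    raw = pd.DataFrame({f: cols[f] for f in filter_set}, index=ds.gene_ids)
    return FilterScoreTable(raw)
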