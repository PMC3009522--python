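"""Expression-dataset container, delimited-text I/O, and the preprocessing /
double cross-validation protocol.

The preprocessing pipeline is fixed in this order:

1. per-gene standardization (mean 0, variance 1; population convention),
2. per-gene min-max normalization into [0, 1],
3. external stratified k-fold split,
4. BSS/WSS ranking computed on external-train samples only,
5. pre-filter to the top-k ranked genes (default 200),
6. internal stratified k-fold split of each external training set.

External test samples are never consulted for ranking, pre-filtering or any
downstream gene-selection step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

log = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "CVPlan",
    "LoadError",
    "read_expression_table",
    "write_expression_table",
    "standardize_genes",
    "normalize_genes",
    "stratified_kfold",
    "bss_wss_scores",
    "prefilter_top_k",
    "build_cv_plan",
]


class LoadError(ValueError):
    """Raised when a delimited expression table fails validation."""


@dataclass
class ExpressionDataset:
    """A genes x samples continuous expression matrix with class labels.

    Parameters
    ----------
    gene_ids
        Unique identifier per gene (row).
    values
        Array of shape ``(n_genes, n_samples)``.
    sample_ids
        Unique identifier per sample (column).
    labels
        One categorical class per sample; at least two classes, each with
        at least two members (required by stratified 3-fold CV and by the
        per-class sensitivity in balanced accuracy).
    """

    gene_ids: list[str]
    values: np.ndarray
    sample_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples matrix")
        n_genes, n_samples = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} value rows"
            )
        if len(self.sample_ids) != n_samples or len(self.labels) != n_samples:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids / {len(self.labels)} labels "
                f"for {n_samples} value columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            dupes = pd.Index(self.gene_ids)
            raise LoadError(
                "duplicate gene ids: "
                + ", ".join(sorted(dupes[dupes.duplicated()].unique()[:5]))
            )
        if len(set(self.sample_ids)) != n_samples:
            raise LoadError("duplicate sample ids")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise LoadError(
                f"non-finite expression value at gene {self.gene_ids[bad[0]]}, "
                f"sample {self.sample_ids[bad[1]]}"
            )
        classes, counts = np.unique(self.labels, return_counts=True)
        if len(classes) < 2:
            raise ValueError("dataset must contain at least 2 classes")
        if counts.min() < 2:
            small = classes[counts.argmin()]
            raise ValueError(f"class {small!r} has fewer than 2 samples")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def samples_by_genes(self) -> np.ndarray:
        """Transposed view (samples x genes) for scikit-learn estimators."""
        return self.values.T

    def subset_genes(self, indices: np.ndarray | list[int]) -> "ExpressionDataset":
        idx = np.asarray(indices, dtype=int)
        return ExpressionDataset(
            [self.gene_ids[i] for i in idx],
            self.values[idx],
            list(self.sample_ids),
            self.labels.copy(),
        )

    def subset_samples(self, indices: np.ndarray | list[int]) -> "ExpressionDataset":
        idx = np.asarray(indices, dtype=int)
        return ExpressionDataset(
            list(self.gene_ids),
            self.values[:, idx],
            [self.sample_ids[i] for i in idx],
            self.labels[idx],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionDataset):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.labels, other.labels)
            and np.allclose(self.values, other.values, atol=1e-12)
        )


@dataclass
class CVPlan:
    """Nested (double) cross-validation plan over one dataset.

    ``external_folds[i]`` is a ``(train, test)`` pair of absolute sample
    indices; ``internal_folds[i]`` is the list of ``(train, test)`` pairs of
    absolute indices drawn from ``external_folds[i][0]`` only, so external
    test samples never enter any internal split.
    """

    external_folds: list[tuple[np.ndarray, np.ndarray]]
    internal_folds: list[list[tuple[np.ndarray, np.ndarray]]]
    fold_count: int = 3
    seed: int = 0
    internal_fold_count: int = field(default=3)

    def validate(self, n_samples: int) -> None:
        all_idx = np.arange(n_samples)
        for (tr, te), inner in zip(self.external_folds, self.internal_folds):
            assert np.array_equal(np.sort(np.concatenate([tr, te])), all_idx)
            assert not set(tr) & set(te)
            for itr, ite in inner:
                assert not set(ite) & set(te), "external test leaked into internal split"
                assert not set(itr) & set(te), "external test leaked into internal split"
                assert set(itr) | set(ite) == set(tr)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

LABEL_ROW = "class"


def _sniff_sep(path: Path) -> str:
    first = path.open().readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_expression_table(
    path: str | Path,
    label_row: str = LABEL_ROW,
    labels_path: str | Path | None = None,
) -> ExpressionDataset:
    """Read a delimited genes x samples table.

    Layout: first column gene ids, header row sample ids.  Class labels come
    either from the row whose id equals ``label_row`` (default ``"class"``)
    or from a two-column ``sample<sep>label`` file given as ``labels_path``.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    sample_ids = [str(c) for c in df.columns]

    if labels_path is not None:
        lab = pd.read_csv(Path(labels_path), sep=_sniff_sep(Path(labels_path)),
                          header=None, index_col=0, dtype=str)
        missing = [s for s in sample_ids if s not in lab.index]
        if missing:
            raise LoadError(f"labels file missing samples: {missing[:5]}")
        labels = lab.iloc[:, 0].reindex(sample_ids).to_numpy()
    else:
        if label_row not in df.index:
            raise LoadError(f"no label row {label_row!r} in {path.name}")
        labels = df.loc[label_row].to_numpy()
        df = df.drop(index=label_row)
    labels = np.asarray([str(v) for v in labels])
    if pd.isna(labels).any() or (labels == "nan").any():
        bad = [sample_ids[i] for i in np.where(labels == "nan")[0]]
        raise LoadError(f"missing class label for samples {bad[:5]}")

    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        for gid, row in df.iterrows():
            for sid, cell in row.items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise LoadError(
                        f"non-numeric cell at gene {gid}, sample {sid}: {cell!r}"
                    ) from exc
        raise LoadError(str(exc)) from exc
    if np.isnan(values).any():
        g, s = np.argwhere(np.isnan(values))[0]
        raise LoadError(
            f"missing value at gene {df.index[g]}, sample {sample_ids[s]}"
        )
    return ExpressionDataset(list(df.index), values, sample_ids, labels)


def write_expression_table(ds: ExpressionDataset, path: str | Path, sep: str = "\t") -> None:
    """Write in the same dialect :func:`read_expression_table` accepts."""
    path = Path(path)
    df = pd.DataFrame(ds.values, index=ds.gene_ids, columns=ds.sample_ids)
    with path.open("w") as fh:
        fh.write(sep.join(["gene_id", *ds.sample_ids]) + "\n")
        fh.write(sep.join([LABEL_ROW, *map(str, ds.labels)]) + "\n")
        df.to_csv(fh, sep=sep, header=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def standardize_genes(ds: ExpressionDataset) -> ExpressionDataset:
    """Scale each gene row to mean 0 and variance 1 (population convention).

    Constant rows have undefined variance; they are mapped to all-zeros and
    a warning is logged.
    """
    mu = ds.values.mean(axis=1, keepdims=True)
    sd = ds.values.std(axis=1, keepdims=True)  # population: ddof=0
    const = sd[:, 0] == 0
    if const.any():
        log.warning(
            "standardize_genes: %d constant gene row(s) mapped to zeros", const.sum()
        )
    safe_sd = np.where(sd == 0, 1.0, sd)
    out = (ds.values - mu) / safe_sd
    out[const] = 0.0
    return ExpressionDataset(list(ds.gene_ids), out, list(ds.sample_ids), ds.labels.copy())


def normalize_genes(ds: ExpressionDataset) -> ExpressionDataset:
    """Min-max rescale each gene row into [0, 1]; constant rows map to 0.5."""
    lo = ds.values.min(axis=1, keepdims=True)
    hi = ds.values.max(axis=1, keepdims=True)
    span = hi - lo
    const = span[:, 0] == 0
    safe = np.where(span == 0, 1.0, span)
    out = (ds.values - lo) / safe
    out[const] = 0.5
    return ExpressionDataset(list(ds.gene_ids), out, list(ds.sample_ids), ds.labels.copy())


def stratified_kfold(
    labels: np.ndarray, k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified k-fold split; returns ``(train, test)`` index pairs.

    If the smallest class has fewer than ``k`` members, ``k`` is reduced to
    that count (with a warning) so stratification stays feasible.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        log.warning(
            "stratified_kfold: reducing k from %d to smallest class size %d",
            k, counts.min(),
        )
        k = int(counts.min())
        if k < 2:
            raise ValueError("smallest class has < 2 members; cannot split")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**32))
    return [
        (np.asarray(tr), np.asarray(te))
        for tr, te in skf.split(np.zeros(len(labels)), labels)
    ]


def bss_wss_scores(ds: ExpressionDataset) -> np.ndarray:
    """Between-group / within-group sum-of-squares ratio per gene.

    For gene j, ``BSS_j = sum_c N_c (xbar_cj - xbar_j)^2`` and
    ``WSS_j = sum_c sum_{i in c} (x_ij - xbar_cj)^2``.  A perfect separator
    (WSS 0, BSS > 0) returns ``+inf`` so it ranks first; a constant gene
    (0/0) returns 0 so it ranks last.
    """
    classes = ds.classes
    if len(classes) < 2:
        raise ValueError("BSS/WSS requires >= 2 classes")
    grand = ds.values.mean(axis=1)
    bss = np.zeros(ds.n_genes)
    wss = np.zeros(ds.n_genes)
    for c in classes:
        mask = ds.labels == c
        xc = ds.values[:, mask]
        mc = xc.mean(axis=1)
        bss += mask.sum() * (mc - grand) ** 2
        wss += ((xc - mc[:, None]) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = bss / wss
    ratio[(wss == 0) & (bss > 0)] = np.inf
    ratio[(wss == 0) & (bss == 0)] = 0.0
    # numerically-constant genes can give 0/0 -> nan through float fuzz
    ratio[np.isnan(ratio)] = 0.0
    return ratio


def prefilter_top_k(
    ds: ExpressionDataset, scores: np.ndarray, k: int
) -> ExpressionDataset:
    """Keep the k highest-scoring genes, preserving original gene order.

    Ties are broken by original gene order (stable sort), so repeated runs
    retain the same genes.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > ds.n_genes:
        raise ValueError(f"k={k} exceeds gene count {ds.n_genes}")
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    keep = np.sort(order[:k])
    return ds.subset_genes(keep)


def build_cv_plan(
    ds: ExpressionDataset, k_external: int = 3, k_internal: int = 3, seed: int = 0
) -> CVPlan:
    """External stratified k-fold plus, per external fold, an internal
    stratified k-fold over that fold's training samples only."""
    ext = stratified_kfold(ds.labels, k_external, seed)
    internal: list[list[tuple[np.ndarray, np.ndarray]]] = []
    for i, (tr, _te) in enumerate(ext):
        inner = stratified_kfold(ds.labels[tr], k_internal, seed + 1000 * (i + 1))
        internal.append([(tr[itr], tr[ite]) for itr, ite in inner])
    plan = CVPlan(ext, internal, fold_count=k_external, seed=seed,
                  internal_fold_count=k_internal)
    plan.validate(ds.n_samples)
    return plan
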