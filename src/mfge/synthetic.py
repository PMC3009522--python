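"""Synthetic expression-data generator with planted informative genes.

Emulates the regime the selection system is built for: many more genes than
samples, a handful of genes whose class-conditional means differ, and the
rest pure class-independent noise.  Ground truth (which genes are
informative) is returned alongside the matrix so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ExpressionDataset

__all__ = ["SyntheticSpec", "generate", "generate_multiclass"]


@dataclass
class SyntheticSpec:
    """Generative law for a planted-gene expression matrix.

    Parameters
    ----------
    n_genes
        Total genes (default 200, the size of a pre-filtered candidate set).
    class_sizes
        Samples per class; default 25/25 binary.  ``(24, 20, 28)`` mirrors a
        three-class leukemia-subtype composition.
    n_informative
        Genes whose class means are shifted (default 10).
    effect_size
        Class-mean shift of informative genes, in noise-sd units
        (default 1.5).
    noise
        ``"gaussian"`` (default) or ``"t"`` for heavy-tailed Student-t noise
        with ``t_df`` degrees of freedom (robustness checks).
    rho
        Optional equicorrelation among the informative genes' noise
        (redundant-gene scenario); 0 disables.
    """

    n_genes: int = 200
    class_sizes: tuple[int, ...] = (25, 25)
    n_informative: int = 10
    effect_size: float = 1.5
    noise: str = "gaussian"
    t_df: float = 3.0
    rho: float = 0.0
    seed: int = 0
    class_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.n_informative > self.n_genes:
            raise ValueError("n_informative exceeds n_genes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        if len(self.class_sizes) < 2:
            raise ValueError("need at least 2 classes")
        if any(s < 2 for s in self.class_sizes):
            raise ValueError("every class needs >= 2 samples")
        if self.noise not in ("gaussian", "t"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if not self.class_names:
            self.class_names = tuple(f"C{i + 1}" for i in range(len(self.class_sizes)))
        elif len(self.class_names) != len(self.class_sizes):
            raise ValueError("class_names / class_sizes length mismatch")


def generate(spec: SyntheticSpec) -> tuple[ExpressionDataset, set[str]]:
    """Draw one dataset from ``spec``; returns ``(dataset, informative ids)``.

    Each informative gene has exactly one class shifted by ``effect_size``
    (classes assigned round-robin across the informative genes), so every
    informative gene separates at least one class pair; null genes are iid
    noise.  Deterministic per ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_samples = sum(spec.class_sizes)
    m = len(spec.class_sizes)
    labels = np.repeat(spec.class_names, spec.class_sizes)

    if spec.noise == "t":
        raw = rng.standard_t(spec.t_df, size=(spec.n_genes, n_samples))
        raw /= np.sqrt(spec.t_df / (spec.t_df - 2))  # unit variance
    else:
        raw = rng.standard_normal((spec.n_genes, n_samples))

    gene_pos = rng.permutation(spec.n_genes)[: spec.n_informative]
    if spec.rho > 0 and spec.n_informative:
        shared = rng.standard_normal(n_samples)
        raw[gene_pos] = (
            np.sqrt(spec.rho) * shared + np.sqrt(1 - spec.rho) * raw[gene_pos]
        )

    for j, g in enumerate(sorted(gene_pos)):
        up_class = spec.class_names[j % m]
        raw[g, labels == up_class] += spec.effect_size

    width = len(str(spec.n_genes))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(spec.n_genes)]
    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    ds = ExpressionDataset(gene_ids, raw, sample_ids, labels)
    truth = {gene_ids[g] for g in gene_pos}
    return ds, truth


def generate_multiclass(spec: SyntheticSpec) -> tuple[ExpressionDataset, set[str]]:
    """Multi-class alias of :func:`generate` (same law; m comes from
    ``spec.class_sizes``, e.g. ``(24, 20, 28)`` for a 3-class task)."""
    return generate(spec)
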