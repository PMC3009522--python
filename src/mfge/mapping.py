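"""Multi-filter score fusion and the gene frequency map.

Raw filter scores live on incommensurate scales (a chi-square statistic, a
ReliefF weight in [-1, 1], entropies in bits ...), so each filter's score
vector is squashed into (0, 1) by softmax scaling — standardize across
genes, then apply the logistic — before the per-gene scores are summed,
multiplied by 10 and rounded (half-up) to an integer, floored at 1 so no
candidate gene is ever excluded.  The integer score becomes the gene's
multiplicity in a multiset "gene frequency map"; sampling genes from that
pool during GA initialization and mutation biases the search toward
filter-favoured genes in proportion to their fused score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "FilterScoreTable",
    "GeneFrequencyMap",
    "PoolExhaustedError",
    "softmax_scale",
    "combine_scores",
    "build_frequency_map",
    "draw_gene",
]


def softmax_scale(scores: np.ndarray) -> np.ndarray:
    """Squash one filter's raw score vector into (0, 1).

    ``v = (s - mean(s)) / std(s)`` (population std across genes), then the
    logistic ``1 / (1 + exp(-v))``.  Order-preserving; a score at the vector
    mean maps to exactly 0.5.  A zero-variance vector carries no ranking
    information: every entry maps to 0.5 and a warning is logged.
    """
    s = np.asarray(scores, dtype=float)
    if s.size < 2:
        raise ValueError("softmax scaling needs at least 2 scores")
    finite = np.isfinite(s)
    if not finite.all():
        # +inf raw scores (perfect separators) dominate: pin them to the max
        # finite transformed value rather than poisoning the mean/std.
        cap = s[finite].max() if finite.any() else 0.0
        s = np.where(finite, s, cap)
        log.warning("softmax_scale: %d non-finite score(s) capped", (~finite).sum())
    sd = s.std()
    if sd == 0:
        log.warning("softmax_scale: zero-variance score vector; all mapped to 0.5")
        return np.full_like(s, 0.5)
    v = (s - s.mean()) / sd
    return 1.0 / (1.0 + np.exp(-v))


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(int)


@dataclass
class FilterScoreTable:
    """Per-gene raw and scaled scores for each filter, plus fused totals.

    ``raw`` is a genes x filters DataFrame; ``scaled``, ``total`` and
    ``integer`` are populated by :func:`combine_scores`.
    """

    raw: pd.DataFrame
    scaled: pd.DataFrame | None = None
    total: pd.Series | None = None
    integer: pd.Series | None = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.raw.index)

    @property
    def filters(self) -> list[str]:
        return list(self.raw.columns)

    def to_csv(self, path: str | Path, sep: str = "\t") -> None:
        df = self.raw.add_prefix("raw_")
        if self.scaled is not None:
            df = df.join(self.scaled.add_prefix("scaled_"))
            df["total"] = self.total
            df["integer"] = self.integer
        df.to_csv(path, sep=sep, index_label="gene_id", float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path, sep: str = "\t") -> "FilterScoreTable":
        df = pd.read_csv(path, sep=sep, index_col="gene_id")
        raw = df[[c for c in df.columns if c.startswith("raw_")]]
        raw.columns = [c[4:] for c in raw.columns]
        table = cls(raw)
        if "integer" in df.columns:
            scaled = df[[c for c in df.columns if c.startswith("scaled_")]]
            scaled.columns = [c[7:] for c in scaled.columns]
            table.scaled = scaled
            table.total = df["total"]
            table.integer = df["integer"].astype(int)
        return table


def combine_scores(table: FilterScoreTable) -> FilterScoreTable:
    """Fuse raw filter scores into totals and integer scores (in place).

    Per filter, raw scores are softmax-scaled across genes; per gene the
    scaled scores are summed, multiplied by 10 and rounded half-up; results
    below 1 are floored to 1 so every candidate stays in the pool.
    """
    scaled = pd.DataFrame(
        {f: softmax_scale(table.raw[f].to_numpy()) for f in table.filters},
        index=table.raw.index,
    )
    total = scaled.sum(axis=1)
    integer = pd.Series(
        np.maximum(1, _round_half_up(10.0 * total.to_numpy())),
        index=table.raw.index,
    )
    table.scaled, table.total, table.integer = scaled, total, integer
    return table


class PoolExhaustedError(RuntimeError):
    """Every gene in the frequency map is excluded from the draw."""


@dataclass
class GeneFrequencyMap:
    """Multiset of gene codes in which gene g appears integer_score(g) times.

    Genes are handled as 1-based integer codes (0 is the GA's empty-slot
    marker); ``gene_ids[code - 1]`` recovers the identifier.
    """

    gene_ids: list[str]
    multiplicities: np.ndarray
    seed: int = 0
    pool: np.ndarray = field(init=False)
    rng: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.multiplicities = np.asarray(self.multiplicities, dtype=int)
        if len(self.multiplicities) != len(self.gene_ids):
            raise ValueError("one multiplicity per gene id required")
        if (self.multiplicities < 1).any():
            raise ValueError("every candidate gene must appear at least once")
        codes = np.arange(1, len(self.gene_ids) + 1)
        self.pool = np.repeat(codes, self.multiplicities)
        self.rng = np.random.default_rng(self.seed)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def reseed(self, seed: int) -> None:
        self.rng = np.random.default_rng(seed)

    def id_of(self, code: int) -> str:
        return self.gene_ids[code - 1]


def build_frequency_map(table: FilterScoreTable, seed: int = 0) -> GeneFrequencyMap:
    """Materialize the frequency map from a combined score table."""
    if table.integer is None:
        table = combine_scores(table)
    if len(table.gene_ids) == 0:
        raise ValueError("empty score table")
    return GeneFrequencyMap(table.gene_ids, table.integer.to_numpy(), seed=seed)


def uniform_frequency_map(gene_ids: list[str], seed: int = 0) -> GeneFrequencyMap:
    """A map with multiplicity 1 for every gene: the unenhanced-GA baseline."""
    if not gene_ids:
        raise ValueError("empty gene list")
    return GeneFrequencyMap(list(gene_ids), np.ones(len(gene_ids), dtype=int), seed=seed)


def draw_gene(
    fmap: GeneFrequencyMap,
    exclude: frozenset[int] | set[int] = frozenset(),
    rng: np.random.Generator | None = None,
) -> int:
    """Draw one gene code from the pool uniformly, rejecting excluded codes.

    The induced distribution over allowed genes stays proportional to the
    integer scores.  Raises :class:`PoolExhaustedError` when every gene is
    excluded.
    """
    rng = rng if rng is not None else fmap.rng
    pool = fmap.pool
    if not exclude:
        return int(pool[rng.integers(len(pool))])
    # rejection sampling; small exclusion sets terminate fast
    for _ in range(32):
        code = int(pool[rng.integers(len(pool))])
        if code not in exclude:
            return code
    allowed = pool[~np.isin(pool, list(exclude))]
    if len(allowed) == 0:
        raise PoolExhaustedError("all genes excluded from the frequency map")
    return int(allowed[rng.integers(len(allowed))])
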