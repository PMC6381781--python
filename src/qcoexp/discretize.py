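"""Rank-based qualitative discretization of expression profiles.

Each gene's continuous profile over n conditions is mapped to integer
levels in {-r..-1, 0, +1..+r}: the lowest r*ceil(q*n) values take negative
levels and the highest r*ceil(q*n) take positive levels, each side split
into r rank chunks of ceil(q*n) with the most extreme chunk at level +-r;
everything else is 0. The representation is invariant under any strictly
increasing transform of the values, which is what makes the downstream
matching score robust to the scale of normalized microarray data.

Ties at the quantile cut are resolved conservatively: a condition receives
a non-zero level only if its value is strictly beyond the first interior
order statistic, so a constant profile discretizes to all zeros and tied
runs never spill extra conditions into the extreme set. Within the extreme
set, rank chunks are assigned in stable (value, condition-order) order so
the output is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, ValidationError

__all__ = [
    "DiscretizationParams",
    "DiscretizedMatrix",
    "discretize_gene",
    "discretize_matrix",
    "write_discretized_matrix",
    "read_discretized_matrix",
]


@dataclass(frozen=True)
class DiscretizationParams:
    """Quantile fraction ``q`` and number of non-zero ranks per sign ``r``.

    ``q`` is the fraction of conditions called responsive at each extreme
    per rank (default 0.06, the cited biclustering algorithm's default for
    microarray data); ``r`` is the number of non-zero levels per sign
    (default 1). ``max_missing`` bounds the tolerated per-gene fraction of
    missing conditions.
    """

    q: float = 0.06
    r: int = 1
    max_missing: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 < self.q < 0.5:
            raise ValidationError(f"q must be in (0, 0.5), got {self.q}")
        if self.r < 1 or int(self.r) != self.r:
            raise ValidationError(f"r must be a positive integer, got {self.r}")
        if 2.0 * self.r * self.q > 1.0:
            raise ValidationError(
                f"2*r*q = {2 * self.r * self.q:g} > 1: extremes would cover "
                "more than the whole profile"
            )
        if not 0.0 <= self.max_missing < 1.0:
            raise ValidationError(f"max_missing must be in [0, 1), got {self.max_missing}")

    def chunk_size(self, n_conditions: int) -> int:
        """Conditions per rank chunk at each extreme: ceil(q*n)."""
        return math.ceil(self.q * n_conditions)


@dataclass(frozen=True)
class DiscretizedMatrix:
    """Integer level matrix (genes x conditions) plus the params that made it."""

    levels: pd.DataFrame
    params: DiscretizationParams

    @property
    def gene_ids(self) -> list[str]:
        return list(self.levels.index)

    @property
    def condition_ids(self) -> list[str]:
        return list(self.levels.columns)

    @property
    def n_conditions(self) -> int:
        return self.levels.shape[1]

    def row(self, gene_id: str) -> np.ndarray:
        return self.levels.loc[gene_id].to_numpy(dtype=np.int64)


def discretize_gene(values: np.ndarray, params: DiscretizationParams) -> np.ndarray:
    """Map one gene's profile to integer levels in {-r..+r}.

    Missing values (NaN) are excluded from ranking and receive level 0; a
    missing fraction above ``params.max_missing`` is an error.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValidationError("expected a 1-D profile")
    if v.size < 2:
        raise ValidationError(f"profile has {v.size} conditions; need >= 2")
    missing = np.isnan(v)
    if missing.mean() > params.max_missing:
        raise ValidationError(
            f"missing fraction {missing.mean():.2f} exceeds {params.max_missing}"
        )
    finite_idx = np.flatnonzero(~missing)
    n = finite_idx.size
    levels = np.zeros(v.size, dtype=np.int64)
    if n < 2:
        return levels
    m = params.chunk_size(n)
    k = params.r * m
    if 2 * k > n:
        raise ValidationError(
            f"2*r*ceil(q*n) = {2 * k} exceeds the {n} observed conditions"
        )
    vals = v[finite_idx]
    # stable ascending order; ties keep original condition order
    asc = finite_idx[np.argsort(vals, kind="stable")]
    sorted_vals = v[asc]
    lo_cut = sorted_vals[k]          # first interior value from below
    hi_cut = sorted_vals[n - k - 1]  # first interior value from above
    low = [i for i in asc[:k] if v[i] < lo_cut]
    high = [i for i in asc[n - k:][::-1] if v[i] > hi_cut]
    for pos, i in enumerate(low):
        levels[i] = -(params.r - pos // m)
    for pos, i in enumerate(high):
        levels[i] = params.r - pos // m
    return levels


def discretize_matrix(m: ExpressionMatrix, params: DiscretizationParams) -> DiscretizedMatrix:
    """Discretize every gene row of an expression matrix."""
    rows = []
    for gene in m.gene_ids:
        try:
            rows.append(discretize_gene(m.row(gene), params))
        except ValidationError as exc:
            raise ValidationError(f"gene {gene!r}: {exc}") from None
    levels = pd.DataFrame(
        np.vstack(rows), index=m.values.index, columns=m.values.columns, dtype=np.int64
    )
    return DiscretizedMatrix(levels=levels, params=params)


def write_discretized_matrix(d: DiscretizedMatrix, path) -> None:
    df = d.levels.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_discretized_matrix(path, params: DiscretizationParams) -> DiscretizedMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return DiscretizedMatrix(levels=df.astype(np.int64), params=params)
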