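"""Functional-bin over-representation testing.

For a gene set against a background, each functional bin is tested with a
one-sided (over-representation) Fisher exact test — the hypergeometric
upper tail of the 2x2 table — and p-values are corrected across bins with
the Benjamini-Hochberg step-up, flagging bins at FDR <= 0.1 by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import FunctionalBinMap, ValidationError

logger = logging.getLogger("qcoexp")

__all__ = ["EnrichmentResult", "fisher_enrichment", "bh_adjust"]


@dataclass(frozen=True)
class EnrichmentResult:
    """One bin's contingency counts and (adjusted) significance.

    ``k`` of the ``n`` set genes fall in the bin, ``K`` of the ``N``
    background genes do.
    """

    bin_label: str
    k: int
    K: int
    n: int
    N: int
    odds_ratio: float
    p: float
    q: float
    significant: bool

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n) and max(self.K, self.n) <= self.N):
            raise ValidationError(
                f"inconsistent contingency counts for {self.bin_label!r}: "
                f"k={self.k}, K={self.K}, n={self.n}, N={self.N}"
            )


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted values, in input order.

    ``q_(i) = min_{j >= i} m * p_(j) / j`` capped at 1; the output
    preserves the ordering of the input p-values.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in q]


def fisher_enrichment(
    gene_set: Iterable[str],
    background: Iterable[str],
    bins: FunctionalBinMap,
    fdr_threshold: float = 0.1,
) -> list[EnrichmentResult]:
    """Test every functional bin for over-representation in ``gene_set``.

    The gene set must be a subset of the background; the bin map is
    restricted to the background, and bins with no background gene are
    skipped with a log entry. Results are sorted by ascending p then bin
    label. A gene belonging to several bins counts once in each.
    """
    gene_set = set(gene_set)
    background = set(background)
    if len(background) < 2:
        raise ValidationError("background must contain at least 2 genes")
    stray = gene_set - background
    if stray:
        raise ValidationError(
            f"{len(stray)} gene(s) of the set are not in the background, "
            f"e.g. {sorted(stray)[:3]}"
        )
    if not 0.0 <= fdr_threshold <= 1.0:
        raise ValidationError(f"fdr_threshold must be in [0, 1], got {fdr_threshold}")
    restricted = bins.restrict(background)
    N, n = len(background), len(gene_set)
    tested: list[tuple[str, int, int]] = []
    for bin_label in sorted(restricted.bin_labels()):
        in_bin = restricted.genes_in_bin(bin_label)
        K = len(in_bin)
        if K == 0:
            logger.info("bin %r has no background gene; skipped", bin_label)
            continue
        k = len(in_bin & gene_set)
        tested.append((bin_label, k, K))
    if not tested:
        return []
    pvals = [float(stats.hypergeom.sf(k - 1, N, K, n)) for _, k, K in tested]
    qvals = bh_adjust(pvals)
    results = []
    for (bin_label, k, K), p, q in zip(tested, pvals, qvals):
        table = [[k, n - k], [K - k, N - K - (n - k)]]
        odds_ratio = stats.fisher_exact(table, alternative="greater")[0]
        results.append(
            EnrichmentResult(
                bin_label=bin_label,
                k=k,
                K=K,
                n=n,
                N=N,
                odds_ratio=float(odds_ratio),
                p=p,
                q=q,
                significant=q <= fdr_threshold,
            )
        )
    return sorted(results, key=lambda r: (r.p, r.bin_label))
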