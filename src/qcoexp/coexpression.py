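"""Bait-seeded qualitative co-expression scoring.

The pairwise score (the BF value) between two discretized profiles is the
number of conditions in which they occupy the *same non-zero* level —
the edge weight of a qualitative-biclustering seed graph. Because only
rank-extreme conditions are non-zero, a high BF identifies a pair whose
strong responses coincide on some condition subset, whether that subset is
all conditions or a to-be-identified fraction of them.

Significance is assessed against a condition-permutation null: the partner
profile is repeatedly permuted across conditions (margins preserved) and
the observed BF compared with the permuted scores. Two tail estimators are
provided:

``conservative``
    the add-one-smoothed upper tail ``(1 + #{BF* >= bf}) / (1 + B)``,
    which is valid but conservative because BF is a small discrete count;
``randomized``
    the classical randomized (exact-style) p-value
    ``(#{BF* > bf} + U * (1 + #{BF* = bf})) / (1 + B)`` with ``U`` drawn
    from the pair's own deterministic RNG stream. This estimator is
    uniform under the null, so edge-calling at level alpha realizes a
    false-positive rate of alpha even though BF takes few distinct values.
    It is the screening default.

All permutation randomness derives from a single user seed: the stream for
a pair is seeded by (seed, hash(bait), hash(partner)), so screens are
reproducible and insensitive to gene ordering.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .discretize import DiscretizedMatrix, DiscretizationParams, discretize_matrix
from .io import BaitSet, ExpressionMatrix, ValidationError

logger = logging.getLogger("qcoexp")

__all__ = [
    "ScreenParams",
    "CoexpressionEdge",
    "bf_score",
    "bf_null_pvalue",
    "expected_null_bf",
    "screen_baits",
    "condition_support_module",
    "pearson_score",
    "compare_methods",
]

SignMode = Literal["same-sign-only", "allow-opposite"]
TieBreak = Literal["conservative", "randomized"]


@dataclass(frozen=True)
class ScreenParams:
    """Edge-calling parameters for a bait screen.

    ``min_bf`` is an absolute floor on the matched-condition count;
    ``alpha`` the level applied to the permutation p-value; ``tie_break``
    selects the tail estimator (see module docstring). ``rng_seed`` governs
    every permutation stream.
    """

    sign_mode: SignMode = "same-sign-only"
    min_bf: int = 0
    alpha: float = 0.01
    n_permutations: int = 1000
    rng_seed: int = 0
    tie_break: TieBreak = "randomized"
    consistency: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.min_bf < 0:
            raise ValidationError(f"min_bf must be >= 0, got {self.min_bf}")
        if self.n_permutations <= 0:
            raise ValidationError("n_permutations must be positive")
        if self.n_permutations < 100:
            warnings.warn(
                f"n_permutations = {self.n_permutations} < 100 gives a coarse "
                "p-value grid",
                stacklevel=2,
            )
        if self.sign_mode not in ("same-sign-only", "allow-opposite"):
            raise ValidationError(f"unknown sign_mode {self.sign_mode!r}")
        if self.tie_break not in ("conservative", "randomized"):
            raise ValidationError(f"unknown tie_break {self.tie_break!r}")
        if not 0.0 < self.consistency <= 1.0:
            raise ValidationError(f"consistency must be in (0, 1], got {self.consistency}")


@dataclass(frozen=True)
class CoexpressionEdge:
    """A called bait--partner co-expression relationship."""

    bait_id: str
    partner_id: str
    bf: int
    support: frozenset[str]
    sign: int
    pvalue: float

    def __post_init__(self) -> None:
        if self.bf != len(self.support):
            raise ValidationError(
                f"bf = {self.bf} but |support| = {len(self.support)} "
                f"for ({self.bait_id}, {self.partner_id})"
            )
        if self.sign not in (-1, 1):
            raise ValidationError(f"sign must be +-1, got {self.sign}")


# ---------------------------------------------------------------------------
# the score
# ---------------------------------------------------------------------------


def bf_score(
    a: np.ndarray,
    b: np.ndarray,
    sign_mode: SignMode = "same-sign-only",
) -> tuple[int, np.ndarray, int]:
    """Matched-condition count between two level vectors.

    Returns ``(bf, support_positions, sign)``. In same-sign mode only
    identical non-zero levels match and sign is +1. Under allow-opposite,
    exactly opposite non-zero levels also match and the reported sign is
    that of the majority match type (+1 on ties).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError(f"level vectors differ in shape: {a.shape} vs {b.shape}")
    same = (a == b) & (a != 0)
    if sign_mode == "same-sign-only":
        support = np.flatnonzero(same)
        return int(same.sum()), support, 1
    if sign_mode != "allow-opposite":
        raise ValidationError(f"unknown sign_mode {sign_mode!r}")
    opp = (a == -b) & (a != 0)
    n_same, n_opp = int(same.sum()), int(opp.sum())
    support = np.flatnonzero(same | opp)
    return n_same + n_opp, support, 1 if n_same >= n_opp else -1


def _match_counts(a: np.ndarray, B: np.ndarray, sign_mode: SignMode) -> np.ndarray:
    """BF of ``a`` against each row of a 2-D level array ``B``."""
    nz = a != 0
    counts = ((B == a) & nz).sum(axis=1)
    if sign_mode == "allow-opposite":
        counts = counts + ((B == -a) & nz).sum(axis=1)
    return counts


def _pair_rng(seed: int, bait_id: str, partner_id: str) -> np.random.Generator:
    """Deterministic per-pair RNG stream derived from (seed, bait, partner)."""
    def h(s: str) -> int:
        return int.from_bytes(hashlib.blake2b(s.encode(), digest_size=4).digest(), "big")

    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, h(bait_id), h(partner_id)])
    )


def bf_null_pvalue(
    bf: int,
    a: np.ndarray,
    b: np.ndarray,
    params: ScreenParams,
    bait_id: str = "a",
    partner_id: str = "b",
    tie_break: TieBreak | None = None,
) -> float:
    """Permutation-null upper-tail p for an observed BF.

    ``b`` is permuted across conditions ``params.n_permutations`` times;
    see the module docstring for the two tail estimators. Deterministic
    for a fixed ``params.rng_seed`` and pair of IDs.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValidationError("level vectors differ in shape")
    mode = tie_break if tie_break is not None else params.tie_break
    rng = _pair_rng(params.rng_seed, bait_id, partner_id)
    nperm = params.n_permutations
    perms = rng.permuted(np.broadcast_to(b, (nperm, b.size)).copy(), axis=1)
    null = _match_counts(a, perms, params.sign_mode)
    if mode == "conservative":
        return float((1 + int((null >= bf).sum())) / (1 + nperm))
    n_gt = int((null > bf).sum())
    n_eq = int((null == bf).sum())
    u = rng.random()
    return float((n_gt + u * (1 + n_eq)) / (1 + nperm))


def expected_null_bf(a: np.ndarray, b: np.ndarray, sign_mode: SignMode = "same-sign-only") -> float:
    """Closed-form permutation-null mean BF: sum_k n_k(a) * n_k(b) / n.

    ``k`` runs over non-zero levels (and their negations under
    allow-opposite).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    n = a.size
    out = 0.0
    for k in np.unique(a[a != 0]):
        out += (a == k).sum() * (b == k).sum() / n
        if sign_mode == "allow-opposite":
            out += (a == k).sum() * (b == -k).sum() / n
    return float(out)


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------


def screen_baits(
    d: DiscretizedMatrix,
    baits: BaitSet,
    params: ScreenParams,
) -> list[CoexpressionEdge]:
    """Score every (bait, other gene) pair and call edges.

    An edge is emitted iff ``bf >= params.min_bf`` and the permutation p is
    ``<= params.alpha``. Baits missing from the matrix are reported and
    skipped; if none are present this is an error. Edges are returned
    grouped by bait (in bait order), descending BF, then partner ID.
    """
    present = [b for b in baits if b in d.levels.index]
    missing = [b for b in baits if b not in d.levels.index]
    for b in missing:
        logger.warning("bait %r absent from the matrix; skipped", b)
    if not present:
        raise ValidationError(f"no bait of {baits.label!r} is present in the matrix")
    if params.min_bf > d.n_conditions:
        logger.warning(
            "min_bf = %d exceeds the %d conditions; no edge can be called",
            params.min_bf,
            d.n_conditions,
        )

    levels = d.levels.to_numpy(dtype=np.int64)
    gene_ids = d.gene_ids
    conditions = np.asarray(d.condition_ids, dtype=object)
    index_of = {g: i for i, g in enumerate(gene_ids)}

    edges: list[CoexpressionEdge] = []
    for bait in present:
        a = levels[index_of[bait]]
        counts = _match_counts(a, levels, params.sign_mode)
        bait_edges: list[CoexpressionEdge] = []
        for j, partner in enumerate(gene_ids):
            if partner == bait:
                continue
            bf = int(counts[j])
            if bf < params.min_bf:
                continue
            b_levels = levels[j]
            if bf == 0 and params.tie_break == "conservative":
                p = 1.0  # every permutation ties at >= 0
            else:
                p = bf_null_pvalue(bf, a, b_levels, params, bait, partner)
            if p > params.alpha:
                continue
            _, support_pos, sign = bf_score(a, b_levels, params.sign_mode)
            bait_edges.append(
                CoexpressionEdge(
                    bait_id=bait,
                    partner_id=partner,
                    bf=bf,
                    support=frozenset(conditions[support_pos]),
                    sign=sign,
                    pvalue=p,
                )
            )
        bait_edges.sort(key=lambda e: (-e.bf, e.partner_id))
        edges.extend(bait_edges)
    return edges


def condition_support_module(
    edges: Sequence[CoexpressionEdge],
    consistency: float = 0.95,
) -> list[tuple[frozenset[str], set[str]]]:
    """Group one bait's partners by maximal shared supporting conditions.

    Greedy: seed each group with the highest-BF unassigned edge, then add
    partners whose support overlaps at least ``consistency`` of the group's
    current condition set, shrinking the set to the running intersection.
    This makes the "to-be-identified" condition subset of each co-expressed
    module explicit. Returns ``(conditions, genes)`` per group.
    """
    if not edges:
        raise ValidationError("no edges to group")
    bait_ids = {e.bait_id for e in edges}
    if len(bait_ids) != 1:
        raise ValidationError(f"edges span several baits: {sorted(bait_ids)}")
    remaining = sorted(edges, key=lambda e: (-e.bf, e.partner_id))
    groups: list[tuple[frozenset[str], set[str]]] = []
    while remaining:
        seed = remaining.pop(0)
        conditions = set(seed.support)
        genes = {seed.partner_id}
        rest: list[CoexpressionEdge] = []
        for e in remaining:
            if conditions and len(set(e.support) & conditions) >= consistency * len(conditions):
                conditions &= set(e.support)
                genes.add(e.partner_id)
            else:
                rest.append(e)
        remaining = rest
        groups.append((frozenset(conditions), genes))
    return groups


# ---------------------------------------------------------------------------
# the Pearson comparator
# ---------------------------------------------------------------------------


def pearson_score(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation of two profiles (error on zero variance)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(f"profiles differ in shape: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValidationError(f"need >= 3 conditions, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for a zero-variance profile")
    return float(stats.pearsonr(x, y).statistic)


def compare_methods(
    m: ExpressionMatrix,
    bait: str,
    dparams: DiscretizationParams | None = None,
    sparams: ScreenParams | None = None,
    d: DiscretizedMatrix | None = None,
) -> pd.DataFrame:
    """Per-gene two-method table for one bait: BF, its permutation p, PCC.

    Genes with zero variance get NaN in the ``pcc`` column. The bait itself
    is excluded. Pass a precomputed ``d`` to avoid re-discretizing.
    """
    if bait not in m.values.index:
        raise ValidationError(f"bait {bait!r} absent from the matrix")
    dparams = dparams or DiscretizationParams()
    sparams = sparams or ScreenParams()
    if d is None:
        d = discretize_matrix(m, dparams)
    a = d.row(bait)
    x = m.row(bait)
    rows = []
    for gene in m.gene_ids:
        if gene == bait:
            continue
        b = d.row(gene)
        bf, _, _ = bf_score(a, b, sparams.sign_mode)
        p = bf_null_pvalue(bf, a, b, sparams, bait, gene)
        y = m.row(gene)
        try:
            pcc = pearson_score(x, y)
        except ValidationError:
            pcc = float("nan")
        rows.append((gene, bf, p, pcc))
    return pd.DataFrame(rows, columns=["gene_id", "bf", "bf_p", "pcc"]).set_index("gene_id")
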