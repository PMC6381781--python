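"""Cross-species homolog mapping and network overlay.

Protein-homology hits (BLAST tabular) connect the genes of two species'
co-expression networks. After threshold filtering, pairs are kept either
per-query best hit (lowest e-value, the shape that yields many-to-one
summaries such as "522 switchgrass TFs correspond to 202 Arabidopsis
TFs"), reciprocally-best, or all passing hits. The overlay step then asks,
for every homolog pair, how similar the two genes' bait neighborhoods are
(Jaccard under a bait-correspondence table), labelling genes conserved,
divergent, or species-specific.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import pandas as pd

from .io import BlastHit, ValidationError
from .network import CoexpressionNetwork

__all__ = ["OrthologMap", "map_homologs", "overlay_networks"]

HitMode = Literal["best-hit", "all-pass", "reciprocal-best"]


@dataclass(frozen=True)
class OrthologMap:
    """Homolog pairs (species A gene, species B gene) with supporting hits."""

    pairs: tuple[tuple[str, str], ...]
    hits: tuple[BlastHit, ...]
    max_evalue: float
    min_identity: float
    mode: str

    def a_genes(self) -> set[str]:
        return {a for a, _ in self.pairs}

    def b_genes(self) -> set[str]:
        return {b for _, b in self.pairs}

    def partners_of_a(self, gene: str) -> set[str]:
        return {b for a, b in self.pairs if a == gene}

    def partners_of_b(self, gene: str) -> set[str]:
        return {a for a, b in self.pairs if b == gene}

    def summary(self) -> tuple[int, int]:
        """(distinct A genes mapped, distinct B genes mapped)."""
        return len(self.a_genes()), len(self.b_genes())

    def transposed(self) -> "OrthologMap":
        return OrthologMap(
            pairs=tuple((b, a) for a, b in self.pairs),
            hits=self.hits,
            max_evalue=self.max_evalue,
            min_identity=self.min_identity,
            mode=self.mode,
        )

    def __len__(self) -> int:
        return len(self.pairs)


def _best_per_query(hits: Sequence[BlastHit]) -> dict[str, BlastHit]:
    """Lowest e-value per query; ties by higher bitscore then subject ID."""
    best: dict[str, BlastHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or (h.evalue, -h.bitscore, h.subject_id) < (
            cur.evalue, -cur.bitscore, cur.subject_id
        ):
            best[h.query_id] = h
    return best


def map_homologs(
    hits: Sequence[BlastHit],
    genes_a: set[str],
    genes_b: set[str],
    max_evalue: float = 1e-10,
    min_identity: float = 0.0,
    mode: HitMode = "best-hit",
) -> OrthologMap:
    """Build an ortholog map from hits of species-A queries vs species-B subjects.

    Hits are restricted to ``genes_a x genes_b`` and to the thresholds.
    ``best-hit`` keeps one subject per query; ``reciprocal-best``
    additionally requires the query to be the best A-side hit of that
    subject; ``all-pass`` keeps every passing hit.
    """
    if max_evalue < 0:
        raise ValidationError(f"max_evalue must be >= 0, got {max_evalue}")
    if not 0.0 <= min_identity <= 100.0:
        raise ValidationError(f"min_identity must be in [0, 100], got {min_identity}")
    passing = [
        h
        for h in hits
        if h.query_id in genes_a
        and h.subject_id in genes_b
        and h.evalue <= max_evalue
        and h.percent_identity >= min_identity
    ]
    if mode == "all-pass":
        kept = passing
    elif mode == "best-hit":
        kept = list(_best_per_query(passing).values())
    elif mode == "reciprocal-best":
        fwd = _best_per_query(passing)
        # best A-side query per subject, same tie-break on the mirrored key
        back: dict[str, BlastHit] = {}
        for h in passing:
            cur = back.get(h.subject_id)
            if cur is None or (h.evalue, -h.bitscore, h.query_id) < (
                cur.evalue, -cur.bitscore, cur.query_id
            ):
                back[h.subject_id] = h
        kept = [
            h
            for q, h in fwd.items()
            if back.get(h.subject_id) is not None and back[h.subject_id].query_id == q
        ]
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    kept = sorted(kept, key=lambda h: (h.query_id, h.subject_id, h.evalue))
    pairs = tuple(dict.fromkeys((h.query_id, h.subject_id) for h in kept))
    return OrthologMap(
        pairs=pairs,
        hits=tuple(kept),
        max_evalue=max_evalue,
        min_identity=min_identity,
        mode=mode,
    )


def overlay_networks(
    net_a: CoexpressionNetwork,
    net_b: CoexpressionNetwork,
    ortho: OrthologMap,
    bait_map: Mapping[str, str],
    min_jaccard: float = 0.5,
) -> pd.DataFrame:
    """Per-gene conservation table across two species' networks.

    ``bait_map`` gives the bait correspondence (species-A bait -> species-B
    bait); it must cover every bait of network A that is to be compared.
    For each homolog pair the Jaccard overlap of bait-neighbor sets is
    computed after translating B baits into the A namespace. Non-bait
    genes of network A are labelled ``conserved`` (some homolog pair
    reaches ``min_jaccard``), ``divergent`` (homologs present but below),
    or ``species-specific`` (no homolog in network B — the "triangle"
    symbol of comparative network figures).
    """
    if not bait_map:
        raise ValidationError("bait correspondence table is required")
    inv_bait = {b: a for a, b in bait_map.items()}
    baits_a = net_a.baits
    baits_b = net_b.baits

    def bait_neighbors_a(gene: str) -> frozenset[str]:
        return frozenset(n for n in net_a.graph.neighbors(gene) if n in baits_a)

    def bait_neighbors_b(gene: str) -> frozenset[str]:
        return frozenset(
            inv_bait[n]
            for n in net_b.graph.neighbors(gene)
            if n in baits_b and n in inv_bait
        )

    rows = []
    for gene in sorted(set(net_a.graph.nodes) - baits_a):
        homologs = sorted(ortho.partners_of_a(gene) & set(net_b.graph.nodes))
        na = bait_neighbors_a(gene)
        if not homologs:
            rows.append(
                {
                    "gene_id": gene,
                    "homologs": "",
                    "best_jaccard": float("nan"),
                    "label": "species-specific",
                }
            )
            continue
        jaccards = []
        for h in homologs:
            nb = bait_neighbors_b(h)
            union = na | nb
            jaccards.append(len(na & nb) / len(union) if union else 0.0)
        best = max(jaccards)
        rows.append(
            {
                "gene_id": gene,
                "homologs": ",".join(homologs),
                "best_jaccard": best,
                "label": "conserved" if best >= min_jaccard else "divergent",
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "homologs", "best_jaccard", "label"]
    ).set_index("gene_id")
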