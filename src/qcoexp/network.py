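"""Assembly, annotation, extension and export of co-expression networks.

A network is an undirected annotated graph over bait and partner genes.
Construction can be restricted to transcription-factor partners (the
screen's usual downstream focus), extended by screening further bait sets
(bait-bait edges are flagged for Figure-style rendering), intersected with
differential-expression lists, summarized as a TF-family distribution or a
per-TF candidate ranking, and exported for Cytoscape (SIF + attribute
tables), GraphML, or a lossless edge TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .coexpression import CoexpressionEdge, ScreenParams, screen_baits
from .discretize import DiscretizedMatrix
from .io import BaitSet, DEGeneList, GeneAnnotation, ValidationError

logger = logging.getLogger("qcoexp")

__all__ = [
    "CoexpressionNetwork",
    "build_network",
    "family_distribution",
    "extend_network",
    "intersect_with_de",
    "rank_tf_candidates",
    "collapse_edges_to_genes",
    "export_network",
    "read_edge_tsv",
]

EXPORT_FORMATS = ("sif", "graphml", "edge-tsv")


@dataclass
class CoexpressionNetwork:
    """An annotated co-expression graph plus its provenance record."""

    graph: nx.Graph
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.provenance:
            raise ValidationError("a network must carry a non-empty provenance record")
        for u, v in self.graph.edges:
            if u == v:
                raise ValidationError(f"self-loop at {u!r}")

    @property
    def baits(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("is_bait")}

    def edge_list(self) -> list[CoexpressionEdge]:
        """Edges as CoexpressionEdge records (bait endpoint first)."""
        out = []
        for u, v, d in self.graph.edges(data=True):
            bait, partner = (u, v) if self.graph.nodes[u].get("is_bait") else (v, u)
            out.append(
                CoexpressionEdge(
                    bait_id=bait,
                    partner_id=partner,
                    bf=d["bf"],
                    support=d["support"],
                    sign=d["sign"],
                    pvalue=d["pvalue"],
                )
            )
        return sorted(out, key=lambda e: (e.bait_id, -e.bf, e.partner_id))

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def _annotate_node(
    g: nx.Graph, gene: str, annotations: Mapping[str, GeneAnnotation], is_bait: bool
) -> None:
    a = annotations.get(gene)
    g.add_node(
        gene,
        tf_family=a.tf_family if a else None,
        species=a.species if a else None,
        display_name=a.display_name if a else None,
        is_bait=bool(is_bait) or bool(g.nodes.get(gene, {}).get("is_bait")),
    )


def build_network(
    edges: Sequence[CoexpressionEdge],
    annotations: Mapping[str, GeneAnnotation] | None = None,
    tf_only: bool = False,
    provenance: dict | None = None,
) -> CoexpressionNetwork:
    """Assemble called edges into an annotated graph.

    With ``tf_only``, partners lacking a TF-family annotation are dropped
    (baits are always retained). If both orientations of a pair occur the
    higher-BF record wins.
    """
    annotations = annotations or {}
    baits = {e.bait_id for e in edges}
    g = nx.Graph()
    kept = 0
    for b in baits:
        _annotate_node(g, b, annotations, is_bait=True)
    for e in edges:
        if e.bait_id == e.partner_id:
            continue
        ann = annotations.get(e.partner_id)
        is_partner_bait = e.partner_id in baits
        if tf_only and not is_partner_bait and (ann is None or not ann.is_tf):
            continue
        _annotate_node(g, e.partner_id, annotations, is_bait=is_partner_bait)
        prev = g.get_edge_data(e.bait_id, e.partner_id)
        if prev is not None and prev["bf"] >= e.bf:
            continue
        g.add_edge(
            e.bait_id,
            e.partner_id,
            bf=e.bf,
            pvalue=e.pvalue,
            sign=e.sign,
            support=frozenset(e.support),
            bait_bait=is_partner_bait,
        )
        kept += 1
    if provenance is None:
        provenance = {"source": "build_network"}
    net = CoexpressionNetwork(graph=g, provenance=dict(provenance))
    logger.info("built network: %d nodes, %d edges (%d records kept)", net.n_nodes(), net.n_edges(), kept)
    return net


def family_distribution(net: CoexpressionNetwork) -> dict[str, int]:
    """Distinct TF nodes per family, in descending count (then name) order."""
    counts: dict[str, int] = {}
    for _, d in net.graph.nodes(data=True):
        fam = d.get("tf_family")
        if fam:
            counts[fam] = counts.get(fam, 0) + 1
    return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))


def extend_network(
    net: CoexpressionNetwork,
    new_baits: BaitSet,
    d: DiscretizedMatrix,
    params: ScreenParams,
    annotations: Mapping[str, GeneAnnotation] | None = None,
    tf_only: bool = False,
) -> CoexpressionNetwork:
    """Screen additional baits and union the result into the network.

    Edges between two baits (old or new) are flagged ``bait_bait``.
    Re-adding baits that are already in the network is a no-op
    (idempotent), and extension order does not matter for a fixed seed.
    """
    new_edges = screen_baits(d, new_baits, params)
    combined = net.edge_list() + new_edges
    all_baits = net.baits | set(new_baits.bait_ids)
    g = nx.Graph()
    merged_ann = dict(_node_annotations(net))
    merged_ann.update(annotations or {})
    for b in sorted(all_baits):
        _annotate_node(g, b, merged_ann, is_bait=True)
    for e in sorted(combined, key=lambda e: (e.bait_id, -e.bf, e.partner_id)):
        if e.partner_id == e.bait_id:
            continue
        ann = merged_ann.get(e.partner_id)
        is_partner_bait = e.partner_id in all_baits
        if tf_only and not is_partner_bait and (ann is None or not ann.is_tf):
            continue
        _annotate_node(g, e.partner_id, merged_ann, is_bait=is_partner_bait)
        prev = g.get_edge_data(e.bait_id, e.partner_id)
        if prev is not None and prev["bf"] >= e.bf:
            continue
        g.add_edge(
            e.bait_id,
            e.partner_id,
            bf=e.bf,
            pvalue=e.pvalue,
            sign=e.sign,
            support=frozenset(e.support),
            bait_bait=is_partner_bait,
        )
    prov = dict(net.provenance)
    extended = sorted(set(prov.get("extended_with", [])) | set(new_baits.bait_ids))
    prov["extended_with"] = extended
    return CoexpressionNetwork(graph=g, provenance=prov)


def _node_annotations(net: CoexpressionNetwork) -> dict[str, GeneAnnotation]:
    out = {}
    for n, d in net.graph.nodes(data=True):
        out[n] = GeneAnnotation(
            gene_id=n,
            tf_family=d.get("tf_family"),
            species=d.get("species"),
            display_name=d.get("display_name"),
        )
    return out


def intersect_with_de(
    net: CoexpressionNetwork,
    bait: str,
    de_lists: Sequence[DEGeneList],
) -> tuple[set[str], pd.DataFrame]:
    """Neighbors of ``bait`` present in every DE list.

    Returns the gene set and a per-gene report with the edge BF and the
    DE direction in each contrast.
    """
    if bait not in net.graph:
        raise ValidationError(f"bait {bait!r} is not in the network")
    if not de_lists:
        raise ValidationError("need at least one DE list")
    neighbors = set(net.graph.neighbors(bait))
    result = neighbors.copy()
    for de in de_lists:
        result &= set(de.gene_ids)
    rows = []
    for gene in sorted(result):
        row = {"gene_id": gene, "bf": net.graph.edges[bait, gene]["bf"]}
        for de in de_lists:
            row[f"direction_{de.label}"] = (de.direction or {}).get(gene, "")
        rows.append(row)
    report = pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame(
        columns=["bf"] + [f"direction_{de.label}" for de in de_lists]
    )
    return result, report


def rank_tf_candidates(net: CoexpressionNetwork) -> pd.DataFrame:
    """Rank non-bait TF partners by bait-neighbor count, then max BF.

    This is a report, not a filter: candidate selection on "number of
    correlated genes and strength of correlation" is left to the analyst.
    """
    baits = net.baits
    rows = []
    for n, d in net.graph.nodes(data=True):
        if n in baits or not d.get("tf_family"):
            continue
        bait_neighbors = [b for b in net.graph.neighbors(n) if b in baits]
        if not bait_neighbors:
            continue
        rows.append(
            {
                "gene_id": n,
                "tf_family": d["tf_family"],
                "n_bait_neighbors": len(bait_neighbors),
                "max_bf": max(net.graph.edges[n, b]["bf"] for b in bait_neighbors),
            }
        )
    df = pd.DataFrame(rows, columns=["gene_id", "tf_family", "n_bait_neighbors", "max_bf"])
    return df.sort_values(
        ["n_bait_neighbors", "max_bf", "gene_id"], ascending=[False, False, True]
    ).set_index("gene_id")


def collapse_edges_to_genes(
    edges: Sequence[CoexpressionEdge],
    probe_map: Mapping[str, str],
) -> list[CoexpressionEdge]:
    """Collapse probe-level edges to gene level, keeping the max-BF probe.

    IDs absent from the map are treated as already gene-level. Ties in BF
    are broken by lower p-value then probe ID, so the result is
    deterministic.
    """
    best: dict[tuple[str, str], CoexpressionEdge] = {}
    for e in sorted(edges, key=lambda e: (-e.bf, e.pvalue, e.bait_id, e.partner_id)):
        key = (probe_map.get(e.bait_id, e.bait_id), probe_map.get(e.partner_id, e.partner_id))
        if key[0] == key[1]:
            continue
        if key not in best:
            best[key] = CoexpressionEdge(
                bait_id=key[0],
                partner_id=key[1],
                bf=e.bf,
                support=e.support,
                sign=e.sign,
                pvalue=e.pvalue,
            )
    return sorted(best.values(), key=lambda e: (e.bait_id, -e.bf, e.partner_id))


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------


def export_network(net: CoexpressionNetwork, fmt: str, out_prefix: str | Path) -> list[Path]:
    """Write the network for external viewers; returns the paths written.

    ``sif`` writes Cytoscape SIF (one ``bait<TAB>coexp<TAB>partner`` line
    per edge) plus node- and edge-attribute TSVs; ``graphml`` a single
    GraphML file; ``edge-tsv`` a lossless single-table export readable by
    :func:`read_edge_tsv`.
    """
    if net.n_edges() == 0:
        raise ValidationError("refusing to export an empty network")
    if fmt not in EXPORT_FORMATS:
        raise ValidationError(f"unknown export format {fmt!r}; choose from {EXPORT_FORMATS}")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    edges = net.edge_list()
    written: list[Path] = []

    if fmt == "edge-tsv":
        path = out_prefix.with_suffix(".edges.tsv")
        with open(path, "w") as fh:
            fh.write("bait\tpartner\tbf\tsign\tpvalue\tsupport\n")
            for e in edges:
                fh.write(
                    f"{e.bait_id}\t{e.partner_id}\t{e.bf}\t{e.sign}\t"
                    f"{e.pvalue:.17g}\t{','.join(sorted(e.support))}\n"
                )
        written.append(path)
    elif fmt == "sif":
        sif = out_prefix.with_suffix(".sif")
        with open(sif, "w") as fh:
            for e in edges:
                fh.write(f"{e.bait_id}\tcoexp\t{e.partner_id}\n")
        nodes = out_prefix.with_suffix(".nodes.tsv")
        with open(nodes, "w") as fh:
            fh.write("gene_id\ttf_family\tspecies\tis_bait\n")
            for n in sorted(net.graph.nodes):
                d = net.graph.nodes[n]
                fh.write(
                    f"{n}\t{d.get('tf_family') or '-'}\t{d.get('species') or ''}\t"
                    f"{int(bool(d.get('is_bait')))}\n"
                )
        eattr = out_prefix.with_suffix(".edge_attrs.tsv")
        with open(eattr, "w") as fh:
            fh.write("bait\tpartner\tbf\tpvalue\tsign\tbait_bait\n")
            for e in edges:
                bb = int(bool(net.graph.edges[e.bait_id, e.partner_id].get("bait_bait")))
                fh.write(f"{e.bait_id}\t{e.partner_id}\t{e.bf}\t{e.pvalue:.17g}\t{e.sign}\t{bb}\n")
        written += [sif, nodes, eattr]
    else:  # graphml
        path = out_prefix.with_suffix(".graphml")
        g = nx.Graph()
        for n, d in net.graph.nodes(data=True):
            g.add_node(
                n,
                tf_family=d.get("tf_family") or "",
                species=d.get("species") or "",
                is_bait=int(bool(d.get("is_bait"))),
            )
        for u, v, d in net.graph.edges(data=True):
            g.add_edge(
                u, v,
                bf=int(d["bf"]),
                pvalue=float(d["pvalue"]),
                sign=int(d["sign"]),
                support=",".join(sorted(d["support"])),
            )
        nx.write_graphml(g, path)
        written.append(path)
    return written


def read_edge_tsv(path: str | Path) -> list[CoexpressionEdge]:
    """Read edges written by ``export_network(..., fmt='edge-tsv')``."""
    path = Path(path)
    edges = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["bait", "partner", "bf", "sign", "pvalue", "support"]:
            raise ValidationError(f"{path}: unexpected edge-tsv header {header}")
        for line in fh:
            bait, partner, bf, sign, pvalue, support = line.rstrip("\n").split("\t")
            edges.append(
                CoexpressionEdge(
                    bait_id=bait,
                    partner_id=partner,
                    bf=int(bf),
                    sign=int(sign),
                    pvalue=float(pvalue),
                    support=frozenset(support.split(",")) if support else frozenset(),
                )
            )
    return edges
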