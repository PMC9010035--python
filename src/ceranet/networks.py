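"""lncRNA-mRNA pairing and PPI first-neighbor extension.

A DE lncRNA is linked to a DE mRNA by genomic relationship, evaluated in
priority order:

1. ``antisense_natural`` — opposite strand, >=1 bp of exon-exon overlap
   (a natural antisense transcript);
2. ``antisense_intronic`` — opposite strand, lncRNA span fully contained in
   one intron of the mRNA;
3. ``proximity`` — span-to-span gap at most ``window`` bases, on either
   strand;
4. none.

The resulting bipartite network is extended with the first PPI neighbors of
its mRNA nodes, keeping every PPI edge inside the induced subgraph on
seeds plus neighbors (so neighbor-neighbor edges are retained).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import networkx as nx

from .annotation import AnnotationSet, GeneAnnotation
from .specificity import FeatureSet

logger = logging.getLogger(__name__)

NODE_TYPES = ("lncRNA", "mRNA", "protein", "miRNA")
EDGE_TYPES = (
    "antisense_natural",
    "antisense_intronic",
    "proximity",
    "ppi",
    "seed_match",
    "cerna",
)

ANTISENSE_CLASSES = ("antisense_natural", "antisense_intronic", "proximity")


class NetworkError(ValueError):
    pass


@dataclass
class TypedNetwork:
    """Undirected network with typed nodes and typed edges.

    Thin wrapper over :class:`networkx.Graph` enforcing the invariants:
    known node/edge types, no self-loops, no duplicate undirected edges with
    conflicting types.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    def add_node(self, node_id: str, node_type: str) -> None:
        if node_type not in NODE_TYPES:
            raise NetworkError(f"unknown node type {node_type!r}")
        existing = self.graph.nodes.get(node_id)
        if existing is not None and existing.get("type") not in (None, node_type):
            raise NetworkError(
                f"node {node_id!r} already typed {existing['type']!r}, got {node_type!r}"
            )
        self.graph.add_node(node_id, type=node_type)

    def add_edge(self, a: str, b: str, edge_type: str, **attrs) -> None:
        if edge_type not in EDGE_TYPES:
            raise NetworkError(f"unknown edge type {edge_type!r}")
        if a == b:
            raise NetworkError(f"self-loop on {a!r}")
        if a not in self.graph or b not in self.graph:
            raise NetworkError(f"edge endpoints must be added first: {a!r}-{b!r}")
        if self.graph.has_edge(a, b):
            if self.graph.edges[a, b].get("type") != edge_type:
                raise NetworkError(
                    f"duplicate edge {a!r}-{b!r} with conflicting type"
                )
            return
        self.graph.add_edge(a, b, type=edge_type, **attrs)

    def nodes_of_type(self, node_type: str) -> List[str]:
        return [n for n, t in self.graph.nodes(data="type") if t == node_type]

    def edges_of_type(self, edge_type: str) -> List[Tuple[str, str]]:
        return [(a, b) for a, b, t in self.graph.edges(data="type") if t == edge_type]

    def node_type(self, node_id: str) -> str:
        return self.graph.nodes[node_id]["type"]

    def edge_type_counts(self) -> Dict[str, int]:
        counts: Dict[str, int] = {}
        for _, _, t in self.graph.edges(data="type"):
            counts[t] = counts.get(t, 0) + 1
        return counts

    def copy(self) -> "TypedNetwork":
        return TypedNetwork(graph=self.graph.copy())

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def _exon_overlap(a: GeneAnnotation, b: GeneAnnotation) -> bool:
    for s1, e1 in a.exons:
        for s2, e2 in b.exons:
            if max(s1, s2) < min(e1, e2):
                return True
    return False


def _span_gap(a: GeneAnnotation, b: GeneAnnotation) -> int:
    gap = max(a.start, b.start) - min(a.end, b.end)
    return max(gap, 0)


def classify_antisense_pair(
    lnc: GeneAnnotation, mrna: GeneAnnotation, window: int
) -> str | None:
    """Classify the genomic relationship of a lncRNA-mRNA pair.

    Returns one of ``antisense_natural``, ``antisense_intronic``,
    ``proximity`` or ``None``, evaluated in that priority order.
    """
    if lnc.chrom != mrna.chrom:
        return None
    if lnc.strand != mrna.strand:
        if _exon_overlap(lnc, mrna):
            return "antisense_natural"
        for istart, iend in mrna.introns():
            if lnc.start >= istart and lnc.end <= iend:
                return "antisense_intronic"
    if _span_gap(lnc, mrna) <= window:
        return "proximity"
    return None


def build_lnc_mrna_network(
    de_lnc: FeatureSet,
    de_mrna: FeatureSet,
    annotation: AnnotationSet,
    window: int = 10_000,
) -> TypedNetwork:
    """Pair DE lncRNAs with DE mRNAs by antisense/proximity relationship.

    Nodes are the DE features participating in at least one classified pair;
    isolated features are excluded.  Unresolvable ids are skipped with a
    warning.
    """
    net = TypedNetwork()
    lnc_genes = []
    for fid in sorted(de_lnc.members):
        g = annotation.get(fid)
        if g is None:
            logger.warning("lncRNA %s not found in annotation; skipped", fid)
            continue
        lnc_genes.append(g)
    mrna_genes = []
    for fid in sorted(de_mrna.members):
        g = annotation.get(fid)
        if g is None:
            logger.warning("mRNA %s not found in annotation; skipped", fid)
            continue
        mrna_genes.append(g)
    for lnc in lnc_genes:
        for mrna in mrna_genes:
            cls = classify_antisense_pair(lnc, mrna, window)
            if cls is None:
                continue
            net.add_node(lnc.gene_id, "lncRNA")
            net.add_node(mrna.gene_id, "mRNA")
            net.add_edge(lnc.gene_id, mrna.gene_id, cls)
    return net


def first_neighbor_extension(
    net: TypedNetwork, ppi: Iterable[Tuple[str, str]]
) -> TypedNetwork:
    """Extend with first PPI neighbors of the network's mRNA nodes.

    Seeds are the mRNA nodes; added nodes are their PPI neighbors (typed
    ``protein`` unless already present); added edges are every PPI edge whose
    endpoints both lie in seeds-union-neighbors.  Existing lncRNA edges are
    preserved unchanged.
    """
    ppi_graph = nx.Graph()
    for a, b in ppi:
        if a != b:
            ppi_graph.add_edge(a, b)
    out = net.copy()
    seeds = set(net.nodes_of_type("mRNA"))
    neighborhood = set(seeds)
    for s in seeds:
        if s in ppi_graph:
            neighborhood |= set(ppi_graph.neighbors(s))
    for node in sorted(neighborhood - set(out.graph.nodes)):
        out.add_node(node, "protein")
    for a, b in ppi_graph.edges():
        if a in neighborhood and b in neighborhood:
            out.add_edge(a, b, "ppi")
    return out
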