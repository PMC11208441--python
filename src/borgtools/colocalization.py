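"""Core-subfamily colocalization graph and core clusters.

Two core subfamilies are colocalized in a genome when some pair of their
member genes lies within ``window_genes`` positions in the genome's gene
order (minimum ordinal distance over member pairs, so extra copies never
break an edge). An edge is kept when that holds in at least ``min_genomes``
genomes; connected components of the resulting graph are the core clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx

from .pangenome import Subfamily

DEFAULT_WINDOW_GENES = 10
DEFAULT_MIN_GENOMES = 5


@dataclass
class CoreClusterGraph:
    nodes: list[str]
    edges: dict[tuple[str, str], int]          # (a, b) -> genome support
    graph: nx.Graph
    window_genes: int
    min_genomes: int


def build_colocalization_graph(core_subfams: list[Subfamily],
                               protein_positions: dict[str, tuple[str, int]],
                               window_genes: int = DEFAULT_WINDOW_GENES,
                               min_genomes: int = DEFAULT_MIN_GENOMES
                               ) -> CoreClusterGraph:
    """Build the colocalization graph over core subfamilies.

    ``protein_positions`` maps protein id -> (genome id, gene ordinal).
    """
    ordinals: dict[str, dict[str, list[int]]] = {}
    for sf in core_subfams:
        per_genome: dict[str, list[int]] = {}
        for pid in sf.members:
            if pid not in protein_positions:
                continue
            g, o = protein_positions[pid]
            per_genome.setdefault(g, []).append(o)
        if not per_genome:
            raise ValueError(f"subfamily {sf.id} has no placed member in any genome")
        ordinals[sf.id] = per_genome

    edges: dict[tuple[str, str], int] = {}
    for sa, sb in combinations(sorted(ordinals), 2):
        support = 0
        for g, oa in ordinals[sa].items():
            ob = ordinals[sb].get(g)
            if ob is None:
                continue
            dist = min(abs(x - y) for x in oa for y in ob)
            if dist <= window_genes:
                support += 1
        if support >= min_genomes:
            edges[(sa, sb)] = support

    graph = nx.Graph()
    graph.add_nodes_from(sorted(ordinals))
    for (a, b), sup in edges.items():
        graph.add_edge(a, b, support=sup)
    return CoreClusterGraph(nodes=sorted(ordinals), edges=edges, graph=graph,
                            window_genes=window_genes, min_genomes=min_genomes)


def extract_clusters(graph: CoreClusterGraph) -> tuple[list[list[str]], list[str]]:
    """Connected components of size >=2 (clusters) and isolated nodes."""
    comps = [sorted(c) for c in nx.connected_components(graph.graph)]
    clusters = sorted((c for c in comps if len(c) >= 2), key=lambda c: (-len(c), c))
    isolated = sorted(n for c in comps if len(c) == 1 for n in c)
    return clusters, isolated


__all__ = ["CoreClusterGraph", "build_colocalization_graph", "extract_clusters",
           "DEFAULT_WINDOW_GENES", "DEFAULT_MIN_GENOMES"]
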