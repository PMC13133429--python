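"""Protein-pair similarity network and community detection.

Chains related by a detected circular permutation or indel become nodes of
an undirected graph; each unordered pair keeps its best (max rearranged TM)
record as the edge weight, with CP/indel flags as edge labels.  Communities
come from Leiden clustering (seeded, resolution-parameterized) or from a
deterministic library-free connected-components fallback.  Edges are
unweighted for clustering by default; weights are kept for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .duplication import DuplicationResult


@dataclass
class PairGraph:
    nodes: list[str] = field(default_factory=list)
    # (id_a, id_b) sorted pair -> (weight, label)
    edges: dict[tuple[str, str], tuple[float, str]] = field(default_factory=dict)

    def edge_list(self) -> list[tuple[str, str, float, str]]:
        return [(a, b, w, lab) for (a, b), (w, lab) in sorted(self.edges.items())]


@dataclass
class Communities:
    membership: dict[str, int]
    sizes: list[int]  # sorted descending
    top10_fraction: float
    method: str


def _label(rec: DuplicationResult) -> str:
    if rec.is_cp and rec.is_indel:
        return "both"
    if rec.is_cp:
        return "cp"
    if rec.is_indel:
        return "indel"
    return "none"


def build_graph(records: list[DuplicationResult]) -> PairGraph:
    """One node per chain, one edge per pair keeping the max-TM record."""
    nodes: dict[str, None] = {}
    edges: dict[tuple[str, str], tuple[float, str]] = {}
    for rec in records:
        a, b = sorted((rec.query_id, rec.target_id))
        if a == b:
            continue
        nodes.setdefault(a)
        nodes.setdefault(b)
        w = rec.tm_rearranged
        if (a, b) not in edges or w > edges[(a, b)][0]:
            edges[(a, b)] = (w, _label(rec))
    return PairGraph(list(nodes), edges)


def _components(graph: PairGraph) -> dict[str, int]:
    adj: dict[str, list[str]] = {n: [] for n in graph.nodes}
    for a, b in graph.edges:
        adj[a].append(b)
        adj[b].append(a)
    membership: dict[str, int] = {}
    comp = 0
    for node in graph.nodes:  # insertion order: deterministic
        if node in membership:
            continue
        stack = [node]
        while stack:
            cur = stack.pop()
            if cur in membership:
                continue
            membership[cur] = comp
            stack.extend(sorted(adj[cur]))
        comp += 1
    return membership


def _leiden(graph: PairGraph, resolution: float, seed: int) -> dict[str, int]:
    import igraph as ig
    import leidenalg

    g = ig.Graph()
    g.add_vertices(graph.nodes)
    g.add_edges([(a, b) for a, b in graph.edges])
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    return {graph.nodes[i]: part.membership[i] for i in range(len(graph.nodes))}


def cluster_graph(
    graph: PairGraph,
    method: str = "leiden",
    resolution: float = 1.0,
    seed: int = 42,
) -> Communities:
    """Partition the pair graph into communities.

    Reports community sizes sorted descending and the fraction of members
    in the 10 largest communities (the skew statistic of CP families).
    """
    if not graph.nodes:
        raise ValueError("cannot cluster an empty graph")
    if method == "leiden":
        membership = _leiden(graph, resolution, seed)
    elif method == "components":
        membership = _components(graph)
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    counts: dict[int, int] = {}
    for c in membership.values():
        counts[c] = counts.get(c, 0) + 1
    sizes = sorted(counts.values(), reverse=True)
    top10 = sum(sizes[:10]) / sum(sizes)
    return Communities(membership, sizes, top10, method)
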