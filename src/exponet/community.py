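"""Iterative edge-betweenness community detection (Girvan-Newman).

At each iteration the single edge with the highest edge-betweenness
(ties broken lexicographically) is removed, betweenness is recomputed,
and the Newman-Girvan modularity of the current connected-component
partition is evaluated on the ORIGINAL graph:

    Q = sum_c ( e_c / m  -  (d_c / 2m)^2 )

with m the original edge count, e_c the original edges inside community
c, and d_c the sum of original degrees in c.  The partition maximizing
Q along the trace is returned.  Communities smaller than a configurable
minimum (3 in the study) can be filtered afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx


@dataclass
class Partition:
    """Assignment of nodes to communities with its modularity."""

    assignment: dict  # node -> community id; -1 marks filtered-out nodes
    modularity_q: float

    @property
    def n_communities(self) -> int:
        return len({c for c in self.assignment.values() if c >= 0})

    def communities(self) -> list[set]:
        groups: dict[int, set] = {}
        for node, cid in self.assignment.items():
            if cid >= 0:
                groups.setdefault(cid, set()).add(node)
        return [groups[c] for c in sorted(groups)]


@dataclass
class ModularityTrace:
    """Per-iteration record of the Girvan-Newman edge-removal process."""

    steps: list[tuple[int, tuple, float]] = field(default_factory=list)

    def append(self, iteration: int, removed_edge: tuple, q: float) -> None:
        if self.steps and iteration <= self.steps[-1][0]:
            raise ValueError("iterations must be strictly increasing")
        self.steps.append((iteration, removed_edge, q))


def edge_betweenness(graph: nx.Graph) -> dict[tuple, float]:
    """Unweighted edge betweenness: for each edge, the sum over unordered
    node pairs of the fraction of shortest paths through that edge."""
    raw = nx.edge_betweenness_centrality(graph, normalized=False)
    return {_canon(e): v for e, v in raw.items()}


def _canon(edge: tuple) -> tuple:
    u, v = edge
    return (u, v) if str(u) <= str(v) else (v, u)


def _modularity(original: nx.Graph, communities: list[set]) -> float:
    """Newman-Girvan modularity of a partition, evaluated on ``original``."""
    m = original.number_of_edges()
    if m == 0:
        return 0.0
    q = 0.0
    for comm in communities:
        e_c = original.subgraph(comm).number_of_edges()
        d_c = sum(d for _, d in original.degree(comm))
        q += e_c / m - (d_c / (2 * m)) ** 2
    return q


def girvan_newman(graph: nx.Graph) -> tuple[Partition, ModularityTrace]:
    """Run the full edge-removal process and return the best partition.

    One edge is removed per iteration (the highest-betweenness one,
    lexicographic tie-break), so the procedure is fully deterministic.
    The initial connected-component partition is scored too, so the best
    Q can never fall below it.
    """
    if graph.number_of_edges() < 1:
        raise ValueError("graph must have at least one edge")
    original = graph.copy()
    work = graph.copy()
    trace = ModularityTrace()

    def components() -> list[set]:
        return [set(c) for c in nx.connected_components(work)]

    best_comms = components()
    best_q = _modularity(original, best_comms)
    iteration = 0
    while work.number_of_edges() > 0:
        iteration += 1
        eb = edge_betweenness(work)
        target = min(eb, key=lambda e: (-eb[e], str(e[0]), str(e[1])))
        work.remove_edge(*target)
        comms = components()
        q = _modularity(original, comms)
        trace.append(iteration, target, q)
        if q > best_q:
            best_q = q
            best_comms = comms

    ordered = sorted(best_comms, key=lambda c: sorted(str(n) for n in c))
    assignment = {n: cid for cid, comm in enumerate(ordered) for n in comm}
    return Partition(assignment=assignment, modularity_q=best_q), trace


def filter_communities(partition: Partition, min_size: int = 3) -> Partition:
    """Drop communities smaller than ``min_size``; their nodes become
    unassigned (community id -1)."""
    sizes: dict[int, int] = {}
    for cid in partition.assignment.values():
        if cid >= 0:
            sizes[cid] = sizes.get(cid, 0) + 1
    keep = {cid for cid, n in sizes.items() if n >= min_size}
    relabel = {cid: i for i, cid in enumerate(sorted(keep))}
    assignment = {
        node: relabel.get(cid, -1) if cid >= 0 else -1
        for node, cid in partition.assignment.items()
    }
    return Partition(assignment=assignment, modularity_q=partition.modularity_q)
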