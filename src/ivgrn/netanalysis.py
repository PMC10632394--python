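"""Analysis of the thresholded regulatory network.

Degrees, Newman modularity on the symmetrized edge weights, fast-greedy
agglomerative community detection, weakly-connected subnetwork extraction,
and standard graph exports (edge-list TSV, GraphML, Matrix Market).

The modularity of a partition D is

    Q(D) = (1/2N) * sum_{i,j} [ (E_ij + E_ji) - d(i) d(j) / (2N) ] delta(i,j)

with N the number of directed regulations, d(i) the total (in+out) degree,
and delta the same-community indicator; the sum runs over all ordered node
pairs (self-pairs contribute only the null-model term since E_ii = 0).
This is standard Newman modularity on the symmetrized graph: the all-in-one
partition scores exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.io import mmwrite

__all__ = [
    "ThresholdedNetwork",
    "PartitionResult",
    "total_degree",
    "modularity",
    "greedy_partition",
    "extract_subnetworks",
    "to_networkx",
    "write_edge_list",
    "write_graphml",
    "write_adjacency_mtx",
]


@dataclass
class ThresholdedNetwork:
    """Directed binary network at a bootstrap-frequency cutoff.

    ``nodes`` are the genes incident to at least one edge; ``edges`` holds
    (regulator, target) pairs.  Optional per-edge frequencies/effect signs
    ride along for export.
    """

    nodes: list[int]
    edges: set[tuple[int, int]]
    cutoff: float
    edge_frequency: dict[tuple[int, int], float] = field(default_factory=dict)
    gene_names: list[str] | None = None

    def __post_init__(self):
        if any(i == j for i, j in self.edges):
            raise ValueError("self-edges are not allowed")

    @property
    def N(self) -> int:
        """Total number of directed regulations."""
        return len(self.edges)

    def name(self, i: int) -> str:
        return self.gene_names[i] if self.gene_names else str(i)


def _symmetrized(network: ThresholdedNetwork) -> dict[tuple[int, int], float]:
    """w_ij = E_ij + E_ji over unordered pairs (each stored once, i < j)."""
    w: dict[tuple[int, int], float] = {}
    for i, j in network.edges:
        key = (min(i, j), max(i, j))
        w[key] = w.get(key, 0.0) + 1.0
    return w


def total_degree(network: ThresholdedNetwork, i: int) -> int:
    """d(i): number of regulations into plus out of gene i (a reciprocal
    pair contributes 2)."""
    if i not in network.nodes:
        raise KeyError(f"gene {i} is not in the network")
    return sum((a == i) + (b == i) for a, b in network.edges)


def _degrees(network: ThresholdedNetwork) -> dict[int, int]:
    d = {i: 0 for i in network.nodes}
    for a, b in network.edges:
        d[a] += 1
        d[b] += 1
    return d


def modularity(network: ThresholdedNetwork, assignment: dict[int, int]) -> float:
    """Evaluate Q for a community assignment (all nodes must be assigned)."""
    if network.N == 0:
        raise ValueError("modularity is undefined on an empty edge set")
    missing = [i for i in network.nodes if i not in assignment]
    if missing:
        raise ValueError(f"assignment misses nodes {missing[:5]}")
    two_n = 2.0 * network.N
    within = 0.0
    for (i, j), wij in _symmetrized(network).items():
        if assignment[i] == assignment[j]:
            within += 2.0 * wij  # both ordered pairs (i,j) and (j,i)
    deg = _degrees(network)
    comm_deg: dict[int, float] = {}
    for i in network.nodes:
        comm_deg[assignment[i]] = comm_deg.get(assignment[i], 0.0) + deg[i]
    null = sum(D * D for D in comm_deg.values()) / two_n
    return (within - null) / two_n


@dataclass
class PartitionResult:
    assignment: dict[int, int]
    modularity: float
    community_sizes: dict[int, int]
    degrees: dict[int, int]


def greedy_partition(network: ThresholdedNetwork) -> PartitionResult:
    """Fast-greedy agglomerative modularity optimization.

    Starts from singleton communities and repeatedly merges the connected
    pair of communities with the largest modularity gain (ties broken by
    the lowest community-id pair), stopping when no merge increases Q;
    the best-Q partition encountered is returned.  Operates on the
    symmetrized weights E_ij + E_ji, as the Q formula dictates.
    """
    if network.N == 0:
        raise ValueError("cannot partition an empty network")
    nodes = sorted(network.nodes)
    two_n = 2.0 * network.N
    comm_of = {i: ci for ci, i in enumerate(nodes)}

    # e[a][b]: fraction of ordered-pair weight between communities a and b
    e: dict[int, dict[int, float]] = {c: {} for c in range(len(nodes))}
    a_frac = {c: 0.0 for c in range(len(nodes))}
    deg = _degrees(network)
    for i in nodes:
        a_frac[comm_of[i]] = deg[i] / two_n
    for (i, j), w in _symmetrized(network).items():
        ci, cj = comm_of[i], comm_of[j]
        e[ci][cj] = e[ci].get(cj, 0.0) + w / two_n
        e[cj][ci] = e[cj].get(ci, 0.0) + w / two_n

    members = {c: [i] for i, c in comm_of.items()}
    current_q = modularity(network, comm_of)
    best_q, best_assign = current_q, dict(comm_of)

    while True:
        best_gain, pair = 0.0, None
        for a in sorted(e):
            for b in sorted(e[a]):
                if b <= a:
                    continue
                gain = 2.0 * (e[a][b] - a_frac[a] * a_frac[b])
                if gain > best_gain + 1e-15:
                    best_gain, pair = gain, (a, b)
        if pair is None:
            break
        a, b = pair
        # merge b into a
        for c, w in list(e[b].items()):
            if c == a:
                continue
            e[a][c] = e[a].get(c, 0.0) + w
            e[c][a] = e[c].get(a, 0.0) + w
            del e[c][b]
        e[a].pop(b, None)
        del e[b]
        a_frac[a] += a_frac.pop(b)
        members[a].extend(members.pop(b))
        for i in members[a]:
            comm_of[i] = a
        current_q += best_gain
        if current_q > best_q + 1e-15:
            best_q, best_assign = current_q, dict(comm_of)

    # relabel communities compactly and deterministically
    relabel: dict[int, int] = {}
    assign = {}
    for i in nodes:
        c = best_assign[i]
        if c not in relabel:
            relabel[c] = len(relabel)
        assign[i] = relabel[c]
    sizes: dict[int, int] = {}
    for c in assign.values():
        sizes[c] = sizes.get(c, 0) + 1
    return PartitionResult(
        assignment=assign,
        modularity=modularity(network, assign),
        community_sizes=sizes,
        degrees=deg,
    )


def extract_subnetworks(
    network: ThresholdedNetwork, tf_list: set[str] | None = None
) -> list[dict]:
    """Weakly-connected components, largest first.

    Each component reports its node list, edge list and (if a transcription
    factor list is supplied) which members are TFs.
    """
    g = to_networkx(network)
    comps = sorted(
        (sorted(c) for c in nx.weakly_connected_components(g)),
        key=lambda c: (-len(c), c[0]),
    )
    out = []
    for comp in comps:
        cset = set(comp)
        entry = {
            "nodes": comp,
            "edges": sorted((i, j) for i, j in network.edges if i in cset),
            "size": len(comp),
        }
        if tf_list is not None:
            entry["tfs"] = sorted(i for i in comp if network.name(i) in tf_list)
        out.append(entry)
    return out


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------


def to_networkx(network: ThresholdedNetwork) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(network.nodes)
    for i, j in sorted(network.edges):
        g.add_edge(i, j, frequency=network.edge_frequency.get((i, j), np.nan))
    return g


def write_edge_list(network: ThresholdedNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("regulator\ttarget\tfrequency\n")
        for i, j in sorted(network.edges):
            f = network.edge_frequency.get((i, j), float("nan"))
            fh.write(f"{network.name(i)}\t{network.name(j)}\t{f:.6g}\n")


def write_graphml(
    network: ThresholdedNetwork,
    path: str | Path,
    partition: PartitionResult | None = None,
) -> None:
    g = to_networkx(network)
    if partition is not None:
        nx.set_node_attributes(g, partition.assignment, "community")
        nx.set_node_attributes(g, partition.degrees, "degree")
    nx.relabel_nodes(g, {i: network.name(i) for i in network.nodes}, copy=False)
    nx.write_graphml(g, path)


def write_adjacency_mtx(network: ThresholdedNetwork, path: str | Path, p: int) -> None:
    rows = [j for _, j in sorted(network.edges)]
    cols = [i for i, _ in sorted(network.edges)]
    A = sp.coo_matrix((np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(p, p))
    mmwrite(str(path), A)
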