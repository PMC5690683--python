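"""Weighted graphs from correlation/contact matrices and their path analysis.

Edge strength s is the matrix entry (nMI, contact frequency or |Δ frequency|,
all in (0, 1]); the path weight is w = 1 - s (floored at 1e-6) so that strong
correlations make short network distances.  ``-log(s)`` is available as an
alternative transform.  All shortest-path machinery is Dijkstra / Yen via
networkx; ties between equal-cost paths are broken by the lexicographically
smallest node sequence, so results are deterministic across platforms.

The preferential-connection score ζ of node i with respect to a source node
is ζ_i = min(0, d_i - <d>): the shortage of i's network distance d_i relative
to the mean finite distance <d> from the source.  Negative ζ marks nodes
preferentially connected to the source; nodes at or beyond the mean, and
disconnected nodes, carry ζ = 0 ("no preferential connection").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .correlations import LabeledMatrix
from .exceptions import ContractError, DegenerateProfileError

__all__ = [
    "NetworkGraph",
    "ZetaProfile",
    "PathSet",
    "build_graph",
    "zeta_scores",
    "delta_zeta",
    "shortest_paths",
    "k_shortest_paths",
    "node_degeneracy",
]

WEIGHT_FLOOR = 1e-6


def build_graph(matrix: LabeledMatrix, weight_transform: str = "1-s") -> nx.Graph:
    """Weighted undirected graph from a matrix with entries in [0, 1].

    Zero entries mean "no edge".  Every edge carries the raw strength ``s``
    and the path weight ``w``.
    """
    values = matrix.values
    if values.min() < 0:
        raise ContractError(f"negative entries not allowed for kind {matrix.kind!r}")
    if values.max() > 1 + 1e-9:
        raise ContractError("matrix entries must lie in [0, 1]")
    if weight_transform not in ("1-s", "-log(s)"):
        raise ContractError(f"unknown weight transform {weight_transform!r}")
    g = nx.Graph(kind=matrix.kind, weight_transform=weight_transform)
    g.add_nodes_from(matrix.labels)
    n = len(matrix.labels)
    for i in range(n):
        for j in range(i + 1, n):
            s = values[i, j]
            if s > 0:
                if weight_transform == "1-s":
                    w = max(1.0 - s, WEIGHT_FLOOR)
                else:
                    w = max(-np.log(s), WEIGHT_FLOOR)
                g.add_edge(matrix.labels[i], matrix.labels[j], s=float(s), w=float(w))
    return g


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def write_edge_list(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for u, v, data in sorted(graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
            fh.write(f"{u}\t{v}\t{data['s']:.6g}\n")


@dataclass
class ZetaProfile:
    """Preferential-connection profile from one source node."""

    source: object
    zeta: dict                      # node -> ζ <= 0
    distance: dict                  # node -> finite network distance
    mean_distance: float
    disconnected: list
    raw_deviation: dict = field(default_factory=dict)  # node -> d_i - <d>, unclamped

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("fragment\tzeta\tdistance\n")
            for node, z in self.zeta.items():
                d = self.distance.get(node, float("inf"))
                fh.write(f"{node}\t{z:.6g}\t{d:.6g}\n")


def zeta_scores(graph: nx.Graph, source) -> ZetaProfile:
    """ζ profile: ζ_i = min(0, d_i - <d>) with d the Dijkstra distance.

    <d> is the mean finite distance over all nodes other than the source;
    disconnected nodes are excluded from the mean and carry ζ = 0.
    """
    if source not in graph:
        raise ContractError(f"source node {source!r} not in graph")
    dist = nx.single_source_dijkstra_path_length(graph, source, weight="w")
    finite_others = {n: d for n, d in dist.items() if n != source}
    if not finite_others:
        raise DegenerateProfileError(f"source {source!r} is disconnected from every node")
    mean_d = float(np.mean(list(finite_others.values())))
    zeta: dict = {}
    raw: dict = {}
    disconnected = []
    for node in graph.nodes:
        if node in dist:
            raw[node] = dist[node] - mean_d
            zeta[node] = min(0.0, raw[node])
        else:
            disconnected.append(node)
            zeta[node] = 0.0
    return ZetaProfile(source=source, zeta=zeta, distance=dict(dist),
                       mean_distance=mean_d, disconnected=disconnected,
                       raw_deviation=raw)


def delta_zeta(bound: ZetaProfile, apo: ZetaProfile) -> dict:
    """Δζ_i = ζ_i(bound) - ζ_i(apo); negative = stronger preferential
    connection to the source in the bound state."""
    if bound.source != apo.source:
        raise ContractError("Δζ requires matching source nodes")
    if set(bound.zeta) != set(apo.zeta):
        raise ContractError("Δζ requires matching node sets")
    return {node: bound.zeta[node] - apo.zeta[node] for node in bound.zeta}


@dataclass
class PathSet:
    """A collection of network paths with per-node traversal counts."""

    pairs: list                     # (source, target) per path query
    paths: list                     # list of node lists (may be several per pair)
    lengths: list                   # total path weight per path
    unreachable: list = field(default_factory=list)
    node_counts: dict = field(default_factory=dict)

    def recount(self) -> None:
        counts: dict = {}
        for p in self.paths:
            for node in p:
                counts[node] = counts.get(node, 0) + 1
        self.node_counts = counts

    def to_json_dict(self) -> dict:
        return {
            "pairs": [[str(s), str(t)] for s, t in self.pairs],
            "paths": [[str(n) for n in p] for p in self.paths],
            "lengths": list(map(float, self.lengths)),
            "unreachable": [str(t) for t in self.unreachable],
            "node_counts": {str(k): v for k, v in self.node_counts.items()},
        }


def _path_length(graph: nx.Graph, path) -> float:
    return sum(graph[u][v]["w"] for u, v in zip(path, path[1:]))


def shortest_paths(graph: nx.Graph, source, target_set) -> PathSet:
    """One minimal-weight path per reachable target (deterministic ties).

    Unreachable targets are reported in ``unreachable``, not raised.
    """
    ps = PathSet(pairs=[], paths=[], lengths=[])
    for target in target_set:
        if target == source:
            ps.pairs.append((source, target))
            ps.paths.append([source])
            ps.lengths.append(0.0)
            continue
        if target not in graph or not nx.has_path(graph, source, target):
            ps.unreachable.append(target)
            continue
        best = min(nx.all_shortest_paths(graph, source, target, weight="w"),
                   key=lambda p: [str(n) for n in p])
        ps.pairs.append((source, target))
        ps.paths.append(best)
        ps.lengths.append(_path_length(graph, best))
    ps.recount()
    return ps


def k_shortest_paths(graph: nx.Graph, source, target, k: int = 5) -> PathSet:
    """Top-k loopless minimal-weight paths (Yen), sorted by (length, nodes).

    Returns fewer than k paths when the graph admits fewer simple paths.
    """
    if k < 1:
        raise ContractError("k must be >= 1")
    ps = PathSet(pairs=[], paths=[], lengths=[])
    if target not in graph or source not in graph or not nx.has_path(graph, source, target):
        ps.unreachable.append(target)
        ps.recount()
        return ps
    collected = []
    gen = nx.shortest_simple_paths(graph, source, target, weight="w")
    kth_len = None
    for path in gen:
        length = _path_length(graph, path)
        if len(collected) < k:
            collected.append((length, path))
            kth_len = max(l for l, _ in collected)
        elif length <= kth_len + 1e-12:
            collected.append((length, path))  # tie with the kth path
        else:
            break
    collected.sort(key=lambda lp: (lp[0], [str(n) for n in lp[1]]))
    collected = collected[:k]
    for length, path in collected:
        ps.pairs.append((source, target))
        ps.paths.append(path)
        ps.lengths.append(length)
    ps.recount()
    return ps


def node_degeneracy(paths: PathSet, residue_set, fragment_span: int | None = None):
    """Fraction of paths containing at least one member of ``residue_set``.

    Nodes match by identity, or — when ``fragment_span`` is given and both
    node and residue are integers — when any residue in
    [node, node + span - 1] belongs to the set (fragment nodes are labelled by
    their first residue).  Returns ``(fraction, per_node_counts)``.
    """
    if not paths.paths:
        raise ContractError("empty path set")
    residue_set = set(residue_set)

    def _matches(node) -> bool:
        if node in residue_set:
            return True
        if fragment_span is not None and isinstance(node, (int, np.integer)):
            return any((node <= r < node + fragment_span) for r in residue_set
                       if isinstance(r, (int, np.integer)))
        return False

    hits = sum(1 for p in paths.paths if any(_matches(n) for n in p))
    return hits / len(paths.paths), dict(paths.node_counts)
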