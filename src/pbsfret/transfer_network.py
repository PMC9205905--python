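"""Chromophore network and candidate energy-transfer pathways.

Chromophores become nodes of an undirected graph; every distance-gated pair
contributes one edge carrying its :class:`~pbsfret.fret_geometry.PairGeometry`
and the relative rate proxy κ²/r⁶ as weight. Terminal emitters (by default
the ApcE α^LCM chromophore at Cys198 and the ApcD chromophore at Cys81) are
designated sinks.

A candidate pathway from a source chromophore to the sinks is formalized as
the simple path maximizing the product of edge weights — additive as the sum
of −log(weight), which Dijkstra solves exactly when every weight ≤ 1 (always
true for the physical κ²/r⁶ scale at Å distances). This is a ranking device
for structure-derived hypotheses, not a kinetic model: excitonic coupling,
spectral tuning by linker proteins, and back-transfer are all outside the
point-dipole picture used here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx

from .chromophores import ChromophoreID
from .errors import DataError
from .fret_geometry import PairGeometry
from .structure_io import AssemblyMap


@dataclass
class TransferGraph:
    graph: nx.Graph                       # nodes: str(ChromophoreID); edge attr "pair"
    sinks: set[str] = field(default_factory=set)
    ids: dict[str, ChromophoreID] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def edge_pairs(self) -> list[PairGeometry]:
        return [d["pair"] for _, _, d in self.graph.edges(data=True)]


@dataclass(frozen=True)
class PathResult:
    """Outcome of a pathway search; ``path`` is empty when no sink is reachable."""

    source: str
    path: tuple[str, ...]
    log_product: float      # sum of log(weight) along the path; −inf if none
    reachable: bool

    @property
    def product(self) -> float:
        return math.exp(self.log_product) if self.reachable else 0.0

    @property
    def status(self) -> str:
        return "ok" if self.reachable else "disconnected from sinks"


def default_sinks(ids: list[ChromophoreID]) -> list[ChromophoreID]:
    """Terminal emitters among ``ids``: α^LCM Cys198 and ApcD Cys81 chromophores."""
    out = [
        cid
        for cid in ids
        if (cid.subunit_tag == "LCM" and cid.attach_residue == 198)
        or (cid.subunit_tag == "ApcD" and cid.attach_residue == 81)
    ]
    return sorted(out)


def build_graph(pairs: list[PairGeometry], sinks: list[ChromophoreID]) -> TransferGraph:
    """Assemble the undirected transfer graph from distance-gated pairs.

    Sinks are recorded (and added as nodes) even if isolated. Duplicate edges
    indicate an upstream deduplication failure and raise.
    """
    g = nx.Graph()
    ids: dict[str, ChromophoreID] = {}
    for p in pairs:
        u, v = str(p.donor_id), str(p.acceptor_id)
        if g.has_edge(u, v):
            raise DataError(f"duplicate edge {u}–{v}; deduplicate pairs upstream")
        if p.weight <= 0:
            raise DataError(f"edge {u}–{v} has non-positive weight")
        g.add_edge(u, v, pair=p, weight=p.weight)
        ids.setdefault(u, p.donor_id)
        ids.setdefault(v, p.acceptor_id)
    sink_set: set[str] = set()
    for s in sinks:
        key = str(s)
        g.add_node(key)
        ids.setdefault(key, s)
        sink_set.add(key)
    return TransferGraph(graph=g, sinks=sink_set, ids=ids)


def bridging_pairs(tg: TransferGraph, amap: AssemblyMap | None = None) -> list[PairGeometry]:
    """Edges whose endpoints lie in different cylinders.

    Sorted by ascending distance, ties by descending weight. Every edge
    endpoint must carry a cylinder annotation (it does whenever the node came
    from a mapped chromophore).
    """
    out: list[PairGeometry] = []
    for u, v, d in tg.graph.edges(data=True):
        for node in (u, v):
            cid = tg.ids.get(node)
            if cid is None or not cid.cylinder:
                raise DataError(f"node {node} has no cylinder annotation")
        if tg.ids[u].cylinder != tg.ids[v].cylinder:
            out.append(d["pair"])
    out.sort(key=lambda p: (p.r, -p.weight, str(p.donor_id), str(p.acceptor_id)))
    return out


def strongest_path(tg: TransferGraph, source: ChromophoreID | str) -> PathResult:
    """Best simple path from ``source`` to any sink, maximizing Π edge weights.

    Equivalent to a shortest path under edge length −log(weight); solved by
    Dijkstra when all weights ≤ 1 and by exhaustive simple-path search
    otherwise (only synthetic toys produce super-unit weights). Ties are
    broken by the lexicographically smallest node sequence.
    """
    src = str(source)
    if src not in tg.graph:
        raise DataError(f"source {src} not in graph")
    if not tg.sinks:
        raise DataError("graph has no designated sinks")
    if src in tg.sinks:
        return PathResult(source=src, path=(src,), log_product=0.0, reachable=True)

    weights = nx.get_edge_attributes(tg.graph, "weight")
    if weights and max(weights.values()) > 1.0:
        return _exhaustive_best_path(tg, src)

    lengths = {(u, v): -math.log(w) for (u, v), w in weights.items()}
    g = tg.graph
    best: PathResult | None = None
    for sink in sorted(tg.sinks):
        if sink not in g:
            continue
        try:
            dist = nx.single_source_dijkstra_path_length(
                g, sink, weight=lambda u, v, d: -math.log(d["weight"])
            )
        except nx.NodeNotFound:  # pragma: no cover
            continue
        if src not in dist:
            continue
        path = _lexicographic_geodesic(g, src, sink, dist, lengths)
        cand = PathResult(source=src, path=tuple(path), log_product=-dist[src], reachable=True)
        if (
            best is None
            or cand.log_product > best.log_product + 1e-12
            or (abs(cand.log_product - best.log_product) <= 1e-12 and cand.path < best.path)
        ):
            best = cand
    if best is None:
        return PathResult(source=src, path=(), log_product=-math.inf, reachable=False)
    return best


def _edge_len(lengths: dict, u: str, v: str) -> float:
    return lengths[(u, v)] if (u, v) in lengths else lengths[(v, u)]


def _lexicographic_geodesic(g, src, sink, dist_from_sink, lengths) -> list[str]:
    """Greedy forward walk along distance-consistent edges, smallest node first."""
    path = [src]
    cur = src
    visited = {src}
    while cur != sink:
        target = dist_from_sink[cur]
        candidates = []
        for nb in g.neighbors(cur):
            if nb in visited or nb not in dist_from_sink:
                continue
            step = _edge_len(lengths, cur, nb)
            if math.isclose(step + dist_from_sink[nb], target, rel_tol=1e-9, abs_tol=1e-12):
                candidates.append(nb)
        cur = min(candidates)  # consistency guarantees candidates is non-empty
        visited.add(cur)
        path.append(cur)
    return path


def _exhaustive_best_path(tg: TransferGraph, src: str) -> PathResult:
    """DFS over all simple paths; used only when some weight exceeds 1."""
    g = tg.graph
    best_log = -math.inf
    best_path: tuple[str, ...] = ()

    def dfs(node: str, log_prod: float, path: list[str], seen: set[str]) -> None:
        nonlocal best_log, best_path
        if node in tg.sinks:
            cand = tuple(path)
            if log_prod > best_log + 1e-12 or (
                abs(log_prod - best_log) <= 1e-12 and (not best_path or cand < best_path)
            ):
                best_log, best_path = log_prod, cand
            return
        for nb in sorted(g.neighbors(node)):
            if nb in seen:
                continue
            w = g.edges[node, nb]["weight"]
            seen.add(nb)
            path.append(nb)
            dfs(nb, log_prod + math.log(w), path, seen)
            path.pop()
            seen.remove(nb)

    dfs(src, 0.0, [src], {src})
    if not best_path:
        return PathResult(source=src, path=(), log_product=-math.inf, reachable=False)
    return PathResult(source=src, path=best_path, log_product=best_log, reachable=True)


# ---------------------------------------------------------------------------
# exports


def write_edge_list(tg: TransferGraph, path) -> None:
    """Plain edge-list TSV: node_a, node_b, r, kappa_sq, weight (4 decimals)."""
    from pathlib import Path

    lines = ["node_a\tnode_b\tr_angstrom\tkappa_sq\tweight"]
    rows = sorted(
        ((str(d["pair"].donor_id), str(d["pair"].acceptor_id), d["pair"]) for _, _, d in tg.graph.edges(data=True)),
        key=lambda t: (t[0], t[1]),
    )
    for u, v, p in rows:
        lines.append(f"{u}\t{v}\t{p.r:.4f}\t{p.kappa_sq:.4f}\t{p.weight:.4e}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_graphml(tg: TransferGraph, path) -> None:
    """GraphML export with scalar edge attributes, for visualization tools."""
    g = nx.Graph()
    for node in tg.graph.nodes:
        g.add_node(node, is_sink=node in tg.sinks)
    for u, v, d in tg.graph.edges(data=True):
        p = d["pair"]
        g.add_edge(u, v, r=float(p.r), kappa_sq=float(p.kappa_sq), weight=float(p.weight))
    nx.write_graphml(g, str(path))
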