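"""Undirected simple graph with the topology metrics used throughout the pipeline.

The :class:`Network` is the object every downstream stage acts on: a simple
undirected graph over opaque string identifiers (typically UniProt accessions),
with optional per-node attributes (display name, ring level, provenance tags).
All metrics treat edges as unweighted (length 1) and iterate nodes in sorted
order so that reports are byte-stable across runs.

Conventions
-----------
* Betweenness counts each unordered pair {s, t} once, endpoints excluded;
  pairs in different components contribute nothing.  This is the undirected
  convention of igraph/networkx with ``normalized=False``.
* Closeness of node *v* is (n - 1) / sum of distances, where *n* is the size
  of *v*'s connected component (not the whole graph); an isolated node has
  closeness 0.  The normalized variant divides by the network-wide maximum.
* Mean shortest-path length averages over *connected* unordered pairs only;
  a network with no connected pair reports NaN, never 0.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

log = logging.getLogger(__name__)

__all__ = [
    "Network",
    "CentralityReport",
    "TopologySummary",
    "connected_components",
    "betweenness",
    "closeness",
    "centrality_report",
    "topology_summary",
    "ego_network",
    "write_graphml",
    "write_centrality_tsv",
]


class Network:
    """Simple undirected graph: no self-loops, no duplicate edges.

    Self-loops and repeated edges offered to :meth:`add_edge` are silently
    collapsed; the counts are kept in :attr:`n_loops_dropped` and
    :attr:`n_duplicates_dropped` and logged at construction from an edge list.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str]] = (),
        nodes: Iterable[str] = (),
        node_attrs: Mapping[str, Mapping[str, object]] | None = None,
    ) -> None:
        self._adj: dict[str, set[str]] = {}
        self._node_attrs: dict[str, dict[str, object]] = {}
        self._edge_attrs: dict[frozenset[str], dict[str, object]] = {}
        self.n_loops_dropped = 0
        self.n_duplicates_dropped = 0
        for n in nodes:
            self.add_node(n)
        for u, v in edges:
            self.add_edge(u, v)
        if node_attrs:
            for n, attrs in node_attrs.items():
                self.add_node(n, **attrs)
        if self.n_loops_dropped or self.n_duplicates_dropped:
            log.info(
                "collapsed %d self-loop(s) and %d duplicate edge(s) at construction",
                self.n_loops_dropped,
                self.n_duplicates_dropped,
            )

    # -- construction -----------------------------------------------------

    def add_node(self, n: str, **attrs: object) -> None:
        self._adj.setdefault(n, set())
        if attrs:
            self._node_attrs.setdefault(n, {}).update(attrs)

    def add_edge(self, u: str, v: str, **attrs: object) -> None:
        if u == v:
            self.n_loops_dropped += 1
            self.add_node(u)
            return
        self.add_node(u)
        self.add_node(v)
        key = frozenset((u, v))
        if v in self._adj[u]:
            self.n_duplicates_dropped += 1
        else:
            self._adj[u].add(v)
            self._adj[v].add(u)
        if attrs:
            self._edge_attrs.setdefault(key, {}).update(attrs)

    # -- inspection -------------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        return sorted(self._adj)

    @property
    def n_nodes(self) -> int:
        return len(self._adj)

    @property
    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self._adj.values()) // 2

    def edges(self) -> list[tuple[str, str]]:
        """Edges as sorted (min, max) pairs, in sorted order."""
        out = []
        for u in self.nodes:
            for v in sorted(self._adj[u]):
                if u < v:
                    out.append((u, v))
        return out

    def __contains__(self, n: str) -> bool:
        return n in self._adj

    def __iter__(self) -> Iterator[str]:
        return iter(self.nodes)

    def has_edge(self, u: str, v: str) -> bool:
        return u in self._adj and v in self._adj[u]

    def neighbors(self, n: str) -> list[str]:
        self._require(n)
        return sorted(self._adj[n])

    def degree(self, n: str) -> int:
        self._require(n)
        return len(self._adj[n])

    def node_attrs(self, n: str) -> dict[str, object]:
        self._require(n)
        return self._node_attrs.get(n, {})

    def edge_attrs(self, u: str, v: str) -> dict[str, object]:
        return self._edge_attrs.get(frozenset((u, v)), {})

    def set_node_attr(self, n: str, key: str, value: object) -> None:
        self._require(n)
        self._node_attrs.setdefault(n, {})[key] = value

    def _require(self, n: str) -> None:
        if n not in self._adj:
            raise KeyError(f"unknown node: {n!r}")

    # -- derived graphs ---------------------------------------------------

    def subgraph(self, keep: Iterable[str]) -> "Network":
        """Induced subgraph on ``keep`` (attributes carried over)."""
        keep_set = set(keep)
        sub = Network()
        for n in sorted(keep_set):
            self._require(n)
            sub.add_node(n, **self._node_attrs.get(n, {}))
        for u, v in self.edges():
            if u in keep_set and v in keep_set:
                sub.add_edge(u, v, **self._edge_attrs.get(frozenset((u, v)), {}))
        return sub

    def without_node(self, v: str) -> "Network":
        """Copy of the graph with ``v`` and its incident edges removed."""
        self._require(v)
        return self.subgraph(n for n in self._adj if n != v)

    def copy(self) -> "Network":
        return self.subgraph(self._adj)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for n in self.nodes:
            g.add_node(n, **self._node_attrs.get(n, {}))
        for u, v in self.edges():
            g.add_edge(u, v, **self._edge_attrs.get(frozenset((u, v)), {}))
        return g


@dataclass(frozen=True)
class CentralityReport:
    """Per-node centralities: degree, betweenness Cb(v), raw and normalized closeness."""

    node: str
    degree: int
    betweenness: float
    closeness_raw: float
    closeness_norm: float


@dataclass(frozen=True)
class TopologySummary:
    """Global topology: component structure and connected-pair mean path length."""

    n_nodes: int
    n_edges: int
    n_components: int
    lcc_size: int
    avg_path_length: float  # NaN when no connected pair exists

    def as_row(self) -> dict[str, object]:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "n_components": self.n_components,
            "lcc_size": self.lcc_size,
            "avg_path_length": self.avg_path_length,
        }


# ---------------------------------------------------------------------------
# metrics


def _bfs_distances(net: Network, source: str) -> dict[str, int]:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for w in net._adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                queue.append(w)
    return dist


def connected_components(net: Network) -> list[set[str]]:
    """Partition of the node set into connected components.

    Components are ordered by decreasing size, ties broken by smallest member,
    so the first entry is always a largest component.
    """
    seen: set[str] = set()
    comps: list[set[str]] = []
    for n in net.nodes:
        if n in seen:
            continue
        comp = set(_bfs_distances(net, n))
        seen |= comp
        comps.append(comp)
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def betweenness(net: Network) -> dict[str, float]:
    """Betweenness Cb(v) = sum over pairs s != v != t of sigma_st(v)/sigma_st.

    Brandes' dependency accumulation; each unordered pair counted once.
    """
    cb = {v: 0.0 for v in net.nodes}
    for s in net.nodes:
        # single-source shortest-path DAG
        stack: list[str] = []
        pred: dict[str, list[str]] = {v: [] for v in net._adj}
        sigma = {v: 0.0 for v in net._adj}
        sigma[s] = 1.0
        dist = {s: 0}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            stack.append(u)
            for w in sorted(net._adj[u]):
                if w not in dist:
                    dist[w] = dist[u] + 1
                    queue.append(w)
                if dist[w] == dist[u] + 1:
                    sigma[w] += sigma[u]
                    pred[w].append(u)
        delta = {v: 0.0 for v in net._adj}
        while stack:
            w = stack.pop()
            for u in pred[w]:
                delta[u] += sigma[u] / sigma[w] * (1.0 + delta[w])
            if w != s:
                cb[w] += delta[w]
        # each unordered pair is visited from both endpoints
    return {v: val / 2.0 for v, val in cb.items()}


def closeness(net: Network, v: str) -> tuple[float, int]:
    """Raw closeness of ``v``: (n - 1) / sum of distances within its component.

    Returns ``(closeness_raw, component_size)``; an isolated node yields 0.
    """
    net._require(v)
    dist = _bfs_distances(net, v)
    n = len(dist)
    if n <= 1:
        return 0.0, n
    total = sum(dist.values())
    return (n - 1) / total, n


def centrality_report(net: Network) -> list[CentralityReport]:
    """Degree, betweenness and closeness for every node, sorted by node id.

    ``closeness_norm`` divides by the network-wide maximum raw closeness, so
    the argmax node(s) score exactly 1.  An edgeless network reports 0.
    """
    btw = betweenness(net)
    raw = {v: closeness(net, v)[0] for v in net.nodes}
    cmax = max(raw.values(), default=0.0)
    return [
        CentralityReport(
            node=v,
            degree=net.degree(v),
            betweenness=btw[v],
            closeness_raw=raw[v],
            closeness_norm=(raw[v] / cmax) if cmax > 0 else 0.0,
        )
        for v in net.nodes
    ]


def topology_summary(net: Network) -> TopologySummary:
    """Component counts, LCC size, and mean shortest path over connected pairs."""
    comps = connected_components(net)
    total = 0
    pairs = 0
    for comp in comps:
        if len(comp) < 2:
            continue
        sub_nodes = comp
        for s in sorted(sub_nodes):
            dist = _bfs_distances(net, s)
            for t, d in dist.items():
                if t > s:
                    total += d
                    pairs += 1
    avg = total / pairs if pairs else math.nan
    return TopologySummary(
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        n_components=len(comps),
        lcc_size=len(comps[0]) if comps else 0,
        avg_path_length=avg,
    )


def ego_network(net: Network, seed: str, radius: int = 2) -> Network:
    """Induced subgraph on all nodes within ``radius`` of ``seed``.

    Every node in the result carries a ``ring`` attribute: 0 for the seed,
    k for nodes at geodesic distance k.
    """
    net._require(seed)
    if radius < 0:
        raise ValueError("radius must be >= 0")
    dist = _bfs_distances(net, seed)
    keep = {n for n, d in dist.items() if d <= radius}
    ego = net.subgraph(keep)
    for n in ego.nodes:
        ego.set_node_attr(n, "ring", dist[n])
    return ego


# ---------------------------------------------------------------------------
# writers


def write_graphml(net: Network, path) -> None:
    """Write the network as GraphML (via networkx), attributes included."""
    import networkx as nx

    g = net.to_networkx()
    # GraphML cannot carry sets/lists: serialize container attributes
    for _, data in g.nodes(data=True):
        for k, v in list(data.items()):
            if isinstance(v, (set, frozenset, list, tuple)):
                data[k] = ";".join(sorted(map(str, v)))
    for _, _, data in g.edges(data=True):
        for k, v in list(data.items()):
            if isinstance(v, (set, frozenset, list, tuple)):
                data[k] = ";".join(sorted(map(str, v)))
    nx.write_graphml(g, path)


def write_centrality_tsv(reports: list[CentralityReport], stream, header_comments: Iterable[str] = ()) -> None:
    for line in header_comments:
        stream.write(f"# {line}\n")
    stream.write("node\tdegree\tbetweenness\tcloseness_raw\tcloseness_norm\n")
    for r in reports:
        stream.write(
            f"{r.node}\t{r.degree}\t{r.betweenness:.10g}\t{r.closeness_raw:.10g}\t{r.closeness_norm:.10g}\n"
        )
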