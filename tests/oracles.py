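"""Independent brute-force oracles the efficient implementations are checked
against.  Everything here is written the slow, obviously-correct way and
shares no code with the package internals."""

from __future__ import annotations

import math
from collections import deque
from fractions import Fraction

from mimicnet.graph_core import Network


def adjacency(net: Network) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {n: set() for n in net.nodes}
    for u, v in net.edges():
        adj[u].add(v)
        adj[v].add(u)
    return adj


def bfs_dist(adj: dict[str, set[str]], s: str) -> dict[str, int]:
    dist = {s: 0}
    q = deque([s])
    while q:
        u = q.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                q.append(w)
    return dist


def all_shortest_paths(adj: dict[str, set[str]], s: str, t: str) -> list[list[str]]:
    """Exhaustive enumeration of every shortest s-t path (DFS backtracking
    over distance-decreasing moves from t)."""
    dist = bfs_dist(adj, s)
    if t not in dist:
        return []
    paths: list[list[str]] = []

    def back(node: str, acc: list[str]) -> None:
        if node == s:
            paths.append([s] + acc)
            return
        for w in adj[node]:
            if dist.get(w, -1) == dist[node] - 1:
                back(w, [node] + acc)

    back(t, [])
    return paths


def brute_betweenness(net: Network) -> dict[str, float]:
    """Cb(v) from explicit path enumeration; each unordered pair once."""
    adj = adjacency(net)
    nodes = net.nodes
    cb = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            paths = all_shortest_paths(adj, s, t)
            if not paths:
                continue
            for p in paths:
                for v in p[1:-1]:
                    cb[v] += 1.0 / len(paths)
    return cb


def brute_components(net: Network) -> list[set[str]]:
    adj = adjacency(net)
    seen: set[str] = set()
    comps = []
    for n in net.nodes:
        if n in seen:
            continue
        comp = set(bfs_dist(adj, n))
        seen |= comp
        comps.append(comp)
    return comps


def brute_topology(net: Network) -> tuple[int, int, float]:
    """(n_components, lcc_size, avg shortest path over connected pairs)."""
    adj = adjacency(net)
    comps = brute_components(net)
    total, pairs = 0, 0
    nodes = net.nodes
    for i, s in enumerate(nodes):
        dist = bfs_dist(adj, s)
        for t in nodes[i + 1 :]:
            if t in dist:
                total += dist[t]
                pairs += 1
    avg = total / pairs if pairs else math.nan
    lcc = max((len(c) for c in comps), default=0)
    return len(comps), lcc, avg


def brute_closeness(net: Network, v: str) -> float:
    adj = adjacency(net)
    dist = bfs_dist(adj, v)
    if len(dist) <= 1:
        return 0.0
    return (len(dist) - 1) / sum(dist.values())


def brute_articulation_points(net: Network) -> set[str]:
    """Nodes whose removal increases the component count (recompute from
    scratch per node)."""
    base = len(brute_components(net))
    out = set()
    for v in net.nodes:
        if len(brute_components(net.without_node(v))) > base:
            out.add(v)
    return out


def enum_fisher_two_sided(a: int, b: int, c: int, d: int) -> Fraction:
    """Exact two-sided probability-mass p by enumerating every table with the
    observed margins, in rational arithmetic."""
    r1, c1, n = a + b, a + c, a + b + c + d
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    denom = math.comb(n, c1)
    masses = {
        x: Fraction(math.comb(r1, x) * math.comb(n - r1, c1 - x), denom)
        for x in range(lo, hi + 1)
    }
    obs = masses[a]
    return sum((m for m in masses.values() if m <= obs), start=Fraction(0))


def random_network(rng, n_max: int = 12, p: float | None = None) -> Network:
    """Random simple graph on up to n_max nodes (possibly disconnected)."""
    n = int(rng.integers(2, n_max + 1))
    p = float(rng.uniform(0.1, 0.7)) if p is None else p
    names = [f"n{i:02d}" for i in range(n)]
    net = Network(nodes=names)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                net.add_edge(names[i], names[j])
    return net


def random_tree(rng, n_max: int = 14) -> Network:
    n = int(rng.integers(2, n_max + 1))
    names = [f"t{i:02d}" for i in range(n)]
    net = Network(nodes=names)
    for i in range(1, n):
        parent = int(rng.integers(0, i))
        net.add_edge(names[parent], names[i])
    return net
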