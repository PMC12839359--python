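"""In silico node-depletion experiments and rule-based node-role calls.

Each knock-out removes a single node (and its incident edges) from the
pristine network and re-measures the topology: number of connected
components, size of the largest connected component (LCC), and the mean
shortest-path length over connected pairs.  Deltas are signed after - before.
Scans are never cumulative: every node is removed from the same baseline.

Role classification is a transparent rank rule over the centralities and the
per-node depletion deltas:

* ``bottleneck`` — degree and betweenness ranks both inside the top fraction
  f1, or depletion both fragments the graph (delta_components > 0) and
  produces one of the top-f1 absolute path-length shifts;
* ``peripheral`` — degree at most ``peripheral_degree`` and betweenness not
  above the median;
* ``local_hub`` — everything else (well-connected inside its neighborhood
  but not a global bridge).

The thresholds are configuration, not code: the underlying networks give no
sharp boundary, so they are echoed into every report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import numpy as np

from .graph_core import CentralityReport, Network, TopologySummary, topology_summary

__all__ = [
    "DepletionResult",
    "NodeRole",
    "RoleConfig",
    "deplete_node",
    "depletion_scan",
    "classify_roles",
    "write_depletion_tsv",
    "write_role_tsv",
]


@dataclass(frozen=True)
class DepletionResult:
    """Topology after removing one node, and deltas vs. the baseline."""

    node: str
    components_after: int
    lcc_after: int
    avg_path_after: float
    delta_components: int
    delta_lcc: int
    delta_path: float  # NaN when either average is undefined


def _delta_path(after: float, before: float) -> float:
    if math.isnan(after) or math.isnan(before):
        return math.nan
    return after - before


def deplete_node(net: Network, v: str, baseline: TopologySummary | None = None) -> DepletionResult:
    """Remove ``v``, re-summarize, and report signed deltas vs. ``baseline``.

    The baseline is computed on ``net`` itself when not supplied (pass it
    explicitly when scanning many nodes to avoid recomputation).
    """
    if baseline is None:
        baseline = topology_summary(net)
    after = topology_summary(net.without_node(v))
    return DepletionResult(
        node=v,
        components_after=after.n_components,
        lcc_after=after.lcc_size,
        avg_path_after=after.avg_path_length,
        delta_components=after.n_components - baseline.n_components,
        delta_lcc=after.lcc_size - baseline.lcc_size,
        delta_path=_delta_path(after.avg_path_length, baseline.avg_path_length),
    )


def depletion_scan(
    net: Network, nodes: Sequence[str]
) -> tuple[TopologySummary, list[DepletionResult]]:
    """One-at-a-time knock-outs of ``nodes``, each from the pristine baseline.

    Unknown nodes fail the whole scan up front, with every offender named.
    Output order follows the input order.
    """
    missing = [n for n in nodes if n not in net]
    if missing:
        raise KeyError(f"nodes not in network: {', '.join(sorted(missing))}")
    baseline = topology_summary(net)
    return baseline, [deplete_node(net, v, baseline) for v in nodes]


@dataclass(frozen=True)
class NodeRole:
    node: str
    label: str  # bottleneck | local_hub | peripheral
    degree_rank: int
    betweenness_rank: int
    delta_path_rank: int


@dataclass(frozen=True)
class RoleConfig:
    """Thresholds for the role rule; defaults calibrated on planted-topology
    benchmarks where ground-truth bridges and pendant chains are known."""

    top_fraction: float = 0.10
    peripheral_degree: int = 3
    require_fragmentation_for_path_rule: bool = True

    def __post_init__(self):
        if not (0.0 < self.top_fraction <= 1.0):
            raise ValueError("top_fraction must be in (0, 1]")
        if self.peripheral_degree < 0:
            raise ValueError("peripheral_degree must be >= 0")


def _competition_ranks(values: Sequence[float]) -> list[int]:
    """Descending competition ranks ("1224"): ties share the best rank."""
    order = sorted(range(len(values)), key=lambda i: -values[i])
    ranks = [0] * len(values)
    for pos, i in enumerate(order):
        if pos > 0 and values[i] == values[order[pos - 1]]:
            ranks[i] = ranks[order[pos - 1]]
        else:
            ranks[i] = pos + 1
    return ranks


def classify_roles(
    centralities: Sequence[CentralityReport],
    depletions: Sequence[DepletionResult],
    cfg: RoleConfig = RoleConfig(),
) -> list[NodeRole]:
    """Assign exactly one role label per node (see module docstring).

    ``centralities`` and ``depletions`` must cover the same node universe.
    """
    cent = {c.node: c for c in centralities}
    depl = {d.node: d for d in depletions}
    if set(cent) != set(depl):
        only_c = sorted(set(cent) - set(depl))
        only_d = sorted(set(depl) - set(cent))
        raise ValueError(
            f"node universes differ (centralities only: {only_c}; depletions only: {only_d})"
        )
    nodes = sorted(cent)
    n = len(nodes)
    k = max(1, math.ceil(cfg.top_fraction * n))

    degrees = [cent[v].degree for v in nodes]
    btw = [cent[v].betweenness for v in nodes]
    abs_dpath = [0.0 if math.isnan(depl[v].delta_path) else abs(depl[v].delta_path) for v in nodes]
    deg_rank = _competition_ranks([float(d) for d in degrees])
    btw_rank = _competition_ranks(btw)
    dpath_rank = _competition_ranks(abs_dpath)
    btw_median = float(np.median(btw)) if btw else 0.0

    roles = []
    for i, v in enumerate(nodes):
        both_central = deg_rank[i] <= k and btw_rank[i] <= k
        path_rule = dpath_rank[i] <= k and (
            depl[v].delta_components > 0 or not cfg.require_fragmentation_for_path_rule
        )
        if both_central or path_rule:
            label = "bottleneck"
        elif degrees[i] <= cfg.peripheral_degree and btw[i] <= btw_median:
            label = "peripheral"
        else:
            label = "local_hub"
        roles.append(
            NodeRole(
                node=v,
                label=label,
                degree_rank=deg_rank[i],
                betweenness_rank=btw_rank[i],
                delta_path_rank=dpath_rank[i],
            )
        )
    return roles


# ---------------------------------------------------------------------------
# writers


def _fmt_path(x: float) -> str:
    return "NA" if math.isnan(x) else f"{x:.4f}"


def _fmt_signed(x: float) -> str:
    if math.isnan(x):
        return "NA"
    return f"{x:+.4f}"


def write_depletion_tsv(
    baseline: TopologySummary,
    results: Iterable[DepletionResult],
    stream: TextIO,
    names: dict[str, str] | None = None,
    header_comments: Iterable[str] = (),
) -> None:
    """Scan report in the knock-out table layout: baseline row first, then one
    row per depleted node with signed deltas."""
    names = names or {}
    for line in header_comments:
        stream.write(f"# {line}\n")
    stream.write("node_name\tnode_id\tcomponents\tlcc\tavg_path\tdelta_components\tdelta_lcc\tdelta_path\n")
    stream.write(
        f"No depletion\t-\t{baseline.n_components}\t{baseline.lcc_size}\t"
        f"{_fmt_path(baseline.avg_path_length)}\t-\t-\t-\n"
    )
    for r in results:
        stream.write(
            f"{names.get(r.node, r.node)}\t{r.node}\t{r.components_after}\t{r.lcc_after}\t"
            f"{_fmt_path(r.avg_path_after)}\t{r.delta_components:+d}\t{r.delta_lcc:+d}\t"
            f"{_fmt_signed(r.delta_path)}\n"
        )


def write_role_tsv(
    roles: Iterable[NodeRole],
    stream: TextIO,
    cfg: RoleConfig = RoleConfig(),
    header_comments: Iterable[str] = (),
) -> None:
    for line in header_comments:
        stream.write(f"# {line}\n")
    stream.write(
        f"# thresholds: top_fraction={cfg.top_fraction} peripheral_degree={cfg.peripheral_degree} "
        f"require_fragmentation_for_path_rule={cfg.require_fragmentation_for_path_rule}\n"
    )
    stream.write("node\trole\tdegree_rank\tbetweenness_rank\tdelta_path_rank\n")
    for r in roles:
        stream.write(f"{r.node}\t{r.label}\t{r.degree_rank}\t{r.betweenness_rank}\t{r.delta_path_rank}\n")
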