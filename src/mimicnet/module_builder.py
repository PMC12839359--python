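"""Seed-based disease-module construction.

The disease module is the union, over sources, of every filtered interaction
that touches at least one seed protein (a strict first-neighborhood subgraph:
edges between two non-seed neighbors are excluded).  Seeds with no surviving
interaction stay in the module as isolated anchor nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, TextIO

from .graph_core import Network
from .interactome_io import InteractionRecord, merge_records, normalize_accession

log = logging.getLogger(__name__)

__all__ = ["SeedSet", "ALZHEIMER_SEEDS", "build_disease_module", "annotate_disease_genes", "write_source_summary"]


@dataclass(frozen=True)
class SeedSet:
    """Ordered seed accessions anchoring the module."""

    accessions: tuple[str, ...]

    def __post_init__(self):
        if not self.accessions:
            raise ValueError("seed set must be non-empty")
        object.__setattr__(self, "accessions", tuple(normalize_accession(a) for a in self.accessions))

    def __contains__(self, acc: str) -> bool:
        return acc in self.accessions

    def __iter__(self):
        return iter(self.accessions)


#: The five Alzheimer's anchors: App, Mapt, Psen1, Psen2, Bace1.
ALZHEIMER_SEEDS = SeedSet(("P05067", "P10636", "P49768", "P49810", "P56817"))


def build_disease_module(
    sources: Mapping[str, Iterable[InteractionRecord]],
    seeds: SeedSet,
) -> tuple[Network, list[dict[str, object]]]:
    """First-neighborhood module around ``seeds``, merged across sources.

    Parameters
    ----------
    sources
        Mapping of source name → already-filtered interaction records.
    seeds
        The anchor proteins.

    Returns
    -------
    (module, summary)
        ``module`` is the merged Network with a boolean ``seed`` node
        attribute; ``summary`` is a per-source table of node/edge counts
        (seed-incident records only) plus a final merged row.

    Raises
    ------
    ValueError
        If no seed-incident record survives in any source.
    """
    seed_set = set(seeds)
    kept_per_source: dict[str, list[InteractionRecord]] = {}
    for name, records in sources.items():
        kept = [r for r in records if r.id_a in seed_set or r.id_b in seed_set]
        kept_per_source[name] = kept

    summary: list[dict[str, object]] = []
    for name, kept in kept_per_source.items():
        sub = merge_records([kept])
        summary.append({"source": name, "n_nodes": sub.n_nodes, "n_edges": sub.n_edges})

    seen_seeds = {
        r.id_a if r.id_a in seed_set else r.id_b
        for kept in kept_per_source.values()
        for r in kept
        if r.id_a in seed_set or r.id_b in seed_set
    }
    # seeds on both endpoints count for both
    for kept in kept_per_source.values():
        for r in kept:
            if r.id_a in seed_set and r.id_b in seed_set:
                seen_seeds |= {r.id_a, r.id_b}
    for s in seeds:
        if s not in seen_seeds:
            log.warning("seed %s has no surviving interaction in any source; kept as isolated node", s)

    module = merge_records(kept_per_source.values())
    for s in seeds:  # anchors always belong to the module
        module.add_node(s)
    if module.n_edges == 0 and not any(kept_per_source.values()):
        raise ValueError("disease module is empty: no seed-incident record survived filtering")

    for n in module.nodes:
        module.set_node_attr(n, "seed", n in seed_set)
    summary.append({"source": "final (duplications deleted)", "n_nodes": module.n_nodes, "n_edges": module.n_edges})
    return module, summary


def annotate_disease_genes(
    net: Network,
    disease_list: Iterable[tuple[str, object]],
    score_cutoff: float = 0.38,
) -> int:
    """Flag module nodes on a disease-association list with score > cutoff.

    ``disease_list`` yields (gene identifier, association score) pairs; the
    inequality is strict, so a gene scored exactly at the cutoff is not
    flagged.  Unparsable scores skip the row with a logged warning.  Returns
    the number of flagged nodes; every node receives a boolean
    ``disease_associated`` attribute.
    """
    flagged_genes: set[str] = set()
    for gene, score in disease_list:
        try:
            s = float(score)  # type: ignore[arg-type]
        except (TypeError, ValueError):
            log.warning("disease list: unparsable score %r for gene %r — row skipped", score, gene)
            continue
        if s > score_cutoff:
            flagged_genes.add(normalize_accession(str(gene)))
    count = 0
    for n in net.nodes:
        hit = n in flagged_genes
        net.set_node_attr(n, "disease_associated", hit)
        count += hit
    log.info("disease annotation: %d of %d module nodes above score cutoff %.3g", count, net.n_nodes, score_cutoff)
    return count


def write_source_summary(summary: list[dict[str, object]], stream: TextIO, header_comments: Iterable[str] = ()) -> None:
    """Provenance summary in the per-source node/edge-count layout."""
    for line in header_comments:
        stream.write(f"# {line}\n")
    stream.write("source\tn_nodes\tn_edges\n")
    for row in summary:
        stream.write(f"{row['source']}\t{row['n_nodes']}\t{row['n_edges']}\n")
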