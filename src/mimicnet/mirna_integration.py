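"""miRNA→target evidence filtering and the regulatory overlay on the module.

Regulatory claims come from miRTarBase-style tables, one row per
(miRNA, gene, assay, publication) tuple.  Only strong direct evidence is
retained: human records whose assay label contains "luciferase" (the reporter
assay demonstrating direct 3'-UTR binding), supported by at least
``min_papers`` distinct publications.  Per-gene overrides can relax the paper
count where a single high-quality study is accepted.

The surviving bipartite miRNA→gene edges are then restricted to genes that
map onto the disease-module nodes (via a supplied symbol↔accession table),
giving the regulated-node fraction and per-miRNA multi-target counts that
drive mimic prioritization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

from .enrichment import ContingencyTable
from .graph_core import Network
from .interactome_io import normalize_accession

log = logging.getLogger(__name__)

__all__ = [
    "MirnaTargetRecord",
    "RegulatoryLayer",
    "normalize_mirna",
    "read_mirna_tsv",
    "read_mapping_tsv",
    "filter_mirna_evidence",
    "attach_regulators",
    "overlap_enrichment",
    "write_layer_tsv",
    "layer_to_graphml_network",
]

HUMAN_TAXID = 9606


def normalize_mirna(name: str) -> str:
    """Canonical mature-miRNA key: lowercase with the "hsa-" prefix.

    "miR-34a-5p" and "hsa-miR-34a-5p" unify to "hsa-mir-34a-5p".
    """
    n = name.strip().lower()
    if not n:
        return n
    if not n.startswith("hsa-"):
        n = "hsa-" + n
    return n


@dataclass(frozen=True)
class MirnaTargetRecord:
    """One miRNA→gene regulatory claim with its experimental support."""

    mirna_id: str
    target_gene: str
    method: str = ""
    pmids: frozenset[str] = frozenset()
    species: int = HUMAN_TAXID
    strong_evidence: bool = False  # dialect flag accepted as 1 paper when pmids are absent

    def __post_init__(self):
        if not self.mirna_id:
            raise ValueError("mirna_id must be non-empty")

    @property
    def n_papers(self) -> int:
        if self.pmids:
            return len(self.pmids)
        return 1 if self.strong_evidence else 0


def read_mirna_tsv(stream: Iterable[str]) -> list[MirnaTargetRecord]:
    """Parse a (mirna, gene, method, pmid, species) table, merging duplicate
    (miRNA, gene) rows by PMID union before any thresholding.

    Rows sharing a (miRNA, gene) pair but differing in method keep the
    luciferase label if any row carries one (the filter is per-claim, and a
    claim validated once by reporter assay stays validated).
    """
    merged: dict[tuple[str, str], dict] = {}
    header: list[str] | None = None
    expected = ["mirna", "gene", "method", "pmid", "species"]
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if header is None:
            if all(c in [p.strip().lower() for p in parts] for c in expected[:2]):
                header = [p.strip().lower() for p in parts]
                continue
            header = expected
        row = dict(zip(header, parts))
        mirna = normalize_mirna(row.get("mirna", ""))
        gene = row.get("gene", "").strip().upper()
        if not mirna or not gene:
            log.warning("mirna table line %d: missing miRNA or gene — skipped", lineno)
            continue
        try:
            species = int(row.get("species", HUMAN_TAXID) or HUMAN_TAXID)
        except ValueError:
            log.warning("mirna table line %d: bad species %r — skipped", lineno, row.get("species"))
            continue
        key = (mirna, gene)
        slot = merged.setdefault(
            key, {"method": "", "pmids": set(), "species": species, "strong": False}
        )
        method = row.get("method", "").strip()
        if "luciferase" in method.lower() or not slot["method"]:
            slot["method"] = method
        pmid = row.get("pmid", "").strip()
        if pmid:
            slot["pmids"].add(pmid)
        if row.get("strong_evidence", "").strip().lower() in {"1", "true", "yes"}:
            slot["strong"] = True
    return [
        MirnaTargetRecord(
            mirna_id=mirna,
            target_gene=gene,
            method=slot["method"],
            pmids=frozenset(slot["pmids"]),
            species=slot["species"],
            strong_evidence=slot["strong"],
        )
        for (mirna, gene), slot in sorted(merged.items())
    ]


def read_mapping_tsv(stream: Iterable[str]) -> dict[str, str]:
    """Symbol→accession mapping table (two tab-separated columns)."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            log.warning("mapping line %d: expected 2 columns — skipped", lineno)
            continue
        symbol, acc = parts[0].strip().upper(), normalize_accession(parts[1])
        if symbol.lower() == "symbol":
            continue  # header
        mapping[symbol] = acc
    return mapping


def filter_mirna_evidence(
    records: Iterable[MirnaTargetRecord],
    min_papers: int = 2,
    method_label: str = "luciferase",
    overrides: Mapping[str, int] | None = None,
) -> list[MirnaTargetRecord]:
    """Strong-evidence filter: human, method matches, enough distinct papers.

    ``overrides`` maps gene symbols to a *lower* per-gene paper threshold
    (e.g. ``{"APOE": 1}`` to accept a single-study claim); overrides can only
    relax the global threshold, never tighten it.
    """
    overrides = {g.upper(): v for g, v in (overrides or {}).items()}
    label = method_label.lower()
    kept = []
    for rec in records:
        if rec.species != HUMAN_TAXID:
            continue
        if label not in rec.method.lower():
            continue
        threshold = min(min_papers, overrides.get(rec.target_gene.upper(), min_papers))
        if rec.n_papers >= threshold:
            kept.append(rec)
    return kept


@dataclass(frozen=True)
class RegulatoryLayer:
    """Bipartite miRNA→module-node overlay."""

    edges: tuple[tuple[str, str], ...]  # (mirna_id, module node)
    regulated_fraction: float
    regulators_per_node: Mapping[str, int]
    targets_per_mirna: Mapping[str, int]

    @property
    def mirnas(self) -> set[str]:
        return {m for m, _ in self.edges}

    def multi_target_mirnas(self, min_targets: int = 2) -> dict[str, int]:
        """miRNAs hitting at least ``min_targets`` module nodes — the
        candidates whose mimics perturb several module members at once."""
        return {m: c for m, c in self.targets_per_mirna.items() if c >= min_targets}


def attach_regulators(
    net: Network,
    records: Iterable[MirnaTargetRecord],
    mapping: Mapping[str, str] | None = None,
) -> RegulatoryLayer:
    """Restrict filtered claims to module nodes and summarize the overlay.

    Gene symbols are translated through ``mapping`` (symbol→accession) when
    given; a target already matching a module node id is accepted directly.
    Unmappable targets are logged and skipped, never fatal.
    """
    mapping = {k.upper(): v for k, v in (mapping or {}).items()}
    module_nodes = set(net.nodes)
    edges: set[tuple[str, str]] = set()
    for rec in records:
        gene = rec.target_gene.upper()
        acc = mapping.get(gene, normalize_accession(gene))
        if acc not in module_nodes:
            log.info("miRNA target %s (%s) not in module — skipped", rec.target_gene, acc)
            continue
        edges.add((rec.mirna_id, acc))
    reg_per_node: dict[str, int] = {}
    targets_per_mirna: dict[str, int] = {}
    for mirna, node in sorted(edges):
        reg_per_node[node] = reg_per_node.get(node, 0) + 1
        targets_per_mirna[mirna] = targets_per_mirna.get(mirna, 0) + 1
    frac = len(reg_per_node) / net.n_nodes if net.n_nodes else 0.0
    return RegulatoryLayer(
        edges=tuple(sorted(edges)),
        regulated_fraction=frac,
        regulators_per_node=reg_per_node,
        targets_per_mirna=targets_per_mirna,
    )


def overlap_enrichment(
    layer_mirnas: set[str],
    literature_mirnas: set[str],
    background_n: int,
) -> ContingencyTable:
    """2x2 table for the overlap between network-derived and literature miRNAs.

    Cells: both / layer only / literature only / neither, against a background
    of ``background_n`` mature miRNAs.  Names are normalized before set
    algebra so prefix variants unify.
    """
    layer = {normalize_mirna(m) for m in layer_mirnas}
    lit = {normalize_mirna(m) for m in literature_mirnas}
    union = layer | lit
    if background_n < len(union):
        raise ValueError(
            f"background ({background_n}) smaller than the union of the two miRNA sets ({len(union)})"
        )
    a = len(layer & lit)
    b = len(layer - lit)
    c = len(lit - layer)
    d = background_n - a - b - c
    return ContingencyTable(a, b, c, d)


# ---------------------------------------------------------------------------
# exports


def write_layer_tsv(layer: RegulatoryLayer, stream: TextIO, header_comments: Iterable[str] = ()) -> None:
    """Gene → semicolon-joined regulator list, one row per regulated node."""
    for line in header_comments:
        stream.write(f"# {line}\n")
    by_gene: dict[str, list[str]] = {}
    for mirna, node in layer.edges:
        by_gene.setdefault(node, []).append(mirna)
    stream.write("gene\tmirnas\n")
    for gene in sorted(by_gene):
        stream.write(f"{gene}\t{'; '.join(sorted(by_gene[gene]))}\n")


def layer_to_graphml_network(net: Network, layer: RegulatoryLayer) -> Network:
    """Module plus diamond miRNA nodes, ready for GraphML export."""
    out = net.copy()
    for n in out.nodes:
        out.set_node_attr(n, "node_kind", "protein")
    for mirna, node in layer.edges:
        out.add_node(mirna, node_kind="mirna", shape="diamond")
        out.add_edge(mirna, node, edge_kind="regulation")
    return out
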