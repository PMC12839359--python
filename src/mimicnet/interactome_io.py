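"""Readers and filters for the three interaction-data dialects, plus the merge.

Three sources feed the disease module, each with its own filtering logic:

* PSI-MITAB 2.5 exports (IntAct style) — filtered on taxon (human, 9606),
  MI confidence score, and interaction-type controlled-vocabulary terms
  ("direct interaction", "physical association").
* STRING-like tables — two identifiers plus a combined score; the physical
  subnetwork is filtered at score >= 0.9 (0-1000 dialect auto-detected).
* BioGRID-like tables — no confidence score; an interactor pair survives if
  it is supported by at least two distinct publications reporting physical,
  low-throughput evidence.

The merge collapses everything to one edge per unordered accession pair,
tagging each edge with the set of databases that attest it.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, TextIO

from .graph_core import Network

log = logging.getLogger(__name__)

__all__ = [
    "InteractionRecord",
    "FilterPolicy",
    "normalize_accession",
    "read_mitab",
    "read_string_table",
    "read_biogrid_table",
    "merge_records",
    "write_edge_tsv",
]

DEFAULT_ALLOWED_TYPES = frozenset({"direct interaction", "physical association"})
# MI identifiers for the same two CV terms, accepted interchangeably
_MI_TYPE_IDS = {"mi:0407": "direct interaction", "mi:0915": "physical association"}


@dataclass(frozen=True)
class InteractionRecord:
    """One evidenced protein-protein interaction with provenance."""

    id_a: str
    id_b: str
    taxid_a: int
    taxid_b: int
    interaction_type: str = ""
    mi_score: float | None = None
    n_publications: int = 0
    detection_class: str = "unknown"  # low_throughput | high_throughput | unknown
    source_db: str = "other"  # intact | string | biogrid | other

    def __post_init__(self):
        if not self.id_a or not self.id_b:
            raise ValueError("interactor identifiers must be non-empty")
        if self.mi_score is not None and not (0.0 <= self.mi_score <= 1.0):
            raise ValueError(f"mi_score out of [0,1]: {self.mi_score}")

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.id_a, self.id_b)))  # type: ignore[return-value]


@dataclass
class FilterPolicy:
    """Per-database filter thresholds, defaulting to the stringent settings."""

    taxid: int = 9606
    min_mi_score: float = 0.65
    allowed_types: frozenset[str] = DEFAULT_ALLOWED_TYPES
    min_publications: int = 2
    require_low_throughput: bool = True
    string_min_score: float = 0.9

    def __post_init__(self):
        if not (0.0 <= self.min_mi_score <= 1.0):
            raise ValueError("min_mi_score must be in [0,1]")
        if not (0.0 <= self.string_min_score <= 1.0):
            raise ValueError("string_min_score must be in [0,1] (0-1000 inputs are rescaled)")
        if self.min_publications < 0:
            raise ValueError("min_publications must be >= 0")


_UNIPROT_ISOFORM = re.compile(r"^([OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9][A-Z][A-Z0-9]{2}[0-9])-\d+$")


def normalize_accession(raw: str) -> str:
    """Canonical node key: strip db prefix and UniProt isoform suffix, uppercase.

    ``"uniprotkb:P05067-2"`` → ``"P05067"``.  Cross-database merging needs a
    single key per gene product.  The suffix strip only fires on
    UniProt-shaped accessions, so dash-bearing identifiers from other
    namespaces stay intact.
    """
    acc = raw.strip()
    if ":" in acc:
        acc = acc.rsplit(":", 1)[1]
    acc = acc.upper()
    m = _UNIPROT_ISOFORM.match(acc)
    if m:
        acc = m.group(1)
    return acc


# ---------------------------------------------------------------------------
# PSI-MITAB 2.5

_TAXID = re.compile(r"taxid:(-?\d+)")
_MISCORE = re.compile(r"intact-miscore:([0-9.eE+-]+)")
_TYPE = re.compile(r'psi-mi:"?(MI:\d+)"?\(([^)]*)\)', re.IGNORECASE)

MITAB_COLUMNS = 15


def _parse_taxid(fieldval: str) -> int | None:
    """Single taxid from a MITAB organism field; None if absent or conflicting."""
    ids = {int(m) for m in _TAXID.findall(fieldval)}
    if len(ids) != 1:
        return None
    return ids.pop()


def _parse_type(fieldval: str) -> str:
    m = _TYPE.search(fieldval)
    if m:
        name = m.group(2).strip().lower()
        if name:
            return name
        return _MI_TYPE_IDS.get(m.group(1).lower(), m.group(1).lower())
    return fieldval.strip().lower()


def _type_allowed(label: str, allowed: frozenset[str]) -> bool:
    allowed_lc = {a.lower() for a in allowed}
    if label in allowed_lc:
        return True
    # accept the raw MI identifier as an alias for its CV name
    return _MI_TYPE_IDS.get(label, None) in allowed_lc


def read_mitab(stream: Iterable[str], policy: FilterPolicy) -> list[InteractionRecord]:
    """Parse a PSI-MITAB 2.5 stream, keeping rows that pass the policy.

    A row is kept iff both organisms are ``policy.taxid``, the intact-miscore
    is present and >= ``policy.min_mi_score``, and the interaction type is in
    ``policy.allowed_types`` (matched by CV name or MI identifier, case
    folded).  Malformed rows are skipped with a logged warning.
    """
    records: list[InteractionRecord] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < MITAB_COLUMNS:
            log.warning("mitab line %d: expected %d columns, got %d — skipped", lineno, MITAB_COLUMNS, len(cols))
            continue
        try:
            id_a = normalize_accession(cols[0])
            id_b = normalize_accession(cols[1])
            if not id_a or not id_b or id_a == "-" or id_b == "-":
                raise ValueError("empty interactor id")
        except ValueError as exc:
            log.warning("mitab line %d: %s — skipped", lineno, exc)
            continue
        tax_a = _parse_taxid(cols[9])
        tax_b = _parse_taxid(cols[10])
        if tax_a is None or tax_b is None:
            log.warning("mitab line %d: missing or conflicting taxon annotation — skipped", lineno)
            continue
        if tax_a != policy.taxid or tax_b != policy.taxid:
            continue
        m = _MISCORE.search(cols[14])
        if not m:
            # no parsable confidence: drop under any positive threshold
            if policy.min_mi_score > 0:
                log.warning("mitab line %d: no intact-miscore — dropped", lineno)
                continue
            score = None
        else:
            try:
                score = float(m.group(1))
            except ValueError:
                log.warning("mitab line %d: unparsable miscore %r — skipped", lineno, m.group(1))
                continue
            if score < policy.min_mi_score:
                continue
        type_label = _parse_type(cols[11])
        if not _type_allowed(type_label, policy.allowed_types):
            continue
        pmids = {p for p in re.findall(r"pubmed:(\S+)", cols[8])}
        records.append(
            InteractionRecord(
                id_a=id_a,
                id_b=id_b,
                taxid_a=tax_a,
                taxid_b=tax_b,
                interaction_type=type_label,
                mi_score=score,
                n_publications=len(pmids),
                source_db="intact",
            )
        )
    return records


# ---------------------------------------------------------------------------
# STRING-like tables


def read_string_table(
    stream: Iterable[str],
    policy: FilterPolicy,
    columns: tuple[str, str, str] = ("protein1", "protein2", "combined_score"),
) -> list[InteractionRecord]:
    """Read a STRING-style export, keeping rows at score >= string_min_score.

    The score dialect (0-1 or 0-1000) is auto-detected: any score > 1 marks
    the table as 0-1000 and all scores are divided by 1000.
    """
    rows: list[tuple[str, str, float]] = []
    header: list[str] | None = None
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = re.split(r"[\t ]+", line)
        if header is None:
            if all(c in parts for c in columns):
                header = parts
                continue
            header = list(columns)  # headerless: assume given order
        try:
            ia = parts[header.index(columns[0])]
            ib = parts[header.index(columns[1])]
            score = float(parts[header.index(columns[2])])
        except (ValueError, IndexError):
            log.warning("string line %d: unparsable row — skipped", lineno)
            continue
        rows.append((normalize_accession(ia), normalize_accession(ib), score))
    if not rows:
        return []
    scale = 1000.0 if max(s for _, _, s in rows) > 1.0 else 1.0
    records = []
    for ia, ib, score in rows:
        score /= scale
        if score >= policy.string_min_score:
            records.append(
                InteractionRecord(
                    id_a=ia,
                    id_b=ib,
                    taxid_a=policy.taxid,
                    taxid_b=policy.taxid,
                    interaction_type="physical association",
                    mi_score=min(score, 1.0),
                    source_db="string",
                )
            )
    return records


# ---------------------------------------------------------------------------
# BioGRID-like tables


def read_biogrid_table(
    stream: Iterable[str],
    policy: FilterPolicy,
    columns: tuple[str, str, str, str, str] = (
        "interactor_a",
        "interactor_b",
        "experimental_system_type",
        "throughput",
        "pmid",
    ),
) -> list[InteractionRecord]:
    """Read a BioGRID-style export; a pair survives with >= min_publications
    distinct PMIDs on physical, low-throughput rows."""
    header: list[str] | None = None
    support: dict[tuple[str, str], set[str]] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if header is None:
            if all(c in parts for c in columns):
                header = parts
                continue
            header = list(columns)
        try:
            ia = normalize_accession(parts[header.index(columns[0])])
            ib = normalize_accession(parts[header.index(columns[1])])
            systype = parts[header.index(columns[2])].strip().lower()
            throughput = parts[header.index(columns[3])].strip().lower()
            pmid = parts[header.index(columns[4])].strip()
        except (ValueError, IndexError):
            log.warning("biogrid line %d: unparsable row — skipped", lineno)
            continue
        if systype != "physical":
            continue
        if policy.require_low_throughput and "low" not in throughput:
            continue
        if not pmid:
            log.warning("biogrid line %d: missing publication id — row not counted", lineno)
            continue
        pair = tuple(sorted((ia, ib)))
        support.setdefault(pair, set()).add(pmid)
    records = []
    for (ia, ib), pmids in sorted(support.items()):
        if len(pmids) >= policy.min_publications:
            records.append(
                InteractionRecord(
                    id_a=ia,
                    id_b=ib,
                    taxid_a=policy.taxid,
                    taxid_b=policy.taxid,
                    interaction_type="physical association",
                    n_publications=len(pmids),
                    detection_class="low_throughput",
                    source_db="biogrid",
                )
            )
    return records


# ---------------------------------------------------------------------------
# merge


def merge_records(record_lists: Iterable[Iterable[InteractionRecord]]) -> Network:
    """Union of already-filtered records into one deduplicated Network.

    One edge per unordered accession pair; the edge attribute ``provenance``
    collects every contributing source database.
    """
    provenance: dict[tuple[str, str], set[str]] = {}
    for records in record_lists:
        for rec in records:
            if rec.id_a == rec.id_b:
                continue
            provenance.setdefault(rec.pair, set()).add(rec.source_db)
    net = Network()
    for (u, v), sources in sorted(provenance.items()):
        net.add_edge(u, v, provenance=frozenset(sources))
    return net


def write_edge_tsv(net: Network, stream: TextIO, header_comments: Iterable[str] = ()) -> None:
    for line in header_comments:
        stream.write(f"# {line}\n")
    stream.write("id_a\tid_b\tprovenance\n")
    for u, v in net.edges():
        prov = net.edge_attrs(u, v).get("provenance", frozenset())
        stream.write(f"{u}\t{v}\t{';'.join(sorted(prov))}\n")
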