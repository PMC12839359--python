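"""Seeded generators for every pipeline input, with planted ground truth.

The generator emits the same file formats the readers consume — PSI-MITAB
2.5 interaction rows, STRING-like and BioGRID-like tables, a miRNA evidence
table, a symbol↔accession mapping and a disease-gene list — built around a
planted topology whose key structures are known exactly:

* dense within-module cliques-with-noise around one designated hub per
  module (the hubs play the role of the disease seeds);
* bridge nodes, each the sole connector of two adjacent modules, carrying a
  pendant chain — so a bridge's removal always fragments the graph more than
  any other node's;
* pendant chains (peripheral by construction);
* low-score inter-module noise edges that no stringent filter should keep;
* a contaminant fraction of non-human rows.

Every stage of the pipeline can therefore be checked against the recorded
:class:`GroundTruth` with no external download.  All generators are pure
functions of their spec and seed: the same seed yields byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import nchypergeom_fisher

__all__ = [
    "SyntheticSpec",
    "MirnaPlan",
    "GroundTruth",
    "generate_interactome",
    "generate_string_table",
    "generate_biogrid_table",
    "generate_mirna_table",
    "generate_disease_list",
    "generate_bundle",
]

MOUSE_TAXID = 10090


@dataclass(frozen=True)
class MirnaPlan:
    """Shape of the synthetic regulator distribution.

    Mirrors what curated tables look like: most module nodes have no strong
    regulator, roughly a fifth have one to a few, and a handful are regulated
    by many miRNAs.  Methods mix reporter-assay and weaker labels; paper
    counts straddle the two-paper threshold.
    """

    fraction_regulated: float = 0.20
    n_many_regulated: int = 3
    many_range: tuple[int, int] = (5, 10)
    few_range: tuple[int, int] = (1, 3)
    luciferase_fraction: float = 0.7
    pmid_choices: tuple[int, ...] = (1, 2, 3)
    # shared pool of mature names, so some miRNAs hit several module genes
    # (multi-target regulators are the prime mimic candidates)
    pool_size: int = 40


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the planted interactome."""

    n_modules: int = 3
    module_sizes: tuple[int, ...] = (8, 8, 8)
    p_intra: float = 0.45
    n_bridges: int = 2
    gateways_per_side: int = 3
    pendant_chain_lengths: tuple[int, ...] = (1, 1)
    chain_attach: str = "bridge"  # "bridge" | "module"
    signal_score_range: tuple[float, float] = (0.70, 0.95)
    noise_score_range: tuple[float, float] = (0.20, 0.45)
    n_noise_edges: int = 10
    contaminant_taxa_fraction: float = 0.10
    mirna_plan: MirnaPlan = field(default_factory=MirnaPlan)
    planted_or: float = 15.0
    rng_seed: int = 0

    def __post_init__(self):
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes must have n_modules entries")
        if any(s < 2 for s in self.module_sizes):
            raise ValueError("module sizes must be >= 2")
        if not (0.0 <= self.p_intra <= 1.0):
            raise ValueError("p_intra must be in [0,1]")
        if not (0.0 <= self.contaminant_taxa_fraction < 1.0):
            raise ValueError("contaminant_taxa_fraction must be in [0,1)")
        if self.n_bridges > max(0, self.n_modules - 1):
            raise ValueError("n_bridges cannot exceed n_modules - 1 (bridges join adjacent modules)")
        if self.chain_attach not in ("bridge", "module"):
            raise ValueError("chain_attach must be 'bridge' or 'module'")
        if self.planted_or <= 0:
            raise ValueError("planted_or must be > 0")
        if self.rng_seed is None:
            raise ValueError("rng_seed is mandatory")


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream verification."""

    modules: dict[str, int]  # node -> module index
    hubs: list[str]  # designated seed hubs, one per module
    bridges: list[str]
    chain_nodes: list[str]
    signal_edges: list[tuple[str, str]]  # sorted pairs, human, high score
    noise_edges: list[tuple[str, str]]
    n_contaminant_rows: int
    role_labels: dict[str, str]  # planted truth: bridges bottleneck, chains peripheral
    mirna_survivors: list[tuple[str, str]] = field(default_factory=list)
    disease_overlap: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        d = asdict(self)
        d["signal_edges"] = [list(e) for e in self.signal_edges]
        d["noise_edges"] = [list(e) for e in self.noise_edges]
        d["mirna_survivors"] = [list(e) for e in self.mirna_survivors]
        return json.dumps(d, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# topology


def _planted_topology(spec: SyntheticSpec, rng: np.random.Generator, max_retries: int = 5):
    """Node names, signal edge list and ground-truth structures."""
    modules: dict[str, int] = {}
    hubs: list[str] = []
    members: list[list[str]] = []
    for i, size in enumerate(spec.module_sizes):
        hub = f"HUB{i + 1:02d}"
        mem = [f"M{i + 1:02d}N{j:02d}" for j in range(1, size)]
        hubs.append(hub)
        members.append([hub] + mem)
        for n in [hub] + mem:
            modules[n] = i

    for attempt in range(max_retries):
        edges: set[tuple[str, str]] = set()
        for i, mem in enumerate(members):
            hub = hubs[i]
            for n in mem[1:]:
                edges.add(tuple(sorted((hub, n))))
            for a_idx in range(1, len(mem)):
                for b_idx in range(a_idx + 1, len(mem)):
                    if rng.random() < spec.p_intra:
                        edges.add(tuple(sorted((mem[a_idx], mem[b_idx]))))
        # hub-spoke construction keeps each module connected by design
        break

    bridges: list[str] = []
    for k in range(spec.n_bridges):
        bridge = f"BRG{k + 1:02d}"
        bridges.append(bridge)
        modules[bridge] = -1
        for side in (k, k + 1):
            mem = members[side]
            n_gw = min(spec.gateways_per_side, len(mem))
            gateways = rng.choice(len(mem), size=n_gw, replace=False)
            for g in sorted(gateways):
                edges.add(tuple(sorted((bridge, mem[g]))))

    chain_nodes: list[str] = []
    for c, length in enumerate(spec.pendant_chain_lengths):
        if spec.chain_attach == "bridge" and bridges:
            anchor = bridges[c % len(bridges)]
        else:
            mod = int(rng.integers(spec.n_modules))
            anchor = members[mod][int(rng.integers(len(members[mod])))]
        prev = anchor
        for j in range(length):
            node = f"CHN{c + 1:02d}{chr(65 + j)}"
            chain_nodes.append(node)
            modules[node] = -2
            edges.add(tuple(sorted((prev, node))))
            prev = node

    all_nodes = sorted(modules)
    # noise: low-score edges between distinct modules (never through bridges/chains)
    noise: set[tuple[str, str]] = set()
    module_nodes = [n for n, m in modules.items() if m >= 0]
    guard = 0
    while len(noise) < spec.n_noise_edges and guard < 50 * (spec.n_noise_edges + 1):
        guard += 1
        u, v = rng.choice(len(module_nodes), size=2, replace=False)
        nu, nv = module_nodes[u], module_nodes[v]
        if modules[nu] == modules[nv]:
            continue
        pair = tuple(sorted((nu, nv)))
        if pair in edges:
            continue
        noise.add(pair)

    role_labels = {b: "bottleneck" for b in bridges}
    role_labels.update({c: "peripheral" for c in chain_nodes})
    gt = GroundTruth(
        modules=modules,
        hubs=hubs,
        bridges=bridges,
        chain_nodes=chain_nodes,
        signal_edges=sorted(edges),
        noise_edges=sorted(noise),
        n_contaminant_rows=0,
        role_labels=role_labels,
    )
    return all_nodes, gt


# ---------------------------------------------------------------------------
# MITAB emission

_DETECTION = ('psi-mi:"MI:0018"(two hybrid)', 'psi-mi:"MI:0006"(anti bait coip)', 'psi-mi:"MI:0096"(pull down)')
_TYPES = ('psi-mi:"MI:0407"(direct interaction)', 'psi-mi:"MI:0915"(physical association)')


def _mitab_row(
    id_a: str,
    id_b: str,
    taxid_a: int,
    taxid_b: int,
    score: float,
    itype: str,
    detection: str,
    pmid: int,
    idx: int,
) -> str:
    def tax(t: int) -> str:
        name = "human" if t == 9606 else "mouse"
        return f"taxid:{t}({name})"

    cols = [
        f"uniprotkb:{id_a}",
        f"uniprotkb:{id_b}",
        "-",
        "-",
        f"uniprotkb:{id_a.lower()}(display_short)",
        f"uniprotkb:{id_b.lower()}(display_short)",
        detection,
        "-",
        f"pubmed:{pmid}",
        tax(taxid_a),
        tax(taxid_b),
        itype,
        'psi-mi:"MI:0469"(IntAct)',
        f"intact:EBI-SYN{idx:06d}",
        f"intact-miscore:{score:.2f}",
    ]
    return "\t".join(cols)


def generate_interactome(spec: SyntheticSpec) -> tuple[list[str], GroundTruth]:
    """Emit PSI-MITAB 2.5 lines for the planted interactome.

    Signal edges carry human taxa and scores from ``signal_score_range``;
    noise edges carry low scores; a contaminant fraction of extra non-human
    rows is appended.  Rows are emitted in shuffled order so no reader can
    rely on emission order.  Returns (lines, ground truth).
    """
    seqs = np.random.SeedSequence(spec.rng_seed).spawn(4)
    rng_topo = np.random.default_rng(seqs[0])
    rng_score = np.random.default_rng(seqs[1])
    rng_contam = np.random.default_rng(seqs[2])
    rng_shuffle = np.random.default_rng(seqs[3])

    _, gt = _planted_topology(spec, rng_topo)

    rows: list[str] = []
    idx = 0
    lo, hi = spec.signal_score_range
    for u, v in gt.signal_edges:
        idx += 1
        rows.append(
            _mitab_row(
                u, v, 9606, 9606,
                float(rng_score.uniform(lo, hi)),
                _TYPES[int(rng_score.integers(len(_TYPES)))],
                _DETECTION[int(rng_score.integers(len(_DETECTION)))],
                int(rng_score.integers(10_000_000, 40_000_000)),
                idx,
            )
        )
    nlo, nhi = spec.noise_score_range
    for u, v in gt.noise_edges:
        idx += 1
        rows.append(
            _mitab_row(
                u, v, 9606, 9606,
                float(rng_score.uniform(nlo, nhi)),
                _TYPES[int(rng_score.integers(len(_TYPES)))],
                _DETECTION[int(rng_score.integers(len(_DETECTION)))],
                int(rng_score.integers(10_000_000, 40_000_000)),
                idx,
            )
        )

    n_base = len(rows)
    f = spec.contaminant_taxa_fraction
    n_contam = int(rng_contam.binomial(n_base, f / (1.0 - f))) if f > 0 else 0
    nodes = sorted(gt.modules)
    for k in range(n_contam):
        idx += 1
        u = nodes[int(rng_contam.integers(len(nodes)))]
        v = f"MUS{k + 1:04d}"
        rows.append(
            _mitab_row(
                u, v, 9606, MOUSE_TAXID,
                float(rng_contam.uniform(lo, hi)),
                _TYPES[int(rng_contam.integers(len(_TYPES)))],
                _DETECTION[int(rng_contam.integers(len(_DETECTION)))],
                int(rng_contam.integers(10_000_000, 40_000_000)),
                idx,
            )
        )
    gt.n_contaminant_rows = n_contam

    order = rng_shuffle.permutation(len(rows))
    return [rows[i] for i in order], gt


def generate_string_table(gt: GroundTruth, rng_seed: int, keep_fraction: float = 0.5) -> list[str]:
    """STRING-like export over a random subset of the signal edges (0-1000
    score dialect, all above the 0.9 cutoff) plus a few sub-threshold rows."""
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed).spawn(1)[0])
    lines = ["protein1 protein2 combined_score"]
    for u, v in gt.signal_edges:
        if rng.random() < keep_fraction:
            lines.append(f"{u} {v} {int(rng.integers(901, 1000))}")
        elif rng.random() < 0.2:
            lines.append(f"{u} {v} {int(rng.integers(150, 899))}")  # dropped by the filter
    return lines


def generate_biogrid_table(gt: GroundTruth, rng_seed: int, keep_fraction: float = 0.5) -> list[str]:
    """BioGRID-like export: surviving pairs get >= 2 distinct physical
    low-throughput PMIDs; decoy pairs get one PMID or high-throughput rows."""
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed).spawn(1)[0])
    lines = ["interactor_a\tinteractor_b\texperimental_system_type\tthroughput\tpmid"]
    for u, v in gt.signal_edges:
        r = rng.random()
        if r < keep_fraction:
            for _ in range(int(rng.integers(2, 4))):
                lines.append(f"{u}\t{v}\tphysical\tLow Throughput\t{int(rng.integers(10_000_000, 40_000_000))}")
        elif r < keep_fraction + 0.2:
            # insufficient support: one distinct PMID repeated, or HTP-only rows
            if rng.random() < 0.5:
                pmid = int(rng.integers(10_000_000, 40_000_000))
                lines.append(f"{u}\t{v}\tphysical\tLow Throughput\t{pmid}")
                lines.append(f"{u}\t{v}\tphysical\tLow Throughput\t{pmid}")
            else:
                for _ in range(3):
                    lines.append(f"{u}\t{v}\tphysical\tHigh Throughput\t{int(rng.integers(10_000_000, 40_000_000))}")
    return lines


# ---------------------------------------------------------------------------
# miRNA evidence


def generate_mirna_table(
    spec: SyntheticSpec, module_nodes: Sequence[str]
) -> tuple[list[str], list[str], GroundTruth | list[tuple[str, str]]]:
    """Synthetic miRNA evidence rows over ``module_nodes``.

    Returns (evidence TSV lines, mapping TSV lines, survivor list).  The
    survivor list records exactly which (miRNA, gene-symbol) claims pass the
    luciferase/two-paper filter, by generator bookkeeping.
    """
    if not module_nodes:
        raise ValueError("module_nodes must be non-empty")
    plan = spec.mirna_plan
    rng = np.random.default_rng(np.random.SeedSequence(spec.rng_seed).spawn(2)[1])

    nodes = sorted(module_nodes)
    n_reg = max(1, round(plan.fraction_regulated * len(nodes)))
    regulated = [nodes[i] for i in rng.choice(len(nodes), size=min(n_reg, len(nodes)), replace=False)]
    many = set(regulated[: plan.n_many_regulated])

    symbol_of = {node: f"SYM{node}" for node in nodes}
    mapping_lines = ["symbol\taccession"] + [f"{symbol_of[n]}\t{n}" for n in nodes]

    pool = [f"hsa-miR-{100 + i}-{'5p' if i % 2 else '3p'}" for i in range(plan.pool_size)]
    lines = ["mirna\tgene\tmethod\tpmid\tspecies"]
    survivors: list[tuple[str, str]] = []
    for node in sorted(regulated):
        lo_n, hi_n = plan.many_range if node in many else plan.few_range
        n_mirnas = min(int(rng.integers(lo_n, hi_n + 1)), len(pool))
        chosen = rng.choice(len(pool), size=n_mirnas, replace=False)
        for idx in sorted(chosen):
            mirna = pool[idx]
            luciferase = rng.random() < plan.luciferase_fraction
            method = "Luciferase reporter assay" if luciferase else ("Western blot" if rng.random() < 0.5 else "qRT-PCR")
            n_pmids = int(plan.pmid_choices[int(rng.integers(len(plan.pmid_choices)))])
            pmids = [str(int(rng.integers(10_000_000, 40_000_000))) for _ in range(n_pmids)]
            for p in pmids:
                lines.append(f"{mirna}\t{symbol_of[node]}\t{method}\t{p}\t9606")
            if luciferase and len(set(pmids)) >= 2:
                survivors.append((mirna.lower(), symbol_of[node]))
    return lines, mapping_lines, sorted(survivors)


# ---------------------------------------------------------------------------
# disease-gene list


def generate_disease_list(
    module_nodes: Sequence[str],
    background_n: int,
    planted_or: float,
    rng_seed: int,
    disease_n: int = 50,
    score_cutoff: float = 0.38,
    n_decoys: int = 10,
) -> tuple[list[str], list[str]]:
    """Disease-gene TSV with a planted module overlap.

    The overlap count is drawn from the Fisher noncentral hypergeometric at
    odds ``planted_or`` with margins (module size, ``disease_n``,
    ``background_n``).  Overlap genes and off-module disease genes receive
    association scores above ``score_cutoff``; ``n_decoys`` extra rows sit at
    or below the cutoff to exercise the strict inequality.  Returns
    (TSV lines, true overlap gene list).
    """
    nodes = sorted(module_nodes)
    m = len(nodes)
    if planted_or <= 0:
        raise ValueError("planted_or must be > 0")
    if disease_n > background_n or m > background_n:
        raise ValueError("margins exceed the background")
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed).spawn(3)[2])
    odds = min(planted_or, 1e6)
    k = int(nchypergeom_fisher(background_n, m, disease_n, odds).rvs(random_state=rng))
    overlap = [nodes[i] for i in rng.choice(m, size=k, replace=False)] if k else []

    lines = ["gene\tscore"]
    for g in sorted(overlap):
        lines.append(f"{g}\t{rng.uniform(score_cutoff + 0.02, 1.0):.3f}")
    for j in range(disease_n - k):
        lines.append(f"OT{j + 1:05d}\t{rng.uniform(score_cutoff + 0.02, 1.0):.3f}")
    non_overlap = [n for n in nodes if n not in set(overlap)]
    for j in range(n_decoys):
        if non_overlap and rng.random() < 0.5:
            g = non_overlap[int(rng.integers(len(non_overlap)))]
        else:
            g = f"DEC{j + 1:04d}"
        # exactly-at-cutoff rows included deliberately: strictly-greater filter must drop them
        score = score_cutoff if rng.random() < 0.3 else float(rng.uniform(0.05, score_cutoff))
        lines.append(f"{g}\t{score:.3f}")
    return lines, sorted(overlap)


# ---------------------------------------------------------------------------
# full bundle


def generate_bundle(spec: SyntheticSpec, outdir, background_n: int = 2000, disease_n: int = 50) -> GroundTruth:
    """Write every synthetic input file into ``outdir`` and the ground-truth
    sidecar next to them.  Returns the ground truth."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    mitab, gt = generate_interactome(spec)
    (out / "interactome.mitab").write_text("\n".join(mitab) + "\n")
    (out / "string.tsv").write_text("\n".join(generate_string_table(gt, spec.rng_seed)) + "\n")
    (out / "biogrid.tsv").write_text("\n".join(generate_biogrid_table(gt, spec.rng_seed)) + "\n")

    module_nodes = [n for n, m in gt.modules.items() if m >= 0]
    mirna_lines, mapping_lines, survivors = generate_mirna_table(spec, module_nodes)
    (out / "mirna_evidence.tsv").write_text("\n".join(mirna_lines) + "\n")
    (out / "symbol_mapping.tsv").write_text("\n".join(mapping_lines) + "\n")
    gt.mirna_survivors = survivors  # type: ignore[assignment]

    disease_lines, overlap = generate_disease_list(
        module_nodes, background_n=background_n, planted_or=spec.planted_or,
        rng_seed=spec.rng_seed, disease_n=disease_n,
    )
    (out / "disease_genes.tsv").write_text("\n".join(disease_lines) + "\n")
    gt.disease_overlap = overlap

    (out / "ground_truth.json").write_text(gt.to_json() + "\n")
    return gt
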