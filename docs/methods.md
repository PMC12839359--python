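# Methods

## Model and procedure

The package treats the interactome as a simple undirected graph: nodes are
gene products keyed by normalized accessions (database prefixes removed,
UniProt isoform suffixes stripped, uppercased, so `uniprotkb:P05067-2` and
`P05067` merge to one node), edges are experimentally supported physical
interactions with unit length. Self-loops and duplicate edges are collapsed
at construction with a logged count. All node iteration is in sorted
identifier order, which makes every report byte-stable across runs and
platforms.

The analysis proceeds in stages, each usable on its own:

1. **Source filtering.** Each interaction dialect has its own evidence
   model. MITAB records survive iff both organisms match the configured
   taxon (default 9606), the `intact-miscore` entry is present and at least
   the threshold, and the interaction-type CV term is allowed (default
   "direct interaction" and "physical association", matched by lowercased
   name or MI identifier — export dialects drift between the two). Records
   with multiple conflicting taxon annotations in one field are dropped and
   logged, as are rows with no parsable confidence score (conservative:
   absence of evidence is not high confidence). STRING-like tables are
   filtered at combined score >= 0.9, with the 0–1000 dialect auto-detected
   when any score exceeds 1. BioGRID-like tables have no score; an
   interactor pair survives with >= 2 *distinct* publication identifiers on
   physical, low-throughput rows — repeats of one PMID count once.
2. **Merge and module.** The merge keeps one edge per unordered accession
   pair and records the contributing databases in an edge `provenance`
   attribute; it is idempotent and order-independent. The disease module is
   the strict first-neighborhood of the seed set: every retained record
   touches at least one seed, and edges between two non-seed neighbors are
   excluded. Seeds with no surviving interaction stay as isolated nodes —
   they are the biological anchors of the analysis, not artifacts of the
   filter. Disease-gene annotation flags module nodes whose association
   score is strictly greater than the cutoff (default 0.38), so a gene
   sitting exactly at the cutoff is not flagged.
3. **Regulatory overlay.** miRNA evidence rows are merged per
   (miRNA, gene) pair by PMID union *before* thresholding, then filtered to
   human claims whose method label contains "luciferase" with >= 2 distinct
   papers. Per-gene overrides can only relax the paper threshold (the
   single-study exception pattern); mature names are normalized to
   lowercase with the `hsa-` prefix so prefix variants unify. Records
   lacking PMIDs but carrying a strong-evidence flag count as one paper —
   curated dialects differ, and the flag still gates acceptance.
4. **Topology and depletion.** Betweenness uses Brandes' accumulation with
   unordered pairs counted once; closeness is component-restricted;
   the mean shortest-path length averages over connected pairs only, and a
   network with no connected pair reports NaN, never 0. Depletion removes
   one node at a time, always from the pristine baseline (never
   cumulatively), and reports signed deltas. A depleted network with no
   connected pair yields an undefined path sentinel and a null delta.
5. **Enrichment.** The two-sided Fisher p sums, in log-gamma space, the
   central hypergeometric masses of all tables with the observed margins
   that are no more probable than the observed one, with a `1 + 1e-7`
   relative slack on the comparison — the convention of the classical exact
   test whose "< 2.2e-16" floor is widely quoted. p-values that underflow
   doubles are reported as a bound ("< 1e-300") alongside the always-finite
   log p. Both odds-ratio conventions are reported because published tables
   mix them: at the module margins used in the worked example the
   conditional MLE gives 14.29 while the raw cross-product rounds to 14.30.
   The cMLE solves `E_θ[a] = a_obs` by bracketed root finding on log θ
   (Brent, xtol 1e-10), with boundary tables mapped to 0 / ∞ and degenerate
   margins to NaN.

## Role classification

The underlying networks offer no sharp boundary between "bottleneck" and
"hub", so the rule is deliberately simple, rank-based and fully echoed into
the report header:

* **bottleneck** — degree and betweenness ranks both within the top
  fraction `f1` (default 0.10, competition ranking with ties sharing the
  best rank), *or* the node's |Δpath| is within the top `f1` and its
  removal fragments the graph (Δcomponents > 0). The magnitude is used
  because a true inter-module bridge typically *lowers* the mean path when
  removed: disconnecting the modules deletes the long cross-module pairs
  from the connected-pair average. Requiring fragmentation alongside the
  path signal (configurable) keeps locally disruptive but non-bridging
  nodes out of the bottleneck class.
* **peripheral** — degree <= `peripheral_degree` (default 3) and
  betweenness at or below the median.
* **local_hub** — everything else: well connected inside its neighborhood
  without bridging modules.

With the default thresholds, the classic qualitative picture emerges on
both the synthetic benchmarks (bridges → bottleneck, chain nodes →
peripheral) and on published human-interactome centrality/depletion tables
when re-scored by this rule (high-degree high-betweenness kinases as
bottlenecks, low-degree below-median proteins as peripheral, moderate
connectors as local hubs).

## What the synthetic generator emulates

`SyntheticSpec` defaults define the benchmark conditions: 3 modules of 8
nodes, intra-module edge probability 0.45 around one designated hub per
module (the hub plays the disease-seed role and guarantees module
connectivity), 2 bridge nodes each joining two adjacent modules through 3
gateway members per side, one length-1 pendant chain per bridge, 10
inter-module noise edges scored U(0.20, 0.45) against signal edges scored
U(0.70, 0.95), and a 10% contaminant fraction of non-human rows. Scores are
split so the stringent filter (0.65) recovers the signal edges exactly
while a permissive threshold admits noise — mirroring the
stringent-vs-permissive sensitivity comparisons done on real interactomes.

Attaching the pendant chains to the bridges is a deliberate structural
choice: it makes each bridge's removal produce strictly more fragments
(its two module sides plus its chain) than any chain interior, so planted
bridges are the unique argmax of Δcomponents and ground-truth recovery is
unambiguous. An elongated-branch preset (longer chains attached to module
members) reproduces the opposite signature — removal of a chain anchor
trims distal nodes and *shortens* the mean path — which is exercised by its
own test. The miRNA plan regulates ~20% of module nodes, draws regulator
names from a shared pool of 40 mature names (so some miRNAs hit several
module genes, the multi-target mimic candidates), mixes luciferase and
weaker assay labels 70/30, and spans paper counts 1–3 across the
two-paper threshold. The disease list draws its module overlap from the
Fisher noncentral hypergeometric at a planted odds ratio (default 15) and
places decoy rows at or below the 0.38 score cutoff to exercise the strict
inequality.

What the generator does *not* emulate: scale-free degree distributions and
the size of real interactomes, sequence-level miRNA-target matching,
correlated evidence across databases, or expression data. Passing the
planted-recovery batteries therefore demonstrates correctness of the
machinery (filters, metrics, estimators, bookkeeping), not biological
validity of any particular real-data conclusion — on real interactomes the
snapshot of the source databases dominates the numbers.

All generators are pure functions of an explicit seed; sub-generators
derive child seeds through `SeedSequence.spawn`, so adding a new generator
never perturbs earlier draws, and MITAB rows are emitted in shuffled order
to catch order-dependent parsing bugs.

## Numerical choices

* Betweenness, closeness, components: exact integer/rational-free BFS
  arithmetic in doubles; the acceptance battery bounds the deviation from
  exhaustive path enumeration below 1e-9 on 200 random graphs (observed
  ~4e-15).
* Fisher p: log-space only; enumeration agreement within 1e-12 in log p for
  every margin combination up to background 30.
* cMLE: bracket expansion on log θ with underflow guards at |log θ| > 745;
  agreement with an independent implementation within 1e-5 relative.
* Undefined averages (no connected pair) propagate as NaN and print as
  "NA"; deltas against an undefined baseline are NA, never 0.
* Depletion problem sizes: the synthetic batteries use ~30-node networks
  and 100 seeds, chosen so the full recovery suite and the acceptance
  script complete in seconds while keeping the planted-structure
  probabilities sharp.

## Known limitations

* Exact replication of published node/edge counts from live databases
  (e.g. a 156-node module or an 8865-node interactome) is out of scope:
  those depend on dated snapshots of IntAct/STRING/BioGRID/miRTarBase. The
  corresponding report layouts are produced and tested; the counts are not
  asserted.
* Identifier mapping is table-driven (symbol ↔ accession TSV); no live
  lookup. Unmapped targets are logged and skipped.
* Only single-node knockouts are modeled — no multi-node attacks, edge
  removals or percolation curves.
* Centralities are unweighted; MITAB 2.6/2.7 extended columns and directed
  or weighted graphs are not supported.
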