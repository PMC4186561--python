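# Methods

## Model

The object of study is a typed directed multigraph over two node classes,
genes and miRNAs, with three edge types:

* `TARGETS` (miRNA → gene): the miRNA binds the gene's transcript and
  silences or degrades it;
* `REGULATES` (gene → miRNA): a transcription factor activates or
  represses transcription of the miRNA gene;
* `HOSTS` (gene → miRNA): the miRNA is encoded in the gene's locus and
  the two are co-transcribed.

The *validated* network is the union of all curated relations of the
three types. Two overlay networks are induced from it by node-set
mapping: the *differential* network from the differentially expressed
gene/miRNA sets and the *associated* network from the (larger)
disease-associated sets. Because the differential sets are contained in
the associated sets, the three networks form a chain
differential ⊆ associated ⊆ validated, edge-wise and (host genes aside)
node-wise; `validate_layering` checks this invariant and the comparison
report is only defined when it holds.

### Edge-retention rules

The mapping step is deliberately simple and fully specified:

* `TARGETS`/`REGULATES`: retained iff **both** endpoints belong to the
  level's gene and miRNA sets. This both-endpoint induction is the
  reading consistent with the shipped per-node tables (e.g. the
  hsa-miR-222 → PTEN edge is present at the associated level but absent
  at the differential level, tracking miR-222's membership).
* `HOSTS`: retained iff the **miRNA** endpoint is in the level's miRNA
  set. Host genes are admitted regardless of their own expression status
  and flagged `host_gene` — a host is pulled into a layer by its miRNA,
  not by its own membership (non-differential hosts of differential
  miRNAs are a real and biologically meaningful case).
* Level members with no retained edge are kept as isolated nodes by
  default (`keep_singletons=True`); figure-style exports can drop them.
  Both behaviors are tested.

A gene that is simultaneously a TF, a target and/or a host is one node
with several roles, never duplicated. A symbol used as both a gene and a
miRNA is a hard consistency error listing all offenders.

Predicted TFs from the promoter scan join the gene sets at the
**associated** level. One shipped fixture (the E2F3 table) places a
predicted TF in its differential-layer gene list, because the published
table it transcribes reports differential-layer neighbors for that TF
even though the TF itself is not differentially expressed; the fixtures
are therefore self-contained per table rather than one global network
(their published sources are mutually inconsistent under any single
induced-subgraph rule — the hsa-miR-20a → E2F3 edge appears in one
table's differential column and is absent from another's).

### Self-adaptation associations

Operationalized as the heterotyped 2-cycle: gene g and miRNA m form a
loop in a network iff that network contains both m →`TARGETS`→ g and
g →`REGULATES`→ m. Every named published instance fits this definition.
`HOSTS` edges are excluded from loop detection and from
predecessor/successor lists (the published tables list only regulatory
neighbors); hosting relations are reported in a separate table section.
Loop detection is tested against a brute-force double loop over all
(gene, miRNA) pairs; by layering, loop lists of a lower layer are subsets
of the layer above.

## Identifier normalization

Gene symbols are upper-cased and resolved through an optional alias map
(two-column TSV); unknown symbols pass through upper-cased with a logged
warning rather than being dropped, since dropping would silently shrink
the networks. miRNA names are canonicalized to
`<organism>-<miR|let>-<suffix>` with the suffix lower-cased
("miR-19a" → "hsa-miR-19a"); paralog suffixes (-1, -2) are distinct
identities, and an optional expansion map sends family names to their
paralogs (hsa-miR-125b → hsa-miR-125b-1, -2). Both normalizers are
idempotent (property-tested under fuzzing). Alias and expansion tables
are external config files, not hard-coded, so curation choices stay
visible and testable.

## PWM scanning

The scanner is a Match-style core/matrix-similarity implementation:

* **Frequencies**: counts + 0.25 pseudocount per cell, row-normalized.
  The pseudocount is small and symmetric and avoids log 0.
* **Information vector**: `I(i) = Σ_b f(i,b) ln(4 f(i,b))` (nats);
  0 for a uniform column, → ln 4 for a fully conserved one.
* **Window score**: `(Current − Min)/(Max − Min)` with
  `Current = Σ_i I(i) f(i, w_i)` and Max/Min using the best/worst base
  per position. The consensus scores exactly 1.0 and the anti-consensus
  0.0. If Max = Min (e.g. a fully uniform matrix) every window scores
  1.0 — the window is vacuously optimal; documented and tested.
* **Core filter**: the core is the contiguous 5-position window of
  maximum summed information, ties broken leftmost. A candidate offset
  must pass the core threshold before the full matrix is scored.
* **Coordinates**: 0-based forward-strand offsets, half-open intervals;
  a minus-strand hit is reported at the forward-strand start of its
  reverse-complement match, so scanning a sequence and its reverse
  complement give mirror-image hit sets (property-tested).
* **N handling**: `N` scores as the worst base at its position
  (conservative: it can only lower a score).
* **Threshold profiles**: high (core 0.95 / matrix 0.95, the default for
  TF prediction), medium (0.90 / 0.85), low (0.80 / 0.75). These are
  this package's stringency presets — they are not calibrated to any
  external scanner's thresholds and must not be read as equivalents.

Raising either threshold never adds a hit (monotonicity is tested).
Predicted TFs are intersected with the TF whitelist (sources of U2),
because only TFs with known TF → miRNA relations can be wired into the
network.

TRANSFAC flat files are parsed via Biopython's motif parser, wrapped to
enforce the `//` block terminator and to report the offending matrix ID
on malformed blocks.

## Synthetic data

The generator emulates the *relational structure* of the five datasets,
not their biology:

* TARGETS and REGULATES relations drawn i.i.d. per pair (defaults: 60
  genes of which 10 TFs and 12 hosts, 40 miRNAs, density 0.05) — sized
  like the study's differential network (tens of nodes) so derived
  overlays are small but non-trivial;
* HOSTS relations at density 0.08, patched so at least one host carries
  two miRNAs and one miRNA has two hosts whenever feasible;
* node sets sampled at frac_differential = 0.4 inside
  frac_associated = 0.7 (containment by construction);
* a configurable number of mutual-regulation 2-cycles planted on
  (TF, miRNA) pairs and recorded; planted-loop endpoints are forced into
  the differential sets so loops are recoverable at every layer;
* promoters: 1,000-nt i.i.d. uniform A/C/G/T backgrounds with consensus
  sites planted at a configurable rate (position, strand recorded).

All generators are pure functions of (config, seed): identical seeds
give byte-identical files. The uniform promoter background and i.i.d.
edge draws are *not* biological — real promoters have GC structure and
real networks heavy-tailed degrees — so passing tests demonstrate
correctness of the machinery (exact recovery of planted structure,
containment, determinism), not performance on genomic sequence.

## Numerical and formatting choices

* All emitted files are sorted (edges lexicographically by
  (etype, source, target); node lists lexicographically) so re-runs are
  byte-identical; the run manifest additionally records input paths,
  which may differ between otherwise identical runs.
* Duplicate relations from multiple source tables collapse to one edge
  with merged provenance.
* Scanning is vectorized over offsets (stride tricks over the encoded
  sequence), keeping the 100-promoter property suites fast; scores are
  float64 throughout.
* Degenerate inputs: empty relation sets give empty networks; a
  sequence shorter than a matrix warns and returns no hits; an empty
  differential set gives an empty (or singleton-only) differential
  network.

## Known limitations

* The published global network sizes depend on 2014-era database
  snapshots and curated disease lists that were never deposited; the
  packaged fixtures cover the published per-node tables, and everything
  else is validated on synthetic data.
* One published table's associated/validated successor columns disagree
  with the running text's counts (16/29 printed vs 14/26 in text); the
  fixtures transcribe the printed columns and no claim is made for
  those two cells.
* The scanner is a faithful Match-style implementation, not a clone of
  any proprietary tool; with public count matrices its scores will not
  numerically match scanners built on licensed matrix libraries.
* Only length-2 cycles are detected; longer feedback structures, motif
  enrichment and pathway annotation are out of scope.
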