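# mirtfnet

Regulatory networks of transcription factors (TFs), microRNAs (miRNAs),
miRNA targets and miRNA host genes, built and compared in three layers.
The package was written for the diffuse large B-cell lymphoma (DLBCL)
setting — where curated differential-expression and disease-association
gene/miRNA lists are mapped onto experimentally validated regulatory
relations — but nothing in it is disease-specific.

## What it computes

The inputs are five datasets:

* **U1** — experimentally validated miRNA → target relations
  (`TARGETS` edges),
* **U2** — validated TF → miRNA relations (`REGULATES` edges),
* **U3** — host-gene → intronic-miRNA relations (`HOSTS` edges),
* **U4** — gene sets: differentially expressed ⊆ disease-associated,
* **U5** — miRNA sets, same two-level structure.

From these the package constructs:

1. the **experimentally validated network**: the union of all relations in
   U1 ∪ U2 ∪ U3 over gene and miRNA nodes;
2. the **differential expression network** and the **disease-associated
   network**: overlay subnetworks induced by mapping the U4/U5 node sets
   onto the validated network.  A `TARGETS` or `REGULATES` edge survives
   iff *both* endpoints are in the level's sets; a `HOSTS` edge is keyed
   on its miRNA only, so a non-differential host gene of a differential
   miRNA stays in the network (flagged `host_gene`).

On top of the three layers it extracts:

* **predecessor/successor tables** per node (who regulates it, whom it
  regulates, in each network),
* **self-adaptation associations**: mutual-regulation pairs where a miRNA
  targets a gene that regulates that miRNA back (heterotyped 2-cycles of
  one `TARGETS` plus one `REGULATES` edge),
* **host-gene features** (hosts encoding several miRNAs, miRNAs encoded in
  several hosts), and
* a **cross-layer comparison report** (edge counts, edges gained per
  layer, nodes whose neighborhoods change).

TFs can also be *predicted* from sequence: 1,000-nt promoter regions are
scanned with TRANSFAC-format position weight matrices using Match-style
scoring — per-position information `I(i) = Σ_b f(i,b) ln(4 f(i,b))`,
min-max-normalized window score `(Current − Min)/(Max − Min)`, a
high-information 5-position core filter before the full-matrix score —
and predicted TFs present in U2 are injected into the associated gene set.

A synthetic-data generator emits all five datasets plus promoters with
planted binding sites and planted feedback loops, with full ground truth,
so the whole pipeline is testable without any database download.

## Worked example

The package ships fixtures transcribing published per-node neighbor
tables. Reproducing the PTEN table:

```python
import mirtfnet as m

fx = m.load_table_fixture("pten")
table = m.neighbor_table("PTEN", fx.differential, fx.associated, fx.validated)
print(table.in_degree("differential", "TARGETS"),
      table.in_degree("associated", "TARGETS"),
      table.in_degree("validated", "TARGETS"))
# 7 8 21
print(table.out_degree("validated", "REGULATES"))
# 9
loops = m.find_self_adaptation(fx.differential, scope="PTEN")
print([(l.gene, l.mirna) for l in loops])
# [('PTEN', 'hsa-miR-19a'), ('PTEN', 'hsa-miR-21')]
```

Reading: 7 differentially expressed miRNAs target PTEN and PTEN regulates
3 of them in the differential network; 8 and 21 miRNAs target it in the
associated and validated networks; PTEN regulates 9 miRNAs in the
validated network; and hsa-miR-19a and hsa-miR-21 each both target PTEN
and are regulated by it — two self-adaptation feedback loops.

The same workflow from the shell, on synthetic data:

```bash
mirtfnet simulate --out syn --seed 4
mirtfnet build --u1 syn/u1.tsv --u2 syn/u2.tsv --u3 syn/u3.tsv \
  --u4-diff syn/u4_differential.txt --u4-assoc syn/u4_associated.txt \
  --u5-diff syn/u5_differential.txt --u5-assoc syn/u5_associated.txt \
  --out nets
```

which prints the node/edge counts of the three networks and writes them
as SIF and GraphML.

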