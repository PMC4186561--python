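# Packaged neighbor-table fixtures

Each subdirectory transcribes one published per-node neighbor table of the
DLBCL three-network study into the pipeline's input formats: `u1.tsv`
(miRNA -> target relations), `u2.tsv` (TF -> miRNA relations), `u3.tsv`
(host relations; empty for these nodes) plus the four node-set files.
Deriving the differential and associated overlays from these inputs
reproduces the table's six columns exactly.

- `pten/` — the miRNAs targeting and regulated by the tumor suppressor
  PTEN (7/8/21 predecessors and 3/3/9 successors across the differential,
  associated and validated networks).
- `mir20a/` — the genes regulating and targeted by hsa-miR-20a.
  Note: the published associated/validated *successor* columns contain 16
  and 29 entries as printed, whereas the running text counts 14 and 26
  targeted genes; the fixtures transcribe the printed columns, and the
  text-vs-column discrepancy for those two cells is left as-is.
- `e2f3/` — the miRNAs targeting and regulated by the predicted
  transcription factor E2F3.  E2F3 itself is not differentially expressed;
  it is a predicted TF admitted to the differential layer, so it appears
  in `genes_differential.txt` for this fixture.

Each fixture is self-contained: node sets list only the members relevant
to its table, so fixtures are not mutually consistent as one global
network and should be loaded one at a time (`mirtfnet.load_table_fixture`).
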