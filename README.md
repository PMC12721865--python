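# synsieve

Quality control for neighbourhood-scale synteny plots.

Comparative analyses of biosynthetic gene clusters (BGCs) and other gene
neighbourhoods usually end in a synteny plot: one track per genomic region,
genes as arrows, links joining homologous genes. Homology searches such as
cblaster routinely return hundreds of hit regions, but most are
near-identical (same strain resequenced, duplicated database entries), which
makes the plot uninformative and often exceeds what plotting tools accept at
all. `synsieve` closes that gap with two stages:

* **collect** — parse a cblaster "binary" hit table, centre a fixed-length
  span on each hit interval, reject hits that are *dispersed* (hit interval
  longer than the requested span, i.e. not genuinely clustered) or *small*
  (span overhangs a fragmented contig), slice the source record and write
  one GenBank file per surviving neighbourhood, named by accession or
  organism so downstream plotting tools can label tracks automatically.
* **sieve** — remove redundant neighbourhoods from any folder of GenBank
  files. For every pair of neighbourhoods *A*, *B* the similarity is

  ```
  s(A, B) = |RBH(A, B)| / min(|genes(A)|, |genes(B)|)
  ```

  where RBH(A, B) is the set of reciprocal best hits from an all-vs-all
  protein comparison (a gene pair (a, b) with b the best-scoring match of a
  in B *and* a the best-scoring match of b in A). Similarity is
  non-transitive — A may resemble B and B resemble C while A and C differ —
  so redundancy removal operates on a graph: nodes are neighbourhoods,
  edges join pairs whose similarity strictly exceeds the threshold
  (default 0.7), and nodes are deleted greedily by maximum degree until no
  edge remains. Survivors are copied byte-identically; a diagnostic
  interactive graph HTML and a histogram of all non-zero pairwise scores
  help tune the threshold.

## Worked example

Generate a synthetic set of four neighbourhoods — three near-identical
copies carrying the same five protein families and one unrelated
neighbourhood — and sieve it:

```bash
python -c "from synsieve import build_neighbourhood_set, default_family_spec; \
           build_neighbourhood_set(default_family_spec(seed=7), 'demo/neighbourhoods')"
synsieve sieve -gf demo/neighbourhoods -sf 0.7 -o demo/sieved
```

which logs `INFO  sieve  kept 2 of 4 neighbourhoods` and writes:

```
demo/sieved/kept/copy_a.gbk      demo/sieved/kept/outsider.gbk
demo/sieved/sieve_report.csv     demo/sieved/edge_weights.csv
demo/sieved/neighbourhood_graph.html   demo/sieved/edge_histogram.png
```

`sieve_report.csv` records the pruning order and why each neighbourhood
fell:

```
label,outcome,trigger_neighbour,degree_at_removal
copy_a,kept,,
outsider,kept,,
copy_c,removed,copy_a,2
copy_b,removed,copy_a,1
```

The three copies score 1.0 against each other (`edge_weights.csv`), so two
of them are pruned; the unrelated neighbourhood shares no reciprocal best
hits and survives untouched. The collect stage works the same way from a
hit table; with `--fetcher fixtures:<dir>` it resolves accessions from a
local folder instead of NCBI, which is how the test suite runs offline.

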