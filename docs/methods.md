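# Methods

## The problem

A homology search for a gene cluster (e.g. with cblaster) returns hit
*records* — genomes or contigs containing a user-defined number of
clustered hits to the query proteins. Turning those into a readable
synteny plot needs two curation steps: extracting a comparable,
fixed-length neighbourhood around each set of hits, and removing the
near-duplicate neighbourhoods that dominate public databases. `synsieve`
implements both, with gene content rather than nucleotide identity as the
similarity currency, so that short or fragmented contigs — where
genome-level metrics such as ANI degrade — are still scored sensibly.

## Coordinates and gene model

All internal coordinates are 0-based half-open; the 1-based inclusive
conventions of GenBank flat files and cblaster tables are converted once,
at the I/O boundary. Only CDS features become genes: the similarity score
is built on protein alignments, so RNA genes and pseudo-features carry no
signal for it. A CDS without a `/translation` qualifier is translated from
its span with translation table 11 when the span is a codon multiple,
otherwise skipped with a warning; trailing stop symbols are stripped to
normalise GenBank dialects. Compound (joined) locations keep their
outermost span as coordinates — preserving plot geometry — but are
translated from the joined exons. Genes are ordered by start, then end,
then id, so parsed gene tables never depend on feature order on disk.

## Collect

For each table row the hit interval `[hit_start, hit_end)` is tested and
centred:

* **dispersed** — `hit_end − hit_start > L` (neighbourhood length `L`):
  the hits are not clustered within the requested span; rejected before
  any record is fetched.
* otherwise `mid = ⌊(hit_start + hit_end)/2⌋`, span
  `[mid − ⌊L/2⌋, mid − ⌊L/2⌋ + L)`. Floor is used for both midpoint and
  half-length so even-length inputs are handled deterministically.
* **small** — the span overhangs the contig. In `--strict` mode the row is
  rejected (fragmented contig); otherwise the span is clamped to the
  contig, provided the clamped span still covers the whole hit interval —
  if clamping would clip the hits themselves the row is rejected anyway.

The fetched record is sliced to the span: CDS fully inside are kept with
coordinates shifted by −start, features straddling a boundary are dropped
and logged (a truncated gene would align as a spurious partial homolog).
Files are named from the sanitized accession or organism
(characters outside `[A-Za-z0-9._-]` → `_`, runs collapsed, ends
stripped), with `_1`, `_2`… suffixes on collision. Every parsed row lands
in exactly one of written / rejected-dispersed / rejected-small /
fetch-failure; the partition is asserted on every run and written to
`collect_report.csv`.

The record source is an injected contract: the production fetcher calls
NCBI Entrez efetch (`gbwithparts`, ≤3 retries with exponential backoff,
contact e-mail required), and a fixture fetcher resolves accessions from a
local folder, so no test or offline run ever touches the network. A record
whose LOCUS length disagrees with its sequence length is reported as
malformed rather than silently sliced.

## Protein comparison and reciprocal best hits

All genes of all neighbourhoods are compared all-vs-all through an
alignment-engine contract. Engines receive a FASTA of every protein
(headers `label::gene_id`) and return tabular hits
(qseqid, sseqid, pident, evalue, bitscore); both files are kept in the run
folder for audit.

* **builtin** (default): Smith–Waterman with BLOSUM62 and BLAST-style gap
  costs (open 11, extend 1 — a length-k gap costs 11 + k). Bitscores use
  the Karlin–Altschul gapped constants for that scheme (λ = 0.267,
  K = 0.041); e-values are computed against the concatenated subject-set
  size, mirroring a database search. Fully deterministic, no external
  binary.
* **blast** / **diamond**: NCBI `blastp` and DIAMOND `blastp`
  (`--very-sensitive`), one best HSP per pair. On low-divergence fixtures
  all engines produce identical RBH matchings (asserted in the tests, with
  the builtin engine cross-checked against `blastp`); bitscores may differ.

Hits are filtered to e-value ≤ 1e-5 and identity ≥ 50% (conventional
homology-screen defaults, both exposed as flags), and within-neighbourhood
comparisons are excluded — paralogs still participate against other
neighbourhoods like any gene. Best hits per direction break ties by
bitscore, then identity, then lexicographically smallest subject id, so
the RBH matching is unique and independent of input order. Reciprocity
makes it a partial matching: no gene appears in two pairs.

## Similarity and pruning

`s(A,B) = |RBH| / min(|genes A|, |genes B|)` lies in [0, 1]; identical
gene content gives 1, no shared homologs gives 0. Pairs scoring *strictly*
above the threshold (default 0.7; "exceeds" is read as `>`) become edges
of the similarity graph. Pruning repeatedly deletes the node with maximal
degree — ties by larger incident-weight sum, then lexicographically
largest label — until the graph is edgeless. This greedy
minimum-vertex-cover heuristic guarantees that no surviving pair exceeds
the threshold while preferentially deleting the most redundant
neighbourhoods, and the full tie ordering makes the kept set deterministic
and independent of file enumeration order. Because the postcondition is
"edgeless", sieving is idempotent, and the non-transitive chain
a–b–c (s(a,b)=s(b,c)=0.9, s(a,c)=0.1) correctly keeps {a, c} rather than
collapsing to one representative. The reported *trigger neighbour* of a
removed node is its heaviest remaining neighbour at removal time (ties to
the smallest label).

Survivors are copied byte-identically — sieve filters, it never rewrites
data. Raising the threshold can only delete edges, so the kept count is
monotone non-decreasing in the threshold.

## Diagnostics

The interactive HTML view embeds the full node/edge data as a JSON block
and renders the *supra-threshold* graph (the structure pruning acted on),
with kept/removed styling and organism tooltips, so redundancy can be
compared with host diversity per sub-network. The histogram instead shows
**all** non-zero pairwise scores in 20 fixed-width bins over (0, 1] with
the active threshold marked: it is the threshold-tuning diagnostic, and
restricting it to supra-threshold edges would hide exactly the scores a
new threshold would act on. Bin counts are also written as CSV and always
sum to the number of non-zero scores.

## Synthetic data

The fixture generator builds neighbourhoods from *protein families*:
uniform-random ancestral proteins (≥30 residues — shorter sequences make
local-alignment behaviour unstable) that each planned neighbourhood
carries as an independently mutated copy (per-residue substitution to a
different residue, default rate 0.02 ≈ 98% identity, typical of
same-species strain divergence). At such low divergence best hits are
unambiguous, so the expected RBH count of a pair is exactly the number of
shared families and the expected similarity is shared / min gene count —
recorded in `manifest.json` and recovered exactly by the pipeline in the
tests. Nucleotides are back-translated with a fixed codon per residue
(lexicographically first table-11 codon) and genes laid head-to-tail with
50 nt spacers, so regeneration under a seed is byte-identical.

What the generator does **not** emulate: indels, rearrangements, codon
usage, overlapping genes, paralog expansions and annotation noise. Passing
tests therefore demonstrate the correctness of the scoring and pruning
machinery under controlled homology, not recall on real, messy assemblies;
on real data the alignment thresholds and the similarity threshold remain
the user's scientific choices.

## Problem sizes and defaults

The test suite and the acceptance script run on 4–5 neighbourhood sets of
3–6 genes (80–120 residues each), 200 random score matrices with up to 15
nodes, 1000 random graphs with up to 7 nodes for the pruning
cross-check, and 100 random round-trip neighbourhoods — sizes at which
the greedy pruning reference and brute-force alignment stay exact oracles.
Defaults: neighbourhood naming by accession, similarity threshold 0.7,
e-value 1e-5, identity 50%, builtin engine, non-strict span clamping.

## Known limitations

* The pruning heuristic is greedy; it guarantees the threshold
  postcondition, not a maximum-cardinality kept set.
* High internal homology (many paralogs of one family inside a
  neighbourhood) weakens the RBH count as a content measure, since the
  matching pairs each gene at most once.
* The builtin engine's e-values are analytic approximations; they are used
  for filtering only, and matchings — not scores — are the contract shared
  across engines.
* Multi-record GenBank files, EMBL/GFF input and nucleotide-level
  similarity are out of scope.
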