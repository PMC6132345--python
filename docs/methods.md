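# Methods

## Detection model

The unit of evidence is a *chimeric junction record*: one supporting read
whose two segments align to discontiguous loci. Records carry the donor and
acceptor coordinates and strands (1-based), a junction-type code (−1
encompassing, 0 no splice motif, 1 GT/AG, 2 CT/AC), and the left/right
flanking repeat lengths — the number of identical bases on either side of
the junction, a proxy for alignment ambiguity.

Filtering is a conjunction of three per-record predicates, applied before
any grouping:

* **mitochondrial** — either end on an excluded chromosome
  (default `{chrM, MT}`); rRNA/mtRNA chimeras are overwhelmingly artifacts;
* **canonical motif** — junction type in `{1, 2}`. "Canonical" is used in
  the splice-vocabulary sense (GT/AG or its reverse complement);
  encompassing (−1) and motif-less (0) records are excluded by default and
  both choices are exposed in `FilterConfig`;
* **repeat length** — `max(repeat_left, repeat_right) < 5` nt. The bound is
  exclusive and applies to the longer side: if either flank is ambiguous
  the breakpoint coordinate is not trustworthy. A single rejected record is
  logged with the *first* failing rule in the fixed order
  mito → motif → repeat; the kept set is order-independent.

Replicates are pooled without read-name deduplication (exact duplicate
(replicate, read, junction) triples collapse with a warning). Fusion
identity is the exact junction 6-tuple — no breakpoint-window clustering —
because biologically distinct events can share one side (the fixture's two
events share their chr16 acceptor while differing on chr6). Support is the
number of *distinct read names* across the pooled replicates, which guards
against double-reported alignments; events with support < 10 are dropped.
Events are ordered by support descending, ties broken lexicographically by
junction key, so output order is total and reproducible.

The thresholds (min support 10, repeat bound 5, canonical types {1,2},
mitochondrial exclusion) are the defaults of `FilterConfig`; all are
user-settable.

## Breakpoint annotation

Gene models are read from GTF (1-based inclusive). Exon numbers are always
recomputed in transcription order — exon 1 of a minus-strand gene has the
highest coordinates — regardless of any `exon_number` attribute, so files
listing exons in ascending coordinate order are handled uniformly. Introns
are the gaps between consecutive exons; intron *k* separates exons *k* and
*k*+1. Each gene is represented by its *canonical* transcript: longest
total CDS, ties broken lexicographically by transcript id (a deterministic
stand-in for curated canonical flags).

A position inside an exon is classified `UTR5`/`UTR3` when it falls outside
the CDS genomic extent, otherwise `EXON`; UTR therefore takes precedence
over EXON inside a terminal coding exon, which is what makes a breakpoint
beyond the stop codon report `UTR3` even though it lies in exon 8. A
position equal to an intron-adjacent exon edge is flagged
`at_splice_boundary` (distance 0); transcript termini are not splice
boundaries. Positions in no gene are `INTERGENIC`; unknown chromosomes log
a warning rather than fail, because junction files routinely mention
contigs absent from a mini-annotation.

Partner orientation: the donor end is taken as the 5' partner and the
acceptor as the 3' partner; when an end lies in a gene whose strand
disagrees with the record strand at that end, the event is flagged
unresolved (annotations are kept). Ends in no gene cannot be checked and
default to donor = 5'.

Breakpoint coordinates are compared for exact equality with exon
boundaries; no normalisation between "last exonic base" and "first
intronic base" conventions is attempted. The fixture adopts the same
convention, so a pipeline bug of ±1 in coordinate handling fails the
boundary tests.

## Fusion product reconstruction

A spliced fusion transcript is the exon prefix 1..k of the 5' gene
followed by the exon suffix m..last of the 3' gene. Frame status uses
codon-phase arithmetic on CDS extents taken from the GTF:

    IN_FRAME  ⇔  L_CDS(exons 1..k)  ≡  L_CDS(exons 1..m−1 of 3' gene)  (mod 3)

with `NONCODING_JUNCTION` when the junction lies outside either CDS (5'
prefix entirely untranslated, 5' junction exon ending past the stop codon,
or no CDS remaining in the 3' suffix). In this package's fixture
convention, CDS features *include* the stop codon; the reader takes CDS
extents as given, so with GENCODE-style CDS (stop excluded) frame
arithmetic is unchanged and only the stop-containing-exon bookkeeping
shifts by one codon.

Translation runs from the 5' parent's start codon to the first stop.
A stop entirely upstream of the junction is an error — such a template
cannot produce a chimeric protein. Predicted mass is the average-isotopic
peptide mass (Biopython `molecular_weight`); reports round to 0.1 kDa
because the only comparable experimental readout is gel migration.

The last retained wild-type residue is `⌊retained CDS nt / 3⌋`
(here 2196/3 = 732); a domain is RETAINED iff it ends at or before that
residue, LOST iff it starts after it, otherwise TRUNCATED. A junction codon
split across the breakpoint counts toward the 5' parent only when complete,
which is what the floor expresses.

Genomic-to-transcript reconciliation: for a DNA-level junction pair, every
exon of the 5' gene whose splice donor lies transcriptionally at/upstream
of the 5' break is crossed with every exon of the 3' gene whose splice
acceptor lies at/downstream of the 3' break (the 5' gene's last exon has no
donor; the 3' gene's exon 1 acceptor is taken as its start so breaks in the
5' flank admit a full-gene join). Candidates are ranked by
(max donor exon, min acceptor exon) — most sequence retained first. The
ranking is a heuristic, exposed as an ordered list rather than a single
answer: for the fixture's 3'UTR-to-intron-9 junction the top candidate is
the exon-7 → exon-10 product actually seen in RNA, with the intervening
stop-containing exon spliced out; *why* that exon is skipped (acceptor
loss vs. exon-definition failure) is not computable from coordinates and
is deliberately out of scope.

## In-silico PCR

Exact string matching only: the forward primer on the template strand, the
reverse primer as its reverse complement strictly downstream of the forward
3' end, all pairings within `max_length` (default 5000 nt, a generous bound
for the assays modelled) reported sorted. No mismatch tolerance or melting
model — the experimental readout being reproduced is band presence/absence.
Reverse-complementing a template provably mirrors amplicons with primer
roles swapped, and the property is tested.

## Synthetic fixtures

The `g292` preset encodes the study conditions:

* **DAXX-like gene** — chr6, minus strand, 8 exons; exon-7 donor at
  33,318,996; 5'UTR 60 nt; CDS 2,223 nt including the stop (740 residues);
  exon 8 carries the last 8 codons + stop + a 474-nt 3'UTR, so residues
  733–740 (the SIM) are exon-8-encoded and the CDS through exon 7 is
  2,196 nt.
* **KIFC3-like gene** — chr16, plus strand, 20 exons of 150 nt; exon-10
  acceptor at 57,766,986; 5'UTR 48 nt so the CDS through exon 9 is
  1,302 nt ≡ 0 (mod 3), making the exon-7 → exon-10 chimera in frame.
* **Neighbours/controls** — a ZBTB22-like gene downstream of the DAXX-like
  3' end on chr6 and a GAPDH-like 3-exon control gene on chr12.
* **Sequence** — regions are random ACGT under the given seed; gene-sense
  exon sequence, GT/AG intron motifs, and the published primer sequences
  are written on top. Primers inside coding sequence are placed at
  codon-phase offsets chosen so no in-frame stop can arise, and the
  generator asserts the full CDS is stop-free. Region FASTA headers carry
  absolute `start=` offsets so printed hg38-scale coordinates are used
  verbatim without a full genome.
* **Junction files** — the major junction with per-replicate supports
  6/5/4 (15 total) and the minor with 4/4/3 (11): the paper-scale analysis
  does not print per-replicate counts, so these are arbitrary passing
  values whose ordering (major > minor) mirrors the reported relative
  abundance. Seven decoy classes cover every rejection path plus
  sub-threshold, intergenic-end and strand-inconsistent cases. Read names
  are replicate-scoped (`R1_read_0001`) so distinct-read arithmetic is
  actually exercised. Line order within a file is a seeded shuffle.
* **Truth JSON** — junctions, supports, expected annotations, frame,
  genomic fusion coordinates, domain table, break residue, protein
  lengths. Everything tests grade against is declared here, and everything
  here is re-derivable by running the pipeline.

The genomic break pair is chr6:33,318,500 (inside the 3'UTR) →
chr16:57,766,800 (inside intron 9). PCR templates (wild-type cDNAs, fusion
cDNA, wild-type chr6 genomic on the gene sense strand, rearranged t(6;16)
genomic) are derived from the fixture at run time by
`g292_pcr_templates`, not stored.

The `random` preset draws 8 genes (3–8 exons, random strands/sizes) and 50
fusion events placed at exon boundaries with supports uniform on 1..20,
for recall benchmarking across the support threshold. It guarantees
structural validity but not reading frame, and its truth set omits frame
status.

**What the fixtures do not emulate:** sequencing error, alignment
ambiguity and multimapping (repeat lengths are assigned, not derived from
sequence), expression-level variation, intra-chromosomal read-through
chimeras, and multi-isoform gene models. Passing tests therefore validate
the *logic* of filtering, annotation, reconstruction and assay prediction
under the declared conventions — not robustness to aligner noise on real
libraries. With real data, the same entry points accept a real GTF and
genome FASTA (a FASTA without `start=` headers is treated as offset 1).

## Numerical and degenerate-input conventions

Deterministic tie-breaks everywhere: event ordering (support desc, then
key), canonical transcript (CDS length desc, then id), overlapping genes
(smallest span, then name), candidate ranking ((−d, a)). Empty inputs are
identities (empty file → no records, no events, ideogram-only plot). All
randomness flows from a single `numpy` `default_rng(seed)`; fixture output
is byte-identical per seed. Problem sizes throughout (fixture of ~85
junction records across 3 replicates, 28-exon gene pair, kilobase-scale
regions) are chosen so the whole suite and the acceptance script run in
seconds while still exercising every code path at real coordinates.

## Known limitations

* Single-isoform consequence calling (canonical transcript only).
* No breakpoint-window clustering: aligner jitter of ±1 bp would split an
  event's support; real-data use may need a tolerant grouping layer.
* Exact-match PCR only; primer mismatches or degenerate bases are out of
  scope.
* The spliced-product ranking is a retention heuristic, not a splicing
  model.
* Mass prediction ignores post-translational modification; it supports
  "larger than wild type" reasoning, not absolute gel positions.
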