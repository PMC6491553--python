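# Methods

`berrymir` re-implements, at desk scale, a plant miRNA annotation workflow
of the kind used to re-annotate the woodland strawberry (*Fragaria vesca*)
genome: small-RNA reads are cleaned and collapsed, mapped exactly to the
genome, screened for qualifying stem-loop precursors, classified against a
known mature set, and used to predict cleavage targets with degradome
support; alongside it, the package computes the summary and comparison
statistics used to describe protein-coding annotations. All stages are
driven by a synthetic-data generator with complete truth tables.

## The discovery pipeline

**Read cleanup.** FASTQ reads are kept when at least 90% of bases have
phred quality >= 28 (`quality_filter(min_q=28, min_pct=90)`), matching the
common `fastq_quality_filter -q 28 -p 90` convention. Adapter trimming is
exact-match: the leftmost occurrence of an adapter prefix of >= 8 nt (or
the full adapter) truncates the read. Untrimmed reads longer than 30 nt
are discarded (an insert that long with no adapter trace is not a usable
sRNA read), and trimmed reads outside 18-30 nt are dropped before mapping;
the 18-30 window is this package's documented choice, bounding the
candidate space around the downstream 20-22 nt selection. Identical
sequences collapse to counted tags (`>tagN_xCOUNT` FASTA dialect).

**Mapping.** `map_exact` enumerates *every* occurrence of each tag on both
genome strands with zero mismatches (including overlapping
self-occurrences), reproducing 0-mismatch short-read aligner semantics
without an index structure; an oracle test checks it against a naive
sliding-window scan. Candidates for hairpin screening are tags of 20-22 nt
with 1-20 genomic matches, both bounds inclusive.

**Folding.** Precursor windows are folded with a maximum-weight
Nussinov-style dynamic program: pair weights GC=3, AU=2, GU=1, hairpin
loops >= 3 nt, deterministic traceback (prefer the 3' base unpaired, then
the smallest pairing partner). This combinatorial scheme was chosen over
thermodynamic free-energy minimisation because it is self-contained and
exactly testable — the fold is verified against exhaustive enumeration of
all nested structures for sequences up to 25 nt. `fold(structure=...)`
accepts an externally computed dot-bracket string for users who prefer a
thermodynamic folder. The fill runs as a numba kernel (O(n^3); a 300-nt
window folds in milliseconds).

**Window extraction and screening.** Each genomic hit yields two candidate
windows per flank size — `[start - flank, end + 20]` and
`[start - 20, end + flank]` — covering a mature on the 3' or the 5' arm.
Because plant precursor arms vary widely, and because folding a short
genuine hairpin inside one long window lets the maximum-weight fold pull
mature end bases into spurious distal pairs, the screen evaluates a ladder
of flank sizes (60, 120, and the configured maximum, default 250 nt) and
keeps the best window: accepted first, then fewer mispairings, fewer
bulges, and finally the upstream window. This mirrors how excision-based
precursor checkers try multiple precursor boundaries.

**Duplex evaluation.** From the fold of a window, the miRNA/miRNA* duplex
is read off the partner table of the mature interval:

- The *star interval* is the largest cluster of mature-partner positions
  that fits in a star-sized window (mature length + 12 nt) entirely on one
  side of the mature, extended by the unpaired mature end lengths plus a
  2-nt allowance for the canonical Dicer 3'-overhang geometry. Clustering
  (rather than taking the raw partner extent) makes the measurement robust
  to stray chance pairs into the flanking sequence, which count as
  mispairings instead of disqualifying the locus.
- *Mispairings* are mature positions with no partner inside the star
  interval — unpaired bases, bases in internal loops, and bases paired
  away into the flanks all count once per mature position.
- *Bulges* are runs of >= 2 unpaired bases on exactly one strand between
  consecutive duplex pairs. Single-nucleotide asymmetries are deliberately
  not counted as bulges: a lone substitution can fold either as a 1-1
  internal loop or, after local re-registration of the helix, as a 1-nt
  bulge, and it is already captured by the mispairing count. Symmetric
  internal loops likewise count as mispairings only. "Central bulge" has
  no standard formal definition; this is the package's documented
  interpretation.
- Structural rejections: a mature that spans the terminal loop (self-pairs
  or pairs on both sides with no dominant cluster), a fully unpaired
  mature, or a terminal loop longer than `max_loop` (default 100 nt — a
  generous bound for plant terminal loops that excludes "hairpins" whose
  two arms are joined by hundreds of structured bases).

**Acceptance.** A locus is called a miRNA precursor iff mispairings <= 4
and bulges <= 1, both bounds inclusive. Accepted loci within 50 nt on the
same strand are merged, keeping the highest-count tag as the mature.

**Classification and naming.** A mature is assigned to a known family when
its best near-identity match — minimum substitution distance over all
ungapped offsets, overhanging bases counted as mismatches, length
difference <= 2 — against a miRBase-style mature FASTA is <= 2. This
replaces a BLAST search against a live database and emulates its
end-gapped behaviour at sRNA scale. Conserved loci sharing a family get
letter suffixes in genomic order when the family has more than one locus
(miRBase convention: a single-locus family keeps the bare name); novel
loci are numbered `miRN1..miRNk` by (chromosome, start). Naming sorts
first, so it is invariant under input permutation.

## Target prediction

Duplexes between a miRNA and a transcript window are scored with the
penalty scheme of the TargetFinder family of tools: mismatch 1.0, gap 1.0,
G:U wobble 0.5, each doubled when the miRNA position (from the 5' end)
lies in 2-13; a perfect reverse complement scores 0 and sites with score
<= 5.0 (inclusive) are reported. At most one gap per duplex is allowed,
so windows of miRNA length ±1 are scanned; overlapping windows reduce to
the local minimum score. The scan is a numba kernel (O(L·m²) per
miRNA/transcript pair); reported sites are re-scored by the explicit
alignment enumerator, which an oracle test checks against an independent
gap-state alignment DP.

Sites are localised to 5'UTR/CDS/3'UTR by the majority of covered bases
against the transcript-coordinate CDS span (ties go to CDS; no CDS means
"noncoding"). Degradome support is the raw count of tags whose exact-match
5' end sits at the expected cleavage position. RISC cleaves between the
target bases paired to miRNA positions 10 and 11; the counter accepts both
bases so that either off-by-one convention of "the position opposite
10-11" is supported, while the generator plants tag 5' ends at the base
paired to position 10 (the 5' end of the 3' cleavage fragment, the
convention degradome tools use).

## Annotation statistics

`summarize` computes the summary-table quantities: locus length is the
gene span; exon counts, CDS and UTR lengths are per-transcript means;
intron lengths come from per-transcript exon gaps; UTR presence is
counted per gene. `percent`/`ratio` round half-up to two decimals, the
convention that reproduces every published percentage from its printed
counts. `compare` declares two genes shared when, on the same strand, some
transcript pair has an identical intron chain (single-exon transcripts:
reciprocal overlap >= 50%) — an approximation of the equal/contained codes
of transcript-comparison tools, since no formal criterion is published.
Gene-ID assignment follows the FvH4_XgXXXXX rules: existing IDs end in 0
and are retained; an added gene takes an unused non-zero last digit
between its neighbours, searched midpoint-first (between ...10 and ...20
the first choice is ...15); splits keep the ID on the longest fragment;
merges retain the lowest ID; removed IDs are retired forever. AED is the
nucleotide-level congruence form 1 − (SN + SP)/2 with SN = |model ∩
evidence|/|evidence| and SP = |model ∩ evidence|/|model|; the
quality-index proxy is the fraction of model exons with an evidence
interval of identical boundaries.

## The synthetic-data generator

The generator emulates the shape of a real study at desk scale: 3
chromosomes of 50 kb at 39% GC (strawberry-like base composition), 20
planted miRNA loci (half drawn verbatim from a generated miRBase-style
reference, half novel), a 10,000-read sRNA library with 20% random
18-30-mer noise and 5% low-quality reads, a 50-gene annotation with
isoforms and UTRs over 46 tissue columns, and a degradome library. These
defaults are the package's study conditions; tests and the acceptance
script run them unchanged.

Planted precursors use the canonical duplex geometry `mature + loop +
star`, star = reverse complement of the mature, with defects introduced as
star-strand substitutions (chosen to pair neither the facing base nor its
±2 neighbours, so a shifted helix register cannot silently repair them)
and 2-nt star-strand insertions. Because a maximum-weight fold can still
re-register a damaged stem, each locus is verified *in genomic context*:
after insertion the locus is screened with the discovery defaults and the
construction is retried deterministically (new loop, letters, position)
until the measured duplex equals the configured defects (for loci within
thresholds) or the hairpin call fails (for loci beyond them). Loci keep
>= 300 nt of clearance from each other, from genes, and from planted
target sites, so later insertions cannot perturb a verified fold window;
planted target sites — exact reverse complements of matures, and hence
mappable loci themselves — are additionally screened and re-placed if
chance complementarity around them would fold into an acceptable hairpin.
Read abundances follow a geometric law (ratio 0.8) partitioned by largest
remainder, so per-locus counts are exact; the signal/noise split is an
exact partition of the configured depth. Adapters are appended verbatim
with no sequencing errors: the mapping stage allows zero mismatches, so
simulated errors would only shrink the signal without exercising any new
code path.

TPM matrices are built per tissue: a configured fraction of genes is
"expressed" (lognormal abundances scaled so each column sums to 10^6);
the rest receive raw values below one TPM after scaling, so the
expressed-gene truth is exactly recoverable with the > 1 TPM rule.

What the generator does **not** emulate: sequencing error models,
isomiR/isoform-level expression, multi-mapping miRNA families sharing one
mature, polycistronic precursors, RNA structure beyond nested pairing, and
the full size and composition biases of real libraries. Passing recovery
tests therefore demonstrates that the pipeline's logic and thresholds act
as specified on data whose ground truth is known — not that the pipeline
would reproduce any particular discovery count on real tissue libraries.

## Problem sizes and numerical choices

Tests and the acceptance script use the generator defaults above
(3 × 50 kb genome, 20 loci, 10k reads, 3 seeds), sizes chosen so the full
suite runs in well under a minute while every stage is exercised end to
end. Ties are broken deterministically everywhere (traceback order,
window preference, lexicographic tag and reference order), and all
randomness flows from a single integer seed through named substreams, so
identical configurations produce byte-identical output files.

## Known limitations

- The combinatorial fold over-pairs relative to thermodynamic structures;
  measured mispairing/bulge counts are meaningful relative to this fold,
  not as free-energy statements. The dot-bracket hook exists for users
  who want RNAfold-style structures.
- `map_exact` is a string-search scan, appropriate for desk-scale genomes
  (up to a few Mb), not a production aligner.
- Degradome support is a raw 5'-end count; no transcriptome-wide peak
  categories or p-values are computed.
- The annotation comparison handles the shared/unique decision only; it
  does not classify the full vocabulary of transfer codes.
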