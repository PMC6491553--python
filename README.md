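# berrymir

Plant miRNA annotation from small-RNA sequencing, miRNA target prediction
with degradome support, and gene-annotation summary statistics — rebuilt
as a compact, fully tested Python package driven by a synthetic-data
generator, so the whole workflow runs and is verifiable on a laptop
without any downloads.

The package targets the analysis style used in genome reannotation
projects for the woodland strawberry (*Fragaria vesca*) and similar plant
genomes: collapsed sRNA tags are mapped exactly to the genome, screened
for stem-loop precursors, named as conserved or novel miRNAs, and matched
to cleavage targets in annotated transcripts; annotation versions are
summarised and compared with the statistics those projects print.

## The core methods

**miRNA discovery.** Reads are quality-filtered (>= 90% of bases at
Q >= 28), adapter-trimmed (exact match, >= 8 nt overlap) and collapsed.
Tags of 20–22 nt with <= 20 exact genomic matches (both strands, zero
mismatches) seed candidate precursor windows, which are folded with a
maximum-weight Nussinov dynamic program (GC = 3, AU = 2, GU = 1, loop >= 3).
A locus is accepted when the miRNA/miRNA\* duplex shows

&nbsp;&nbsp;&nbsp;&nbsp;mispairings <= 4 and bulges <= 1 (both inclusive),

with the star arm read off the fold under the 2-nt 3′-overhang convention.
Matures within 2 substitutions of a known plant mature (all ungapped
offsets, length difference <= 2) join that family (`fve-miR156a`, ...);
the rest are numbered `fve-miRN1..k` in genomic order.

**Target prediction.** Duplexes are scored with position-weighted
penalties — mismatch 1, gap 1, G:U wobble 0.5, doubled at miRNA positions
2–13 — and sites with score <= 5 are reported, localised to
5′UTR/CDS/3′UTR, and annotated with the count of degradome tags whose 5′
ends fall at the cleavage site (the target bases paired to miRNA
positions 10–11).

**Annotation statistics.** Summary tables (gene counts, exon/intron/UTR
lengths, isoforms per locus), intron-chain-based comparison of two GFF3
annotations, FvH4-style gene-ID assignment for added/split/merged genes,
expressed-gene counts (max TPM > 1 across tissues), and Annotation Edit
Distance / exon-support metrics, with half-up percentage rounding.

**Synthetic data.** `berrymir.synthetic_data` generates a genome with
planted hairpins (controllable duplex defects, verified in genomic
context), sRNA libraries with adapters, noise and low-quality reads, a
toy annotation with UTRs and isoforms carrying planted target sites, a
degradome, and a 46-tissue TPM matrix — all with truth tables and
byte-identical reproducibility per seed.

See `docs/methods.md` for the model details and the design choices.

## Worked example

```bash
# generate a small dataset with 6 planted miRNA loci and truth tables
python -c "
from berrymir.config import SimulationConfig
from berrymir.synthetic_data import simulate_dataset, write_dataset
cfg = SimulationConfig(seed=7, n_true_mirnas=6, read_depth=2000, n_genes=20)
write_dataset(simulate_dataset(cfg), 'demo')"

berrymir collapse -i demo/reads.fastq -a TGGAATTCTCGGGTGCCAAGG -o tags.fa
# -> 406 tags from 2100 reads
berrymir classify -g demo/genome.fa -t tags.fa \
    -r demo/reference_mature.fa -o mirna.tsv
# -> 12 loci (6 conserved)
berrymir targets -m mirna.tsv -t demo/transcripts.fa \
    -g demo/annotation.gff3 -d demo/degradome.fa -o targets.tsv
# -> 14 target sites at cutoff 5.0
```

`mirna.tsv` begins:

```
name         family  status     chrom  start  end    strand  mature_seq             mispairings
fve-miR156a  miR156  conserved  chr1   14526  14546  +       AACGGCCGGUUGGACACAACU  0
fve-miR156b  miR156  conserved  chr1   14562  14582  -       AACGGCCGGUUGGACACAACU  0
fve-miRN1    NOVEL   novel      chr1   24407  24427  +       CCUGACACAUAAGUAGUUGUC  0
```

The 2,100 raw reads collapse to 406 distinct tags (planted matures plus
random noise); the noise tags either fail the 20–22 nt window or do not
map, so only planted loci survive screening. Each perfect-stem precursor
is an exact inverted repeat, so its star arm also maps and is reported as
a second locus on the opposite strand — that is why 6 planted loci yield
12 reported ones here (miR156a/b are the two arms of one precursor), and
why conserved families are lettered. `targets.tsv` rows with score 0.0
are the planted perfect sites; for example

```
mirna        transcript   start  end  score  region  degradome_reads
fve-miR156a  gene0001.t1  61     81   0.0    5UTR    5
```

is a planted 5′UTR site whose five simulated degradome tags all start at
the transcript base paired to miRNA position 10.

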