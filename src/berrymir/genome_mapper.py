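"""Exact (0-mismatch) mapping of collapsed tags to both genome strands.

All occurrences are enumerated, including overlapping self-occurrences;
minus-strand hits are reported in forward-strand coordinates with
``strand == "-"``. Candidate tags for hairpin screening are those of
20-22 nt with between 1 and 20 genomic matches (strand-summed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from ._seq import is_dna, revcomp
from .srna_preprocess import SmallRNATag


@dataclass(frozen=True)
class GenomicHit:
    tag_seq: str
    chrom: str
    start: int  # 1-based inclusive, forward strand
    end: int
    strand: str

    def __post_init__(self):
        assert self.end - self.start + 1 == len(self.tag_seq)


def _find_all(haystack: str, needle: str) -> list[int]:
    """0-based start positions of every (possibly overlapping) occurrence."""
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def map_exact(tags, genome: dict[str, str]) -> dict[str, list[GenomicHit]]:
    """All exact occurrences of each tag on both strands of the genome."""
    hits: dict[str, list[GenomicHit]] = {}
    for tag in tags:
        seq = tag.sequence if isinstance(tag, SmallRNATag) else str(tag)
        if not is_dna(seq):
            warnings.warn(f"skipping tag with non-ACGT characters: {seq[:30]}")
            continue
        found = []
        rc = revcomp(seq)
        for chrom in sorted(genome):
            s = genome[chrom]
            for i in _find_all(s, seq):
                found.append(GenomicHit(seq, chrom, i + 1, i + len(seq), "+"))
            for i in _find_all(s, rc):
                found.append(GenomicHit(seq, chrom, i + 1, i + len(seq), "-"))
        found.sort(key=lambda h: (h.chrom, h.start, h.strand))
        hits[seq] = found
    return hits


def candidate_filter(tags, hits: dict[str, list[GenomicHit]],
                     min_len: int = 20, max_len: int = 22,
                     max_hits: int = 20) -> list[SmallRNATag]:
    """Keep tags with length in [min_len, max_len] and 1..max_hits matches."""
    kept = []
    for tag in tags:
        n = len(hits.get(tag.sequence, []))
        if min_len <= tag.length <= max_len and 1 <= n <= max_hits:
            kept.append(tag)
    return kept


def to_bed(hits: dict[str, list[GenomicHit]],
           counts: dict[str, int] | None = None) -> str:
    """6-column BED (0-based half-open); score column holds the tag count."""
    lines = []
    for seq in sorted(hits):
        for h in hits[seq]:
            score = counts.get(seq, 0) if counts else 0
            lines.append(f"{h.chrom}\t{h.start - 1}\t{h.end}\t{seq}\t"
                         f"{score}\t{h.strand}")
    return "\n".join(lines) + ("\n" if lines else "")
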