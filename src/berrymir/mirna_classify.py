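"""Family assignment and naming of discovered miRNA loci.

A discovered mature is *conserved* when it lies within ``max_mismatch``
substitutions of a known plant mature (near-identity over all ungapped
offsets, overhanging bases counted as mismatches, length difference at most
2); otherwise it is *novel*. Conserved loci sharing a family receive letter
suffixes in genomic order (``miR171a``, ``miR171b``, ...; a single-locus
family keeps the bare name); novel loci are numbered ``miRN1``..``miRNk``
ordered by (chromosome, start).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import pandas as pd

from ._seq import dna, rna
from .genome_mapper import GenomicHit
from .hairpin_discovery import HairpinCandidate

NOVEL = "NOVEL"


@dataclass
class MiRNALocus:
    name: str
    family: str  # family label or NOVEL
    mature_seq: str  # RNA alphabet
    locus: GenomicHit
    precursor: tuple[int, int]
    mispairings: int = 0
    bulges: int = 0
    tag_count: int = 1


def family_of(reference_name: str) -> str:
    """``ath-miR156a`` -> ``miR156`` (miRBase mature.fa header dialect)."""
    m = re.search(r"(miR[A-Za-z]?\d+)", reference_name)
    return m.group(1) if m else reference_name


def _offset_distance(q: str, r: str) -> int:
    """Minimum substitution distance over all ungapped offsets.

    Bases of either sequence outside the overlap count as mismatches.
    """
    lq, lr = len(q), len(r)
    best = lq + lr
    for off in range(-lq + 1, lr):
        # q[i] faces r[i + off]
        overlap = 0
        mism = 0
        for i in range(lq):
            j = i + off
            if 0 <= j < lr:
                overlap += 1
                if q[i] != r[j]:
                    mism += 1
        d = mism + (lq - overlap) + (lr - overlap)
        best = min(best, d)
    return best


def assign_family(mature: str, reference: list[tuple[str, str]],
                  max_mismatch: int = 2, max_len_diff: int = 2):
    """Best near-identity match; returns ``(family, distance, ref_name)``.

    ``family`` is :data:`NOVEL` when no reference entry of compatible
    length is within ``max_mismatch``. Ties break on the lexicographically
    smallest reference name.
    """
    if not reference:
        warnings.warn("empty reference set: everything is novel")
        return NOVEL, None, None
    q = dna(mature)
    best = None
    for name, ref_seq in sorted(reference):
        r = dna(ref_seq)
        if abs(len(q) - len(r)) > max_len_diff:
            continue
        d = _offset_distance(q, r)
        if best is None or d < best[0]:
            best = (d, name)
    if best is None or best[0] > max_mismatch:
        return NOVEL, (best[0] if best else None), (best[1] if best else None)
    return family_of(best[1]), best[0], best[1]


def classify_candidates(candidates: list[HairpinCandidate],
                        reference: list[tuple[str, str]],
                        max_mismatch: int = 2,
                        prefix: str = "fve") -> list[MiRNALocus]:
    """Assign families to accepted hairpin candidates and name the loci."""
    loci = []
    for c in candidates:
        fam, _d, _ref = assign_family(c.tag.sequence, reference, max_mismatch)
        loci.append(MiRNALocus(
            name="", family=fam, mature_seq=rna(c.tag.sequence),
            locus=c.hit, precursor=c.window,
            mispairings=c.duplex.mispairings if c.duplex else -1,
            bulges=c.duplex.bulges if c.duplex else -1,
            tag_count=c.tag.count))
    return name_loci(loci, prefix=prefix)


def _letters():
    import itertools
    import string
    for size in (1, 2):
        for combo in itertools.product(string.ascii_lowercase, repeat=size):
            yield "".join(combo)


def name_loci(loci: list[MiRNALocus], prefix: str = "fve") -> list[MiRNALocus]:
    """Stable naming: sort by (chromosome, start) before assigning names."""
    ordered = sorted(loci, key=lambda l: (l.locus.chrom, l.locus.start,
                                          l.locus.strand))
    by_family: dict[str, list[MiRNALocus]] = {}
    for l in ordered:
        if l.family != NOVEL:
            by_family.setdefault(l.family, []).append(l)
    for fam, members in by_family.items():
        if len(members) == 1:
            members[0].name = f"{prefix}-{fam}"
        else:
            for letter, l in zip(_letters(), members):
                l.name = f"{prefix}-{fam}{letter}"
    novel_no = 0
    for l in ordered:
        if l.family == NOVEL:
            novel_no += 1
            l.name = f"{prefix}-miRN{novel_no}"
    return ordered


def chromosome_distribution(loci: list[MiRNALocus]) -> dict[str, int]:
    """Locus counts per chromosome; order follows sorted chromosome names."""
    counts: dict[str, int] = {}
    for l in sorted(loci, key=lambda l: l.locus.chrom):
        counts[l.locus.chrom] = counts.get(l.locus.chrom, 0) + 1
    return counts


def compare_family_sets(set_old, set_new) -> tuple[list[str], list[str]]:
    """(gained, lost) family names, both sorted."""
    old, new = set(set_old), set(set_new)
    return sorted(new - old), sorted(old - new)


def loci_table(loci: list[MiRNALocus]) -> pd.DataFrame:
    rows = [{
        "name": l.name,
        "family": l.family,
        "status": "conserved" if l.family != NOVEL else "novel",
        "chrom": l.locus.chrom,
        "start": l.locus.start,
        "end": l.locus.end,
        "strand": l.locus.strand,
        "mature_seq": l.mature_seq,
        "mispairings": l.mispairings,
        "bulges": l.bulges,
        "tag_count": l.tag_count,
    } for l in loci]
    return pd.DataFrame(rows, columns=["name", "family", "status", "chrom",
                                       "start", "end", "strand", "mature_seq",
                                       "mispairings", "bulges", "tag_count"])
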