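"""Small-RNA read cleanup: quality filtering, adapter trimming, collapsing.

Reads enter as ``(id, seq, phred-quality-list)`` tuples (see
:func:`berrymir.io.read_fastq`) and leave as :class:`SmallRNATag` objects,
one per distinct sequence with its collapsed read count. The quality filter
reproduces the ``-q 28 -p 90`` convention: keep a read iff at least
``min_pct`` percent of its bases have quality >= ``min_q``. Adapter
matching is exact: the leftmost position where an adapter prefix of at
least ``min_overlap`` bases (or the full adapter) matches truncates the
read.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence


@dataclass(frozen=True)
class SmallRNATag:
    sequence: str
    count: int

    def __post_init__(self):
        assert self.count >= 1

    @property
    def length(self) -> int:
        return len(self.sequence)


def quality_filter(reads: Iterable[tuple[str, str, Sequence[int]]],
                   min_q: int = 28, min_pct: float = 90.0):
    """Keep reads where >= ``min_pct`` % of bases have phred >= ``min_q``."""
    kept = []
    for rid, seq, quals in reads:
        if not seq:
            continue
        good = sum(1 for q in quals if q >= min_q)
        if 100.0 * good / len(seq) >= min_pct:
            kept.append((rid, seq, quals))
    return kept


def _trim_point(seq: str, adapter: str, min_overlap: int) -> int | None:
    """Leftmost position where an adapter prefix of >= min_overlap matches."""
    la = len(adapter)
    L = len(seq)
    for pos in range(L):
        k = min(la, L - pos)
        if k < min_overlap:
            break
        if seq[pos:pos + k] == adapter[:k]:
            return pos
    return None


def trim_adapter(reads, adapter: str, min_overlap: int = 8,
                 max_untrimmed: int = 30,
                 min_len: int = 18, max_len: int = 30):
    """Trim the 3' adapter; drop unusable reads.

    Untrimmed reads longer than ``max_untrimmed`` are discarded (an intact
    insert that long cannot be an sRNA with a missed adapter); trimmed reads
    outside ``[min_len, max_len]`` are discarded before mapping.
    """
    if len(adapter) < min_overlap:
        raise ValueError("adapter shorter than min_overlap")
    out = []
    for rid, seq, quals in reads:
        pos = _trim_point(seq, adapter, min_overlap)
        if pos is None:
            if len(seq) > max_untrimmed:
                continue
            trimmed = seq
        elif pos == 0:
            continue  # adapter dimer
        else:
            trimmed = seq[:pos]
        if min_len <= len(trimmed) <= max_len:
            out.append((rid, trimmed, quals[:len(trimmed)]))
    return out


def collapse(reads) -> list[SmallRNATag]:
    """One tag per distinct sequence; counts sum to the number of reads.

    Accepts ``(id, seq, qual)`` tuples, plain strings, or existing tags
    (whose counts are preserved, making the operation idempotent).
    Deterministic order: count descending, then sequence.
    """
    counter: Counter[str] = Counter()
    for r in reads:
        if isinstance(r, SmallRNATag):
            counter[r.sequence] += r.count
        elif isinstance(r, str):
            counter[r] += 1
        else:
            counter[r[1]] += 1
    tags = [SmallRNATag(seq, n) for seq, n in counter.items()]
    tags.sort(key=lambda t: (-t.count, t.sequence))
    return tags


def preprocess(reads, adapter: str, min_q: int = 28, min_pct: float = 90.0,
               min_overlap: int = 8) -> list[SmallRNATag]:
    """quality_filter -> trim_adapter -> collapse."""
    return collapse(trim_adapter(quality_filter(reads, min_q, min_pct),
                                 adapter, min_overlap))
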