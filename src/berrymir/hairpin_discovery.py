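"""Hairpin precursor screening.

Candidate tags are expanded into two precursor windows (mature on the 5' or
the 3' arm), each window is folded with a maximum-weight Nussinov-style
dynamic program (GC=3, AU=2, GU=1, hairpin loops >= 3 nt), and the
miRNA/miRNA* duplex implied by the fold is scored. A locus is accepted when
the duplex shows at most ``max_mispair`` mispairings (mature bases not
paired into the star interval) and at most ``max_bulge`` single-strand
bulges, and the implied precursor is compact (terminal loop and star-arm
stretch within bounds).

The folding is combinatorial, not thermodynamic: it is exactly testable
against exhaustive enumeration, and a hook (``structure=``) accepts an
externally computed dot-bracket string for users who prefer free-energy
folding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from ._seq import encode, revcomp, rna
from .genome_mapper import GenomicHit, candidate_filter, map_exact
from .srna_preprocess import SmallRNATag

MIN_FOLD_LEN = 10

#: pair weights, indexed by base codes (A=0, C=1, G=2, U=3)
_W = np.zeros((4, 4), dtype=np.int32)
_W[0, 3] = _W[3, 0] = 2  # A:U
_W[2, 1] = _W[1, 2] = 3  # G:C
_W[2, 3] = _W[3, 2] = 1  # G:U


class FoldError(ValueError):
    pass


@dataclass
class FoldResult:
    sequence: str  # RNA alphabet
    structure: str  # dot-bracket
    pairs: list  # 1-based (i, j) with i < j

    def partner(self) -> np.ndarray:
        """1-based partner array; 0 = unpaired (index 0 unused)."""
        p = np.zeros(len(self.sequence) + 1, dtype=np.int64)
        for i, j in self.pairs:
            p[i], p[j] = j, i
        return p


@njit(cache=True)
def _nussinov_fill(codes, W, min_loop):  # pragma: no cover - numba
    n = codes.shape[0]
    M = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = M[i, j - 1]
            for k in range(i, j - min_loop):
                w = W[codes[k], codes[j]]
                if w > 0:
                    left = M[i, k - 1] if k > i else 0
                    right = M[k + 1, j - 1] if k + 1 <= j - 1 else 0
                    s = left + w + right
                    if s > best:
                        best = s
            M[i, j] = best
    return M


def _traceback(M, codes, min_loop):
    """Deterministic traceback: prefer j unpaired, then the smallest k."""
    n = len(codes)
    pairs = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        while j - i > min_loop:
            if M[i, j] == M[i, j - 1]:
                j -= 1
                continue
            for k in range(i, j - min_loop):
                w = _W[codes[k], codes[j]]
                if w > 0:
                    left = M[i, k - 1] if k > i else 0
                    right = M[k + 1, j - 1]
                    if left + w + right == M[i, j]:
                        pairs.append((k + 1, j + 1))
                        stack.append((k + 1, j - 1))
                        j = k - 1
                        break
            else:  # pragma: no cover - would indicate a DP bug
                raise AssertionError("traceback failed")
    pairs.sort()
    return pairs


def fold(sequence: str, min_loop: int = 3,
         structure: str | None = None) -> FoldResult:
    """Maximum-weight nested secondary structure of ``sequence``.

    ``structure`` short-circuits the dynamic program with an externally
    supplied dot-bracket string (e.g. from a thermodynamic folder).
    """
    seq_rna = rna(sequence)
    if len(seq_rna) < MIN_FOLD_LEN:
        raise FoldError(f"sequence shorter than {MIN_FOLD_LEN} nt")
    if structure is not None:
        if len(structure) != len(seq_rna):
            raise FoldError("structure length != sequence length")
        stack, pairs = [], []
        for i, c in enumerate(structure):
            if c == "(":
                stack.append(i)
            elif c == ")":
                if not stack:
                    raise FoldError("unbalanced brackets")
                pairs.append((stack.pop() + 1, i + 1))
            elif c != ".":
                raise FoldError(f"bad dot-bracket character {c!r}")
        if stack:
            raise FoldError("unbalanced brackets")
        pairs.sort()
        return FoldResult(seq_rna, structure, pairs)
    codes = encode(seq_rna)
    M = _nussinov_fill(codes, _W, min_loop)
    pairs = _traceback(M, codes, min_loop)
    db = ["."] * len(seq_rna)
    for i, j in pairs:
        db[i - 1], db[j - 1] = "(", ")"
    return FoldResult(seq_rna, "".join(db), pairs)


# ---------------------------------------------------------------------------
# duplex evaluation

@dataclass
class DuplexStats:
    mispairings: int
    bulges: int
    star_start: int  # 1-based positions within the folded window
    star_end: int
    mature_arm: str  # "5p" or "3p"
    loop_gap: int  # bases between the mature and star intervals


def evaluate_duplex(fold_result: FoldResult, mature_start: int,
                    mature_end: int, max_loop: int = 100,
                    star_stretch: int = 8):
    """Score the miRNA/miRNA* duplex implied by a fold.

    Returns ``(DuplexStats | None, reason)``. The star interval is taken
    from the partners of the mature's outermost paired bases, extended by
    the unpaired mature end lengths plus the 2-nt 3'-overhang allowance.
    Mispairings are mature positions without a partner inside the star
    interval; bulges are maximal runs of bases on exactly one strand
    between consecutive duplex pairs. Structural rejections: the mature
    spans the terminal loop, the terminal loop exceeds ``max_loop``, or the
    star interval is more than ``star_stretch`` nt longer than the mature.
    """
    n = len(fold_result.sequence)
    a, b = mature_start, mature_end
    L = b - a + 1
    if not (1 <= a <= b <= n):
        raise ValueError("mature interval outside the folded sequence")
    ptr = fold_result.partner()
    mature_positions = range(a, b + 1)
    if any(a <= ptr[i] <= b for i in mature_positions if ptr[i]):
        return None, "mature_spans_loop"
    partners = [(i, int(ptr[i])) for i in mature_positions if ptr[i]]
    if not partners:
        return None, "mature_unpaired"

    # the star arm is the largest cluster of partners that fits in a
    # star-sized interval on one side of the mature; stray distal pairs
    # (chance complementarity in the flanks) then count as mispairings
    # instead of disqualifying the locus
    width = L + star_stretch + 4
    qs = sorted(q for _, q in partners)
    best_cluster = None
    lo_idx = 0
    for hi_idx in range(len(qs)):
        while qs[hi_idx] - qs[lo_idx] + 1 > width:
            lo_idx += 1
        # the cluster must not straddle the mature interval
        while qs[lo_idx] < a <= qs[hi_idx] or qs[lo_idx] <= b < qs[hi_idx]:
            lo_idx += 1
        size = hi_idx - lo_idx + 1
        if best_cluster is None or size > best_cluster[0]:
            best_cluster = (size, qs[lo_idx], qs[hi_idx])
    if best_cluster is None:  # pragma: no cover - partners always non-empty
        return None, "mature_unpaired"
    _size, q_lo, q_hi = best_cluster
    arm = "5p" if q_lo > b else "3p"

    # extend for unpaired mature ends plus the 2-nt 3'-overhang allowance
    in_cluster = [(i, q) for i, q in partners if q_lo <= q <= q_hi]
    p_first, p_last = in_cluster[0][0], in_cluster[-1][0]
    if arm == "5p":
        q_hi += (p_first - a) + 2
        q_lo -= (b - p_last) + 2
        q_lo = max(q_lo, b + 1)
    else:
        q_hi += (b - p_last) + 2
        q_lo -= (p_first - a) + 2
        q_hi = min(q_hi, a - 1)
    q_lo, q_hi = max(1, q_lo), min(n, q_hi)
    loop_gap = (q_lo - b - 1) if arm == "5p" else (a - q_hi - 1)
    if loop_gap > max_loop:
        return None, "loop_too_long"

    # duplex pairs: mature positions whose partner lies inside the star
    duplex = [(i, q) for i, q in partners if q_lo <= q <= q_hi]
    mispair = sum(1 for i in mature_positions
                  if not ptr[i] or not (q_lo <= ptr[i] <= q_hi))
    # bulges: single-strand runs of >= 2 nt between consecutive duplex
    # pairs. 1-nt asymmetries are not counted here — a substitution
    # mispairing can fold either as a 1-1 internal loop or, after local
    # re-registration, as a 1-nt bulge, and it is already counted as a
    # mispairing. Runs on both strands (internal loops) also count as
    # mispairings only.
    bulges = 0
    for (i1, j1), (i2, j2) in zip(duplex, duplex[1:]):
        gap_m = i2 - i1 - 1
        gap_s = abs(j2 - j1) - 1
        if gap_m >= 2 and gap_s == 0:
            bulges += 1
        elif gap_s >= 2 and gap_m == 0:
            bulges += 1
    stats = DuplexStats(mispairings=mispair, bulges=bulges,
                        star_start=q_lo, star_end=q_hi, mature_arm=arm,
                        loop_gap=max(loop_gap, 0))
    return stats, "ok"


def call_hairpin(stats: DuplexStats | None, max_mispair: int = 4,
                 max_bulge: int = 1) -> tuple[bool, str]:
    """Accept iff mispairings <= max_mispair and bulges <= max_bulge."""
    if stats is None:
        return False, "no_duplex"
    if stats.mispairings > max_mispair:
        return False, "too_many_mispairings"
    if stats.bulges > max_bulge:
        return False, "too_many_bulges"
    return True, "accepted"


# ---------------------------------------------------------------------------
# windows and the discovery pipeline

def extract_windows(hit: GenomicHit, chrom_length: int,
                    flank: int = 250) -> list[tuple[int, int]]:
    """Two candidate precursor windows (mature on 3' resp. 5' arm)."""
    a = (max(1, hit.start - flank), min(chrom_length, hit.end + 20))
    b = (max(1, hit.start - 20), min(chrom_length, hit.end + flank))
    return [a, b]


@dataclass
class HairpinCandidate:
    tag: SmallRNATag
    hit: GenomicHit
    window: tuple[int, int]  # genomic, forward strand
    fold: FoldResult
    duplex: DuplexStats | None
    accepted: bool
    reason: str


def _window_candidate(tag, hit, window, genome, min_loop, max_mispair,
                      max_bulge, max_loop):
    wstart, wend = window
    seq = genome[hit.chrom][wstart - 1:wend]
    if hit.strand == "+":
        m1 = hit.start - wstart + 1
        m2 = hit.end - wstart + 1
    else:
        seq = revcomp(seq)
        m1 = wend - hit.end + 1
        m2 = wend - hit.start + 1
    if len(seq) < MIN_FOLD_LEN:
        return None
    fr = fold(seq, min_loop=min_loop)
    stats, reason = evaluate_duplex(fr, m1, m2, max_loop=max_loop)
    ok, call_reason = call_hairpin(stats, max_mispair, max_bulge)
    return HairpinCandidate(tag, hit, window, fr, stats, ok,
                            call_reason if stats is not None else reason)


def screen_hit(tag: SmallRNATag, hit: GenomicHit, genome: dict[str, str],
               flank: int = 250, min_loop: int = 3, max_mispair: int = 4,
               max_bulge: int = 1, max_loop: int = 100) -> HairpinCandidate | None:
    """Evaluate candidate precursor windows for one genomic hit.

    Precursor arm lengths vary widely, and a long random flank folded
    together with a genuine short hairpin can pull mature bases into
    spurious distal pairs; so, like excision-based precursor checkers, the
    screen tries a ladder of flank sizes up to ``flank`` (both arms each)
    and keeps the best window. Ties resolve by fewer mispairings, then
    fewer bulges, then the upstream-flank window at the largest flank
    tried first.
    """
    ladder = sorted({min(60, flank), min(120, flank), flank})
    windows: list[tuple[int, int]] = []
    for fl in ladder:
        for w in extract_windows(hit, len(genome[hit.chrom]), fl):
            if w not in windows:
                windows.append(w)
    cands = []
    for w in windows:
        c = _window_candidate(tag, hit, w, genome, min_loop, max_mispair,
                              max_bulge, max_loop)
        if c is not None:
            cands.append(c)
    if not cands:
        return None

    def key(c: HairpinCandidate):
        mp = c.duplex.mispairings if c.duplex else 10 ** 6
        bg = c.duplex.bulges if c.duplex else 10 ** 6
        return (not c.accepted, mp, bg, windows.index(c.window))

    return min(cands, key=key)


def discover(tags, genome: dict[str, str], *, flank: int = 250,
             min_len: int = 20, max_len: int = 22, max_hits: int = 20,
             min_loop: int = 3, max_mispair: int = 4, max_bulge: int = 1,
             max_loop: int = 100, merge_distance: int = 50,
             hits: dict[str, list[GenomicHit]] | None = None) -> list[HairpinCandidate]:
    """Full screen: map, filter, fold, call; merge nearby loci.

    Loci within ``merge_distance`` nt on the same strand are merged,
    keeping the candidate whose tag has the highest count.
    """
    if hits is None:
        hits = map_exact(tags, genome)
    candidates = candidate_filter(tags, hits, min_len, max_len, max_hits)
    accepted: list[HairpinCandidate] = []
    for tag in candidates:
        for hit in hits[tag.sequence]:
            c = screen_hit(tag, hit, genome, flank, min_loop, max_mispair,
                           max_bulge, max_loop)
            if c is not None and c.accepted:
                accepted.append(c)
    accepted.sort(key=lambda c: (c.hit.chrom, c.hit.start, c.hit.strand,
                                 -c.tag.count, c.tag.sequence))
    merged: list[HairpinCandidate] = []
    for c in accepted:
        prev = merged[-1] if merged else None
        if (prev is not None and prev.hit.chrom == c.hit.chrom
                and prev.hit.strand == c.hit.strand
                and c.hit.start - prev.hit.end <= merge_distance):
            if c.tag.count > prev.tag.count:
                merged[-1] = c
            continue
        merged.append(c)
    return merged


def to_gff3(candidates: list[HairpinCandidate]) -> str:
    """miRBase-dialect GFF3: precursor rows with child miRNA rows."""
    lines = ["##gff-version 3"]
    for i, c in enumerate(candidates, 1):
        wstart, wend = c.window
        pid = f"MI_{i}"
        lines.append("\t".join([
            c.hit.chrom, "berrymir", "miRNA_primary_transcript", str(wstart),
            str(wend), ".", c.hit.strand, ".", f"ID={pid}"]))
        lines.append("\t".join([
            c.hit.chrom, "berrymir", "miRNA", str(c.hit.start),
            str(c.hit.end), ".", c.hit.strand, ".",
            f"ID={pid}_mat;Parent={pid}"]))
    return "\n".join(lines) + "\n"
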