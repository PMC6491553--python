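"""miRNA target prediction with position-weighted duplex scoring.

The score of a miRNA/target duplex is the sum of per-position penalties
over the best alignment with at most one gap: mismatch 1.0, gap 1.0, G:U
wobble 0.5, each doubled when the miRNA position (counted from its 5' end)
falls in the seed-proximal region 2-13. A perfect reverse complement scores
0; sites scoring at most the cutoff (default 5.0) are reported. Each site
is localized to 5'UTR/CDS/3'UTR from the annotation and annotated with the
number of degradome reads whose 5' ends sit at the expected cleavage
position (the target bases paired to miRNA positions 10-11).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from ._seq import dna

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}  # miRNA base first, target base second


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class ScoringScheme:
    mismatch: float = 1.0
    gap: float = 1.0
    wobble: float = 0.5
    seed_start: int = 2
    seed_end: int = 13
    seed_multiplier: float = 2.0

    def mult(self, p: int) -> float:
        return self.seed_multiplier if self.seed_start <= p <= self.seed_end \
            else 1.0

    def pair_penalty(self, p: int, mir_base: str, tgt_base: str) -> float:
        if (mir_base, tgt_base) in _WC:
            return 0.0
        if (mir_base, tgt_base) in _WOBBLE:
            return self.wobble * self.mult(p)
        return self.mismatch * self.mult(p)


DEFAULT_SCHEME = ScoringScheme()


@dataclass
class TargetSite:
    mirna_name: str
    transcript_id: str
    site_start: int  # 1-based transcript coordinates
    site_end: int
    score: float
    alignment: tuple[str, str, str]  # miRNA 3'->5', pair line, target 5'->3'
    region: str = "unknown"
    degradome_reads: int = 0


def _alignment_variants(m: int, w: int):
    if w == m:
        yield ("nogap", 0)
    elif w == m - 1:
        for g in range(1, m + 1):  # miRNA position g faces a target gap
            yield ("del", g)
    elif w == m + 1:
        for g in range(m + 1):  # extra target base before column g
            yield ("ins", g)


def score_duplex(mirna: str, target_window: str,
                 scheme: ScoringScheme = DEFAULT_SCHEME,
                 max_gaps: int = 1):
    """Best-alignment penalty score; returns ``(score, alignment)``.

    The target window is given 5'->3'; alignment columns run from the
    target 5' end, so column k faces miRNA position m - k (miRNA drawn
    3'->5'). With at most one gap the window must be within 1 nt of the
    miRNA length.
    """
    mir = dna(mirna)
    tgt = dna(target_window)
    m, w = len(mir), len(tgt)
    if abs(w - m) > max_gaps:
        raise ScoringError(
            f"window length {w} incompatible with miRNA length {m} "
            f"and {max_gaps} gap(s)")
    best = None
    for kind, g in _alignment_variants(m, w):
        score = 0.0
        mir_line, pair_line, tgt_line = [], [], []
        ti = 0
        for k in range(m):
            p = m - k
            if kind == "ins" and k == g:
                p_ins = min(max(m - g, 1), m)
                score += scheme.gap * scheme.mult(p_ins)
                mir_line.append("-")
                pair_line.append(" ")
                tgt_line.append(tgt[ti])
                ti += 1
            if kind == "del" and p == g:
                score += scheme.gap * scheme.mult(p)
                mir_line.append(mir[p - 1])
                pair_line.append(" ")
                tgt_line.append("-")
                continue
            mb, tb = mir[p - 1], tgt[ti]
            pen = scheme.pair_penalty(p, mb, tb)
            score += pen
            mir_line.append(mb)
            pair_line.append("|" if (mb, tb) in _WC
                             else ("o" if (mb, tb) in _WOBBLE else " "))
            tgt_line.append(tb)
            ti += 1
        if kind == "ins" and g == m:
            p_ins = 1
            score += scheme.gap * scheme.mult(p_ins)
            mir_line.append("-")
            pair_line.append(" ")
            tgt_line.append(tgt[ti])
            ti += 1
        if best is None or score < best[0]:
            best = (score, ("".join(mir_line), "".join(pair_line),
                            "".join(tgt_line)))
    return best


# ---------------------------------------------------------------------------
# vectorized transcript scan

@njit(cache=True)
def _scan_scores(t, colpen, gd, gi):  # pragma: no cover - numba
    """Best score per start for window lengths m, m-1 and m+1."""
    L = t.shape[0]
    m = colpen.shape[0]
    n0 = max(L - m + 1, 0)
    S0 = np.full(n0, np.inf)
    for s in range(n0):
        tot = 0.0
        for k in range(m):
            tot += colpen[k, t[s + k]]
        S0[s] = tot
    n1 = max(L - (m - 1) + 1, 0)
    S1 = np.full(n1, np.inf)
    for s in range(n1):
        best = np.inf
        for k0 in range(m):
            sc = gd[k0]
            for k in range(k0):
                sc += colpen[k, t[s + k]]
            for k in range(k0 + 1, m):
                sc += colpen[k, t[s + k - 1]]
            if sc < best:
                best = sc
        S1[s] = best
    n2 = max(L - (m + 1) + 1, 0)
    S2 = np.full(n2, np.inf)
    for s in range(n2):
        best = np.inf
        for g in range(m + 1):
            sc = gi[g]
            for k in range(g):
                sc += colpen[k, t[s + k]]
            for k in range(g, m):
                sc += colpen[k, t[s + k + 1]]
            if sc < best:
                best = sc
        S2[s] = best
    return S0, S1, S2


_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"


def _penalty_tables(mir: str, scheme: ScoringScheme):
    m = len(mir)
    colpen = np.zeros((m, 4))
    for k in range(m):
        p = m - k
        for b in range(4):
            colpen[k, b] = scheme.pair_penalty(p, mir[p - 1], _BASES[b])
    gd = np.array([scheme.gap * scheme.mult(m - k) for k in range(m)])
    gi = np.array([scheme.gap * scheme.mult(min(max(m - g, 1), m))
                   for g in range(m + 1)])
    return colpen, gd, gi


def scan_transcript(mirna: str, transcript_seq: str, cutoff: float = 5.0,
                    scheme: ScoringScheme = DEFAULT_SCHEME):
    """All sites scoring <= cutoff, overlapping windows reduced to minima.

    Returns ``(site_start, site_end, score)`` tuples, 1-based inclusive.
    """
    mir = dna(mirna)
    seq = dna(transcript_seq)
    m = len(mir)
    if len(seq) < m - 1:
        return []
    t = np.array([_CODE.get(c, 0) for c in seq], dtype=np.int8)
    colpen, gd, gi = _penalty_tables(mir, scheme)
    S0, S1, S2 = _scan_scores(t, colpen, gd, gi)
    raw = []
    for arr, length in ((S0, m), (S1, m - 1), (S2, m + 1)):
        for s in range(len(arr)):
            if arr[s] <= cutoff:
                raw.append((s + 1, s + length, float(arr[s]), length))
    if not raw:
        return []
    # cluster overlapping windows, keep the local minimum
    raw.sort(key=lambda x: (x[0], x[1]))
    clusters = []
    cur = [raw[0]]
    cur_end = raw[0][1]
    for site in raw[1:]:
        if site[0] <= cur_end:
            cur.append(site)
            cur_end = max(cur_end, site[1])
        else:
            clusters.append(cur)
            cur = [site]
            cur_end = site[1]
    clusters.append(cur)
    out = []
    for group in clusters:
        best = min(group, key=lambda x: (x[2], x[0], abs(x[3] - m)))
        out.append((best[0], best[1], best[2]))
    return out


# ---------------------------------------------------------------------------
# region localization and degradome support

@dataclass
class TranscriptInfo:
    """Transcript length and CDS span in transcript coordinates."""
    tx_id: str
    length: int
    cds_start: int | None  # None = no CDS annotated
    cds_end: int | None


def locate_region(site_start: int, site_end: int,
                  info: TranscriptInfo | None) -> str:
    """5UTR / CDS / 3UTR by majority of covered bases; ties go to CDS."""
    if info is None:
        warnings.warn("transcript absent from annotation; region unknown")
        return "unknown"
    if info.cds_start is None:
        return "noncoding"
    c1, c2 = info.cds_start, info.cds_end
    n5 = max(0, min(site_end, c1 - 1) - site_start + 1)
    ncds = max(0, min(site_end, c2) - max(site_start, c1) + 1)
    n3 = max(0, site_end - max(site_start, c2 + 1) + 1)
    best = max(n5, ncds, n3)
    if ncds == best:
        return "CDS"
    return "5UTR" if n5 >= n3 else "3UTR"


def cleavage_positions(site_start: int, mirna_len: int) -> tuple[int, int]:
    """Transcript bases paired to miRNA positions 10 and 11."""
    return site_start + mirna_len - 10, site_start + mirna_len - 11


def degradome_support(site_start: int, mirna_len: int, transcript_seq: str,
                      degradome_tags) -> int:
    """Reads whose exact-match 5' end sits at the cleavage position."""
    targets = set(cleavage_positions(site_start, mirna_len))
    seq = dna(transcript_seq)
    count = 0
    for tag in degradome_tags:
        tseq = dna(tag[1] if isinstance(tag, tuple) else str(tag))
        if not tseq:
            continue
        i = seq.find(tseq)
        while i != -1:
            if i + 1 in targets:
                count += 1
            i = seq.find(tseq, i + 1)
    return count


# ---------------------------------------------------------------------------
# full scan

def scan_targets(mirnas, transcripts: dict[str, str], cutoff: float = 5.0,
                 scheme: ScoringScheme = DEFAULT_SCHEME,
                 tx_info: dict[str, TranscriptInfo] | None = None,
                 degradome_tags=None) -> list[TargetSite]:
    """Scan every miRNA against every transcript.

    ``mirnas`` yields ``(name, sequence)`` pairs. When ``tx_info`` /
    ``degradome_tags`` are provided, sites are localized to transcript
    regions and annotated with degradome read support.
    """
    sites = []
    for name, mir_seq in mirnas:
        mir = dna(mir_seq)
        for tx_id in sorted(transcripts):
            seq = dna(transcripts[tx_id])
            for s1, s2, _score in scan_transcript(mir, seq, cutoff, scheme):
                score, alignment = score_duplex(mir, seq[s1 - 1:s2], scheme)
                if score > cutoff:
                    continue
                site = TargetSite(name, tx_id, s1, s2, score, alignment)
                if tx_info is not None:
                    site.region = locate_region(s1, s2, tx_info.get(tx_id))
                if degradome_tags is not None:
                    site.degradome_reads = degradome_support(
                        s1, len(mir), seq, degradome_tags)
                sites.append(site)
    return sites


def targets_table(sites: list[TargetSite]) -> pd.DataFrame:
    rows = [{
        "mirna": s.mirna_name, "transcript": s.transcript_id,
        "start": s.site_start, "end": s.site_end, "score": s.score,
        "region": s.region, "degradome_reads": s.degradome_reads,
        "alignment_mirna_3to5": s.alignment[0],
        "alignment_pairs": s.alignment[1],
        "alignment_target_5to3": s.alignment[2],
    } for s in sites]
    return pd.DataFrame(rows, columns=[
        "mirna", "transcript", "start", "end", "score", "region",
        "degradome_reads", "alignment_mirna_3to5", "alignment_pairs",
        "alignment_target_5to3"])
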