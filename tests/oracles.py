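"""Independent brute-force oracles used to cross-check the fast paths.

These deliberately re-derive each quantity with a different algorithm from
the implementation: recursive enumeration instead of the bottom-up fold DP,
a sliding-window scan instead of str.find mapping, a gap-state alignment DP
instead of gap-placement enumeration, and a naive double loop for the
offset-Hamming distance.
"""

from functools import lru_cache

PAIR_WEIGHT = {
    ("A", "U"): 2, ("U", "A"): 2,
    ("G", "C"): 3, ("C", "G"): 3,
    ("G", "U"): 1, ("U", "G"): 1,
}


def fold_max_weight(seq: str, min_loop: int = 3) -> int:
    """Maximum pairing weight by recursion over 'first base unpaired or
    paired with k', cached per interval."""
    s = seq.upper().replace("T", "U")

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if j - i < min_loop + 1:
            return 0
        top = best(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            w = PAIR_WEIGHT.get((s[i], s[k]), 0)
            if w:
                top = max(top, w + best(i + 1, k - 1) + best(k + 1, j))
        return top

    return best(0, len(s) - 1)


def enumerate_structures(seq: str, min_loop: int = 3):
    """Yield every nested structure as a frozenset of (i, j) pairs
    (0-based). Exponential; only for very short sequences."""
    s = seq.upper().replace("T", "U")

    def rec(i: int, j: int):
        if j - i < min_loop + 1:
            yield frozenset()
            return
        yield from rec(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if (s[i], s[k]) in PAIR_WEIGHT:
                for left in rec(i + 1, k - 1):
                    for right in rec(k + 1, j):
                        yield frozenset({(i, k)}) | left | right

    yield from rec(0, len(s) - 1)


def structure_weight(seq: str, pairs) -> int:
    s = seq.upper().replace("T", "U")
    return sum(PAIR_WEIGHT[(s[i], s[j])] for i, j in pairs)


COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def naive_scan(genome: dict, tag: str):
    """All exact occurrences on both strands by per-position comparison."""
    rc = "".join(COMPLEMENT[c] for c in reversed(tag))
    hits = []
    for chrom in sorted(genome):
        s = genome[chrom]
        for i in range(len(s) - len(tag) + 1):
            window = s[i:i + len(tag)]
            if window == tag:
                hits.append((chrom, i + 1, i + len(tag), "+"))
            if window == rc:
                hits.append((chrom, i + 1, i + len(tag), "-"))
    return hits


def duplex_min_score(mirna: str, window: str, max_gaps: int = 1,
                     mismatch: float = 1.0, gap: float = 1.0,
                     wobble: float = 0.5, seed=(2, 13), mult: float = 2.0):
    """Minimum duplex penalty by a gap-state alignment DP.

    States: (i miRNA bases consumed from the 3' end, j target bases
    consumed from the 5' end, g gaps used). miRNA position p = m - i for
    the next column.
    """
    mir = mirna.upper().replace("U", "T")
    tgt = window.upper().replace("U", "T")
    m, w = len(mir), len(tgt)
    wc = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
    wob = {("G", "T"), ("T", "G")}

    def m_of(p):
        return mult if seed[0] <= p <= seed[1] else 1.0

    INF = float("inf")
    dp = [[[INF] * (max_gaps + 1) for _ in range(w + 1)] for _ in range(m + 1)]
    for g in range(max_gaps + 1):
        dp[0][0][0] = 0.0
    for i in range(m + 1):
        for j in range(w + 1):
            for g in range(max_gaps + 1):
                cur = dp[i][j][g]
                if cur == INF:
                    continue
                if i < m and j < w:
                    p = m - i
                    pair = (mir[p - 1], tgt[j])
                    pen = 0.0 if pair in wc else (
                        wobble * m_of(p) if pair in wob else mismatch * m_of(p))
                    if cur + pen < dp[i + 1][j + 1][g]:
                        dp[i + 1][j + 1][g] = cur + pen
                if i < m and g < max_gaps:  # miRNA base faces a target gap
                    p = m - i
                    pen = gap * m_of(p)
                    if cur + pen < dp[i + 1][j][g + 1]:
                        dp[i + 1][j][g + 1] = cur + pen
                if j < w and g < max_gaps:  # extra target base
                    p = min(max(m - i, 1), m)
                    pen = gap * m_of(p)
                    if cur + pen < dp[i][j + 1][g + 1]:
                        dp[i][j + 1][g + 1] = cur + pen
    return min(dp[m][w])


def offset_hamming(q: str, r: str) -> int:
    """Minimum substitution distance over all ungapped offsets; overhangs
    count as mismatches."""
    best = len(q) + len(r)
    for off in range(-len(q), len(r) + 1):
        mism = 0
        overlap = 0
        for i, c in enumerate(q):
            j = i + off
            if 0 <= j < len(r):
                overlap += 1
                mism += c != r[j]
        best = min(best, mism + (len(q) - overlap) + (len(r) - overlap))
    return best
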