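"""Synthetic dataset generator.

Builds a miniature, fully-known analogue of a plant sRNA-seq study: a random
genome with miRNA hairpin precursors planted at known positions, a collapsed
small-RNA read library (with adapters, noise and low-quality reads), a toy
protein-coding annotation whose transcripts carry planted miRNA target
sites, a degradome library with 5' ends concentrated at the expected
cleavage positions, and a gene x tissue TPM matrix. Every planted feature is
recorded in truth tables so the discovery and statistics modules can be
tested for exact recovery.

Geometry of a planted precursor (mature on the 5' arm)::

    5'- [mature] [loop] [star] -3'

where star is the reverse complement of the mature, optionally degraded with
``star_mispairings`` substitutions (which break base pairs without creating
G:U wobbles) and ``star_bulges`` 2-nt insertions (single-strand bulges).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from ._seq import dna, random_seq, revcomp, rna
from .config import ConfigurationError, SimulationConfig

# distinct substreams per generator stage, so stages are individually
# reproducible and independent
_STREAMS = {
    "genome": 1,
    "hairpins": 2,
    "srna": 3,
    "annotation": 4,
    "tpm": 5,
    "degradome": 6,
    "reference": 7,
}


def _rng(cfg: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, _STREAMS[stage]])


class CapacityError(RuntimeError):
    """Raised when the genome is too short for the requested insertions."""


@dataclass
class TruthRecord:
    """One planted miRNA locus; coordinates are 1-based inclusive."""

    locus_id: str
    chrom: str
    start: int  # mature interval on the forward strand
    end: int
    strand: str
    mature_seq: str  # RNA alphabet
    family: str  # reference family name or "novel"
    mispairings: int
    bulges: int
    precursor_start: int
    precursor_end: int
    planted_targets: list = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.start <= self.end
        assert 20 <= len(self.mature_seq) <= 22


class PlantedTarget(NamedTuple):
    locus_id: str
    transcript_id: str
    site_start: int  # 1-based transcript coordinates
    site_end: int
    region: str
    cleavage_pos: int  # transcript base paired to miRNA position 10
    n_tags: int


class FastqRead(NamedTuple):
    id: str
    seq: str
    qual: str


# ---------------------------------------------------------------------------
# genome

def generate_genome(cfg: SimulationConfig) -> dict[str, str]:
    """Random chromosomes with the configured GC content."""
    if cfg.n_chromosomes <= 0 or cfg.chrom_length <= 0:
        raise ConfigurationError("need n_chromosomes >= 1 and chrom_length >= 1")
    rng = _rng(cfg, "genome")
    return {
        f"chr{i + 1}": random_seq(rng, cfg.chrom_length, cfg.gc_fraction)
        for i in range(cfg.n_chromosomes)
    }


# ---------------------------------------------------------------------------
# reference mature set (miRBase-like)

_FAMILY_POOL = [
    "miR156", "miR159", "miR160", "miR164", "miR166", "miR167", "miR171",
    "miR172", "miR319", "miR390", "miR393", "miR396", "miR398", "miR828",
    "miR2118", "miR7125", "miR5290", "miR1511", "miR169", "miR399",
]


def make_reference_set(cfg: SimulationConfig, n_families: int | None = None):
    """Synthetic known-mature reference, miRBase ``mature.fa`` dialect.

    Returns a list of ``(name, mature_rna)`` pairs such as
    ``("ath-miR156", "UGACAGAAGAGAGUGAGCACA")``. Sequences are random: the
    reference only needs to be internally consistent with the loci planted
    from it, not biologically real.
    """
    rng = _rng(cfg, "reference")
    if n_families is None:
        n_families = max(8, math.ceil(cfg.conserved_fraction * cfg.n_true_mirnas))
    if n_families > len(_FAMILY_POOL):
        n_families = len(_FAMILY_POOL)
    out = []
    for fam in _FAMILY_POOL[:n_families]:
        seq = random_seq(rng, cfg.mature_length, 0.5)
        out.append((f"ath-{fam}", rna(seq)))
    return out


# ---------------------------------------------------------------------------
# hairpin planting

# substitutions that break a pair without creating a G:U wobble,
# keyed by the mature base the star position faces
_NONPAIRING = {"A": "ACG", "C": "ACT", "G": "AG", "T": "CT"}
_PARTNERS = {"A": "T", "C": "G", "G": "CT", "T": "AG"}


def _pick_positions(rng: np.random.Generator, n: int, lo: int, hi: int,
                    min_gap: int = 2) -> list[int]:
    """n distinct positions in [lo, hi], pairwise at least min_gap apart."""
    if n == 0:
        return []
    # spacing transform: sample without the gap constraint in a shrunken
    # range, then re-expand
    shrink = (n - 1) * (min_gap - 1)
    if hi - shrink < lo or n > hi - shrink - lo + 1:
        raise CapacityError("mature too short for requested defects")
    base = sorted(rng.choice(np.arange(lo, hi - shrink + 1), size=n,
                             replace=False))
    return [int(p) + i * (min_gap - 1) for i, p in enumerate(base)]


def _disruptive_base(mature_dna: str, i: int, rng: np.random.Generator) -> str:
    """A star base that pairs neither mature[i] nor its close neighbours."""
    L = len(mature_dna)
    context = mature_dna[max(0, i - 2):min(L, i + 3)]
    forbidden = set()
    for b in context:
        forbidden.update(_PARTNERS[b])
    strict = [c for c in _NONPAIRING[mature_dna[i]] if c not in forbidden]
    choices = strict or list(_NONPAIRING[mature_dna[i]])
    return choices[int(rng.integers(len(choices)))]


def build_precursor(mature_dna: str, loop_seq: str, mispairings: int,
                    bulges: int, rng: np.random.Generator) -> str:
    """mature + loop + degraded star, 5' arm geometry (single attempt)."""
    L = len(mature_dna)
    star = list(revcomp(mature_dna))  # star[k] faces mature[L - 1 - k]
    sub_mature_pos = _pick_positions(rng, mispairings, 3, L - 4)
    for i in sub_mature_pos:
        star[L - 1 - i] = _disruptive_base(mature_dna, i, rng)
    # 2-nt insertions on the star strand, away from the substitutions
    if bulges:
        ins_mature_pos = _pick_positions(rng, bulges, 5, L - 6, min_gap=4)
        ins_star = sorted((L - 1 - i for i in ins_mature_pos), reverse=True)
        for k in ins_star:
            i = L - 1 - k
            insert = "".join(_disruptive_base(mature_dna, i, rng)
                             for _ in range(2))
            star[k:k] = list(insert)
    return mature_dna + loop_seq + "".join(star)


def verified_precursor(mature_dna: str, cfg: SimulationConfig,
                       mispairings: int, bulges: int,
                       rng: np.random.Generator, max_attempts: int = 200) -> str:
    """Build a precursor whose *folded* duplex shows the configured defects.

    The maximum-weight fold can locally re-register a damaged stem, so a
    single construction attempt does not guarantee the measured
    mispairing/bulge counts. This retries (deterministically, driven by
    ``rng``) until folding the bare precursor reproduces the configuration:
    exactly ``(mispairings, bulges)`` for plantable loci, and a failing
    hairpin call for loci meant to violate the thresholds.
    """
    from .hairpin_discovery import call_hairpin, evaluate_duplex, fold

    want_good = mispairings <= 4 and bulges <= 1
    L = len(mature_dna)
    for _ in range(max_attempts):
        loop_seq = random_seq(rng, cfg.loop_length, 0.4)
        prec = build_precursor(mature_dna, loop_seq, mispairings, bulges, rng)
        stats, _reason = evaluate_duplex(fold(prec), 1, L)
        ok, _ = call_hairpin(stats)
        if want_good:
            if (stats is not None and stats.mispairings == mispairings
                    and stats.bulges == bulges):
                return prec
        else:
            if not ok and (stats is None
                           or stats.mispairings >= min(mispairings, 5)
                           or stats.bulges >= 2):
                return prec
    raise CapacityError(
        f"could not realise a precursor with {mispairings} mispairings "
        f"and {bulges} bulges for {mature_dna}")


def _place_intervals(rng: np.random.Generator, genome: dict[str, str],
                     lengths: list[int], occupied: list[tuple[str, int, int]],
                     margin: int = 300, min_sep: int = 200,
                     max_tries: int = 2000) -> list[tuple[str, int]]:
    """Non-overlapping 1-based start positions, round-robin over chromosomes."""
    chroms = list(genome)
    placed = []
    for idx, length in enumerate(lengths):
        chrom = chroms[idx % len(chroms)]
        clen = len(genome[chrom])
        hi = clen - margin - length
        if hi <= margin:
            raise CapacityError("chromosome too short for insertion")
        for _ in range(max_tries):
            start = int(rng.integers(margin, hi + 1))
            ok = all(
                c != chrom or start > e + min_sep or start + length - 1 < s - min_sep
                for c, s, e in occupied)
            if ok:
                occupied.append((chrom, start, start + length - 1))
                placed.append((chrom, start))
                break
        else:
            raise CapacityError("could not place requested loci")
    return placed


def plant_hairpins(genome: dict[str, str], cfg: SimulationConfig,
                   mispairing_schedule: Sequence[int] | None = None,
                   bulge_schedule: Sequence[int] | None = None,
                   reference: list[tuple[str, str]] | None = None,
                   occupied: list | None = None):
    """Insert ``cfg.n_true_mirnas`` hairpin precursors into the genome.

    Returns ``(modified genome, truth records)``. Per-locus defect counts may
    be given explicitly via the schedules; otherwise ``cfg.star_mispairings``
    / ``cfg.star_bulges`` apply to every locus. The first
    ``round(conserved_fraction * n)`` loci take their mature sequence from
    ``reference`` (generated if not supplied); the rest are novel random
    matures.

    Each planted locus is verified *in genomic context*: the locus is
    screened with the discovery defaults, and the construction is retried
    (new loop, substitution letters and position, deterministically) until
    the folded duplex measures exactly the configured defects (loci within
    thresholds) or fails the hairpin call (loci beyond thresholds). Loci
    are kept >= 300 nt apart so later insertions cannot perturb a verified
    fold window.
    """
    from .genome_mapper import GenomicHit
    from .hairpin_discovery import screen_hit
    from .srna_preprocess import SmallRNATag

    rng = _rng(cfg, "hairpins")
    n = cfg.n_true_mirnas
    mis = list(mispairing_schedule) if mispairing_schedule is not None \
        else [cfg.star_mispairings] * n
    bul = list(bulge_schedule) if bulge_schedule is not None \
        else [cfg.star_bulges] * n
    if len(mis) != n or len(bul) != n:
        raise ConfigurationError("schedule length must equal n_true_mirnas")
    if reference is None:
        reference = make_reference_set(cfg)
    n_conserved = round(cfg.conserved_fraction * n)

    matures: list[tuple[str, str]] = []  # (mature_dna, family)
    seen = set()
    for i in range(n):
        if i < n_conserved and i < len(reference):
            name, seq = reference[i]
            fam = name.split("-", 1)[1]
            mat = dna(seq)
        else:
            fam = "novel"
            mat = random_seq(rng, cfg.mature_length, 0.5)
            while mat in seen:
                mat = random_seq(rng, cfg.mature_length, 0.5)
        seen.add(mat)
        matures.append((mat, fam))

    occupied = occupied if occupied is not None else []
    mutable = {c: list(s) for c, s in genome.items()}
    chroms = list(genome)
    truth = []
    for i, (mat, fam) in enumerate(matures):
        L = len(mat)
        want_good = mis[i] <= 4 and bul[i] <= 1
        chrom = chroms[i % len(chroms)]
        clen = len(mutable[chrom])
        committed = False
        for attempt in range(120):
            loop_seq = random_seq(rng, cfg.loop_length, 0.4)
            prec = build_precursor(mat, loop_seq, mis[i], bul[i], rng)
            start = int(rng.integers(300, clen - 300 - len(prec) + 1))
            pend = start + len(prec) - 1
            if any(c == chrom and start <= e + 300 and pend >= s - 300
                   for c, s, e in occupied):
                continue
            strand = "+" if i % 2 == 0 else "-"
            segment = prec if strand == "+" else revcomp(prec)
            saved = mutable[chrom][start - 1:start - 1 + len(prec)]
            mutable[chrom][start - 1:start - 1 + len(prec)] = list(segment)
            if strand == "+":
                mstart, mend = start, start + L - 1
            else:
                mstart, mend = pend - L + 1, pend
            view = dict(genome)
            view[chrom] = "".join(mutable[chrom])
            cand = screen_hit(SmallRNATag(mat, 1),
                              GenomicHit(mat, chrom, mstart, mend, strand),
                              view)
            ok = False
            if want_good:
                ok = (cand is not None and cand.accepted
                      and cand.duplex.mispairings == mis[i]
                      and cand.duplex.bulges == bul[i])
            else:
                ok = cand is None or not cand.accepted
            if not ok:
                mutable[chrom][start - 1:start - 1 + len(prec)] = saved
                continue
            occupied.append((chrom, start, pend))
            truth.append(TruthRecord(
                locus_id=f"locus{i + 1}", chrom=chrom, start=mstart,
                end=mend, strand=strand, mature_seq=rna(mat), family=fam,
                mispairings=mis[i], bulges=bul[i],
                precursor_start=start, precursor_end=pend))
            committed = True
            break
        if not committed:
            raise CapacityError(
                f"could not place locus {i + 1} with {mis[i]} mispairings "
                f"and {bul[i]} bulges")
    return {c: "".join(s) for c, s in mutable.items()}, truth


# ---------------------------------------------------------------------------
# sRNA library

def _largest_remainder(total: int, weights: np.ndarray) -> list[int]:
    """Integer partition of ``total`` proportional to ``weights`` (exact sum)."""
    shares = total * weights / weights.sum()
    counts = np.floor(shares).astype(int)
    rem = total - counts.sum()
    order = np.argsort(-(shares - counts), kind="stable")
    for j in order[:rem]:
        counts[j] += 1
    return counts.tolist()


def simulate_srna_library(truth: list[TruthRecord], cfg: SimulationConfig):
    """Raw small-RNA reads (adapter-bearing) as FASTQ records.

    The read count is partitioned deterministically: ``round((1 - noise) *
    depth)`` signal reads distributed over loci by a geometric abundance law
    (ratio ``cfg.abundance_ratio``), the remainder random 18-30-mers. An
    additional ``round(low_quality_fraction * depth)`` reads are copies of
    signal reads with degraded qualities, meant to be removed by the
    quality filter.
    """
    if not truth and cfg.noise_fraction < 1.0:
        raise ConfigurationError("no planted loci and noise_fraction < 1")
    rng = _rng(cfg, "srna")
    n_signal = math.floor((1.0 - cfg.noise_fraction) * cfg.read_depth + 0.5)
    n_noise = cfg.read_depth - n_signal
    reads: list[FastqRead] = []

    if truth:
        weights = np.array([cfg.abundance_ratio ** i for i in range(len(truth))])
        counts = _largest_remainder(n_signal, weights)
    else:
        counts = []
    for rec, count in zip(truth, counts):
        raw = dna(rec.mature_seq) + cfg.adapter
        q = "I" * len(raw)
        for j in range(count):
            reads.append(FastqRead(f"sig_{rec.locus_id}_{j + 1}", raw, q))

    for j in range(n_noise):
        ln = int(rng.integers(18, 31))
        raw = random_seq(rng, ln, 0.5) + cfg.adapter
        reads.append(FastqRead(f"noise_{j + 1}", raw, "I" * len(raw)))

    n_lowq = math.floor(cfg.low_quality_fraction * cfg.read_depth + 0.5)
    signal_reads = [r for r in reads if r.id.startswith("sig_")]
    for j in range(n_lowq):
        src = signal_reads[j % len(signal_reads)] if signal_reads else \
            FastqRead("x", random_seq(rng, 21, 0.5) + cfg.adapter, "")
        nbad = math.ceil(0.2 * len(src.seq))
        qual = "#" * nbad + "I" * (len(src.seq) - nbad)
        reads.append(FastqRead(f"lowq_{j + 1}", src.seq, qual))
    return reads


# ---------------------------------------------------------------------------
# annotation, targets, degradome, TPM

@dataclass
class GeneSketch:
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # genomic, sorted, 1-based inclusive
    transcripts: list  # list of (mrna_id, [exon indices kept])
    utr5_len: int  # transcript-coordinate UTR lengths (0 = no UTR)
    utr3_len: int


def _effective_cds(sk: "GeneSketch", exons) -> tuple[int, int, int, int]:
    """(cds_start, cds_end, utr5_len, utr3_len) in transcript coordinates.

    Transcripts too short to hold both UTRs and a non-trivial CDS fall
    back to whole-transcript CDS with no UTRs.
    """
    txlen = _tx_length(exons)
    cds1, cds2 = sk.utr5_len + 1, txlen - sk.utr3_len
    if cds2 < cds1 + 30:
        return 1, txlen, 0, 0
    return cds1, cds2, sk.utr5_len, sk.utr3_len


def _screen_site(mature_dna: str, chrom: str, ga: int, gb: int,
                 strand: str, genome_view: dict[str, str]) -> bool:
    """True when the discovery screen would accept this occurrence."""
    from .genome_mapper import GenomicHit
    from .hairpin_discovery import screen_hit
    from .srna_preprocess import SmallRNATag

    cand = screen_hit(SmallRNATag(mature_dna, 1),
                      GenomicHit(mature_dna, chrom, ga, gb, strand),
                      genome_view)
    return cand is not None and cand.accepted


@dataclass
class AnnotationBundle:
    genome: dict[str, str]
    gff3: str
    transcripts: dict[str, str]
    tpm: pd.DataFrame
    degradome: list[tuple[str, str]]
    target_truth: list[PlantedTarget]
    expressed_genes: list[str]


def _tx_exons(sketch: GeneSketch, keep: list[int]) -> list[tuple[int, int]]:
    return [sketch.exons[i] for i in keep]


def _tx_length(exons: list[tuple[int, int]]) -> int:
    return sum(e - s + 1 for s, e in exons)


def _tx_to_genome(exons: list[tuple[int, int]], strand: str, tpos: int) -> int:
    """Map a 1-based transcript position to a 1-based genomic position."""
    if strand == "+":
        off = tpos
        for s, e in exons:
            ln = e - s + 1
            if off <= ln:
                return s + off - 1
            off -= ln
    else:
        off = tpos
        for s, e in reversed(exons):
            ln = e - s + 1
            if off <= ln:
                return e - off + 1
            off -= ln
    raise ValueError("transcript position outside exons")


def _genome_slice(genome: dict[str, str], chrom: str, start: int, end: int) -> str:
    return genome[chrom][start - 1:end]


def _tx_sequence(genome, chrom, exons, strand) -> str:
    seq = "".join(_genome_slice(genome, chrom, s, e) for s, e in exons)
    return seq if strand == "+" else revcomp(seq)


def _map_tx_interval(exons, strand, t1, t2):
    """Genomic intervals (list) covering transcript interval [t1, t2]."""
    g1 = _tx_to_genome(exons, strand, t1)
    g2 = _tx_to_genome(exons, strand, t2)
    lo, hi = min(g1, g2), max(g1, g2)
    out = []
    for s, e in exons:
        a, b = max(s, lo), min(e, hi)
        if a <= b:
            out.append((a, b))
    return out


def simulate_annotation(genome: dict[str, str], truth: list[TruthRecord],
                        cfg: SimulationConfig,
                        occupied: list | None = None) -> AnnotationBundle:
    """Toy gene annotation + planted target sites + degradome + TPM.

    Transcript sequences are derived from the (modified) genome, so target
    sites planted as reverse complements of planted matures appear both in
    the genome and in the transcript FASTA. Degradome tags start at the
    transcript base paired to miRNA position 10 of each planted site.
    """
    rng = _rng(cfg, "annotation")
    occupied = occupied if occupied is not None else [
        (t.chrom, t.precursor_start, t.precursor_end) for t in truth]

    sketches: list[GeneSketch] = []
    span_lengths = []
    structures = []
    for i in range(cfg.n_genes):
        n_ex = int(rng.integers(1, 6))
        ex_lens = [int(rng.integers(120, 301)) for _ in range(n_ex)]
        in_lens = [int(rng.integers(60, 201)) for _ in range(n_ex - 1)]
        structures.append((ex_lens, in_lens))
        span_lengths.append(sum(ex_lens) + sum(in_lens))
    placed = _place_intervals(rng, genome, span_lengths, occupied,
                              margin=300, min_sep=300)
    for i, ((chrom, gstart), (ex_lens, in_lens)) in enumerate(zip(placed, structures)):
        gene_id = f"gene{i + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        pos = gstart
        for j, ln in enumerate(ex_lens):
            exons.append((pos, pos + ln - 1))
            pos += ln + (in_lens[j] if j < len(in_lens) else 0)
        transcripts = [(f"{gene_id}.t1", list(range(len(exons))))]
        if len(exons) >= 3 and rng.random() < cfg.isoform_fraction:
            skip = int(rng.integers(1, len(exons) - 1))
            transcripts.append(
                (f"{gene_id}.t2", [k for k in range(len(exons)) if k != skip]))
        has_utr = rng.random() < cfg.utr_fraction
        utr5 = int(rng.integers(60, 121)) if has_utr else 0
        utr3 = int(rng.integers(80, 161)) if has_utr else 0
        sketches.append(GeneSketch(gene_id, chrom, strand, exons,
                                   transcripts, utr5, utr3))

    # ---- plant target sites ------------------------------------------------
    mutable = {c: list(s) for c, s in genome.items()}
    target_truth: list[PlantedTarget] = []
    n_sites = round(cfg.planted_target_fraction * cfg.n_genes)
    region_cycle = ["5UTR", "CDS", "3UTR"]
    # target sites are reverse complements of planted matures; keep them
    # well clear of the precursor fold windows
    forbidden = [(t.chrom, t.precursor_start - 300, t.precursor_end + 300)
                 for t in truth]
    site_idx = 0
    deg_rng = _rng(cfg, "degradome")
    utr_genes = [s for s in sketches if s.utr5_len > 0]
    plain_order = utr_genes + [s for s in sketches if s.utr5_len == 0]
    for sk in plain_order:
        if site_idx >= n_sites or not truth:
            break
        region = region_cycle[site_idx % 3]
        if region != "CDS" and sk.utr5_len == 0:
            region = "CDS"
        trec = truth[site_idx % len(truth)]
        mature_dna = dna(trec.mature_seq)
        m = len(mature_dna)
        mrna_id, keep = sk.transcripts[0]
        exons = _tx_exons(sk, keep)
        txlen = _tx_length(exons)
        cds1, cds2, eff_utr5, _eff_utr3 = _effective_cds(sk, exons)
        if region != "CDS" and eff_utr5 == 0:
            region = "CDS"
        if region == "5UTR":
            lo, hi = 5, cds1 - 1 - m
        elif region == "3UTR":
            lo, hi = cds2 + 1, txlen - m - 35
        else:
            lo, hi = cds1 + 5, cds2 - m - 5
        hi = min(hi, txlen - m - 35)  # room for a downstream degradome tag
        if hi < lo:
            continue
        # the site must sit inside a single exon so the genomic write is
        # contiguous
        cum = 0
        spans = []  # candidate transcript-coordinate ranges, one per exon
        tx_order = exons if sk.strand == "+" else list(reversed(exons))
        for s, e in tx_order:
            ln = e - s + 1
            t_lo, t_hi = cum + 1, cum + ln
            a, b = max(lo, t_lo), min(hi, t_hi - m + 1)
            if b >= a and (t_hi - a + 1) >= m:
                spans.append((a, min(b, t_hi - m + 1)))
            cum += ln
        if not spans:
            continue
        site_tx_seq = revcomp(mature_dna)  # target site as read on the mRNA
        t1 = None
        for _attempt in range(12):
            a, b = spans[_attempt % len(spans)]
            cand_t1 = int(deg_rng.integers(a, b + 1))
            g_intervals = _map_tx_interval(exons, sk.strand, cand_t1,
                                           cand_t1 + m - 1)
            assert len(g_intervals) == 1
            ga, gb = g_intervals[0]
            if any(c == sk.chrom and not (gb < s or ga > e)
                   for c, s, e in forbidden):
                continue
            seg = site_tx_seq if sk.strand == "+" else revcomp(site_tx_seq)
            saved = mutable[sk.chrom][ga - 1:gb]
            mutable[sk.chrom][ga - 1:gb] = list(seg)
            # the written site is an exact reverse-complement occurrence of
            # the mature and therefore maps; make sure chance
            # complementarity around it cannot screen as a hairpin locus
            view = dict(genome)
            view[sk.chrom] = "".join(mutable[sk.chrom])
            hit_strand = "+" if sk.strand == "-" else "-"
            screened = _screen_site(mature_dna, sk.chrom, ga, gb, hit_strand,
                                    view)
            if screened:
                mutable[sk.chrom][ga - 1:gb] = saved
                continue
            t1 = cand_t1
            forbidden.append((sk.chrom, ga, gb))
            break
        if t1 is None:
            continue
        t2 = t1 + m - 1
        cleave = t1 + (m - 10)  # base paired to miRNA position 10
        n_tags = cfg.degradome_reads_per_site + (site_idx % 3)
        target_truth.append(PlantedTarget(
            trec.locus_id, mrna_id, t1, t2, region, cleave, n_tags))
        trec.planted_targets.append((mrna_id, t1))
        site_idx += 1

    final_genome = {c: "".join(s) for c, s in mutable.items()}

    # ---- GFF3 + transcript FASTA ------------------------------------------
    lines = ["##gff-version 3"]
    tx_seqs: dict[str, str] = {}
    for sk in sketches:
        g1 = min(s for s, _ in sk.exons)
        g2 = max(e for _, e in sk.exons)
        lines.append("\t".join([
            sk.chrom, "berrymir_sim", "gene", str(g1), str(g2), ".",
            sk.strand, ".", f"ID={sk.gene_id}"]))
        for mrna_id, keep in sk.transcripts:
            exons = _tx_exons(sk, keep)
            t1 = min(s for s, _ in exons)
            t2 = max(e for _, e in exons)
            lines.append("\t".join([
                sk.chrom, "berrymir_sim", "mRNA", str(t1), str(t2), ".",
                sk.strand, ".", f"ID={mrna_id};Parent={sk.gene_id}"]))
            for s, e in exons:
                lines.append("\t".join([
                    sk.chrom, "berrymir_sim", "exon", str(s), str(e), ".",
                    sk.strand, ".", f"Parent={mrna_id}"]))
            txlen = _tx_length(exons)
            cds1, cds2, utr5_len, utr3_len = _effective_cds(sk, exons)
            for s, e in _map_tx_interval(exons, sk.strand, cds1, cds2):
                lines.append("\t".join([
                    sk.chrom, "berrymir_sim", "CDS", str(s), str(e), ".",
                    sk.strand, "0", f"Parent={mrna_id}"]))
            if utr5_len > 0:
                for s, e in _map_tx_interval(exons, sk.strand, 1, utr5_len):
                    lines.append("\t".join([
                        sk.chrom, "berrymir_sim", "five_prime_UTR", str(s),
                        str(e), ".", sk.strand, ".", f"Parent={mrna_id}"]))
            if utr3_len > 0:
                for s, e in _map_tx_interval(exons, sk.strand, cds2 + 1, txlen):
                    lines.append("\t".join([
                        sk.chrom, "berrymir_sim", "three_prime_UTR", str(s),
                        str(e), ".", sk.strand, ".", f"Parent={mrna_id}"]))
            tx_seqs[mrna_id] = _tx_sequence(final_genome, sk.chrom, exons,
                                            sk.strand)
    gff3 = "\n".join(lines) + "\n"

    # ---- degradome ---------------------------------------------------------
    degradome: list[tuple[str, str]] = []
    cleave_by_tx: dict[str, set[int]] = {}
    for pt in target_truth:
        cleave_by_tx.setdefault(pt.transcript_id, set()).update(
            {pt.cleavage_pos, pt.cleavage_pos + 1})
    k = 0
    for pt in target_truth:
        seq = tx_seqs[pt.transcript_id]
        tag = seq[pt.cleavage_pos - 1:pt.cleavage_pos - 1 + 20]
        for _ in range(pt.n_tags):
            k += 1
            degradome.append((f"deg_{k}", tag))
    tx_ids = sorted(tx_seqs)
    for j in range(cfg.degradome_noise_tags):
        tid = tx_ids[int(deg_rng.integers(len(tx_ids)))]
        seq = tx_seqs[tid]
        for _ in range(20):
            pos = int(deg_rng.integers(1, max(2, len(seq) - 20)))
            if pos not in cleave_by_tx.get(tid, set()):
                break
        degradome.append((f"degnoise_{j + 1}", seq[pos - 1:pos - 1 + 20]))

    # ---- TPM matrix --------------------------------------------------------
    tpm_rng = _rng(cfg, "tpm")
    gene_ids = [sk.gene_id for sk in sketches]
    n_expr = round(cfg.expressed_fraction * cfg.n_genes)
    order = tpm_rng.permutation(cfg.n_genes)
    expressed = sorted(gene_ids[i] for i in order[:n_expr])
    expr_mask = np.array([g in set(expressed) for g in gene_ids])
    tissues = [f"tissue{j + 1:02d}" for j in range(cfg.n_tissues)]
    mat = np.zeros((cfg.n_genes, cfg.n_tissues))
    base = tpm_rng.lognormal(mean=2.0, sigma=1.2, size=cfg.n_genes)
    for j in range(cfg.n_tissues):
        unexpr = tpm_rng.uniform(0.05, 0.8, size=(~expr_mask).sum())
        raw = base * tpm_rng.lognormal(0.0, 0.8, size=cfg.n_genes)
        col = np.zeros(cfg.n_genes)
        col[~expr_mask] = unexpr
        scale = (1e6 - unexpr.sum()) / raw[expr_mask].sum() if expr_mask.any() else 0
        col[expr_mask] = raw[expr_mask] * scale
        mat[:, j] = col
    tpm = pd.DataFrame(mat, index=pd.Index(gene_ids, name="gene_id"),
                       columns=tissues)

    return AnnotationBundle(final_genome, gff3, tx_seqs, tpm, degradome,
                            target_truth, expressed)


# ---------------------------------------------------------------------------
# orchestration

@dataclass
class SyntheticDataset:
    cfg: SimulationConfig
    genome: dict[str, str]
    truth: list[TruthRecord]
    reference: list[tuple[str, str]]
    reads: list[FastqRead]
    annotation: AnnotationBundle


def simulate_dataset(cfg: SimulationConfig,
                     mispairing_schedule: Sequence[int] | None = None,
                     bulge_schedule: Sequence[int] | None = None) -> SyntheticDataset:
    """Run every generator stage in order; single entry point for tests/CLI."""
    genome = generate_genome(cfg)
    reference = make_reference_set(cfg)
    occupied: list = []
    genome, truth = plant_hairpins(genome, cfg, mispairing_schedule,
                                   bulge_schedule, reference, occupied)
    annotation = simulate_annotation(genome, truth, cfg, occupied)
    reads = simulate_srna_library(truth, cfg)
    return SyntheticDataset(cfg, annotation.genome, truth, reference, reads,
                            annotation)


TRUTH_COLUMNS = ["locus_id", "chrom", "start", "end", "strand", "mature_seq",
                 "family", "mispairings", "bulges", "precursor_start",
                 "precursor_end", "planted_targets"]


def truth_table(truth: list[TruthRecord]) -> pd.DataFrame:
    rows = []
    for t in truth:
        d = {k: getattr(t, k) for k in TRUTH_COLUMNS[:-1]}
        d["planted_targets"] = ";".join(f"{tid}:{pos}"
                                        for tid, pos in t.planted_targets)
        rows.append(d)
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Write every artifact of a dataset as plain-text files."""
    from pathlib import Path

    from . import io as bio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bio.write_fasta(out / "genome.fa", ds.genome.items())
    bio.write_fasta(out / "reference_mature.fa", ds.reference)
    bio.write_fastq(out / "reads.fastq", ds.reads)
    bio.write_fasta(out / "reads.fa", [(r.id, r.seq) for r in ds.reads])
    (out / "annotation.gff3").write_text(ds.annotation.gff3)
    bio.write_fasta(out / "transcripts.fa", sorted(ds.annotation.transcripts.items()))
    bio.write_fasta(out / "degradome.fa", ds.annotation.degradome)
    ds.annotation.tpm.to_csv(out / "tpm.tsv", sep="\t", float_format="%.4f")
    truth_table(ds.truth).to_csv(out / "truth.tsv", sep="\t", index=False)
    pd.DataFrame(ds.annotation.target_truth).to_csv(
        out / "targets_truth.tsv", sep="\t", index=False)
    pd.Series(ds.annotation.expressed_genes, name="gene_id").to_csv(
        out / "expressed_truth.tsv", sep="\t", index=False)
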