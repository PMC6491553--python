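"""Annotation summary statistics, comparison, gene-ID bookkeeping.

Covers the bookkeeping around a GFF3 gene annotation: per-annotation
summary statistics (gene counts, exon/intron/CDS/UTR lengths, isoform
numbers), structural comparison of two annotations by intron-chain
identity, the FvH4-style gene-ID assignment rules for added / split /
merged / removed genes, expressed-gene counting from a TPM matrix, and
evidence-support metrics (Annotation Edit Distance and an exon-level
quality-index proxy).

Percentages are rounded half-up to two decimals throughout, matching the
convention used in published annotation reports.
"""

from __future__ import annotations

import re
import tempfile
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import gffutils
import pandas as pd

from .target_prediction import TranscriptInfo


# ---------------------------------------------------------------------------
# models and parsing

@dataclass
class TranscriptModel:
    tx_id: str
    exons: list  # [(start, end)] 1-based inclusive, sorted
    cds: list  # [(start, end)]
    utr5: list
    utr3: list
    strand: str = "+"

    @property
    def intron_chain(self) -> tuple:
        return tuple((e1 + 1, s2 - 1)
                     for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]))

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: list = field(default_factory=list)


class AnnotationParseError(ValueError):
    pass


def parse_gff3(source) -> dict[str, GeneModel]:
    """Parse a GFF3 file (path or text) into gene models via gffutils."""
    text = None
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        path = str(source)
    else:
        text = str(source)
        tmp = tempfile.NamedTemporaryFile("w", suffix=".gff3", delete=False)
        tmp.write(text)
        tmp.close()
        path = tmp.name
    try:
        db = gffutils.create_db(path, dbfn=":memory:", force=True,
                                keep_order=True,
                                merge_strategy="create_unique")
    except Exception as exc:
        raise AnnotationParseError(f"GFF3 parse failure: {exc}") from exc
    models: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        gm = GeneModel(gene.id, gene.seqid, gene.strand, gene.start, gene.end)
        for mrna in db.children(gene, featuretype="mRNA", order_by="start"):
            def spans(ftype):
                return sorted((f.start, f.end) for f in
                              db.children(mrna, featuretype=ftype))
            exons = spans("exon")
            if not exons:
                raise AnnotationParseError(
                    f"mRNA {mrna.id} of gene {gene.id} has no exon rows")
            tm = TranscriptModel(mrna.id, exons, spans("CDS"),
                                 spans("five_prime_UTR"),
                                 spans("three_prime_UTR"), mrna.strand)
            gm.transcripts.append(tm)
        if gm.transcripts:
            models[gm.gene_id] = gm
    return models


def _tx_coord(exons, strand, gpos):
    """Genomic -> 1-based transcript coordinate."""
    off = 0
    if strand == "+":
        for s, e in exons:
            if s <= gpos <= e:
                return off + gpos - s + 1
            off += e - s + 1
    else:
        for s, e in reversed(exons):
            if s <= gpos <= e:
                return off + e - gpos + 1
            off += e - s + 1
    raise ValueError("position not exonic")


def transcript_registry(models: dict[str, GeneModel]) -> dict[str, TranscriptInfo]:
    """Transcript-coordinate CDS spans, for target-site localization."""
    reg = {}
    for gm in models.values():
        for tm in gm.transcripts:
            length = sum(e - s + 1 for s, e in tm.exons)
            if tm.cds:
                glo = min(s for s, _ in tm.cds)
                ghi = max(e for _, e in tm.cds)
                t1 = _tx_coord(tm.exons, gm.strand, glo if gm.strand == "+" else ghi)
                t2 = _tx_coord(tm.exons, gm.strand, ghi if gm.strand == "+" else glo)
                reg[tm.tx_id] = TranscriptInfo(tm.tx_id, length, t1, t2)
            else:
                reg[tm.tx_id] = TranscriptInfo(tm.tx_id, length, None, None)
    return reg


# ---------------------------------------------------------------------------
# rounding helpers

def ratio(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """Half-up rounded quotient (the printed-table convention)."""
    if denominator == 0:
        raise ZeroDivisionError("denominator is zero")
    q = Decimal(numerator) / Decimal(denominator)
    exp = Decimal(1).scaleb(-ndigits)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


def percent(numerator: int, denominator: int, ndigits: int = 2) -> float:
    """100 * numerator / denominator, rounded half-up to ``ndigits``."""
    if denominator == 0:
        raise ZeroDivisionError("denominator is zero")
    q = Decimal(numerator) * 100 / Decimal(denominator)
    exp = Decimal(1).scaleb(-ndigits)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# summary statistics

@dataclass
class AnnotationSummary:
    n_genes: int
    n_transcripts: int
    mean_locus_length: float
    mean_exon_number: float
    mean_cds_length: float
    mean_intron_length: float
    n_with_5utr: int
    n_with_3utr: int
    n_with_both_utr: int
    mean_5utr_len: float
    mean_3utr_len: float
    n_genes_with_isoforms: int
    mean_isoforms_per_gene: float

    def as_series(self) -> pd.Series:
        return pd.Series(vars(self))


def _mean(values, ndigits=2):
    return round(sum(values) / len(values), ndigits) if values else 0.0


def summarize(models: dict[str, GeneModel]) -> AnnotationSummary:
    """Table-style summary of an annotation.

    Locus length is the gene span; intron lengths are per-transcript exon
    gaps; exon number and CDS/UTR lengths are per-transcript means; UTR
    presence is counted per gene (any transcript).
    """
    if not models:
        raise AnnotationParseError("no gene features found")
    genes = list(models.values())
    locus_lengths = [g.end - g.start + 1 for g in genes]
    exon_counts, cds_lens, intron_lens = [], [], []
    utr5_lens, utr3_lens = [], []
    n5 = n3 = nboth = n_iso = 0
    n_tx = 0
    for g in genes:
        has5 = any(t.utr5 for t in g.transcripts)
        has3 = any(t.utr3 for t in g.transcripts)
        n5 += has5
        n3 += has3
        nboth += has5 and has3
        n_iso += len(g.transcripts) >= 2
        for t in g.transcripts:
            n_tx += 1
            exon_counts.append(len(t.exons))
            if t.cds:
                cds_lens.append(sum(e - s + 1 for s, e in t.cds))
            intron_lens.extend(e - s + 1 for s, e in t.intron_chain)
            if t.utr5:
                utr5_lens.append(sum(e - s + 1 for s, e in t.utr5))
            if t.utr3:
                utr3_lens.append(sum(e - s + 1 for s, e in t.utr3))
    return AnnotationSummary(
        n_genes=len(genes),
        n_transcripts=n_tx,
        mean_locus_length=_mean(locus_lengths),
        mean_exon_number=_mean(exon_counts),
        mean_cds_length=_mean(cds_lens),
        mean_intron_length=_mean(intron_lens),
        n_with_5utr=n5,
        n_with_3utr=n3,
        n_with_both_utr=nboth,
        mean_5utr_len=_mean(utr5_lens),
        mean_3utr_len=_mean(utr3_lens),
        n_genes_with_isoforms=n_iso,
        mean_isoforms_per_gene=ratio(n_tx, len(genes)),
    )


# ---------------------------------------------------------------------------
# annotation comparison

@dataclass
class CompareResult:
    shared: list  # [(gene_a, gene_b)]
    only_a: list
    only_b: list
    class_codes: dict  # gene id (from B) -> class code


def _overlap(a, b):
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def _transcripts_shared(ta: TranscriptModel, tb: TranscriptModel) -> bool:
    if len(ta.exons) > 1 and len(tb.exons) > 1:
        return ta.intron_chain == tb.intron_chain
    if len(ta.exons) == 1 and len(tb.exons) == 1:
        ov = _overlap(ta.span, tb.span)
        la = ta.span[1] - ta.span[0] + 1
        lb = tb.span[1] - tb.span[0] + 1
        return ov >= 0.5 * la and ov >= 0.5 * lb
    return False


def compare(models_a: dict[str, GeneModel],
            models_b: dict[str, GeneModel]) -> CompareResult:
    """Cuffcompare-style structural comparison of two annotations.

    Two genes are *shared* when, on the same strand, at least one
    transcript pair has an identical intron chain (single-exon
    transcripts: reciprocal overlap >= 50%). Class codes per gene of B:
    ``identical`` (identical exon coordinates for some transcript pair),
    ``intron-chain-match``, ``overlap`` (span overlap only), ``novel``.
    """
    by_chrom: dict[tuple, list] = {}
    for g in models_a.values():
        by_chrom.setdefault((g.chrom, g.strand), []).append(g)
    shared, only_b = [], []
    class_codes = {}
    matched_a = set()
    for gb in models_b.values():
        candidates = [ga for ga in by_chrom.get((gb.chrom, gb.strand), [])
                      if _overlap((ga.start, ga.end), (gb.start, gb.end)) > 0]
        code = "novel"
        partner = None
        for ga in candidates:
            for ta in ga.transcripts:
                for tb in gb.transcripts:
                    if ta.exons == tb.exons:
                        code, partner = "identical", ga
                    elif _transcripts_shared(ta, tb) and code != "identical":
                        code, partner = "intron-chain-match", ga
            if code == "identical":
                break
        if partner is None and candidates:
            code = "overlap"
        class_codes[gb.gene_id] = code
        if partner is not None:
            shared.append((partner.gene_id, gb.gene_id))
            matched_a.add(partner.gene_id)
        else:
            only_b.append(gb.gene_id)
    only_a = sorted(set(models_a) - matched_a)
    return CompareResult(shared, only_a, sorted(only_b), class_codes)


# ---------------------------------------------------------------------------
# gene-ID assignment (FvH4_XgXXXXX dialect)

_ID_RE = re.compile(r"^(?P<prefix>\w+_)(?P<chrom>\w+?)g(?P<num>\d{5})$")


class IdCapacityError(RuntimeError):
    pass


def _parse_id(gene_id: str):
    m = _ID_RE.match(gene_id)
    if not m:
        raise ValueError(f"gene id {gene_id!r} does not follow FvH4_XgXXXXX")
    return m.group("prefix"), m.group("chrom"), int(m.group("num"))


def _format_id(prefix: str, chrom: str, num: int) -> str:
    return f"{prefix}{chrom}g{num:05d}"


class IdAssigner:
    """Stateful ID bookkeeping for one annotation update.

    Existing IDs end in 0; new genes between two neighbours take an unused
    non-zero last digit, searched midpoint-first; split genes keep the
    original ID on the longest fragment; merged genes retain the lowest
    ID; removed IDs are retired and never reused.
    """

    def __init__(self, existing_ids):
        self.used = set(existing_ids)
        self.retired: set[str] = set()
        for gid in existing_ids:
            _parse_id(gid)  # validate

    def _candidates(self, left_num: int, right_num: int):
        mid = (left_num + right_num) / 2
        nums = [n for n in range(left_num + 1, right_num) if n % 10 != 0]
        nums.sort(key=lambda n: (abs(n - mid), n))
        return nums

    def add_between(self, left_id: str, right_id: str) -> str:
        prefix, chrom, lnum = _parse_id(left_id)
        prefix2, chrom2, rnum = _parse_id(right_id)
        if (prefix, chrom) != (prefix2, chrom2):
            raise ValueError("neighbours on different chromosomes")
        for n in self._candidates(lnum, rnum):
            gid = _format_id(prefix, chrom, n)
            if gid not in self.used and gid not in self.retired:
                self.used.add(gid)
                return gid
        raise IdCapacityError(
            f"no free id between {left_id} and {right_id}")

    def split(self, gene_id: str, n_fragments: int, longest_index: int,
              next_id: str | None = None) -> list[str]:
        """Longest fragment keeps the ID; the others get new IDs after it."""
        if gene_id not in self.used:
            raise ValueError(f"unknown gene id {gene_id}")
        prefix, chrom, num = _parse_id(gene_id)
        if next_id is None:
            next_id = _format_id(prefix, chrom, num + 10)
        out: list[str | None] = [None] * n_fragments
        out[longest_index] = gene_id
        left = gene_id
        for i in range(n_fragments):
            if out[i] is None:
                new = self.add_between(left, next_id)
                out[i] = new
                left = new
        return out  # type: ignore[return-value]

    def merge(self, gene_ids: list[str]) -> str:
        nums = sorted(gene_ids, key=lambda g: _parse_id(g)[2])
        kept = nums[0]
        for gid in nums[1:]:
            self.used.discard(gid)
            self.retired.add(gid)
        return kept

    def remove(self, gene_id: str) -> None:
        self.used.discard(gene_id)
        self.retired.add(gene_id)


def assign_ids(existing_ids, events) -> dict:
    """Apply add/split/merge/remove events; returns an event -> id(s) map.

    ``events`` is a list of tuples: ``("add", left_id, right_id)``,
    ``("split", gene_id, n_fragments, longest_index)``,
    ``("merge", [ids...])`` or ``("remove", gene_id)``.
    """
    assigner = IdAssigner(existing_ids)
    result = {}
    for i, ev in enumerate(events):
        kind = ev[0]
        if kind == "add":
            result[i] = assigner.add_between(ev[1], ev[2])
        elif kind == "split":
            result[i] = assigner.split(ev[1], ev[2], ev[3])
        elif kind == "merge":
            result[i] = assigner.merge(list(ev[1]))
        elif kind == "remove":
            assigner.remove(ev[1])
            result[i] = None
        else:
            raise ValueError(f"unknown event kind {kind!r}")
    return result


# ---------------------------------------------------------------------------
# expression

def expressed_count(tpm: pd.DataFrame, threshold: float = 1.0):
    """Genes whose maximum TPM over tissues strictly exceeds ``threshold``.

    Returns ``(count, per-gene max Series)``; the max vector feeds
    log10(TPM + 1) density plots.
    """
    if (tpm.values < 0).any():
        raise ValueError("negative TPM values")
    gene_max = tpm.max(axis=1)
    return int((gene_max > threshold).sum()), gene_max


# ---------------------------------------------------------------------------
# evidence support (AED / QI)

@dataclass
class SupportMetrics:
    aed: float
    qi_exon_fraction: float


def _merge_intervals(intervals):
    out = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _total(intervals):
    return sum(e - s + 1 for s, e in intervals)


def _intersection(a, b):
    out = []
    for s1, e1 in a:
        for s2, e2 in b:
            s, e = max(s1, s2), min(e1, e2)
            if s <= e:
                out.append((s, e))
    return _merge_intervals(out)


def support_metrics(model_exons, evidence_intervals) -> SupportMetrics:
    """Annotation Edit Distance and exon-support fraction.

    With nucleotide-level sensitivity SN = |model ∩ evidence| / |evidence|
    and specificity SP = |model ∩ evidence| / |model|,
    AED = 1 - (SN + SP) / 2; 0 means exact agreement, 1 no overlap. The
    quality-index proxy is the fraction of model exons with an evidence
    interval of identical boundaries.
    """
    model = _merge_intervals(model_exons)
    if not model:
        raise ValueError("empty gene model")
    evidence = _merge_intervals(evidence_intervals)
    inter = _intersection(model, evidence)
    sn = _total(inter) / _total(evidence) if evidence else 0.0
    sp = _total(inter) / _total(model)
    aed = 1.0 - (sn + sp) / 2.0
    ev_set = set(map(tuple, evidence_intervals))
    qi = sum(1 for ex in model_exons if tuple(ex) in ev_set) / len(model_exons)
    return SupportMetrics(aed=aed, qi_exon_fraction=qi)
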