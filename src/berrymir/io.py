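"""FASTA/FASTQ/BED readers and writers (Biopython-backed)."""

from __future__ import annotations

from typing import Iterable

from Bio import SeqIO


class ParseError(ValueError):
    """Malformed sequence record; carries the (0-based) record index."""

    def __init__(self, message: str, index: int):
        super().__init__(f"record {index}: {message}")
        self.index = index


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def read_fasta(path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


def read_genome(path) -> dict[str, str]:
    return {name: seq.upper() for name, seq in read_fasta(path)}


def write_fastq(path, reads) -> None:
    """``reads`` yields objects with ``id``, ``seq``, ``qual`` attributes."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


def read_fastq(path):
    """Parse phred+33 FASTQ into ``(id, seq, quality-scores)`` tuples.

    Raises :class:`ParseError` naming the offending record index.
    """
    out = []
    it = SeqIO.parse(str(path), "fastq")
    idx = 0
    while True:
        try:
            rec = next(it)
        except StopIteration:
            break
        except ValueError as exc:
            raise ParseError(str(exc), idx) from exc
        out.append((rec.id, str(rec.seq),
                    rec.letter_annotations["phred_quality"]))
        idx += 1
    return out


def write_collapsed_fasta(path, tags) -> None:
    """Collapsed tags in the common ``>tagN_xCOUNT`` dialect."""
    with open(path, "w") as fh:
        for i, t in enumerate(tags):
            fh.write(f">tag{i + 1}_x{t.count}\n{t.sequence}\n")


def read_collapsed_fasta(path):
    from .srna_preprocess import SmallRNATag

    tags = []
    for name, seq in read_fasta(path):
        if "_x" not in name:
            raise ValueError(f"not a collapsed-tag header: {name}")
        count = int(name.rsplit("_x", 1)[1])
        tags.append(SmallRNATag(sequence=seq.upper(), count=count))
    return tags
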