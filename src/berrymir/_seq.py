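"""Small sequence utilities shared across the package.

DNA alphabet (ACGT) is used internally everywhere; conversion to/from the
RNA alphabet happens only at I/O edges and in user-facing mature sequences.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAATGCAA")

#: integer codes used by the folding / scoring kernels
BASE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


def revcomp(seq: str) -> str:
    """Reverse complement (DNA or RNA in; DNA out)."""
    return seq.translate(_COMPLEMENT)[::-1]


def dna(seq: str) -> str:
    """Normalize to upper-case DNA."""
    return seq.upper().replace("U", "T")


def rna(seq: str) -> str:
    """Normalize to upper-case RNA."""
    return seq.upper().replace("T", "U")


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as int8 codes (A=0, C=1, G=2, T/U=3)."""
    try:
        return np.array([BASE_CODES[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"non-ACGTU character in sequence: {exc}") from None


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """Random DNA sequence with expected GC content ``gc``."""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(np.array(list("ACGT")), size=length, p=p))


def is_dna(seq: str) -> bool:
    return all(c in "ACGT" for c in seq)
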