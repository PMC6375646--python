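"""DNA operator sequences: validation, integer encoding, Hamming distance, FASTA I/O.

Operator sequences are plain Python strings over the alphabet ``ACGT``
(positions numbered 1..L left-to-right on the printed strand). Matrices and
the samplers work on an integer encoding where A=0, C=1, G=2, T=3 — the fixed
column order used everywhere in this package.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

# The three natural lac operators (21 bp each).
O1 = "AATTGTGAGCGGATAACAATT"
O2 = "AAATGTGAGCGAGTAACAACC"
O3 = "GGCAGTGAGCGCAACGCAATT"

# Reported LacI binding energies of the natural operators, in kBT.
OPERATOR_ENERGIES_KBT = {"O1": -15.3, "O2": -13.9, "O3": -9.7}


def validate_sequence(seq: str) -> str:
    """Return the canonical (uppercase) form of ``seq``.

    Raises ``ValueError`` identifying the first offending position if any
    character is not one of A/C/G/T. Ambiguity codes (N, R, ...) are rejected:
    a linear energy matrix scores definite bases only.
    """
    s = seq.upper()
    for i, ch in enumerate(s):
        if ch not in BASE_INDEX:
            raise ValueError(
                f"invalid base {ch!r} at position {i + 1} (1-based); "
                "sequences must contain only A/C/G/T"
            )
    return s


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as an int8 array with A=0, C=1, G=2, T=3."""
    s = validate_sequence(seq)
    return np.array([BASE_INDEX[c] for c in s], dtype=np.int8)


def encode_many(seqs: Iterable[str]) -> np.ndarray:
    """Encode equal-length sequences into an (n, L) int8 array."""
    rows = [np.array([BASE_INDEX[c] for c in validate_sequence(s)], dtype=np.int8) for s in seqs]
    if not rows:
        return np.empty((0, 0), dtype=np.int8)
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
    return np.vstack(rows)


def decode(codes: Sequence[int]) -> str:
    """Inverse of :func:`encode`."""
    return "".join(ALPHABET[int(c)] for c in codes)


def hamming_distance(a: str, b: str) -> int:
    """Number of mismatched positions between two equal-length sequences."""
    a = validate_sequence(a)
    b = validate_sequence(b)
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def read_fasta(path) -> dict[str, str]:
    """Read a multi-record FASTA file into an ordered {id: sequence} dict."""
    return {rec.id: validate_sequence(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, records: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{validate_sequence(seq)}\n")
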