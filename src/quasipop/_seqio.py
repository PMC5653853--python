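"""Sequence encoding helpers and FASTA/FASTQ input/output.

Sequences are handled internally as numpy ``uint8`` code arrays
(A=0, C=1, G=2, T=3, anything else=4) so that simulation, mapping and
pileup construction stay vectorised.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

A, C, G, T, OTHER = 0, 1, 2, 3, 4

BASES = "ACGT"

# ASCII byte -> code, case-insensitive; unknown bases map to OTHER.
_ENCODE_LUT = np.full(256, OTHER, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i

_DECODE_LUT = np.frombuffer(b"ACGTN", dtype=np.uint8)

# complement in code space: A<->T, C<->G, N->N
_COMP_LUT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

_COMP_STR = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a nucleotide string into a uint8 code array."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _ENCODE_LUT[np.frombuffer(seq, dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back into an uppercase string."""
    return _DECODE_LUT[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP_LUT[codes[::-1]]


def revcomp(seq: str) -> str:
    return seq.translate(_COMP_STR)[::-1]


def phred_to_ascii(quals: np.ndarray) -> str:
    return (quals.astype(np.uint8) + 33).tobytes().decode("ascii")


def ascii_to_phred(qstr: str) -> np.ndarray:
    return np.frombuffer(qstr.encode("ascii"), dtype=np.uint8) - 33


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ``{id: sequence}`` dict (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str, np.ndarray]]:
    """Yield ``(id, bases, phred_array)`` per record of a FASTQ file."""
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq, ascii_to_phred(qual)


class FastqWriter:
    """Buffered plain-text FASTQ writer (Sanger Phred+33)."""

    def __init__(self, path: str | Path):
        self._fh = open(path, "w", buffering=io.DEFAULT_BUFFER_SIZE * 16)

    def write(self, read_id: str, bases: str, quals: np.ndarray | str) -> None:
        q = quals if isinstance(quals, str) else phred_to_ascii(quals)
        self._fh.write(f"@{read_id}\n{bases}\n+\n{q}\n")

    def close(self) -> None:
        self._fh.close()

    def __enter__(self) -> "FastqWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def write_fastq(records: Iterable[tuple[str, str, np.ndarray]], path: str | Path) -> int:
    n = 0
    with FastqWriter(path) as w:
        for rid, bases, quals in records:
            w.write(rid, bases, quals)
            n += 1
    return n
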