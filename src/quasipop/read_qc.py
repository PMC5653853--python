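"""Read quality filtering: sliding-window trimming and the variant-calling read filter."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Literal

import numpy as np

from ._seqio import FastqWriter, ascii_to_phred, iter_fastq

__all__ = [
    "SequencedRead",
    "sliding_window_trim",
    "variant_read_filter",
    "filter_pairs",
    "trim_fastq",
    "filter_fastq_pair",
    "QCStats",
]


@dataclass(frozen=True)
class SequencedRead:
    """One sequenced read with per-base Phred qualities."""

    id: str
    bases: str
    qualities: np.ndarray  # uint8 Phred scores

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise ValueError(f"read {self.id}: {len(self.bases)} bases vs {len(self.qualities)} qualities")
        if len(self.qualities) and (self.qualities.max() > 60):
            raise ValueError(f"read {self.id}: Phred score outside [0, 60]")

    def __len__(self) -> int:
        return len(self.bases)


def sliding_window_trim(read: SequencedRead, window: int = 5, min_mean_q: float = 20.0) -> SequencedRead | None:
    """Truncate a read at the first low-quality sliding window.

    Windows of size ``window`` advance one base at a time from the 5' end;
    trailing windows shorter than ``window`` are judged by their own mean.
    At the first window whose mean quality drops below ``min_mean_q``, the
    read is cut: bases from the window start are kept only while their
    individual quality stays at or above the threshold. A read truncated to
    length zero is dropped (returns None).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(read)
    if n == 0:
        return None
    q = read.qualities.astype(np.float64)
    csum = np.concatenate(([0.0], np.cumsum(q)))
    starts = np.arange(n)
    ends = np.minimum(starts + window, n)
    means = (csum[ends] - csum[starts]) / (ends - starts)
    failing = np.nonzero(means < min_mean_q)[0]
    if failing.size == 0:
        return read
    cut = int(failing[0])
    while cut < n and q[cut] >= min_mean_q:
        cut += 1
    if cut == 0:
        return None
    return SequencedRead(read.id, read.bases[:cut], read.qualities[:cut])


def variant_read_filter(
    read: SequencedRead,
    min_mean_q: float = 30.0,
    min_len: int = 50,
    mode: Literal["or", "and"] = "or",
) -> bool:
    """Keep/drop decision for the variant-calling read filter.

    Default mode "or" removes a read when its mean quality is below
    ``min_mean_q`` OR its length is below ``min_len``; mode "and" removes it
    only when both conditions hold.
    """
    short = len(read) < min_len
    low_q = len(read) == 0 or float(read.qualities.mean()) < min_mean_q
    if mode == "or":
        return not (short or low_q)
    if mode == "and":
        return not (short and low_q)
    raise ValueError(f"unknown mode {mode!r}")


def filter_pairs(
    pairs: Iterable[tuple[SequencedRead, SequencedRead]],
    min_mean_q: float = 30.0,
    min_len: int = 50,
    mode: Literal["or", "and"] = "or",
) -> Iterator[tuple[SequencedRead, SequencedRead]]:
    """Yield only pairs where both mates pass :func:`variant_read_filter`."""
    for r1, r2 in pairs:
        if variant_read_filter(r1, min_mean_q, min_len, mode) and variant_read_filter(
            r2, min_mean_q, min_len, mode
        ):
            yield r1, r2


@dataclass
class QCStats:
    reads_in: int = 0
    reads_kept: int = 0
    bases_kept: int = 0

    def log_line(self, label: str) -> str:
        return f"{label}: reads in {self.reads_in}, reads kept {self.reads_kept}, bases kept {self.bases_kept}"


def trim_fastq(in_path: str | Path, out_path: str | Path, window: int = 5, min_mean_q: float = 20.0) -> QCStats:
    """Apply sliding-window trimming to a FASTQ file."""
    stats = QCStats()
    with FastqWriter(out_path) as w:
        for rid, bases, quals in iter_fastq(in_path):
            stats.reads_in += 1
            trimmed = sliding_window_trim(SequencedRead(rid, bases, quals), window, min_mean_q)
            if trimmed is not None:
                stats.reads_kept += 1
                stats.bases_kept += len(trimmed)
                w.write(trimmed.id, trimmed.bases, trimmed.qualities)
    return stats


def filter_fastq_pair(
    r1_in: str | Path,
    r2_in: str | Path,
    r1_out: str | Path,
    r2_out: str | Path,
    min_mean_q: float = 30.0,
    min_len: int = 50,
    mode: Literal["or", "and"] = "or",
) -> QCStats:
    """Apply the variant read filter to a FASTQ pair, dropping pairs where either mate fails."""
    stats = QCStats()
    with FastqWriter(r1_out) as w1, FastqWriter(r2_out) as w2:
        for (id1, b1, q1), (id2, b2, q2) in zip(iter_fastq(r1_in), iter_fastq(r2_in), strict=True):
            stats.reads_in += 2
            r1 = SequencedRead(id1, b1, q1)
            r2 = SequencedRead(id2, b2, q2)
            if variant_read_filter(r1, min_mean_q, min_len, mode) and variant_read_filter(
                r2, min_mean_q, min_len, mode
            ):
                stats.reads_kept += 2
                stats.bases_kept += len(r1) + len(r2)
                w1.write(r1.id, r1.bases, r1.qualities)
                w2.write(r2.id, r2.bases, r2.qualities)
    return stats
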