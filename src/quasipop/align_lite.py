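"""Ungapped substitution-only read mapping plus text-SAM ingest/export.

Mapping is seed-and-verify: exact k-mer seeds against a reference index
propose candidate placements on both strands, each candidate is scored by
its full ungapped mismatch count, and the best placement wins. Ties break
deterministically (smallest start, then + strand). Gapped alignments must
come from an external mapper via :func:`read_sam`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from ._seqio import ascii_to_phred, decode, encode, iter_fastq, revcomp_codes
from .popgen_sim import ReferenceGenome

__all__ = [
    "AlignedRead",
    "KmerIndex",
    "index_reference",
    "map_read",
    "map_fastq_pair",
    "SamIngest",
    "read_sam",
    "write_sam",
]

logger = logging.getLogger(__name__)

_EMPTY = np.empty(0, dtype=np.int64)


@dataclass
class AlignedRead:
    """A read placed on a reference, stored in reference orientation.

    ``start`` is the 1-based leftmost reference base. For minus-strand
    placements ``bases``/``quals`` hold the reverse complement of the read
    as sequenced, i.e. the sequence as it aligns to the forward reference.
    ``qname`` identifies the fragment: both mates of a pair share it.
    """

    read_id: str
    ref_id: str
    start: int
    strand: str  # "+" or "-"
    bases: np.ndarray  # uint8 codes, reference orientation
    quals: np.ndarray  # uint8 Phred
    n_mismatch: int
    mapq: int
    qname: str = ""
    is_read2: bool = False

    def __post_init__(self) -> None:
        if not self.qname:
            self.qname = self.read_id.rsplit("/", 1)[0]

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def end(self) -> int:
        """1-based inclusive rightmost reference base."""
        return self.start + len(self.bases) - 1

    @property
    def sequence(self) -> str:
        return decode(self.bases)


class KmerIndex:
    """Exact k-mer -> sorted 0-based position lists for one reference."""

    def __init__(self, reference: ReferenceGenome, k: int = 21):
        if k > reference.length:
            raise ValueError(f"k={k} exceeds reference length {reference.length}")
        self.reference = reference
        self.k = k
        self.ref_codes = reference.codes()
        buf = self.ref_codes.tobytes()
        positions: dict[bytes, list[int]] = {}
        for i in range(reference.length - k + 1):
            positions.setdefault(buf[i : i + k], []).append(i)
        self._index = {kmer: np.asarray(pos, dtype=np.int64) for kmer, pos in positions.items()}

    def __len__(self) -> int:
        return len(self._index)

    def lookup(self, kmer: str | bytes | np.ndarray) -> np.ndarray:
        """0-based positions of an exact k-mer (empty array if absent)."""
        if isinstance(kmer, np.ndarray):
            key = kmer.tobytes()
        elif isinstance(kmer, str):
            key = encode(kmer).tobytes()
        else:
            key = kmer
        return self._index.get(key, _EMPTY)


def index_reference(reference: ReferenceGenome, k: int = 21) -> KmerIndex:
    return KmerIndex(reference, k=k)


def _candidate_starts(codes: np.ndarray, index: KmerIndex, seed_step: int) -> set[int]:
    k = index.k
    m = len(codes)
    buf = codes.tobytes()
    starts: set[int] = set()
    offsets = list(range(0, m - k + 1, seed_step))
    if offsets and offsets[-1] != m - k:
        offsets.append(m - k)
    L = index.reference.length
    for off in offsets:
        for pos in index.lookup(buf[off : off + k]):
            s = int(pos) - off
            if 0 <= s and s + m <= L:
                starts.add(s)
    return starts


def map_read(
    read_id: str,
    bases: str | np.ndarray,
    quals: np.ndarray,
    index: KmerIndex,
    max_mismatch_frac: float = 0.1,
    seed_step: int = 10,
) -> AlignedRead | None:
    """Map one read; returns None when no acceptable placement exists.

    Candidates from both orientations are scored by full ungapped mismatch
    count; the winner must have at most ``max_mismatch_frac * len`` mismatches.
    Mapping confidence is 0 on a tied best score, otherwise scales with the
    gap to the runner-up (60 when unambiguous).
    """
    codes = encode(bases) if isinstance(bases, str) else bases
    m = len(codes)
    if m < index.k:
        return None
    ref = index.ref_codes
    rc = revcomp_codes(codes)

    def _best_for(step: int):
        best: tuple[int, int, str] | None = None  # (mismatches, start, strand)
        second: int | None = None
        for strand, oriented in (("+", codes), ("-", rc)):
            for s in sorted(_candidate_starts(oriented, index, step)):
                mm = int(np.count_nonzero(ref[s : s + m] != oriented))
                cand = (mm, s, strand)
                if best is None or cand < best:
                    if best is not None:
                        second = best[0] if second is None else min(second, best[0])
                    best = cand
                elif second is None or mm < second:
                    second = mm
        return best, second

    best, second_mm = _best_for(seed_step)
    if (best is None or best[0] > max_mismatch_frac * m) and seed_step > 1:
        # sparse seeds may all be corrupted by mismatches: retry densely
        best, second_mm = _best_for(1)
    if best is None:
        return None
    mm, s, strand = best
    if mm > max_mismatch_frac * m:
        return None
    if second_mm is None:
        mapq = 60
    elif second_mm == mm:
        mapq = 0
    else:
        mapq = min(60, 6 * (second_mm - mm))
    oriented = codes if strand == "+" else rc
    oriented_q = quals if strand == "+" else quals[::-1]
    return AlignedRead(
        read_id=read_id,
        ref_id=index.reference.id,
        start=s + 1,
        strand=strand,
        bases=oriented.copy(),
        quals=np.asarray(oriented_q, dtype=np.uint8).copy(),
        n_mismatch=mm,
        mapq=mapq,
    )


def map_fastq_pair(
    r1_path: str | Path,
    r2_path: str | Path,
    index: KmerIndex,
    max_mismatch_frac: float = 0.1,
    seed_step: int = 10,
) -> list[AlignedRead]:
    """Map a FASTQ pair; mates are linked via a shared qname. Unmapped reads are dropped."""
    out: list[AlignedRead] = []
    n_unmapped = 0
    for mate, path in ((False, r1_path), (True, r2_path)):
        for rid, bases, quals in iter_fastq(path):
            aln = map_read(rid, bases, quals, index, max_mismatch_frac, seed_step)
            if aln is None:
                n_unmapped += 1
                continue
            aln.is_read2 = mate
            out.append(aln)
    if n_unmapped:
        logger.info("map_fastq_pair: %d reads unmapped", n_unmapped)
    return out


# ---------------------------------------------------------------------------
# SAM


@dataclass
class SamIngest:
    reads: list[AlignedRead]
    n_skipped: int


_ALLOWED_CIGAR_OPS = {0, 4, 7, 8}  # M, S, =, X


def read_sam(path: str | Path, reference: ReferenceGenome) -> SamIngest:
    """Read a text SAM file into :class:`AlignedRead` records.

    Records whose CIGAR contains anything beyond matches/mismatches and
    soft clips (M/=/X/S) are skipped with a counted warning; soft-clipped
    bases are trimmed. Coordinates stay 1-based; minus-strand records keep
    their SAM (reference-oriented) sequence.
    """
    reads: list[AlignedRead] = []
    n_skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for sq in fh.header.get("SQ", []):
            if sq["SN"] == reference.id and sq["LN"] != reference.length:
                raise ValueError(
                    f"SAM header length {sq['LN']} for {reference.id} does not match "
                    f"reference length {reference.length}"
                )
        for rec in fh:
            if rec.is_unmapped:
                n_skipped += 1
                continue
            if rec.reference_name != reference.id:
                raise ValueError(
                    f"record {rec.query_name}: reference {rec.reference_name!r} "
                    f"does not match {reference.id!r}"
                )
            ops = {op for op, _ in (rec.cigartuples or [])}
            if not ops or not ops <= _ALLOWED_CIGAR_OPS:
                n_skipped += 1
                continue
            seq = rec.query_alignment_sequence
            quals = rec.query_alignment_qualities
            if seq is None or quals is None:
                n_skipped += 1
                continue
            start = rec.reference_start + 1
            if start + len(seq) - 1 > reference.length:
                raise ValueError(f"record {rec.query_name}: alignment exceeds reference bounds")
            bases = encode(seq)
            nm = rec.get_tag("NM") if rec.has_tag("NM") else int(
                np.count_nonzero(reference.codes()[start - 1 : start - 1 + len(seq)] != bases)
            )
            reads.append(
                AlignedRead(
                    read_id=rec.query_name,
                    ref_id=reference.id,
                    start=start,
                    strand="-" if rec.is_reverse else "+",
                    bases=bases,
                    quals=np.asarray(quals, dtype=np.uint8),
                    n_mismatch=int(nm),
                    mapq=int(rec.mapping_quality),
                    qname=rec.query_name,
                    is_read2=bool(rec.is_read2),
                )
            )
    if n_skipped:
        logger.warning("read_sam: skipped %d records (unmapped or unsupported CIGAR)", n_skipped)
    return SamIngest(reads=reads, n_skipped=n_skipped)


def write_sam(reads: Sequence[AlignedRead], reference: ReferenceGenome, path: str | Path) -> None:
    """Write alignments as text SAM with NM tags; mates are paired by qname."""
    by_qname: dict[str, list[AlignedRead]] = {}
    for r in reads:
        by_qname.setdefault(r.qname, []).append(r)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": reference.id, "LN": reference.length}],
        "PG": [{"ID": "quasipop", "PN": "quasipop"}],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for qname, group in by_qname.items():
            paired = len(group) == 2
            for r in group:
                a = pysam.AlignedSegment(fh.header)
                a.query_name = qname
                flag = 0
                if paired:
                    flag |= 0x1 | (0x80 if r.is_read2 else 0x40)
                    mate = group[0] if r is group[1] else group[1]
                    a.next_reference_id = 0
                    a.next_reference_start = mate.start - 1
                    if mate.strand == "-":
                        flag |= 0x20
                if r.strand == "-":
                    flag |= 0x10
                a.flag = flag
                a.reference_id = 0
                a.reference_start = r.start - 1
                a.mapping_quality = r.mapq
                a.cigarstring = f"{len(r.bases)}M"
                a.query_sequence = r.sequence
                a.query_qualities = pysam.qualitystring_to_array(
                    (r.quals + 33).tobytes().decode("ascii")
                )
                a.set_tag("NM", int(r.n_mismatch))
                fh.write(a)
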