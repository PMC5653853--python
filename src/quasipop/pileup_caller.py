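"""Pileup construction, sample consensus, low-frequency variant calling and
the multi-configuration two-standard-deviation consensus filter.

Variants are reported against the sample consensus (the majority-allele
sequence of the sequenced population), not the original reference, so that
majority changes within the population are not miscalled as low-frequency
variants. Calls require a configurable minimum depth (default 100x), a
minimum alternative-allele count, and an alternative-allele fraction
strictly above the frequency threshold (default 1%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from ._seqio import BASES, decode, encode
from .align_lite import AlignedRead
from .popgen_sim import ReferenceGenome

__all__ = [
    "PileupColumn",
    "Pileup",
    "ConsensusSequence",
    "VariantCall",
    "CallerConfig",
    "DEFAULT_GRID",
    "FragmentBases",
    "collate_fragments",
    "merge_mates",
    "build_pileup",
    "call_consensus",
    "call_variants",
    "consensus_filter",
    "run_multi_config",
    "classify_substitution",
    "SubstitutionClass",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PileupColumn:
    """Per-position allele tallies (a view into a :class:`Pileup`)."""

    position: int  # 1-based
    counts_fwd: np.ndarray  # (4,) per-allele counts, + strand
    counts_rev: np.ndarray  # (4,) per-allele counts, - strand
    mean_qual: np.ndarray  # (4,) mean base quality per allele (NaN if absent)

    @property
    def counts(self) -> np.ndarray:
        return self.counts_fwd + self.counts_rev

    @property
    def depth(self) -> int:
        return int(self.counts.sum())


class FragmentBases(NamedTuple):
    """Flattened per-fragment base contributions (mate overlaps resolved)."""

    frag_ids: np.ndarray  # int32, index into ``qnames``
    positions: np.ndarray  # int64, 0-based reference positions
    bases: np.ndarray  # uint8 codes
    quals: np.ndarray  # uint8 Phred
    strands: np.ndarray  # uint8, 0 = "+", 1 = "-"
    qnames: list[str]


def merge_mates(a: AlignedRead, b: AlignedRead) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Merge two mates into per-position fragment arrays.

    Where the mates overlap, the base with the higher quality wins
    (the leftmost mate on a tie). Returns (positions0, bases, quals, strands).
    """
    if b.start < a.start or (b.start == a.start and b.is_read2 and not a.is_read2):
        a, b = b, a
    sa, ea = a.start - 1, a.start - 1 + len(a)
    sb, eb = b.start - 1, b.start - 1 + len(b)
    st_a = np.uint8(0 if a.strand == "+" else 1)
    st_b = np.uint8(0 if b.strand == "+" else 1)
    if sb >= ea:  # disjoint
        pos = np.concatenate([np.arange(sa, ea), np.arange(sb, eb)])
        bases = np.concatenate([a.bases, b.bases])
        quals = np.concatenate([a.quals, b.quals])
        strands = np.concatenate([np.full(len(a), st_a), np.full(len(b), st_b)]).astype(np.uint8)
        return pos, bases, quals, strands
    lo, hi = sb, min(ea, eb)
    ia = slice(lo - sa, hi - sa)
    ib = slice(0, hi - lo)
    use_b = b.quals[ib] > a.quals[ia]
    ov_bases = np.where(use_b, b.bases[ib], a.bases[ia])
    ov_quals = np.where(use_b, b.quals[ib], a.quals[ia])
    ov_strands = np.where(use_b, st_b, st_a).astype(np.uint8)
    parts_pos = [np.arange(sa, lo), np.arange(lo, hi)]
    parts_bases = [a.bases[: lo - sa], ov_bases]
    parts_quals = [a.quals[: lo - sa], ov_quals]
    parts_strands = [np.full(lo - sa, st_a, dtype=np.uint8), ov_strands]
    if eb > ea:  # b extends past a
        parts_pos.append(np.arange(ea, eb))
        parts_bases.append(b.bases[ea - sb :])
        parts_quals.append(b.quals[ea - sb :])
        parts_strands.append(np.full(eb - ea, st_b, dtype=np.uint8))
    elif ea > eb:  # b nested inside a
        parts_pos.append(np.arange(eb, ea))
        parts_bases.append(a.bases[eb - sa :])
        parts_quals.append(a.quals[eb - sa :])
        parts_strands.append(np.full(ea - eb, st_a, dtype=np.uint8))
    return (
        np.concatenate(parts_pos),
        np.concatenate(parts_bases).astype(np.uint8),
        np.concatenate(parts_quals).astype(np.uint8),
        np.concatenate(parts_strands),
    )


def collate_fragments(
    aligned_reads: Iterable[AlignedRead],
    reference: ReferenceGenome,
    merge: bool = True,
) -> FragmentBases:
    """Group reads into fragments by qname and flatten their base contributions.

    With ``merge`` (default) overlapping mates contribute one base per
    fragment position (the higher-quality base wins); without it every read
    contributes independently.
    """
    groups: dict[str, list[AlignedRead]] = {}
    for r in aligned_reads:
        if r.start < 1 or r.end > reference.length:
            raise ValueError(f"read {r.read_id}: alignment outside reference bounds")
        groups.setdefault(r.qname, []).append(r)

    qnames: list[str] = []
    fids, poss, bss, qls, sts = [], [], [], [], []
    for qname, reads in groups.items():
        fid = len(qnames)
        qnames.append(qname)
        if merge and len(reads) == 2:
            pos, bases, quals, strands = merge_mates(reads[0], reads[1])
            fids.append(np.full(len(pos), fid, dtype=np.int32))
            poss.append(pos)
            bss.append(bases)
            qls.append(quals)
            sts.append(strands)
        else:
            for r in reads:
                st = np.uint8(0 if r.strand == "+" else 1)
                n = len(r)
                fids.append(np.full(n, fid, dtype=np.int32))
                poss.append(np.arange(r.start - 1, r.start - 1 + n))
                bss.append(r.bases)
                qls.append(r.quals)
                sts.append(np.full(n, st, dtype=np.uint8))
    if not fids:
        empty = FragmentBases(
            np.empty(0, np.int32), np.empty(0, np.int64), np.empty(0, np.uint8),
            np.empty(0, np.uint8), np.empty(0, np.uint8), [],
        )
        return empty
    return FragmentBases(
        np.concatenate(fids),
        np.concatenate(poss).astype(np.int64),
        np.concatenate(bss).astype(np.uint8),
        np.concatenate(qls).astype(np.uint8),
        np.concatenate(sts),
        qnames,
    )


class Pileup:
    """Dense per-position allele counts for one reference."""

    def __init__(self, reference: ReferenceGenome, min_base_q: int = 20):
        self.reference = reference
        self.min_base_q = min_base_q
        L = reference.length
        self.counts_fwd = np.zeros((L, 4), dtype=np.int32)
        self.counts_rev = np.zeros((L, 4), dtype=np.int32)
        self.qual_sum = np.zeros((L, 4), dtype=np.int64)

    @property
    def counts(self) -> np.ndarray:
        return self.counts_fwd + self.counts_rev

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def column(self, position: int) -> PileupColumn:
        i = position - 1
        cnt = self.counts[i].astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_q = np.where(cnt > 0, self.qual_sum[i] / cnt, np.nan)
        return PileupColumn(
            position=position,
            counts_fwd=self.counts_fwd[i].copy(),
            counts_rev=self.counts_rev[i].copy(),
            mean_qual=mean_q,
        )


def build_pileup(
    aligned_reads: Iterable[AlignedRead] | FragmentBases,
    reference: ReferenceGenome,
    min_base_q: int = 20,
    merge_mates_flag: bool = True,
) -> Pileup:
    """Accumulate a pileup; bases below ``min_base_q`` are excluded.

    Accepts either raw aligned reads or a pre-collated :class:`FragmentBases`
    (so a multi-configuration run collates fragments once).
    """
    frags = (
        aligned_reads
        if isinstance(aligned_reads, FragmentBases)
        else collate_fragments(aligned_reads, reference, merge=merge_mates_flag)
    )
    p = Pileup(reference, min_base_q=min_base_q)
    keep = (frags.quals >= min_base_q) & (frags.bases < 4)
    pos = frags.positions[keep]
    base = frags.bases[keep]
    qual = frags.quals[keep].astype(np.int64)
    strand = frags.strands[keep]
    fwd = strand == 0
    np.add.at(p.counts_fwd, (pos[fwd], base[fwd]), 1)
    np.add.at(p.counts_rev, (pos[~fwd], base[~fwd]), 1)
    np.add.at(p.qual_sum, (pos, base), qual)
    return p


@dataclass
class ConsensusSequence:
    """Majority-allele sequence of the sequenced sample."""

    sequence: str
    support: np.ndarray  # fraction of reads agreeing with the consensus base

    def codes(self) -> np.ndarray:
        return encode(self.sequence)


def call_consensus(pileup: Pileup, reference: ReferenceGenome) -> ConsensusSequence:
    """Per position: the modal allele; ties and zero depth fall back to the reference base."""
    counts = pileup.counts
    depth = counts.sum(axis=1)
    ref_codes = reference.codes()
    winner = counts.argmax(axis=1).astype(np.uint8)
    maxc = counts.max(axis=1)
    ref_ties = counts[np.arange(len(ref_codes)), ref_codes] == maxc
    winner = np.where(ref_ties | (depth == 0), ref_codes, winner).astype(np.uint8)
    with np.errstate(invalid="ignore", divide="ignore"):
        support = np.where(depth > 0, counts[np.arange(len(winner)), winner] / np.maximum(depth, 1), 0.0)
    return ConsensusSequence(sequence=decode(winner), support=support)


@dataclass
class VariantCall:
    """A called variant site, reported against the sample consensus."""

    position: int
    ref_allele: str
    alt_allele: str
    alt_frequency: float
    alt_count: int
    depth: int
    frequency_estimates: list[float] = field(default_factory=list)
    filters: set[str] = field(default_factory=lambda: {"PASS"})

    @property
    def key(self) -> tuple[int, str]:
        return (self.position, self.alt_allele)

    @property
    def passed(self) -> bool:
        return self.filters == {"PASS"}


def call_variants(
    pileup: Pileup,
    consensus: ConsensusSequence,
    min_freq: float = 0.01,
    min_depth: int = 100,
    min_alt_count: int = 2,
) -> list[VariantCall]:
    """Emit one call per non-consensus allele passing all thresholds.

    A site qualifies when depth >= ``min_depth``, the allele count is at
    least ``min_alt_count`` and the allele fraction is strictly above
    ``min_freq``. Multi-allelic positions emit separate calls.
    """
    if not 0.0 < min_freq < 1.0:
        raise ValueError(f"min_freq {min_freq} not in (0, 1)")
    counts = pileup.counts
    depth = counts.sum(axis=1)
    cons = consensus.codes()
    calls: list[VariantCall] = []
    for allele in range(4):
        ac = counts[:, allele]
        mask = (
            (cons != allele)
            & (depth >= min_depth)
            & (ac >= min_alt_count)
            & (ac > min_freq * depth)
        )
        for i in np.nonzero(mask)[0]:
            calls.append(
                VariantCall(
                    position=int(i) + 1,
                    ref_allele=consensus.sequence[i],
                    alt_allele=BASES[allele],
                    alt_frequency=float(ac[i] / depth[i]),
                    alt_count=int(ac[i]),
                    depth=int(depth[i]),
                )
            )
    calls.sort(key=lambda c: c.key)
    return calls


def consensus_filter(frequency_estimates: Sequence[float], k_sd: float = 2.0) -> bool:
    """True iff every estimate lies within mean +/- k_sd * sample SD (n-1).

    All-equal estimates (SD = 0) are included. The decision is scale-invariant.
    """
    x = np.asarray(frequency_estimates, dtype=float)
    if x.size < 2:
        raise ValueError("consensus_filter requires at least 2 estimates")
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        return True
    mean = float(x.mean())
    return bool(np.all(np.abs(x - mean) <= k_sd * sd))


@dataclass(frozen=True)
class CallerConfig:
    """One internal parameterization of the calling grid."""

    min_base_q: int = 20
    min_alt_count: int = 2


#: 3 base-quality cutoffs x 2 allele-count cutoffs = six configurations.
DEFAULT_GRID: tuple[CallerConfig, ...] = tuple(
    CallerConfig(min_base_q=q, min_alt_count=a) for q in (15, 20, 25) for a in (2, 4)
)


def run_multi_config(
    read_sets: Sequence[Sequence[AlignedRead] | FragmentBases],
    reference: ReferenceGenome,
    configs: Sequence[CallerConfig] | None = None,
    min_freq: float = 0.01,
    min_depth: int = 100,
    k_sd: float = 2.0,
    consensus_min_base_q: int = 20,
) -> tuple[list[VariantCall], ConsensusSequence]:
    """Run the calling grid and merge per-site frequency vectors.

    Either one read set is called under several :class:`CallerConfig`
    parameterizations, or several read sets (e.g. six externally produced
    SAM alignments) are each called once; lengths are broadcast. A site
    missed by a configuration contributes frequency 0. Sites whose vector
    fails the two-SD consensus are flagged ``sd2_fail``; the reported
    frequency is the mean of all estimates and must itself exceed
    ``min_freq`` (else the site is flagged ``low_freq``).
    """
    if configs is None:
        configs = DEFAULT_GRID if len(read_sets) == 1 else tuple(
            CallerConfig() for _ in read_sets
        )
    if len(read_sets) == 1 and len(configs) > 1:
        read_sets = list(read_sets) * len(configs)
    elif len(configs) == 1 and len(read_sets) > 1:
        configs = list(configs) * len(read_sets)
    if len(read_sets) != len(configs):
        raise ValueError(f"{len(read_sets)} read sets vs {len(configs)} configurations")
    n_runs = len(configs)

    # collate each distinct read set once; pileups cached per (set, min_base_q)
    collated: dict[int, FragmentBases] = {}
    for rs in read_sets:
        if id(rs) not in collated:
            collated[id(rs)] = (
                rs if isinstance(rs, FragmentBases) else collate_fragments(rs, reference)
            )
    pileups: dict[tuple[int, int], Pileup] = {}

    def pileup_for(rs, min_base_q: int) -> Pileup:
        key = (id(rs), min_base_q)
        if key not in pileups:
            pileups[key] = build_pileup(collated[id(rs)], reference, min_base_q=min_base_q)
        return pileups[key]

    consensus = call_consensus(pileup_for(read_sets[0], consensus_min_base_q), reference)

    merged: dict[tuple[int, str], VariantCall] = {}
    estimates: dict[tuple[int, str], np.ndarray] = {}
    for run_i, (rs, cfg) in enumerate(zip(read_sets, configs)):
        p = pileup_for(rs, cfg.min_base_q)
        for call in call_variants(p, consensus, min_freq, min_depth, cfg.min_alt_count):
            if call.key not in merged:
                merged[call.key] = call
                estimates[call.key] = np.zeros(n_runs)
            estimates[call.key][run_i] = call.alt_frequency

    out: list[VariantCall] = []
    for key in sorted(merged):
        base = merged[key]
        est = estimates[key]
        base.frequency_estimates = [float(v) for v in est]
        base.alt_frequency = float(est.mean())
        failures: set[str] = set()
        if n_runs >= 2 and not consensus_filter(est, k_sd=k_sd):
            failures.add("sd2_fail")
        # the merged (mean) frequency must itself clear the reporting threshold
        if base.alt_frequency <= min_freq:
            failures.add("low_freq")
        base.filters = failures if failures else {"PASS"}
        out.append(base)
    if n_runs < 2:
        logger.info("run_multi_config: single configuration, two-SD consensus filter skipped")
    return out, consensus


class SubstitutionClass(NamedTuple):
    kind: str  # "transition" | "transversion"
    spectrum: str  # "AT_to_GC" | "GC_to_AT" | "other"


def classify_substitution(ref_allele: str, alt_allele: str) -> SubstitutionClass:
    """Classify a substitution by transition/transversion and AT<->GC direction."""
    if ref_allele not in BASES or alt_allele not in BASES:
        raise ValueError(f"invalid alleles {ref_allele!r}->{alt_allele!r}")
    if ref_allele == alt_allele:
        raise ValueError("ref and alt alleles are identical")
    purines = {"A", "G"}
    kind = (
        "transition"
        if (ref_allele in purines) == (alt_allele in purines)
        else "transversion"
    )
    if (ref_allele, alt_allele) in {("A", "G"), ("T", "C")}:
        spectrum = "AT_to_GC"
    elif (ref_allele, alt_allele) in {("G", "A"), ("C", "T")}:
        spectrum = "GC_to_AT"
    else:
        spectrum = "other"
    return SubstitutionClass(kind=kind, spectrum=spectrum)
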