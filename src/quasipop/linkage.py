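"""Read-backed pairwise co-occurrence of variant sites.

For two called sites, fragments (mate pairs merged, overlap resolved as in
pileup construction) covering BOTH positions are classified by the allele
they carry at each: both alternative, only one, or neither. The headline
percentage is 100 * n_both / (n_both + n_only_i + n_only_j) — the share of
fragments carrying one or both variants that carry both. Bases matching
neither the consensus nor the called alternative are excluded from the four
counts and tallied separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._seqio import encode
from .align_lite import AlignedRead
from .pileup_caller import FragmentBases, VariantCall, collate_fragments, merge_mates
from .popgen_sim import ReferenceGenome

__all__ = [
    "PairCooccurrence",
    "SiteAlleles",
    "fragment_alleles",
    "site_alleles",
    "cooccurrence",
    "cooccurrence_matrix",
    "matrix_to_frame",
]

REF, ALT, OTHER_BASE = 0, 1, 2


@dataclass(frozen=True)
class PairCooccurrence:
    """Fragment-level co-occurrence counts for one pair of variant sites."""

    position_i: int
    alt_i: str
    position_j: int
    alt_j: str
    n_both: int
    n_only_i: int
    n_only_j: int
    n_neither: int
    n_other: int

    @property
    def informative_fragments(self) -> int:
        return self.n_both + self.n_only_i + self.n_only_j + self.n_neither

    @property
    def cooccurrence_pct(self) -> float:
        denom = self.n_both + self.n_only_i + self.n_only_j
        return 100.0 * self.n_both / denom if denom > 0 else float("nan")


@dataclass
class SiteAlleles:
    """Per-fragment allele classification at one variant site."""

    position: int
    ref_allele: str
    alt_allele: str
    frag_ids: np.ndarray  # fragments covering the site, sorted
    classes: np.ndarray  # uint8: 0 ref, 1 alt, 2 other


def _as_site(site) -> tuple[int, str, str]:
    if isinstance(site, VariantCall):
        return site.position, site.ref_allele, site.alt_allele
    pos, ref, alt = site
    return int(pos), ref, alt


def fragment_alleles(
    aligned_pair: Sequence[AlignedRead],
    site,
) -> str:
    """Classify one fragment's base at a site: "ref", "alt", "other" or "uncovered".

    Mate-overlap disagreements resolve to the higher-quality base, matching
    pileup construction.
    """
    pos, ref, alt = _as_site(site)
    reads = list(aligned_pair)
    if len(reads) == 2:
        positions, bases, _, _ = merge_mates(reads[0], reads[1])
    else:
        r = reads[0]
        positions = np.arange(r.start - 1, r.start - 1 + len(r))
        bases = r.bases
    hit = np.nonzero(positions == pos - 1)[0]
    if hit.size == 0:
        return "uncovered"
    base = int(bases[hit[0]])
    if base == int(encode(ref)[0]):
        return "ref"
    if base == int(encode(alt)[0]):
        return "alt"
    return "other"


def site_alleles(frags: FragmentBases, site) -> SiteAlleles:
    """Vectorised per-fragment classification at one site over collated fragments."""
    pos, ref, alt = _as_site(site)
    sel = frags.positions == pos - 1
    fids = frags.frag_ids[sel]
    bases = frags.bases[sel]
    order = np.argsort(fids, kind="stable")
    fids, bases = fids[order], bases[order]
    ref_code, alt_code = int(encode(ref)[0]), int(encode(alt)[0])
    classes = np.full(len(bases), OTHER_BASE, dtype=np.uint8)
    classes[bases == ref_code] = REF
    classes[bases == alt_code] = ALT
    return SiteAlleles(pos, ref, alt, fids, classes)


def _pair_counts(si: SiteAlleles, sj: SiteAlleles) -> PairCooccurrence:
    common, ii, jj = np.intersect1d(si.frag_ids, sj.frag_ids, return_indices=True)
    ci, cj = si.classes[ii], sj.classes[jj]
    ok = (ci != OTHER_BASE) & (cj != OTHER_BASE)
    n_other = int(len(common) - ok.sum())
    ci, cj = ci[ok], cj[ok]
    return PairCooccurrence(
        position_i=si.position,
        alt_i=si.alt_allele,
        position_j=sj.position,
        alt_j=sj.alt_allele,
        n_both=int(np.sum((ci == ALT) & (cj == ALT))),
        n_only_i=int(np.sum((ci == ALT) & (cj == REF))),
        n_only_j=int(np.sum((ci == REF) & (cj == ALT))),
        n_neither=int(np.sum((ci == REF) & (cj == REF))),
        n_other=n_other,
    )


def cooccurrence(
    aligned_reads: Iterable[AlignedRead] | FragmentBases,
    reference: ReferenceGenome,
    site_i,
    site_j,
) -> PairCooccurrence:
    """Count fragment-level co-occurrence of two variant sites."""
    pi, _, ai = _as_site(site_i)
    pj, _, aj = _as_site(site_j)
    if (pi, ai) == (pj, aj):
        raise ValueError("site_i and site_j are the same site")
    frags = (
        aligned_reads
        if isinstance(aligned_reads, FragmentBases)
        else collate_fragments(aligned_reads, reference)
    )
    return _pair_counts(site_alleles(frags, site_i), site_alleles(frags, site_j))


def cooccurrence_matrix(
    aligned_reads: Iterable[AlignedRead] | FragmentBases,
    reference: ReferenceGenome,
    calls: Sequence[VariantCall],
    max_span: int = 900,
    min_informative: int = 20,
) -> list[PairCooccurrence]:
    """Co-occurrence for every pair of calls; pairs beyond ``max_span`` keep zero counts.

    All pairs are emitted (ordered by position); the percentage is NaN when
    the pair has fewer than ``min_informative`` informative fragments — raw
    counts are always retained so alternative ratios can be recomputed.
    """
    frags = (
        aligned_reads
        if isinstance(aligned_reads, FragmentBases)
        else collate_fragments(aligned_reads, reference)
    )
    per_site = {c.key: site_alleles(frags, c) for c in calls}
    out: list[PairCooccurrence] = []
    for ci, cj in combinations(sorted(calls, key=lambda c: c.key), 2):
        if abs(ci.position - cj.position) > max_span:
            out.append(
                PairCooccurrence(ci.position, ci.alt_allele, cj.position, cj.alt_allele, 0, 0, 0, 0, 0)
            )
        else:
            out.append(_pair_counts(per_site[ci.key], per_site[cj.key]))
    return out


def matrix_to_frame(pairs: Sequence[PairCooccurrence], min_informative: int = 20) -> pd.DataFrame:
    """Tabulate a co-occurrence matrix; pct is NA below ``min_informative`` fragments."""
    rows = []
    for p in pairs:
        pct = p.cooccurrence_pct if p.informative_fragments >= min_informative else float("nan")
        rows.append(
            {
                "site_i": p.position_i,
                "alt_i": p.alt_i,
                "site_j": p.position_j,
                "alt_j": p.alt_j,
                "n_both": p.n_both,
                "n_only_i": p.n_only_i,
                "n_only_j": p.n_only_j,
                "n_neither": p.n_neither,
                "n_other": p.n_other,
                "pct": pct,
            }
        )
    cols = ["site_i", "alt_i", "site_j", "alt_j", "n_both", "n_only_i", "n_only_j", "n_neither", "n_other", "pct"]
    return pd.DataFrame(rows, columns=cols)
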