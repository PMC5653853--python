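"""Synthetic phage populations with planted variants and paired-end read simulation.

A population is a weighted set of genome haplotypes over one reference.
Every downstream quantity that the pipeline estimates — per-site alternative
allele frequency and pairwise co-occurrence of variant sites — is available
in closed form from the haplotype weights, and is written out as
machine-readable truth tables next to the simulated reads.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from ._seqio import BASES, FastqWriter, decode, encode, phred_to_ascii, revcomp_codes, write_fasta

__all__ = [
    "PopulationError",
    "ReferenceGenome",
    "PlantedVariant",
    "Haplotype",
    "HaplotypePopulation",
    "ReadSimConfig",
    "SimResult",
    "random_reference",
    "random_variants",
    "nested_haplotype_spec",
    "build_population",
    "simulate_reads",
    "simulate_coinfection_pool",
]

MIN_GENOME_LENGTH = 1000

TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


class PopulationError(ValueError):
    """Raised when a population specification violates its invariants."""


@dataclass(frozen=True)
class ReferenceGenome:
    """A linear genome sequence over {A,C,G,T}."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < MIN_GENOME_LENGTH:
            raise PopulationError(
                f"reference {self.id!r}: length {len(self.sequence)} < {MIN_GENOME_LENGTH}"
            )
        if set(self.sequence) - set(BASES):
            bad = sorted(set(self.sequence) - set(BASES))
            raise PopulationError(f"reference {self.id!r}: non-ACGT characters {bad}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def codes(self) -> np.ndarray:
        return encode(self.sequence)


@dataclass(frozen=True)
class PlantedVariant:
    """A single-nucleotide variant planted at a known population frequency.

    ``position`` is 1-based; ``target_frequency`` is a fraction in (0, 1).
    """

    position: int
    ref_allele: str
    alt_allele: str
    target_frequency: float

    def __post_init__(self) -> None:
        if self.ref_allele not in BASES or self.alt_allele not in BASES:
            raise PopulationError(f"variant at {self.position}: alleles must be A/C/G/T")
        if self.ref_allele == self.alt_allele:
            raise PopulationError(f"variant at {self.position}: ref == alt")
        if not 0.0 < self.target_frequency < 1.0:
            raise PopulationError(
                f"variant at {self.position}: target frequency {self.target_frequency} not in (0,1)"
            )

    @property
    def key(self) -> tuple[int, str]:
        return (self.position, self.alt_allele)


@dataclass(frozen=True)
class Haplotype:
    """One genome haplotype: a subset of the planted variants plus a weight."""

    id: str
    variant_indices: frozenset[int]
    weight: float


@dataclass
class HaplotypePopulation:
    """Weighted haplotypes over a reference; ground truth for all estimates."""

    reference: ReferenceGenome
    variants: tuple[PlantedVariant, ...]
    haplotypes: tuple[Haplotype, ...]

    def __post_init__(self) -> None:
        total = sum(h.weight for h in self.haplotypes)
        if abs(total - 1.0) > 1e-9:
            raise PopulationError(f"haplotype weights sum to {total}, expected 1")
        if any(h.weight <= 0 for h in self.haplotypes):
            raise PopulationError("haplotype weights must be > 0")

    # ---- closed-form truth -------------------------------------------------

    def site_frequency(self, variant_index: int) -> float:
        """Marginal population frequency of one planted variant."""
        return sum(h.weight for h in self.haplotypes if variant_index in h.variant_indices)

    def site_frequencies(self) -> dict[tuple[int, str], float]:
        return {v.key: self.site_frequency(i) for i, v in enumerate(self.variants)}

    def pair_weights(self, i: int, j: int) -> tuple[float, float, float, float]:
        """(both, only_i, only_j, neither) genome-weight fractions for two variants."""
        w_both = w_i = w_j = w_neither = 0.0
        for h in self.haplotypes:
            has_i = i in h.variant_indices
            has_j = j in h.variant_indices
            if has_i and has_j:
                w_both += h.weight
            elif has_i:
                w_i += h.weight
            elif has_j:
                w_j += h.weight
            else:
                w_neither += h.weight
        return w_both, w_i, w_j, w_neither

    def expected_cooccurrence_pct(self, i: int, j: int) -> float:
        """Expected % of variant-bearing genomes carrying both variants.

        Matches the fragment-level co-occurrence statistic:
        100 * P(both) / P(one or both). NaN when neither variant segregates.
        """
        w_both, w_i, w_j, _ = self.pair_weights(i, j)
        denom = w_both + w_i + w_j
        return 100.0 * w_both / denom if denom > 0 else float("nan")

    # ---- sequences ---------------------------------------------------------

    def haplotype_codes(self) -> np.ndarray:
        """(n_haplotypes, genome_length) uint8 code matrix."""
        ref = self.reference.codes()
        mat = np.tile(ref, (len(self.haplotypes), 1))
        for hi, h in enumerate(self.haplotypes):
            for vi in h.variant_indices:
                v = self.variants[vi]
                mat[hi, v.position - 1] = encode(v.alt_allele)[0]
        return mat

    # ---- truth tables ------------------------------------------------------

    def variants_table(self) -> pd.DataFrame:
        rows = [
            {
                "position": v.position,
                "ref": v.ref_allele,
                "alt": v.alt_allele,
                "frequency": self.site_frequency(i),
                "target_frequency": v.target_frequency,
            }
            for i, v in enumerate(self.variants)
        ]
        return pd.DataFrame(rows, columns=["position", "ref", "alt", "frequency", "target_frequency"])

    def haplotypes_table(self) -> pd.DataFrame:
        rows = [
            {
                "haplotype": h.id,
                "weight": h.weight,
                "variants": ",".join(
                    f"{self.variants[i].position}{self.variants[i].alt_allele}"
                    for i in sorted(h.variant_indices)
                ),
            }
            for h in self.haplotypes
        ]
        return pd.DataFrame(rows, columns=["haplotype", "weight", "variants"])

    def pairs_table(self) -> pd.DataFrame:
        rows = []
        for i, j in combinations(range(len(self.variants)), 2):
            w_both, w_i, w_j, w_neither = self.pair_weights(i, j)
            rows.append(
                {
                    "position_i": self.variants[i].position,
                    "alt_i": self.variants[i].alt_allele,
                    "position_j": self.variants[j].position,
                    "alt_j": self.variants[j].alt_allele,
                    "w_both": w_both,
                    "w_only_i": w_i,
                    "w_only_j": w_j,
                    "w_neither": w_neither,
                    "expected_pct": self.expected_cooccurrence_pct(i, j),
                }
            )
        cols = [
            "position_i", "alt_i", "position_j", "alt_j",
            "w_both", "w_only_i", "w_only_j", "w_neither", "expected_pct",
        ]
        return pd.DataFrame(rows, columns=cols)

    def write_truth(self, outdir: str | Path, prefix: str = "truth") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.variants_table().to_csv(outdir / f"{prefix}_variants.tsv", sep="\t", index=False)
        self.haplotypes_table().to_csv(outdir / f"{prefix}_haplotypes.tsv", sep="\t", index=False)
        self.pairs_table().to_csv(outdir / f"{prefix}_pairs.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# construction helpers


def random_reference(length: int, seed_or_rng: int | np.random.Generator, id: str = "sim_ref") -> ReferenceGenome:
    rng = np.random.default_rng(seed_or_rng) if isinstance(seed_or_rng, (int, np.integer)) else seed_or_rng
    codes = rng.integers(0, 4, size=length, dtype=np.uint8)
    return ReferenceGenome(id=id, sequence=decode(codes))


def random_variants(
    reference: ReferenceGenome,
    frequencies: Sequence[float],
    rng: np.random.Generator,
    min_separation: int = 10,
    at_gc_bias: float = 0.0,
    edge_margin: int = 0,
) -> list[PlantedVariant]:
    """Plant one variant per requested frequency at random distinct positions.

    ``at_gc_bias`` is the probability of forcing an AT->GC transition
    (A->G / T->C) when the reference base allows it; 0 disables the bias.
    ``edge_margin`` keeps positions at least that far from the genome
    termini, where linear-fragment simulation leaves reduced coverage.
    """
    n = len(frequencies)
    positions: list[int] = []
    taken = np.zeros(reference.length + 1, dtype=bool)
    attempts = 0
    lo_bound = 1 + edge_margin
    hi_bound = reference.length - edge_margin
    if hi_bound - lo_bound + 1 < n * (min_separation + 1):
        raise PopulationError("genome too short for requested variants and margins")
    while len(positions) < n:
        attempts += 1
        if attempts > 1000 * n:
            raise PopulationError("could not place variants with requested separation")
        pos = int(rng.integers(lo_bound, hi_bound + 1))
        lo, hi = max(1, pos - min_separation), min(reference.length, pos + min_separation)
        if taken[lo : hi + 1].any():
            continue
        taken[pos] = True
        positions.append(pos)
    positions.sort()
    variants = []
    for pos, freq in zip(positions, frequencies):
        ref_base = reference.sequence[pos - 1]
        if at_gc_bias > 0 and ref_base in "AT" and rng.random() < at_gc_bias:
            alt = TRANSITION[ref_base]
        else:
            choices = [b for b in BASES if b != ref_base]
            alt = choices[int(rng.integers(0, 3))]
        variants.append(PlantedVariant(pos, ref_base, alt, float(freq)))
    return variants


def nested_haplotype_spec(
    planted_variants: Sequence[PlantedVariant],
) -> list[tuple[frozenset[int], float]]:
    """Nested haplotype construction realising arbitrary marginal frequencies.

    Variants sorted by descending frequency f1 >= f2 >= ... >= fn are stacked:
    haplotype k carries variants {1..k} with weight f_k - f_{k+1}, plus a
    variant-free haplotype of weight 1 - f1. Marginals are exact; linkage is
    complete (every pair of planted variants co-occurs maximally).
    """
    order = sorted(range(len(planted_variants)), key=lambda i: -planted_variants[i].target_frequency)
    freqs = [planted_variants[i].target_frequency for i in order]
    spec: list[tuple[frozenset[int], float]] = []
    for k in range(len(order)):
        nxt = freqs[k + 1] if k + 1 < len(order) else 0.0
        w = freqs[k] - nxt
        if w > 0:
            spec.append((frozenset(order[: k + 1]), w))
    spec.append((frozenset(), 1.0 - (freqs[0] if freqs else 0.0)))
    return spec


def build_population(
    reference: ReferenceGenome,
    planted_variants: Sequence[PlantedVariant],
    haplotype_spec: Iterable[tuple[Iterable[int], float]],
    freq_tol: float = 1e-6,
    truth_dir: str | Path | None = None,
) -> HaplotypePopulation:
    """Assemble and validate a :class:`HaplotypePopulation`.

    ``haplotype_spec`` is an iterable of ``(variant_indices, weight)`` pairs,
    indices referring into ``planted_variants``. Realised marginal frequencies
    must match each variant's target within ``freq_tol``. When ``truth_dir``
    is given, the truth tables are written there as TSV.
    """
    variants = tuple(planted_variants)
    n = len(variants)
    per_pos_alts: dict[int, set[str]] = {}
    seen_keys: set[tuple[int, str]] = set()
    for v in variants:
        if not 1 <= v.position <= reference.length:
            raise PopulationError(f"variant position {v.position} out of range 1..{reference.length}")
        if reference.sequence[v.position - 1] != v.ref_allele:
            raise PopulationError(
                f"variant at {v.position}: ref allele {v.ref_allele} does not match reference "
                f"base {reference.sequence[v.position - 1]}"
            )
        if v.key in seen_keys:
            raise PopulationError(f"duplicate variant {v.key}")
        seen_keys.add(v.key)
        per_pos_alts.setdefault(v.position, set()).add(v.alt_allele)
    for pos, alts in per_pos_alts.items():
        if len(alts) > 3:
            raise PopulationError(f"position {pos}: more than 3 alternative alleles")

    haplotypes = []
    for hi, (subset, weight) in enumerate(haplotype_spec):
        idx = frozenset(int(i) for i in subset)
        for i in idx:
            if not 0 <= i < n:
                raise PopulationError(f"haplotype {hi}: unknown variant index {i}")
        haplotypes.append(Haplotype(id=f"hap{hi:03d}", variant_indices=idx, weight=float(weight)))

    pop = HaplotypePopulation(reference=reference, variants=variants, haplotypes=tuple(haplotypes))
    for i, v in enumerate(variants):
        realised = pop.site_frequency(i)
        if abs(realised - v.target_frequency) > freq_tol:
            raise PopulationError(
                f"variant at {v.position}: realised frequency {realised:.6f} differs from "
                f"target {v.target_frequency:.6f} by more than {freq_tol}"
            )
    if truth_dir is not None:
        pop.write_truth(truth_dir)
    return pop


# ---------------------------------------------------------------------------
# read simulation


#: Phred scores used by the calibrated quality model
_CAL_Q_HIGH = 35
_CAL_Q_LOW = 12


@dataclass
class ReadSimConfig:
    """Paired-end read simulation parameters (2 x read_length, fold coverage).

    ``quality`` is a constant Phred score, a per-cycle profile, or the string
    ``"calibrated"``. The first two emit fixed qualities with substitution
    errors placed independently of them (truth stays maximally tractable).
    The calibrated model emits a high/low quality per base and concentrates
    errors at the low-quality bases so that each base errs at the rate its
    Phred score claims, while the overall per-base error rate still equals
    ``substitution_error_rate`` — mirroring how real base callers flag
    unreliable cycles.
    """

    read_length: int = 300
    insert_mean: float = 600.0
    insert_sd: float = 60.0
    mean_coverage: float = 100.0
    substitution_error_rate: float = 0.0
    quality: int | str | Sequence[int] = 35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 50:
            raise PopulationError(f"read_length {self.read_length} < 50")
        if self.mean_coverage <= 0:
            raise PopulationError("mean_coverage must be > 0")
        if not 0.0 <= self.substitution_error_rate < 0.05:
            raise PopulationError("substitution_error_rate must be in [0, 0.05)")
        if self.insert_mean < self.read_length:
            warnings.warn(
                "insert_mean < read_length: mates will fully overlap", stacklevel=2
            )
        if self.calibrated:
            e_high = 10.0 ** (-_CAL_Q_HIGH / 10)
            if self.substitution_error_rate <= e_high:
                raise PopulationError(
                    f"calibrated quality model needs error rate > {e_high:.2g}"
                )

    @property
    def calibrated(self) -> bool:
        return isinstance(self.quality, str) and self.quality == "calibrated"

    def low_quality_fraction(self) -> float:
        """Fraction of bases emitted at the low Phred score (calibrated model)."""
        e_high = 10.0 ** (-_CAL_Q_HIGH / 10)
        e_low = 10.0 ** (-_CAL_Q_LOW / 10)
        return (self.substitution_error_rate - e_high) / (e_low - e_high)

    def quality_profile(self) -> np.ndarray:
        """Per-cycle Phred scores, length ``read_length`` (non-calibrated models)."""
        if self.calibrated:
            raise PopulationError("calibrated model has no fixed profile")
        if isinstance(self.quality, (int, np.integer)):
            return np.full(self.read_length, self.quality, dtype=np.uint8)
        prof = np.asarray(self.quality, dtype=np.uint8)
        if prof.shape != (self.read_length,):
            raise PopulationError("quality profile length must equal read_length")
        return prof


@dataclass
class SimResult:
    n_pairs: int
    r1_path: Path
    r2_path: Path
    truth_path: Path


_CHUNK = 20_000


def _n_fragments(length: int, config: ReadSimConfig) -> int:
    n = int(round(config.mean_coverage * length / (2 * config.read_length)))
    if n < 1:
        raise PopulationError("coverage too low: fewer than one fragment")
    return n


def _sim_chunk(
    hap_mat: np.ndarray,
    weights: np.ndarray,
    config: ReadSimConfig,
    rng: np.random.Generator,
    n: int,
):
    """Simulate ``n`` fragments; returns (hap_idx, start0, insert, r1, r2, q1, q2).

    ``q1``/``q2`` are per-base Phred matrices under the calibrated quality
    model and None otherwise (constant/profile qualities).
    """
    L = hap_mat.shape[1]
    rl = config.read_length
    hap_idx = np.searchsorted(np.cumsum(weights), rng.random(n), side="right")
    hap_idx = np.minimum(hap_idx, len(weights) - 1)
    insert = np.rint(rng.normal(config.insert_mean, config.insert_sd, size=n)).astype(np.int64)
    insert = np.clip(insert, rl, L)
    # uniform fragment start within [0, L - insert]
    start = np.floor(rng.random(n) * (L - insert + 1)).astype(np.int64)

    offs = np.arange(rl, dtype=np.int64)
    r1 = hap_mat[hap_idx[:, None], start[:, None] + offs]
    tail = hap_mat[hap_idx[:, None], (start + insert - rl)[:, None] + offs]
    r2 = _COMP4[tail[:, ::-1]]

    e = config.substitution_error_rate
    quals: list[np.ndarray | None] = [None, None]
    if config.calibrated:
        p_low = config.low_quality_fraction()
        for i, mat in enumerate((r1, r2)):
            q = np.where(
                rng.random(mat.shape, dtype=np.float32) < p_low, _CAL_Q_LOW, _CAL_Q_HIGH
            ).astype(np.uint8)
            err_p = np.where(q == _CAL_Q_LOW, 10.0 ** (-_CAL_Q_LOW / 10), 10.0 ** (-_CAL_Q_HIGH / 10))
            mask = rng.random(mat.shape, dtype=np.float32) < err_p
            shift = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
            mat[mask] = (mat[mask] + shift) % 4
            quals[i] = q
    elif e > 0:
        for mat in (r1, r2):
            mask = rng.random(mat.shape, dtype=np.float32) < e
            shift = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
            mat[mask] = (mat[mask] + shift) % 4
    return hap_idx, start, insert, r1, r2, quals[0], quals[1]


_COMP4 = np.array([3, 2, 1, 0], dtype=np.uint8)


def _write_pairs(
    pop: HaplotypePopulation,
    config: ReadSimConfig,
    rng: np.random.Generator,
    n_frag: int,
    w1: FastqWriter,
    w2: FastqWriter,
    truth_fh,
    id_prefix: str,
    source: str,
    start_index: int = 0,
) -> int:
    hap_mat = pop.haplotype_codes()
    weights = np.array([h.weight for h in pop.haplotypes])
    qstr = None if config.calibrated else phred_to_ascii(config.quality_profile())
    hap_ids = [h.id for h in pop.haplotypes]
    done = 0
    while done < n_frag:
        n = min(_CHUNK, n_frag - done)
        hap_idx, start, insert, r1, r2, q1, q2 = _sim_chunk(hap_mat, weights, config, rng, n)
        b1 = _DECODE_ROWS(r1)
        b2 = _DECODE_ROWS(r2)
        qs1 = _QUAL_ROWS(q1) if q1 is not None else None
        qs2 = _QUAL_ROWS(q2) if q2 is not None else None
        for i in range(n):
            rid = f"{id_prefix}{start_index + done + i:08d}"
            w1.write(f"{rid}/1", b1[i], qs1[i] if qs1 else qstr)
            w2.write(f"{rid}/2", b2[i], qs2[i] if qs2 else qstr)
            truth_fh.write(
                f"{rid}\t{source}\t{hap_ids[hap_idx[i]]}\t{start[i] + 1}\t{insert[i]}\n"
            )
        done += n
    return done


def _DECODE_ROWS(mat: np.ndarray) -> list[str]:
    from ._seqio import _DECODE_LUT

    flat = _DECODE_LUT[mat].tobytes().decode("ascii")
    w = mat.shape[1]
    return [flat[i : i + w] for i in range(0, len(flat), w)]


def _QUAL_ROWS(qmat: np.ndarray) -> list[str]:
    flat = (qmat + 33).astype(np.uint8).tobytes().decode("ascii")
    w = qmat.shape[1]
    return [flat[i : i + w] for i in range(0, len(flat), w)]


def simulate_reads(
    population: HaplotypePopulation,
    config: ReadSimConfig,
    outdir: str | Path,
    prefix: str = "reads",
) -> SimResult:
    """Simulate paired-end reads from a population into ``outdir``.

    Writes ``<prefix>_R1.fastq``/``<prefix>_R2.fastq`` plus a truth TSV
    recording, for every pair, its source haplotype, 1-based fragment start
    and insert size. Deterministic for a fixed ``config.seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    n_frag = _n_fragments(population.reference.length, config)
    r1_path = outdir / f"{prefix}_R1.fastq"
    r2_path = outdir / f"{prefix}_R2.fastq"
    truth_path = outdir / f"{prefix}_truth.tsv"
    with FastqWriter(r1_path) as w1, FastqWriter(r2_path) as w2, open(truth_path, "w") as tfh:
        tfh.write("read_id\tsource\thaplotype\tfragment_start\tinsert_size\n")
        _write_pairs(population, config, rng, n_frag, w1, w2, tfh, f"{prefix}:", population.reference.id)
    return SimResult(n_pairs=n_frag, r1_path=r1_path, r2_path=r2_path, truth_path=truth_path)


def simulate_coinfection_pool(
    population_a: HaplotypePopulation,
    population_b: HaplotypePopulation,
    mix_fraction: float,
    config: ReadSimConfig,
    outdir: str | Path,
    prefix: str = "pool",
) -> SimResult:
    """Simulate one read pool from two co-infecting populations.

    Each fragment is drawn from population A with probability ``mix_fraction``
    and from B otherwise. The total fragment count is set so that
    ``config.mean_coverage`` is the pool-wide fold coverage over the combined
    genome length; per-genome coverage follows from ``mix_fraction`` and the
    two genome lengths. The truth TSV labels each pair's source genome.
    """
    if population_a.reference.id == population_b.reference.id:
        raise PopulationError("co-infection requires distinct reference ids")
    if not 0.0 < mix_fraction < 1.0:
        raise PopulationError(f"mix_fraction {mix_fraction} not in (0, 1)")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    combined = population_a.reference.length + population_b.reference.length
    n_total = int(round(config.mean_coverage * combined / (2 * config.read_length)))
    if n_total < 1:
        raise PopulationError("coverage too low: fewer than one fragment")
    n_a = int(rng.binomial(n_total, mix_fraction))
    r1_path = outdir / f"{prefix}_R1.fastq"
    r2_path = outdir / f"{prefix}_R2.fastq"
    truth_path = outdir / f"{prefix}_truth.tsv"
    with FastqWriter(r1_path) as w1, FastqWriter(r2_path) as w2, open(truth_path, "w") as tfh:
        tfh.write("read_id\tsource\thaplotype\tfragment_start\tinsert_size\n")
        _write_pairs(population_a, config, rng, n_a, w1, w2, tfh,
                     f"{prefix}:", population_a.reference.id, start_index=0)
        _write_pairs(population_b, config, rng, n_total - n_a, w1, w2, tfh,
                     f"{prefix}:", population_b.reference.id, start_index=n_a)
    return SimResult(n_pairs=n_total, r1_path=r1_path, r2_path=r2_path, truth_path=truth_path)
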