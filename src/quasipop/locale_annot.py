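"""Genome localisation of called variants: gene categories, per-category
summaries and codon-level consequences.

Genes carry a functional category (non-structural, structural,
adsorption-associated, other/unknown); positions outside every gene are
implicitly non-coding. Adsorption-associated genes are structural genes and
can be folded into structural totals on request.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from ._seqio import revcomp
from .popgen_sim import ReferenceGenome

__all__ = [
    "CATEGORIES",
    "Gene",
    "GeneAnnotation",
    "AnnotatedVariant",
    "CategoryCount",
    "CategorySummary",
    "CodonConsequence",
    "assign_category",
    "annotate_variants",
    "summarise_categories",
    "structural_module_count",
    "codon_consequence",
    "multi_snp_codons",
]

#: gene categories; "non_coding" applies only to positions outside all genes
GENE_CATEGORIES = ("non_structural", "structural", "adsorption", "other_unknown")
CATEGORIES = GENE_CATEGORIES + ("non_coding",)


@dataclass(frozen=True)
class Gene:
    """One annotated gene (1-based inclusive coordinates)."""

    id: str
    start: int
    end: int
    strand: str
    category: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"gene {self.id}: bad interval {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.id}: strand must be + or -")
        if self.category not in GENE_CATEGORIES:
            raise ValueError(f"gene {self.id}: unknown category {self.category!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


class GeneAnnotation:
    """Non-overlapping gene set over one genome; overlaps are rejected at load."""

    def __init__(self, genes: Iterable[Gene], genome_length: int | None = None):
        self.genes = sorted(genes, key=lambda g: g.start)
        self.genome_length = genome_length
        prev = None
        for g in self.genes:
            if genome_length is not None and g.end > genome_length:
                raise ValueError(f"gene {g.id}: end {g.end} beyond genome length {genome_length}")
            if prev is not None and g.start <= prev.end:
                raise ValueError(f"genes {prev.id} and {g.id} overlap")
            prev = g
        self._starts = [g.start for g in self.genes]

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def gene_at(self, position: int) -> Gene | None:
        i = bisect.bisect_right(self._starts, position) - 1
        if i >= 0 and self.genes[i].contains(position):
            return self.genes[i]
        return None

    def by_id(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.id == gene_id:
                return g
        raise KeyError(gene_id)

    # ---- GFF3 --------------------------------------------------------------

    def to_gff3(self, path: str | Path, seqid: str = "genome") -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            if self.genome_length:
                fh.write(f"##sequence-region {seqid} 1 {self.genome_length}\n")
            for g in self.genes:
                attrs = f"ID={g.id};category={g.category}"
                fh.write(
                    f"{seqid}\tquasipop\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )

    @classmethod
    def from_gff3(cls, path: str | Path, genome_length: int | None = None) -> "GeneAnnotation":
        genes = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 9:
                    raise ValueError(f"malformed GFF3 line: {line!r}")
                _, _, ftype, start, end, _, strand, _, attrs = fields[:9]
                if ftype not in ("gene", "CDS"):
                    continue
                attr_map = dict(
                    kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
                )
                genes.append(
                    Gene(
                        id=attr_map.get("ID", f"gene{len(genes)}"),
                        start=int(start),
                        end=int(end),
                        strand=strand if strand in "+-" else "+",
                        category=attr_map.get("category", "other_unknown"),
                    )
                )
        return cls(genes, genome_length=genome_length)


@dataclass(frozen=True)
class CodonConsequence:
    codon_number: int
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str

    @property
    def synonymous(self) -> bool:
        return self.ref_aa == self.alt_aa

    @property
    def label(self) -> str:
        if self.synonymous:
            return "synonymous"
        return f"{self.ref_aa}{self.codon_number}{self.alt_aa}"


@dataclass
class AnnotatedVariant:
    """A variant call localised on the genome."""

    call: object  # VariantCall-like: .position/.ref_allele/.alt_allele
    gene_id: str | None
    category: str
    codon: CodonConsequence | None = None
    substitution: object | None = None

    @property
    def position(self) -> int:
        return self.call.position

    @property
    def aa_label(self) -> str | None:
        return self.codon.label if self.codon is not None else None


def assign_category(call, annotation: GeneAnnotation) -> AnnotatedVariant:
    """Assign a call to its gene category; intergenic positions are non_coding."""
    if annotation.genome_length is not None and not (
        1 <= call.position <= annotation.genome_length
    ):
        raise ValueError(f"call position {call.position} beyond genome bounds")
    gene = annotation.gene_at(call.position)
    if gene is None:
        return AnnotatedVariant(call=call, gene_id=None, category="non_coding")
    return AnnotatedVariant(call=call, gene_id=gene.id, category=gene.category)


def codon_consequence(call, gene: Gene, reference: ReferenceGenome) -> CodonConsequence:
    """Translate the reference vs mutated codon containing a call.

    Codon N covers gene-relative bases 3N-2..3N on the coding strand;
    minus-strand genes are read reverse-complemented.
    """
    if not gene.contains(call.position):
        raise ValueError(f"call at {call.position} outside gene {gene.id}")
    if gene.length % 3 != 0:
        raise ValueError(f"gene {gene.id}: length {gene.length} not divisible by 3")
    gene_seq = reference.sequence[gene.start - 1 : gene.end]
    if gene.strand == "+":
        offset = call.position - gene.start
        coding = gene_seq
        alt_base = call.alt_allele
    else:
        offset = gene.end - call.position
        coding = revcomp(gene_seq)
        alt_base = revcomp(call.alt_allele)
    codon_number = offset // 3 + 1
    within = offset % 3
    ref_codon = coding[3 * (codon_number - 1) : 3 * codon_number]
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    return CodonConsequence(
        codon_number=codon_number,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
    )


def annotate_variants(
    calls: Sequence,
    annotation: GeneAnnotation,
    reference: ReferenceGenome | None = None,
) -> list[AnnotatedVariant]:
    """Category assignment plus (when a reference is given) codon consequences."""
    from .pileup_caller import classify_substitution

    out = []
    for call in calls:
        av = assign_category(call, annotation)
        av.substitution = classify_substitution(call.ref_allele, call.alt_allele)
        if av.gene_id is not None and reference is not None:
            gene = annotation.by_id(av.gene_id)
            if gene.length % 3 == 0:
                av.codon = codon_consequence(call, gene, reference)
        out.append(av)
    return out


@dataclass(frozen=True)
class CategoryCount:
    snp_count: int
    genes_total: int
    genes_with_snp: int


@dataclass
class CategorySummary:
    """Per-category SNP counts and genes-with-SNP tallies."""

    counts: dict[str, CategoryCount]

    @property
    def total_snps(self) -> int:
        return sum(c.snp_count for c in self.counts.values())

    def structural_total(self) -> CategoryCount:
        """Structural-module totals with adsorption genes folded in."""
        s, a = self.counts["structural"], self.counts["adsorption"]
        return CategoryCount(
            snp_count=s.snp_count + a.snp_count,
            genes_total=s.genes_total + a.genes_total,
            genes_with_snp=s.genes_with_snp + a.genes_with_snp,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "category": cat,
                "snp_count": c.snp_count,
                "genes_total": c.genes_total,
                "genes_with_snp": c.genes_with_snp,
            }
            for cat, c in self.counts.items()
        ]
        return pd.DataFrame(rows, columns=["category", "snp_count", "genes_total", "genes_with_snp"])


def summarise_categories(
    annotated_variants: Sequence[AnnotatedVariant],
    annotation: GeneAnnotation,
) -> CategorySummary:
    """Per-category SNP counts plus distinct-genes-with->=1-SNP tallies."""
    snp_counts = {cat: 0 for cat in CATEGORIES}
    genes_hit: dict[str, set[str]] = {cat: set() for cat in CATEGORIES}
    for av in annotated_variants:
        snp_counts[av.category] += 1
        if av.gene_id is not None:
            genes_hit[av.category].add(av.gene_id)
    genes_total = {cat: 0 for cat in CATEGORIES}
    for g in annotation:
        genes_total[g.category] += 1
    return CategorySummary(
        counts={
            cat: CategoryCount(
                snp_count=snp_counts[cat],
                genes_total=genes_total[cat],
                genes_with_snp=len(genes_hit[cat]),
            )
            for cat in CATEGORIES
        }
    )


def structural_module_count(annotated_variants: Sequence[AnnotatedVariant]) -> int:
    """Variants inside the structural module (structural + adsorption genes)."""
    return sum(av.category in ("structural", "adsorption") for av in annotated_variants)


def multi_snp_codons(
    annotated_variants: Sequence[AnnotatedVariant],
) -> list[tuple[str, int, list[str]]]:
    """Codons carrying >= 2 distinct calls: (gene_id, codon_number, labels)."""
    groups: dict[tuple[str, int], list[str]] = {}
    for av in annotated_variants:
        if av.gene_id is None or av.codon is None:
            continue
        groups.setdefault((av.gene_id, av.codon.codon_number), []).append(av.codon.label)
    return [
        (gene, codon, labels)
        for (gene, codon), labels in sorted(groups.items())
        if len(labels) >= 2
    ]
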