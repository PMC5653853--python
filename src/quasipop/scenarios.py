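"""Self-contained benchmark scenarios used by the acceptance checks.

Each scenario builds its inputs from scratch (random reference, planted
haplotypes, simulated reads), runs the relevant part of the pipeline, and
returns the measured quantity together with the ground truth.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .align_lite import index_reference, map_fastq_pair
from .cli_pipeline import PipelineConfig, run_pipeline
from .locale_annot import (
    Gene,
    GeneAnnotation,
    assign_category,
    structural_module_count,
)
from .pileup_caller import VariantCall
from .popgen_sim import (
    ReadSimConfig,
    build_population,
    nested_haplotype_spec,
    random_reference,
    random_variants,
    simulate_coinfection_pool,
)
from ._seqio import write_fasta

__all__ = [
    "twenty_site_scenario",
    "category_fixture",
    "coinfection_scenario",
]

#: planted population frequencies (%) for the 20-site calling scenario:
#: 15 above the 1% reporting threshold, 5 below it.
TWENTY_SITE_FREQS_PCT = (
    1.44, 2.0, 3.3, 5.0, 8.31, 10.0, 12.0, 15.0, 20.0, 25.0,
    30.0, 35.0, 40.0, 46.8, 47.2,
    0.5, 0.5, 0.5, 0.5, 0.5,
)

#: 15 fixed variant positions for the category-assignment fixture
CATEGORY_FIXTURE_POSITIONS = (
    1200, 4800, 9100, 14300, 26050, 27400, 30200, 33900,
    36100, 36550, 37000, 37420, 37910, 38300, 38760,
)


@dataclass
class ScenarioResult:
    value: int
    n: int
    detail: dict


def _split_haplotype_spec(variants, threshold: float):
    """Nested haplotypes for supra-threshold sites; each sub-threshold site
    on its own mutually exclusive haplotype (decorrelates their sampling)."""
    supra = [i for i, v in enumerate(variants) if v.target_frequency > threshold]
    sub = [i for i, v in enumerate(variants) if v.target_frequency <= threshold]
    spec = []
    nested = nested_haplotype_spec([variants[i] for i in supra])
    sub_total = sum(variants[i].target_frequency for i in sub)
    for subset, w in nested:
        mapped = frozenset(supra[j] for j in subset)
        if not mapped:  # carve the exclusive sub-threshold haplotypes out of the wild type
            w -= sub_total
        spec.append((mapped, w))
    for i in sub:
        spec.append((frozenset([i]), variants[i].target_frequency))
    return spec


def twenty_site_scenario(seed: int, workdir: str | Path | None = None) -> ScenarioResult:
    """Full pipeline on a 43 kb population with 20 planted sites at 1000x.

    Returns the number of PASS variant records in the output VCF.
    """
    rng = np.random.default_rng(seed)
    reference = random_reference(43_000, rng, id="simA")
    freqs = [f / 100.0 for f in TWENTY_SITE_FREQS_PCT]
    variants = random_variants(reference, freqs, rng, min_separation=20, edge_margin=700)
    population = build_population(reference, variants, _split_haplotype_spec(variants, 0.01))

    with tempfile.TemporaryDirectory() as tmp:
        outdir = Path(workdir) if workdir else Path(tmp)
        outdir.mkdir(parents=True, exist_ok=True)
        from .popgen_sim import simulate_reads

        sim = simulate_reads(
            population,
            ReadSimConfig(
                read_length=300,
                insert_mean=650,
                insert_sd=50,
                mean_coverage=1000,
                substitution_error_rate=0.002,
                quality="calibrated",
                seed=seed,
            ),
            outdir,
        )
        ref_fasta = outdir / "reference.fasta"
        write_fasta({reference.id: reference.sequence}, ref_fasta)
        result = run_pipeline(
            PipelineConfig(
                reference_fasta=str(ref_fasta),
                outdir=str(outdir / "pipeline"),
                fastq_r1=str(sim.r1_path),
                fastq_r2=str(sim.r2_path),
                min_freq=0.01,
                min_depth=100,
                seed=seed,
            )
        )
        truth = population.variants_table()
        return ScenarioResult(
            value=result.n_pass,
            n=sim.n_pairs,
            detail={
                "calls": [(c.position, c.alt_allele, c.alt_frequency) for c in result.calls if c.passed],
                "truth": truth,
            },
        )


def category_fixture() -> tuple[list[VariantCall], GeneAnnotation]:
    """Fixed 15-position variant list plus a 43 kb annotation whose
    structural module spans 25,000-40,000 with a tail-fibre (adsorption)
    gene at 36,000-39,000."""
    genes = [
        Gene(id="gp01_polymerase", start=500, end=10_000, strand="+", category="non_structural"),
        Gene(id="gp10_helicase", start=10_500, end=20_000, strand="+", category="non_structural"),
        Gene(id="gp20_unknown", start=20_500, end=24_500, strand="+", category="other_unknown"),
        Gene(id="gp25_capsid", start=25_000, end=30_999, strand="+", category="structural"),
        Gene(id="gp30_tail_tube", start=31_000, end=35_999, strand="+", category="structural"),
        Gene(id="gp39_tail_fibre", start=36_000, end=38_999, strand="+", category="adsorption"),
        Gene(id="gp42_baseplate", start=39_000, end=40_000, strand="+", category="structural"),
        Gene(id="gp45_lysin", start=40_500, end=42_500, strand="+", category="other_unknown"),
    ]
    annotation = GeneAnnotation(genes, genome_length=43_000)
    calls = [
        VariantCall(position=p, ref_allele="A", alt_allele="G", alt_frequency=0.05,
                    alt_count=50, depth=1000)
        for p in CATEGORY_FIXTURE_POSITIONS
    ]
    return calls, annotation


def category_counts() -> tuple[int, int]:
    """(structural-module sites, tail-fibre-gene sites) for the fixed fixture."""
    calls, annotation = category_fixture()
    annotated = [assign_category(c, annotation) for c in calls]
    n_structural = structural_module_count(annotated)
    n_tail_fibre = sum(av.gene_id == "gp39_tail_fibre" for av in annotated)
    return n_structural, n_tail_fibre


def coinfection_scenario(seed: int, workdir: str | Path | None = None) -> ScenarioResult:
    """Two-phage co-infection pool; variants called on the partner genome B.

    Genome A (43 kb) is variant-free; genome B (86 kb) carries 75 planted
    sites: 67 with frequencies evenly spaced 1.4-21.2% and 8 at 0.5%. The
    pool mixes fragments 50:50 and is sized so B sees ~500x; pool reads are
    mapped to both genomes, fragments mapping better to A are discarded, and
    PASS records on B are counted.
    """
    rng = np.random.default_rng(seed)
    ref_a = random_reference(43_000, rng, id="simA")
    ref_b = random_reference(86_000, rng, id="simB")
    pop_a = build_population(ref_a, [], [(frozenset(), 1.0)])
    freqs_b = [0.014 + (0.212 - 0.014) * i / 66 for i in range(67)] + [0.005] * 8
    variants_b = random_variants(ref_b, freqs_b, rng, min_separation=20, edge_margin=700)
    pop_b = build_population(ref_b, variants_b, _split_haplotype_spec(variants_b, 0.01))

    # pool-wide coverage chosen so that half the fragments give B 500x:
    # 0.5 * cov * (L_A + L_B) / L_B = 500
    combined = ref_a.length + ref_b.length
    pool_cov = 500 * ref_b.length / (0.5 * combined)

    with tempfile.TemporaryDirectory() as tmp:
        outdir = Path(workdir) if workdir else Path(tmp)
        outdir.mkdir(parents=True, exist_ok=True)
        sim = simulate_coinfection_pool(
            pop_a,
            pop_b,
            mix_fraction=0.5,
            config=ReadSimConfig(
                read_length=300,
                insert_mean=650,
                insert_sd=50,
                mean_coverage=pool_cov,
                substitution_error_rate=0.002,
                quality="calibrated",
                seed=seed,
            ),
            outdir=outdir,
        )
        idx_a = index_reference(ref_a)
        idx_b = index_reference(ref_b)
        reads_a = map_fastq_pair(sim.r1_path, sim.r2_path, idx_a)
        reads_b = map_fastq_pair(sim.r1_path, sim.r2_path, idx_b)

        # per-fragment competitive assignment: keep fragments whose total
        # mismatch count on B beats (or B alone maps) their placement on A
        mm_a: dict[str, int] = {}
        for r in reads_a:
            mm_a[r.qname] = mm_a.get(r.qname, 0) + r.n_mismatch
        mm_b: dict[str, int] = {}
        for r in reads_b:
            mm_b[r.qname] = mm_b.get(r.qname, 0) + r.n_mismatch
        keep = {q for q, mm in mm_b.items() if q not in mm_a or mm < mm_a[q]}
        b_reads = [r for r in reads_b if r.qname in keep]

        from .pileup_caller import run_multi_config

        calls, _ = run_multi_config([b_reads], ref_b, min_freq=0.01, min_depth=100)
        n_pass = sum(c.passed for c in calls)
        return ScenarioResult(
            value=n_pass,
            n=sim.n_pairs,
            detail={"truth": pop_b.variants_table()},
        )
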