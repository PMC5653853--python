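import numpy as np
import pytest

from quasipop.popgen_sim import (
    PlantedVariant,
    ReadSimConfig,
    ReferenceGenome,
    build_population,
    nested_haplotype_spec,
    random_reference,
    random_variants,
    simulate_reads,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_reference(rng):
    return random_reference(2000, rng, id="toy")


@pytest.fixture
def toy_variants(toy_reference, rng):
    return random_variants(toy_reference, [0.05, 0.40], rng, edge_margin=400)


@pytest.fixture
def toy_population(toy_reference, toy_variants):
    return build_population(toy_reference, toy_variants, nested_haplotype_spec(toy_variants))


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """A 3 kb population with two planted variants, simulated at 600x.

    Shared across pileup/linkage/pipeline tests to keep the suite fast.
    """
    rng = np.random.default_rng(777)
    reference = random_reference(3000, rng, id="bundle")
    variants = random_variants(reference, [0.08, 0.30], rng, edge_margin=700, min_separation=40)
    population = build_population(reference, variants, nested_haplotype_spec(variants))
    outdir = tmp_path_factory.mktemp("sim_bundle")
    config = ReadSimConfig(
        read_length=300,
        insert_mean=650,
        insert_sd=50,
        mean_coverage=600,
        substitution_error_rate=0.002,
        quality=35,
        seed=777,
    )
    sim = simulate_reads(population, config, outdir)
    return {
        "reference": reference,
        "variants": variants,
        "population": population,
        "config": config,
        "sim": sim,
        "outdir": outdir,
    }
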