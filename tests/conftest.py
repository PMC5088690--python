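import numpy as np
import pytest

import apydim as ad
from apydim import pipeline, relmat


def random_spd(n: int, rng: np.random.Generator) -> np.ndarray:
    """Well-conditioned random symmetric positive definite matrix."""
    b = rng.standard_normal((n, n))
    return b @ b.T + n * np.eye(n)


@pytest.fixture(scope="session")
def tiny_config() -> ad.SimConfig:
    return ad.SimConfig(
        ne=20,
        genome_length=2.0,
        n_chrom=4,
        n_snp=400,
        n_qtl=60,
        n_generations=4,
        n_per_generation=150,
        genotyped_generations=(3, 4),
        heritability=0.3,
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_pop(tiny_config) -> ad.SimulatedPopulation:
    return ad.simulate_population(tiny_config)


@pytest.fixture(scope="session")
def tiny_rels(tiny_pop) -> relmat.RelationshipSet:
    return relmat.build_relationships(
        tiny_pop.genotypes, tiny_pop.genotyped_ids, tiny_pop.pedigree, 0.95
    )


@pytest.fixture(scope="session")
def tiny_experiment_config(tiny_config) -> pipeline.ExperimentConfig:
    return pipeline.ExperimentConfig(
        sim=tiny_config, thresholds=(0.90, 0.95, 0.98), core_seed=777
    )


@pytest.fixture(scope="session")
def tiny_report(tiny_experiment_config) -> pipeline.ExperimentReport:
    return pipeline.run_experiment(tiny_experiment_config)
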