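"""Simulator tests: meiosis, drift, trait model, reproducibility."""

import numpy as np
import pandas as pd
import pytest

from apydim.synthpop import (
    GenomeMap,
    SimConfig,
    assign_trait,
    heterozygosity,
    make_gamete,
    run_burn_in,
    simulate_population,
)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(ne=1),
        dict(genome_length=0.0),
        dict(n_snp=0),
        dict(heritability=0.0),
        dict(heritability=1.5),
        dict(n_chrom=0),
        dict(genotyped_generations=(0,)),
        dict(genotyped_generations=(9,)),
    ],
)
def test_config_rejects_invalid_parameters(kwargs):
    base = dict(ne=10, genome_length=1.0, n_chrom=2, n_snp=50, n_qtl=5,
                n_generations=3, n_per_generation=20, seed=0)
    base.update(kwargs)
    with pytest.raises(ValueError):
        SimConfig(**base)


def test_config_defaults():
    cfg = SimConfig(ne=10, genome_length=1.0, n_snp=50, n_generations=5)
    assert cfg.burn_in_generations == 40
    assert cfg.genotyped_generations == (3, 4, 5)
    assert np.allclose(cfg.chrom_lengths.sum(), cfg.genome_length)


def test_simulated_population_structure(tiny_pop, tiny_config):
    cfg = tiny_config
    ped = tiny_pop.pedigree
    assert len(ped) == cfg.n_generations * cfg.n_per_generation
    # ids are 1..n in birth order; parents precede offspring (0 = unknown)
    assert np.array_equal(ped["animal"].to_numpy(), np.arange(1, len(ped) + 1))
    assert (ped["sire"] < ped["animal"]).all() and (ped["dam"] < ped["animal"]).all()
    assert (ped["sire"] != ped["dam"])[ped["sire"] > 0].all()
    assert set(np.unique(tiny_pop.genotypes)) <= {0, 1, 2}
    # genotyped set matches the configured generations
    expect = ped.loc[ped["generation"].isin(cfg.genotyped_generations), "animal"]
    assert np.array_equal(tiny_pop.genotyped_ids, expect.to_numpy())
    assert tiny_pop.genotypes.shape == (len(expect), cfg.n_snp)
    assert len(tiny_pop.phenotypes) == len(ped)
    # SNP panel was drawn from loci segregating at the end of burn-in, so
    # nearly all markers should still be polymorphic among genotyped animals
    freq = tiny_pop.genotypes.mean(axis=0) / 2
    assert np.mean((freq > 0) & (freq < 1)) > 0.95


def test_heritability_calibration(tiny_pop):
    gen1 = tiny_pop.pedigree["generation"].to_numpy() == 1
    vg = tiny_pop.tbv[gen1].var()
    vy = tiny_pop.phenotypes.loc[gen1, "value"].var()
    assert vg / vy == pytest.approx(0.3, abs=0.06)


def test_simulation_is_deterministic():
    cfg = SimConfig(ne=10, genome_length=1.0, n_chrom=2, n_snp=80, n_qtl=10,
                    n_generations=2, n_per_generation=40, seed=5)
    a, b = simulate_population(cfg), simulate_population(cfg)
    assert np.array_equal(a.genotypes, b.genotypes)
    assert a.pedigree.equals(b.pedigree)
    assert a.phenotypes.equals(b.phenotypes)
    assert np.array_equal(a.tbv, b.tbv)
    assert np.array_equal(a.qtl_effects, b.qtl_effects)


def test_snp_shortfall_raises_named_error():
    cfg = SimConfig(ne=2, genome_length=0.1, n_chrom=1, n_snp=50, n_qtl=2,
                    n_generations=1, n_per_generation=5, burn_in_generations=60,
                    genotyped_generations=(1,), seed=1)
    with pytest.raises(ValueError, match="shortfall"):
        simulate_population(cfg)


# ---------------------------------------------------------------------------
# meiosis kernel
# ---------------------------------------------------------------------------


def _map_1chrom(n_loci, length):
    return GenomeMap(
        np.array([length]),
        np.zeros(n_loci, dtype=int),
        (np.arange(n_loci) + 0.5) / n_loci * length if length > 0 else np.zeros(n_loci),
    )


def test_gamete_zero_length_chromosome_is_intact_copy():
    gmap = _map_1chrom(30, 0.0)
    rng = np.random.default_rng(0)
    hap = np.vstack([np.zeros(30, dtype=np.int8), np.ones(30, dtype=np.int8)])
    for _ in range(10):
        g = make_gamete(hap, gmap, rng)
        assert np.array_equal(g, hap[0]) or np.array_equal(g, hap[1])


def test_gamete_identical_parental_haplotypes_invariant():
    gmap = _map_1chrom(50, 2.0)
    rng = np.random.default_rng(1)
    hap = np.tile(rng.integers(0, 2, 50).astype(np.int8), (2, 1))
    for _ in range(10):
        assert np.array_equal(make_gamete(hap, gmap, rng), hap[0])


def test_gamete_poisson_crossover_mean():
    """On a 1-Morgan chromosome the mean crossover count is 1."""
    n_loci = 400
    gmap = _map_1chrom(n_loci, 1.0)
    hap = np.vstack([np.zeros(n_loci, dtype=np.int8), np.ones(n_loci, dtype=np.int8)])
    rng = np.random.default_rng(2)
    switches = 0
    n = 10_000
    for _ in range(n):
        g = make_gamete(hap, gmap, rng)
        switches += int(np.sum(g[1:] != g[:-1]))
    assert switches / n == pytest.approx(1.0, abs=0.05)


def test_gamete_input_validation():
    with pytest.raises(ValueError, match="empty"):
        GenomeMap(np.array([1.0]), np.zeros(0, dtype=int), np.zeros(0))
    gmap = _map_1chrom(10, 1.0)
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError):
        make_gamete(np.zeros((2, 5), dtype=np.int8), gmap, rng)
    with pytest.raises(ValueError):
        make_gamete(np.zeros(10, dtype=np.int8), gmap, rng)


# ---------------------------------------------------------------------------
# drift
# ---------------------------------------------------------------------------


def test_heterozygosity_decay_matches_drift_expectation():
    """H_t / H_0 ≈ (1 - 1/2Ne)^t under random union of gametes."""
    ne, t, reps = 20, 10, 10
    ratios = []
    for s in range(reps):
        cfg = SimConfig(ne=ne, genome_length=1.0, n_chrom=2, n_snp=1500, n_qtl=10,
                        burn_in_generations=t, seed=300 + s)
        b = run_burn_in(cfg)
        h0 = float(np.mean(2 * b.founder_freq * (1 - b.founder_freq)))
        ratios.append(heterozygosity(b.haplotypes, b.n_initial_loci) / h0)
    expected = (1 - 1 / (2 * ne)) ** t
    mean = np.mean(ratios)
    se = np.std(ratios, ddof=1) / np.sqrt(reps)
    assert abs(mean - expected) < 3 * se


# ---------------------------------------------------------------------------
# trait model
# ---------------------------------------------------------------------------


def test_trait_h2_one_phenotype_equals_tbv():
    rng = np.random.default_rng(0)
    dosages = rng.integers(0, 3, size=(200, 50))
    gens = np.repeat([1, 2], 100)
    _, _, tbv, y = assign_trait(dosages, gens, 10, heritability=1.0, rng=rng)
    assert np.allclose(y, tbv)


def test_trait_injected_zero_effects_give_zero_tbv():
    rng = np.random.default_rng(0)
    dosages = rng.integers(0, 3, size=(50, 20))
    gens = np.ones(50, dtype=int)
    _, eff, tbv, y = assign_trait(
        dosages, gens, 5, heritability=0.5, rng=rng, effects=np.zeros(5)
    )
    assert np.all(eff == 0) and np.all(tbv == 0)


def test_trait_too_many_qtl_raises():
    rng = np.random.default_rng(0)
    dosages = np.full((30, 10), 2, dtype=int)  # every locus fixed
    with pytest.raises(ValueError, match="segregating"):
        assign_trait(dosages, np.ones(30, dtype=int), 5, 0.5, rng)


def test_offspring_tbv_regresses_on_midparent_with_unit_slope():
    """Additive inheritance: E[TBV_offspring] = midparent TBV."""
    slopes = []
    for s in range(3):
        pop = simulate_population(
            SimConfig(ne=20, genome_length=2.0, n_chrom=4, n_snp=300, n_qtl=60,
                      n_generations=2, n_per_generation=300,
                      genotyped_generations=(1, 2), heritability=0.5, seed=200 + s)
        )
        tbv = pd.Series(pop.tbv, index=pop.pedigree["animal"].to_numpy())
        off = pop.pedigree[(pop.pedigree["sire"] > 0) & (pop.pedigree["dam"] > 0)]
        mid = (tbv[off["sire"]].to_numpy() + tbv[off["dam"]].to_numpy()) / 2
        slopes.append(np.polyfit(mid, tbv[off["animal"]].to_numpy(), 1)[0])
    assert np.mean(slopes) == pytest.approx(1.0, abs=0.15)
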