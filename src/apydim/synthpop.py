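"""Forward-in-time simulation of livestock-like populations.

The simulator produces the raw material every downstream stage of the
package consumes: a pedigree, 0/1/2 SNP genotypes for the genotyped
generations, true breeding values and single-record phenotypes.

The design mimics the classical genomic-prediction benchmark layout:
discrete non-overlapping generations under random mating without
selection, a burn-in phase at constant census size ``ne`` that builds up
drift linkage disequilibrium, followed by an expansion phase of
``n_per_generation`` animals per generation whose last generations are
genotyped.  Under random mating with distinct parents and Poisson family
sizes, census size and effective population size coincide, so ``ne`` is
controlled directly by the number of breeders.

Recombination follows Haldane's model: per chromosome the crossover
count is Poisson with mean equal to the map length in Morgan, crossover
positions are uniform, and chromosomes assort independently.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "GenomeMap",
    "SimulatedPopulation",
    "make_gamete",
    "run_burn_in",
    "assign_trait",
    "simulate_population",
    "heterozygosity",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated population.

    Parameters
    ----------
    ne
        Effective (== census) population size during burn-in; also the
        number of parents available to the first expansion generation.
    genome_length
        Total map length in Morgan, split equally over ``n_chrom``
        chromosomes.
    n_chrom
        Number of chromosomes.
    n_snp
        Number of biallelic markers retained on the SNP panel.  Only
        loci still segregating at the end of burn-in are eligible.
    n_qtl
        Number of additive causal loci; disjoint from the SNP panel.
    n_generations
        Number of expansion generations (pedigree-recorded).
    n_per_generation
        Animals born per expansion generation.
    genotyped_generations
        Which expansion generations are genotyped (1-based labels).
    heritability
        Narrow-sense h² of the simulated trait on the observed scale,
        calibrated in the first expansion generation.
    burn_in_generations
        Length of the constant-size burn-in; ``None`` selects the
        default ``4 * ne``, long enough for drift LD to approach its
        stationary profile.
    seed
        Seed for every random draw in the simulation.
    """

    ne: int
    genome_length: float
    n_snp: int
    n_chrom: int = 10
    n_qtl: int = 100
    n_generations: int = 5
    n_per_generation: int = 500
    genotyped_generations: tuple[int, ...] = ()
    heritability: float = 0.3
    burn_in_generations: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ne < 2:
            raise ValueError(f"ne must be >= 2, got {self.ne}")
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.n_snp < 1:
            raise ValueError("n_snp must be >= 1")
        if self.n_chrom < 1:
            raise ValueError("n_chrom must be >= 1")
        if not 0.0 < self.heritability <= 1.0:
            raise ValueError("heritability must be in (0, 1]")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if self.n_per_generation < 1:
            raise ValueError("n_per_generation must be >= 1")
        gg = self.genotyped_generations
        if not gg:
            # default: the last min(3, n_generations) generations
            k = min(3, self.n_generations)
            gg = tuple(range(self.n_generations - k + 1, self.n_generations + 1))
            object.__setattr__(self, "genotyped_generations", gg)
        if any(g < 1 or g > self.n_generations for g in gg):
            raise ValueError(f"genotyped_generations {gg} outside 1..{self.n_generations}")
        if self.burn_in_generations is None:
            object.__setattr__(self, "burn_in_generations", 4 * self.ne)
        if self.burn_in_generations < 0:
            raise ValueError("burn_in_generations must be >= 0")

    @property
    def chrom_lengths(self) -> np.ndarray:
        """Per-chromosome map lengths (equal split of ``genome_length``)."""
        return np.full(self.n_chrom, self.genome_length / self.n_chrom)


@dataclass(frozen=True)
class GenomeMap:
    """Marker map: chromosome assignment and Morgan position per locus.

    Loci are stored sorted by (chromosome, position) so each chromosome
    occupies a contiguous slice.
    """

    chrom_lengths: np.ndarray
    chrom_index: np.ndarray  # per-locus chromosome id, 0-based
    positions: np.ndarray  # per-locus position within chromosome, Morgan

    def __post_init__(self) -> None:
        if self.positions.size == 0:
            raise ValueError("marker map is empty")
        object.__setattr__(self, "_slices", self._build_slices())

    def _build_slices(self) -> list[slice]:
        out = []
        for c in range(len(self.chrom_lengths)):
            lo, hi = np.searchsorted(self.chrom_index, [c, c + 1])
            out.append(slice(int(lo), int(hi)))
        return out

    @property
    def n_loci(self) -> int:
        return self.positions.size

    def chrom_slices(self) -> list[slice]:
        return self._slices  # type: ignore[attr-defined]

    def subset(self, idx: np.ndarray) -> "GenomeMap":
        idx = np.sort(np.asarray(idx))
        return GenomeMap(self.chrom_lengths, self.chrom_index[idx], self.positions[idx])


def _even_map(chrom_lengths: np.ndarray, n_loci: int) -> GenomeMap:
    """Allocate ``n_loci`` evenly spaced loci proportionally to map length."""
    total = chrom_lengths.sum()
    per = np.maximum(1, np.round(n_loci * chrom_lengths / total).astype(int))
    # fix rounding so counts sum to n_loci
    while per.sum() > n_loci:
        per[np.argmax(per)] -= 1
    while per.sum() < n_loci:
        per[np.argmin(per)] += 1
    chrom_index = np.repeat(np.arange(len(chrom_lengths)), per)
    positions = np.concatenate(
        [(np.arange(k) + 0.5) / k * L for k, L in zip(per, chrom_lengths)]
    )
    return GenomeMap(chrom_lengths, chrom_index, positions)


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------


def make_gamete(
    parent_haplotypes: np.ndarray, genome_map: GenomeMap, rng: np.random.Generator
) -> np.ndarray:
    """Sample one recombinant gamete from a phased parental haplotype pair.

    Crossover counts are Poisson with mean equal to the chromosome map
    length (no interference); positions are uniform on the chromosome;
    chromosomes assort independently.  A chromosome of length 0 Morgan
    is transmitted as an intact copy of one parental haplotype.
    """
    hap = np.asarray(parent_haplotypes)
    if hap.ndim != 2 or hap.shape[0] != 2:
        raise ValueError("parent_haplotypes must have shape (2, n_loci)")
    if hap.shape[1] != genome_map.n_loci:
        raise ValueError("haplotypes not aligned to the marker map")
    gamete = np.empty(genome_map.n_loci, dtype=hap.dtype)
    for c, sl in enumerate(genome_map.chrom_slices()):
        if sl.start == sl.stop:
            continue
        length = genome_map.chrom_lengths[c]
        start = int(rng.integers(2))
        k = int(rng.poisson(length)) if length > 0 else 0
        if k == 0:
            gamete[sl] = hap[start, sl]
            continue
        cx = np.sort(rng.uniform(0.0, length, size=k))
        n_before = np.searchsorted(cx, genome_map.positions[sl], side="right")
        take_second = (start + n_before) % 2
        gamete[sl] = np.where(take_second == 0, hap[0, sl], hap[1, sl])
    return gamete


def _mate_generation(
    haps: np.ndarray,
    n_offspring: int,
    gmap: GenomeMap,
    rng: np.random.Generator,
    allow_self: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One round of hermaphroditic random mating.

    ``haps`` holds the parental generation as 2 rows per individual.
    With ``allow_self`` the two parents are drawn independently (random
    union of gametes, the idealized Wright-Fisher scheme used during
    burn-in); otherwise sire and dam are distinct, as required for a
    pedigree.  Returns offspring haplotypes (2 rows each) plus the
    0-based sire and dam indices used for each offspring.
    """
    n_parents = haps.shape[0] // 2
    sires = rng.integers(n_parents, size=n_offspring)
    if allow_self:
        dams = rng.integers(n_parents, size=n_offspring)
    else:
        # distinct dam, uniform over the remaining parents
        dams = (sires + 1 + rng.integers(n_parents - 1, size=n_offspring)) % n_parents
    out = np.empty((2 * n_offspring, haps.shape[1]), dtype=haps.dtype)
    for k in range(n_offspring):
        out[2 * k] = make_gamete(haps[2 * sires[k] : 2 * sires[k] + 2], gmap, rng)
        out[2 * k + 1] = make_gamete(haps[2 * dams[k] : 2 * dams[k] + 2], gmap, rng)
    return out, sires, dams


# ---------------------------------------------------------------------------
# burn-in
# ---------------------------------------------------------------------------


@dataclass
class BurnInResult:
    haplotypes: np.ndarray  # (2*ne, n_surviving_loci) int8
    genome_map: GenomeMap
    founder_freq: np.ndarray  # realized allele frequencies at generation 0
    n_initial_loci: int = 0


def _n_candidate_loci(config: SimConfig) -> int:
    """Oversampling needed so enough loci survive drift during burn-in.

    The proportion of loci still segregating after t generations at
    size N decays asymptotically like exp(-t/2N); an empirical constant
    of ~0.5 (founder frequencies uniform on (0.05, 0.95)) plus a 1.6x
    safety factor keeps shortfalls rare without excessive oversampling.
    Fixed loci are pruned during burn-in, so over-allocation is cheap.
    """
    need = config.n_snp + config.n_qtl + max(10, config.n_qtl // 5)
    t = config.burn_in_generations
    surv = min(0.95, 0.5 * math.exp(-t / (2.0 * config.ne)))
    return int(min(need * 1.6 / max(surv, 0.005), need * 400))


def run_burn_in(config: SimConfig, rng: np.random.Generator | None = None) -> BurnInResult:
    """Build drift LD: constant-size random mating from linkage equilibrium.

    Founder haplotypes are drawn independently per locus with allele
    frequencies uniform on (0.05, 0.95); ``burn_in_generations`` rounds
    of random mating at census size ``ne`` follow.  Loci that fix are
    dropped as burn-in proceeds (without mutation they can never
    segregate again); ``n_initial_loci`` records the starting count so
    per-genome averages can still include the fixed loci.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_loci = _n_candidate_loci(config)
    gmap = _even_map(config.chrom_lengths, n_loci)
    p0 = rng.uniform(0.05, 0.95, size=n_loci)
    haps = (rng.random((2 * config.ne, n_loci)) < p0).astype(np.int8)
    founder_freq = haps.mean(axis=0)
    prune_every = max(4, config.ne // 4)
    for g in range(config.burn_in_generations):
        haps, _, _ = _mate_generation(haps, config.ne, gmap, rng, allow_self=True)
        if (g + 1) % prune_every == 0:
            freq = haps.mean(axis=0)
            seg = np.flatnonzero((freq > 0.0) & (freq < 1.0))
            if seg.size == 0:
                raise ValueError(
                    f"no loci segregate after {g + 1} burn-in generations: "
                    f"shortfall of {config.n_snp} markers; increase the genome "
                    "or shorten the burn-in"
                )
            if seg.size < haps.shape[1]:
                haps = np.ascontiguousarray(haps[:, seg])
                gmap = gmap.subset(seg)
    return BurnInResult(haps, gmap, founder_freq, n_initial_loci=n_loci)


def heterozygosity(haplotypes: np.ndarray, n_total_loci: int | None = None) -> float:
    """Mean expected heterozygosity 2p(1-p) across loci.

    ``n_total_loci`` lets pruned (fixed) loci count as zero when the
    haplotype matrix only carries the still-segregating subset.
    """
    h = np.asarray(haplotypes)
    p = h.mean(axis=0)
    total = float(np.sum(2.0 * p * (1.0 - p)))
    return total / (n_total_loci if n_total_loci is not None else h.shape[1])


# ---------------------------------------------------------------------------
# trait model
# ---------------------------------------------------------------------------


def assign_trait(
    dosages: np.ndarray,
    generations: np.ndarray,
    n_qtl: int,
    heritability: float,
    rng: np.random.Generator,
    reference_generation: int | None = None,
    effects: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Sample an additive trait on top of existing genotypes.

    QTL are drawn from the segregating columns of ``dosages``; raw
    allele-substitution effects are standard normal, then rescaled so
    that var(TBV) = h² in the reference generation (phenotypic variance
    1 by construction, residual variance 1 - h²).  Phenotypes are
    y = TBV + e with independent normal residuals; with h² = 1 the
    residual vanishes and the phenotype equals the TBV.

    Returns ``(qtl_columns, effects, tbv, phenotype_values)``.
    ``effects`` may be injected (already on the final scale) for
    degenerate test scenarios; no rescaling is applied then.
    """
    dosages = np.asarray(dosages)
    generations = np.asarray(generations)
    if not 0.0 < heritability <= 1.0:
        raise ValueError("heritability must be in (0, 1]")
    freq = dosages.mean(axis=0) / 2.0
    seg = np.flatnonzero((freq > 0.0) & (freq < 1.0))
    if n_qtl > seg.size:
        raise ValueError(
            f"n_qtl={n_qtl} exceeds the {seg.size} segregating loci available"
        )
    qtl_cols = np.sort(rng.choice(seg, size=n_qtl, replace=False))
    if reference_generation is None:
        reference_generation = int(generations.min())
    ref = generations == reference_generation

    if effects is None:
        raw = rng.standard_normal(n_qtl)
        tbv_raw = dosages[:, qtl_cols].astype(float) @ raw
        v_ref = tbv_raw[ref].var()
        if v_ref <= 0:
            raise ValueError("true breeding values have zero variance in the reference generation")
        scale = math.sqrt(heritability / v_ref)
        effects = raw * scale
        tbv = tbv_raw * scale
        var_e = 1.0 - heritability
    else:
        effects = np.asarray(effects, dtype=float)
        tbv = dosages[:, qtl_cols].astype(float) @ effects
        v_ref = tbv[ref].var()
        var_e = v_ref * (1.0 - heritability) / heritability if v_ref > 0 else 0.0
    resid = rng.standard_normal(dosages.shape[0]) * math.sqrt(var_e)
    y = tbv + resid
    return qtl_cols, effects, tbv, y


# ---------------------------------------------------------------------------
# full simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedPopulation:
    """Output of :func:`simulate_population`.

    ``pedigree`` covers the expansion generations only (burn-in parents
    of generation 1 are recorded as unknown, id 0); animal ids are
    1-based and in birth order.  ``genotypes`` holds gene contents
    (0/1/2) for the genotyped animals at the ``n_snp`` panel markers, in
    ``genotyped_ids`` (birth) order.
    """

    config: SimConfig
    pedigree: pd.DataFrame  # columns: animal, sire, dam, generation
    genotyped_ids: np.ndarray
    genotypes: np.ndarray  # (n_genotyped, n_snp) int8
    snp_map: GenomeMap
    qtl_effects: np.ndarray
    tbv: np.ndarray  # aligned with pedigree rows
    phenotypes: pd.DataFrame  # columns: animal, value, generation, fixed_effect


def simulate_population(config: SimConfig) -> SimulatedPopulation:
    """Run burn-in, expansion, marker selection, and trait assignment."""
    rng = np.random.default_rng(config.seed)
    burn = run_burn_in(config, rng)
    haps, gmap = burn.haplotypes, burn.genome_map

    freq = haps.mean(axis=0)
    seg = np.flatnonzero((freq > 0.0) & (freq < 1.0))
    n_reserve = config.n_qtl + max(10, config.n_qtl // 5)
    need = config.n_snp + n_reserve
    if seg.size < need:
        raise ValueError(
            f"only {seg.size} loci segregate after burn-in but "
            f"{need} are required (n_snp={config.n_snp} plus "
            f"{n_reserve} trait-locus candidates): shortfall of {need - seg.size}"
        )
    retained = np.sort(rng.choice(seg, size=need, replace=False))
    # disjoint partition: trait-locus candidates vs SNP panel
    qtl_pool_local = np.sort(rng.choice(need, size=n_reserve, replace=False))
    snp_local = np.setdiff1d(np.arange(need), qtl_pool_local)
    gmap = gmap.subset(retained)
    haps = np.ascontiguousarray(haps[:, retained])

    n_gen, n_per = config.n_generations, config.n_per_generation
    total = n_gen * n_per
    sire_ids = np.zeros(total, dtype=np.int64)
    dam_ids = np.zeros(total, dtype=np.int64)
    gen_label = np.repeat(np.arange(1, n_gen + 1), n_per)
    dosage = np.empty((total, need), dtype=np.int8)

    prev_haps = haps
    prev_ids = np.zeros(config.ne, dtype=np.int64)  # burn-in parents: unknown
    for g in range(n_gen):
        off_haps, sires, dams = _mate_generation(prev_haps, n_per, gmap, rng)
        rows = slice(g * n_per, (g + 1) * n_per)
        sire_ids[rows] = prev_ids[sires]
        dam_ids[rows] = prev_ids[dams]
        dosage[rows] = off_haps[0::2] + off_haps[1::2]
        prev_haps = off_haps
        prev_ids = np.arange(g * n_per + 1, (g + 1) * n_per + 1, dtype=np.int64)

    animal_ids = np.arange(1, total + 1, dtype=np.int64)
    pedigree = pd.DataFrame(
        {"animal": animal_ids, "sire": sire_ids, "dam": dam_ids, "generation": gen_label}
    )

    qtl_local, qtl_effects, tbv, y = assign_trait(
        dosage[:, qtl_pool_local],
        gen_label,
        config.n_qtl,
        config.heritability,
        rng,
        reference_generation=1,
    )

    geno_mask = np.isin(gen_label, config.genotyped_generations)
    genotyped_ids = animal_ids[geno_mask]
    genotypes = np.ascontiguousarray(dosage[np.ix_(geno_mask, snp_local)])
    phenotypes = pd.DataFrame(
        {
            "animal": animal_ids,
            "value": y,
            "generation": gen_label,
            "fixed_effect": gen_label,
        }
    )
    logger.info(
        "simulated population: ne=%d, %d pedigree records, %d genotyped, %d SNPs",
        config.ne, total, genotyped_ids.size, config.n_snp,
    )
    return SimulatedPopulation(
        config=config,
        pedigree=pedigree,
        genotyped_ids=genotyped_ids,
        genotypes=genotypes,
        snp_map=gmap.subset(snp_local),
        qtl_effects=qtl_effects,
        tbv=tbv,
        phenotypes=phenotypes,
    )


def vary_ne(config: SimConfig, ne: int, seed: int) -> SimConfig:
    """Convenience: same design at a different effective size and seed."""
    return replace(config, ne=ne, seed=seed, burn_in_generations=None if config.burn_in_generations == 4 * config.ne else config.burn_in_generations)
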