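# Methods

This note records the models, parameter choices, numerical decisions and
known limitations behind `apydim`, in the order the pipeline runs.

## Population simulator (`synthpop`)

**Model.** Discrete, non-overlapping generations; hermaphroditic random
mating; no selection, migration, mutation or sex chromosomes.  Two phases:

1. *Burn-in* at constant census size `ne` for `burn_in_generations`
   (default `4·ne`) builds drift linkage disequilibrium from
   linkage-equilibrium founders whose allele frequencies are drawn
   uniformly on (0.05, 0.95).  Burn-in mates by random union of gametes
   (selfing allowed), the idealized Wright–Fisher scheme, so census size
   equals effective size exactly and expected heterozygosity decays as
   H₀(1 − 1/2Ne)ᵗ — a relation the test suite checks against 10
   replicate runs.
2. *Expansion* produces `n_per_generation` animals per generation for
   `n_generations` generations, with distinct sire and dam drawn
   uniformly from the previous generation (a pedigree requires two
   parents).  Generation-1 parents come from the final burn-in
   generation and are recorded as unknown (id 0).

**Recombination** follows Haldane: per chromosome, crossover count ~
Poisson(map length in Morgan), positions uniform, no interference,
independent assortment across chromosomes.  Chromosomes split the total
map length equally; candidate loci are evenly spaced.

**Marker panel.** Only loci still segregating at the end of burn-in are
eligible; the panel of `n_snp` markers and a disjoint pool of QTL
candidates are drawn from them.  Loci that later fix during expansion are
retained (they carry zero information and the GRM code warns about them),
so the marker count is constant across generations.  Because most loci
fix during a 4·Ne burn-in, candidate loci are oversampled using an
empirical survival rate of ≈0.5·exp(−t/2Ne) with a 1.6× safety factor,
and fixed loci are pruned as burn-in proceeds (exact: without mutation a
fixed locus never segregates again).  A shortfall raises an error naming
the deficit rather than silently shrinking the panel.

**Trait.** `n_qtl` additive loci with standard-normal raw effects,
rescaled so var(TBV) = h² in the first expansion generation (phenotypic
variance 1, residuals N(0, 1 − h²)); y = TBV + e, single record per
animal, generation label doubling as the fixed-effect class and as the
truncation time axis.  With h² = 1 the phenotype equals the TBV.  The
trait parameters have no canonical values for this kind of benchmark;
defaults (`n_qtl` in the hundreds, h² = 0.3) are typical of moderately
heritable production traits.

**What the simulator does not emulate:** selection and the resulting
Bulmer effect, overlapping generations, genotyping error, imputation,
family structure from unequal sex ratios, varying recombination maps.
Passing tests therefore demonstrate correctness of the machinery and the
drift/LD scaling of dimensionality, not quantitative transfer of any
specific accuracy value to real breeding programs.

## Relationship matrices (`relmat`)

VanRaden GRM G₀ = ZZ′/2Σp(1−p) with observed frequencies; missing calls
are imputed with 2p before centering (they then contribute nothing).
Monomorphic markers are kept with a logged warning — they add zero to
numerator and denominator.  The pedigree NRM uses the tabular method with
inbreeding (a_jj = 1 + 0.5·a_sd), vectorized row-wise, and is checked
against an independent recursive-kinship oracle.  Blending
G = wG₀ + (1−w)A₂₂ restores positive definiteness; default w = 0.95, at
the top of the 0.90–0.95 range used in routine evaluations, keeping G
close to G₀.  All matrices are dense; the intended scale is ≤ ~10,000
genotyped animals.

## Spectrum and Ne (`dimension`)

Full symmetric eigendecomposition (LAPACK via `scipy.linalg.eigh`);
negative eigenvalues are clamped to zero for the cumulative accounting,
so total variation equals the trace for PSD input.  The count at
fraction f is the smallest k whose cumulative share reaches f, with a
1e−9 tie tolerance so exact ties are not lost to rounding.  The SVD
route on Z gives integer-identical counts (spectra differ by the scalar
2Σp(1−p)) and is cheaper when animals outnumber markers.

Ne estimation interpolates an observed count90 on simulated reference
curves in log(count)–log(Ne) coordinates — the count-vs-Ne relation is
near a power law, so piecewise-linear interpolation on log axes is
accurate with a coarse grid.  Curves are regenerated by this package (not
transcribed from elsewhere) and carry their provenance (L, sample size,
SNP count); estimates from mismatched designs get a warning attached.
Outside the grid the outer segment is extended linearly and the estimate
flagged as extrapolated.  Estimation uses the 90% threshold only: higher
thresholds are the first to be distorted when SNPs or genotyped animals
are scarce.  The 12× sufficiency rule (`snp_sufficiency_warning`) flags
counts whose 12-fold exceeds the SNP or animal number as likely
underestimates of the true dimensionality.  Genome-length rescaling uses
Ne ∝ 1/L at constant Me.

## APY inverse (`apycore`)

Stored factored (G⁻¹cc, Gcn, diag M⁻¹nn) and exposed as a linear
operator with O(n·n_core) matrix-vector products; dense assembly exists
as a test/debug path only, preserving the linear-memory property that
makes APY viable for very large populations.  Core selection is random
without replacement (seeded); explicit user-supplied core lists cover
"proven animals" strategies.  The conditional variance m_nn,i must
exceed 1e−8·g_ii — at or below that the non-core animal lies in the core
span (e.g. a clone) and an error names it.  Core animals keep their
genotype-file order; results are permutation-equivariant (tested).
`implied_grm` reconstructs the matrix the APY inverse actually inverts
(exact on core rows/columns, non-core pairs projected through the core),
which is the main convergence diagnostic.  The core subset is redrawn
independently per run with a recorded seed; no nesting across
thresholds.

## Evaluation (`evaluate`)

Animal-model MME with a class fixed-effect design (one level per
generation, no separate intercept, hence full rank).  Variance
components are inputs: λ = σe²/σu², by default derived from the
simulated h² as (1−h²)/h².  Systems with ≤5000 equations are solved
densely (symmetric solve); larger ones by conjugate gradients with a
Jacobi preconditioner to a relative residual of 1e−10 (default), which
leaves reported metrics identical to the direct path at 1e−6.
Non-convergence raises with the residual history.  Single-step mode
assembles H⁻¹ = A⁻¹ + [0,0; 0, G⁻¹ − A₂₂⁻¹] with unscaled blocks
(τ = ω = 1) over all pedigree animals; it reduces exactly to
genotyped-only GBLUP when every animal is genotyped (tested).

Validation under truncation: training records have generation ≤ cutoff;
validation animals are genotyped animals whose records all fall later.
Metrics: predictive ability (corr of GEBV with phenotypes adjusted by
full-data fixed-effect estimates), reliability R² of a realized
dependent on GEBV, inter-inverse GEBV correlation, and corr(GEBV, TBV)
in simulation.  Dairy-style daughter deviations need lactation data
structures that are out of scope; the realized dependent is instead the
simulated progeny-mean stand-in
d_i = 2·mean_o(y*_o − 0.5·TBV_mate(o)) over ≥5 phenotyped offspring,
which is unbiased for TBV_i (E[d_i] = TBV_i) but uses mate TBV and is
therefore simulation-only.

## Pipeline and reference design (`pipeline`)

`run_experiment` chains all stages, persists artifacts per stage, and
reports one row per explained-variation threshold plus a 100% row for
the regular inverse; all randomness funnels through recorded seeds and a
config hash makes reports comparable.  The repeated-records/permanent-
environment extension and richer fixed-effect models are config-level
concerns left out of the default path.

The *reference validation design* (`benchmark_design`) is a pig-sized
population: Ne = 40, 10 Morgan over 10 chromosomes, 5000 SNPs, 500 QTL,
six generations of 1000 animals with the last three genotyped
(3000 animals), h² = 0.3, truncation before the last generation.  These
sizes keep a full replicate (simulation, 3000×3000 eigendecomposition,
three GBLUP solves) around half a minute on one CPU, so multi-replicate
checks remain desk-scale.

### A known scale limitation

On the reference design the eigenvalue count at 98% variation is ≈460
for 3000 genotyped animals and 5000 SNPs — beyond the 12× sufficiency
limit (5000/12 ≈ 417), so the 98% count is itself data-limited and sits
below the point where accuracy plateaus in core size.  Consequently,
while APY-vs-regular GEBV correlations at the 98% core reach ≈0.99,
halving that core costs ≈0.02–0.04 in realized accuracy here, more than
the <0.01 observed in large populations where the 98% count is well
resolved.  This is the expected behaviour of truncated spectra at small
sample sizes, and exactly what `snp_sufficiency_warning` flags on this
design; it should be kept in mind when transferring core-halving
robustness statements to small datasets.
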