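"""End-to-end experiment orchestration and file formats.

Runs the full analysis chain — simulate a population, build the
relationship matrices, profile the GRM spectrum, invert with APY at
core sizes tied to explained-variation thresholds, evaluate GEBV with
each inverse against the regular inverse, and summarize everything in a
machine-readable report whose 100% row is the regular-inverse baseline.

Also defines the plain-text dialects shared by the command line stages:

* genotypes: header ``animal snp_1 .. snp_m``, then one row per animal
  with its id and m space-separated 0/1/2 calls (``NA`` = missing);
* pedigree CSV: ``animal,sire,dam`` (0 = unknown), birth order;
* phenotype CSV: ``animal,value,generation,fixed_effect``;
* matrices: HDF5 container with named datasets.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from . import apycore, dimension, evaluate, relmat, synthpop

logger = logging.getLogger(__name__)

__all__ = [
    "write_genotypes",
    "read_genotypes",
    "write_pedigree",
    "read_pedigree",
    "write_phenotypes",
    "read_phenotypes",
    "save_matrices",
    "load_matrices",
    "save_apy_inverse",
    "load_apy_inverse",
    "write_population",
    "ExperimentConfig",
    "ExperimentReport",
    "run_experiment",
    "plot_eigen_profile",
    "plot_report_curve",
]


# ---------------------------------------------------------------------------
# text formats
# ---------------------------------------------------------------------------


def write_genotypes(path, animal_ids, genotypes) -> None:
    g = np.asarray(genotypes)
    with open(path, "w") as fh:
        fh.write("animal " + " ".join(f"snp_{j + 1}" for j in range(g.shape[1])) + "\n")
        for a, row in zip(animal_ids, g):
            calls = " ".join("NA" if (isinstance(v, float) and np.isnan(v)) else str(int(v)) for v in row)
            fh.write(f"{int(a)} {calls}\n")


def read_genotypes(path) -> tuple[np.ndarray, np.ndarray]:
    """Returns (animal_ids, gene_content); missing calls become NaN."""
    ids: list[int] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        header = fh.readline().split()
        if not header or header[0] != "animal":
            raise ValueError(f"{path}: line 1: expected header starting with 'animal'")
        n_snp = len(header) - 1
        for lineno, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != n_snp + 1:
                raise ValueError(
                    f"{path}: line {lineno}: expected {n_snp + 1} fields, got {len(parts)}"
                )
            try:
                ids.append(int(parts[0]))
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: bad animal id {parts[0]!r}") from None
            row = np.empty(n_snp)
            for j, tok in enumerate(parts[1:]):
                if tok == "NA":
                    row[j] = np.nan
                elif tok in ("0", "1", "2"):
                    row[j] = float(tok)
                else:
                    raise ValueError(
                        f"{path}: line {lineno}: invalid genotype code {tok!r} "
                        "(expected 0, 1, 2 or NA)"
                    )
            rows.append(row)
    geno = np.vstack(rows) if rows else np.empty((0, n_snp))
    if not np.isnan(geno).any():
        geno = geno.astype(np.int8)
    return np.array(ids, dtype=np.int64), geno


def write_pedigree(path, pedigree: pd.DataFrame) -> None:
    pedigree[["animal", "sire", "dam"]].to_csv(path, index=False)


def read_pedigree(path) -> pd.DataFrame:
    ped = pd.read_csv(path)
    required = {"animal", "sire", "dam"}
    if not required.issubset(ped.columns):
        raise ValueError(f"{path}: pedigree needs columns {sorted(required)}")
    seen: set[int] = set()
    for lineno, row in enumerate(ped.itertuples(index=False), start=2):
        for parent in (row.sire, row.dam):
            if parent != 0 and int(parent) not in seen:
                raise ValueError(
                    f"{path}: line {lineno}: parent id {int(parent)} of animal "
                    f"{int(row.animal)} is nonzero but not previously listed"
                )
        seen.add(int(row.animal))
    return ped.astype({"animal": np.int64, "sire": np.int64, "dam": np.int64})


def write_phenotypes(path, phenotypes: pd.DataFrame) -> None:
    phenotypes[["animal", "value", "generation", "fixed_effect"]].to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"animal", "value", "generation", "fixed_effect"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: phenotype file needs columns {sorted(required)}")
    return df


def write_population(outdir, pop: synthpop.SimulatedPopulation) -> dict:
    """Persist a simulated population in the text dialects; returns the paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genotypes": os.path.join(outdir, "genotypes.txt"),
        "pedigree": os.path.join(outdir, "pedigree.csv"),
        "phenotypes": os.path.join(outdir, "phenotypes.csv"),
        "tbv": os.path.join(outdir, "tbv.csv"),
    }
    write_genotypes(paths["genotypes"], pop.genotyped_ids, pop.genotypes)
    write_pedigree(paths["pedigree"], pop.pedigree)
    write_phenotypes(paths["phenotypes"], pop.phenotypes)
    pd.DataFrame({"animal": pop.pedigree["animal"], "tbv": pop.tbv}).to_csv(
        paths["tbv"], index=False
    )
    return paths


# ---------------------------------------------------------------------------
# matrix container
# ---------------------------------------------------------------------------


def save_matrices(path, **named_arrays) -> None:
    with h5py.File(path, "w") as fh:
        for name, arr in named_arrays.items():
            fh.create_dataset(name, data=np.asarray(arr))


def load_matrices(path, names=None) -> dict:
    with h5py.File(path, "r") as fh:
        keys = list(fh.keys()) if names is None else list(names)
        return {k: fh[k][()] for k in keys}


def save_apy_inverse(path, apy: apycore.ApyInverse, seed=None, strategy="random") -> None:
    save_matrices(
        path,
        core_ids=apy.partition.core_ids,
        noncore_ids=apy.partition.noncore_ids,
        all_ids=apy.partition.all_ids,
        gcc_inv=apy.gcc_inv,
        gcn=apy.gcn,
        mnn_inv=apy.mnn_inv_diag,
    )
    sidecar = {
        "n_core": int(apy.partition.n_core),
        "n_total": int(apy.partition.all_ids.size),
        "seed": seed,
        "strategy": strategy,
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_apy_inverse(path) -> apycore.ApyInverse:
    d = load_matrices(path)
    part = apycore.CorePartition(d["core_ids"], d["noncore_ids"], d["all_ids"])
    t = d["gcc_inv"] @ d["gcn"]
    gcc = np.linalg.inv(d["gcc_inv"])
    return apycore.ApyInverse(
        partition=part, gcc_inv=d["gcc_inv"], gcn=d["gcn"],
        mnn_inv_diag=d["mnn_inv"], _t=t, _gcc=gcc,
    )


# ---------------------------------------------------------------------------
# experiment orchestration
# ---------------------------------------------------------------------------


@dataclass
class ExperimentConfig:
    """Configuration of one end-to-end experiment."""

    sim: synthpop.SimConfig
    blend_weight: float = relmat.DEFAULT_BLEND_WEIGHT
    thresholds: tuple[float, ...] = dimension.DEFAULT_THRESHOLDS
    core_strategy: str = "random"
    core_seed: int = 12345
    evaluation: evaluate.EvaluationConfig | None = None
    ne_grid: tuple[int, ...] | None = None
    ne_replicates: int = 1
    replicates: int = 1
    min_progeny: int = 5

    def __post_init__(self) -> None:
        if any(not 0 < t <= 1 for t in self.thresholds):
            raise ValueError("thresholds must lie in (0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.evaluation is None:
            h2 = self.sim.heritability
            lam = evaluate.EvaluationConfig.lambda_from_h2(h2) if h2 < 1 else 1e-6
            cutoff = self.sim.n_generations - 1
            self.evaluation = evaluate.EvaluationConfig(
                variance_ratio=lam, truncation_cutoff=cutoff
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        d["sim"] = synthpop.SimConfig(**{
            **d["sim"],
            "genotyped_generations": tuple(d["sim"].get("genotyped_generations") or ()),
        })
        if d.get("evaluation"):
            d["evaluation"] = evaluate.EvaluationConfig(**d["evaluation"])
        for key in ("thresholds", "ne_grid"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ExperimentReport:
    """Per-threshold APY results plus the regular-inverse baseline row."""

    rows: list[dict]
    baseline: dict
    ne_block: dict
    provenance: dict
    timestamp: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    def to_dict(self) -> dict:
        return {
            "rows": self.rows,
            "baseline": self.baseline,
            "ne": self.ne_block,
            "provenance": self.provenance,
            "timestamp": self.timestamp,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows + [self.baseline])

    def content_hash(self) -> str:
        d = self.to_dict()
        d.pop("timestamp")
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()

    def save(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=str)
        self.to_frame().to_csv(os.path.join(outdir, "report.csv"), index=False)


def _evaluation_metrics(
    result: evaluate.EvaluationResult,
    pop: synthpop.SimulatedPopulation,
    val_ids: np.ndarray,
    adj_phen: pd.Series,
    tbv: pd.Series,
    dependent: pd.Series,
    baseline: evaluate.EvaluationResult | None,
) -> dict:
    m: dict = {}
    m["predictive_ability"] = evaluate.predictive_ability(result.gebv, adj_phen, val_ids)
    m["accuracy_vs_tbv"] = evaluate.accuracy_vs_tbv(result.gebv, tbv, val_ids)
    if len(dependent) >= 3:
        parents = dependent.index.to_numpy()
        m["validation_r2"] = evaluate.validation_r2(dependent, result.gebv, parents)
    else:
        m["validation_r2"] = None
    if baseline is not None:
        m["corr_with_regular"] = evaluate.compare_inverses(baseline, result, val_ids)
    return m


def run_experiment(config: ExperimentConfig, outdir=None, curves=None) -> ExperimentReport:
    """Simulate → matrices → spectrum → APY per threshold → evaluation → report."""
    stage = "simulate"
    try:
        pop = synthpop.simulate_population(config.sim)
        if outdir is not None:
            write_population(outdir, pop)

        stage = "relationship-matrices"
        rels = relmat.build_relationships(
            pop.genotypes, pop.genotyped_ids, pop.pedigree, config.blend_weight
        )
        if outdir is not None:
            import os

            save_matrices(
                os.path.join(outdir, "matrices.h5"),
                grm_raw=rels.grm_raw,
                grm_blended=rels.grm_blended,
                nrm_genotyped=rels.nrm_genotyped,
                genotyped_ids=pop.genotyped_ids,
            )

        stage = "eigen-profile"
        profile = dimension.eigen_profile(rels.grm_raw)
        counts = profile.counts(config.thresholds)
        n_geno = pop.genotyped_ids.size
        suff = {
            t: dimension.snp_sufficiency_warning(c, config.sim.n_snp, n_geno)
            for t, c in counts.items()
        }

        stage = "evaluate-regular"
        ev = config.evaluation
        ginv_reg = apycore.regular_inverse(rels.grm_blended)
        res_reg = evaluate.gblup(pop.phenotypes, pop.genotyped_ids, ginv_reg, ev)
        cutoff = ev.truncation_cutoff
        val_ids = evaluate.validation_animals(pop.phenotypes, pop.genotyped_ids, cutoff)
        full = evaluate.gblup(
            pop.phenotypes, pop.genotyped_ids, ginv_reg,
            dataclasses.replace(ev, truncation_cutoff=None),
        )
        geno_phen = pop.phenotypes[pop.phenotypes["animal"].isin(pop.genotyped_ids)]
        adj = evaluate.adjust_phenotypes(geno_phen, full.fixed_effect_estimates)
        tbv = pd.Series(pop.tbv, index=pop.pedigree["animal"].to_numpy())
        parent_pool = pop.genotyped_ids[
            ~np.isin(pop.genotyped_ids, val_ids)
        ]  # candidate validation parents: genotyped, pre-cutoff
        dependent = evaluate.progeny_mean_dependent(
            pop.pedigree, adj, tbv, parent_pool, min_progeny=config.min_progeny
        )
        base_metrics = _evaluation_metrics(res_reg, pop, val_ids, adj, tbv, dependent, None)
        baseline_row = {
            "threshold": 1.0,
            "eigen_count": None,
            "n_core": n_geno,
            "inverse": "regular",
            **base_metrics,
        }

        stage = "apy-thresholds"
        rows = []
        core_rng = np.random.default_rng(config.core_seed)
        for t in config.thresholds:
            n_core = min(counts[t], n_geno)
            seed = int(core_rng.integers(2**31))
            part = apycore.select_core(
                pop.genotyped_ids, n_core, seed=seed, strategy=config.core_strategy
            )
            apy = apycore.apy_inverse(rels.grm_blended, part)
            res = evaluate.gblup(pop.phenotypes, pop.genotyped_ids, apy, ev)
            metrics = _evaluation_metrics(res, pop, val_ids, adj, tbv, dependent, res_reg)
            rows.append(
                {
                    "threshold": t,
                    "eigen_count": counts[t],
                    "n_core": n_core,
                    "inverse": "apy",
                    "core_seed": seed,
                    "snp_sufficiency": suff[t],
                    **metrics,
                }
            )

        stage = "ne-estimate"
        count90 = dimension.count_for_fraction(profile, 0.90)
        ne_block: dict = {"count90": count90, "genome_length": config.sim.genome_length}
        if curves is None and config.ne_grid is not None:
            curves = dimension.build_reference_curves(
                config.ne_grid, config.sim, replicates=config.ne_replicates,
                seed=config.core_seed,
            )
        if curves is not None:
            est = dimension.estimate_ne(
                count90,
                curves,
                query_design={
                    "genome_length": config.sim.genome_length,
                    "n_genotyped": n_geno,
                    "n_snp": config.sim.n_snp,
                },
            )
            ne_block.update(
                ne=est.ne,
                threshold_used=est.threshold_used,
                genome_length_assumed=est.genome_length_assumed,
                extrapolated=est.extrapolated,
            )

        report = ExperimentReport(
            rows=rows,
            baseline=baseline_row,
            ne_block=ne_block,
            provenance={
                "config_hash": config.config_hash(),
                "sim_seed": config.sim.seed,
                "core_seed": config.core_seed,
                "n_genotyped": int(n_geno),
                "n_validation": int(val_ids.size),
                "blend_weight": config.blend_weight,
                "variance_ratio": ev.variance_ratio,
                "truncation_cutoff": cutoff,
            },
        )
        if outdir is not None:
            report.save(outdir)
        return report
    except Exception as e:
        raise RuntimeError(f"experiment failed during stage '{stage}': {e}") from e


# ---------------------------------------------------------------------------
# reference validation design
# ---------------------------------------------------------------------------


def benchmark_design(seed: int = 0) -> synthpop.SimConfig:
    """The package's reference validation design.

    A pig-sized population (Ne = 40) on a 10-Morgan, 10-chromosome
    genome with 5000 SNPs and 500 QTL: six generations of 1000 animals,
    the last three genotyped (3000 animals), heritability 0.3.  Used to
    benchmark APY fidelity and core-size sensitivity at desk scale.
    """
    return synthpop.SimConfig(
        ne=40,
        genome_length=10.0,
        n_chrom=10,
        n_snp=5000,
        n_qtl=500,
        n_generations=6,
        n_per_generation=1000,
        genotyped_generations=(4, 5, 6),
        heritability=0.3,
        seed=seed,
    )


def core_size_sensitivity(
    sim_config: synthpop.SimConfig,
    blend_weight: float = relmat.DEFAULT_BLEND_WEIGHT,
    core_seed: int = 0,
) -> dict:
    """APY fidelity at the 98%-variation core size and under core halving.

    Simulates one population, blends the GRM, counts eigenvalues at 98%
    explained variation, and solves GBLUP on truncated data three ways:
    with the regular inverse, with an APY inverse whose random core size
    equals the 98% count, and with an independent random core of half
    that size.  Validation animals are the genotyped last generation,
    whose phenotypes fall after the truncation point.
    """
    pop = synthpop.simulate_population(sim_config)
    rels = relmat.build_relationships(
        pop.genotypes, pop.genotyped_ids, pop.pedigree, blend_weight
    )
    profile = dimension.eigen_profile(rels.grm_raw)
    c98 = dimension.count_for_fraction(profile, 0.98)
    cutoff = sim_config.n_generations - 1
    ev = evaluate.EvaluationConfig(
        variance_ratio=evaluate.EvaluationConfig.lambda_from_h2(sim_config.heritability),
        truncation_cutoff=cutoff,
    )
    ginv = apycore.regular_inverse(rels.grm_blended)
    res_reg = evaluate.gblup(pop.phenotypes, pop.genotyped_ids, ginv, ev)
    val = evaluate.validation_animals(pop.phenotypes, pop.genotyped_ids, cutoff)
    tbv = pd.Series(pop.tbv, index=pop.pedigree["animal"].to_numpy())

    rng = np.random.default_rng(core_seed)
    results = {}
    for label, n_core in (("core98", c98), ("core_half", max(1, c98 // 2))):
        part = apycore.select_core(
            pop.genotyped_ids, n_core, seed=int(rng.integers(2**31))
        )
        apy = apycore.apy_inverse(rels.grm_blended, part)
        results[label] = evaluate.gblup(pop.phenotypes, pop.genotyped_ids, apy, ev)

    return {
        "count90": dimension.count_for_fraction(profile, 0.90),
        "count98": c98,
        "n_genotyped": int(pop.genotyped_ids.size),
        "n_validation": int(val.size),
        "corr_apy_regular": evaluate.compare_inverses(res_reg, results["core98"], val),
        "accuracy_regular": evaluate.accuracy_vs_tbv(res_reg.gebv, tbv, val),
        "accuracy_core98": evaluate.accuracy_vs_tbv(results["core98"].gebv, tbv, val),
        "accuracy_core_half": evaluate.accuracy_vs_tbv(results["core_half"].gebv, tbv, val),
    }


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------


def plot_eigen_profile(profile: dimension.EigenProfile, path) -> None:
    """Eigenvalue count vs explained variation, log-scaled count axis."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frac = profile.cumulative_fraction
    k = np.arange(1, frac.size + 1)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(100 * frac, k)
    ax.set_yscale("log")
    ax.set_xlabel("% of explained variation")
    ax.set_ylabel("number of largest eigenvalues")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_report_curve(report: ExperimentReport, path, metric="accuracy_vs_tbv") -> None:
    """Accuracy (or another metric) vs explained-variation threshold."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = [100 * r["threshold"] for r in report.rows] + [100.0]
    ys = [r[metric] for r in report.rows] + [report.baseline[metric]]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(xs, ys, marker="o")
    ax.set_xlabel("% of explained variation (100 = regular inverse)")
    ax.set_ylabel(metric)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
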