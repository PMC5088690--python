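"""GBLUP / single-step GBLUP mixed-model equations and validation metrics.

The animal model is ``y = Xb + Wu + e`` with fixed effects ``b`` (by
default one class per generation), additive breeding values ``u`` with
``var(u) = G σu²``, and ``λ = σe²/σu²`` supplied by the user (variance
components are inputs, not estimated).  The mixed-model equations

    [X'X   X'W        ] [b]   [X'y]
    [W'X   W'W + λ G⁻¹] [u] = [W'y]

are solved directly for small systems and by Jacobi-preconditioned
conjugate gradients otherwise; ``G⁻¹`` can be a dense matrix or the
factored APY operator.  In single-step mode the genomic inverse is
replaced over all pedigree animals by

    H⁻¹ = A⁻¹ + [0 0; 0 G⁻¹ − A22⁻¹]

(unscaled, i.e. τ = ω = 1).

Validation mirrors the data-truncation design used in genomic
evaluation: GEBV from truncated records are compared with information
that only accrues later — phenotypes adjusted for fixed effects
(predictive ability), realized progeny means (reliability R²), GEBV
from a different inverse, or the simulated true breeding values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse
from scipy.sparse.linalg import LinearOperator, cg

from .apycore import ApyInverse, regular_inverse
from .relmat import build_nrm, extract_genotyped_block

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationConfig",
    "EvaluationResult",
    "ConvergenceError",
    "truncate_records",
    "validation_animals",
    "solve_mme",
    "gblup",
    "single_step_gblup",
    "adjust_phenotypes",
    "progeny_mean_dependent",
    "predictive_ability",
    "validation_r2",
    "compare_inverses",
    "accuracy_vs_tbv",
]

DIRECT_SOLVE_MAX_EQUATIONS = 5000


class ConvergenceError(RuntimeError):
    def __init__(self, msg: str, residual_history=None):
        super().__init__(msg)
        self.residual_history = residual_history or []


@dataclass
class EvaluationConfig:
    """Solver and model settings for one evaluation run."""

    mode: str = "gblup"  # "gblup" (genotyped-only) or "single-step"
    variance_ratio: float = 7.0 / 3.0  # λ = σe²/σu²; default matches h² = 0.3
    truncation_cutoff: int | None = None
    solver: str = "auto"  # "auto" | "direct" | "cg"
    tolerance: float = 1e-10
    max_iterations: int = 5000

    def __post_init__(self) -> None:
        if self.variance_ratio <= 0:
            raise ValueError("variance ratio λ must be positive")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.mode not in ("gblup", "single-step"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.solver not in ("auto", "direct", "cg"):
            raise ValueError(f"unknown solver {self.solver!r}")

    @staticmethod
    def lambda_from_h2(h2: float) -> float:
        if not 0 < h2 < 1:
            raise ValueError("h² must be in (0, 1) to derive a variance ratio")
        return (1.0 - h2) / h2


@dataclass
class EvaluationResult:
    gebv: pd.Series  # indexed by animal id
    fixed_effect_estimates: dict
    converged: bool
    n_iterations: int = 0
    metrics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# data truncation
# ---------------------------------------------------------------------------


def truncate_records(phenotypes: pd.DataFrame, cutoff) -> pd.DataFrame:
    """Keep records whose generation/time label is <= cutoff."""
    out = phenotypes[phenotypes["generation"] <= cutoff]
    if out.empty:
        raise ValueError(f"truncation at {cutoff} removes every record")
    return out


def validation_animals(
    phenotypes: pd.DataFrame, genotyped_ids: np.ndarray, cutoff
) -> np.ndarray:
    """Genotyped animals whose records all fall after the cutoff."""
    by_animal = phenotypes.groupby("animal")["generation"].min()
    late = by_animal[by_animal > cutoff].index.to_numpy()
    ids = np.asarray(genotyped_ids)
    val = ids[np.isin(ids, late)]
    if val.size == 0:
        warnings.warn("validation set is empty after truncation", stacklevel=2)
    return val


# ---------------------------------------------------------------------------
# mixed-model equations
# ---------------------------------------------------------------------------


class _GinvOperator:
    """Uniform wrapper for a dense G-inverse or the factored APY inverse."""

    def __init__(self, ginv, n: int):
        self.n = n
        self._ginv = ginv
        if isinstance(ginv, ApyInverse):
            if ginv.n != n:
                raise ValueError("APY inverse size does not match the animal set")
        else:
            self._ginv = np.asarray(ginv, dtype=float)
            if self._ginv.shape != (n, n):
                raise ValueError("G-inverse shape does not match the animal set")

    def matvec(self, v):
        if isinstance(self._ginv, ApyInverse):
            return self._ginv.matvec(v)
        return self._ginv @ v

    def diagonal(self):
        if isinstance(self._ginv, ApyInverse):
            return self._ginv.diagonal()
        return np.diag(self._ginv)

    def dense(self):
        if isinstance(self._ginv, ApyInverse):
            return self._ginv.dense()
        return self._ginv


def solve_mme(
    y: np.ndarray,
    X: np.ndarray,
    record_animal: np.ndarray,
    ginv,
    n_animals: int,
    variance_ratio: float,
    solver: str = "auto",
    tolerance: float = 1e-10,
    max_iterations: int = 5000,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Solve the animal-model MME.

    ``record_animal`` maps each record to a 0-based animal position;
    animals without records still receive breeding values through the
    relationship structure.  Returns ``(b, u, info)``.
    """
    if variance_ratio <= 0:
        raise ValueError("variance ratio λ must be positive")
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    rec = np.asarray(record_animal, dtype=np.int64)
    n_rec, n_fix = X.shape
    if y.size != n_rec or rec.size != n_rec:
        raise ValueError("y, X and record_animal must agree in record count")
    gop = _GinvOperator(ginv, n_animals)
    W = scipy.sparse.csr_matrix(
        (np.ones(n_rec), (np.arange(n_rec), rec)), shape=(n_rec, n_animals)
    )
    xtx = X.T @ X
    xtw = X.T @ W
    wtw_diag = np.asarray(W.sum(axis=0)).ravel()  # W'W is diagonal (0/1 incidence)
    rhs = np.concatenate([X.T @ y, W.T @ y])
    n_eq = n_fix + n_animals

    use_direct = solver == "direct" or (solver == "auto" and n_eq <= DIRECT_SOLVE_MAX_EQUATIONS)
    if use_direct:
        lhs = np.zeros((n_eq, n_eq))
        lhs[:n_fix, :n_fix] = xtx
        lhs[:n_fix, n_fix:] = xtw.toarray() if scipy.sparse.issparse(xtw) else xtw
        lhs[n_fix:, :n_fix] = lhs[:n_fix, n_fix:].T
        lhs[n_fix:, n_fix:] = variance_ratio * gop.dense()
        lhs[n_fix:, n_fix:][np.diag_indices(n_animals)] += wtw_diag
        sol = scipy.linalg.solve(lhs, rhs, assume_a="sym")
        info = {"solver": "direct", "n_iterations": 0, "converged": True}
    else:
        xtw_d = np.asarray(xtw.todense()) if scipy.sparse.issparse(xtw) else xtw

        def mv(v):
            b, u = v[:n_fix], v[n_fix:]
            top = xtx @ b + xtw_d @ u
            bottom = xtw_d.T @ b + wtw_diag * u + variance_ratio * gop.matvec(u)
            return np.concatenate([top, bottom])

        diag = np.concatenate(
            [np.maximum(np.diag(xtx), 1e-12), wtw_diag + variance_ratio * gop.diagonal()]
        )
        op = LinearOperator((n_eq, n_eq), matvec=mv)
        precond = LinearOperator((n_eq, n_eq), matvec=lambda v: v / diag)
        history: list[float] = []

        def callback(xk):
            history.append(float(np.linalg.norm(rhs - mv(xk))))

        sol, flag = cg(
            op, rhs, rtol=tolerance, atol=0.0, maxiter=max_iterations, M=precond,
            callback=callback,
        )
        if flag != 0:
            raise ConvergenceError(
                f"conjugate gradient did not converge in {max_iterations} iterations "
                f"(last residual {history[-1] if history else float('nan'):.3e})",
                history,
            )
        info = {"solver": "cg", "n_iterations": len(history), "converged": True}
    return sol[:n_fix], sol[n_fix:], info


def _design_from_records(records: pd.DataFrame) -> tuple[np.ndarray, list]:
    """One-hot fixed-effect design (class model, no separate intercept)."""
    levels = sorted(records["fixed_effect"].unique())
    lut = {lv: k for k, lv in enumerate(levels)}
    X = np.zeros((len(records), len(levels)))
    X[np.arange(len(records)), records["fixed_effect"].map(lut).to_numpy()] = 1.0
    return X, levels


def gblup(
    phenotypes: pd.DataFrame,
    genotyped_ids: np.ndarray,
    ginv,
    config: EvaluationConfig,
) -> EvaluationResult:
    """Genotyped-animals-only GBLUP on (optionally truncated) records."""
    ids = np.asarray(genotyped_ids)
    recs = phenotypes
    if config.truncation_cutoff is not None:
        recs = truncate_records(recs, config.truncation_cutoff)
    recs = recs[recs["animal"].isin(ids)]
    if recs.empty:
        raise ValueError("no phenotype records remain for genotyped animals")
    pos = {int(a): k for k, a in enumerate(ids)}
    rec_animal = recs["animal"].map(pos).to_numpy(dtype=np.int64)
    X, levels = _design_from_records(recs)
    b, u, info = solve_mme(
        recs["value"].to_numpy(),
        X,
        rec_animal,
        ginv,
        ids.size,
        config.variance_ratio,
        solver=config.solver,
        tolerance=config.tolerance,
        max_iterations=config.max_iterations,
    )
    return EvaluationResult(
        gebv=pd.Series(u, index=ids),
        fixed_effect_estimates=dict(zip(levels, b)),
        converged=info["converged"],
        n_iterations=info["n_iterations"],
    )


def single_step_gblup(
    phenotypes: pd.DataFrame,
    pedigree: pd.DataFrame,
    genotyped_ids: np.ndarray,
    ginv,
    config: EvaluationConfig,
    nrm: np.ndarray | None = None,
) -> EvaluationResult:
    """Single-step GBLUP over all pedigree animals.

    ``H⁻¹ = A⁻¹ + [0 0; 0 G⁻¹ − A22⁻¹]`` with unscaled blocks; intended
    for moderate pedigrees (dense A handling).
    """
    if nrm is None:
        a, ped_ids = build_nrm(pedigree)
    else:
        a, ped_ids = nrm, pedigree["animal"].to_numpy()
    a22 = extract_genotyped_block(a, genotyped_ids, ped_ids)
    hinv = regular_inverse(a)
    gpos = {int(x): k for k, x in enumerate(ped_ids)}
    gidx = np.array([gpos[int(x)] for x in genotyped_ids])
    gdense = _GinvOperator(ginv, len(genotyped_ids)).dense()
    hinv[np.ix_(gidx, gidx)] += gdense - regular_inverse(a22)

    recs = phenotypes
    if config.truncation_cutoff is not None:
        recs = truncate_records(recs, config.truncation_cutoff)
    recs = recs[recs["animal"].isin(ped_ids)]
    rec_animal = recs["animal"].map(gpos).to_numpy(dtype=np.int64)
    X, levels = _design_from_records(recs)
    b, u, info = solve_mme(
        recs["value"].to_numpy(),
        X,
        rec_animal,
        hinv,
        len(ped_ids),
        config.variance_ratio,
        solver=config.solver,
        tolerance=config.tolerance,
        max_iterations=config.max_iterations,
    )
    return EvaluationResult(
        gebv=pd.Series(u, index=ped_ids),
        fixed_effect_estimates=dict(zip(levels, b)),
        converged=info["converged"],
        n_iterations=info["n_iterations"],
    )


# ---------------------------------------------------------------------------
# validation metrics
# ---------------------------------------------------------------------------


def adjust_phenotypes(
    phenotypes: pd.DataFrame, fixed_effect_estimates: dict
) -> pd.Series:
    """y minus the fixed-effect estimate of each record's class.

    The estimates should come from a full-data model so validation
    records (whose classes were absent from the truncated solve) can be
    adjusted.
    """
    est = phenotypes["fixed_effect"].map(fixed_effect_estimates)
    if est.isna().any():
        missing = phenotypes.loc[est.isna(), "fixed_effect"].unique()
        raise ValueError(f"no fixed-effect estimate for classes {list(missing)}")
    adj = phenotypes["value"] - est
    adj.index = phenotypes["animal"].to_numpy()
    return adj


def progeny_mean_dependent(
    pedigree: pd.DataFrame,
    adjusted_phenotypes: pd.Series,
    tbv: pd.Series,
    parent_ids: np.ndarray,
    min_progeny: int = 5,
) -> pd.Series:
    """Realized progeny-mean stand-in for daughter deviations.

    For parent i with offspring o mated to known partners,
    ``d_i = 2 · mean_o( yadj_o − 0.5 · TBV_mate(o) )``: the adjusted
    offspring record minus the mate's transmitted value, doubled back to
    the breeding-value scale, so E[d_i] = TBV_i.  Mate TBV are known in
    simulation only, which is the intended use.  Parents with fewer than
    ``min_progeny`` phenotyped offspring are omitted.
    """
    parents = set(int(p) for p in parent_ids)
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for _, row in pedigree.iterrows():
        o = int(row["animal"])
        if o not in adjusted_phenotypes.index:
            continue
        for p, mate in ((int(row["sire"]), int(row["dam"])), (int(row["dam"]), int(row["sire"]))):
            if p in parents and mate in tbv.index:
                dev = adjusted_phenotypes[o] - 0.5 * tbv[mate]
                sums[p] = sums.get(p, 0.0) + dev
                counts[p] = counts.get(p, 0) + 1
    keep = {p: 2.0 * sums[p] / counts[p] for p in sums if counts[p] >= min_progeny}
    return pd.Series(keep, dtype=float)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 3:
        raise ValueError(f"need at least 3 validation animals, got {a.size}")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined: a vector has zero variance")
    return float(np.corrcoef(a, b)[0, 1])


def _aligned(series_a: pd.Series, series_b: pd.Series, ids) -> tuple[np.ndarray, np.ndarray]:
    ids = np.asarray(ids)
    for s in (series_a, series_b):
        missing = ids[~np.isin(ids, s.index)]
        if missing.size:
            raise ValueError(f"ids missing from inputs: {missing[:5].tolist()} ...")
    return series_a.loc[ids].to_numpy(), series_b.loc[ids].to_numpy()


def predictive_ability(
    gebv: pd.Series, adjusted_phenotypes: pd.Series, validation_ids
) -> float:
    """corr(GEBV from truncated data, adjusted phenotype) over validation animals."""
    a, b = _aligned(gebv, adjusted_phenotypes, validation_ids)
    return _pearson(a, b)


def validation_r2(
    realized_dependent: pd.Series, gebv: pd.Series, validation_ids
) -> float:
    """R² of the regression of a realized dependent variable on GEBV."""
    d, g = _aligned(realized_dependent, gebv, validation_ids)
    return _pearson(d, g) ** 2


def compare_inverses(
    result_regular: EvaluationResult, result_apy: EvaluationResult, validation_ids
) -> float:
    """corr(GEBV_regular, GEBV_APY) over validation animals."""
    a, b = _aligned(result_regular.gebv, result_apy.gebv, validation_ids)
    return _pearson(a, b)


def accuracy_vs_tbv(gebv: pd.Series, tbv: pd.Series, validation_ids) -> float:
    """corr(GEBV, simulated true breeding value) over validation animals."""
    a, b = _aligned(gebv, tbv, validation_ids)
    return _pearson(a, b)
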