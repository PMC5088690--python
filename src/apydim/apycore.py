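"""APY inverse of the genomic relationship matrix.

The Algorithm for Proven and Young writes breeding values of "non-core"
animals as linear functions of a small "core" subset, which makes the
approximated GRM inverse

    G_apy^-1 = [[Gcc^-1, 0], [0, 0]]
             + [-Gcc^-1 Gcn; I] Mnn^-1 [-Gnc Gcc^-1, I],

    Mnn = diag{ m_nn,i } = diag{ g_ii - g_ic Gcc^-1 g_ci },

sparse and cheap: cubic cost only in the core size, linear in the
number of non-core animals.  The inverse is kept in factored form
(Gcc^-1, Gcn, diag Mnn^-1) and exposed as a linear operator; dense
assembly exists as a test/debug path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

logger = logging.getLogger(__name__)

__all__ = [
    "CorePartition",
    "ApyInverse",
    "select_core",
    "apy_inverse",
    "implied_grm",
    "regular_inverse",
]

MNN_RELATIVE_TOL = 1e-8


@dataclass(frozen=True)
class CorePartition:
    """Ordered split of the genotyped animals into core and non-core."""

    core_ids: np.ndarray
    noncore_ids: np.ndarray
    all_ids: np.ndarray

    def __post_init__(self) -> None:
        core = np.asarray(self.core_ids)
        non = np.asarray(self.noncore_ids)
        if core.size == 0:
            raise ValueError("core subset must be non-empty")
        if np.intersect1d(core, non).size:
            raise ValueError("core and non-core overlap")
        if not np.array_equal(np.sort(np.concatenate([core, non])), np.sort(self.all_ids)):
            raise ValueError("core ∪ non-core must equal the genotyped set")

    @property
    def n_core(self) -> int:
        return int(np.asarray(self.core_ids).size)

    def indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Positions of core and non-core animals within ``all_ids``."""
        pos = {int(a): k for k, a in enumerate(self.all_ids)}
        c = np.array([pos[int(a)] for a in self.core_ids], dtype=np.int64)
        n = np.array([pos[int(a)] for a in self.noncore_ids], dtype=np.int64)
        return c, n


def select_core(
    genotyped_ids: np.ndarray,
    n_core: int,
    seed: int = 0,
    strategy: str = "random",
    core_ids: np.ndarray | None = None,
) -> CorePartition:
    """Choose the core subset.

    ``strategy="random"`` samples uniformly without replacement (seeded,
    deterministic); ``strategy="given"`` takes an explicit id list, for
    user-defined choices such as proven sires plus dams.  Animals keep
    their genotype-file order within both blocks.
    """
    ids = np.asarray(genotyped_ids)
    if strategy == "random":
        if not 1 <= n_core <= ids.size:
            raise ValueError(f"n_core must be in 1..{ids.size}, got {n_core}")
        rng = np.random.default_rng(seed)
        chosen = np.sort(rng.choice(ids.size, size=n_core, replace=False))
        mask = np.zeros(ids.size, dtype=bool)
        mask[chosen] = True
    elif strategy == "given":
        if core_ids is None or len(core_ids) == 0:
            raise ValueError("strategy 'given' requires a non-empty core_ids list")
        mask = np.isin(ids, np.asarray(core_ids))
        if mask.sum() != len(set(int(i) for i in core_ids)):
            raise ValueError("core_ids contains animals outside the genotyped set")
    else:
        raise ValueError(f"unknown core selection strategy: {strategy!r}")
    return CorePartition(core_ids=ids[mask], noncore_ids=ids[~mask], all_ids=ids)


@dataclass
class ApyInverse:
    """Factored APY inverse of a blended GRM.

    Stores ``Gcc^-1``, ``Gcn`` and the diagonal of ``Mnn^-1``; provides
    a matrix-vector product in the original animal order and, for tests
    and small problems, dense assembly.
    """

    partition: CorePartition
    gcc_inv: np.ndarray
    gcn: np.ndarray  # core × non-core block of G
    mnn_inv_diag: np.ndarray
    _t: np.ndarray = field(repr=False)  # T = Gcc^-1 Gcn, cached
    _gcc: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return self.partition.all_ids.size

    @property
    def core_ids(self) -> np.ndarray:
        return self.partition.core_ids

    def matvec(self, v: np.ndarray) -> np.ndarray:
        """G_apy^-1 @ v, in original genotype order, O(n·n_core)."""
        v = np.asarray(v, dtype=float)
        c, nn = self.partition.indices()
        vc, vn = v[c], v[nn]
        w = self.mnn_inv_diag * (vn - self._t.T @ vc)
        out = np.empty_like(v)
        out[c] = self.gcc_inv @ vc - self._t @ w
        out[nn] = w
        return out

    def diagonal(self) -> np.ndarray:
        """Diagonal of the assembled inverse, without dense assembly."""
        c, nn = self.partition.indices()
        d = np.empty(self.n)
        d[c] = np.diag(self.gcc_inv) + (self._t**2 * self.mnn_inv_diag).sum(axis=1)
        d[nn] = self.mnn_inv_diag
        return d

    def dense(self) -> np.ndarray:
        """Assemble the full APY inverse (test/debug path)."""
        c, nn = self.partition.indices()
        k, m = c.size, nn.size
        inv = np.zeros((self.n, self.n))
        p = np.zeros((self.n, m))
        p[c] = -self._t
        p[nn] = np.eye(m)
        inv[np.ix_(c, c)] = self.gcc_inv
        inv += (p * self.mnn_inv_diag) @ p.T
        return (inv + inv.T) / 2.0


def apy_inverse(grm_blended: np.ndarray, partition: CorePartition) -> ApyInverse:
    """Factored APY inverse of G for the given core/non-core partition.

    Requires a positive-definite core block and strictly positive
    conditional variances ``m_nn,i = g_ii - g_ic Gcc^-1 g_ci``; an
    ``m_nn,i`` at or below ``1e-8 × g_ii`` signals a non-core animal in
    the linear span of the core (e.g. a clone of a core animal).
    """
    g = np.asarray(grm_blended, dtype=float)
    c, nn = partition.indices()
    gcc = g[np.ix_(c, c)]
    gcn = g[np.ix_(c, nn)]
    try:
        cho = scipy.linalg.cho_factor(gcc, lower=True)
    except scipy.linalg.LinAlgError as e:
        raise ValueError(f"core block Gcc is not positive definite: {e}") from None
    gcc_inv = scipy.linalg.cho_solve(cho, np.eye(c.size))
    gcc_inv = (gcc_inv + gcc_inv.T) / 2.0
    t = scipy.linalg.cho_solve(cho, gcn) if nn.size else np.empty((c.size, 0))
    gnn_diag = np.diag(g)[nn]
    mnn = gnn_diag - np.einsum("ij,ij->j", gcn, t) if nn.size else np.empty(0)
    bad = np.flatnonzero(mnn <= MNN_RELATIVE_TOL * gnn_diag)
    if bad.size:
        animal = partition.noncore_ids[bad[0]]
        raise ValueError(
            f"non-core animal {animal} has conditional variance m_nn={mnn[bad[0]]:.3e} "
            "within the core span (near-duplicate/clone); choose a different core"
        )
    logger.debug("APY inverse: n=%d, n_core=%d", len(partition.all_ids), c.size)
    return ApyInverse(
        partition=partition,
        gcc_inv=gcc_inv,
        gcn=gcn,
        mnn_inv_diag=1.0 / mnn if nn.size else mnn,
        _t=t,
        _gcc=gcc,
    )


def implied_grm(apy: ApyInverse) -> np.ndarray:
    """The GRM the APY inverse actually inverts.

    ``G~ = [[Gcc, Gcn], [Gnc, Gnc Gcc^-1 Gcn + Mnn]]`` in the original
    animal order: identical to G on the core-core, core-noncore blocks,
    while non-core/non-core elements are replaced by their projection
    through the core (plus Mnn on the diagonal).
    """
    c, nn = apy.partition.indices()
    n = apy.n
    out = np.zeros((n, n))
    out[np.ix_(c, c)] = apy._gcc
    out[np.ix_(c, nn)] = apy.gcn
    out[np.ix_(nn, c)] = apy.gcn.T
    if nn.size:
        gnn = apy.gcn.T @ apy._t
        gnn[np.diag_indices_from(gnn)] += 1.0 / apy.mnn_inv_diag
        out[np.ix_(nn, nn)] = gnn
    return (out + out.T) / 2.0


def regular_inverse(grm_blended: np.ndarray) -> np.ndarray:
    """Dense inverse of G via Cholesky factorization."""
    g = np.asarray(grm_blended, dtype=float)
    try:
        cho = scipy.linalg.cho_factor(g, lower=True)
    except scipy.linalg.LinAlgError:
        raise ValueError(
            "matrix is not positive definite; blend the raw GRM with A22 "
            "(w < 1) before inverting"
        ) from None
    inv = scipy.linalg.cho_solve(cho, np.eye(g.shape[0]))
    return (inv + inv.T) / 2.0
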