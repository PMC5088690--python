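"""Genomic and pedigree relationship matrices.

Implements VanRaden's first GRM, ``G0 = ZZ' / 2 Σ p_j (1 - p_j)`` with
``Z`` the gene-content matrix centered at twice the allele frequency,
the numerator relationship matrix ``A`` by the tabular method (with
inbreeding), its genotyped principal submatrix ``A22``, and the blended,
positive-definite ``G = w G0 + (1 - w) A22``.

Missing genotype calls (NaN) are imputed with the column mean ``2 p_j``
before centering, so they contribute nothing to relationships.
Monomorphic markers are retained with a warning: they contribute zero to
both numerator and denominator of ``G0``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "observed_allele_frequencies",
    "impute_missing",
    "center_gene_content",
    "build_grm",
    "build_nrm",
    "extract_genotyped_block",
    "blend_grm",
    "RelationshipSet",
    "build_relationships",
]

DEFAULT_BLEND_WEIGHT = 0.95


def observed_allele_frequencies(gene_content: np.ndarray) -> np.ndarray:
    """Per-marker allele frequency p_j from observed 0/1/2 gene contents.

    ``p_j = (sum of non-missing gene contents at j) / (2 × non-missing count)``.
    Missing calls are NaN.  A marker with no non-missing call is an error.
    """
    m = np.asarray(gene_content, dtype=float)
    if m.ndim != 2:
        raise ValueError("gene_content must be 2-D (animals × markers)")
    n_obs = np.sum(~np.isnan(m), axis=0)
    if np.any(n_obs == 0):
        bad = int(np.flatnonzero(n_obs == 0)[0])
        raise ValueError(f"marker {bad} has no non-missing calls")
    return np.nansum(m, axis=0) / (2.0 * n_obs)


def impute_missing(gene_content: np.ndarray, allele_freq: np.ndarray) -> np.ndarray:
    """Replace missing calls with their expectation 2 p_j."""
    m = np.array(gene_content, dtype=float)
    miss = np.isnan(m)
    if miss.any():
        m[miss] = np.broadcast_to(2.0 * allele_freq, m.shape)[miss]
    return m


def center_gene_content(gene_content: np.ndarray, allele_freq: np.ndarray) -> np.ndarray:
    """Z = M - 2 p_j, after mean imputation of missing calls."""
    p = np.asarray(allele_freq, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    m = impute_missing(gene_content, p)
    if m.shape[1] != p.size:
        raise ValueError("allele_freq not aligned to gene_content columns")
    return m - 2.0 * p


def build_grm(gene_content: np.ndarray, allele_freq: np.ndarray) -> np.ndarray:
    """VanRaden GRM: G0 = ZZ' / 2 Σ p_j (1 - p_j)."""
    p = np.asarray(allele_freq, dtype=float)
    z = center_gene_content(gene_content, p)
    mono = (p == 0.0) | (p == 1.0)
    if mono.any():
        logger.warning(
            "%d monomorphic markers contribute nothing to the GRM", int(mono.sum())
        )
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom == 0.0:
        raise ValueError("all markers are monomorphic: GRM denominator 2Σp(1-p) is zero")
    g0 = (z @ z.T) / denom
    return (g0 + g0.T) / 2.0  # enforce exact symmetry


def _pedigree_arrays(pedigree) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(pedigree, pd.DataFrame):
        a = pedigree["animal"].to_numpy(dtype=np.int64)
        s = pedigree["sire"].to_numpy(dtype=np.int64)
        d = pedigree["dam"].to_numpy(dtype=np.int64)
    else:
        arr = np.asarray(pedigree, dtype=np.int64)
        a, s, d = arr[:, 0], arr[:, 1], arr[:, 2]
    return a, s, d


def build_nrm(pedigree) -> tuple[np.ndarray, np.ndarray]:
    """Numerator relationship matrix by the tabular method, with inbreeding.

    ``pedigree`` is a DataFrame with columns animal/sire/dam (or an
    (n, 3) integer array), rows in birth order, 0 = unknown parent.
    Returns ``(A, animal_ids)``.

    For animal j (later-born) with parents s, d:
    ``a_ij = 0.5 (a_is + a_id)`` and ``a_jj = 1 + 0.5 a_sd``.
    """
    animals, sires, dams = _pedigree_arrays(pedigree)
    n = animals.size
    index = {0: -1}
    for k, a in enumerate(animals):
        if a in index:
            raise ValueError(f"duplicate animal id {a} in pedigree")
        index[int(a)] = k
    sidx = np.empty(n, dtype=np.int64)
    didx = np.empty(n, dtype=np.int64)
    for k in range(n):
        for parent, out in ((sires[k], sidx), (dams[k], didx)):
            if int(parent) not in index:
                raise ValueError(
                    f"parent {parent} of animal {animals[k]} not previously listed"
                )
            j = index[int(parent)]
            if j >= k:
                raise ValueError(
                    f"pedigree not in birth order (cycle?): parent {parent} "
                    f"does not precede animal {animals[k]}"
                )
            out[k] = j

    A = np.zeros((n, n))
    for j in range(n):
        s, d = sidx[j], didx[j]
        row = np.zeros(j)
        if s >= 0:
            row += A[:j, s]
        if d >= 0:
            row += A[:j, d]
        A[:j, j] = A[j, :j] = 0.5 * row
        A[j, j] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return A, animals


def extract_genotyped_block(
    nrm: np.ndarray, genotyped_ids: np.ndarray, pedigree_ids: np.ndarray | None = None
) -> np.ndarray:
    """Principal submatrix A22 of ``nrm`` in ``genotyped_ids`` order.

    ``pedigree_ids`` gives the id labelling of the rows of ``nrm``;
    by default rows are labelled 1..n.
    """
    nrm = np.asarray(nrm)
    if pedigree_ids is None:
        pedigree_ids = np.arange(1, nrm.shape[0] + 1)
    index = {int(a): k for k, a in enumerate(pedigree_ids)}
    try:
        pos = np.array([index[int(g)] for g in genotyped_ids])
    except KeyError as e:
        raise ValueError(f"genotyped id {e.args[0]} not in pedigree") from None
    return nrm[np.ix_(pos, pos)]


def blend_grm(
    grm_raw: np.ndarray, nrm_genotyped: np.ndarray, blend_weight: float = DEFAULT_BLEND_WEIGHT
) -> np.ndarray:
    """G = w G0 + (1 - w) A22 — restores positive definiteness for w < 1."""
    if not 0.0 <= blend_weight <= 1.0:
        raise ValueError("blend_weight must be in [0, 1]")
    g0 = np.asarray(grm_raw, dtype=float)
    a22 = np.asarray(nrm_genotyped, dtype=float)
    if g0.shape != a22.shape:
        raise ValueError(f"shape mismatch: G0 {g0.shape} vs A22 {a22.shape}")
    g = blend_weight * g0 + (1.0 - blend_weight) * a22
    return (g + g.T) / 2.0


@dataclass
class RelationshipSet:
    """All relationship matrices for one genotyped population."""

    allele_freq: np.ndarray
    grm_raw: np.ndarray
    nrm: np.ndarray
    nrm_ids: np.ndarray
    nrm_genotyped: np.ndarray
    blend_weight: float
    grm_blended: np.ndarray


def build_relationships(
    gene_content: np.ndarray,
    genotyped_ids: np.ndarray,
    pedigree,
    blend_weight: float = DEFAULT_BLEND_WEIGHT,
) -> RelationshipSet:
    """Observed frequencies → G0; pedigree → A, A22; blend → G."""
    p = observed_allele_frequencies(gene_content)
    g0 = build_grm(gene_content, p)
    a, ids = build_nrm(pedigree)
    a22 = extract_genotyped_block(a, genotyped_ids, ids)
    g = blend_grm(g0, a22, blend_weight)
    return RelationshipSet(
        allele_freq=p,
        grm_raw=g0,
        nrm=a,
        nrm_ids=ids,
        nrm_genotyped=a22,
        blend_weight=blend_weight,
        grm_blended=g,
    )
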