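"""Dimensionality of genomic information.

The number of largest eigenvalues of the raw GRM that explain a given
fraction of its variation is a proxy for the number of independent
chromosome segments (Me) segregating in a population, and therefore for
the product of effective population size (Ne) and genome length.  This
module profiles GRM spectra, counts eigenvalues at explained-variation
thresholds, estimates Ne by interpolating an observed count against
simulated reference curves, rescales Ne between genome-length
assumptions (Ne ~ 1/L at constant Me), and flags designs whose SNP or
animal numbers are too small for the counts to be trusted.

Because ``ZZ'`` and ``Z'Z`` share nonzero eigenvalues, a singular value
decomposition of the centered gene-content matrix ``Z`` gives threshold
counts identical to an eigendecomposition of ``G0`` (the spectra differ
only by the scalar ``2Σp(1-p)``); both routes are provided.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import scipy.linalg

from .relmat import build_grm, observed_allele_frequencies
from .synthpop import SimConfig, simulate_population, vary_ne

logger = logging.getLogger(__name__)

__all__ = [
    "EigenProfile",
    "ReferenceCurves",
    "NeEstimate",
    "eigen_profile",
    "count_for_fraction",
    "svd_counts",
    "build_reference_curves",
    "estimate_ne",
    "adjust_ne_for_genome_length",
    "snp_sufficiency_warning",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = (0.90, 0.95, 0.98, 0.99)

# slack when locating the smallest k with cumulative fraction >= f, so
# that exact ties (e.g. equal eigenvalues) are not missed to rounding
_TIE_EPS = 1e-9


@dataclass
class EigenProfile:
    """Descending spectrum of a GRM with cumulative explained variation.

    Negative eigenvalues (numerical, or from an indefinite raw GRM) are
    clamped to zero for the cumulative accounting, so ``total_variation``
    equals the trace for PSD input.
    """

    eigenvalues: np.ndarray
    total_variation: float
    cumulative_fraction: np.ndarray

    def counts(self, thresholds=DEFAULT_THRESHOLDS) -> dict[float, int]:
        return {t: count_for_fraction(self, t) for t in thresholds}


def _profile_from_spectrum(values: np.ndarray) -> EigenProfile:
    values = np.sort(values)[::-1]
    clamped = np.maximum(values, 0.0)
    total = float(clamped.sum())
    if total <= 0.0:
        raise ValueError("degenerate spectrum: no positive eigenvalues")
    cum = np.cumsum(clamped) / total
    cum[-1] = 1.0
    return EigenProfile(values, total, cum)


def eigen_profile(grm_raw: np.ndarray, symmetry_tol: float = 1e-8) -> EigenProfile:
    """Full symmetric eigendecomposition of the raw GRM."""
    g = np.asarray(grm_raw, dtype=float)
    if g.ndim != 2 or g.shape[0] != g.shape[1]:
        raise ValueError("GRM must be square")
    if not np.allclose(g, g.T, atol=symmetry_tol, rtol=0.0):
        raise ValueError("matrix is not symmetric within tolerance")
    values = scipy.linalg.eigh(g, eigvals_only=True)
    return _profile_from_spectrum(values)


def count_for_fraction(profile: EigenProfile, fraction: float) -> int:
    """Smallest k such that the top-k eigenvalues explain ``fraction``."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    k = int(np.searchsorted(profile.cumulative_fraction, fraction - _TIE_EPS, side="left"))
    return k + 1


def svd_counts(centered: np.ndarray) -> EigenProfile:
    """Spectrum profile from the SVD of Z (squared singular values).

    Threshold counts agree exactly with ``eigen_profile(build_grm(...))``
    since the GRM spectrum is the squared singular values divided by the
    constant 2Σp(1-p), which cancels in the cumulative fractions.
    """
    z = np.asarray(centered, dtype=float)
    if not np.any(z):
        raise ValueError("centered matrix is identically zero: degenerate profile")
    s = scipy.linalg.svd(z, compute_uv=False)
    return _profile_from_spectrum(s**2)


# ---------------------------------------------------------------------------
# Ne estimation against simulated reference curves
# ---------------------------------------------------------------------------


@dataclass
class ReferenceCurves:
    """count90-vs-Ne reference built from simulated populations."""

    ne: np.ndarray  # sorted grid
    count90: np.ndarray  # mean count at the 90% threshold per grid point
    threshold: float
    genome_length: float
    n_genotyped: int
    n_snp: int
    replicates: int
    per_replicate: list[list[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ne = np.asarray(self.ne, dtype=float)
        self.count90 = np.asarray(self.count90, dtype=float)
        if self.ne.size < 2:
            raise ValueError("reference curves need at least 2 grid points")
        if np.any(np.diff(self.ne) <= 0):
            raise ValueError("ne grid must be strictly increasing")
        if np.any(np.diff(self.count90) <= 0):
            raise ValueError("reference counts must increase strictly with ne")


@dataclass
class NeEstimate:
    ne: float
    threshold_used: float
    genome_length_assumed: float
    extrapolated: bool = False
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ne <= 0:
            raise ValueError("Ne estimate must be positive")


def build_reference_curves(
    ne_grid,
    sim_config_template: SimConfig,
    replicates: int = 1,
    seed: int = 0,
    threshold: float = 0.90,
) -> ReferenceCurves:
    """Simulate populations along an Ne grid and record mean count90.

    Each grid point runs ``replicates`` independent simulations of the
    template design (same genome, sample size and SNP panel) at the
    given Ne; the eigenvalue count at ``threshold`` explained variation
    of the raw GRM is averaged over replicates.
    """
    ne_grid = sorted(int(x) for x in ne_grid)
    if len(ne_grid) < 2:
        raise ValueError("ne_grid must contain at least 2 values for interpolation")
    seed_rng = np.random.default_rng(seed)
    means, per_rep = [], []
    for ne in ne_grid:
        counts = []
        for r in range(replicates):
            sub = int(seed_rng.integers(2**31))
            try:
                pop = simulate_population(vary_ne(sim_config_template, ne, sub))
                p = observed_allele_frequencies(pop.genotypes)
                prof = eigen_profile(build_grm(pop.genotypes, p))
                counts.append(count_for_fraction(prof, threshold))
            except Exception as e:
                raise RuntimeError(
                    f"reference simulation failed at ne={ne}, replicate {r}: {e}"
                ) from e
        per_rep.append(counts)
        means.append(float(np.mean(counts)))
        logger.info("reference curve point ne=%d: count%d=%s", ne, int(threshold * 100), counts)
    tmpl = sim_config_template
    return ReferenceCurves(
        ne=np.array(ne_grid, dtype=float),
        count90=np.array(means),
        threshold=threshold,
        genome_length=tmpl.genome_length,
        n_genotyped=tmpl.n_per_generation * len(tmpl.genotyped_generations),
        n_snp=tmpl.n_snp,
        replicates=replicates,
        per_replicate=per_rep,
    )


def estimate_ne(
    observed_count90: float,
    curves: ReferenceCurves,
    query_design: dict | None = None,
) -> NeEstimate:
    """Interpolate Ne from an observed count90 on the reference curves.

    Interpolation is piecewise linear in log(count) vs log(ne): the
    count-vs-Ne relation is close to a power law, i.e. nearly linear on
    logarithmic axes.  Observations outside the grid are linearly
    extrapolated on the outer segment and flagged.

    ``query_design`` may carry ``genome_length``/``n_genotyped``/``n_snp``
    of the queried population; mismatches with the curve provenance
    attach a warning to the estimate.
    """
    if observed_count90 <= 0:
        raise ValueError("observed count must be positive")
    x = np.log(curves.count90)
    y = np.log(curves.ne)
    lx = np.log(observed_count90)
    extrapolated = bool(lx < x[0] or lx > x[-1])
    if extrapolated:
        i = 0 if lx < x[0] else len(x) - 2
        slope = (y[i + 1] - y[i]) / (x[i + 1] - x[i])
        ly = y[i] + slope * (lx - x[i])
    else:
        ly = float(np.interp(lx, x, y))
    notes = []
    if query_design:
        for key, curve_val in (
            ("genome_length", curves.genome_length),
            ("n_genotyped", curves.n_genotyped),
            ("n_snp", curves.n_snp),
        ):
            if key in query_design and not np.isclose(query_design[key], curve_val, rtol=0.05):
                notes.append(
                    f"{key} of query ({query_design[key]}) differs from curve provenance "
                    f"({curve_val}); the interpolated Ne may be biased"
                )
    for msg in notes:
        warnings.warn(msg, stacklevel=2)
    return NeEstimate(
        ne=float(np.exp(ly)),
        threshold_used=curves.threshold,
        genome_length_assumed=curves.genome_length,
        extrapolated=extrapolated,
        warnings=notes,
    )


def adjust_ne_for_genome_length(
    ne: float, length_reference: float, length_target: float
) -> NeEstimate:
    """Rescale Ne between genome-length assumptions: Ne ~ 1/L at constant Me.

    E.g. an estimate of 32 under a 30-Morgan genome becomes 48 under a
    20-Morgan genome.
    """
    if length_reference <= 0 or length_target <= 0:
        raise ValueError("genome lengths must be positive")
    est = ne if isinstance(ne, (int, float)) else ne.ne
    return NeEstimate(
        ne=float(est) * length_reference / length_target,
        threshold_used=0.90,
        genome_length_assumed=length_target,
    )


def snp_sufficiency_warning(count: int, n_snp: int, n_genotyped: int) -> str | None:
    """12x rule: counts are likely underestimated when SNPs or animals are scarce.

    Identifying the independent segments behind an eigenvalue count
    requires roughly 12 times as many SNPs (and genotyped animals) as
    the count itself; below that the dimensionality is underestimated.
    Returns the warning message (also emitted via ``warnings``) or None.
    """
    if count <= 0:
        return None
    msgs = []
    if n_snp < 12 * count:
        msgs.append(f"n_snp={n_snp} < 12 × count ({12 * count})")
    if n_genotyped < 12 * count:
        msgs.append(f"n_genotyped={n_genotyped} < 12 × count ({12 * count})")
    if not msgs:
        return None
    msg = (
        "eigenvalue count is likely an underestimate of the true dimensionality: "
        + "; ".join(msgs)
    )
    warnings.warn(msg, stacklevel=2)
    return msg
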