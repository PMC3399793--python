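"""Gaussian-threshold haplotype simulator.

The latent-normal approach: estimate a per-site threshold ``z_i`` from the
observed allele-1 frequency and a latent correlation matrix from the observed
pairwise joint allele-1 probabilities (tetrachoric correlations); repair the
matrix to positive definite by flooring its eigenvalues; draw multivariate
normal vectors; and dichotomize each coordinate at its threshold (allele 1
when the draw falls at or below ``z_i``, so that ``P(allele 1) = freq1``).

Dichotomizing correlated normals attenuates their correlation, which is why
this family of simulators systematically loses LD at moderate-to-high-LD
pairs; the evaluation framework quantifies that loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri

from .bvn import bvn_cdf
from .panel import HaplotypePanel

__all__ = [
    "GaussConfig",
    "LatentGaussModel",
    "tetrachoric_rho",
    "fit_latent_model",
    "make_positive_definite",
    "simulate_gauss",
]

_RHO_LO = -1.0 + 1e-9
_RHO_HI = 1.0 - 1e-9


@dataclass(frozen=True)
class GaussConfig:
    """Configuration for :func:`simulate_gauss`."""

    n_haplotypes_out: int
    floor_tolerance: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_haplotypes_out < 2:
            raise ValueError("n_haplotypes_out must be >= 2")
        if self.floor_tolerance <= 0:
            raise ValueError("floor_tolerance must be positive")


@dataclass
class LatentGaussModel:
    """Fitted latent-normal model for a panel.

    ``thresholds[i] = Phi^-1(freq1_i)``; ``sigma`` is the tetrachoric
    correlation matrix (unit diagonal); ``sigma_repaired`` is the
    eigenvalue-floored positive-definite matrix actually sampled from.
    """

    thresholds: np.ndarray
    sigma: np.ndarray
    sigma_repaired: np.ndarray
    floor_tolerance: float


def _frechet_bounds(p_a: float, p_b: float) -> tuple[float, float]:
    return max(0.0, p_a + p_b - 1.0), min(p_a, p_b)


def tetrachoric_rho(p_a: float, p_b: float, p_ab: float, *,
                    tol: float = 1e-10) -> float:
    """Latent correlation rho solving ``Phi2(z_a, z_b; rho) = p_ab`` with
    ``z = Phi^-1(p)``, found by bisection (Phi2 is increasing in rho).

    Joint probabilities at a Frechet bound return +/-1 exactly; outside the
    bounds is a domain error.
    """
    if not (0.0 < p_a < 1.0 and 0.0 < p_b < 1.0):
        raise ValueError("marginal probabilities must lie strictly in (0, 1)")
    lo, hi = _frechet_bounds(p_a, p_b)
    if p_ab < lo - 1e-12 or p_ab > hi + 1e-12:
        raise ValueError(
            f"joint probability {p_ab} outside Frechet bounds [{lo}, {hi}]"
        )
    if p_ab >= hi - 1e-15:
        return 1.0
    if p_ab <= lo + 1e-15:
        return -1.0
    z_a = ndtri(p_a)
    z_b = ndtri(p_b)
    rho_lo, rho_hi = _RHO_LO, _RHO_HI
    # bisect on interval width: near |rho| = 1 the CDF is nearly flat in
    # rho, so a residual-only stopping rule would return early with a poor
    # root; the residual check is a bonus exit once the bracket is tight
    while rho_hi - rho_lo > 1e-13:
        mid = 0.5 * (rho_lo + rho_hi)
        f = bvn_cdf(z_a, z_b, mid) - p_ab
        if abs(f) < tol and rho_hi - rho_lo < 1e-8:
            return mid
        if f < 0.0:
            rho_lo = mid
        else:
            rho_hi = mid
    return 0.5 * (rho_lo + rho_hi)


def _tetrachoric_many(z_a, z_b, p_ab, n_iter: int = 60) -> np.ndarray:
    """Vectorized bisection for arrays of pairs (fixed iteration count gives
    interval width 2/2^60, far below any practical tolerance)."""
    z_a = np.asarray(z_a, float)
    z_b = np.asarray(z_b, float)
    p_ab = np.asarray(p_ab, float)
    lo = np.full_like(p_ab, _RHO_LO)
    hi = np.full_like(p_ab, _RHO_HI)
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        f = bvn_cdf(z_a, z_b, mid) - p_ab
        lo = np.where(f < 0.0, mid, lo)
        hi = np.where(f < 0.0, hi, mid)
    return 0.5 * (lo + hi)


def fit_latent_model(panel: HaplotypePanel,
                     floor_tolerance: float = 1e-6) -> LatentGaussModel:
    """Fit thresholds and the tetrachoric correlation matrix to a panel.

    All sites must be polymorphic; monoallelic sites have no finite
    threshold and must be removed first (see
    :meth:`HaplotypePanel.drop_monoallelic`).
    """
    freq = panel.freq1()
    mono = np.flatnonzero((freq == 0.0) | (freq == 1.0))
    if mono.size:
        raise ValueError(
            "monoallelic sites must be removed before latent-model fitting: "
            f"site indices {mono.tolist()}"
        )
    m = panel.n_sites
    z = ndtri(freq)
    X = panel.alleles.astype(np.float64)
    P11 = (X @ X.T) / panel.n_haplotypes

    iu, ju = np.triu_indices(m, k=1)
    p_a, p_b, p_ab = freq[iu], freq[ju], P11[iu, ju]
    lo_b = np.maximum(0.0, p_a + p_b - 1.0)
    hi_b = np.minimum(p_a, p_b)
    rho_flat = np.empty(iu.size)
    at_hi = p_ab >= hi_b - 1e-15
    at_lo = p_ab <= lo_b + 1e-15
    inner = ~(at_hi | at_lo)
    rho_flat[at_hi] = 1.0
    rho_flat[at_lo] = -1.0
    if inner.any():
        rho_flat[inner] = _tetrachoric_many(
            z[iu][inner], z[ju][inner], p_ab[inner]
        )
    sigma = np.eye(m)
    sigma[iu, ju] = rho_flat
    sigma[ju, iu] = rho_flat
    repaired = make_positive_definite(sigma, floor_tolerance)
    return LatentGaussModel(
        thresholds=z,
        sigma=sigma,
        sigma_repaired=repaired,
        floor_tolerance=floor_tolerance,
    )


def make_positive_definite(m: np.ndarray, tol: float) -> np.ndarray:
    """Eigenvalue flooring: decompose a symmetric matrix, raise every
    eigenvalue below ``tol`` up to ``tol``, and reassemble.  A matrix whose
    eigenvalues already clear the floor is returned unchanged (to rounding).
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {m.shape}")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("matrix must be symmetric")
    vals, vecs = np.linalg.eigh(m)
    if vals[0] >= tol:
        return m.copy()
    floored = np.maximum(vals, tol)
    out = (vecs * floored) @ vecs.T
    return 0.5 * (out + out.T)


def simulate_gauss(panel: HaplotypePanel, cfg: GaussConfig,
                   model: LatentGaussModel | None = None) -> HaplotypePanel:
    """Draw a simulated panel by thresholding multivariate normal vectors.

    A pre-fitted ``model`` may be supplied to amortize the tetrachoric fit
    across replicates; otherwise the model is fitted from ``panel``.
    """
    if model is None:
        model = fit_latent_model(panel, cfg.floor_tolerance)
    rng = np.random.default_rng(cfg.seed)
    chol = np.linalg.cholesky(model.sigma_repaired)
    draws = rng.standard_normal((cfg.n_haplotypes_out, panel.n_sites)) @ chol.T
    alleles = (draws <= model.thresholds[None, :]).T.astype(np.uint8)
    return panel.with_alleles(alleles, label=f"{panel.label}:gauss")
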