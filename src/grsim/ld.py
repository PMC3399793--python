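"""Pairwise linkage disequilibrium from phased haplotypes.

All statistics are computed from direct haplotype counts (inputs are phased,
so no EM frequency estimation is involved).  For a pair of biallelic sites
with allele-1 frequencies ``p_a``, ``p_b`` and joint allele-1 frequency
``p_ab``:

* ``D = p_ab - p_a * p_b``
* ``D' = D / Dmax`` with ``Dmax = min(p_a (1-p_b), (1-p_a) p_b)`` when
  ``D > 0`` and ``min(p_a p_b, (1-p_a)(1-p_b))`` when ``D < 0``
* ``r = D / sqrt(p_a (1-p_a) p_b (1-p_b))``; ``r2 = r**2``

Standard errors: ``SE(r) = sqrt((1 - r^2) / (n - 2))`` with *n* the haplotype
count, and an asymptotic (delta-method) SE of D' under multinomial sampling
of the four gamete classes, in the spirit of Zapata et al.'s approximate
variance.  LD with a monoallelic site is undefined and raises
:class:`MonoallelicSiteError`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .panel import HaplotypePanel

__all__ = [
    "SiteFrequency",
    "PairLD",
    "MonoallelicSiteError",
    "site_frequencies",
    "pair_ld",
    "se_r",
    "se_dprime",
    "ld_matrices",
    "se_dprime_matrix",
]


class MonoallelicSiteError(ValueError):
    """LD requested for a pair involving a monoallelic site."""

    def __init__(self, site_index: int):
        self.site_index = site_index
        super().__init__(f"site {site_index} is monoallelic; LD undefined")


@dataclass(frozen=True)
class SiteFrequency:
    index: int
    freq1: float
    maf: float
    is_monoallelic: bool


@dataclass(frozen=True)
class PairLD:
    """LD statistics for one ordered site pair."""

    index_a: int
    index_b: int
    p_a: float
    p_b: float
    p_ab: float
    D: float
    Dprime: float
    r: float
    r2: float
    se_r: float
    se_Dprime: float  # NaN when the asymptotic variance is degenerate


def site_frequencies(panel: HaplotypePanel) -> list[SiteFrequency]:
    """Allele-1 frequency, MAF and monoallelic flag for every site."""
    f = panel.freq1()
    maf = np.minimum(f, 1.0 - f)
    return [
        SiteFrequency(index=i, freq1=float(f[i]), maf=float(maf[i]),
                      is_monoallelic=bool(maf[i] == 0.0))
        for i in range(panel.n_sites)
    ]


def _dmax(p_a: float, p_b: float, D: float) -> float:
    if D >= 0:
        return min(p_a * (1.0 - p_b), (1.0 - p_a) * p_b)
    return min(p_a * p_b, (1.0 - p_a) * (1.0 - p_b))


def _dprime_from_probs(p11: float, p10: float, p01: float) -> float:
    """D' as a function of gamete-class proportions (allele order 1/0 at the
    two sites); used both directly and for delta-method differentiation."""
    p_a = p11 + p10
    p_b = p11 + p01
    D = p11 - p_a * p_b
    dmax = _dmax(p_a, p_b, D)
    if dmax <= 0.0:
        return 0.0
    return D / dmax


def pair_ld(panel: HaplotypePanel, i: int, j: int) -> PairLD:
    """All pairwise LD statistics for sites ``i`` and ``j`` of a panel.

    Raises
    ------
    MonoallelicSiteError
        If either site is fixed; callers typically drop such pairs.
    """
    a = panel.alleles[i].astype(np.int64)
    b = panel.alleles[j].astype(np.int64)
    n = panel.n_haplotypes
    p_a = a.sum() / n
    p_b = b.sum() / n
    if p_a in (0.0, 1.0):
        raise MonoallelicSiteError(i)
    if p_b in (0.0, 1.0):
        raise MonoallelicSiteError(j)
    p_ab = (a & b).sum() / n
    D = p_ab - p_a * p_b
    dprime = _dprime_from_probs(p_ab, p_a - p_ab, p_b - p_ab)
    r = D / math.sqrt(p_a * (1.0 - p_a) * p_b * (1.0 - p_b))
    return PairLD(
        index_a=i,
        index_b=j,
        p_a=p_a,
        p_b=p_b,
        p_ab=p_ab,
        D=D,
        Dprime=dprime,
        r=r,
        r2=r * r,
        se_r=se_r(r, n),
        se_Dprime=_se_dprime_from_probs(
            p_ab, p_a - p_ab, p_b - p_ab, 1.0 - p_a - p_b + p_ab, n
        ),
    )


def se_r(r: float, n: int) -> float:
    """Standard error of the allelic correlation:
    ``sqrt((1 - r^2) / (n - 2))``, *n* = number of haplotypes."""
    if n <= 2:
        raise ValueError(f"need more than 2 haplotypes for SE(r), got n={n}")
    if abs(r) > 1.0 + 1e-12:
        raise ValueError(f"|r| must be <= 1, got {r}")
    return math.sqrt(max(0.0, 1.0 - r * r) / (n - 2))


def _se_dprime_from_probs(
    p11: float, p10: float, p01: float, p00: float, n: int
) -> float:
    """Delta-method SE of D' from the four gamete-class proportions.

    The gradient of D' with respect to the class proportions is taken
    numerically (central differences); the multinomial variance of a smooth
    statistic f(p) is ``(sum_i p_i g_i^2 - (sum_i p_i g_i)^2) / n``.
    Returns NaN on the |D'| = 1 boundary (a zero-count class), where the
    asymptotic variance is degenerate.
    """
    probs = np.array([p11, p10, p01, p00], dtype=float)
    dprime = _dprime_from_probs(p11, p10, p01)
    if abs(dprime) >= 1.0 - 1e-12:
        return math.nan
    h = 1e-7
    grad = np.empty(4)
    for k in range(4):
        up = probs.copy()
        dn = probs.copy()
        up[k] += h
        dn[k] -= h
        grad[k] = (
            _dprime_from_probs(up[0], up[1], up[2])
            - _dprime_from_probs(dn[0], dn[1], dn[2])
        ) / (2.0 * h)
    mean_g = float(probs @ grad)
    var = (float(probs @ grad**2) - mean_g**2) / n
    return math.sqrt(max(0.0, var))


def se_dprime(panel: HaplotypePanel, i: int, j: int) -> float:
    """Asymptotic SE of D' for a site pair; NaN when |D'| = 1 (degenerate
    variance: one gamete class unobserved)."""
    a = panel.alleles[i].astype(np.int64)
    b = panel.alleles[j].astype(np.int64)
    n = panel.n_haplotypes
    p_a = a.sum() / n
    p_b = b.sum() / n
    if p_a in (0.0, 1.0):
        raise MonoallelicSiteError(i)
    if p_b in (0.0, 1.0):
        raise MonoallelicSiteError(j)
    p11 = (a & b).sum() / n
    return _se_dprime_from_probs(
        p11, p_a - p11, p_b - p11, 1.0 - p_a - p_b + p11, n
    )


def ld_matrices(panel: HaplotypePanel) -> dict[str, np.ndarray]:
    """Vectorized all-pairs LD for a panel.

    Returns a dict with square symmetric matrices ``D``, ``Dprime`` (signed),
    ``abs_Dprime``, ``r`` (signed) and ``r2``; entries involving a
    monoallelic site (and the diagonal) are NaN.  Agrees with
    :func:`pair_ld` entry-by-entry on polymorphic pairs.
    """
    X = panel.alleles.astype(np.float64)
    n = panel.n_haplotypes
    p = X.mean(axis=1)
    P11 = (X @ X.T) / n
    D = P11 - np.outer(p, p)
    q = 1.0 - p
    with np.errstate(divide="ignore", invalid="ignore"):
        dmax_pos = np.minimum(np.outer(p, q), np.outer(q, p))
        dmax_neg = np.minimum(np.outer(p, p), np.outer(q, q))
        dmax = np.where(D >= 0, dmax_pos, dmax_neg)
        dprime = np.where(dmax > 0, D / np.where(dmax > 0, dmax, 1.0), 0.0)
        denom = np.sqrt(np.outer(p * q, p * q))
        r = np.where(denom > 0, D / np.where(denom > 0, denom, 1.0), 0.0)
    bad = (p == 0.0) | (p == 1.0)
    mask = bad[:, None] | bad[None, :]
    np.fill_diagonal(mask, True)
    for m in (D, dprime, r):
        m[mask] = np.nan
    return {
        "D": D,
        "Dprime": dprime,
        "abs_Dprime": np.abs(dprime),
        "r": r,
        "r2": r * r,
    }


def se_dprime_matrix(panel: HaplotypePanel) -> np.ndarray:
    """All-pairs asymptotic SE of D'; NaN for monoallelic sites, the
    diagonal, and |D'| = 1 boundary pairs."""
    n_sites = panel.n_sites
    n = panel.n_haplotypes
    X = panel.alleles.astype(np.float64)
    p = X.mean(axis=1)
    P11 = (X @ X.T) / n
    out = np.full((n_sites, n_sites), np.nan)
    poly = np.flatnonzero((p > 0.0) & (p < 1.0))
    for ii, i in enumerate(poly):
        for j in poly[ii + 1:]:
            p11 = P11[i, j]
            se = _se_dprime_from_probs(
                p11, p[i] - p11, p[j] - p11, 1.0 - p[i] - p[j] + p11, n
            )
            out[i, j] = out[j, i] = se
    return out
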