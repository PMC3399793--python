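"""Mosaic (haplotype-copying) simulator.

Each new haplotype is a mosaic of segments copied from a panel of templates,
in the style of the Li-Stephens copying model: starting from a chosen locus
and a uniformly chosen template, the copy path walks outward site by site,
switching to a uniformly chosen template (self-switches allowed) at each
interval with probability

    ``1 - exp(-4 * Ne * weight * d / k)``

where ``d`` is the interval's genetic distance in Morgans, ``Ne`` the
effective population size, and ``k`` the current number of templates.  After
the copy path is fixed, each site's allele is flipped independently with the
per-SNP mutation probability ``theta / (theta + k0)``, ``k0`` being the
*original* haplotype count.  By default every finished haplotype joins the
template panel, emulating several generations of random mating and giving
this method its extra between-replicate variation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .panel import GeneticMap, HaplotypePanel

__all__ = [
    "MosaicConfig",
    "mutation_prob",
    "jump_prob",
    "simulate_mosaic_haplotype",
    "simulate_mosaic",
]


@dataclass(frozen=True)
class MosaicConfig:
    """Parameters for :func:`simulate_mosaic`.

    ``theta`` is the mutation parameter (expected mutations per SNP for the
    original sample); ``effective_pop_size`` scales the copy-switch
    intensity; ``weight`` multiplies the recombination-rate vector;
    ``start_locus`` is a site index or ``"random"``; with ``grow_panel``
    (default) each new haplotype is appended to the template panel.
    """

    n_haplotypes_out: int
    theta: float = 0.0
    effective_pop_size: float = 11418.0
    weight: float = 1.0
    start_locus: int | str = "random"
    grow_panel: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValueError("theta must be nonnegative")
        if self.effective_pop_size <= 0:
            raise ValueError("effective_pop_size must be positive")
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        if self.n_haplotypes_out < 0:
            raise ValueError("n_haplotypes_out must be nonnegative")


def mutation_prob(theta: float, k: int) -> float:
    """Per-SNP per-haplotype mutation probability ``theta / (theta + k)``
    for a sample of ``k`` original haplotypes."""
    if k < 1:
        raise ValueError(f"k must be a positive haplotype count, got {k}")
    if theta < 0:
        raise ValueError(f"theta must be nonnegative, got {theta}")
    return theta / (theta + k)


def jump_prob(map_interval_cM: float, Ne: float, weight: float, k: int) -> float:
    """Copy-switch probability over one inter-site interval:
    ``1 - exp(-4 Ne weight d / k)`` with ``d`` in Morgans."""
    if map_interval_cM < 0:
        raise ValueError("interval genetic distance must be nonnegative")
    d_morgans = map_interval_cM / 100.0
    return -math.expm1(-4.0 * Ne * weight * d_morgans / k)


def _interval_cM(panel: HaplotypePanel, gmap: GeneticMap) -> np.ndarray:
    cum = gmap.cM_at(panel.positions_bp)
    return np.diff(cum)


def _walk(templates: np.ndarray, intervals: np.ndarray, jp: np.ndarray,
          t0: int, rng: np.random.Generator) -> np.ndarray:
    """Template index at each site along one direction of the walk.

    ``intervals`` indexes the crossed intervals in walk order; returns the
    template in force after each interval.
    """
    m = len(intervals)
    if m == 0:
        return np.empty(0, dtype=np.int64)
    jumps = rng.random(m) < jp[intervals]
    targets = rng.integers(templates.shape[1], size=m)
    # index of the most recent jump at or before each step (0 = none yet)
    last = np.maximum.accumulate(np.where(jumps, np.arange(1, m + 1), 0))
    out = np.where(last == 0, t0, targets[np.maximum(last - 1, 0)])
    return out


def simulate_mosaic_haplotype(
    templates: np.ndarray,
    panel: HaplotypePanel,
    gmap: GeneticMap,
    cfg: MosaicConfig,
    rng: np.random.Generator,
    k_original: int | None = None,
) -> np.ndarray:
    """Simulate one mosaic haplotype copied from ``templates`` (a
    ``n_sites x k`` matrix of current templates over ``panel``'s sites).

    The walk starts at ``cfg.start_locus`` (uniform random site if
    ``"random"``) on a uniformly chosen template and proceeds to the right
    and then to the left, independently.  Mutation uses ``k_original``
    (defaults to the template count).
    """
    cM = _interval_cM(panel, gmap)
    rho_base = 4.0 * cfg.effective_pop_size * cfg.weight * cM / 100.0
    return _simulate_one(templates, rho_base, cfg, panel.n_sites,
                         k_original, rng)


def _simulate_one(
    templates: np.ndarray,
    rho_base: np.ndarray,
    cfg: MosaicConfig,
    n_sites: int,
    k_original: int | None,
    rng: np.random.Generator,
) -> np.ndarray:
    k = templates.shape[1]
    k0 = k if k_original is None else k_original
    jp = -np.expm1(-rho_base / k)

    if cfg.start_locus == "random":
        s = int(rng.integers(n_sites))
    else:
        s = int(cfg.start_locus)
        if not 0 <= s < n_sites:
            raise ValueError(f"start locus {s} outside [0, {n_sites})")

    t0 = int(rng.integers(k))
    path = np.empty(n_sites, dtype=np.int64)
    path[s] = t0
    right = _walk(templates, np.arange(s, n_sites - 1), jp, t0, rng)
    path[s + 1:] = right
    left = _walk(templates, np.arange(s - 1, -1, -1), jp, t0, rng)
    if s > 0:
        path[s - 1::-1] = left

    hap = templates[np.arange(n_sites), path].astype(np.uint8)
    mu = mutation_prob(cfg.theta, k0)
    if mu > 0.0:
        flips = rng.random(n_sites) < mu
        hap = hap ^ flips.astype(np.uint8)
    return hap


def simulate_mosaic(
    panel: HaplotypePanel, gmap: GeneticMap, cfg: MosaicConfig
) -> HaplotypePanel:
    """Generate a replicate panel of sequentially simulated mosaic
    haplotypes; deterministic for a given seed.

    With ``grow_panel`` the template set grows as haplotypes are produced
    (the copy-switch probability shrinks as ``k`` grows accordingly), while
    the mutation probability always uses the original haplotype count.
    """
    rng = np.random.default_rng(cfg.seed)
    n_out = cfg.n_haplotypes_out
    if n_out == 0:
        return panel.with_alleles(
            np.empty((panel.n_sites, 0), dtype=np.uint8),
            label=f"{panel.label}:mosaic",
        )
    k0 = panel.n_haplotypes
    max_k = k0 + (n_out if cfg.grow_panel else 0)
    templates = np.empty((panel.n_sites, max_k), dtype=np.uint8)
    templates[:, :k0] = panel.alleles
    k = k0
    cM = _interval_cM(panel, gmap)
    rho_base = 4.0 * cfg.effective_pop_size * cfg.weight * cM / 100.0
    out = np.empty((panel.n_sites, n_out), dtype=np.uint8)
    for m in range(n_out):
        hap = _simulate_one(
            templates[:, :k], rho_base, cfg, panel.n_sites, k0, rng
        )
        out[:, m] = hap
        if cfg.grow_panel:
            templates[:, k] = hap
            k += 1
    return panel.with_alleles(out, label=f"{panel.label}:mosaic")
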