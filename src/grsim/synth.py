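"""Synthetic haplotype panels and genetic maps with controllable LD.

Panels are built by a founder-block construction: the site range is
partitioned into blocks, a small number of founder haplotypes is drawn per
block (site frequencies from a MAF spectrum bounded below by ``maf_floor``),
and every output haplotype copies one founder per block (uniformly,
independently across blocks) before a light per-site mutation noise is
applied.  With two founders per block and small noise, within-block pairs
sit at |D'| near 1 while between-block pairs are at linkage equilibrium up
to finite-sample noise — giving direct control over which strata are
populated.  Maps have a uniform background rate punctuated by hotspot
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import GeneticMap, HaplotypePanel, SiteRecord

__all__ = ["Hotspot", "SynthSpec", "make_panel", "make_map", "gr_mini_spec"]


@dataclass(frozen=True)
class Hotspot:
    """A recombination hotspot: ``width_bp`` starting at ``start_bp`` with
    local rate ``rate_cM_per_Mb`` replacing the background."""

    start_bp: int
    width_bp: int
    rate_cM_per_Mb: float


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for one synthetic panel + map pair."""

    n_sites: int = 100
    n_haplotypes: int = 400
    region_length_bp: int = 300_000
    block_boundaries: tuple[int, ...] = (25, 50, 75)  # site indices starting new blocks
    founders_per_block: int = 2
    mutation_noise: float = 0.02
    maf_floor: float = 0.05
    background_rate: float = 1.0  # cM/Mb
    hotspots: tuple[Hotspot, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.founders_per_block < 1:
            raise ValueError("founders_per_block must be >= 1")
        if not 0.0 <= self.mutation_noise < 0.5:
            raise ValueError("mutation_noise must lie in [0, 0.5)")
        if not 0.0 <= self.maf_floor < 0.5:
            raise ValueError("maf_floor must lie in [0, 0.5)")
        b = self.block_boundaries
        if any(x <= 0 or x >= self.n_sites for x in b) or list(b) != sorted(set(b)):
            raise ValueError(
                "block_boundaries must be strictly increasing site indices "
                "inside (0, n_sites)"
            )
        spans = sorted((h.start_bp, h.start_bp + h.width_bp) for h in self.hotspots)
        for (_, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("hotspot intervals must not overlap")

    @property
    def blocks(self) -> list[range]:
        edges = [0, *self.block_boundaries, self.n_sites]
        return [range(a, b) for a, b in zip(edges, edges[1:])]


def gr_mini_spec(seed: int = 0) -> SynthSpec:
    """The default desk-scale fixture ("GR-mini"): 100 sites over 300 kb,
    400 haplotypes, 4 blocks of 2 founders, 2% mutation noise, and three
    10 kb / 50 cM/Mb hotspots at the block boundaries."""
    length = 300_000
    spacing = length // 101  # sites at spacing, 2*spacing, ...
    boundaries = (25, 50, 75)
    hotspots = tuple(
        Hotspot(
            start_bp=(b * spacing + (b + 1) * spacing) // 2 - 5_000,
            width_bp=10_000,
            rate_cM_per_Mb=50.0,
        )
        for b in boundaries
    )
    return SynthSpec(hotspots=hotspots, seed=seed)


def _site_positions(spec: SynthSpec) -> np.ndarray:
    spacing = spec.region_length_bp // (spec.n_sites + 1)
    if spacing < 1:
        raise ValueError("region too short for the requested site count")
    return spacing * np.arange(1, spec.n_sites + 1, dtype=np.int64)


def make_panel(spec: SynthSpec) -> HaplotypePanel:
    """Generate a founder-block panel; deterministic for a given seed."""
    rng = np.random.default_rng(spec.seed)
    pos = _site_positions(spec)

    # allele-1 frequency spectrum: MAF in [maf_floor, 0.5], skewed toward
    # rare variants, with the major/minor orientation randomized
    u = rng.random(spec.n_sites)
    maf = spec.maf_floor + (0.5 - spec.maf_floor) * u**2
    flip = rng.random(spec.n_sites) < 0.5
    freq = np.where(flip, 1.0 - maf, maf)

    alleles = np.empty((spec.n_sites, spec.n_haplotypes), dtype=np.uint8)
    for block in spec.blocks:
        idx = np.arange(block.start, block.stop)
        founders = (
            rng.random((idx.size, spec.founders_per_block)) < freq[idx, None]
        ).astype(np.uint8)
        choice = rng.integers(spec.founders_per_block, size=spec.n_haplotypes)
        alleles[idx] = founders[:, choice]
    if spec.mutation_noise > 0.0:
        flips = rng.random(alleles.shape) < spec.mutation_noise
        alleles = alleles ^ flips.astype(np.uint8)

    sites = [
        SiteRecord(site_id=f"snp{i + 1}", position_bp=int(pos[i]),
                   allele0="A", allele1="G")
        for i in range(spec.n_sites)
    ]
    return HaplotypePanel(sites=sites, alleles=alleles,
                          label=f"synth-seed{spec.seed}")


def make_map(spec: SynthSpec) -> GeneticMap:
    """Generate the matching genetic map: background rate with hotspot
    intervals, positions covering the full region, cumulative column
    integrated from the rates."""
    length = spec.region_length_bp
    breaks = {1, length}
    for h in spec.hotspots:
        if not (1 <= h.start_bp and h.start_bp + h.width_bp <= length):
            raise ValueError("hotspot outside region")
        breaks.add(h.start_bp)
        breaks.add(h.start_bp + h.width_bp)
    positions = np.array(sorted(breaks), dtype=np.int64)

    rates = np.full(len(positions), spec.background_rate)
    for h in spec.hotspots:
        inside = (positions >= h.start_bp) & (positions < h.start_bp + h.width_bp)
        rates[inside] = h.rate_cM_per_Mb
    rates[-1] = 0.0  # rate beyond the last position is unused

    widths_mb = np.diff(positions) / 1e6
    cum = np.concatenate([[0.0], np.cumsum(rates[:-1] * widths_mb)])
    return GeneticMap(positions_bp=positions, rate_cM_per_Mb=rates,
                      cumulative_cM=cum)
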