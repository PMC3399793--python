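"""Core containers: haplotype panels and genetic maps.

A :class:`HaplotypePanel` is the unit of simulation input and output: an
ordered list of biallelic SNP sites together with a ``{0, 1}`` allele matrix of
shape ``n_sites x n_haplotypes``.  A :class:`GeneticMap` carries physical
positions with local recombination rates (cM/Mb) and cumulative genetic
distance (cM), and converts physical spans into per-meiosis recombination
fractions via the Haldane map function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SiteRecord",
    "HaplotypePanel",
    "GeneticMap",
    "PanelFormatError",
    "interval_recomb_fraction",
]


class PanelFormatError(ValueError):
    """Malformed panel, legend, VCF or map input."""


@dataclass(frozen=True)
class SiteRecord:
    """One biallelic SNP site: identifier, 1-based bp position and alleles."""

    site_id: str
    position_bp: int
    allele0: str
    allele1: str

    def __post_init__(self) -> None:
        if self.position_bp <= 0:
            raise PanelFormatError(
                f"site {self.site_id!r}: position_bp must be positive, "
                f"got {self.position_bp}"
            )
        if self.allele0 == self.allele1:
            raise PanelFormatError(
                f"site {self.site_id!r}: alleles must differ, both {self.allele0!r}"
            )


@dataclass
class HaplotypePanel:
    """Phased haplotypes at an ordered set of biallelic sites.

    Parameters
    ----------
    sites
        Site metadata, strictly increasing in ``position_bp``.
    alleles
        ``uint8`` matrix of 0/1 alleles, shape ``(n_sites, n_haplotypes)``.
        Allele 1 refers to each site's ``allele1``.
    label
        Free-text panel name carried through I/O and simulation.
    """

    sites: list[SiteRecord]
    alleles: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2:
            raise PanelFormatError("allele matrix must be 2-D (sites x haplotypes)")
        if len(self.sites) != self.alleles.shape[0]:
            raise PanelFormatError(
                f"{len(self.sites)} sites but allele matrix has "
                f"{self.alleles.shape[0]} rows"
            )
        if self.n_sites < 1:
            raise PanelFormatError("panel needs at least one site")
        # a 0-column panel is allowed as a degenerate simulation *output*
        # (requesting zero haplotypes); a single haplotype is never valid
        if self.n_haplotypes == 1:
            raise PanelFormatError("panel needs at least two haplotypes")
        if not np.isin(self.alleles, (0, 1)).all():
            bad = np.unique(self.alleles[~np.isin(self.alleles, (0, 1))])
            raise PanelFormatError(f"alleles must be 0/1, found {bad.tolist()}")
        pos = self.positions_bp
        if np.any(np.diff(pos) <= 0):
            i = int(np.flatnonzero(np.diff(pos) <= 0)[0])
            raise PanelFormatError(
                f"site positions must be strictly increasing; "
                f"{self.sites[i].site_id} at {pos[i]} followed by "
                f"{self.sites[i + 1].site_id} at {pos[i + 1]}"
            )

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[1]

    @property
    def positions_bp(self) -> np.ndarray:
        return np.asarray([s.position_bp for s in self.sites], dtype=np.int64)

    def freq1(self) -> np.ndarray:
        """Per-site frequency of allele 1."""
        return self.alleles.mean(axis=1)

    def maf(self) -> np.ndarray:
        """Per-site minor allele frequency."""
        f = self.freq1()
        return np.minimum(f, 1.0 - f)

    def monoallelic_mask(self) -> np.ndarray:
        """Boolean mask of sites fixed for either allele in this panel."""
        return self.maf() == 0.0

    def subset_sites(self, indices: np.ndarray | list[int]) -> "HaplotypePanel":
        """Panel restricted to the given site indices (order preserved)."""
        idx = np.asarray(indices, dtype=np.intp)
        return HaplotypePanel(
            sites=[self.sites[int(i)] for i in idx],
            alleles=self.alleles[idx],
            label=self.label,
        )

    def drop_monoallelic(self) -> "HaplotypePanel":
        """Panel with monoallelic sites removed (Gaussian-threshold
        simulation requires all sites polymorphic)."""
        keep = np.flatnonzero(~self.monoallelic_mask())
        return self.subset_sites(keep)

    def with_alleles(self, alleles: np.ndarray, label: str | None = None) -> "HaplotypePanel":
        """New panel sharing this panel's site metadata."""
        return HaplotypePanel(
            sites=list(self.sites),
            alleles=alleles,
            label=self.label if label is None else label,
        )

    def same_sites(self, other: "HaplotypePanel") -> bool:
        return self.sites == other.sites

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplotypePanel):
            return NotImplemented
        return (
            self.sites == other.sites
            and self.alleles.shape == other.alleles.shape
            and bool((self.alleles == other.alleles).all())
        )


@dataclass(frozen=True)
class GeneticMap:
    """Variable recombination map over a region.

    ``rate_cM_per_Mb[i]`` applies from ``positions_bp[i]`` up to
    ``positions_bp[i+1]``; ``cumulative_cM`` is the genetic distance from an
    arbitrary baseline (maps are treated as translation invariant).
    """

    positions_bp: np.ndarray
    rate_cM_per_Mb: np.ndarray
    cumulative_cM: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "positions_bp", np.asarray(self.positions_bp, dtype=np.int64)
        )
        object.__setattr__(
            self, "rate_cM_per_Mb", np.asarray(self.rate_cM_per_Mb, dtype=float)
        )
        object.__setattr__(
            self, "cumulative_cM", np.asarray(self.cumulative_cM, dtype=float)
        )
        n = len(self.positions_bp)
        if not (len(self.rate_cM_per_Mb) == len(self.cumulative_cM) == n):
            raise PanelFormatError("map columns must have equal length")
        if n == 0:
            raise PanelFormatError("empty genetic map")
        if np.any(np.diff(self.positions_bp) <= 0):
            raise PanelFormatError("map positions must be strictly increasing")
        if np.any(self.rate_cM_per_Mb < 0):
            raise PanelFormatError("recombination rates must be nonnegative")
        if np.any(np.diff(self.cumulative_cM) < 0):
            raise PanelFormatError("cumulative cM must be nondecreasing")

    @property
    def span_bp(self) -> tuple[int, int]:
        return int(self.positions_bp[0]), int(self.positions_bp[-1])

    def cM_at(self, pos_bp) -> np.ndarray | float:
        """Cumulative genetic position (cM) at physical position(s), by linear
        interpolation of the cumulative column inside map intervals."""
        pos = np.asarray(pos_bp)
        lo, hi = self.span_bp
        if np.any(pos < lo) or np.any(pos > hi):
            raise ValueError(
                f"position outside map span [{lo}, {hi}]"
            )
        out = np.interp(pos, self.positions_bp, self.cumulative_cM)
        return float(out) if np.isscalar(pos_bp) else out

    def distance_cM(self, pos_a: int, pos_b: int) -> float:
        """Genetic distance in cM between two physical positions."""
        return float(self.cM_at(pos_b) - self.cM_at(pos_a))

    def scaled(self, weight: float) -> "GeneticMap":
        """Map with rates and cumulative distances multiplied by ``weight``."""
        base = self.cumulative_cM[0]
        return GeneticMap(
            positions_bp=self.positions_bp,
            rate_cM_per_Mb=self.rate_cM_per_Mb * weight,
            cumulative_cM=base + (self.cumulative_cM - base) * weight,
        )


def interval_recomb_fraction(gmap: GeneticMap, pos_a: int, pos_b: int) -> float:
    """Recombination fraction between two positions under the Haldane map
    function (no crossover interference): ``0.5 * (1 - exp(-2 d))`` with *d*
    the genetic distance in Morgans.  Lies in ``[0, 0.5)``.
    """
    if pos_a >= pos_b:
        raise ValueError(f"pos_a must precede pos_b, got {pos_a} >= {pos_b}")
    d_morgans = gmap.distance_cM(pos_a, pos_b) / 100.0
    return 0.5 * (1.0 - math.exp(-2.0 * d_morgans))
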