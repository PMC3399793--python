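"""Simulation-fidelity evaluation: MAF and LD deltas, SD/SE ratios,
stratified summaries, median-delta matrices, and dichotomization
attenuation.

Conventions
-----------
* Deltas are ``replicate - original``, pooled over sites (MAF) or site pairs
  (LD) and over replicates.
* The D' measure used for deltas, strata and SD/SE ratios is the magnitude
  |D'| in [0, 1] (the usual reporting convention, under which a loss of LD is
  a negative delta regardless of a pair's coupling/repulsion orientation);
  r keeps its sign where the SD/SE ratio of r is computed.
* Pairs involving a site monoallelic in a *replicate* are dropped from that
  replicate only; pairs monoallelic in the original panel are dropped
  everywhere (their original LD is undefined).
* Stratum membership (LD and MAF bins) is decided by the ORIGINAL panel.
* Quantiles use linear interpolation between order statistics (type 7);
  SDs use the n-1 denominator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .bvn import bvn_cdf
from .ld import ld_matrices, se_dprime_matrix, se_r
from .panel import HaplotypePanel

__all__ = [
    "DeltaSummary",
    "DeltaResult",
    "RatioSummary",
    "StratifiedReport",
    "delta_maf",
    "delta_ld",
    "sd_se_ratio",
    "stratified_deltas",
    "median_delta_matrix",
    "phi_dichotomized",
]

LD_BIN_EDGES = (0.2, 0.8)
MAF_BIN_EDGES = (0.1, 0.3)
LD_BIN_LABELS = ("<=0.2", "0.2-0.8", ">=0.8")
MAF_BIN_LABELS = ("<=0.1", "0.1-0.3", ">=0.3")

_MEASURES = {"Dprime": "abs_Dprime", "r2": "r2", "r": "r"}


@dataclass(frozen=True)
class DeltaSummary:
    """Eight-number summary of a pooled delta distribution
    (N / Min / Q1 / Median / Q3 / Max / Mean / SD)."""

    n: int
    min: float
    q1: float
    median: float
    q3: float
    max: float
    mean: float
    sd: float

    @classmethod
    def from_values(cls, values: np.ndarray) -> "DeltaSummary":
        v = np.asarray(values, dtype=float)
        v = v[~np.isnan(v)]
        if v.size == 0:
            return cls(0, *(math.nan,) * 7)
        q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
        sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        return cls(
            n=int(v.size),
            min=float(v.min()),
            q1=float(q1),
            median=float(med),
            q3=float(q3),
            max=float(v.max()),
            mean=float(v.mean()),
            sd=sd,
        )

    def as_series(self) -> pd.Series:
        return pd.Series(
            {"N": self.n, "Min": self.min, "Q1": self.q1, "Median": self.median,
             "Q3": self.q3, "Max": self.max, "Mean": self.mean, "SD": self.sd}
        )


@dataclass
class DeltaResult:
    """Pooled deltas plus their summary; ``per_replicate_mean`` gives the
    alternative aggregation (mean delta within each replicate)."""

    deltas: np.ndarray
    summary: DeltaSummary
    per_replicate_mean: np.ndarray


@dataclass(frozen=True)
class RatioSummary:
    """Quartiles of the per-pair (replicate SD) / (original SE) ratio;
    pairs whose original SE is undefined are excluded and counted."""

    measure: str
    n_pairs: int
    n_excluded: int
    median: float
    q1: float
    q3: float


@dataclass
class StratifiedReport:
    """Per-stratum delta summaries, binned by original-panel LD or by
    original-panel MAF (both pair members in the bin)."""

    measure: str
    ld_bins: dict[str, DeltaSummary] = field(default_factory=dict)
    maf_bins: dict[str, DeltaSummary] = field(default_factory=dict)


def _check_alignment(original: HaplotypePanel,
                     replicates: list[HaplotypePanel]) -> None:
    for r, rep in enumerate(replicates):
        if not original.same_sites(rep):
            raise ValueError(f"replicate {r} site list differs from original")


def delta_maf(original: HaplotypePanel,
              replicates: list[HaplotypePanel]) -> DeltaResult:
    """Per-site MAF change (replicate − original), pooled over sites and
    replicates."""
    _check_alignment(original, replicates)
    m0 = original.maf()
    rows = [rep.maf() - m0 for rep in replicates]
    deltas = np.concatenate(rows)
    return DeltaResult(
        deltas=deltas,
        summary=DeltaSummary.from_values(deltas),
        per_replicate_mean=np.array([row.mean() for row in rows]),
    )


def _pair_measure(panel: HaplotypePanel, measure: str) -> np.ndarray:
    try:
        key = _MEASURES[measure]
    except KeyError:
        raise ValueError(
            f"measure must be one of {sorted(_MEASURES)}, got {measure!r}"
        ) from None
    return ld_matrices(panel)[key]


def _delta_stacks(original: HaplotypePanel, replicates: list[HaplotypePanel],
                  measure: str):
    """Upper-triangle original values and per-replicate deltas (NaN where a
    pair is dropped in that replicate)."""
    _check_alignment(original, replicates)
    m0 = _pair_measure(original, measure)
    iu, ju = np.triu_indices(original.n_sites, k=1)
    base = m0[iu, ju]
    rep_deltas = np.vstack([
        _pair_measure(rep, measure)[iu, ju] - base for rep in replicates
    ])
    return iu, ju, base, rep_deltas


def delta_ld(original: HaplotypePanel, replicates: list[HaplotypePanel],
             measure: str = "Dprime") -> DeltaResult:
    """Per-pair LD change (replicate − original) for ``measure`` in
    ``{"Dprime", "r2"}``, pooled over pairs and replicates.

    N counts only pairs defined in both the original panel and the given
    replicate (monoallelic drop rule), so it need not be a multiple of the
    replicate count.
    """
    _, _, _, rep_deltas = _delta_stacks(original, replicates, measure)
    flat = rep_deltas.ravel()
    per_rep = np.array([
        np.nanmean(row) if np.any(~np.isnan(row)) else np.nan
        for row in rep_deltas
    ])
    return DeltaResult(
        deltas=flat[~np.isnan(flat)],
        summary=DeltaSummary.from_values(flat),
        per_replicate_mean=per_rep,
    )


def sd_se_ratio(original: HaplotypePanel, replicates: list[HaplotypePanel],
                measure: str = "Dprime") -> RatioSummary:
    """Per-pair ratio of the across-replicate SD of the LD estimate to the
    original panel's SE of that estimate, summarized by quartiles.

    ``measure`` is ``"Dprime"`` (SE from the asymptotic D' variance) or
    ``"r"`` (SE from the closed-form SE of r).  Pairs with an undefined or
    zero SE, or fewer than two defined replicate values, are excluded and
    counted in ``n_excluded``.
    """
    if len(replicates) < 2:
        raise ValueError("need at least two replicates for an SD")
    _check_alignment(original, replicates)
    iu, ju = np.triu_indices(original.n_sites, k=1)
    if measure == "Dprime":
        se = se_dprime_matrix(original)[iu, ju]
        vals = np.vstack([
            ld_matrices(rep)["abs_Dprime"][iu, ju] for rep in replicates
        ])
    elif measure == "r":
        m = ld_matrices(original)
        r0 = m["r"][iu, ju]
        n = original.n_haplotypes
        se = np.where(np.isnan(r0), np.nan,
                      np.sqrt(np.maximum(0.0, 1.0 - r0**2) / (n - 2)))
        vals = np.vstack([ld_matrices(rep)["r"][iu, ju] for rep in replicates])
    else:
        raise ValueError(f"measure must be 'Dprime' or 'r', got {measure!r}")

    n_def = np.sum(~np.isnan(vals), axis=0)
    with np.errstate(invalid="ignore"):
        sd = np.full(iu.size, np.nan)
        ok_sd = n_def >= 2
        for p in np.flatnonzero(ok_sd):
            v = vals[:, p]
            sd[p] = np.std(v[~np.isnan(v)], ddof=1)
    valid = ok_sd & ~np.isnan(se) & (se > 0.0)
    # pairs undefined in the original panel are not "excluded", they simply
    # have no LD to compare; exclusions count defined pairs we had to drop
    defined0 = ~np.isnan(
        _pair_measure(original, "Dprime" if measure == "Dprime" else "r")
    )[iu, ju]
    n_excluded = int(np.sum(defined0 & ~valid))
    ratios = sd[valid] / se[valid]
    if ratios.size == 0:
        return RatioSummary(measure, 0, n_excluded,
                            math.nan, math.nan, math.nan)
    q1, med, q3 = np.quantile(ratios, [0.25, 0.5, 0.75])
    return RatioSummary(measure, int(ratios.size), n_excluded,
                        float(med), float(q1), float(q3))


def stratified_deltas(original: HaplotypePanel,
                      replicates: list[HaplotypePanel],
                      measure: str = "Dprime") -> StratifiedReport:
    """Delta summaries within LD strata (original-pair LD <= 0.2, 0.2-0.8,
    >= 0.8) and MAF strata (both sites' original MAF <= 0.1, 0.1-0.3,
    >= 0.3)."""
    iu, ju, base, rep_deltas = _delta_stacks(original, replicates, measure)
    report = StratifiedReport(measure=measure)

    lo, hi = LD_BIN_EDGES
    ld_masks = (base <= lo, (base > lo) & (base < hi), base >= hi)
    for label, mask in zip(LD_BIN_LABELS, ld_masks):
        report.ld_bins[label] = DeltaSummary.from_values(
            rep_deltas[:, mask].ravel()
        )

    maf = original.maf()
    ma, mb = maf[iu], maf[ju]
    lo, hi = MAF_BIN_EDGES
    maf_masks = (
        (ma <= lo) & (mb <= lo),
        (ma > lo) & (ma < hi) & (mb > lo) & (mb < hi),
        (ma >= hi) & (mb >= hi),
    )
    for label, mask in zip(MAF_BIN_LABELS, maf_masks):
        report.maf_bins[label] = DeltaSummary.from_values(
            rep_deltas[:, mask].ravel()
        )
    return report


def median_delta_matrix(original: HaplotypePanel,
                        replicates: list[HaplotypePanel],
                        measure: str = "Dprime") -> np.ndarray:
    """Symmetric site-by-site matrix of the across-replicate median of
    (replicate LD − original LD); NaN where undefined in the original or in
    every replicate, and on the diagonal."""
    _check_alignment(original, replicates)
    m0 = _pair_measure(original, measure)
    stack = np.stack([
        _pair_measure(rep, measure) - m0 for rep in replicates
    ])
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pairs
        return np.nanmedian(stack, axis=0)


def phi_dichotomized(rho: float, c1: float, c2: float) -> float:
    """Correlation between indicators ``1{X <= c1}`` and ``1{Y <= c2}`` for
    standard bivariate normal (X, Y) with correlation ``rho``.

    This is the phi coefficient after dichotomizing at the given cut points;
    its magnitude never exceeds |rho| (dichotomization attenuation, the
    mechanism behind the Gaussian-threshold simulator's LD loss).  For
    median cuts it reduces to ``2 arcsin(rho) / pi``.
    """
    if abs(rho) >= 1.0:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    p1 = float(ndtr(c1))
    p2 = float(ndtr(c2))
    p11 = float(bvn_cdf(c1, c2, rho))
    return (p11 - p1 * p2) / math.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
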