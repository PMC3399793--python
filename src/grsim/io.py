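"""Readers and writers for haplotype panels and recombination maps.

Supported formats:

* IMPUTE-style ``.legend`` (header ``id position allele0 allele1``) plus
  ``.hap`` (one row per site of space-separated 0/1 tokens, one column per
  haplotype);
* phased VCF v4.x (biallelic SNPs, ``|``-separated GT, no missing calls),
  read and written through :mod:`pysam`;
* HapMap genetic-map text (header + three whitespace-delimited columns:
  position, rate in cM/Mb, cumulative cM).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pysam

from .panel import GeneticMap, HaplotypePanel, PanelFormatError, SiteRecord

__all__ = [
    "read_hap_legend",
    "write_hap_legend",
    "read_phased_vcf",
    "write_phased_vcf",
    "read_genetic_map",
    "write_genetic_map",
]

_LEGEND_HEADER = ("id", "position", "allele0", "allele1")


def read_hap_legend(hap_path, legend_path, label: str | None = None) -> HaplotypePanel:
    """Read a phased panel from a ``.hap``/``.legend`` pair.

    The legend supplies site metadata in file order; the hap matrix must have
    one row per legend site and a constant number of 0/1 tokens per row.
    """
    legend_path = Path(legend_path)
    hap_path = Path(hap_path)

    sites: list[SiteRecord] = []
    with open(legend_path) as fh:
        header = fh.readline().split()
        if tuple(header[:4]) != _LEGEND_HEADER:
            raise PanelFormatError(
                f"{legend_path}: expected legend header "
                f"'{' '.join(_LEGEND_HEADER)}', got {' '.join(header[:4])!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            tok = line.split()
            if not tok:
                continue
            if len(tok) < 4:
                raise PanelFormatError(
                    f"{legend_path}:{lineno}: expected 4 columns, got {len(tok)}"
                )
            try:
                pos = int(tok[1])
            except ValueError as err:
                raise PanelFormatError(
                    f"{legend_path}:{lineno}: non-integer position {tok[1]!r}"
                ) from err
            sites.append(SiteRecord(tok[0], pos, tok[2], tok[3]))

    rows: list[np.ndarray] = []
    width: int | None = None
    with open(hap_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok:
                continue
            if width is None:
                width = len(tok)
            elif len(tok) != width:
                raise PanelFormatError(
                    f"{hap_path}:{lineno}: ragged row, expected {width} "
                    f"alleles, got {len(tok)}"
                )
            if not set(tok) <= {"0", "1"}:
                bad = sorted(set(tok) - {"0", "1"})
                raise PanelFormatError(
                    f"{hap_path}:{lineno}: non-0/1 token(s) {bad}"
                )
            rows.append(np.fromiter((int(t) for t in tok), dtype=np.uint8))

    if len(rows) != len(sites):
        raise PanelFormatError(
            f"{hap_path}: {len(rows)} hap rows but legend lists "
            f"{len(sites)} sites"
        )
    positions = [s.position_bp for s in sites]
    if any(b <= a for a, b in zip(positions, positions[1:])):
        raise PanelFormatError(
            f"{legend_path}: site positions must be strictly increasing"
        )
    return HaplotypePanel(
        sites=sites,
        alleles=np.vstack(rows),
        label=label if label is not None else hap_path.stem,
    )


def write_hap_legend(panel: HaplotypePanel, hap_path, legend_path) -> None:
    """Write a panel as a ``.hap``/``.legend`` pair (inverse of
    :func:`read_hap_legend`)."""
    with open(legend_path, "w") as fh:
        fh.write(" ".join(_LEGEND_HEADER) + "\n")
        for s in panel.sites:
            fh.write(f"{s.site_id} {s.position_bp} {s.allele0} {s.allele1}\n")
    with open(hap_path, "w") as fh:
        for row in panel.alleles:
            fh.write(" ".join("1" if a else "0" for a in row) + "\n")


def read_phased_vcf(vcf_path, label: str | None = None) -> HaplotypePanel:
    """Read a phased VCF into a panel.

    Each diploid sample contributes two haplotype columns in sample order,
    left allele first; REF maps to 0 and ALT to 1.  Unphased separators,
    missing genotypes and multi-allelic records are errors.
    """
    vcf_path = Path(vcf_path)
    sites: list[SiteRecord] = []
    rows: list[list[int]] = []
    with pysam.VariantFile(os.fspath(vcf_path)) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise PanelFormatError(
                    f"{vcf_path}: record {rec.id or rec.pos} is not biallelic"
                )
            row: list[int] = []
            for sample in rec.samples.values():
                gt = sample["GT"]
                if gt is None or any(a is None for a in gt):
                    raise PanelFormatError(
                        f"{vcf_path}: missing genotype at {rec.pos}"
                    )
                if len(gt) != 2:
                    raise PanelFormatError(
                        f"{vcf_path}: non-diploid genotype at {rec.pos}"
                    )
                if not sample.phased:
                    raise PanelFormatError(
                        f"{vcf_path}: unphased genotype at {rec.pos}"
                    )
                row.extend(int(a) for a in gt)
            sites.append(
                SiteRecord(
                    site_id=rec.id or f"{rec.chrom}:{rec.pos}",
                    position_bp=rec.pos,
                    allele0=rec.ref,
                    allele1=rec.alts[0],
                )
            )
            rows.append(row)
    if not sites:
        raise PanelFormatError(f"{vcf_path}: no variant records")
    return HaplotypePanel(
        sites=sites,
        alleles=np.asarray(rows, dtype=np.uint8),
        label=label if label is not None else vcf_path.stem,
    )


def write_phased_vcf(panel: HaplotypePanel, vcf_path, chrom: str = "1") -> None:
    """Write a panel as a phased VCF, pairing consecutive haplotype columns
    into diploid samples.  Requires an even haplotype count."""
    if panel.n_haplotypes % 2 != 0:
        raise ValueError(
            f"need an even haplotype count to pair into samples, "
            f"got {panel.n_haplotypes}"
        )
    n_samples = panel.n_haplotypes // 2
    header = pysam.VariantHeader()
    header.add_line("##source=grsim")
    header.formats.add("GT", 1, "String", "Genotype")
    header.contigs.add(chrom, length=int(panel.sites[-1].position_bp) + 1)
    for i in range(n_samples):
        header.add_sample(f"S{i}")
    with pysam.VariantFile(os.fspath(vcf_path), "w", header=header) as vcf:
        for s, row in zip(panel.sites, panel.alleles):
            rec = vcf.new_record(
                contig=chrom,
                start=s.position_bp - 1,
                stop=s.position_bp,
                id=s.site_id,
                alleles=(s.allele0, s.allele1),
            )
            for i in range(n_samples):
                rec.samples[i]["GT"] = (int(row[2 * i]), int(row[2 * i + 1]))
                rec.samples[i].phased = True
            vcf.write(rec)


def read_genetic_map(map_path) -> GeneticMap:
    """Read a HapMap-style genetic map (one header line, then columns
    position / rate cM/Mb / cumulative cM)."""
    map_path = Path(map_path)
    data = []
    with open(map_path) as fh:
        fh.readline()  # header
        for lineno, line in enumerate(fh, start=2):
            tok = line.split()
            if not tok:
                continue
            if len(tok) < 3:
                raise PanelFormatError(
                    f"{map_path}:{lineno}: expected 3 columns, got {len(tok)}"
                )
            try:
                data.append((int(float(tok[0])), float(tok[1]), float(tok[2])))
            except ValueError as err:
                raise PanelFormatError(
                    f"{map_path}:{lineno}: unparseable row {line.rstrip()!r}"
                ) from err
    if not data:
        raise PanelFormatError(f"{map_path}: empty map")
    pos, rate, cum = map(np.asarray, zip(*data))
    return GeneticMap(positions_bp=pos, rate_cM_per_Mb=rate, cumulative_cM=cum)


def write_genetic_map(gmap: GeneticMap, map_path) -> None:
    """Write a genetic map in HapMap text format."""
    with open(map_path, "w") as fh:
        fh.write("position COMBINED_rate(cM/Mb) Genetic_Map(cM)\n")
        for p, r, c in zip(gmap.positions_bp, gmap.rate_cM_per_Mb, gmap.cumulative_cM):
            fh.write(f"{int(p)} {r:.10g} {c:.10g}\n")
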