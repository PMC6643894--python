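"""Shared pysam-based VCF writing helpers (plain uncompressed VCF 4.2)."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence

import pysam

from .genome import GenomeBuild


def _header(
    genome: Optional[GenomeBuild],
    contigs: Sequence[str],
    samples: Iterable[str] = (),
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    if genome is not None:
        for c in genome.chromosomes:
            header.contigs.add(c.name, length=c.length)
    else:
        for name in contigs:
            header.contigs.add(name)
    samples = list(samples)
    if samples:
        header.formats.add("GT", 1, "String", "Genotype")
        header.formats.add(
            "AD", "R", "Integer", "Allelic depths for the ref and alt alleles"
        )
        for s in samples:
            header.add_sample(s)
    return header


def _seen_contigs(rows: Sequence[tuple]) -> list[str]:
    return list(dict.fromkeys(r[0] for r in rows))


def write_sites(
    path: str | Path,
    genome: Optional[GenomeBuild],
    sites: Iterable[tuple[str, int, str, str]],
) -> None:
    """Write site-only VCF records ``(chrom, pos, ref, alt)``."""
    rows = list(sites)
    header = _header(genome, _seen_contigs(rows))
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for chrom, pos, ref, alt in rows:
            rec = vf.new_record(
                contig=chrom, start=pos - 1, stop=pos - 1 + len(ref), alleles=(ref, alt)
            )
            vf.write(rec)


def write_genotyped(
    path: str | Path,
    genome: Optional[GenomeBuild],
    sample: str,
    sites: Iterable[tuple[str, int, str, str, tuple[int, int], tuple[int, int]]],
) -> None:
    """Write one-sample records ``(chrom, pos, ref, alt, GT, AD)``."""
    rows = list(sites)
    header = _header(genome, _seen_contigs(rows), [sample])
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for chrom, pos, ref, alt, gt, ad in rows:
            rec = vf.new_record(
                contig=chrom, start=pos - 1, stop=pos, alleles=(ref, alt)
            )
            rec.samples[sample]["GT"] = gt
            rec.samples[sample]["AD"] = ad
            vf.write(rec)
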