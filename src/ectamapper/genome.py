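"""Reference genome, gene models and marker map.

Coordinates are 1-based closed throughout, matching VCF and GFF3. The
genetic map is uniform per chromosome (a constant cM/Mb density), which is
the minimal model needed to simulate recombination when only physical
positions are known.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Chromosome",
    "GenomeBuild",
    "GeneModel",
    "Marker",
    "MarkerMap",
    "read_genome",
    "write_genome",
    "read_gene_models",
    "write_gene_models",
    "read_marker_map",
    "write_marker_map",
    "pos_to_cm",
]

#: Default genetic-map density (cM per Mb). C. elegans averages ~5 cM/Mb
#: over a ~100 Mb genome carrying ~300 cM of map.
DEFAULT_CM_PER_MB = 5.0


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"chromosome {self.name!r}: length must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"chromosome {self.name!r}: sequence length "
                f"{len(self.sequence)} != declared length {self.length}"
            )


@dataclass(frozen=True)
class GenomeBuild:
    """An ordered set of chromosomes plus a uniform genetic-map density."""

    chromosomes: tuple[Chromosome, ...]
    cm_per_mb: float = DEFAULT_CM_PER_MB

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        if self.cm_per_mb <= 0:
            raise ValueError("cm_per_mb must be > 0")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def chrom(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"unknown chromosome {name!r}")

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)

    def base_at(self, chrom: str, pos: int) -> str:
        """Reference base (upper case) at a 1-based position."""
        c = self.chrom(chrom)
        if c.sequence is None:
            raise ValueError(f"chromosome {chrom!r} carries no sequence")
        if not 1 <= pos <= c.length:
            raise ValueError(f"position {pos} outside {chrom} (1..{c.length})")
        return c.sequence[pos - 1].upper()


@dataclass(frozen=True)
class GeneModel:
    """One transcript: exon structure plus CDS intervals with frame.

    Intervals are 1-based closed ``(start, end)``; CDS intervals carry the
    GFF3 frame as a third element. ``complete`` marks models whose CDS is a
    whole open reading frame (length divisible by three).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int, int], ...] = ()
    complete: bool = True

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        _check_sorted_disjoint(self.gene_id, "exons", [(s, e) for s, e in self.exons])
        _check_sorted_disjoint(self.gene_id, "CDS", [(s, e) for s, e, _ in self.cds])
        for s, e, _ in self.cds:
            if not any(es <= s and e <= ee for es, ee in self.exons):
                raise ValueError(
                    f"{self.gene_id}: CDS interval {s}-{e} outside declared exons"
                )
        if self.complete and self.cds and self.cds_length % 3 != 0:
            raise ValueError(
                f"{self.gene_id}: complete model has CDS length "
                f"{self.cds_length}, not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] - self.exons[i][1] > 1
        ]


def _check_sorted_disjoint(gene_id: str, what: str, ivals: list[tuple[int, int]]) -> None:
    prev_end = 0
    for s, e in ivals:
        if s > e:
            raise ValueError(f"{gene_id}: {what} interval {s}-{e} inverted")
        if s <= prev_end:
            raise ValueError(f"{gene_id}: {what} intervals overlap or are unsorted")
        prev_end = e


@dataclass(frozen=True, order=True)
class Marker:
    """A known mapping-strain SNV used as a linkage marker."""

    chrom: str
    pos: int
    ref_allele: str
    map_allele: str

    def __post_init__(self) -> None:
        if self.ref_allele == self.map_allele:
            raise ValueError(f"{self.chrom}:{self.pos}: ref == mapping allele")


class MarkerMap:
    """Position-sorted, unique catalog of mapping-strain SNVs per chromosome."""

    def __init__(self, markers: Iterable[Marker], skipped: int = 0):
        seen: dict[tuple[str, int], Marker] = {}
        unsorted_seen = False
        last: Optional[tuple[str, int]] = None
        for m in markers:
            key = (m.chrom, m.pos)
            if key in seen:
                raise ValueError(f"duplicate marker at {m.chrom}:{m.pos}")
            if last is not None and last[0] == m.chrom and m.pos < last[1]:
                unsorted_seen = True
            seen[key] = m
            last = key
        if unsorted_seen:
            warnings.warn("marker map was unsorted; sorting", stacklevel=2)
        by_chrom: dict[str, list[Marker]] = {}
        for m in seen.values():
            by_chrom.setdefault(m.chrom, []).append(m)
        for lst in by_chrom.values():
            lst.sort(key=lambda m: m.pos)
        self._by_chrom = by_chrom
        #: count of non-SNV records skipped on read (never silently dropped)
        self.skipped = skipped

    @property
    def chroms(self) -> list[str]:
        return list(self._by_chrom)

    def on(self, chrom: str) -> list[Marker]:
        return list(self._by_chrom.get(chrom, []))

    def __iter__(self):
        for chrom in self._by_chrom:
            yield from self._by_chrom[chrom]

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())


# ---------------------------------------------------------------------------
# FASTA


def read_genome(path: str | Path, cm_per_mb: float = DEFAULT_CM_PER_MB) -> GenomeBuild:
    """Load a reference genome from FASTA, one chromosome per record."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    names = [r.id for r in records]
    if len(set(names)) != len(names):
        raise ValueError(f"{path}: duplicate record names")
    chroms = tuple(
        Chromosome(r.id, len(r.seq), str(r.seq).upper()) for r in records
    )
    return GenomeBuild(chroms, cm_per_mb=cm_per_mb)


def write_genome(genome: GenomeBuild, path: str | Path) -> None:
    records = []
    for c in genome.chromosomes:
        if c.sequence is None:
            raise ValueError(f"chromosome {c.name!r} has no sequence to write")
        records.append(SeqRecord(Seq(c.sequence), id=c.name, description=""))
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3


def read_gene_models(path: str | Path, genome: GenomeBuild) -> list[GeneModel]:
    """Parse gene models (one per mRNA) from GFF3.

    Exon and CDS children are attached via their ``Parent`` attributes;
    CDS frame is taken from column 8. A CDS interval outside the declared
    exons, or a seqid absent from *genome*, is an error.
    """
    db = gffutils.create_db(
        str(path), ":memory:", keep_order=True, merge_strategy="create_unique"
    )
    known = set(genome.names)
    models: list[GeneModel] = []
    for mrna in db.features_of_type(("mRNA", "transcript")):
        if mrna.seqid not in known:
            raise ValueError(f"{path}: unknown seqid {mrna.seqid!r}")
        exons = tuple(
            (f.start, f.end)
            for f in db.children(mrna, featuretype="exon", order_by="start")
        )
        cds = tuple(
            (f.start, f.end, int(f.frame) if f.frame != "." else 0)
            for f in db.children(mrna, featuretype="CDS", order_by="start")
        )
        if not exons:  # models given as bare CDS
            exons = tuple((s, e) for s, e, _ in cds)
        models.append(
            GeneModel(
                gene_id=mrna.id,
                chrom=mrna.seqid,
                strand=mrna.strand,
                exons=exons,
                cds=cds,
            )
        )
    return models


def write_gene_models(models: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as minimal, valid GFF3 (gene/mRNA/exon/CDS)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            start, end = g.span
            base = f"{g.chrom}\tectamapper\t"
            tail = f"\t.\t{g.strand}\t"
            fh.write(
                f"{base}gene\t{start}\t{end}{tail}.\tID=gene:{g.gene_id}\n"
            )
            fh.write(
                f"{base}mRNA\t{start}\t{end}{tail}.\t"
                f"ID={g.gene_id};Parent=gene:{g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{base}exon\t{s}\t{e}{tail}.\t"
                    f"ID={g.gene_id}.e{i};Parent={g.gene_id}\n"
                )
            for i, (s, e, frame) in enumerate(g.cds, 1):
                fh.write(
                    f"{base}CDS\t{s}\t{e}{tail}{frame}\t"
                    f"ID={g.gene_id}.c{i};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# Marker map VCF

_BASES = {"A", "C", "G", "T"}


def read_marker_map(path: str | Path) -> MarkerMap:
    """Read the catalog of known mapping-strain SNVs from VCF 4.2.

    Only biallelic SNV records become markers; indels and multiallelic
    records are skipped and counted on the returned map's ``skipped``
    attribute.
    """
    import pysam

    markers: list[Marker] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf.fetch() if vf.index is not None else vf:
            alts = rec.alts or ()
            if (
                len(alts) != 1
                or len(rec.ref) != 1
                or len(alts[0]) != 1
                or rec.ref.upper() not in _BASES
                or alts[0].upper() not in _BASES
            ):
                skipped += 1
                continue
            markers.append(
                Marker(rec.chrom, rec.pos, rec.ref.upper(), alts[0].upper())
            )
    return MarkerMap(markers, skipped=skipped)


def write_marker_map(
    markers: MarkerMap, genome: GenomeBuild, path: str | Path
) -> None:
    from . import _vcf

    _vcf.write_sites(
        path,
        genome,
        ((m.chrom, m.pos, m.ref_allele, m.map_allele) for m in markers),
    )


# ---------------------------------------------------------------------------
# Genetic coordinates


def pos_to_cm(genome: GenomeBuild, chrom: str, pos: float) -> float:
    """Physical position (bp) to genetic position (cM) on the uniform map.

    The map is linear: ``pos / 1e6 * cm_per_mb``. Position 0 (the
    chromosome origin in zero-offset terms) maps to 0 cM; positions up to
    the chromosome length are accepted.
    """
    c = genome.chrom(chrom)
    if not 0 <= pos <= c.length:
        raise ValueError(f"position {pos} outside {chrom} (0..{c.length})")
    return pos / 1e6 * genome.cm_per_mb
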