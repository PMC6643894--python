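"""Codon-level consequence annotation of SNVs against gene models.

Classifies each variant as intergenic, intronic, splice_site, synonymous,
missense, nonsense, stop_lost or start_lost, with HGVS-like protein
change notation (e.g. ``W123*``) for coding classes. One annotation is
emitted per overlapping transcript; a severity-ranked shortlist within a
mapped interval supports candidate prioritization.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from Bio.Seq import Seq

from .genome import GeneModel, GenomeBuild
from .linkage import LinkageCall
from .variants import Variant

__all__ = [
    "EffectAnnotation",
    "RefMismatchError",
    "annotate_variant",
    "annotate_set",
    "enumerate_cds_effects",
    "prioritize_candidates",
    "most_severe_per_gene",
    "write_annotation_tsv",
    "SEVERITY_RANK",
]

#: splice window: this many bases into the intron from either boundary
SPLICE_WINDOW = 2

CODING_CLASSES = {"synonymous", "missense", "nonsense", "stop_lost", "start_lost"}

#: severity groups for prioritization (lower rank = more severe)
SEVERITY_RANK = {
    "nonsense": 0,
    "splice_site": 0,
    "start_lost": 0,
    "stop_lost": 0,
    "missense": 1,
    "synonymous": 2,
    "intronic": 3,
    "intergenic": 4,
}


class RefMismatchError(ValueError):
    """The variant's declared REF does not match the reference sequence."""


@dataclass(frozen=True)
class EffectAnnotation:
    variant: Variant
    gene_id: Optional[str]
    effect_class: str
    protein_change: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.protein_change is not None) != (self.effect_class in CODING_CLASSES):
            raise ValueError(
                "protein_change must be present exactly for coding classes"
            )


def _cds_index(gene: GeneModel, pos: int) -> Optional[int]:
    """0-based index of a genomic position within the spliced CDS, 5'→3'."""
    ivals = list(gene.cds)
    if gene.strand == "-":
        ivals = ivals[::-1]
    offset = 0
    for s, e, _frame in ivals:
        if s <= pos <= e:
            return offset + (pos - s if gene.strand == "+" else e - pos)
        offset += e - s + 1
    return None


def _cds_sequence(gene: GeneModel, genome: GenomeBuild) -> str:
    c = genome.chrom(gene.chrom)
    if c.sequence is None:
        raise ValueError(f"chromosome {gene.chrom!r} carries no sequence")
    seq = "".join(c.sequence[s - 1 : e].upper() for s, e, _ in gene.cds)
    if gene.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def _classify_cds_snv(cds_seq: str, idx: int, alt_coding: str) -> tuple[str, str]:
    """Class + protein notation for a substitution at CDS index *idx*."""
    codon_i = idx // 3
    within = idx % 3
    codon = cds_seq[3 * codon_i : 3 * codon_i + 3]
    alt_codon = codon[:within] + alt_coding + codon[within + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    change = f"{aa_ref}{codon_i + 1}{aa_alt}"
    if codon_i == 0:
        # any substitution in the initiator codon abolishes the canonical start
        return "start_lost", change
    if aa_ref == aa_alt:
        return "synonymous", change
    if aa_ref == "*":
        return "stop_lost", change
    if aa_alt == "*":
        return "nonsense", change
    return "missense", change


def annotate_variant(
    v: Variant, genes: Sequence[GeneModel], genome: GenomeBuild
) -> list[EffectAnnotation]:
    """Annotate one SNV against every overlapping transcript.

    The declared REF is verified against the genome sequence (a mismatch
    is an error naming the position). Reverse-strand transcripts translate
    reverse-complemented alleles; the standard nuclear genetic code is
    used. If no transcript overlaps, a single intergenic record is
    returned. Output order follows the input gene order (deterministic).
    """
    ref_here = genome.base_at(v.chrom, v.pos)
    if ref_here != v.ref.upper():
        raise RefMismatchError(
            f"{v.chrom}:{v.pos}: variant REF {v.ref!r} != reference {ref_here!r}"
        )

    out: list[EffectAnnotation] = []
    for gene in genes:
        if gene.chrom != v.chrom:
            continue
        span = gene.span
        if not span[0] <= v.pos <= span[1]:
            continue
        # splice sites: within SPLICE_WINDOW bp inside an intron boundary
        splice = any(
            s <= v.pos <= min(s + SPLICE_WINDOW - 1, e)
            or max(e - SPLICE_WINDOW + 1, s) <= v.pos <= e
            for s, e in gene.introns
        )
        if splice:
            out.append(EffectAnnotation(v, gene.gene_id, "splice_site"))
            continue
        idx = _cds_index(gene, v.pos) if gene.cds else None
        if idx is None:
            out.append(EffectAnnotation(v, gene.gene_id, "intronic"))
            continue
        cds_seq = _cds_sequence(gene, genome)
        alt_coding = (
            v.alt.upper()
            if gene.strand == "+"
            else str(Seq(v.alt.upper()).complement())
        )
        cls, change = _classify_cds_snv(cds_seq, idx, alt_coding)
        out.append(EffectAnnotation(v, gene.gene_id, cls, change))
    if not out:
        out.append(EffectAnnotation(v, None, "intergenic"))
    return out


def annotate_set(
    variants, genes: Sequence[GeneModel], genome: GenomeBuild
) -> list[EffectAnnotation]:
    out: list[EffectAnnotation] = []
    for v in variants:
        out.extend(annotate_variant(v, genes, genome))
    return out


def enumerate_cds_effects(gene: GeneModel, genome: GenomeBuild) -> pd.DataFrame:
    """Every possible SNV in the CDS, with its effect class.

    Returns 3 rows (alt alleles) per CDS base. Classes are produced by
    ``annotate_variant`` so the table doubles as an exhaustive oracle
    input for cross-checking against full-CDS re-translation.
    """
    if not gene.cds:
        raise ValueError(f"{gene.gene_id}: no CDS")
    if gene.cds_length % 3 != 0:
        raise ValueError(f"{gene.gene_id}: incomplete CDS")
    rows = []
    for s, e, _frame in gene.cds:
        for pos in range(s, e + 1):
            ref = genome.base_at(gene.chrom, pos)
            for alt in "ACGT":
                if alt == ref:
                    continue
                v = Variant(gene.chrom, pos, ref, alt)
                anns = [
                    a
                    for a in annotate_variant(v, [gene], genome)
                    if a.gene_id == gene.gene_id
                ]
                rows.append(
                    {
                        "chrom": gene.chrom,
                        "pos": pos,
                        "ref": ref,
                        "alt": alt,
                        "gene_id": gene.gene_id,
                        "effect_class": anns[0].effect_class,
                        "protein_change": anns[0].protein_change,
                    }
                )
    return pd.DataFrame(rows)


def prioritize_candidates(
    annotated: Sequence[EffectAnnotation], call: LinkageCall
) -> list[EffectAnnotation]:
    """Severity-ranked shortlist of annotations inside the mapped interval.

    Keeps annotations on the linked chromosome within the candidate
    interval, ordered most-severe first (nonsense/splice/start/stop loss,
    then missense, synonymous, intronic, intergenic), stable by position
    within a rank. An empty shortlist is a legitimate outcome.
    """
    if not call.linked or call.interval is None:
        raise ValueError("candidate prioritization requires a linked interval")
    start, end = call.interval
    kept = [
        a
        for a in annotated
        if a.variant.chrom == call.chrom and start <= a.variant.pos <= end
    ]
    kept.sort(key=lambda a: (SEVERITY_RANK[a.effect_class], a.variant.pos))
    return kept


def most_severe_per_gene(
    annotated: Sequence[EffectAnnotation],
) -> dict[str, EffectAnnotation]:
    """Collapse to the single most severe annotation per gene (summary view)."""
    best: dict[str, EffectAnnotation] = {}
    for a in annotated:
        if a.gene_id is None:
            continue
        cur = best.get(a.gene_id)
        if cur is None or SEVERITY_RANK[a.effect_class] < SEVERITY_RANK[cur.effect_class]:
            best[a.gene_id] = a
    return best


def write_annotation_tsv(
    annotated: Sequence[EffectAnnotation], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tgene_id\teffect_class\tprotein_change\n")
        for a in annotated:
            v = a.variant
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t"
                f"{a.gene_id or '.'}\t{a.effect_class}\t{a.protein_change or '.'}\n"
            )
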