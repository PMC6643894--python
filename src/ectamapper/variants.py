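"""Variant-set algebra: exclusive lists by subtraction and sibling detection.

A screen yields many independently mutagenized strains. Variants shared
between strains are either background (pre-existing in the parental
strain) or evidence of a sibling relationship — two isolates descending
from the same mutagenized F1. Subtracting every other strain's calls from
a strain's call set leaves its *exclusive* list, the candidate set for its
phenotype; near-complete sharing of induced variants identifies siblings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "Variant",
    "VariantSet",
    "read_variants",
    "write_variants",
    "subtract",
    "jaccard",
    "detect_siblings",
    "write_sibling_report",
]

_BASES = {"A", "C", "G", "T"}

VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True, order=True)
class Variant:
    """A biallelic SNV keyed by (chrom, pos, ref, alt)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"{self.chrom}:{self.pos}: ref == alt")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(f"{self.chrom}:{self.pos}: only SNVs are modeled")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


class VariantSet:
    """One strain's called variants, with set semantics on exact keys.

    Presence/absence only: genotype and quality fields play no role in the
    subtraction or overlap logic.
    """

    def __init__(self, strain_id: str, variants: Iterable[Variant] = (), skipped: int = 0):
        self.strain_id = strain_id
        self._by_key: dict[VariantKey, Variant] = {}
        for v in variants:
            self._by_key[v.key] = v
        self.skipped = skipped

    def __len__(self) -> int:
        return len(self._by_key)

    def __contains__(self, v: Variant) -> bool:
        return v.key in self._by_key

    def __iter__(self):
        """Iterate in sorted (chrom, pos, ref, alt) order."""
        return iter(sorted(self._by_key.values()))

    @property
    def keys(self) -> frozenset[VariantKey]:
        return frozenset(self._by_key)

    def add(self, v: Variant) -> None:
        self._by_key[v.key] = v

    def __repr__(self) -> str:
        return f"VariantSet({self.strain_id!r}, n={len(self)})"


def read_variants(path: str | Path, strain_id: Optional[str] = None) -> VariantSet:
    """Read a strain's biallelic SNVs from VCF 4.2.

    Non-SNV and multiallelic records are skipped and counted on the result's
    ``skipped`` attribute. The strain id defaults to the file stem.
    """
    import pysam

    if strain_id is None:
        strain_id = Path(path).stem
    out: list[Variant] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
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
            out.append(Variant(rec.chrom, rec.pos, rec.ref.upper(), alts[0].upper()))
    return VariantSet(strain_id, out, skipped=skipped)


def write_variants(vs: VariantSet, path: str | Path, genome=None) -> None:
    """Write a variant set as site-sorted VCF 4.2."""
    from . import _vcf

    _vcf.write_sites(path, genome, ((v.chrom, v.pos, v.ref, v.alt) for v in vs))


def subtract(target: VariantSet, others: Sequence[VariantSet]) -> VariantSet:
    """Exclusive list: variants of *target* present in none of *others*."""
    excluded: set[VariantKey] = set()
    for o in others:
        excluded |= o.keys
    kept = [v for v in target if v.key not in excluded]
    return VariantSet(target.strain_id, kept)


def jaccard(a: VariantSet, b: VariantSet) -> float:
    """|A∩B| / |A∪B| on variant keys; 0 when both sets are empty."""
    union = a.keys | b.keys
    if not union:
        return 0.0
    return len(a.keys & b.keys) / len(union)


def detect_siblings(
    strains: Sequence[VariantSet], threshold: float = 0.5
) -> list[list[str]]:
    """Partition strains into sibling groups by single-linkage overlap.

    Strains whose pairwise Jaccard overlap reaches *threshold* are linked;
    connected components are sibling groups. True siblings share one
    mutagenized genome and hence the bulk of their induced variants, while
    independent strains share essentially none, so the default threshold of
    0.5 separates the two regimes by a wide margin.

    Groups are ordered by their lexicographically first strain id, members
    sorted within each group, so output is independent of input order.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    n = len(strains)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if jaccard(strains[i], strains[j]) >= threshold:
                parent[find(i)] = find(j)

    groups: dict[int, list[str]] = {}
    for i, s in enumerate(strains):
        groups.setdefault(find(i), []).append(s.strain_id)
    out = [sorted(g) for g in groups.values()]
    out.sort(key=lambda g: g[0])
    return out


def write_sibling_report(
    strains: Sequence[VariantSet],
    groups: Sequence[Sequence[str]],
    path: str | Path,
) -> None:
    """TSV report: strain_id, group_id, max pairwise overlap with any other."""
    by_id = {s.strain_id: s for s in strains}
    with open(path, "w") as fh:
        fh.write("strain_id\tgroup_id\tmax_pairwise_jaccard\n")
        for gid, group in enumerate(groups, 1):
            for sid in group:
                best = max(
                    (
                        jaccard(by_id[sid], other)
                        for other in strains
                        if other.strain_id != sid
                    ),
                    default=0.0,
                )
                fh.write(f"{sid}\t{gid}\t{best:.4f}\n")
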