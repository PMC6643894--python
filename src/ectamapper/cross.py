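"""Synthetic mapping-cross engine.

Emulates the wet-lab procedure behind mapping-by-sequencing of a recessive
C. elegans mutant: EMS mutagenesis of a homozygous strain, a cross to a
polymorphic mapping strain (the "Hawaiian" isolate CB4856, whose known
SNVs serve as markers), phenotype-based selection of F2 animals that are
homozygous for the causal variant, and pooled sequencing of the selected
animals read out as per-marker allele depths.

The genetics that make the method work: every selected F2 carries two
gametes bearing the mutant allele at the causal site, and such a gamete
carries the mapping-strain allele at a marker only if a recombination
event separated marker and causal locus. Under a no-interference
(Haldane) model the expected pooled mapping-allele frequency at genetic
distance d is therefore exactly the recombination fraction
r(d) = (1 - exp(-2d/100)) / 2 (d in cM), rising from 0 at the causal
locus to 0.5 on unlinked chromosomes. That closed form is the oracle the
simulator is tested against.

All randomness flows from a single seed; identical configurations produce
bit-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .genome import Chromosome, GenomeBuild, GeneModel, Marker, MarkerMap, pos_to_cm
from .variants import Variant, VariantSet

__all__ = [
    "DEFAULT_EMS_SPECTRUM",
    "CrossConfig",
    "MutantStrain",
    "F2Pool",
    "AlleleCounts",
    "mutagenize",
    "make_sibling",
    "haldane_r",
    "simulate_meiosis",
    "simulate_cross",
    "gate_f2",
    "simulate_pool_readcounts",
    "write_pool_vcf",
    "read_pool_counts",
    "write_strain_vcf",
    "write_truth",
    "synthetic_genome",
    "synthetic_marker_map",
]

_BASES = ("A", "C", "G", "T")


def _default_spectrum() -> dict[tuple[str, str], float]:
    """EMS substitution spectrum: 87% G:C→A:T transitions, remainder uniform.

    EMS alkylates guanine, so the canonical spectrum is dominated by
    G→A / C→T transitions; the residual 13% is split evenly over the ten
    other single-base substitutions.
    """
    spectrum = {("G", "A"): 0.435, ("C", "T"): 0.435}
    others = [
        (r, a) for r in _BASES for a in _BASES if r != a and (r, a) not in spectrum
    ]
    for key in others:
        spectrum[key] = 0.13 / len(others)
    return spectrum


DEFAULT_EMS_SPECTRUM = _default_spectrum()

#: effect classes that count as damaging when constraining the causal variant
_DAMAGING = {"missense", "nonsense", "splice_site", "start_lost", "stop_lost"}


@dataclass
class CrossConfig:
    """Parameters of one simulated screen cross.

    n_f2
        number of phenotype-selected F2 animals pooled for sequencing
        (the protocol singles >15; default 50).
    depth
        mean sequencing depth per marker site (Poisson).
    error_rate
        per-read allele miscall probability (flips to the other allele).
    mutation_rate
        induced EMS variants per bp (default 3e-6, ~300 per 100 Mb genome
        for a standard 50 mM dose).
    spectrum
        probability table over (ref, alt) substitution types.
    seed
        master seed; every stochastic operation derives from it.
    """

    n_f2: int = 50
    depth: float = 30.0
    error_rate: float = 0.002
    mutation_rate: float = 3e-6
    spectrum: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_EMS_SPECTRUM)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_f2 < 1:
            raise ValueError("n_f2 must be >= 1")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.mutation_rate < 0:
            raise ValueError("mutation_rate must be >= 0")
        total = sum(self.spectrum.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"spectrum must sum to 1 (got {total})")
        for ref, alt in self.spectrum:
            if ref not in _BASES or alt not in _BASES or ref == alt:
                raise ValueError(f"bad substitution type {ref}->{alt}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class MutantStrain:
    """A homozygous EMS-mutagenized strain with one designated causal variant."""

    strain_id: str
    variants: VariantSet
    causal: Optional[Variant]

    def __post_init__(self) -> None:
        if self.causal is not None and self.causal not in self.variants:
            raise ValueError("causal variant must be among the induced variants")


@dataclass
class F2Pool:
    """Genotypes of the selected F2 pool at the marker sites.

    ``genotypes`` is an (n_animals, n_markers) matrix of mapping-strain
    allele counts in {0, 1, 2}, columns in the marker map's iteration
    order. Every animal is homozygous mutant at the causal site by
    construction (phenotype selection).
    """

    markers: MarkerMap
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        if self.genotypes.shape[1] != len(self.markers):
            raise ValueError("genotype matrix does not match marker count")

    @property
    def map_allele_freq(self) -> np.ndarray:
        """True per-marker mapping-strain allele frequency in the pool."""
        return self.genotypes.mean(axis=0) / 2.0


@dataclass
class AlleleCounts:
    """Per-marker sequencing read counts for ref and mapping alleles."""

    chrom: np.ndarray
    pos: np.ndarray
    ref_allele: np.ndarray
    map_allele: np.ndarray
    ref_count: np.ndarray
    map_count: np.ndarray

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def depth(self) -> np.ndarray:
        return self.ref_count + self.map_count


# ---------------------------------------------------------------------------
# Mutagenesis


def _sample_site(
    genome: GenomeBuild,
    ref_base: str,
    rng: np.random.Generator,
    used: set[tuple[str, int]],
    max_tries: int = 100_000,
) -> tuple[str, int]:
    """Uniformly sample an unused genomic site whose reference base matches."""
    lengths = np.array([c.length for c in genome.chromosomes], dtype=float)
    probs = lengths / lengths.sum()
    for _ in range(max_tries):
        ci = rng.choice(len(lengths), p=probs)
        c = genome.chromosomes[ci]
        pos = int(rng.integers(1, c.length + 1))
        if (c.name, pos) in used:
            continue
        if c.sequence[pos - 1].upper() == ref_base:
            return c.name, pos
    raise RuntimeError(f"could not place a {ref_base} substitution site")


def mutagenize(
    genome: GenomeBuild,
    config: CrossConfig,
    rng: Optional[np.random.Generator] = None,
    strain_id: str = "strain1",
    causal_genes: Optional[Sequence[GeneModel]] = None,
    require_damaging: bool = False,
    require_causal: bool = True,
) -> MutantStrain:
    """Simulate EMS mutagenesis of a homozygous strain.

    The induced variant count is Poisson(mutation_rate × genome size);
    substitution types are drawn from the configured spectrum and placed
    at uniformly random sites carrying the matching reference base. One
    variant is designated causal — drawn uniformly from the induced set,
    or, if *causal_genes* is given, placed inside one of those genes' CDS
    (optionally constrained to a damaging consequence).
    """
    if rng is None:
        rng = config.rng()
    if any(c.sequence is None for c in genome.chromosomes):
        raise ValueError("mutagenize requires chromosome sequences")

    n = int(rng.poisson(config.mutation_rate * genome.total_length))
    types = list(config.spectrum)
    probs = np.array([config.spectrum[t] for t in types])
    used: set[tuple[str, int]] = set()
    out: list[Variant] = []
    for _ in range(n):
        ref, alt = types[rng.choice(len(types), p=probs)]
        chrom, pos = _sample_site(genome, ref, rng, used)
        used.add((chrom, pos))
        out.append(Variant(chrom, pos, ref, alt))

    causal: Optional[Variant] = None
    if causal_genes is not None:
        causal = _sample_causal_in_cds(
            genome, config, rng, causal_genes, require_damaging, used
        )
        out = [v for v in out if (v.chrom, v.pos) != (causal.chrom, causal.pos)]
        out.append(causal)
    elif require_causal:
        if not out:
            raise ValueError(
                "no induced variants to pick a causal variant from "
                "(mutation_rate x genome size is too small)"
            )
        causal = out[int(rng.integers(len(out)))]

    return MutantStrain(strain_id, VariantSet(strain_id, out), causal)


def _sample_causal_in_cds(
    genome: GenomeBuild,
    config: CrossConfig,
    rng: np.random.Generator,
    genes: Sequence[GeneModel],
    require_damaging: bool,
    used: set[tuple[str, int]],
    max_tries: int = 10_000,
) -> Variant:
    from . import effects

    types = list(config.spectrum)
    probs = np.array([config.spectrum[t] for t in types])
    for _ in range(max_tries):
        gene = genes[int(rng.integers(len(genes)))]
        s, e, _frame = gene.cds[int(rng.integers(len(gene.cds)))]
        pos = int(rng.integers(s, e + 1))
        ref = genome.base_at(gene.chrom, pos)
        # condition the spectrum on the reference base at the chosen site
        idx = [i for i, (r, _a) in enumerate(types) if r == ref]
        if not idx:
            continue
        p = probs[idx] / probs[idx].sum()
        ref_alt = types[idx[int(rng.choice(len(idx), p=p))]]
        v = Variant(gene.chrom, pos, ref_alt[0], ref_alt[1])
        if require_damaging:
            anns = effects.annotate_variant(v, [gene], genome)
            if not any(a.effect_class in _DAMAGING for a in anns):
                continue
        return v
    raise RuntimeError("could not place a causal CDS variant")


def make_sibling(
    strain: MutantStrain,
    genome: GenomeBuild,
    config: CrossConfig,
    rng: np.random.Generator,
    strain_id: str,
    private_fraction: float = 0.05,
) -> MutantStrain:
    """Derive a sibling strain: same mutagenized genome plus private noise.

    Siblings descend from the same mutagenized F1, so they share the
    induced variant set (including the causal variant); each isolate
    additionally accumulates a small number of private calls —
    *private_fraction* of the shared count — modeling call noise and
    independent late mutations.
    """
    shared = list(strain.variants)
    n_private = int(round(private_fraction * len(shared)))
    used = {(v.chrom, v.pos) for v in shared}
    types = list(config.spectrum)
    probs = np.array([config.spectrum[t] for t in types])
    private: list[Variant] = []
    for _ in range(n_private):
        ref, alt = types[rng.choice(len(types), p=probs)]
        chrom, pos = _sample_site(genome, ref, rng, used)
        used.add((chrom, pos))
        private.append(Variant(chrom, pos, ref, alt))
    return MutantStrain(
        strain_id, VariantSet(strain_id, shared + private), strain.causal
    )


# ---------------------------------------------------------------------------
# Meiosis and the cross


def haldane_r(d_cm: float) -> float:
    """Haldane map function: genetic distance (cM) → recombination fraction.

    r = (1 - exp(-2d/100)) / 2 assuming crossovers are Poisson with no
    interference; r rises monotonically from 0 to an asymptote of 0.5.
    """
    if d_cm < 0:
        raise ValueError("genetic distance must be >= 0")
    return (1.0 - math.exp(-2.0 * d_cm / 100.0)) / 2.0


def simulate_meiosis(
    hetero_chrom: tuple[np.ndarray, np.ndarray],
    positions: np.ndarray,
    genome: GenomeBuild,
    chrom: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one gamete haplotype from a heterozygous chromosome pair.

    *hetero_chrom* is the pair of parental haplotypes, each an allele
    array over *positions* (bp, sorted). Crossover count is Poisson in the
    chromosome's genetic length (Morgans), crossover positions uniform on
    the genetic map, and the gamete alternates parental origin at each
    crossover, starting from a uniformly chosen parent.
    """
    hap_a, hap_b = hetero_chrom
    positions = np.asarray(positions)
    if len(positions) == 0:
        return np.empty(0, dtype=hap_a.dtype if hasattr(hap_a, "dtype") else int)
    length_cm = pos_to_cm(genome, chrom, genome.chrom(chrom).length)
    n_xo = rng.poisson(length_cm / 100.0)
    start = int(rng.integers(2))
    if n_xo == 0:
        return (hap_a if start == 0 else hap_b).copy()
    xo_cm = np.sort(rng.uniform(0.0, length_cm, size=n_xo))
    pos_cm = positions / 1e6 * genome.cm_per_mb
    parity = (start + np.searchsorted(xo_cm, pos_cm, side="right")) % 2
    return np.where(parity == 0, hap_a, hap_b)


def simulate_cross(
    strain: MutantStrain,
    markers: MarkerMap,
    genome: GenomeBuild,
    config: CrossConfig,
    rng: Optional[np.random.Generator] = None,
) -> F2Pool:
    """Simulate the mapping cross and phenotype-based F2 selection.

    The mutant is crossed to the mapping strain; the F1 is uniformly
    heterozygous. Each candidate F2 is formed from two independent F1
    gametes and retained iff homozygous for the causal (non-mapping)
    allele — the genetic meaning of selecting recessive phenotype-positive
    animals. Exactly ``config.n_f2`` retained animals are returned.

    Because chromosomes assort independently, the non-causal chromosomes
    are simulated only for the animals that pass selection; this is
    distributionally identical to simulating everything and rejecting.
    """
    if rng is None:
        rng = config.rng()
    if strain.causal is None:
        raise ValueError("strain has no causal variant; selection impossible")
    causal = strain.causal
    if causal.chrom not in genome.names:
        raise ValueError(f"causal chromosome {causal.chrom!r} not in genome")
    if not markers.on(causal.chrom):
        raise ValueError(
            f"causal chromosome {causal.chrom!r} carries no markers"
        )

    marker_chroms = markers.chroms
    # positions on the causal chromosome: markers plus the causal site
    cpos = np.array([m.pos for m in markers.on(causal.chrom)])
    causal_idx = np.searchsorted(cpos, causal.pos)
    causal_is_marker = causal_idx < len(cpos) and cpos[causal_idx] == causal.pos
    if not causal_is_marker:
        cpos_full = np.insert(cpos, causal_idx, causal.pos)
    else:
        cpos_full = cpos
    keep = np.ones(len(cpos_full), dtype=bool)
    if not causal_is_marker:
        keep[causal_idx] = False

    n = config.n_f2
    # haplotype coding: 0 = mutant parent (non-mapping allele), 1 = mapping
    hap_mut = np.zeros(len(cpos_full), dtype=np.int8)
    hap_map = np.ones(len(cpos_full), dtype=np.int8)
    causal_rows: list[np.ndarray] = []
    max_tries = max(200 * n, 10_000)
    tries = 0
    while len(causal_rows) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("F2 selection failed to accept enough animals")
        g1 = simulate_meiosis((hap_mut, hap_map), cpos_full, genome, causal.chrom, rng)
        g2 = simulate_meiosis((hap_mut, hap_map), cpos_full, genome, causal.chrom, rng)
        if g1[causal_idx] == 0 and g2[causal_idx] == 0:
            causal_rows.append((g1 + g2)[keep])

    blocks: dict[str, np.ndarray] = {causal.chrom: np.array(causal_rows, dtype=np.int8)}
    for chrom in marker_chroms:
        if chrom == causal.chrom:
            continue
        pos = np.array([m.pos for m in markers.on(chrom)])
        hm = np.zeros(len(pos), dtype=np.int8)
        hp = np.ones(len(pos), dtype=np.int8)
        rows = [
            simulate_meiosis((hm, hp), pos, genome, chrom, rng)
            + simulate_meiosis((hm, hp), pos, genome, chrom, rng)
            for _ in range(n)
        ]
        blocks[chrom] = np.array(rows, dtype=np.int8)

    genotypes = np.concatenate([blocks[c] for c in marker_chroms], axis=1)
    return F2Pool(markers, genotypes)


def gate_f2(
    candidates: Sequence[tuple[float, float]],
    size_range: tuple[float, float],
    fluor_min: float,
) -> list[int]:
    """Sorter-style gate on (size, fluorescence) event records.

    Mimics selecting objects of wild-type size but elevated fluorescence
    on a worm sorter: returns the indices, in input order, whose size lies
    within *size_range* (inclusive) and fluorescence is >= *fluor_min*.
    """
    lo, hi = size_range
    return [
        i
        for i, (size, fluor) in enumerate(candidates)
        if lo <= size <= hi and fluor >= fluor_min
    ]


# ---------------------------------------------------------------------------
# Pooled sequencing


def simulate_pool_readcounts(
    pool: F2Pool,
    markers: MarkerMap,
    config: CrossConfig,
    rng: Optional[np.random.Generator] = None,
) -> AlleleCounts:
    """Sequence the pooled F2 DNA at marker sites (allele-depth level).

    Total depth per marker is Poisson(depth); each read samples an allele
    at the pool's true frequency and is miscalled (flipped to the other
    allele) with probability error_rate. The observed mapping-allele
    probability per read is thus f(1-eps) + (1-f)eps.
    """
    if rng is None:
        rng = config.rng()
    if pool.genotypes.shape[0] == 0:
        raise ValueError("empty pool")
    f = pool.map_allele_freq
    eps = config.error_rate
    p_obs = f * (1 - eps) + (1 - f) * eps
    depth = rng.poisson(config.depth, size=len(f))
    map_count = rng.binomial(depth, p_obs)
    ref_count = depth - map_count
    mlist = list(markers)
    return AlleleCounts(
        chrom=np.array([m.chrom for m in mlist]),
        pos=np.array([m.pos for m in mlist]),
        ref_allele=np.array([m.ref_allele for m in mlist]),
        map_allele=np.array([m.map_allele for m in mlist]),
        ref_count=ref_count.astype(np.int64),
        map_count=map_count.astype(np.int64),
    )


def write_pool_vcf(
    counts: AlleleCounts,
    genome: Optional[GenomeBuild],
    path: str | Path,
    sample: str = "pool",
) -> None:
    """Write pooled allele depths as a one-sample VCF with AD fields."""
    from . import _vcf

    def _gt(r: int, m: int) -> tuple[int, int]:
        if m == 0:
            return (0, 0)
        if r == 0:
            return (1, 1)
        return (0, 1)

    _vcf.write_genotyped(
        path,
        genome,
        sample,
        (
            (
                str(counts.chrom[i]),
                int(counts.pos[i]),
                str(counts.ref_allele[i]),
                str(counts.map_allele[i]),
                _gt(int(counts.ref_count[i]), int(counts.map_count[i])),
                (int(counts.ref_count[i]), int(counts.map_count[i])),
            )
            for i in range(len(counts))
        ),
    )


def read_pool_counts(path: str | Path) -> AlleleCounts:
    """Read per-site allele depths (AD of the first sample) from VCF."""
    import pysam

    chrom, pos, ref, alt, rc, mc = [], [], [], [], [], []
    with pysam.VariantFile(str(path)) as vf:
        if not vf.header.samples:
            raise ValueError(f"{path}: pooled VCF has no sample column")
        sample = vf.header.samples[0]
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            ad = rec.samples[sample].get("AD")
            if ad is None or len(ad) < 2 or ad[0] is None:
                continue
            chrom.append(rec.chrom)
            pos.append(rec.pos)
            ref.append(rec.ref.upper())
            alt.append(rec.alts[0].upper())
            rc.append(int(ad[0]))
            mc.append(int(ad[1]))
    return AlleleCounts(
        chrom=np.array(chrom),
        pos=np.array(pos, dtype=np.int64),
        ref_allele=np.array(ref),
        map_allele=np.array(alt),
        ref_count=np.array(rc, dtype=np.int64),
        map_count=np.array(mc, dtype=np.int64),
    )


def write_strain_vcf(
    strain: MutantStrain, genome: Optional[GenomeBuild], path: str | Path
) -> None:
    """Write the strain's homozygous induced variants (GT 1/1, depth-free)."""
    from . import _vcf

    _vcf.write_sites(
        path, genome, ((v.chrom, v.pos, v.ref, v.alt) for v in strain.variants)
    )


def write_truth(strain: MutantStrain, config: CrossConfig, path: str | Path) -> None:
    """Write the simulation ground truth (causal site + config echo) as TSV."""
    with open(path, "w") as fh:
        fh.write("key\tvalue\n")
        fh.write(f"strain_id\t{strain.strain_id}\n")
        if strain.causal is not None:
            fh.write(f"causal_chrom\t{strain.causal.chrom}\n")
            fh.write(f"causal_pos\t{strain.causal.pos}\n")
            fh.write(f"causal_ref\t{strain.causal.ref}\n")
            fh.write(f"causal_alt\t{strain.causal.alt}\n")
        fh.write(f"n_variants\t{len(strain.variants)}\n")
        fh.write(f"n_f2\t{config.n_f2}\n")
        fh.write(f"depth\t{config.depth}\n")
        fh.write(f"error_rate\t{config.error_rate}\n")
        fh.write(f"mutation_rate\t{config.mutation_rate}\n")
        fh.write(f"seed\t{config.seed}\n")


# ---------------------------------------------------------------------------
# Synthetic reference data


_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]


def synthetic_genome(
    n_chromosomes: int = 5,
    chrom_length: int = 20_000_000,
    cm_per_mb: float = 5.0,
    seed: int = 0,
    with_sequence: bool = True,
) -> GenomeBuild:
    """A toy multi-chromosome genome with random sequence (~36% GC)."""
    rng = np.random.default_rng(seed)
    chroms = []
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    probs = np.array([0.32, 0.18, 0.18, 0.32])
    for i in range(n_chromosomes):
        name = f"chr{_ROMAN[i]}" if i < len(_ROMAN) else f"chr{i + 1}"
        seq = None
        if with_sequence:
            idx = rng.choice(4, size=chrom_length, p=probs)
            seq = bases[idx].tobytes().decode("ascii")
        chroms.append(Chromosome(name, chrom_length, seq))
    return GenomeBuild(tuple(chroms), cm_per_mb=cm_per_mb)


def synthetic_marker_map(
    genome: GenomeBuild, spacing: int = 100_000, seed: int = 0
) -> MarkerMap:
    """Evenly spaced mapping-strain SNV markers, one every *spacing* bp."""
    rng = np.random.default_rng(seed)
    markers = []
    for c in genome.chromosomes:
        for pos in range(spacing, c.length + 1, spacing):
            ref = c.sequence[pos - 1].upper() if c.sequence is not None else "A"
            if ref not in _BASES:
                ref = "A"
            alts = [b for b in _BASES if b != ref]
            markers.append(Marker(c.name, pos, ref, alts[int(rng.integers(3))]))
    return MarkerMap(markers)
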