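import itertools

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import settings

from ectamapper.genome import Chromosome, GeneModel, GenomeBuild

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

NON_STOP_CODONS = [
    c
    for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
    if str(Seq(c).translate()) != "*"
]


def make_cds_chromosome(
    n_codons: int = 100,
    flank: int = 100,
    strand: str = "+",
    seed: int = 5,
    n_exons: int = 1,
    intron_len: int = 50,
):
    """A toy chromosome carrying one complete CDS gene.

    The CDS is ATG + (n_codons - 2) random non-stop codons + TAA, split
    into *n_exons* equal-ish pieces separated by introns. Returns
    (genome, gene, cds_string).
    """
    rng = np.random.default_rng(seed)
    codons = ["ATG"]
    for _ in range(n_codons - 2):
        codons.append(NON_STOP_CODONS[rng.integers(len(NON_STOP_CODONS))])
    codons.append("TAA")
    cds = "".join(codons)
    coding = cds if strand == "+" else str(Seq(cds).reverse_complement())

    # split the genomic coding stretch into exon pieces with introns between
    piece = len(coding) // n_exons
    bounds = [piece * i for i in range(n_exons)] + [len(coding)]
    flank_seq = "".join(rng.choice(list("ACGT"), flank))
    intron_seq = "".join(rng.choice(list("ACGT"), intron_len))
    seq_parts = [flank_seq]
    exons = []
    cursor = flank
    for i in range(n_exons):
        chunk = coding[bounds[i] : bounds[i + 1]]
        exons.append((cursor + 1, cursor + len(chunk)))
        seq_parts.append(chunk)
        cursor += len(chunk)
        if i < n_exons - 1:
            seq_parts.append(intron_seq)
            cursor += intron_len
    seq_parts.append(flank_seq)
    seq = "".join(seq_parts)

    genome = GenomeBuild((Chromosome("chrI", len(seq), seq),))
    gene = GeneModel(
        gene_id="toy1",
        chrom="chrI",
        strand=strand,
        exons=tuple(exons),
        cds=tuple((s, e, 0) for s, e in exons),
    )
    return genome, gene, cds


@pytest.fixture(scope="session")
def small_genome():
    """2 x 1 Mb sequenced toy genome shared across fast tests."""
    from ectamapper.cross import synthetic_genome

    return synthetic_genome(n_chromosomes=2, chrom_length=1_000_000, seed=42)


@pytest.fixture(scope="session")
def small_markers(small_genome):
    from ectamapper.cross import synthetic_marker_map

    return synthetic_marker_map(small_genome, spacing=50_000, seed=42)
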