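import collections

import numpy as np
import pytest
from Bio.Seq import Seq

from ectamapper.effects import (
    RefMismatchError,
    SEVERITY_RANK,
    annotate_variant,
    enumerate_cds_effects,
    most_severe_per_gene,
    prioritize_candidates,
)
from ectamapper.genome import Chromosome, GeneModel, GenomeBuild
from ectamapper.linkage import LinkageCall
from ectamapper.variants import Variant

from conftest import make_cds_chromosome


def translation_oracle(cds, idx, alt_coding):
    """Classify a CDS substitution by full-protein re-translation and diff."""
    mutant = cds[:idx] + alt_coding + cds[idx + 1 :]
    p_ref = str(Seq(cds).translate())
    p_alt = str(Seq(mutant).translate())
    codon_i = idx // 3
    if codon_i == 0:
        return "start_lost"
    if p_ref[codon_i] == p_alt[codon_i]:
        return "synonymous"
    if p_ref[codon_i] == "*":
        return "stop_lost"
    if p_alt[codon_i] == "*":
        return "nonsense"
    return "missense"


class TestAnnotate:
    def test_variant_far_from_genes_is_intergenic(self):
        genome, gene, _ = make_cds_chromosome()
        pos = 50  # inside the 100 bp flank, 500+ bp from nothing else
        ref = genome.base_at("chrI", pos)
        alt = "A" if ref != "A" else "C"
        (ann,) = annotate_variant(Variant("chrI", pos, ref, alt), [gene], genome)
        assert ann.effect_class == "intergenic"
        assert ann.gene_id is None
        assert ann.protein_change is None

    def test_tryptophan_codon_to_stop_is_nonsense(self):
        # hand-built gene: ATG TGG TAA; G->A at codon-2 position 3 gives TGA
        seq = "TTTTTTTTTT" + "ATGTGGTAA" + "TTTTTTTTTT"
        genome = GenomeBuild((Chromosome("chrI", len(seq), seq),))
        gene = GeneModel("g", "chrI", "+", exons=((11, 19),), cds=((11, 19, 0),))
        (ann,) = annotate_variant(Variant("chrI", 16, "G", "A"), [gene], genome)
        assert ann.effect_class == "nonsense"
        assert ann.protein_change == "W2*"

    def test_ref_mismatch_raises_naming_position(self):
        genome, gene, _ = make_cds_chromosome()
        pos = gene.cds[0][0] + 5
        ref = genome.base_at("chrI", pos)
        wrong = "A" if ref != "A" else "G"
        alt = "C" if wrong != "C" else "T"
        with pytest.raises(RefMismatchError, match=f"chrI:{pos}"):
            annotate_variant(Variant("chrI", pos, wrong, alt), [gene], genome)

    def test_corrupted_reference_always_detected(self):
        """Deliberately corrupted ref alleles are all caught by verification."""
        genome, gene, _ = make_cds_chromosome(seed=8)
        rng = np.random.default_rng(8)
        caught = 0
        trials = 50
        for _ in range(trials):
            pos = int(rng.integers(gene.cds[0][0], gene.cds[0][1] + 1))
            true_ref = genome.base_at("chrI", pos)
            wrong = rng.choice([b for b in "ACGT" if b != true_ref])
            alt = next(b for b in "ACGT" if b not in (wrong, true_ref))
            with pytest.raises(RefMismatchError):
                annotate_variant(Variant("chrI", pos, wrong, alt), [gene], genome)
            caught += 1
        assert caught == trials

    def test_splice_site_window_overrides_intronic(self):
        genome, gene, _ = make_cds_chromosome(n_exons=2, intron_len=50, seed=9)
        intron_start, intron_end = gene.introns[0]
        for pos in (intron_start, intron_start + 1, intron_end - 1, intron_end):
            ref = genome.base_at("chrI", pos)
            alt = "A" if ref != "A" else "C"
            (ann,) = annotate_variant(Variant("chrI", pos, ref, alt), [gene], genome)
            assert ann.effect_class == "splice_site", pos
        mid = (intron_start + intron_end) // 2
        ref = genome.base_at("chrI", mid)
        alt = "A" if ref != "A" else "C"
        (ann,) = annotate_variant(Variant("chrI", mid, ref, alt), [gene], genome)
        assert ann.effect_class == "intronic"

    def test_premature_stop_in_third_exon_is_nonsense(self):
        """A 3-exon gene with a stop-introducing SNV in exon 3 classes nonsense."""
        genome, gene, cds = make_cds_chromosome(n_codons=90, n_exons=3, seed=10)
        # find a nonsense-producing site whose genomic position is in exon 3
        e3_start, e3_end = gene.exons[2]
        table = enumerate_cds_effects(gene, genome)
        hits = table[
            (table.effect_class == "nonsense")
            & (table.pos >= e3_start)
            & (table.pos <= e3_end)
        ]
        assert not hits.empty
        row = hits.iloc[0]
        (ann,) = annotate_variant(
            Variant("chrI", int(row.pos), row.ref, row.alt), [gene], genome
        )
        assert ann.effect_class == "nonsense"
        assert ann.protein_change.endswith("*")


class TestEnumerate:
    def test_300bp_cds_yields_900_rows(self):
        genome, gene, _ = make_cds_chromosome(n_codons=100)
        table = enumerate_cds_effects(gene, genome)
        assert len(table) == 900

    def test_every_row_matches_full_translation_oracle(self):
        genome, gene, cds = make_cds_chromosome(n_codons=40, seed=11)
        table = enumerate_cds_effects(gene, genome)
        start = gene.cds[0][0]
        for row in table.itertuples(index=False):
            idx = row.pos - start
            assert row.effect_class == translation_oracle(cds, idx, row.alt), row

    def test_reverse_strand_gives_identical_class_multiset(self):
        fwd_genome, fwd_gene, _ = make_cds_chromosome(n_codons=40, seed=12, strand="+")
        rev_genome, rev_gene, _ = make_cds_chromosome(n_codons=40, seed=12, strand="-")
        fwd = enumerate_cds_effects(fwd_gene, fwd_genome)
        rev = enumerate_cds_effects(rev_gene, rev_genome)
        assert collections.Counter(fwd.effect_class) == collections.Counter(
            rev.effect_class
        )

    def test_incomplete_cds_rejected(self):
        genome, gene, _ = make_cds_chromosome()
        broken = GeneModel(
            gene.gene_id,
            gene.chrom,
            gene.strand,
            gene.exons,
            cds=((gene.cds[0][0], gene.cds[0][1] - 1, 0),),
            complete=False,
        )
        with pytest.raises(ValueError, match="incomplete"):
            enumerate_cds_effects(broken, genome)


class TestPrioritize:
    def _ann(self, genome, gene, effect_class):
        table = enumerate_cds_effects(gene, genome)
        row = table[table.effect_class == effect_class].iloc[0]
        v = Variant("chrI", int(row.pos), row.ref, row.alt)
        (ann,) = annotate_variant(v, [gene], genome)
        return ann

    def test_nonsense_ranks_before_synonymous(self):
        genome, gene, _ = make_cds_chromosome(seed=13)
        anns = [
            self._ann(genome, gene, "synonymous"),
            self._ann(genome, gene, "nonsense"),
        ]
        call = LinkageCall("chrI", 0.02, True, interval=(1, 10_000))
        ranked = prioritize_candidates(anns, call)
        assert [a.effect_class for a in ranked] == ["nonsense", "synonymous"]

    def test_outside_interval_dropped_and_empty_allowed(self):
        genome, gene, _ = make_cds_chromosome(seed=13)
        ann = self._ann(genome, gene, "missense")
        call = LinkageCall("chrI", 0.02, True, interval=(900_000, 990_000))
        assert prioritize_candidates([ann], call) == []

    def test_unlinked_call_rejected(self):
        call = LinkageCall("chrI", 0.4, False)
        with pytest.raises(ValueError):
            prioritize_candidates([], call)

    def test_severity_ranks_cover_all_classes(self):
        assert set(SEVERITY_RANK) == {
            "nonsense",
            "splice_site",
            "start_lost",
            "stop_lost",
            "missense",
            "synonymous",
            "intronic",
            "intergenic",
        }

    def test_most_severe_per_gene_collapses(self):
        genome, gene, _ = make_cds_chromosome(seed=13)
        anns = [
            self._ann(genome, gene, "synonymous"),
            self._ann(genome, gene, "nonsense"),
        ]
        best = most_severe_per_gene(anns)
        assert best[gene.gene_id].effect_class == "nonsense"
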