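"""Codon-level effect annotation of candidate variants.

Builds a toy single-exon gene (ATG + 98 codons + TAA) and classifies
every possible SNV in its coding sequence, then shows one nonsense
variant in detail with its protein-change notation.
"""

import itertools

import numpy as np
from Bio.Seq import Seq

import ectamapper as em
from ectamapper.genome import Chromosome, GeneModel, GenomeBuild
from ectamapper.variants import Variant

rng = np.random.default_rng(12)
non_stop = [c for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
            if str(Seq(c).translate()) != "*"]
cds = "ATG" + "".join(non_stop[rng.integers(len(non_stop))] for _ in range(98)) + "TAA"
flank = "".join(rng.choice(list("ACGT"), 100))
seq = flank + cds + flank

genome = GenomeBuild((Chromosome("chrI", len(seq), seq),))
gene = GeneModel("toy1", "chrI", "+", exons=((101, 400),), cds=((101, 400, 0),))

table = em.enumerate_cds_effects(gene, genome)
print(f"all possible CDS SNVs: {len(table)}")
print(table["effect_class"].value_counts().to_string())

stop = table[table.effect_class == "nonsense"].iloc[0]
v = Variant("chrI", int(stop.pos), stop.ref, stop.alt)
(ann,) = em.annotate_variant(v, [gene], genome)
print(f"\nexample: {v.chrom}:{v.pos} {v.ref}>{v.alt} in {ann.gene_id} -> "
      f"{ann.effect_class} ({ann.protein_change})")
print("the notation means the encoded residue is replaced by a premature stop")
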