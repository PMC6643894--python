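"""Exclusive variant lists and sibling detection across strains.

Three mutagenized strains: two siblings (shared mutagenized genome plus
private noise calls) and one independent. Sibling overlap is near 1,
independent overlap near 0; exclusive lists subtract only non-siblings.
"""

import numpy as np

import ectamapper as em

genome = em.synthetic_genome(n_chromosomes=2, chrom_length=2_000_000, seed=8)
cfg = em.CrossConfig(mutation_rate=1e-4, seed=8)
rng = np.random.default_rng(8)

s1 = em.mutagenize(genome, cfg, rng=rng, strain_id="s1")
s1_sib = em.make_sibling(s1, genome, cfg, rng, strain_id="s1_sib")
s2 = em.mutagenize(genome, cfg, rng=rng, strain_id="s2")

sets = [s1.variants, s1_sib.variants, s2.variants]
print("pairwise Jaccard overlap of induced-variant sets:")
print(f"  s1 vs s1_sib: {em.jaccard(s1.variants, s1_sib.variants):.3f}  (siblings)")
print(f"  s1 vs s2:     {em.jaccard(s1.variants, s2.variants):.3f}  (independent)")

groups = em.detect_siblings(sets, threshold=0.5)
print(f"sibling groups: {groups}")

# exclusive list for s1: subtract the independent strain only — a sibling
# shares the causal variant, so subtracting it would erase the candidate
exclusive = em.subtract(s1.variants, [s2.variants])
print(f"s1 exclusive list: {len(exclusive)} of {len(s1.variants)} variants "
      f"(causal retained: {s1.causal in exclusive})")
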