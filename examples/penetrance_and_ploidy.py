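"""Screen quantification: penetrance intervals and DAPI-intensity ploidy.

Recomputes two published-style penetrance figures from their counts with
Wilson intervals, contrasts two genotypes, and estimates endoreduplicated
nuclear ploidy from integrated intensities normalized to 2N references.
"""

import pandas as pd

import ectamapper as em

# penetrance: 85/91 animals scored phenotype-positive prints as 93.4%
r1 = em.penetrance(85, 91)
r2 = em.penetrance(77, 78)
print(f"85/91 -> {r1.display}% (95% Wilson CI {r1.ci[0]:.1f}-{r1.ci[1]:.1f})")
print(f"77/78 -> {r2.display}% (95% Wilson CI {r2.ci[0]:.1f}-{r2.ci[1]:.1f})")

cmp = em.compare_penetrance(r2, r1)
print(f"difference {cmp.difference:+.1f} points "
      f"(Newcombe CI {cmp.ci[0]:.1f} to {cmp.ci[1]:.1f}), Fisher p = {cmp.p_value:.3f}")

# a printed percentage that no integer count can produce is flagged
print(f"consistent count for 80.1% of 108: {em.consistent_count(80.1, 108)}")

# ploidy: intensities relative to diploid reference nuclei (e.g. tail neurons)
nuclei = pd.DataFrame({
    "nucleus_id": ["ref1", "ref2", "hyp_a", "hyp_b", "hyp_c"],
    "intensity": [100.0, 104.0, 205.0, 410.0, 1630.0],
    "is_reference": [True, True, False, False, False],
})
for est in em.estimate_ploidy(nuclei):
    if not est.is_reference:
        print(f"{est.nucleus_id}: ploidy {est.ploidy:.1f} -> class {est.class_label}")
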