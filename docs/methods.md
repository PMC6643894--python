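# Methods

This note documents the models, defaults and numerical choices behind
`ectamapper`, and what the simulation-based tests do and do not establish
about real data.

## The genetic model

The package targets mapping-by-sequencing of a recessive mutant from a
forward genetic screen in *C. elegans*. A homozygous, EMS-mutagenized
mutant strain is crossed to a wild isolate (the "Hawaiian" mapping strain,
CB4856) that differs from the laboratory background at many known SNV
positions — the markers. F2 progeny are selected for the mutant phenotype,
which for a recessive allele means selecting animals homozygous for the
causal variant. The selected animals are pooled and sequenced, and the
pooled mapping-strain allele frequency is read out at every marker.

Each selected F2 contributes two gametes that carry the mutant allele at
the causal site. Such a gamete carries the mapping-strain allele at a
marker only if recombination separated marker and causal locus, so the
expected pooled frequency at genetic distance *d* equals the recombination
fraction. Under the Haldane (no-interference) map function,

    r(d) = (1 − e^(−2d/100)) / 2,   d in cM,

rising from 0 at the causal site to 0.5 at large distance and on other
chromosomes. This closed form is the independent oracle the simulator is
validated against: over 200 simulated pools the mean frequency at markers
0–50 cM from the causal locus matches r(d) within Monte-Carlo error.

Assumptions: full recessivity and complete, error-free phenotype
selection; no crossover interference (Haldane rather than Kosambi); a
uniform genetic map (constant cM/Mb per chromosome, default 5 cM/Mb,
matching the genome-wide average of ~300 cM over ~100 Mb); autosomal
inheritance throughout (no X-dosage or male special-casing); strains are
treated as fully homozygous lines.

## Simulation components

**Mutagenesis.** Induced variant count is Poisson(μ × genome size).
Default μ = 3 × 10⁻⁶ per bp (~300 variants per 100-Mb genome), a standard
figure for a 50 mM EMS dose in worms. Substitution types follow a
configurable spectrum, by default 87% G:C→A:T transitions (the canonical
EMS bias from guanine alkylation) with the remaining 13% spread uniformly
over the other ten substitutions. Sites are uniform among positions whose
reference base matches the drawn type. One variant is designated causal;
it can be constrained to fall in a CDS with a damaging consequence, which
is how the end-to-end recovery simulations are configured.

**Meiosis.** Per chromosome, crossover count is Poisson in the genetic
length (Morgans) with positions uniform on the genetic map; the gamete
alternates parental origin at each crossover starting from a uniformly
chosen parent. Since chromosomes assort independently, the cross
simulator draws the causal chromosome first, applies the homozygosity
selection, and simulates the remaining chromosomes only for accepted
animals — distributionally identical to simulating everything and
rejecting, and ~4× cheaper.

**Pooled sequencing.** Depth per marker is i.i.d. Poisson(D), default
D = 30. Each read samples an allele at the pool's true frequency and is
flipped to the other allele with probability ε (default 0.002), giving an
observed per-read mapping-allele probability f(1−ε) + (1−f)ε.
Overdispersion, alignment artifacts and base-quality structure are
deliberately out of scope: the model works at the allele-count level.

**What the generator does not emulate.** Real marker sets are irregularly
spaced and locally biased (e.g. around indels and repetitive regions);
real pools carry cross-contamination, phenotyping errors and partially
penetrant selection; variant callers produce genotype-quality structure
that the presence/absence set algebra ignores. Passing the recovery tests
therefore demonstrates correctness of the statistical machinery under the
stated model, not robustness to those artifacts.

## Linkage mapping

Observed frequency is computed at markers with depth ≥ `min_depth`
(default 5, suppressing ε-driven outliers at low coverage); shallower
markers are excluded and counted. Each chromosome's profile is smoothed
with locally weighted regression implemented from scratch: for each point,
the ⌈αn⌉ nearest neighbors by |x − xᵢ| receive tricube weights
(1 − (Δ/Δmax)³)³ and a weighted least-squares polynomial is evaluated at
xᵢ. Defaults are degree 1 and span α = 0.3, classic first-degree loess
with no robustness iterations. The implementation solves a centered,
√w-scaled least-squares system per point; an independent normal-equations
oracle in the test suite agrees to ≤ 10⁻⁸. Degenerate neighborhoods
(duplicated x, all weights zero) fall back to the neighbor mean; fewer
than degree+1 points is an error. Degree-1 fits can locally leave the
data range near boundaries; degree-0 fits cannot.

The linked chromosome is the argmin over chromosomes of the minimum
fitted frequency, provided it falls below `link_threshold` (default 0.25,
midway between the causal-locus expectation of 0 and the unlinked 0.5).
Ties break to the earliest chromosome in input order with a warning —
deterministic output is preferred over an arbitrary alternative. The
candidate interval is the maximal contiguous sub-threshold run of markers
containing the argmin (default threshold 0.25); it always contains at
least the argmin marker. No bootstrap confidence interval is attached;
the interval is a heuristic localization, and on short, tightly linked
chromosomes it can legitimately span the whole marker range. Fitting is
unweighted by depth; depth-weighted fitting was considered and left out
because the read-out already averages hundreds of reads per smoothing
window and the added coupling complicates the oracle.

Under the default study design used by the recovery tests — 5 chromosomes
× 20 Mb, markers every 100 kb, N = 50 pooled F2s, D = 30, ε = 0.002,
α = 0.3 — the linked chromosome is recovered in ≥ 95% and the interval
covers the true causal position in ≥ 90% of seeded replicates. These
problem sizes are the package's reference conditions; the exactness-style
checks (loess oracle, set algebra, annotation, determinism) are
scale-free and run on smaller instances.

## Variant-set algebra and siblings

Variant identity is the exact key (chrom, pos, ref, alt) on normalized
biallelic SNVs; genotype and quality fields are ignored (exclusive lists
are presence-based). Only SNVs are modeled: EMS induces point mutations,
and indel records are parsed, skipped and counted, never silently
dropped. Subtraction of all other (non-sibling) strains yields each
strain's exclusive list.

Sibling strains — isolates descending from the same mutagenized F1 —
share the bulk of their induced variants, while independent strains share
essentially none (genome-scale key collisions are negligible). Detection
is single-linkage grouping on pairwise Jaccard overlap with a default
threshold of 0.5, which sits in a wide empty margin between the two
regimes (simulated siblings with 5% private calls overlap ≈ 0.9;
independents ≈ 0). The published screen does not state the criterion used
for its sibling calls; this rule is this package's explicit
operationalization. In the pipeline, exclusive lists subtract only
strains outside the sibling group — subtracting a sibling would erase the
shared causal variant itself.

## Effect annotation

Variants are classified against transcript models at codon level:
intergenic, intronic, splice_site, synonymous, missense, nonsense,
stop_lost, start_lost, with protein notation like `W123*`. The declared
REF is always verified against the genome sequence; a mismatch is an
error naming the position. CDS coordinates are accumulated across exons
in transcription order; reverse-strand transcripts complement the alleles
and the standard nuclear code is used. Conventions: the splice window is
2 bp into the intron at each boundary (donor/acceptor dinucleotides) and
overrides intronic; any SNV in the initiator codon is start_lost
regardless of the encoded alternative; exonic non-coding (UTR) positions
have no dedicated class and fall through to intronic — a known
simplification, acceptable for the CDS-focused candidate logic. One
annotation is emitted per overlapping transcript, with a separate
most-severe-per-gene summary view. Candidate prioritization keeps
annotations inside the mapped interval and ranks
nonsense/splice/start/stop-loss > missense > synonymous > intronic,
stable by position within rank.

The annotation logic is validated exhaustively: every possible SNV in a
toy 300-bp CDS, on both strands, is compared against an oracle that
mutates the full CDS string, re-translates, and diffs the proteins.

## Screen statistics

Penetrance is k/n with a Wilson score interval — many screen genotypes
sit near 0% or 100%, where the Wald interval degenerates. Displayed
percentages use half-up rounding to one decimal, matching how screen
tables are printed, and a checker inverts printed percentages to their
unique consistent integer count where one exists; printed figures with no
consistent count are flagged as arithmetically inconsistent. Contrasts
between genotypes use the difference with a Newcombe hybrid score
interval and a two-sided Fisher exact test. The published screen reports
neither intervals nor tests; these are added utilities.

Ploidy is estimated from integrated DNA-stain intensity as
2·I/mean(I_ref) against diploid reference nuclei, with a discrete class
2^j·2N, j = round(log₂(ploidy/2)) with ties to the even exponent —
endoreduplication doubles genome content, so classes are powers of two
times 2N. Estimates are invariant to any common intensity scale.

## Determinism and configuration

All randomness flows from explicit seeds (NumPy `default_rng`); the
pipeline derives per-strain streams from the run seed, and two runs with
the same configuration produce byte-identical VCF/TSV/BED/JSON outputs.
The run configuration is a single YAML file echoed verbatim into the
report for provenance. Plots (frequency vs. position with the loess
curve, one panel per chromosome) are produced by an explicit call or the
CLI `--plot` flag rather than by default, keeping the default output set
byte-comparable.

## Known limitations

- Single causal locus per strain; two-gene architectures are out of scope.
- No interference, uniform genetic map, no X-chromosome special-casing,
  no balancer chromosomes.
- Allele-count-level sequencing model only; no read simulation or
  aligner/caller artifacts.
- Heuristic candidate interval without a bootstrap confidence level.
- Marker density and pool size of real experiments are unknown inputs;
  both are configuration, not inferences.
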