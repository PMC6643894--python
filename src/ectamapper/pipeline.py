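"""End-to-end orchestration of the mutant-identification analysis.

One seeded, configurable run covers: simulate (or ingest) per-strain
variant calls and pooled marker depths → sibling detection → exclusive
variant lists → per-chromosome frequency profiles → loess fit → linkage
call → candidate interval → effect annotation → prioritized shortlist.
Every stage's outputs are written under ``out_dir/<strain_id>/``; a
failure in one strain is recorded and does not abort the others.

Exclusive lists subtract only strains *outside* a strain's sibling group:
siblings share their induced variants by descent, so subtracting them
would erase the causal variant itself.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from . import cross as cs
from . import effects as fx
from . import linkage as lk
from . import variants as vr
from .genome import GenomeBuild, GeneModel, MarkerMap, read_gene_models, read_genome, read_marker_map, write_gene_models, write_marker_map

__all__ = ["RunConfig", "RunReport", "StrainInput", "run_pipeline"]


@dataclass
class StrainInput:
    """Ingest-mode pointers to one strain's files."""

    strain_id: str
    pool_vcf: str
    variants_vcf: str


@dataclass
class RunConfig:
    mode: str = "simulate"
    seed: int = 0
    out_dir: str = "out"
    # shared analysis settings
    cross: cs.CrossConfig = field(default_factory=cs.CrossConfig)
    loess: lk.LoessConfig = field(default_factory=lk.LoessConfig)
    min_depth: int = 5
    link_threshold: float = 0.25
    interval_threshold: float = 0.25
    sibling_threshold: float = 0.5
    # simulate-mode study design
    n_strains: int = 1
    n_sibling_clones: int = 0  # extra strains cloned from the first strain
    n_chromosomes: int = 5
    chrom_length: int = 20_000_000
    cm_per_mb: float = 5.0
    marker_spacing: int = 100_000
    gene_spacing: int = 1_000_000
    cds_length: int = 999
    # ingest-mode inputs
    fasta: Optional[str] = None
    gff3: Optional[str] = None
    markers_vcf: Optional[str] = None
    strains: list[StrainInput] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "ingest"):
            raise ValueError("mode must be 'simulate' or 'ingest'")
        if not 0 < self.link_threshold < 0.5 or not 0 < self.interval_threshold < 0.5:
            raise ValueError("linkage thresholds must be in (0, 0.5)")
        if not 0 < self.sibling_threshold <= 1:
            raise ValueError("sibling_threshold must be in (0, 1]")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        if self.mode == "ingest":
            for name in ("fasta", "gff3", "markers_vcf"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ValueError(f"ingest mode: {name} missing or not found: {p}")
            if not self.strains:
                raise ValueError("ingest mode: no strains given")
            for s in self.strains:
                for p in (s.pool_vcf, s.variants_vcf):
                    if not Path(p).exists():
                        raise ValueError(f"ingest mode: file not found: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "cross" in raw:
            cc = dict(raw["cross"])
            if "spectrum" in cc:
                cc["spectrum"] = {
                    tuple(k.split(">")): v for k, v in cc["spectrum"].items()
                }
            raw["cross"] = cs.CrossConfig(**cc)
        if "loess" in raw:
            raw["loess"] = lk.LoessConfig(**raw["loess"])
        if "strains" in raw:
            raw["strains"] = [StrainInput(**s) for s in raw["strains"]]
        return cls(**raw)

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["cross"]["spectrum"] = {
            f"{r}>{a}": p for (r, a), p in d["cross"]["spectrum"].items()
        }
        return yaml.safe_dump(d, sort_keys=True)


@dataclass
class RunReport:
    config_echo: str
    sibling_groups: list[list[str]]
    strains: dict[str, dict[str, Any]]
    errors: dict[str, str]

    @property
    def exit_code(self) -> int:
        """0 = clean, 2 = at least one strain failed a stage."""
        return 2 if self.errors else 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "sibling_groups": self.sibling_groups,
                "strains": self.strains,
                "errors": self.errors,
                "config": self.config_echo,
            },
            indent=2,
            sort_keys=True,
        )


def _simulate_inputs(config: RunConfig):
    genome = cs.synthetic_genome(
        n_chromosomes=config.n_chromosomes,
        chrom_length=config.chrom_length,
        cm_per_mb=config.cm_per_mb,
        seed=config.seed,
    )
    markers = cs.synthetic_marker_map(
        genome, spacing=config.marker_spacing, seed=config.seed
    )
    genes = _synthetic_gene_models(
        genome, spacing=config.gene_spacing, cds_length=config.cds_length
    )
    return genome, markers, genes


def _synthetic_gene_models(
    genome: GenomeBuild, spacing: int, cds_length: int
) -> list[GeneModel]:
    """Single-exon CDS gene models tiled at regular offsets on every chromosome."""
    genes = []
    for c in genome.chromosomes:
        i = 0
        for start in range(spacing // 2, c.length - cds_length, spacing):
            i += 1
            end = start + cds_length - 1
            genes.append(
                GeneModel(
                    gene_id=f"{c.name}.g{i}",
                    chrom=c.name,
                    strand="+",
                    exons=((start, end),),
                    cds=((start, end, 0),),
                )
            )
    return genes


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis; see the module docstring for stage order."""
    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)

    strain_sets: dict[str, vr.VariantSet] = {}
    counts_by_strain: dict[str, cs.AlleleCounts] = {}
    truth: dict[str, vr.Variant] = {}
    errors: dict[str, str] = {}

    if config.mode == "simulate":
        genome, markers, genes = _simulate_inputs(config)
        write_marker_map(markers, genome, out_root / "markers.vcf")
        write_gene_models(genes, out_root / "genes.gff3")
        sims: list[cs.MutantStrain] = []
        for i in range(config.n_strains):
            rng = np.random.default_rng([config.seed, i])
            strain = cs.mutagenize(
                genome,
                config.cross,
                rng=rng,
                strain_id=f"sim{i + 1}",
                causal_genes=genes,
                require_damaging=True,
            )
            sims.append(strain)
        for j in range(config.n_sibling_clones):
            rng = np.random.default_rng([config.seed, config.n_strains + j])
            sims.append(
                cs.make_sibling(
                    sims[0], genome, config.cross, rng, strain_id=f"sim1_sib{j + 1}"
                )
            )
        for i, strain in enumerate(sims):
            sdir = out_root / strain.strain_id
            sdir.mkdir(exist_ok=True)
            rng = np.random.default_rng([config.seed, 1000 + i])
            cs.write_strain_vcf(strain, genome, sdir / "variants.vcf")
            cs.write_truth(strain, config.cross, sdir / "truth.tsv")
            pool = cs.simulate_cross(strain, markers, genome, config.cross, rng=rng)
            counts = cs.simulate_pool_readcounts(pool, markers, config.cross, rng=rng)
            cs.write_pool_vcf(counts, genome, sdir / "pool.vcf", sample=strain.strain_id)
            strain_sets[strain.strain_id] = strain.variants
            counts_by_strain[strain.strain_id] = counts
            truth[strain.strain_id] = strain.causal
    else:
        genome = read_genome(config.fasta)
        markers = read_marker_map(config.markers_vcf)
        genes = read_gene_models(config.gff3, genome)
        for s in config.strains:
            strain_sets[s.strain_id] = vr.read_variants(
                s.variants_vcf, strain_id=s.strain_id
            )
            counts_by_strain[s.strain_id] = cs.read_pool_counts(s.pool_vcf)

    # --- sibling detection across all strains ----------------------------
    sets = list(strain_sets.values())
    groups = vr.detect_siblings(sets, threshold=config.sibling_threshold)
    vr.write_sibling_report(sets, groups, out_root / "siblings.tsv")
    group_of = {sid: i for i, g in enumerate(groups) for sid in g}

    # --- per-strain stages ------------------------------------------------
    results: dict[str, dict[str, Any]] = {}
    for sid, vset in strain_sets.items():
        sdir = out_root / sid
        sdir.mkdir(exist_ok=True)
        res: dict[str, Any] = {
            "sibling_group": group_of[sid],
            "n_variants": len(vset),
        }
        try:
            others = [
                o
                for oid, o in strain_sets.items()
                if oid != sid and group_of[oid] != group_of[sid]
            ]
            exclusive = vr.subtract(vset, others)
            vr.write_variants(exclusive, sdir / "exclusive.vcf", genome=genome)
            res["n_exclusive"] = len(exclusive)

            counts = counts_by_strain[sid]
            if len(counts) == 0:
                raise ValueError("pooled VCF carries no usable allele depths")
            profiles = lk.marker_allele_frequencies(counts, min_depth=config.min_depth)
            lk.fit_profiles(profiles, config.loess)
            lk.write_profile_tsv(profiles, sdir / "frequencies.tsv")
            call = lk.call_linked_chromosome(profiles, config.link_threshold)
            res["linked"] = call.linked
            res["linked_chrom"] = call.chrom
            res["min_fitted_freq"] = round(call.min_fitted_freq, 6)
            if call.linked:
                call.interval = lk.candidate_interval(
                    profiles[call.chrom], config.interval_threshold
                )
                res["interval"] = list(call.interval)
            lk.write_interval_bed(call, sdir / "interval.bed")

            if call.linked:
                annotated = fx.annotate_set(exclusive, genes, genome)
                shortlist = fx.prioritize_candidates(annotated, call)
                fx.write_annotation_tsv(shortlist, sdir / "candidates.tsv")
                res["n_candidates"] = len(shortlist)
                res["candidates"] = [
                    {
                        "chrom": a.variant.chrom,
                        "pos": a.variant.pos,
                        "gene_id": a.gene_id,
                        "effect_class": a.effect_class,
                        "protein_change": a.protein_change,
                    }
                    for a in shortlist[:20]
                ]
                if sid in truth and truth[sid] is not None:
                    causal = truth[sid]
                    res["causal_in_shortlist"] = any(
                        a.variant.key == causal.key for a in shortlist
                    )
        except Exception as exc:  # noqa: BLE001 — per-strain isolation
            errors[sid] = f"{type(exc).__name__}: {exc}"
        results[sid] = res

    report = RunReport(
        config_echo=config.to_yaml(),
        sibling_groups=groups,
        strains=results,
        errors=errors,
    )
    (out_root / "report.json").write_text(report.to_json())
    return report
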