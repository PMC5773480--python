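"""End-to-end orchestration: simulate -> call -> classify -> enrich -> report.

A single :class:`PipelineConfig` drives the whole run.  The global seed
is expanded into independent per-stage substreams, every report row
carries the seed and a hash of the config, and all outputs are
deterministic TSV/JSON so two runs with the same config are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from dataclasses import replace as dc_replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrichment, features, hotspots, io, sce
from .genome import GaplessMap
from .simulate import SimulationParams, SyntheticGenomeSpec, generate_genome, simulate_cells

logger = logging.getLogger("g4sce")

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    genome: SyntheticGenomeSpec = field(default_factory=SyntheticGenomeSpec)
    simulation: SimulationParams = field(default_factory=SimulationParams)
    seed: int = 0
    n_permutations: int = 1000
    shift_min: int = 2_000_000
    shift_max: int = 50_000_000
    g4_cutoff: int = 10_000  # region size cutoff for motif-scale features
    gene_cutoff: int = 100_000  # region size cutoff for gene/promoter features
    promoter_length: int = 1000
    flanks: tuple[int, ...] = ()
    subsample_target: int | None = None
    recurrence_max_fraction: float = 0.05
    min_reads: int = 10
    epsilon: float = 0.02
    hotspot_min_cells: int = 3

    def validate(self) -> None:
        self.genome.validate()
        self.simulation.validate()
        if self.n_permutations <= 0 or self.g4_cutoff <= 0 or self.gene_cutoff <= 0:
            raise ValueError("permutations and cutoffs must be positive")
        if self.shift_min > self.shift_max:
            raise ValueError("shift_min must not exceed shift_max")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["genome"]["chrom_lengths"] = list(np.atleast_1d(self.genome.chrom_lengths).tolist()) if not isinstance(self.genome.chrom_lengths, int) else self.genome.chrom_lengths
        d["flanks"] = list(self.flanks)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "genome" in d:
            g = dict(d["genome"])
            if isinstance(g.get("chrom_lengths"), list):
                g["chrom_lengths"] = tuple(g["chrom_lengths"])
            d["genome"] = SyntheticGenomeSpec(**g)
        if "simulation" in d:
            d["simulation"] = SimulationParams(**d["simulation"])
        if "flanks" in d:
            d["flanks"] = tuple(d["flanks"])
        return cls(**d)


def _substreams(seed: int, n: int) -> list[int]:
    """Expand a global seed into per-stage integer seeds (< 2**31)."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def build_foi_grid(genome, promoter_length: int = 1000) -> dict[str, tuple[pd.DataFrame, str]]:
    """The feature-of-interest taxonomy tested for SCE enrichment.

    Returns name -> (interval table, cutoff class) where cutoff class is
    'gene' (large size cutoff) or 'g4' (stringent cutoff).  Covers gene
    bodies and promoters with/without motifs, motif families by loop
    class, motif genomic context by strand and host-gene activity, plus
    A-rich and high-GC control tracks.
    """
    genes_act = features.attach_activity(genome.genes, genome.expression)
    bodies = features.gene_bodies(genes_act)
    motifs = features.classify_motif_context(genome.g4_motifs, genes_act)
    proms = features.promoter_regions(genes_act, promoter_length, genome.genome_index.lengths)

    def genes_with_motifs(sub_bodies):
        has = set()
        for chrom, ms in motifs.groupby("chrom", sort=False):
            gb = sub_bodies[sub_bodies["chrom"] == chrom]
            for g in gb.itertuples():
                if ((ms["start"] < g.end) & (ms["end"] > g.start)).any():
                    has.add(g.gene_id)
        return has

    has_g4 = genes_with_motifs(bodies)
    active = bodies["activity"] == "active"
    in_g4 = bodies["gene_id"].isin(has_g4)

    prom_has_g4 = set()
    for chrom, ms in motifs.groupby("chrom", sort=False):
        pb = proms[proms["chrom"] == chrom]
        for p in pb.itertuples():
            if ((ms["start"] < p.end) & (ms["end"] > p.start)).any():
                prom_has_g4.add(p.gene_id)

    grid: dict[str, tuple[pd.DataFrame, str]] = {
        "genes": (bodies, "gene"),
        "genes_active_with_g4": (bodies[active & in_g4], "gene"),
        "genes_active_without_g4": (bodies[active & ~in_g4], "gene"),
        "genes_silent_with_g4": (bodies[~active & in_g4], "gene"),
        "genes_silent_without_g4": (bodies[~active & ~in_g4], "gene"),
        "promoters": (proms, "gene"),
        "promoters_with_g4": (proms[proms["gene_id"].isin(prom_has_g4)], "gene"),
        "promoters_without_g4": (proms[~proms["gene_id"].isin(prom_has_g4)], "gene"),
        "g4_canonical": (motifs, "g4"),
        "g4_intergenic": (motifs[motifs["context"] == "intergenic"], "g4"),
        "g4_transcribed_strand": (motifs[motifs["context"] == "transcribed_strand"], "g4"),
        "g4_non_transcribed_strand": (motifs[motifs["context"] == "non_transcribed_strand"], "g4"),
        "g4_transcribed_strand_active": (
            motifs[(motifs["context"] == "transcribed_strand") & (motifs["gene_activity"] == "active")],
            "g4",
        ),
        "g4_non_transcribed_strand_active": (
            motifs[(motifs["context"] == "non_transcribed_strand") & (motifs["gene_activity"] == "active")],
            "g4",
        ),
        "g4_transcribed_strand_silent": (
            motifs[(motifs["context"] == "transcribed_strand") & (motifs["gene_activity"] == "silent")],
            "g4",
        ),
        "g4_non_transcribed_strand_silent": (
            motifs[(motifs["context"] == "non_transcribed_strand") & (motifs["gene_activity"] == "silent")],
            "g4",
        ),
    }
    for loop_class, (lo, hi) in features.LOOP_CLASSES.items():
        if loop_class == "1-7":
            continue  # canonical class already present
        grid[f"g4_loops_{loop_class}"] = (features.scan_genome(genome.sequences, lo, hi), "g4")
    a_rich = features.scan_genome(genome.sequences, 1, 7, base="A")
    grid["a_rich"] = (a_rich, "g4")
    gc_parts = []
    for chrom, seq in genome.sequences.items():
        w = features.gc_windows(seq, window=1000, top_fraction=0.1)
        w.insert(0, "chrom", chrom)
        gc_parts.append(w)
    grid["gc_top_decile"] = (pd.concat(gc_parts, ignore_index=True), "g4")
    return grid


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full synthetic pipeline and write a report bundle.

    Returns the manifest (also written to ``manifest.json``).
    """
    config.validate()
    out = io.ensure_dir(outdir)
    cfg_hash = config.config_hash()
    seeds = _substreams(config.seed, 4)
    logging.basicConfig(level=logging.INFO)

    # per-stage seeds are derived copies; the caller's config is not mutated
    genome_spec = dc_replace(config.genome, seed=seeds[0])
    sim_params = dc_replace(config.simulation, seed=seeds[1])
    io.write_json(out / "config.json", config.to_dict())

    logger.info("stage=generate_genome seed=%d", seeds[0])
    genome = generate_genome(genome_spec)
    io.write_fasta(out / "genome.fa", genome.sequences)
    io.write_gaps_bed(out / "gaps.bed", genome.genome_index)
    io.write_genes(out / "genes.tsv", genome.genes)
    io.write_expression(out / "expression.tsv", genome.expression)
    io.write_bed(out / "g4_motifs.bed", genome.g4_motifs.assign(name=".", score=0)[
        ["chrom", "start", "end", "name", "score", "strand"]
    ])

    logger.info("stage=simulate_cells seed=%d n_cells=%d", seeds[1], config.simulation.n_cells)
    reads, truth = simulate_cells(genome, sim_params)
    io.write_reads(out / "reads.tsv", reads)
    io.write_json(out / "truth.json", truth.to_dict())

    logger.info("stage=call_sces n_reads=%d", len(reads))
    called = sce.call_sces_for_cells(reads, min_reads=config.min_reads, epsilon=config.epsilon)
    kept, removed = sce.filter_recurrent(
        called, cell_count=config.simulation.n_cells, max_fraction=config.recurrence_max_fraction
    )
    io.write_bed(out / "sce_regions.bed", kept.assign(name=kept["cell"])[
        ["chrom", "start", "end", "name", "resolution", "homolog"]
    ])
    summary = sce.resolution_summary(kept) if len(kept) else {"n_sces": 0}
    summary["size_correlation_r2"] = (
        sce.chromosome_size_correlation(kept, genome.genome_index, config.simulation.n_cells)
        if len(kept) and len(genome.genome_index.chromosomes) >= 3
        else None
    )
    io.write_json(out / "resolution_summary.json", summary)

    gmap = GaplessMap(genome.genome_index)
    grid = build_foi_grid(genome, config.promoter_length)
    logger.info("stage=enrichment n_fois=%d n_sces=%d", len(grid), len(kept))
    enrich_rows = []
    results_json = {}
    rng = np.random.default_rng(seeds[2])
    for name, (foi, cls) in sorted(grid.items()):
        cutoff = config.g4_cutoff if cls == "g4" else config.gene_cutoff
        used = enrichment.apply_size_cutoff(kept, cutoff)
        if config.subsample_target is not None and config.subsample_target < len(used):
            used = enrichment.subsample_sces(used, config.subsample_target, seed=int(rng.integers(2**31 - 1)))
        res = enrichment.permute_overlap(
            used,
            foi,
            gmap,
            n_permutations=config.n_permutations,
            shift_min=config.shift_min,
            shift_max=config.shift_max,
            seed=int(rng.integers(2**31 - 1)),
            foi_name=name,
        )
        row = res.to_dict()
        row.update({"cutoff": cutoff, "seed_global": config.seed, "config_hash": cfg_hash})
        enrich_rows.append(row)
        results_json[name] = row
    enrich_df = pd.DataFrame(enrich_rows)
    enrich_df.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    io.write_json(out / "enrichment.json", results_json)

    logger.info("stage=hotspots")
    cands = hotspots.detect_hotspots(kept, min_cells=config.hotspot_min_cells)
    scored = hotspots.score_hotspots(
        cands,
        kept,
        genome.genome_index.total_effective_length(),
        n_libraries_total=config.simulation.n_cells,
    )
    scored.to_csv(out / "hotspots.tsv", sep="\t", index=False)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "config_hash": cfg_hash,
        "counts": {
            "reads": int(len(reads)),
            "true_sces": int(len(truth.true_sces)),
            "called_sces": int(len(called)),
            "kept_sces": int(len(kept)),
            "removed_recurrent": int(len(removed)),
            "hotspot_candidates": int(len(cands)),
            "fois": len(grid),
        },
        "outputs": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    assert manifest["counts"]["called_sces"] == manifest["counts"]["kept_sces"] + manifest["counts"]["removed_recurrent"]
    io.write_json(out / "manifest.json", manifest)
    return manifest
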