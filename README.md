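# g4sce

Mapping sister chromatid exchanges from single-cell template-strand
sequencing and testing their association with G-quadruplex motifs.

## The problem

Strand-seq sequences only the parental DNA template strands of a single
cell, so each read's mapping orientation — Crick (`C`, reference plus
strand) or Watson (`W`, minus strand) — reports which template strand
the cell inherited. A diploid chromosome is in state WW, WC or CC, and a
sister chromatid exchange (SCE) appears as a one-step switch in that
state along the chromosome, localized to the gap between two informative
reads (typically kilobases at 1–2% genome coverage). In BLM-helicase-
deficient (Bloom syndrome) cells, SCE rates are ~10-fold elevated and
the exchanges concentrate at quadruplex-forming sequence motifs
(G<sub>3+</sub>N<sub>1–7</sub>G<sub>3+</sub>N<sub>1–7</sub>G<sub>3+</sub>N<sub>1–7</sub>G<sub>3+</sub>)
in transcribed genes.

This package is for analysts who want to make — and stress-test — that
kind of claim. It provides:

- **`g4sce.sce`** — template-strand state segmentation (exact penalized
  changepoint search on the binomial read-label likelihood), SCE region
  calling, recurrent-artifact filtering, homolog assignment, resolution
  summaries;
- **`g4sce.features`** — G4 / A-rich motif scanning on both strands,
  GC-content control windows, gene activity (FPKM > 1), promoter and
  motif strand-context classification;
- **`g4sce.enrichment`** — the core statistic: a circular-shift
  permutation test of SCE/feature overlap in assembly-gap-excluded
  coordinates, with size cutoffs, flanking and subsampling sensitivity
  analyses (observed overlap / median of 1,000 permuted overlaps;
  empirical p floored at 0.001);
- **`g4sce.hotspots`** — recurrent SCE hotspot detection with an exact
  binomial bin probability;
- **`g4sce.allelic`** — allele-specific G4 detection in F1-hybrid
  genomes, SCE–motif homolog concordance (exact binomial against the
  50% null), copy-neutral LOH calling and a naive ploidy check;
- **`g4sce.simulate`** — a synthetic Strand-seq generator that plants
  SCEs (optionally enriched at G4 motifs in active genes on the
  measurement scale), SNPs, allele-specific motifs, LOH segments and
  trisomies, and emits exact ground truth for every dataset.

See `docs/methods.md` for the models, conventions and limitations.

## Worked example

Simulate a Bloom-like line on a 3 × 30 Mb synthetic genome with a
planted 1.2-fold excess of SCE placement at G4 motifs in active genes,
call SCEs, and test G4 enrichment:

```python
import numpy as np
from g4sce import enrichment, sce
from g4sce.genome import GaplessMap
from g4sce.simulate import (SimulationParams, SyntheticGenomeSpec,
                            generate_genome, simulate_cells)

genome = generate_genome(SyntheticGenomeSpec(seed=11))
params = SimulationParams(n_cells=300, g4_enrichment_factor=1.2, seed=1)
reads, truth = simulate_cells(genome, params)        # ~8M directional reads

called = sce.call_sces_for_cells(reads)
kept, removed = sce.filter_recurrent(called, cell_count=params.n_cells)
print(sce.resolution_summary(kept)["median_resolution"])

used = enrichment.apply_size_cutoff(kept, 10_000)    # 10 kb cutoff
res = enrichment.permute_overlap(used, genome.g4_motifs,
                                 GaplessMap(genome.genome_index), seed=2)
print(res.n_sces_used, res.observed_overlap, res.median_permuted,
      round(res.relative_enrichment, 3), res.p_enrich_str)
```

Output of this exact snippet:

```
3950.0
514 216 188.0 1.149 0.005
```

Reading it: the 300 simulated libraries yielded 514 SCE regions at or
below the 10 kb size cutoff, with a median mapping resolution of
~3.9 kb. 216 of them overlap at least one G4 motif, against a median of
188 under 1,000 random circular shifts — a 15% relative enrichment on
this single replicate (5 of the 1,000 permutations reached the observed
overlap, p = 0.005). Single replicates scatter by a few percentage
points around the planted 20%; `scripts/acceptance.py` (below) takes the
median over ten replicates, which recovers it closely. With
`g4_enrichment_factor=1.0` the same pipeline reports enrichments
scattered around 1.0 with calibrated p-values.

The same chain is scriptable from the shell:

```bash
g4sce simulate --outdir demo --n-cells 50 --seed 7
g4sce scan --fasta demo/genome.fa --out demo/motifs.bed
g4sce call-sce --reads demo/reads.tsv --out demo/sces.tsv
g4sce run-all --outdir demo_full --seed 7     # full report bundle
```

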