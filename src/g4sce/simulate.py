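"""Synthetic Strand-seq data with known ground truth.

The generator produces (a) genomes with assembly gaps, planted
quadruplex motifs at a target mean spacing, and annotated genes with an
expression table; (b) single-cell directional-read datasets with planted
sister chromatid exchanges (SCEs); and (c) F1-hybrid variants with
heterozygous SNPs, allele-specific motifs, planted copy-neutral LOH
segments and trisomies.  Every dataset is emitted together with a
:class:`TruthSet` so downstream callers can be scored exactly.

SCE placement model
-------------------
Each cell receives ``Poisson(sce_rate_per_cell)`` exchanges.  Breakpoints
are drawn from a two-component mixture: a uniform component over non-gap
bases and an excess component uniform over bases of G4 motifs inside
active genes.  The ``g4_enrichment_factor`` parameterizes the mixture on
the scale of the downstream measurement: it is the expected relative
enrichment (observed / median permuted overlap) of called SCE regions
against the G4 motif track under the standard analysis (region size
cutoff, circular-shift permutations).  The generator converts the factor
into a mixture weight by a pilot calibration (see
:func:`calibrate_excess_ratio`) that runs the production caller on a
pilot dataset, measuring both the null overlap probability of called
regions and how often a region whose breakpoint sits inside a motif
actually covers that motif.  With factor 1.0 the
excess component has zero weight and placement is exactly uniform.  A
per-base density interpretation of the factor (multiplying the point
mass of the ~0.3% of bases inside motifs) would be unmeasurable by the
region-overlap statistic and is deliberately not used; factors below 1
fall back to per-base thinning of motif bases.

Template-strand logic mirrors diploid Strand-seq: each chromosome starts
in WW, WC or CC (uniform over the three states) and each SCE flips the
template strand of exactly one homolog.  Reads are a homogeneous Poisson
process over non-gap bases; each read is drawn from one homolog and
carries that homolog's current template label (W or C), flipped with a
small symmetric noise probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import features
from .genome import GaplessMap, GenomeIndex

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SyntheticGenomeSpec:
    """Parameters for a synthetic genome.

    Defaults emulate, at 1/30 scale, the genome properties the analysis
    depends on: mean G4 motif spacing ~8.6 kb, ~60% of genes
    transcribed, and a small fraction of assembly-gapped sequence.
    """

    n_chromosomes: int = 3
    chrom_lengths: tuple[int, ...] | int = 30_000_000
    gap_fraction: float = 0.02
    g4_spacing_target: float = 8600.0
    gene_count: int = 200
    active_fraction: float = 0.6
    snp_rate: float = 0.008
    seed: int = 0

    def lengths(self) -> list[int]:
        if isinstance(self.chrom_lengths, int):
            return [self.chrom_lengths] * self.n_chromosomes
        if len(self.chrom_lengths) != self.n_chromosomes:
            raise ValueError("chrom_lengths must match n_chromosomes")
        return list(self.chrom_lengths)

    def validate(self) -> None:
        if any(l <= 0 for l in self.lengths()):
            raise ValueError("chromosome lengths must be positive")
        if not (0 <= self.gap_fraction < 0.5):
            raise ValueError("gap_fraction must be in [0, 0.5)")
        if not (0 < self.active_fraction <= 1):
            raise ValueError("active_fraction must be in (0, 1]")
        if self.g4_spacing_target < 100:
            raise ValueError("g4_spacing_target too small to host motifs")
        if min(self.lengths()) < 10 * self.g4_spacing_target:
            raise ValueError(
                "chromosome too short for requested feature density: "
                f"need >= {int(10 * self.g4_spacing_target)} bases"
            )


@dataclass
class SimulationParams:
    """Parameters for single-cell read simulation.

    ``coverage_fraction`` of 0.015 matches the ~1-2% per-library genome
    coverage typical of Strand-seq; ``read_length`` 50 matches
    single-end 50 bp sequencing; the SCE rate is a BS-like rate scaled
    to the synthetic genome size (roughly 2 exchanges per 90 Mb).
    """

    n_cells: int = 300
    sce_rate_per_cell: float = 2.0
    g4_enrichment_factor: float = 1.0
    coverage_fraction: float = 0.015
    read_length: int = 50
    background_noise: float = 0.02
    size_cutoff_calibration: int = 10_000
    excess_weight: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.g4_enrichment_factor < 0:
            raise ValueError("g4_enrichment_factor must be >= 0")
        if not (0 < self.coverage_fraction <= 1):
            raise ValueError("coverage_fraction must be in (0, 1]")
        if not (0 <= self.background_noise < 0.5):
            raise ValueError("background_noise must be in [0, 0.5)")
        if self.read_length <= 0 or self.n_cells <= 0:
            raise ValueError("read_length and n_cells must be positive")


@dataclass
class TruthSet:
    """Ground truth emitted alongside every simulated dataset."""

    true_sces: pd.DataFrame  # cell, chrom, pos, homolog
    true_loh: pd.DataFrame  # chrom, start, end, haplotype_retained (clonal)
    true_trisomies: list[tuple[str, str]]  # (chrom, duplicated haplotype)
    allelic_g4_truth: pd.DataFrame  # chrom, start, end, strand, haplotype
    excess_weight: float = 0.0  # realized mixture weight of the G4 component
    snp_alleles: dict | None = None  # chrom -> {pos: (allele_A, allele_B)} in F1 mode

    def to_dict(self) -> dict:
        return {
            "true_sces": self.true_sces.to_dict(orient="list"),
            "true_loh": self.true_loh.to_dict(orient="list"),
            "true_trisomies": [list(t) for t in self.true_trisomies],
            "allelic_g4_truth": self.allelic_g4_truth.to_dict(orient="list"),
            "excess_weight": self.excess_weight,
        }


@dataclass
class SyntheticGenome:
    sequences: dict[str, str]
    genome_index: GenomeIndex
    genes: pd.DataFrame  # gene_id, chrom, tss, tes, strand
    expression: pd.DataFrame  # gene_id, fpkm
    g4_motifs: pd.DataFrame  # full rescan of the generated sequence
    planted_g4: pd.DataFrame  # motifs written by the generator
    spec: SyntheticGenomeSpec = field(repr=False, default=None)


def _place_gaps(rng, length: int, gap_fraction: float) -> np.ndarray:
    if gap_fraction <= 0:
        return np.empty((0, 2), dtype=np.int64)
    total = int(round(length * gap_fraction))
    n_gaps = max(1, min(3, total // 50_000)) if total >= 1000 else 1
    widths = np.full(n_gaps, total // n_gaps, dtype=np.int64)
    widths[0] += total - widths.sum()
    placed: list[tuple[int, int]] = []
    for w in widths:
        for _ in range(1000):
            s = int(rng.integers(0, length - w))
            if all(s + w + 1000 <= ps or s >= pe + 1000 for ps, pe in placed):
                placed.append((s, s + int(w)))
                break
        else:  # pragma: no cover - pathological fraction
            raise ValueError("could not place assembly gaps; gap_fraction too high")
    placed.sort()
    return np.asarray(placed, dtype=np.int64)


def _random_sequence(rng, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _plant_motifs(rng, arr: np.ndarray, gaps: np.ndarray, spacing: float, base: str = "G") -> list[tuple[int, int, str]]:
    """Write quadruplex motifs at ~exponential spacing; skip gaps."""
    length = len(arr)
    anchor = ord(base)
    comp = ord({"G": "C", "A": "T"}[base])
    gap_starts = gaps[:, 0] if gaps.size else np.empty(0, dtype=np.int64)
    gap_ends = gaps[:, 1] if gaps.size else np.empty(0, dtype=np.int64)
    out = []
    pos = int(rng.exponential(spacing)) + 1
    while pos < length - 60:
        run_lens = rng.integers(3, 5, size=4)
        loop_lens = rng.integers(1, 8, size=3)
        strand = "+" if rng.random() < 0.5 else "-"
        # build motif bytes: anchor runs joined by loops drawn from the
        # two bases that can neither extend a run nor seed a complement run
        loop_alphabet = np.frombuffer(b"AT" if base == "G" else b"CG", dtype=np.uint8)
        parts = []
        for k in range(4):
            parts.append(np.full(run_lens[k], anchor, dtype=np.uint8))
            if k < 3:
                parts.append(loop_alphabet[rng.integers(0, 2, size=loop_lens[k])])
        motif = np.concatenate(parts)
        if strand == "-":
            table = np.zeros(256, dtype=np.uint8)
            for a, b in zip(b"ACGT", b"TGCA"):
                table[a] = b
            motif = table[motif[::-1]]
        mlen = len(motif)
        end = pos + mlen
        # reject placements whose motif or sanitized flanks touch a gap
        j = np.searchsorted(gap_ends, pos - 8, side="right")
        in_gap = j < len(gap_starts) and gap_starts[j] < end + 8
        if not in_gap and end + 8 < length and pos >= 8:
            arr[pos:end] = motif
            # clear 8 bases on each flank of anchor/complement bases so no
            # background run can chain into the motif (max loop is 7)
            for flank in (slice(pos - 8, pos), slice(end, end + 8)):
                seg = arr[flank]
                mask = (seg == anchor) | (seg == comp)
                seg[mask] = loop_alphabet[rng.integers(0, 2, size=int(mask.sum()))]
            out.append((pos, end, strand))
        pos = end + 20 + int(rng.exponential(spacing)) + 1
    return out


def _place_genes(rng, spec: SyntheticGenomeSpec, gi: GenomeIndex) -> pd.DataFrame:
    lengths = gi.lengths
    chroms = list(lengths)
    weights = np.array([lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    rows = []
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for g in range(spec.gene_count):
        for _ in range(2000):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            L = lengths[chrom]
            glen = int(rng.integers(20_000, 150_000))
            s = int(rng.integers(0, max(1, L - glen)))
            e = s + glen
            gaps = gi.gaps[chrom]
            hits_gap = gaps.size and np.any((gaps[:, 0] < e) & (gaps[:, 1] > s))
            hits_gene = any(ps < e and pe > s for ps, pe in placed[chrom])
            if not hits_gap and not hits_gene:
                placed[chrom].append((s, e))
                strand = "+" if rng.random() < 0.5 else "-"
                tss, tes = (s, e) if strand == "+" else (e, s)
                rows.append((f"gene_{g:04d}", chrom, tss, tes, strand))
                break
        else:
            raise ValueError("chromosomes too short to place requested gene count")
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "tes", "strand"])


def generate_genome(spec: SyntheticGenomeSpec) -> SyntheticGenome:
    """Generate a genome, gene annotation, expression table and G4 truth.

    The planted motif set is returned together with a full rescan of the
    generated sequence (planted plus the rare spontaneous motifs), which
    serves as the definitive motif track for downstream analysis.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lengths = spec.lengths()
    chroms = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    sequences: dict[str, str] = {}
    gaps: dict[str, np.ndarray] = {}
    planted_rows = []
    for chrom, L in zip(chroms, lengths):
        g = _place_gaps(rng, L, spec.gap_fraction)
        arr = _random_sequence(rng, L)
        for s, e in g:
            arr[s:e] = ord("N")
        for s, e, strand in _plant_motifs(rng, arr, g, spec.g4_spacing_target):
            planted_rows.append((chrom, s, e, strand))
        gaps[chrom] = g
        sequences[chrom] = arr.tobytes().decode("ascii")
    gi = GenomeIndex(lengths=dict(zip(chroms, lengths)), gaps=gaps)
    planted = pd.DataFrame(planted_rows, columns=["chrom", "start", "end", "strand"])
    genes = _place_genes(rng, spec, gi)
    n_active = int(round(spec.active_fraction * spec.gene_count))
    fpkm = np.empty(spec.gene_count)
    fpkm[:n_active] = 1.0 + rng.lognormal(mean=1.5, sigma=1.0, size=n_active)
    fpkm[n_active:] = rng.uniform(0.0, 0.99, size=spec.gene_count - n_active)
    order = rng.permutation(spec.gene_count)
    expression = pd.DataFrame({"gene_id": genes["gene_id"], "fpkm": np.round(fpkm[order], 4)})
    g4_motifs = features.scan_genome(sequences, loop_min=1, loop_max=7)
    return SyntheticGenome(
        sequences=sequences,
        genome_index=gi,
        genes=genes,
        expression=expression,
        g4_motifs=g4_motifs,
        planted_g4=planted,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def _active_gene_motifs(genome_or_parts) -> pd.DataFrame:
    genes, expression, motifs = genome_or_parts
    genes_act = features.attach_activity(genes, expression)
    bodies = features.gene_bodies(genes_act)
    active = bodies[bodies["activity"] == "active"]
    keep = np.zeros(len(motifs), dtype=bool)
    mids = ((motifs["start"] + motifs["end"]) // 2).to_numpy()
    mchrom = motifs["chrom"].to_numpy()
    for chrom, sub in active.groupby("chrom", sort=False):
        gs = np.sort(sub["start"].to_numpy())
        ge = sub.sort_values("start")["end"].to_numpy()
        mask = mchrom == chrom
        idx = np.searchsorted(gs, mids[mask], side="right") - 1
        ok = (idx >= 0) & (mids[mask] < ge[np.maximum(idx, 0)])
        keep[np.flatnonzero(mask)[ok]] = True
    return motifs[keep].reset_index(drop=True)


def calibrate_excess_ratio(
    genome: SyntheticGenome,
    params: SimulationParams,
    n_pilot_cells: int = 120,
    pilot_rate: float = 5.0,
    n_shifts: int = 200,
    seed: int | None = None,
) -> float:
    """Calibration ratio converting an enrichment factor into a mixture weight.

    The target factor f is defined on the measurement scale: the
    expected relative enrichment (observed / null overlap) of called,
    cutoff-filtered SCE regions against the G4 motif track.  Because a
    called region's boundary is only statistically localized, a region
    whose breakpoint sits inside a motif covers that motif with
    probability well below one, so the weight cannot be derived from
    geometry alone.  Instead a pilot dataset with every exchange placed
    inside an active-gene motif is simulated and processed with the
    production caller and size cutoff, giving the per-region motif
    coverage p1; the null overlap p0 comes from random circular shifts
    of the same regions.  The mixture weight for factor f is then
    ``(f - 1) * r`` with ``r = p0 / (p1 - p0)``, which makes the
    expected relative enrichment equal f by construction.
    """
    from . import enrichment as _enrichment
    from . import sce as _sce

    rng = np.random.default_rng(params.seed + 991 if seed is None else seed)
    pilot = replace(
        params,
        n_cells=n_pilot_cells,
        sce_rate_per_cell=pilot_rate,
        g4_enrichment_factor=1.0,
        excess_weight=None,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    prng = np.random.default_rng(pilot.seed)
    reads, _ = _simulate_reads(genome, pilot, prng, f1=None, w_excess=1.0)
    called = _sce.call_sces_for_cells(reads)
    regions = called[(called["end"] - called["start"]) <= params.size_cutoff_calibration]
    if len(regions) < 50:
        raise ValueError("calibration pilot produced too few SCE regions")
    gmap = GaplessMap(genome.genome_index)
    index = _enrichment._FoiIndex(genome.g4_motifs, gmap)
    hits1 = 0
    null_hits = 0
    null_total = 0
    shifts = rng.integers(2_000_000, 50_000_001, size=n_shifts)
    for chrom, sub in regions.groupby("chrom", sort=False):
        L = gmap.effective_length(chrom)
        gl = np.array(
            [gmap.interval_to_gapless(chrom, int(r.start), int(r.end)) for r in sub.itertuples()],
            dtype=np.int64,
        )
        gs, ge = gl[:, 0], gl[:, 1]
        hits1 += int(index.any_overlap(chrom, gs, ge).sum())
        s = (gs[:, None] + shifts[None, :]) % L
        e = s + (ge - gs)[:, None]
        wrap = e > L
        hit = index.any_overlap(chrom, s, np.minimum(e, L))
        if wrap.any():
            hit |= wrap & index.any_overlap(chrom, np.zeros_like(s), np.where(wrap, e - L, 0))
        null_hits += int(hit.sum())
        null_total += hit.size
    p1 = hits1 / len(regions)
    p0 = null_hits / null_total
    if p1 <= p0:
        raise ValueError(
            f"calibration failed: motif coverage p1={p1:.3f} does not exceed null p0={p0:.3f}"
        )
    return p0 / (p1 - p0)


def _sample_motif_bases(rng, motifs: pd.DataFrame, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Uniformly sample n bases from a motif interval set -> (row idx, pos)."""
    widths = (motifs["end"] - motifs["start"]).to_numpy()
    cum = np.cumsum(widths)
    u = rng.integers(0, cum[-1], size=n)
    idx = np.searchsorted(cum, u, side="right")
    offset = u - (cum[idx] - widths[idx])
    pos = motifs["start"].to_numpy()[idx] + offset
    return idx, pos


class _F1Options:
    def __init__(self, snps_by_chrom, snp_hap_allele, allelic_motifs, loh, trisomy, concordance):
        self.snps_by_chrom = snps_by_chrom  # chrom -> sorted positions
        self.snp_hap_allele = snp_hap_allele  # unused by read engine; kept for sequences
        self.allelic_motifs = allelic_motifs  # DataFrame or None
        self.loh = loh  # list of (chrom, start, end, hap)
        self.trisomy = trisomy  # dict chrom -> duplicated hap
        self.concordance = concordance  # prob SCE sits on intact homolog near allelic motif


def _simulate_reads(
    genome: SyntheticGenome,
    params: SimulationParams,
    rng: np.random.Generator,
    f1: _F1Options | None = None,
    w_excess: float = 0.0,
) -> tuple[pd.DataFrame, TruthSet]:
    gi = genome.genome_index
    gmap = GaplessMap(gi)
    chroms = gi.chromosomes
    eff = np.array([gmap.effective_length(c) for c in chroms], dtype=float)
    chrom_probs = eff / eff.sum()
    lam = params.coverage_fraction / params.read_length

    active_motifs = _active_gene_motifs((genome.genes, genome.expression, genome.g4_motifs))
    if w_excess > 0 and active_motifs.empty:
        raise ValueError("no G4 motifs in active genes; cannot plant enrichment")
    am_sorted = active_motifs.sort_values(["chrom", "start"]).reset_index(drop=True)
    motif_pos_by_chrom = {
        c: (s["start"].to_numpy(), s["end"].to_numpy())
        for c, s in am_sorted.groupby("chrom", sort=False)
    }

    # allele-specific motif lookup for concordance biasing (F1 mode)
    if f1 is not None and f1.allelic_motifs is not None and len(f1.allelic_motifs):
        am = f1.allelic_motifs.sort_values(["chrom", "start"])
        am_by_chrom = {
            c: (s["start"].to_numpy(), s["end"].to_numpy(), s["haplotype"].to_numpy())
            for c, s in am.groupby("chrom", sort=False)
        }
    else:
        am_by_chrom = {}

    hap_codes = {"A": 0, "B": 1}
    # per-read accumulators (integer codes; strings materialized once at the end)
    acc_chrom: list[np.ndarray] = []
    acc_start: list[np.ndarray] = []
    acc_label: list[np.ndarray] = []
    acc_hap: list[np.ndarray] = []
    acc_cell: list[np.ndarray] = []
    chrom_code = {c: i for i, c in enumerate(chroms)}

    sce_rows = []
    low_coverage = 0
    for ci in range(params.n_cells):
        cell = f"cell_{ci:04d}"
        n_sce = int(rng.poisson(params.sce_rate_per_cell))
        sce_chrom: list[str] = []
        sce_pos: list[int] = []
        for _ in range(n_sce):
            if w_excess > 0 and rng.random() < w_excess:
                idx, pos = _sample_motif_bases(rng, am_sorted, 1)
                sce_chrom.append(str(am_sorted["chrom"].iloc[int(idx[0])]))
                sce_pos.append(int(pos[0]))
                continue
            c = chroms[int(rng.choice(len(chroms), p=chrom_probs))]
            g = int(gmap.to_genomic(c, [int(rng.integers(0, gmap.effective_length(c)))])[0])
            if params.g4_enrichment_factor < 1.0:
                # per-base thinning of motif bases for depletion factors
                while _pos_in_sorted(motif_pos_by_chrom.get(c), g) and rng.random() > params.g4_enrichment_factor:
                    c = chroms[int(rng.choice(len(chroms), p=chrom_probs))]
                    g = int(gmap.to_genomic(c, [int(rng.integers(0, gmap.effective_length(c)))])[0])
            sce_chrom.append(c)
            sce_pos.append(g)

        for chrom in chroms:
            L_eff = gmap.effective_length(chrom)
            rate_scale = 1.5 if (f1 and chrom in f1.trisomy) else 1.0
            n_reads = int(rng.poisson(lam * L_eff * rate_scale))
            if n_reads < 2:
                low_coverage += 1
            starts = np.sort(gmap.to_genomic(chrom, rng.integers(0, L_eff, size=n_reads)))

            # initial state uniform over {WW, WC, CC}; template 1=W, 0=C
            state = int(rng.integers(0, 3))
            if state == 0:
                tmpl = np.array([1, 1], dtype=np.int8)
            elif state == 2:
                tmpl = np.array([0, 0], dtype=np.int8)
            else:
                tmpl = np.array([1, 0], dtype=np.int8) if rng.random() < 0.5 else np.array([0, 1], dtype=np.int8)

            # source homolog per read: 0=A, 1=B
            if f1 and chrom in f1.trisomy:
                dup = hap_codes[f1.trisomy[chrom]]
                src = np.where(rng.random(n_reads) < (2.0 / 3.0), dup, 1 - dup).astype(np.int8)
            else:
                src = (rng.random(n_reads) < 0.5).astype(np.int8)
            if f1 is not None:
                for lchrom, ls, le, lhap in f1.loh:
                    if lchrom == chrom:
                        inside = (starts >= ls) & (starts < le)
                        src[inside] = hap_codes[lhap]

            # assign each SCE on this chromosome to a homolog (with optional
            # concordance bias towards the intact-motif haplotype)
            bp_here = sorted(p for c, p in zip(sce_chrom, sce_pos) if c == chrom)
            bp_by_hom: dict[int, list[int]] = {0: [], 1: []}
            for p in bp_here:
                hom = int(rng.random() < 0.5)
                if f1 is not None and chrom in am_by_chrom:
                    ams, ame, amh = am_by_chrom[chrom]
                    j = int(np.searchsorted(ams, p, side="right"))
                    near = None
                    for cand in (j - 1, j):
                        if 0 <= cand < len(ams):
                            d = 0 if ams[cand] <= p < ame[cand] else min(abs(p - int(ame[cand])), abs(int(ams[cand]) - p))
                            if d <= 15_000:
                                near = cand
                                break
                    if near is not None:
                        intact = hap_codes[amh[near]]
                        hom = intact if rng.random() < f1.concordance else 1 - intact
                bp_by_hom[hom].append(p)
                # observable localization window: between the flipping
                # homolog's flanking reads (filled in below)
                sce_rows.append([cell, chrom, int(p), "AB"[hom], 0, gi.lengths[chrom]])

            label = np.empty(n_reads, dtype=np.int8)
            for hom in (0, 1):
                bp = np.asarray(bp_by_hom[hom], dtype=np.int64)
                sel = src == hom
                parity = (np.searchsorted(bp, starts[sel], side="right") % 2).astype(np.int8)
                label[sel] = tmpl[hom] ^ parity
                # localization windows for this homolog's breakpoints
                h_starts = starts[sel]
                if bp.size:
                    j = np.searchsorted(h_starts, bp, side="left")
                    for k, p in enumerate(bp):
                        row = next(r for r in reversed(sce_rows) if r[0] == cell and r[1] == chrom and r[2] == int(p))
                        left_end = int(h_starts[j[k] - 1]) + params.read_length if j[k] > 0 else 0
                        right_start = int(h_starts[j[k]]) if j[k] < len(h_starts) else gi.lengths[chrom]
                        # a read spanning the breakpoint carries its start's
                        # state; clamp so the window always contains the bp
                        row[4] = min(left_end, int(p))
                        row[5] = max(right_start, int(p) + 1)
            flip = rng.random(n_reads) < params.background_noise
            label[flip] ^= 1

            hap = np.full(n_reads, 2, dtype=np.int8)  # 2 = untagged
            if f1 is not None:
                snp_pos = f1.snps_by_chrom.get(chrom)
                if snp_pos is not None and snp_pos.size:
                    n_in = np.searchsorted(snp_pos, starts + params.read_length) - np.searchsorted(snp_pos, starts)
                    hap[n_in > 0] = src[n_in > 0]

            acc_chrom.append(np.full(n_reads, chrom_code[chrom], dtype=np.int16))
            acc_start.append(starts)
            acc_label.append(label)
            acc_hap.append(hap)
            acc_cell.append(np.full(n_reads, ci, dtype=np.int32))

    if low_coverage:
        warnings.warn(f"{low_coverage} cell-chromosomes had < 2 reads; emitted anyway")

    starts_all = np.concatenate(acc_start) if acc_start else np.empty(0, dtype=np.int64)
    label_all = np.concatenate(acc_label) if acc_label else np.empty(0, dtype=np.int8)
    hap_all = np.concatenate(acc_hap) if acc_hap else np.empty(0, dtype=np.int8)
    cell_names = [f"cell_{i:04d}" for i in range(params.n_cells)]
    reads = pd.DataFrame(
        {
            "chrom": pd.Categorical.from_codes(
                np.concatenate(acc_chrom) if acc_chrom else np.empty(0, dtype=np.int16), categories=chroms
            ).astype(str),
            "start": starts_all,
            "end": starts_all + params.read_length,
            "label": np.array(["C", "W"], dtype=object)[label_all],
            "hap": np.array(["A", "B", "."], dtype=object)[hap_all],
            "cell": pd.Categorical.from_codes(
                np.concatenate(acc_cell) if acc_cell else np.empty(0, dtype=np.int32), categories=cell_names
            ).astype(str),
        }
    )
    true_sces = pd.DataFrame(
        sce_rows, columns=["cell", "chrom", "pos", "homolog", "window_start", "window_end"]
    )
    loh_df = pd.DataFrame(
        [(c, s, e, h) for c, s, e, h in (f1.loh if f1 else [])],
        columns=["chrom", "start", "end", "haplotype_retained"],
    )
    truth = TruthSet(
        true_sces=true_sces,
        true_loh=loh_df,
        true_trisomies=[(c, h) for c, h in (f1.trisomy.items() if f1 else [])],
        allelic_g4_truth=(
            f1.allelic_motifs
            if f1 is not None and f1.allelic_motifs is not None
            else pd.DataFrame(columns=["chrom", "start", "end", "strand", "haplotype"])
        ),
        excess_weight=w_excess,
    )
    return reads, truth


def _pos_in_sorted(arrs, pos: int) -> bool:
    if arrs is None:
        return False
    ms, me = arrs
    j = int(np.searchsorted(ms, pos, side="right")) - 1
    return j >= 0 and pos < me[j]


def _resolve_excess_weight(genome: SyntheticGenome, params: SimulationParams) -> float:
    """Mixture weight of the motif-placed component for this parameter set."""
    f = params.g4_enrichment_factor
    if f <= 1.0:
        return 0.0
    if params.excess_weight is not None:
        return float(params.excess_weight)
    w = (f - 1.0) * calibrate_excess_ratio(genome, params)
    if w > 0.95:
        warnings.warn(f"factor {f} requires mixture weight {w:.2f}; capping at 0.95")
        w = 0.95
    return w


def simulate_cells(
    genome: SyntheticGenome, params: SimulationParams
) -> tuple[pd.DataFrame, TruthSet]:
    """Simulate directional reads for ``params.n_cells`` single cells.

    Returns the read table (chrom, start, end, W|C label, haplotype tag,
    cell id) and the ground-truth :class:`TruthSet`.
    """
    params.validate()
    w = _resolve_excess_weight(genome, params)
    rng = np.random.default_rng(params.seed)
    return _simulate_reads(genome, params, rng, f1=None, w_excess=w)


def simulate_f1_hybrid(
    genome: SyntheticGenome,
    params: SimulationParams,
    snp_rate: float | None = None,
    planted_loh: list[tuple[str, int, int, str]] | None = None,
    planted_trisomy: list[str] | None = None,
    allelic_fraction: float = 0.2,
    concordance: float = 0.5,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthSet]:
    """Simulate an F1-hybrid line with haplotype-tagged reads.

    SNPs are placed at ``snp_rate`` per non-gap base.  A fraction of the
    planted G4 motifs is made allele-specific by writing a run-breaking
    substitution into one haplotype.  ``concordance`` is the probability
    that an SCE arising within 15 kb of an allele-specific motif is
    placed on the motif-bearing homolog (0.5 = no causal link).
    Clonal LOH segments (copy-neutral: reads in the segment all come
    from the retained haplotype at unchanged density) and trisomies
    (1.5x read density, duplicated haplotype sampled at 2/3) apply to
    every cell.

    Returns ``(reads, allelic_g4_table, truth)``.
    """
    params.validate()
    if snp_rate is None:
        snp_rate = genome.spec.snp_rate if genome.spec else 0.008
    if snp_rate <= 0:
        raise ValueError("snp_rate must be > 0 in F1-hybrid mode")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    gi = genome.genome_index
    gmap = GaplessMap(gi)

    # engineered allele-specific motifs: break one haplotype's first run
    planted = genome.planted_g4.reset_index(drop=True)
    n_allelic = int(round(allelic_fraction * len(planted)))
    pick = np.sort(rng.choice(len(planted), size=n_allelic, replace=False)) if n_allelic else np.array([], dtype=int)
    al_rows = []
    motif_snps: dict[tuple[str, int], tuple[str, str]] = {}  # (chrom,pos) -> (allele_A, allele_B)
    for i in pick:
        row = planted.iloc[int(i)]
        intact = "A" if rng.random() < 0.5 else "B"
        pos = int(row["start"]) + 1  # second base of the first run
        ref = genome.sequences[row["chrom"]][pos]
        broken_allele = {"G": "A", "C": "T"}.get(ref)
        if broken_allele is None:  # motif start not on an anchor base; skip
            continue
        alleles = (ref, broken_allele) if intact == "A" else (broken_allele, ref)
        motif_snps[(row["chrom"], pos)] = alleles
        al_rows.append((row["chrom"], int(row["start"]), int(row["end"]), row["strand"], intact))
    allelic_g4 = pd.DataFrame(al_rows, columns=["chrom", "start", "end", "strand", "haplotype"])

    # background SNPs outside any scanned motif (so the engineered set
    # stays the exact allele-specific truth)
    snps_by_chrom: dict[str, np.ndarray] = {}
    snp_alleles: dict[str, dict[int, tuple[str, str]]] = {}
    for chrom in gi.chromosomes:
        L_eff = gmap.effective_length(chrom)
        n_snp = rng.poisson(snp_rate * L_eff)
        pos = np.unique(gmap.to_genomic(chrom, rng.integers(0, L_eff, size=n_snp)))
        sub = genome.g4_motifs[genome.g4_motifs["chrom"] == chrom]
        if len(sub):
            ms = np.sort(sub["start"].to_numpy() - 1)
            me = sub.sort_values("start")["end"].to_numpy() + 1
            j = np.searchsorted(ms, pos, side="right") - 1
            in_motif = (j >= 0) & (pos < me[np.maximum(j, 0)])
            pos = pos[~in_motif]
        alleles: dict[int, tuple[str, str]] = {}
        seq = genome.sequences[chrom]
        alt_choices = rng.integers(0, 3, size=len(pos))
        hap_of_alt = rng.random(len(pos)) < 0.5
        for p, altc, a_is_alt in zip(pos, alt_choices, hap_of_alt):
            ref = seq[p]
            if ref == "N":
                continue
            alts = [b for b in "ACGT" if b != ref]
            alt = alts[int(altc)]
            alleles[int(p)] = (alt, ref) if a_is_alt else (ref, alt)
        for (c, p), al in motif_snps.items():
            if c == chrom:
                alleles[p] = al
        snp_alleles[chrom] = alleles
        snps_by_chrom[chrom] = np.array(sorted(alleles), dtype=np.int64)

    trisomy = {}
    for chrom in planted_trisomy or []:
        trisomy[chrom] = "A" if rng.random() < 0.5 else "B"
    f1 = _F1Options(
        snps_by_chrom=snps_by_chrom,
        snp_hap_allele=snp_alleles,
        allelic_motifs=allelic_g4,
        loh=list(planted_loh or []),
        trisomy=trisomy,
        concordance=concordance,
    )
    reads, truth = _simulate_reads(
        genome, params, rng, f1=f1, w_excess=_resolve_excess_weight(genome, params)
    )
    truth.snp_alleles = snp_alleles
    return reads, allelic_g4, truth


def haplotype_sequences(genome: SyntheticGenome, snp_alleles: dict[str, dict[int, tuple[str, str]]]) -> tuple[dict[str, str], dict[str, str]]:
    """Materialize haplotype A and B sequences from reference + SNP alleles."""
    hapA, hapB = {}, {}
    for chrom, seq in genome.sequences.items():
        a = bytearray(seq, "ascii")
        b = bytearray(seq, "ascii")
        for pos, (al_a, al_b) in snp_alleles.get(chrom, {}).items():
            a[pos] = ord(al_a)
            b[pos] = ord(al_b)
        hapA[chrom] = a.decode("ascii")
        hapB[chrom] = b.decode("ascii")
    return hapA, hapB
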