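"""Circular-shift permutation test for SCE / feature overlap.

The observed statistic is the number of SCE regions intersecting at
least one feature interval (binary per region: a region overlapping
three motifs counts once).  The null distribution is built by shifting
every region downstream by a random offset drawn uniformly from
[shift_min, shift_max] bases, wrapping around the end of each
chromosome as if it were circular.  All arithmetic happens in
gap-excluded ("gapless") coordinates so a shifted region can never land
inside an assembly gap; features are likewise projected into gapless
space (clipped at gap boundaries) before overlap counting.  Enrichment
is reported relative to the median permuted overlap, and the empirical
p-value is the fraction of permutations with overlap at least (for
enrichment) or at most (for depletion) the observed count, floored at
1/n_permutations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GaplessMap


@dataclass
class PermutationResult:
    foi_name: str
    n_sces_used: int
    observed_overlap: int
    permuted_overlaps: np.ndarray
    median_permuted: float
    relative_enrichment: float | None
    p_enrich: float
    p_deplete: float
    p_enrich_str: str
    p_deplete_str: str
    n_permutations: int
    seed: int | None
    n_dropped_gap: int = 0

    def to_dict(self, include_permutations: bool = False) -> dict:
        d = {
            "foi_name": self.foi_name,
            "n_sces_used": self.n_sces_used,
            "observed_overlap": self.observed_overlap,
            "median_permuted": self.median_permuted,
            "relative_enrichment": self.relative_enrichment,
            "p_enrich": self.p_enrich,
            "p_deplete": self.p_deplete,
            "p_enrich_str": self.p_enrich_str,
            "p_deplete_str": self.p_deplete_str,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "n_dropped_gap": self.n_dropped_gap,
        }
        if include_permutations:
            d["permuted_overlaps"] = self.permuted_overlaps.tolist()
        return d


def build_gapless_map(genome_index) -> GaplessMap:
    """Gap-excluded coordinate map (see :class:`g4sce.genome.GaplessMap`)."""
    return GaplessMap(genome_index)


def apply_size_cutoff(sces: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Keep regions whose mapping resolution is at most the cutoff (inclusive)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    res = sces["end"] - sces["start"]
    return sces[res <= cutoff].reset_index(drop=True)


def add_flanks(sces: pd.DataFrame, flank: int, genome_index) -> pd.DataFrame:
    """Widen regions by `flank` bases on both sides, clipped at chromosome ends."""
    out = sces.copy()
    out["start"] = np.maximum(out["start"] - flank, 0)
    lim = out["chrom"].map(genome_index.lengths).to_numpy()
    out["end"] = np.minimum(out["end"] + flank, lim)
    if "resolution" in out.columns:
        out["resolution"] = out["end"] - out["start"]
    return out


def subsample_sces(sces: pd.DataFrame, target_n: int, seed: int | None = None) -> pd.DataFrame:
    """Uniform sample without replacement of `target_n` regions."""
    if target_n > len(sces):
        raise ValueError("target_n exceeds number of regions")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(sces), size=target_n, replace=False))
    return sces.iloc[idx].reset_index(drop=True)


def shift_regions(sces: pd.DataFrame, n: int, gmap: GaplessMap) -> pd.DataFrame:
    """Shift every region downstream by n bases on a circular chromosome.

    Operates in gapless coordinates: the region is moved +n modulo the
    chromosome's effective (gap-excluded) length and mapped back to
    genomic coordinates.  A region wrapping the origin splits into two
    arcs; a region crossing assembly gaps in genomic space likewise
    splits into one genomic piece per non-gap block.  The ``region_id``
    column identifies pieces of the same region.  A region that overlaps
    a gap cannot be mapped and raises ``ValueError``.
    """
    if n < 0:
        raise ValueError("shift must be non-negative")
    rows = []
    for rid, row in enumerate(sces.itertuples()):
        chrom = row.chrom
        gs, ge = gmap.interval_to_gapless(chrom, int(row.start), int(row.end))
        L = gmap.effective_length(chrom)
        s = (gs + n) % L
        e = s + (ge - gs)
        arcs = [(s, min(e, L))]
        if e > L:
            arcs.append((0, e - L))
        for a, b in arcs:
            for g0, g1 in gmap.gapless_interval_to_genomic(chrom, a, b):
                rows.append((chrom, g0, g1, rid))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "region_id"])


class _FoiIndex:
    """Merged feature intervals per chromosome, in gapless coordinates."""

    def __init__(self, foi: pd.DataFrame, gmap: GaplessMap):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in gmap.genome_index.chromosomes:
            sub = foi[foi["chrom"] == chrom]
            pieces: list[tuple[int, int]] = []
            for row in sub.itertuples():
                pieces.extend(gmap.interval_to_gapless_pieces(chrom, int(row.start), int(row.end)))
            if not pieces:
                continue
            pieces.sort()
            merged = [list(pieces[0])]
            for a, b in pieces[1:]:
                if a <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], b)
                else:
                    merged.append([a, b])
            arr = np.asarray(merged, dtype=np.int64)
            self.by_chrom[chrom] = (arr[:, 0], arr[:, 1])

    def any_overlap(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Vectorized: does [start, end) intersect any feature interval?"""
        if chrom not in self.by_chrom:
            return np.zeros(starts.shape, dtype=bool)
        fs, fe = self.by_chrom[chrom]
        j = np.searchsorted(fe, starts, side="right")
        j_c = np.minimum(j, len(fs) - 1)
        return (j < len(fs)) & (fs[j_c] < ends) & (fe[j_c] > starts)


def permute_overlap(
    sces: pd.DataFrame,
    foi: pd.DataFrame,
    gmap: GaplessMap,
    n_permutations: int = 1000,
    shift_min: int = 2_000_000,
    shift_max: int = 50_000_000,
    seed: int | None = None,
    per_chromosome: bool = False,
    foi_name: str = "foi",
    on_gap: str = "drop",
) -> PermutationResult:
    """Circular-shift permutation test of SCE / feature overlap.

    One shift is drawn uniformly from [shift_min, shift_max] per
    permutation and applied to all regions (``per_chromosome=True``
    draws an independent shift per chromosome instead).  Regions
    overlapping assembly gaps are dropped (``on_gap='drop'``, recorded
    in the result) or raise (``on_gap='error'``).
    """
    rng = np.random.default_rng(seed)
    keep_mask = np.array(
        [not gmap.overlaps_gap(r.chrom, int(r.start), int(r.end)) for r in sces.itertuples()],
        dtype=bool,
    ) if len(sces) else np.zeros(0, dtype=bool)
    n_dropped = int((~keep_mask).sum())
    if n_dropped and on_gap == "error":
        bad = sces[~keep_mask].iloc[0]
        raise ValueError(f"SCE region {bad['chrom']}:{bad['start']}-{bad['end']} overlaps an assembly gap")
    used = sces[keep_mask].reset_index(drop=True)

    index = _FoiIndex(foi, gmap)
    shifts = rng.integers(shift_min, shift_max + 1, size=n_permutations)

    observed = 0
    permuted = np.zeros(n_permutations, dtype=np.int64)
    for chrom, sub in used.groupby("chrom", sort=False):
        L = gmap.effective_length(chrom)
        gl = np.array(
            [gmap.interval_to_gapless(chrom, int(r.start), int(r.end)) for r in sub.itertuples()],
            dtype=np.int64,
        )
        gs, ge = gl[:, 0], gl[:, 1]
        lengths = ge - gs
        observed += int(index.any_overlap(chrom, gs, ge).sum())
        if per_chromosome:
            chrom_shifts = rng.integers(shift_min, shift_max + 1, size=n_permutations)
        else:
            chrom_shifts = shifts
        s = (gs[:, None] + chrom_shifts[None, :]) % L
        e = s + lengths[:, None]
        wrap = e > L
        hit = index.any_overlap(chrom, s, np.minimum(e, L))
        if wrap.any():
            zeros = np.zeros_like(s)
            hit |= wrap & index.any_overlap(chrom, zeros, np.where(wrap, e - L, 0))
        # shift invariants: count and gapless length conserved by construction
        permuted += hit.sum(axis=0)

    n_exceed = int((permuted >= observed).sum())
    n_recede = int((permuted <= observed).sum())
    p_enrich = max(n_exceed, 1) / n_permutations
    p_deplete = max(n_recede, 1) / n_permutations
    med = float(np.median(permuted))
    rel = float(observed / med) if med > 0 else None
    return PermutationResult(
        foi_name=foi_name,
        n_sces_used=int(len(used)),
        observed_overlap=int(observed),
        permuted_overlaps=permuted,
        median_permuted=med,
        relative_enrichment=rel,
        p_enrich=p_enrich,
        p_deplete=p_deplete,
        p_enrich_str=(f"< {1 / n_permutations:g}" if n_exceed == 0 else f"{p_enrich:g}"),
        p_deplete_str=(f"< {1 / n_permutations:g}" if n_recede == 0 else f"{p_deplete:g}"),
        n_permutations=n_permutations,
        seed=seed,
        n_dropped_gap=n_dropped,
    )


def expression_quartile_correlation(
    sces: pd.DataFrame, genes: pd.DataFrame, expression: pd.DataFrame
) -> tuple[float, np.ndarray]:
    """R^2 of per-quartile SCE counts against expression quartile rank.

    Active genes (FPKM > 1) are split into four equal-size categories by
    expression; the statistic is the OLS R^2 of the number of SCE
    regions overlapping genes in each category against quartile rank.
    Returns (r_squared, counts per quartile low->high).
    """
    from . import features

    genes_act = features.attach_activity(genes, expression)
    active = features.gene_bodies(genes_act[genes_act["activity"] == "active"])
    if len(active) < 4:
        raise ValueError("need >= 4 active genes")
    q = pd.qcut(active["fpkm"], 4, labels=False, duplicates="drop")
    counts = np.zeros(4, dtype=np.int64)
    for chrom, sub in active.assign(quartile=q).groupby("chrom", sort=False):
        sc = sces[sces["chrom"] == chrom]
        if sc.empty:
            continue
        ss = sc["start"].to_numpy()
        se = sc["end"].to_numpy()
        for row in sub.itertuples():
            counts[int(row.quartile)] += int(((ss < row.end) & (se > row.start)).sum())
    x = np.arange(4, dtype=float)
    y = counts.astype(float)
    if np.allclose(y, y[0]):
        return 0.0, counts
    lr = stats.linregress(x, y)
    return float(lr.rvalue**2), counts
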