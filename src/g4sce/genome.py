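"""Genome index and gap-excluded coordinate arithmetic.

A :class:`GenomeIndex` records chromosome lengths and assembly-gap
intervals.  A :class:`GaplessMap` built from it provides a bijection
between non-gap genomic bases and a compacted "gapless" coordinate
system ``[0, effective_length)`` per chromosome.  All circular-shift
permutations operate in gapless space so that shifted intervals can
never land inside an assembly gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class GenomeIndex:
    """Chromosome names/lengths plus sorted, non-overlapping gap intervals.

    Parameters
    ----------
    lengths:
        Mapping chromosome name -> length in bases.
    gaps:
        Mapping chromosome name -> ``(n, 2)`` integer array of 0-based
        half-open gap intervals.  Chromosomes may be absent (no gaps).
    """

    lengths: dict[str, int]
    gaps: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length {length}")
        norm: dict[str, np.ndarray] = {}
        for chrom in self.lengths:
            arr = np.asarray(self.gaps.get(chrom, np.empty((0, 2), dtype=np.int64)), dtype=np.int64)
            arr = arr.reshape(-1, 2)
            if arr.size:
                order = np.argsort(arr[:, 0])
                arr = arr[order]
                if np.any(arr[:, 0] >= arr[:, 1]):
                    raise ValueError(f"empty or inverted gap interval on {chrom}")
                if np.any(arr[1:, 0] < arr[:-1, 1]):
                    raise ValueError(f"overlapping gap intervals on {chrom}")
                if arr[0, 0] < 0 or arr[-1, 1] > self.lengths[chrom]:
                    raise ValueError(f"gap outside chromosome bounds on {chrom}")
            norm[chrom] = arr
        unknown = set(self.gaps) - set(self.lengths)
        if unknown:
            raise ValueError(f"gaps given for unknown chromosomes: {sorted(unknown)}")
        self.gaps = norm

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths)

    def gap_length(self, chrom: str) -> int:
        g = self.gaps[chrom]
        return int((g[:, 1] - g[:, 0]).sum()) if g.size else 0

    def effective_length(self, chrom: str) -> int:
        """Length of the chromosome excluding assembly gaps."""
        return self.lengths[chrom] - self.gap_length(chrom)

    def total_effective_length(self) -> int:
        return sum(self.effective_length(c) for c in self.lengths)


class _ChromMap:
    """Per-chromosome piecewise-linear map genomic <-> gapless."""

    __slots__ = (
        "length",
        "effective_length",
        "gap_starts",
        "gap_ends",
        "cum_gap",
        "block_genomic_starts",
        "block_gapless_starts",
        "block_gapless_ends",
    )

    def __init__(self, length: int, gaps: np.ndarray):
        self.length = length
        self.gap_starts = gaps[:, 0].copy() if gaps.size else np.empty(0, dtype=np.int64)
        self.gap_ends = gaps[:, 1].copy() if gaps.size else np.empty(0, dtype=np.int64)
        widths = self.gap_ends - self.gap_starts
        # cum_gap[i] = total gap bases in gaps[:i]
        self.cum_gap = np.concatenate([[0], np.cumsum(widths)]).astype(np.int64)
        self.effective_length = int(length - self.cum_gap[-1])
        # non-gap blocks: block i runs from prev gap end to gap i start
        self.block_genomic_starts = np.concatenate([[0], self.gap_ends]).astype(np.int64)
        self.block_gapless_starts = self.block_genomic_starts - self.cum_gap
        block_genomic_ends = np.concatenate([self.gap_starts, [length]]).astype(np.int64)
        self.block_gapless_ends = block_genomic_ends - self.cum_gap


class GaplessMap:
    """Bijection between non-gap genomic bases and gapless coordinates."""

    def __init__(self, genome_index: GenomeIndex):
        self.genome_index = genome_index
        self._maps = {
            chrom: _ChromMap(genome_index.lengths[chrom], genome_index.gaps[chrom])
            for chrom in genome_index.lengths
        }

    def effective_length(self, chrom: str) -> int:
        return self._maps[chrom].effective_length

    def to_gapless(self, chrom: str, pos) -> np.ndarray:
        """Map genomic base positions to gapless coordinates.

        Raises ``ValueError`` if any position lies inside a gap or
        outside the chromosome.
        """
        m = self._maps[chrom]
        pos = np.asarray(pos, dtype=np.int64)
        if pos.size and (pos.min() < 0 or pos.max() >= m.length):
            raise ValueError(f"position outside chromosome {chrom}")
        if not m.gap_starts.size:
            return pos
        i = np.searchsorted(m.gap_starts, pos, side="right")
        inside = (i > 0) & (pos < m.gap_ends[np.maximum(i - 1, 0)])
        if np.any(inside):
            bad = pos[inside][0]
            raise ValueError(f"position {bad} on {chrom} lies inside an assembly gap")
        return pos - m.cum_gap[i]

    def to_genomic(self, chrom: str, gpos) -> np.ndarray:
        """Inverse of :meth:`to_gapless`."""
        m = self._maps[chrom]
        gpos = np.asarray(gpos, dtype=np.int64)
        if gpos.size and (gpos.min() < 0 or gpos.max() >= m.effective_length):
            raise ValueError(f"gapless position outside [0, {m.effective_length}) on {chrom}")
        i = np.searchsorted(m.block_gapless_starts, gpos, side="right") - 1
        return gpos + m.cum_gap[i]

    def overlaps_gap(self, chrom: str, start: int, end: int) -> bool:
        m = self._maps[chrom]
        if not m.gap_starts.size:
            return False
        j = np.searchsorted(m.gap_ends, start, side="right")
        return j < m.gap_starts.size and m.gap_starts[j] < end

    def interval_to_gapless(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """Map a gap-free genomic interval to a gapless interval.

        The interval must not intersect any gap; otherwise a
        ``ValueError`` is raised naming the interval.
        """
        if self.overlaps_gap(chrom, start, end):
            raise ValueError(f"interval {chrom}:{start}-{end} overlaps an assembly gap")
        s = int(self.to_gapless(chrom, [start])[0])
        return s, s + (end - start)

    def interval_to_gapless_pieces(self, chrom: str, start: int, end: int) -> list[tuple[int, int]]:
        """Map an arbitrary genomic interval to gapless pieces.

        Gap bases are removed; the interval may split into several
        gapless intervals (or vanish if fully inside gaps).
        """
        m = self._maps[chrom]
        start = max(0, int(start))
        end = min(m.length, int(end))
        if start >= end:
            return []
        pieces = []
        bs, be = m.block_genomic_starts, np.concatenate([m.gap_starts, [m.length]])
        first = np.searchsorted(be, start, side="right")
        for k in range(first, len(bs)):
            if bs[k] >= end:
                break
            a = max(start, int(bs[k]))
            b = min(end, int(be[k]))
            if a < b:
                pieces.append((a - int(m.cum_gap[k]), b - int(m.cum_gap[k])))
        return pieces

    def gapless_interval_to_genomic(self, chrom: str, gstart: int, gend: int) -> list[tuple[int, int]]:
        """Map a gapless interval back to (possibly several) genomic intervals."""
        m = self._maps[chrom]
        if gstart >= gend:
            return []
        pieces = []
        k = int(np.searchsorted(m.block_gapless_starts, gstart, side="right")) - 1
        while k < len(m.block_gapless_starts) and m.block_gapless_starts[k] < gend:
            a = max(gstart, int(m.block_gapless_starts[k]))
            b = min(gend, int(m.block_gapless_ends[k]))
            if a < b:
                pieces.append((a + int(m.cum_gap[k]), b + int(m.cum_gap[k])))
            k += 1
        return pieces
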