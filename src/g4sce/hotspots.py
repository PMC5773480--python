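"""SCE hotspot detection and bin-based hotspot probabilities.

A hotspot candidate is a maximal genomic interval where SCE regions
from at least ``min_cells`` distinct cells mutually overlap.  Its
probability is scored by asking how likely the observed number of
events in one genome bin of the hotspot's size would be if the
cell line's total SCE count were scattered uniformly over the
gap-excluded genome: an upper-tail binomial probability
``P(X >= k), X ~ Binomial(total, hotspot_length / effective_genome)``
(a Poisson upper tail is available as an approximation).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

HOTSPOT_COLUMNS = [
    "chrom",
    "start",
    "end",
    "n_libraries_with_sce",
    "n_libraries_total",
    "total_sces",
    "p_value",
]


def detect_hotspots(sces: pd.DataFrame, min_cells: int = 3) -> pd.DataFrame:
    """Find maximal intervals covered by SCE regions of >= min_cells cells.

    Per-cell regions are merged first so one cell never counts twice at
    a position.  The candidate interval is the run of bases where the
    distinct-cell coverage stays at or above the threshold (for exactly
    ``min_cells`` overlapping regions this is their intersection).
    """
    if sces.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_cells"])
    rows = []
    for chrom, sub in sces.groupby("chrom", sort=False):
        events = []  # (pos, delta)
        for cell, cr in sub.groupby("cell", sort=False):
            iv = cr.sort_values("start")[["start", "end"]].to_numpy()
            merged = [list(iv[0])]
            for s, e in iv[1:]:
                if s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            for s, e in merged:
                events.append((s, 1))
                events.append((e, -1))
        events.sort()
        cov = 0
        run_start = None
        peak = 0
        for pos, delta in events:
            prev = cov
            cov += delta
            if prev < min_cells <= cov:
                run_start = pos
                peak = cov
            elif cov >= min_cells:
                peak = max(peak, cov)
            elif prev >= min_cells > cov:
                rows.append((chrom, int(run_start), int(pos), int(peak)))
                run_start = None
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_cells"])


def hotspot_pvalue(
    hotspot_length: int,
    genome_effective_length: int,
    total_sces: int,
    observed_in_hotspot: int,
    method: str = "binomial",
) -> float:
    """Upper-tail probability of the observed event count in one bin.

    ``P(X >= observed)`` with ``X ~ Binomial(total_sces, hotspot_length
    / genome_effective_length)``; ``method='poisson'`` uses the matching
    Poisson tail instead.
    """
    if total_sces <= 0 or genome_effective_length <= 0:
        raise ValueError("total_sces and genome_effective_length must be positive")
    if hotspot_length > genome_effective_length:
        raise ValueError("hotspot longer than the effective genome")
    if observed_in_hotspot > total_sces:
        raise ValueError("observed count exceeds total")
    if observed_in_hotspot <= 0:
        return 1.0
    frac = hotspot_length / genome_effective_length
    if method == "binomial":
        return float(stats.binom.sf(observed_in_hotspot - 1, total_sces, frac))
    if method == "poisson":
        return float(stats.poisson.sf(observed_in_hotspot - 1, total_sces * frac))
    raise ValueError(f"unknown method {method!r}")


def score_hotspots(
    candidates: pd.DataFrame,
    sces: pd.DataFrame,
    genome_effective_length: int,
    n_libraries_total: int,
    method: str = "binomial",
    count_unit: str = "sces",
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Attach library counts and bin probabilities to hotspot candidates.

    ``count_unit='sces'`` scores the number of SCE events in the
    hotspot; ``'libraries'`` scores the number of distinct cells.  With
    ``bonferroni=True`` p-values are multiplied by the number of
    hotspot-sized bins in the effective genome (capped at 1).
    """
    total = int(len(sces))
    rows = []
    for cand in candidates.itertuples():
        sub = sces[
            (sces["chrom"] == cand.chrom)
            & (sces["start"] < cand.end)
            & (sces["end"] > cand.start)
        ]
        n_libs = int(sub["cell"].nunique())
        observed = len(sub) if count_unit == "sces" else n_libs
        total_for_test = total if count_unit == "sces" else int(sces["cell"].nunique())
        length = int(cand.end - cand.start)
        p = hotspot_pvalue(length, genome_effective_length, total_for_test, observed, method=method)
        if bonferroni and length > 0:
            p = min(1.0, p * (genome_effective_length // max(length, 1)))
        rows.append(
            (cand.chrom, int(cand.start), int(cand.end), n_libs, n_libraries_total, len(sub), p)
        )
    return pd.DataFrame(rows, columns=HOTSPOT_COLUMNS)
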