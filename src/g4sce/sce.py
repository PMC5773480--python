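"""Template-strand state inference and SCE calling from directional reads.

Per cell and chromosome, reads carry a W (Watson, reference minus) or C
(Crick, reference plus) label.  A diploid chromosome's template-strand
state is WW, WC or CC, with expected Watson read fractions 1, 1/2 and 0
up to a symmetric label-error rate ``epsilon``.  The chromosome is
segmented by an exact penalized changepoint search (PELT) maximizing the
per-read binomial log-likelihood with a free Watson fraction per segment
and a BIC-style penalty per changepoint; segments are then snapped to
the best-likelihood state of the three and same-state neighbours merged.
An SCE
is called between adjacent segments whose states differ; the called
region runs from the end of the last informative read of the left
segment to the start of the first informative read of the right segment,
so its width is the local inter-read distance (the mapping resolution).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

SEGMENT_COLUMNS = ["chrom", "start", "end", "state", "cell", "n_reads", "first_read_start", "last_read_end"]
SCE_COLUMNS = ["chrom", "start", "end", "cell", "homolog", "resolution"]

_STATES = ("WW", "WC", "CC")


def _state_logprobs(epsilon: float) -> np.ndarray:
    # P(read is W | state) for WW, WC, CC
    p = np.array([1.0 - epsilon, 0.5, epsilon])
    return np.log(p), np.log1p(-p)


def _best_state(cw, n0, n1, lp, lq) -> str:
    k = cw[n1] - cw[n0]
    n = n1 - n0
    lls = k * lp + (n - k) * lq
    # on a tie the heterozygous WC state wins (it is the symmetric choice)
    order = np.argsort(-lls, kind="mergesort")
    best = order[0]
    if lls[1] == lls[best]:
        best = 1
    return _STATES[int(best)]


def infer_strand_states(
    reads: pd.DataFrame,
    min_reads: int = 10,
    epsilon: float = 0.02,
    penalty: float | None = None,
) -> pd.DataFrame:
    """Segment one cell's reads into template-strand state segments.

    ``reads`` must belong to a single cell.  Chromosomes with fewer than
    ``min_reads`` reads are uncallable and contribute no segments.  The
    default split penalty is ``2 * ln(n_reads)`` per chromosome, the
    BIC charge for the two extra parameters (location and rate) of each
    changepoint.
    """
    from ._segment import segment_labels

    cells = reads["cell"].unique()
    if len(cells) > 1:
        raise ValueError("infer_strand_states expects reads from a single cell")
    cell = cells[0] if len(cells) else ""
    rows = []
    for chrom, sub in reads.groupby("chrom", sort=False):
        sub = sub.sort_values(["start", "end"], kind="mergesort")
        n = len(sub)
        if n < min_reads:
            continue  # uncallable chromosome
        w = (sub["label"].to_numpy() == "W").astype(np.int64)
        pen = penalty if penalty is not None else 2.0 * np.log(n)
        bounds = segment_labels(w, pen, min_reads)
        cw = np.concatenate([[0], np.cumsum(w)]).astype(np.int64)
        lp, lq = _state_logprobs(epsilon)
        edges = [0] + bounds  # bounds exclude 0 and include n
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        segs = []
        for a, b in zip(edges[:-1], edges[1:]):
            segs.append([a, b, _best_state(cw, a, b, lp, lq)])
        # merge adjacent segments that landed in the same state
        merged = [segs[0]]
        for a, b, st in segs[1:]:
            if st == merged[-1][2]:
                merged[-1][1] = b
            else:
                merged.append([a, b, st])
        # re-localize each boundary with the state-constrained likelihood:
        # with the flanking states known, the ML changepoint is sharper
        # than under the free-rate search
        for i in range(len(merged) - 1):
            a = merged[i][0]
            c = merged[i + 1][1]
            stL = _STATES.index(merged[i][2])
            stR = _STATES.index(merged[i + 1][2])
            cand = np.arange(a + 1, c)
            kL = cw[cand] - cw[a]
            nL = cand - a
            kR = cw[c] - cw[cand]
            nR = c - cand
            ll = (
                kL * lp[stL]
                + (nL - kL) * lq[stL]
                + kR * lp[stR]
                + (nR - kR) * lq[stR]
            )
            s = int(cand[int(np.argmax(ll))])
            merged[i][1] = s
            merged[i + 1][0] = s
        for a, b, st in merged:
            rows.append(
                (
                    chrom,
                    int(starts[a]),
                    int(ends[b - 1]),
                    st,
                    cell,
                    b - a,
                    int(starts[a]),
                    int(ends[b - 1]),
                )
            )
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def call_sces(segments: pd.DataFrame) -> pd.DataFrame:
    """Call one SCE region per adjacent state change.

    The region is the interval between the last informative read of the
    left segment and the first informative read of the right segment.
    Adjacent segments two steps apart (WW->CC) are emitted as two
    stacked SCEs covering the same region, with a warning.
    """
    rows = []
    doubles = 0
    for (cell, chrom), sub in segments.groupby(["cell", "chrom"], sort=False):
        sub = sub.sort_values("start", kind="mergesort")
        for left, right in zip(sub.iloc[:-1].itertuples(), sub.iloc[1:].itertuples()):
            start = int(left.last_read_end)
            end = int(right.first_read_start)
            if end <= start:  # overlapping boundary reads; clamp to 1 bp
                start = end - 1
            step = abs(_STATES.index(left.state) - _STATES.index(right.state))
            n_copies = 1 if step == 1 else 2
            if step == 2:
                doubles += 1
            for _ in range(n_copies):
                rows.append((chrom, start, end, cell, "none", end - start))
    if doubles:
        warnings.warn(f"{doubles} double state switches (WW<->CC) emitted as stacked SCE pairs")
    return pd.DataFrame(rows, columns=SCE_COLUMNS)


def call_sces_for_cells(
    reads: pd.DataFrame,
    min_reads: int = 10,
    epsilon: float = 0.02,
    penalty: float | None = None,
) -> pd.DataFrame:
    """Run state inference and SCE calling for every cell in a read table.

    Equivalent to :func:`infer_strand_states` + :func:`call_sces` per
    cell, but sorts the table once and works on numpy slices so large
    multi-cell datasets stay fast.
    """
    from ._segment import segment_labels

    if reads.empty:
        return pd.DataFrame(columns=SCE_COLUMNS)
    # sort once on integer codes; object-dtype sorts are slow at millions of rows
    cell_codes, cell_names = pd.factorize(reads["cell"], sort=True)
    chrom_codes, chrom_names = pd.factorize(reads["chrom"], sort=True)
    order = np.lexsort(
        (reads["end"].to_numpy(), reads["start"].to_numpy(), chrom_codes, cell_codes)
    )
    cell_c = cell_codes[order]
    chrom_c = chrom_codes[order]
    cells = cell_names.to_numpy()[cell_c]
    chroms = chrom_names.to_numpy()[chrom_c]
    starts = reads["start"].to_numpy()[order]
    ends = reads["end"].to_numpy()[order]
    labels = (reads["label"].to_numpy() == "W").astype(np.int64)[order]
    # group boundaries of the (cell, chrom) blocks
    new_block = np.flatnonzero((cell_c[1:] != cell_c[:-1]) | (chrom_c[1:] != chrom_c[:-1])) + 1
    block_edges = np.concatenate([[0], new_block, [len(reads)]])
    lp, lq = _state_logprobs(epsilon)
    rows = []
    doubles = 0
    for g0, g1 in zip(block_edges[:-1], block_edges[1:]):
        n = g1 - g0
        if n < min_reads:
            continue
        w = labels[g0:g1]
        pen = penalty if penalty is not None else 2.0 * np.log(n)
        bounds = segment_labels(w, pen, min_reads)
        if len(bounds) <= 1:
            continue
        cw = np.concatenate([[0], np.cumsum(w)])
        edges = [0] + bounds
        states = [
            _best_state(cw, a, b, lp, lq) for a, b in zip(edges[:-1], edges[1:])
        ]
        merged = [[edges[0], edges[1], states[0]]]
        for (a, b), st in zip(zip(edges[1:-1], edges[2:]), states[1:]):
            if st == merged[-1][2]:
                merged[-1][1] = b
            else:
                merged.append([a, b, st])
        if len(merged) < 2:
            continue
        for i in range(len(merged) - 1):
            a = merged[i][0]
            c = merged[i + 1][1]
            stL = _STATES.index(merged[i][2])
            stR = _STATES.index(merged[i + 1][2])
            cand = np.arange(a + 1, c)
            kL = cw[cand] - cw[a]
            nL = cand - a
            kR = cw[c] - cw[cand]
            nR = c - cand
            ll = kL * lp[stL] + (nL - kL) * lq[stL] + kR * lp[stR] + (nR - kR) * lq[stR]
            s = int(cand[int(np.argmax(ll))])
            merged[i][1] = s
            merged[i + 1][0] = s
        gs = starts[g0:g1]
        ge = ends[g0:g1]
        for left, right in zip(merged[:-1], merged[1:]):
            r_start = int(ge[left[1] - 1])
            r_end = int(gs[right[0]])
            if r_end <= r_start:
                r_start = r_end - 1
            step = abs(_STATES.index(left[2]) - _STATES.index(right[2]))
            if step == 2:
                doubles += 1
            for _ in range(1 if step == 1 else 2):
                rows.append((chroms[g0], r_start, r_end, cells[g0], "none", r_end - r_start))
    if doubles:
        warnings.warn(f"{doubles} double state switches (WW<->CC) emitted as stacked SCE pairs")
    return pd.DataFrame(rows, columns=SCE_COLUMNS)


def filter_recurrent(
    sces: pd.DataFrame,
    cell_count: int,
    max_fraction: float = 0.05,
    reciprocal_overlap: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove SCE regions recurring at the same location across cells.

    Regions are clustered across cells by single-linkage with >=
    ``reciprocal_overlap`` mutual overlap; clusters present in more than
    ``max_fraction`` of cells (strict) are removed as putative stable
    rearrangements rather than genuine exchanges.
    Returns ``(kept, removed)``.
    """
    if cell_count <= 0:
        raise ValueError("cell_count must be positive")
    if sces.empty:
        return sces.copy(), sces.iloc[0:0].copy()
    df = sces.reset_index(drop=True)
    cluster = np.arange(len(df))

    def find(x):
        while cluster[x] != x:
            cluster[x] = cluster[cluster[x]]
            x = cluster[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            cluster[rb] = ra

    for chrom, sub in df.groupby("chrom", sort=False):
        idx = sub.sort_values("start", kind="mergesort").index.to_numpy()
        starts = df.loc[idx, "start"].to_numpy()
        ends = df.loc[idx, "end"].to_numpy()
        active: list[int] = []
        for i in range(len(idx)):
            active = [j for j in active if ends[j] > starts[i]]
            for j in active:
                ovl = min(ends[i], ends[j]) - max(starts[i], starts[j])
                if ovl <= 0:
                    continue
                li = ends[i] - starts[i]
                lj = ends[j] - starts[j]
                if ovl >= reciprocal_overlap * li and ovl >= reciprocal_overlap * lj:
                    union(int(idx[j]), int(idx[i]))
            active.append(i)
    roots = np.array([find(i) for i in range(len(df))])
    df = df.assign(_cluster=roots)
    cells_per_cluster = df.groupby("_cluster")["cell"].nunique()
    # a cluster must recur in >1 cell to count as an artifact, whatever
    # the fraction threshold works out to for small cell counts
    threshold = max(max_fraction * cell_count, 1.0)
    bad = cells_per_cluster[cells_per_cluster > threshold].index
    removed = df[df["_cluster"].isin(bad)].drop(columns="_cluster")
    kept = df[~df["_cluster"].isin(bad)].drop(columns="_cluster")
    return kept.reset_index(drop=True), removed.reset_index(drop=True)


def assign_homolog(
    sces: pd.DataFrame,
    reads: pd.DataFrame,
    window: int = 2_000_000,
    min_reads_side: int = 3,
    min_fraction_change: float = 0.35,
) -> pd.DataFrame:
    """Assign each SCE to the homolog whose template state switches.

    Haplotype-tagged reads within ``window`` of the region are split by
    haplotype; a haplotype is deemed to switch when its Watson-read
    fraction changes by at least ``min_fraction_change`` across the
    region with ``min_reads_side`` tagged reads on each side.  If
    neither or both haplotypes switch the SCE is uninformative
    (homolog ``none``).
    """
    out = sces.copy().reset_index(drop=True)
    out["homolog"] = "none"
    tagged = reads[reads["hap"].isin(["A", "B"])]
    by_key = {k: v for k, v in tagged.groupby(["cell", "chrom"], sort=False)}
    for i, sce in out.iterrows():
        sub = by_key.get((sce["cell"], sce["chrom"]))
        if sub is None:
            continue
        lo, hi = sce["start"] - window, sce["end"] + window
        near = sub[(sub["start"] >= lo) & (sub["start"] < hi)]
        switching = []
        for hap, hap_reads in near.groupby("hap", sort=True):
            left = hap_reads[hap_reads["end"] <= sce["start"]]
            right = hap_reads[hap_reads["start"] >= sce["end"]]
            if len(left) < min_reads_side or len(right) < min_reads_side:
                continue
            fl = (left["label"] == "W").mean()
            fr = (right["label"] == "W").mean()
            if abs(fl - fr) >= min_fraction_change:
                switching.append(hap)
        if len(switching) == 1:
            out.at[i, "homolog"] = switching[0]
    return out


def resolution_summary(sces: pd.DataFrame) -> dict:
    """Median mapping resolution, fraction below 100 kb, per-cell counts."""
    if sces.empty:
        raise ValueError("no SCEs to summarize")
    res = sces["resolution"].to_numpy()
    per_cell = sces.groupby("cell").size()
    return {
        "n_sces": int(len(sces)),
        "median_resolution": float(np.median(res)),
        "fraction_below_100kb": float((res < 100_000).mean()),
        "mean_sces_per_cell": float(per_cell.mean()),
        "per_cell_counts": per_cell.to_dict(),
    }


def chromosome_size_correlation(sces: pd.DataFrame, genome_index, n_cells: int) -> float:
    """OLS R^2 of mean SCEs per chromosome per cell against chromosome length."""
    chroms = genome_index.chromosomes
    if len(chroms) < 3:
        raise ValueError("need >= 3 chromosomes for a size correlation")
    counts = sces.groupby("chrom").size()
    y = np.array([counts.get(c, 0) / n_cells for c in chroms], dtype=float)
    x = np.array([genome_index.lengths[c] for c in chroms], dtype=float)
    if np.allclose(y, y[0]) or np.allclose(x, x[0]):
        return 0.0
    lr = stats.linregress(x, y)
    return float(lr.rvalue**2)
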