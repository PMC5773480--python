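"""Motif scanning and gene/promoter/motif-context classification.

The central scanner finds canonical quadruplex-forming motifs
``G3+ N(1..x) G3+ N(1..x) G3+ N(1..x) G3+`` on both strands.  The match
convention is: runs greedy, loops lazy, matches leftmost and
non-overlapping per strand (after a match, scanning resumes at its end),
so every match starts and ends at a maximal anchor-base run.  Loop bases
are unrestricted apart from ambiguity (N rejected), so a long G-run can
satisfy several pattern runs at once.  Minus-strand motifs are found by
scanning the reverse complement and mapping coordinates back.

A-rich control motifs (``A3+ N(1..x) ... A3+``) reuse the same scanner
with a different anchor base, and "high GC content" control regions are
the top tiling windows ranked by GC fraction.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")

MOTIF_COLUMNS = ["chrom", "start", "end", "strand"]
LOOP_CLASSES = {"1-3": (1, 3), "1-7": (1, 7), "1-12": (1, 12)}


def revcomp(seq: str) -> str:
    return seq.encode("ascii").translate(_COMPLEMENT)[::-1].decode("ascii")


def _validate_sequence(arr: np.ndarray) -> None:
    ok = (
        (arr == ord("A"))
        | (arr == ord("C"))
        | (arr == ord("G"))
        | (arr == ord("T"))
        | (arr == ord("N"))
    )
    if not ok.all():
        pos = int(np.flatnonzero(~ok)[0])
        raise ValueError(f"non-ACGTN character {chr(arr[pos])!r} at position {pos}")


def _scan_plus(seq: str, base: str, loop_min: int, loop_max: int) -> list[tuple[int, int]]:
    """Leftmost non-overlapping matches of the quadruplex pattern.

    Runs are greedy and loops lazy, so a match always begins and ends at
    maximal anchor-base runs; loops may themselves contain anchor bases
    (a single run of >= 15 G satisfies the canonical pattern).  Loop
    characters are restricted to unambiguous bases, so candidates
    containing N are rejected.  After a match, scanning resumes at its
    end.
    """
    pat = re.compile(f"{base}{{3,}}(?:[ACGT]{{{loop_min},{loop_max}}}?{base}{{3,}}){{3}}")
    out: list[tuple[int, int]] = []
    pos = 0
    while True:
        m = pat.search(seq, pos)
        if m is None:
            return out
        out.append(m.span())
        pos = m.end()


def scan_g4(
    sequence: str,
    loop_min: int = 1,
    loop_max: int = 7,
    strand_mode: str = "both",
    base: str = "G",
) -> pd.DataFrame:
    """Scan one sequence for quadruplex motifs on one or both strands.

    Returns a DataFrame with columns start, end, strand, sorted by
    (start, end, strand).  Coordinates are 0-based half-open on the
    given (plus) sequence for both strands.
    """
    if not (1 <= loop_min <= loop_max):
        raise ValueError("require 1 <= loop_min <= loop_max")
    if strand_mode not in ("both", "plus", "minus"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    seq = sequence.upper()
    _validate_sequence(np.frombuffer(seq.encode("ascii"), dtype=np.uint8))
    rows = []
    if strand_mode in ("both", "plus"):
        for s, e in _scan_plus(seq, base, loop_min, loop_max):
            rows.append((s, e, "+"))
    if strand_mode in ("both", "minus"):
        rc = revcomp(seq)
        L = len(seq)
        for s, e in _scan_plus(rc, base, loop_min, loop_max):
            rows.append((L - e, L - s, "-"))
    df = pd.DataFrame(rows, columns=["start", "end", "strand"])
    return df.sort_values(["start", "end", "strand"], kind="mergesort").reset_index(drop=True)


def scan_genome(
    sequences: dict[str, str],
    loop_min: int = 1,
    loop_max: int = 7,
    strand_mode: str = "both",
    base: str = "G",
) -> pd.DataFrame:
    """Scan every chromosome; adds a `chrom` column."""
    parts = []
    for chrom, seq in sequences.items():
        df = scan_g4(seq, loop_min, loop_max, strand_mode, base=base)
        df.insert(0, "chrom", chrom)
        parts.append(df)
    if not parts:
        return pd.DataFrame(columns=MOTIF_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def scan_a_rich(sequence: str, loop_min: int = 1, loop_max: int = 7) -> pd.DataFrame:
    """A-rich control motif A3+ N(1..x) x4 (T-runs on the minus strand)."""
    return scan_g4(sequence, loop_min, loop_max, strand_mode="both", base="A")


def gc_windows(sequence: str, window: int = 1000, top_fraction: float = 0.1) -> pd.DataFrame:
    """Top tiling windows by GC fraction.

    The sequence is tiled with non-overlapping windows of the given
    width (final partial window included); windows are ranked by GC
    fraction and the top ``ceil(top_fraction * n_windows)`` are
    returned, position-sorted.  Ties rank by position.
    """
    if window < 100:
        raise ValueError("window must be >= 100")
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    _validate_sequence(arr)
    is_gc = ((arr == ord("G")) | (arr == ord("C"))).astype(np.int64)
    cum = np.concatenate([[0], np.cumsum(is_gc)])
    starts = np.arange(0, len(arr), window, dtype=np.int64)
    ends = np.minimum(starts + window, len(arr))
    frac = (cum[ends] - cum[starts]) / (ends - starts)
    k = max(1, int(np.ceil(top_fraction * len(starts))))
    order = np.lexsort((starts, -frac))[:k]
    sel = np.sort(order)
    return pd.DataFrame({"start": starts[sel], "end": ends[sel], "gc_fraction": frac[sel]})


def classify_gene_activity(expression: pd.DataFrame, threshold: float = 1.0) -> pd.Series:
    """Active iff FPKM strictly exceeds the threshold (default 1), else silent.

    FPKM exactly at the threshold is classified silent: "active" is
    defined by a strict inequality and the boundary case is otherwise
    undefined.
    """
    if (expression["fpkm"] < 0).any():
        raise ValueError("negative FPKM value")
    act = np.where(expression["fpkm"] > threshold, "active", "silent")
    return pd.Series(act, index=expression["gene_id"].to_numpy(), name="activity")


def attach_activity(genes: pd.DataFrame, expression: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Join FPKM and activity onto the gene table; missing genes are silent."""
    activity = classify_gene_activity(expression, threshold)
    genes = genes.copy()
    genes["fpkm"] = genes["gene_id"].map(
        pd.Series(expression["fpkm"].to_numpy(), index=expression["gene_id"].to_numpy())
    )
    missing = genes["fpkm"].isna()
    if missing.any():
        import warnings

        warnings.warn(f"{int(missing.sum())} genes missing from expression table; classified silent")
        genes.loc[missing, "fpkm"] = 0.0
    genes["activity"] = genes["gene_id"].map(activity).fillna("silent")
    return genes


def gene_bodies(genes: pd.DataFrame) -> pd.DataFrame:
    """Gene body intervals [min(tss,tes), max(tss,tes))."""
    out = genes.copy()
    out["start"] = np.minimum(genes["tss"], genes["tes"])
    out["end"] = np.maximum(genes["tss"], genes["tes"])
    return out


def promoter_regions(genes: pd.DataFrame, length: int = 1000, chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """1 kb (by default) regions upstream of each TSS, clipped at chromosome ends."""
    if length <= 0:
        raise ValueError("promoter length must be positive")
    plus = genes["strand"] == "+"
    start = np.where(plus, genes["tss"] - length, genes["tss"])
    end = np.where(plus, genes["tss"], genes["tss"] + length)
    start = np.maximum(start, 0)
    if chrom_lengths is not None:
        lim = genes["chrom"].map(chrom_lengths).to_numpy()
        end = np.minimum(end, lim)
    out = pd.DataFrame(
        {"chrom": genes["chrom"], "start": start.astype(np.int64), "end": end.astype(np.int64),
         "gene_id": genes["gene_id"], "strand": genes["strand"]}
    )
    return out[out["start"] < out["end"]].reset_index(drop=True)


def classify_motif_context(motifs: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Fill `context` and `gene_activity` for each motif.

    A motif outside all gene bodies is intergenic.  Inside a gene body,
    a motif on the strand opposite the gene's annotated (sense) strand
    lies on the transcribed (template) strand; a motif on the same
    strand lies on the non-transcribed strand.  A motif overlapping two
    genes is assigned to the gene with the larger overlap (ties to the
    5'-most gene on the chromosome).
    """
    if "activity" not in genes.columns:
        raise ValueError("genes must carry an `activity` column")
    bodies = gene_bodies(genes)
    out = motifs.copy().reset_index(drop=True)
    out["context"] = "intergenic"
    out["gene_activity"] = "none"
    out["gene_id"] = ""
    for chrom, sub in out.groupby("chrom", sort=False):
        gb = bodies[bodies["chrom"] == chrom]
        if gb.empty:
            continue
        gs = gb["start"].to_numpy()
        ge = gb["end"].to_numpy()
        order = np.argsort(gs, kind="mergesort")
        gs, ge = gs[order], ge[order]
        gsub = gb.iloc[order]
        for idx, m in sub.iterrows():
            lo = np.searchsorted(gs, m["end"], side="left")
            cand = [j for j in range(lo) if ge[j] > m["start"]]
            if not cand:
                continue
            ovl = [min(ge[j], m["end"]) - max(gs[j], m["start"]) for j in cand]
            best = cand[int(np.argmax(ovl))]  # argmax is first max -> 5'-most on tie
            g = gsub.iloc[best]
            out.at[idx, "context"] = (
                "transcribed_strand" if m["strand"] != g["strand"] else "non_transcribed_strand"
            )
            out.at[idx, "gene_activity"] = g["activity"]
            out.at[idx, "gene_id"] = g["gene_id"]
    return out
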