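"""Allele-specific G4 motifs, homolog concordance, and LOH/ploidy calling.

In an F1-hybrid line the two homologs differ at millions of SNPs, some
of which destroy (or create) a quadruplex motif on exactly one
haplotype.  An SCE whose region overlaps a single such allele-specific
motif and whose homolog could be assigned from haplotype-tagged reads is
"informative": if motifs cause exchanges, informative SCEs should sit on
the motif-bearing homolog more than the 50% expected by chance, which is
scored with an exact binomial test.

LOH segments are called from binned haplotype read counts as runs of
bins dominated by one haplotype at diploid copy number; haplotype-pure
runs at reduced copy number are deletions, not LOH, and are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import features


def find_allelic_g4(
    hap_a_sequences: dict[str, str],
    hap_b_sequences: dict[str, str],
    loop_min: int = 1,
    loop_max: int = 7,
) -> pd.DataFrame:
    """Motifs present on exactly one haplotype (SNP-only model).

    The haplotype sequences must be aligned base-for-base (substitutions
    only), so motif coordinates are directly comparable.  Both strands
    of both haplotypes are scanned; a motif counts as allele-specific
    when no same-strand motif on the other haplotype overlaps it.
    Returns columns chrom, start, end, strand, haplotype (the homolog
    carrying the intact motif).
    """
    if set(hap_a_sequences) != set(hap_b_sequences):
        raise ValueError("haplotypes must cover the same chromosomes")
    for c in hap_a_sequences:
        if len(hap_a_sequences[c]) != len(hap_b_sequences[c]):
            raise ValueError(f"haplotype sequences differ in length on {c} (SNP-only model)")
    ma = features.scan_genome(hap_a_sequences, loop_min, loop_max)
    mb = features.scan_genome(hap_b_sequences, loop_min, loop_max)
    rows = []
    for hap, own, other in (("A", ma, mb), ("B", mb, ma)):
        for (chrom, strand), sub in own.groupby(["chrom", "strand"], sort=False):
            osub = other[(other["chrom"] == chrom) & (other["strand"] == strand)]
            os_ = np.sort(osub["start"].to_numpy())
            oe = osub.sort_values("start")["end"].to_numpy()
            for r in sub.itertuples():
                j = np.searchsorted(oe, r.start, side="right")
                overlaps = j < len(os_) and os_[j] < r.end
                if not overlaps:
                    rows.append((chrom, int(r.start), int(r.end), strand, hap))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "haplotype"])
    return out.sort_values(["chrom", "start", "haplotype"], kind="mergesort").reset_index(drop=True)


@dataclass
class ConcordanceResult:
    n_informative: int
    n_concordant: int
    fraction_concordant: float | None
    p_value: float | None
    sidedness: str
    per_haplotype: dict

    def to_dict(self) -> dict:
        return {
            "n_informative": self.n_informative,
            "n_concordant": self.n_concordant,
            "fraction_concordant": self.fraction_concordant,
            "p_value": self.p_value,
            "sidedness": self.sidedness,
            "per_haplotype": self.per_haplotype,
        }


def concordance_test(
    sces: pd.DataFrame, allelic_g4s: pd.DataFrame, sidedness: str = "one-sided"
) -> ConcordanceResult:
    """Do SCEs fall on the homolog carrying the intact motif?

    Informative SCEs are regions with an assigned homolog that overlap
    exactly one allele-specific motif.  Under the null each informative
    SCE has a 50% chance of sitting on the motif-bearing homolog; the
    one-sided p-value is P(X >= concordant), the two-sided variant uses
    the exact binomial test.
    """
    if sidedness not in ("one-sided", "two-sided"):
        raise ValueError("sidedness must be 'one-sided' or 'two-sided'")
    informative = 0
    concordant = 0
    per_hap = {"A": {"n": 0, "concordant": 0}, "B": {"n": 0, "concordant": 0}}
    with_hom = sces[sces["homolog"].isin(["A", "B"])]
    for chrom, sub in with_hom.groupby("chrom", sort=False):
        g = allelic_g4s[allelic_g4s["chrom"] == chrom].sort_values("start")
        gs = g["start"].to_numpy()
        ge = g["end"].to_numpy()
        gh = g["haplotype"].to_numpy()
        for r in sub.itertuples():
            lo = np.searchsorted(gs, r.end, side="left")
            hits = [j for j in range(lo) if ge[j] > r.start]
            if len(hits) != 1:
                continue
            informative += 1
            hap = gh[hits[0]]
            per_hap[hap]["n"] += 1
            if hap == r.homolog:
                concordant += 1
                per_hap[hap]["concordant"] += 1
    if informative == 0:
        return ConcordanceResult(0, 0, None, None, sidedness, per_hap)
    if sidedness == "one-sided":
        p = float(stats.binom.sf(concordant - 1, informative, 0.5))
    else:
        p = float(stats.binomtest(concordant, informative, 0.5).pvalue)
    return ConcordanceResult(
        n_informative=informative,
        n_concordant=concordant,
        fraction_concordant=concordant / informative,
        p_value=p,
        sidedness=sidedness,
        per_haplotype=per_hap,
    )


def bin_haplotype_counts(reads: pd.DataFrame, genome_index, bin_width: int = 1_000_000) -> pd.DataFrame:
    """Per-cell fixed-width bins with haplotype-tagged and total read counts."""
    rows = []
    for (cell, chrom), sub in reads.groupby(["cell", "chrom"], sort=True):
        L = genome_index.lengths[chrom]
        n_bins = int(np.ceil(L / bin_width))
        edges = np.arange(n_bins + 1) * bin_width
        pos = sub["start"].to_numpy()
        total = np.histogram(pos, bins=edges)[0]
        a = np.histogram(pos[(sub["hap"] == "A").to_numpy()], bins=edges)[0]
        b = np.histogram(pos[(sub["hap"] == "B").to_numpy()], bins=edges)[0]
        for i in range(n_bins):
            rows.append((cell, chrom, int(edges[i]), int(min(edges[i + 1], L)), int(a[i]), int(b[i]), int(total[i])))
    return pd.DataFrame(rows, columns=["cell", "chrom", "bin_start", "bin_end", "count_A", "count_B", "count_total"])


LOH_COLUMNS = ["cell", "chrom", "start", "end", "haplotype_retained", "n_bins", "copy_state"]


def call_loh(
    bins: pd.DataFrame,
    min_bins: int = 3,
    purity: float = 0.95,
    copy_tolerance: float = 0.25,
) -> pd.DataFrame:
    """Call copy-neutral LOH segments from binned haplotype counts.

    A segment is a maximal run of >= ``min_bins`` consecutive bins (per
    cell and chromosome) in which one haplotype holds at least
    ``purity`` of the informative (tagged) reads and the total read
    count stays within ``copy_tolerance`` of the cell's median bin count
    (the diploid baseline).  Bins with zero informative reads are
    skipped; haplotype-pure runs at reduced total coverage are treated
    as deletions and not called.
    """
    out_rows = []
    for cell, cell_bins in bins.groupby("cell", sort=True):
        baseline = float(np.median(cell_bins["count_total"].to_numpy()))
        if baseline <= 0:
            continue
        for chrom, sub in cell_bins.groupby("chrom", sort=False):
            sub = sub.sort_values("bin_start")
            run: list[tuple] = []
            run_hap = None

            def flush():
                nonlocal run, run_hap
                if run_hap is not None and len(run) >= min_bins:
                    out_rows.append(
                        (cell, chrom, run[0][0], run[-1][1], run_hap, len(run), "diploid")
                    )
                run, run_hap = [], None

            for r in sub.itertuples():
                informative = r.count_A + r.count_B
                if informative == 0:
                    continue  # uninformative bin: neither extends nor breaks a run
                frac_a = r.count_A / informative
                hap = "A" if frac_a >= purity else ("B" if 1 - frac_a >= purity else None)
                copy_ok = abs(r.count_total - baseline) <= copy_tolerance * baseline
                if hap is None or not copy_ok:
                    flush()
                    continue
                if run_hap not in (None, hap):
                    flush()
                run_hap = hap
                run.append((r.bin_start, r.bin_end))
            flush()
    return pd.DataFrame(out_rows, columns=LOH_COLUMNS)


def naive_ploidy(
    reads: pd.DataFrame,
    genome_index,
    trisomy_threshold: float = 1.25,
    monosomy_threshold: float = 0.75,
) -> pd.DataFrame:
    """Per (cell, chromosome) copy state from relative read density.

    Density is reads per effective base; the per-cell diploid baseline
    is the median density across chromosomes.  Ratios above the trisomy
    threshold flag a gained chromosome, below the monosomy threshold a
    lost one.  A deliberately naive stand-in for a full HMM-based copy
    number caller, sufficient to exclude copy-abnormal regions.
    """
    rows = []
    eff = {c: genome_index.effective_length(c) for c in genome_index.chromosomes}
    for cell, sub in reads.groupby("cell", sort=True):
        counts = sub.groupby("chrom").size()
        dens = {c: counts.get(c, 0) / eff[c] for c in eff}
        baseline = float(np.median(list(dens.values())))
        for c in eff:
            ratio = dens[c] / baseline if baseline > 0 else np.nan
            state = "diploid"
            if ratio >= trisomy_threshold:
                state = "trisomy"
            elif ratio <= monosomy_threshold:
                state = "monosomy"
            rows.append((cell, c, float(ratio), state))
    return pd.DataFrame(rows, columns=["cell", "chrom", "density_ratio", "copy_state"])
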