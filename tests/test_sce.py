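"""SCE caller: state inference, region definition, filters, summaries."""

import numpy as np
import pandas as pd
import pytest

from conftest import match_fraction, precision_fraction
from g4sce import sce
from g4sce.genome import GenomeIndex
from g4sce.simulate import SimulationParams, simulate_cells


def make_reads(labels, start=0, spacing=1000, read_len=50, chrom="chr1", cell="c0"):
    starts = start + spacing * np.arange(len(labels))
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + read_len,
            "label": list(labels),
            "hap": ".",
            "cell": cell,
        }
    )


class TestInferStrandStates:
    def test_noiseless_switch_gives_two_segments(self):
        reads = make_reads("WC" * 20 + "C" * 40)
        segs = sce.infer_strand_states(reads)
        assert list(segs["state"]) == ["WC", "CC"]
        # the trailing C of the WC block is ambiguous and may join either side
        assert abs(segs.iloc[0]["n_reads"] - 40) <= 1
        assert abs(segs.iloc[1]["n_reads"] - 40) <= 1

    def test_all_watson_is_single_ww_segment(self):
        segs = sce.infer_strand_states(make_reads("W" * 50))
        assert list(segs["state"]) == ["WW"]

    def test_too_few_reads_is_uncallable(self):
        segs = sce.infer_strand_states(make_reads("W" * 5))
        assert segs.empty

    def test_label_swap_mirrors_states_and_keeps_regions(self):
        rng = np.random.default_rng(0)
        labels = ["W" if rng.random() < 0.5 else "C" for _ in range(60)] + [
            "W" if rng.random() < 0.98 else "C" for _ in range(60)
        ]
        reads = make_reads("".join(labels))
        swapped = reads.assign(label=reads["label"].map({"W": "C", "C": "W"}))
        segs = sce.infer_strand_states(reads)
        segs_sw = sce.infer_strand_states(swapped)
        mirror = {"WW": "CC", "WC": "WC", "CC": "WW"}
        assert [mirror[s] for s in segs["state"]] == list(segs_sw["state"])
        assert list(segs[["start", "end"]].itertuples(index=False)) == list(
            segs_sw[["start", "end"]].itertuples(index=False)
        )

    def test_multiple_cells_rejected(self):
        reads = pd.concat([make_reads("W" * 20, cell="a"), make_reads("W" * 20, cell="b")])
        with pytest.raises(ValueError, match="single cell"):
            sce.infer_strand_states(reads)


class TestCallSces:
    def test_region_is_the_inter_read_gap(self):
        segs = pd.DataFrame(
            [
                ("chr1", 100_000, 350_000, "WC", "c0", 40, 100_000, 350_000),
                ("chr1", 361_000, 600_000, "CC", "c0", 40, 361_000, 600_000),
            ],
            columns=sce.SEGMENT_COLUMNS,
        )
        out = sce.call_sces(segs)
        assert len(out) == 1
        r = out.iloc[0]
        assert (r["start"], r["end"], r["resolution"]) == (350_000, 361_000, 11_000)

    def test_abutting_reads_give_resolution_one(self):
        segs = pd.DataFrame(
            [
                ("chr1", 0, 1000, "WW", "c0", 20, 0, 1000),
                ("chr1", 1001, 3000, "WC", "c0", 20, 1001, 3000),
            ],
            columns=sce.SEGMENT_COLUMNS,
        )
        out = sce.call_sces(segs)
        assert out.iloc[0]["resolution"] == 1

    def test_double_switch_emits_stacked_pair_with_warning(self):
        segs = pd.DataFrame(
            [
                ("chr1", 0, 1000, "WW", "c0", 20, 0, 1000),
                ("chr1", 2000, 3000, "CC", "c0", 20, 2000, 3000),
            ],
            columns=sce.SEGMENT_COLUMNS,
        )
        with pytest.warns(UserWarning, match="double"):
            out = sce.call_sces(segs)
        assert len(out) == 2
        assert (out["start"] == 1000).all() and (out["end"] == 2000).all()

    def test_noiseless_one_step_switch_end_to_end(self):
        reads = make_reads("W" * 40 + "WC" * 20, spacing=1000)
        out = sce.call_sces(sce.infer_strand_states(reads))
        assert len(out) == 1
        # ML boundary sits before the first C read (index 41)
        assert (out.iloc[0]["start"], out.iloc[0]["end"]) == (40_050, 41_000)

    def test_noiseless_two_step_switch_is_stacked_double(self):
        reads = make_reads("W" * 40 + "C" * 40, spacing=1000)
        with pytest.warns(UserWarning, match="double"):
            out = sce.call_sces(sce.infer_strand_states(reads))
        assert len(out) == 2
        assert (out["start"] == 39_050).all() and (out["end"] == 40_000).all()

    def test_fast_path_equals_per_cell_path(self, small_dataset):
        reads, _, _ = small_dataset
        sub = reads[reads["cell"].isin([f"cell_{i:04d}" for i in range(8)])]
        fast = sce.call_sces_for_cells(sub).sort_values(["cell", "chrom", "start"]).reset_index(drop=True)
        parts = []
        for _, cr in sub.groupby("cell"):
            segs = sce.infer_strand_states(cr)
            if len(segs):
                parts.append(sce.call_sces(segs))
        slow = pd.concat(parts).sort_values(["cell", "chrom", "start"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(fast, slow)


class TestRecallPrecision:
    def test_noiseless_dense_reads_are_perfectly_called(self, small_genome):
        params = SimulationParams(
            n_cells=25, sce_rate_per_cell=2.0, coverage_fraction=0.05, background_noise=0.0, seed=31
        )
        reads, truth = simulate_cells(small_genome, params)
        called = sce.call_sces_for_cells(reads)
        assert match_fraction(called, truth.true_sces) >= 0.97
        assert precision_fraction(called, truth.true_sces) >= 0.97

    def test_default_noise_keeps_recall_and_precision_high(self, small_dataset):
        reads, truth, _ = small_dataset
        called = sce.call_sces_for_cells(reads)
        assert match_fraction(called, truth.true_sces) >= 0.92
        assert precision_fraction(called, truth.true_sces) >= 0.92

    def test_resolution_equals_independent_inter_read_gap(self, small_dataset):
        """Every emitted resolution is an actual gap between adjacent reads."""
        reads, _, _ = small_dataset
        called = sce.call_sces_for_cells(reads)
        by_key = {k: np.sort(v["start"].to_numpy()) for k, v in reads.groupby(["cell", "chrom"])}
        ends_by_key = {k: v.sort_values("start")["end"].to_numpy() for k, v in reads.groupby(["cell", "chrom"])}
        for r in called.head(50).itertuples():
            starts = by_key[(r.cell, r.chrom)]
            ends = ends_by_key[(r.cell, r.chrom)]
            j = np.searchsorted(starts, r.end)
            assert starts[j] == r.end
            assert ends[j - 1] == r.start or r.resolution == 1


class TestFilterRecurrent:
    def base_sces(self, n_cells, region=(1000, 5000)):
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "start": region[0],
                "end": region[1],
                "cell": [f"c{i}" for i in range(n_cells)],
                "homolog": "none",
                "resolution": region[1] - region[0],
            }
        )

    def test_region_in_six_percent_of_cells_removed(self):
        kept, removed = sce.filter_recurrent(self.base_sces(6), cell_count=100)
        assert kept.empty and len(removed) == 6

    def test_region_in_five_percent_of_cells_kept(self):
        kept, removed = sce.filter_recurrent(self.base_sces(5), cell_count=100)
        assert removed.empty and len(kept) == 5

    def test_reciprocal_overlap_threshold(self):
        # 40% mutual overlap does not cluster -> both kept
        a = self.base_sces(4, region=(0, 10_000))
        b = self.base_sces(4, region=(6_000, 16_000)).assign(cell=[f"d{i}" for i in range(4)])
        kept, removed = sce.filter_recurrent(pd.concat([a, b], ignore_index=True), cell_count=100)
        assert removed.empty

    def test_planted_inversion_removed_true_sces_untouched(self, small_dataset):
        reads, truth, params = small_dataset
        called = sce.call_sces_for_cells(reads)
        inversion = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": 5_500_000,
                "end": 5_504_000,
                "cell": sorted(reads["cell"].unique()),
                "homolog": "none",
                "resolution": 4000,
            }
        )
        combined = pd.concat([called, inversion], ignore_index=True)
        kept, removed = sce.filter_recurrent(combined, cell_count=params.n_cells)
        assert len(removed) == params.n_cells  # the artifact, in every cell
        assert (removed["start"] == 5_500_000).all()
        assert len(kept) == len(called)


class TestHomologAssignment:
    def make_f1_reads(self, switch_hap="A"):
        rows = []
        for hap in ("A", "B"):
            for i in range(12):
                pos = 100_000 + i * 10_000
                label = "W"
                if hap == switch_hap and pos >= 160_000:
                    label = "C"
                rows.append(("chr1", pos, pos + 50, label, hap, "c0"))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "label", "hap", "cell"])

    def sce_row(self):
        return pd.DataFrame(
            [("chr1", 155_050, 160_000, "c0", "none", 4950)],
            columns=["chrom", "start", "end", "cell", "homolog", "resolution"],
        )

    def test_switch_in_haplotype_a_assigns_a(self):
        out = sce.assign_homolog(self.sce_row(), self.make_f1_reads("A"))
        assert out.iloc[0]["homolog"] == "A"

    def test_no_tagged_reads_gives_none(self):
        reads = self.make_f1_reads("A").assign(hap=".")
        out = sce.assign_homolog(self.sce_row(), reads)
        assert out.iloc[0]["homolog"] == "none"

    def test_both_switching_is_uninformative(self):
        a = self.make_f1_reads("A")
        b = self.make_f1_reads("B")
        both = pd.concat([a[a["hap"] == "A"], b[b["hap"] == "B"]], ignore_index=True)
        out = sce.assign_homolog(self.sce_row(), both)
        assert out.iloc[0]["homolog"] == "none"


class TestSummaries:
    def test_median_resolution(self):
        sces = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": [0, 0, 0],
                "end": [5000, 10_000, 15_000],
                "cell": ["a", "b", "c"],
                "homolog": "none",
                "resolution": [5000, 10_000, 15_000],
            }
        )
        s = sce.resolution_summary(sces)
        assert s["median_resolution"] == 10_000
        assert s["fraction_below_100kb"] == 1.0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            sce.resolution_summary(pd.DataFrame(columns=sce.SCE_COLUMNS))

    def test_size_correlation_proportional_counts(self):
        gi = GenomeIndex({"chr1": 1_000_000, "chr2": 2_000_000, "chr3": 3_000_000})
        rows = []
        for i, chrom in enumerate(gi.chromosomes, start=1):
            for k in range(10 * i):
                rows.append((chrom, k, k + 10, f"c{k}", "none", 10))
        sces = pd.DataFrame(rows, columns=sce.SCE_COLUMNS)
        assert sce.chromosome_size_correlation(sces, gi, n_cells=10) == pytest.approx(1.0)

    def test_size_correlation_constant_counts_is_zero(self):
        gi = GenomeIndex({"chr1": 1_000_000, "chr2": 2_000_000, "chr3": 3_000_000})
        rows = [(c, 0, 10, "c0", "none", 10) for c in gi.chromosomes]
        sces = pd.DataFrame(rows, columns=sce.SCE_COLUMNS)
        assert sce.chromosome_size_correlation(sces, gi, n_cells=1) == 0.0


def test_recurrence_threshold_floors_at_one_cell():
    """With few cells, singleton clusters are never removed as recurrent."""
    sces = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": [1000, 50_000, 90_000],
            "end": [5000, 54_000, 94_000],
            "cell": ["c0", "c1", "c2"],
            "homolog": "none",
            "resolution": 4000,
        }
    )
    kept, removed = sce.filter_recurrent(sces, cell_count=10)
    assert removed.empty and len(kept) == 3
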