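"""Allele-specific motifs, homolog concordance, LOH and ploidy calling."""

import numpy as np
import pandas as pd
import pytest

from g4sce import allelic
from g4sce.genome import GenomeIndex
from g4sce.simulate import SimulationParams, simulate_f1_hybrid


class TestFindAllelicG4:
    BACKBONE = "ACTTAC" * 20

    def with_motif(self, broken=False):
        motif = "GAGTGGGTGGGTGGG" if broken else "GGGTGGGTGGGTGGG"
        return self.BACKBONE[:50] + motif + self.BACKBONE[50:]

    def test_run_breaking_snp_makes_motif_allele_specific(self):
        a = {"chr1": self.with_motif(broken=False)}
        b = {"chr1": self.with_motif(broken=True)}  # G->A in the first run
        out = allelic.find_allelic_g4(a, b)
        assert len(out) == 1
        assert out.iloc[0]["haplotype"] == "A"
        assert (out.iloc[0]["start"], out.iloc[0]["end"]) == (50, 65)

    def test_motif_on_both_haplotypes_excluded(self):
        seqs = {"chr1": self.with_motif()}
        assert allelic.find_allelic_g4(seqs, dict(seqs)).empty

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            allelic.find_allelic_g4({"c": "ACGT"}, {"c": "ACGTA"})

    def test_recovers_generator_truth(self, small_genome):
        from g4sce.simulate import haplotype_sequences

        params = SimulationParams(n_cells=2, seed=13)
        _, allelic_truth, truth = simulate_f1_hybrid(small_genome, params, seed=14)
        hap_a, hap_b = haplotype_sequences(small_genome, truth.snp_alleles)
        found = allelic.find_allelic_g4(hap_a, hap_b)
        found_keys = set(zip(found["chrom"], found["start"], found["haplotype"]))
        truth_keys = set(zip(allelic_truth["chrom"], allelic_truth["start"], allelic_truth["haplotype"]))
        # every engineered allele-specific motif is recovered with its haplotype
        missing = truth_keys - found_keys
        assert len(missing) <= 0.02 * len(truth_keys)


class TestConcordance:
    def informative_df(self, homologs, haplotypes):
        sces = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": [i * 10_000 for i in range(len(homologs))],
                "end": [i * 10_000 + 100 for i in range(len(homologs))],
                "cell": [f"c{i}" for i in range(len(homologs))],
                "homolog": homologs,
                "resolution": 100,
            }
        )
        g4 = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": [i * 10_000 + 10 for i in range(len(haplotypes))],
                "end": [i * 10_000 + 40 for i in range(len(haplotypes))],
                "strand": "+",
                "haplotype": haplotypes,
            }
        )
        return sces, g4

    def test_five_of_five_concordant(self):
        sces, g4 = self.informative_df(["A"] * 5, ["A"] * 5)
        res = allelic.concordance_test(sces, g4)
        assert res.n_informative == 5 and res.n_concordant == 5
        assert res.p_value == pytest.approx(1 / 32)

    def test_two_of_four_concordant(self):
        sces, g4 = self.informative_df(["A", "A", "B", "B"], ["A", "B", "A", "B"])
        res = allelic.concordance_test(sces, g4)
        assert res.n_informative == 4 and res.n_concordant == 2
        assert res.p_value == pytest.approx(11 / 16)

    def test_region_overlapping_two_motifs_not_informative(self):
        sces, g4 = self.informative_df(["A"], ["A"])
        extra = pd.DataFrame(
            {"chrom": ["chr1"], "start": [50], "end": [80], "strand": ["+"], "haplotype": ["B"]}
        )
        res = allelic.concordance_test(sces, pd.concat([g4, extra], ignore_index=True))
        assert res.n_informative == 0
        assert res.p_value is None

    def test_unassigned_homolog_not_informative(self):
        sces, g4 = self.informative_df(["none"], ["A"])
        assert allelic.concordance_test(sces, g4).n_informative == 0

    @pytest.mark.parametrize("n,k", [(3, 2), (8, 6), (12, 7), (20, 14), (20, 10)])
    def test_one_sided_p_matches_exhaustive_enumeration(self, n, k):
        """p equals the fraction of all 2^n outcomes with >= k concordant."""
        outcomes = np.arange(2**n, dtype=np.uint32)
        popcount = np.zeros(2**n, dtype=np.int64)
        for bit in range(n):
            popcount += (outcomes >> bit) & 1
        expected = float((popcount >= k).mean())
        sces, g4 = self.informative_df(["A"] * n, ["A"] * k + ["B"] * (n - k))
        res = allelic.concordance_test(sces, g4)
        assert res.n_concordant == k
        assert res.p_value == pytest.approx(expected, rel=1e-9)

    def test_two_sided_mode(self):
        sces, g4 = self.informative_df(["A"] * 5, ["A"] * 5)
        res = allelic.concordance_test(sces, g4, sidedness="two-sided")
        assert res.p_value == pytest.approx(2 / 32)

    def test_null_coin_flip_type_one_error(self):
        """Under a fair-coin null, P(p <= 0.05) stays near 0.05."""
        rng = np.random.default_rng(99)
        hits = 0
        n_inf = 40
        reps = 500
        for _ in range(reps):
            homs = np.where(rng.random(n_inf) < 0.5, "A", "A")
            haps = np.where(rng.random(n_inf) < 0.5, "A", "B")
            sces, g4 = self.informative_df(list(homs), list(haps))
            res = allelic.concordance_test(sces, g4)
            if res.p_value <= 0.05:
                hits += 1
        assert 0.03 <= hits / reps <= 0.07

    def test_parameter_recovery_from_f1_simulation(self, small_genome):
        """SCEs planted on the intact homolog at rate 0.7 are recovered."""
        from g4sce import sce

        params = SimulationParams(n_cells=150, sce_rate_per_cell=3.0, seed=23)
        reads, allelic_g4, truth = simulate_f1_hybrid(
            small_genome, params, allelic_fraction=0.5, concordance=0.7, seed=24
        )
        called = sce.call_sces_for_cells(reads)
        with_hom = sce.assign_homolog(called, reads)
        res = allelic.concordance_test(with_hom, allelic_g4)
        assert res.n_informative >= 20
        se = np.sqrt(0.7 * 0.3 / res.n_informative)
        assert abs(res.fraction_concordant - 0.7) <= max(2.5 * se, 0.12)


class TestCallLoh:
    def bins(self, counts, totals=None, cell="c0", chrom="chr1", width=1_000_000):
        rows = []
        for i, (a, b) in enumerate(counts):
            tot = totals[i] if totals else a + b + 10
            rows.append((cell, chrom, i * width, (i + 1) * width, a, b, tot))
        return pd.DataFrame(
            rows, columns=["cell", "chrom", "bin_start", "bin_end", "count_A", "count_B", "count_total"]
        )

    def test_hand_traceable_fixture(self):
        bins = self.bins(
            [(10, 12), (11, 9), (12, 0), (10, 0), (11, 0), (9, 11)],
            totals=[22, 20, 22, 20, 21, 20],
        )
        out = allelic.call_loh(bins, min_bins=3)
        assert len(out) == 1
        seg = out.iloc[0]
        assert (seg["start"], seg["end"], seg["haplotype_retained"], seg["n_bins"]) == (
            2_000_000,
            5_000_000,
            "A",
            3,
        )

    def test_all_mixed_bins_give_no_calls(self):
        bins = self.bins([(10, 12), (11, 9), (12, 10), (10, 11), (11, 10), (9, 11)])
        assert allelic.call_loh(bins).empty

    def test_deletion_not_called_as_loh(self):
        # haplotype-pure run at half coverage is a deletion, not LOH
        bins = self.bins(
            [(10, 12), (11, 9), (6, 0), (5, 0), (6, 0), (9, 11)],
            totals=[22, 20, 11, 10, 11, 20],
        )
        assert allelic.call_loh(bins).empty

    def test_short_pure_run_below_min_bins_not_called(self):
        bins = self.bins(
            [(10, 12), (12, 0), (10, 0), (9, 11)], totals=[22, 22, 20, 20]
        )
        assert allelic.call_loh(bins, min_bins=3).empty

    def test_recovers_planted_loh_from_f1_reads(self, small_genome):
        params = SimulationParams(n_cells=12, sce_rate_per_cell=1.0, seed=33)
        reads, _, truth = simulate_f1_hybrid(
            small_genome, params, planted_loh=[("chr1", 2_000_000, 5_000_000, "B")], seed=34
        )
        bins = allelic.bin_haplotype_counts(reads, small_genome.genome_index)
        out = allelic.call_loh(bins)
        assert set(out["cell"]) == set(reads["cell"].unique())
        for row in out.itertuples():
            assert row.chrom == "chr1"
            assert row.haplotype_retained == "B"
            assert row.start >= 1_000_000 and row.end <= 6_000_000

    def test_no_planted_loh_means_no_calls(self, small_genome):
        params = SimulationParams(n_cells=10, sce_rate_per_cell=1.0, seed=35)
        reads, _, _ = simulate_f1_hybrid(small_genome, params, planted_loh=[], seed=36)
        bins = allelic.bin_haplotype_counts(reads, small_genome.genome_index)
        assert allelic.call_loh(bins).empty


class TestNaivePloidy:
    def make_reads(self, dens, gi, cell="c0"):
        rows = []
        rng = np.random.default_rng(1)
        for chrom, d in dens.items():
            n = int(d * gi.effective_length(chrom))
            starts = rng.integers(0, gi.lengths[chrom] - 100, size=n)
            for s in starts:
                rows.append((chrom, s, s + 50, "W", ".", cell))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "label", "hap", "cell"])

    def test_density_ratio_thresholds(self):
        gi = GenomeIndex({"chr1": 1_000_000, "chr2": 1_000_000, "chr3": 1_000_000})
        reads = self.make_reads({"chr1": 0.001, "chr2": 0.0015, "chr3": 0.001}, gi)
        out = allelic.naive_ploidy(reads, gi).set_index("chrom")
        assert out.loc["chr1", "copy_state"] == "diploid"
        assert out.loc["chr2", "copy_state"] == "trisomy"

    def test_monosomy_flagged(self):
        gi = GenomeIndex({"chr1": 1_000_000, "chr2": 1_000_000, "chr3": 1_000_000})
        reads = self.make_reads({"chr1": 0.001, "chr2": 0.0005, "chr3": 0.001}, gi)
        out = allelic.naive_ploidy(reads, gi).set_index("chrom")
        assert out.loc["chr2", "copy_state"] == "monosomy"

    def test_planted_trisomy_flagged_in_most_cells(self):
        # needs >= 3 chromosomes: the diploid baseline is the median
        # per-chromosome density, degenerate for a 2-chromosome genome
        from g4sce.simulate import SyntheticGenomeSpec, generate_genome

        genome = generate_genome(
            SyntheticGenomeSpec(n_chromosomes=3, chrom_lengths=3_000_000, gene_count=15, seed=45)
        )
        params = SimulationParams(n_cells=40, sce_rate_per_cell=1.0, seed=43)
        reads, _, truth = simulate_f1_hybrid(genome, params, planted_trisomy=["chr2"], seed=44)
        out = allelic.naive_ploidy(reads, genome.genome_index)
        flagged = out[(out["chrom"] == "chr2") & (out["copy_state"] == "trisomy")]
        assert len(flagged) >= 0.95 * params.n_cells
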