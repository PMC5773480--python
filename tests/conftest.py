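import numpy as np
import pytest

from g4sce.simulate import (
    SimulationParams,
    SyntheticGenomeSpec,
    generate_genome,
    simulate_cells,
)


@pytest.fixture(scope="session")
def small_genome():
    """2 x 8 Mb genome with gaps, genes and planted motifs (seeded)."""
    spec = SyntheticGenomeSpec(
        n_chromosomes=2, chrom_lengths=8_000_000, gene_count=40, seed=42
    )
    return generate_genome(spec)


@pytest.fixture(scope="session")
def small_dataset(small_genome):
    """60-cell uniform-placement dataset with truth (seeded)."""
    params = SimulationParams(n_cells=60, sce_rate_per_cell=2.0, seed=7)
    reads, truth = simulate_cells(small_genome, params)
    return reads, truth, params


def match_fraction(called, truth_sces, slack=50_000):
    """Fraction of true SCEs whose localization window (± slack) is hit."""
    tp = 0
    for r in truth_sces.itertuples():
        sub = called[(called["cell"] == r.cell) & (called["chrom"] == r.chrom)]
        if ((sub["start"] < r.window_end + slack) & (sub["end"] > r.window_start - slack)).any():
            tp += 1
    return tp / max(len(truth_sces), 1)


def precision_fraction(called, truth_sces, slack=50_000):
    """Fraction of called regions matching some true localization window."""
    ok = 0
    for r in called.itertuples():
        sub = truth_sces[(truth_sces["cell"] == r.cell) & (truth_sces["chrom"] == r.chrom)]
        if ((sub["window_start"] - slack < r.end) & (sub["window_end"] + slack > r.start)).any():
            ok += 1
    return ok / max(len(called), 1)
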