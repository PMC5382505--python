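"""Session fixtures: simulated study datasets shared across test modules."""

from __future__ import annotations

import pytest

from lrcorrect.pipeline import PipelineOptions, run_correction
from lrcorrect.simulate import (LongReadConfig, RepeatFamily, ShortReadConfig,
                                SimulationConfig, simulate_all)


@pytest.fixture(scope="session")
def small_sim():
    """Quick 30 kb fixture with one similar-repeat family, gapped contigs."""
    cfg = SimulationConfig(
        genome_length=30_000,
        repeat_families=[RepeatFamily(2, 1000, 0.04)],
        contig_gap_fraction=0.05,
        long_read=LongReadConfig(coverage=10, mean_length=4000),
        short_read=ShortReadConfig(coverage=40),
        seed=1)
    return simulate_all(cfg)


@pytest.fixture(scope="session")
def small_results(small_sim):
    results, graph, report = run_correction(
        small_sim.long_reads, small_sim.contigs, small_sim.alignments,
        PipelineOptions(), short_reads=[s for _i, s in small_sim.short_reads])
    return results, graph, report


@pytest.fixture(scope="session")
def rescue_sim():
    """Repeat-rescue study: 100 kb genome, one 2-copy 1 kb repeat family at
    4% divergence, contigs missing one copy plus 5% of unique sequence,
    20x long reads at 15% error, 40x short reads."""
    cfg = SimulationConfig(
        genome_length=100_000,
        repeat_families=[RepeatFamily(2, 1000, 0.04)],
        contig_gap_fraction=0.05,
        drop_repeat_copy=True,
        long_read=LongReadConfig(coverage=20, mean_length=8000,
                                 error_rate=0.15),
        short_read=ShortReadConfig(coverage=40),
        seed=7)
    return simulate_all(cfg)


@pytest.fixture(scope="session")
def rescue_results(rescue_sim):
    results, graph, report = run_correction(
        rescue_sim.long_reads, rescue_sim.contigs, rescue_sim.alignments,
        PipelineOptions(mode="ordinary"),
        short_reads=[s for _i, s in rescue_sim.short_reads])
    return results, graph, report


@pytest.fixture(scope="session")
def rescue_results_repeat_free(rescue_sim):
    results, graph, report = run_correction(
        rescue_sim.long_reads, rescue_sim.contigs, rescue_sim.alignments,
        PipelineOptions(mode="repeat-free"))
    return results, graph, report


@pytest.fixture(scope="session")
def disambig_sim():
    """Support-disambiguation study: both repeat copies present in the
    contigs, so repeat regions have rival candidates in both copies."""
    cfg = SimulationConfig(
        genome_length=80_000,
        repeat_families=[RepeatFamily(2, 1000, 0.05)],
        contig_gap_fraction=0.0,
        drop_repeat_copy=False,
        long_read=LongReadConfig(coverage=20, mean_length=8000,
                                 error_rate=0.15),
        short_read=ShortReadConfig(coverage=40),
        seed=11)
    return simulate_all(cfg)
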