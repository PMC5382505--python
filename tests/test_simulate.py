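"""Synthetic fixtures: determinism, error model, repeat structure, aligner."""

import edlib
import numpy as np
import pytest

from lrcorrect import cigar as cg
from lrcorrect.seqio import revcomp
from lrcorrect.simulate import (LongReadConfig, RepeatFamily, ShortReadConfig,
                                SimulationConfig, simulate_all,
                                simulate_contigs, simulate_genome,
                                simulate_long_reads, toy_align,
                                toy_align_denovo)


def _cfg(**kw):
    base = dict(genome_length=30_000,
                repeat_families=[RepeatFamily(2, 1000, 0.04)],
                contig_gap_fraction=0.05,
                long_read=LongReadConfig(coverage=8, mean_length=3000),
                short_read=ShortReadConfig(coverage=10),
                seed=3)
    base.update(kw)
    return SimulationConfig(**base)


def test_generators_deterministic_under_seed():
    d1 = simulate_all(_cfg())
    d2 = simulate_all(_cfg())
    assert d1.genome == d2.genome
    assert list(d1.long_reads.items()) == list(d2.long_reads.items())
    assert d1.short_reads == d2.short_reads
    assert d1.alignments == d2.alignments


def test_similar_repeat_divergence_near_config():
    cfg = _cfg(repeat_families=[RepeatFamily(2, 1000, 0.05)])
    genome, copies = simulate_genome(cfg)
    assert len(copies) == 2
    a = genome[copies[0].start:copies[0].end]
    b = genome[copies[1].start:copies[1].end]
    dist = edlib.align(a, b)["editDistance"]
    # pairwise divergence ~ 5% with binomial noise (3 sigma ~ 2%)
    assert 0.05 * 1000 * 0.4 <= dist <= 0.05 * 1000 * 1.8


def test_zero_divergence_copies_identical():
    cfg = _cfg(repeat_families=[RepeatFamily(2, 500, 0.0)])
    genome, copies = simulate_genome(cfg)
    segs = [genome[c.start:c.end] for c in copies]
    assert segs[0] == segs[1]


def test_no_repeat_families_no_annotation():
    cfg = _cfg(repeat_families=[])
    _genome, copies = simulate_genome(cfg)
    assert copies == []


def test_contigs_tile_genome_without_gaps():
    cfg = _cfg(contig_gap_fraction=0.0, drop_repeat_copy=False)
    genome, copies = simulate_genome(cfg)
    contigs, truth = simulate_contigs(genome, cfg, copies)
    covered = sum(t.end - t.start for t in truth)
    assert covered == len(genome)
    for t in truth:
        assert contigs.seq(t.contig_id) == genome[t.start:t.end]


def test_gap_fraction_and_dropped_copy():
    cfg = _cfg()
    genome, copies = simulate_genome(cfg)
    contigs, truth = simulate_contigs(genome, cfg, copies)
    covered = sum(t.end - t.start for t in truth)
    missing = len(genome) - covered
    # one whole repeat copy (1000) plus ~5% of the genome
    target = 1000 + 0.05 * len(genome)
    assert missing == pytest.approx(target, rel=0.35)
    dropped = copies[-1] if copies[-1].copy > copies[0].copy else copies[0]
    for t in truth:
        assert not (t.start < dropped.end and dropped.start < t.end)
    # the surviving copy remains available as a rescue template
    kept = copies[0] if dropped is copies[-1] else copies[-1]
    assert any(t.start <= kept.start and kept.end <= t.end for t in truth)


def test_error_free_reads_are_exact_substrings():
    cfg = _cfg(long_read=LongReadConfig(coverage=3, mean_length=2000,
                                        error_rate=0.0))
    genome, _copies = simulate_genome(cfg)
    reads, truth = simulate_long_reads(genome, cfg)
    for rid, seq in reads.items():
        rec = truth.records[rid]
        want = genome[rec.start:rec.end]
        if rec.strand == "-":
            want = revcomp(want)
        assert seq == want
        assert cg.parse_cigar(rec.error_script) == [(len(seq), "=")]


def test_empirical_error_rate_within_three_sigma():
    cfg = _cfg(genome_length=100_000,
               long_read=LongReadConfig(coverage=10, mean_length=5000,
                                        error_rate=0.15))
    genome, _copies = simulate_genome(cfg)
    reads, truth = simulate_long_reads(genome, cfg)
    assert len(reads) >= 100
    dist = 0
    total = 0
    for rid, seq in reads.items():
        t = truth.truth_seq(rid)
        dist += edlib.align(seq, t)["editDistance"]
        total += len(t)
    rate = dist / total
    sigma = np.sqrt(0.15 * 0.85 / total)
    # alignment parsimony re-explains some scripted errors, so the measured
    # rate sits slightly below the generative rate
    assert 0.15 - 0.02 <= rate <= 0.15 + 3 * sigma


def test_strand_balance():
    cfg = _cfg()
    genome, _copies = simulate_genome(cfg)
    _reads, truth = simulate_long_reads(genome, cfg)
    strands = [r.strand for r in truth.records.values()]
    frac = strands.count("-") / len(strands)
    assert 0.3 < frac < 0.7


# ---------------------------------------------------------------------------
# truth-guided aligner

def test_toy_align_repeat_region_gets_two_candidates():
    cfg = _cfg(contig_gap_fraction=0.0, drop_repeat_copy=False)
    data = simulate_all(cfg)
    copies = data.repeats
    multi = 0
    for rec in data.truth.records.values():
        over = [c for c in copies
                if min(rec.end, c.end) - max(rec.start, c.start) >= 200]
        if not over:
            continue
        hits = [a for a in data.alignments if a.read_id == rec.read_id]
        if len(hits) >= 2:
            multi += 1
    assert multi > 0


def test_toy_align_unique_read_single_candidate():
    cfg = _cfg(repeat_families=[], contig_gap_fraction=0.0)
    data = simulate_all(cfg)
    by_read = {}
    for a in data.alignments:
        by_read.setdefault(a.read_id, []).append(a)
    # reads within one contig get exactly one alignment
    n_single = sum(1 for alns in by_read.values() if len(alns) == 1)
    assert n_single >= 0.8 * len(by_read)


def test_toy_align_true_hit_identity_dominates_repeat_hit():
    cfg = _cfg(genome_length=60_000, contig_gap_fraction=0.0,
               drop_repeat_copy=False,
               long_read=LongReadConfig(coverage=15, mean_length=4000))
    data = simulate_all(cfg)
    copies = {(c.family, c.copy): c for c in data.repeats}
    true_ids, repeat_ids = [], []
    for a in data.alignments:
        rec = data.truth.records[a.read_id]
        # map the aligned contig interval back to genome coordinates
        ct = {t.contig_id: t for t in data.contig_truth}[a.contig_id]
        g0 = ct.start + a.contig_start
        g1 = ct.start + a.contig_end
        if g0 >= rec.start - 50 and g1 <= rec.end + 50:
            true_ids.append(a.identity)
        else:
            repeat_ids.append(a.identity)
    assert repeat_ids, "fixture should produce similar-repeat hits"
    assert np.mean(true_ids) > np.mean(repeat_ids)


def test_alignment_scripts_consistent():
    data = simulate_all(_cfg())
    for a in data.alignments:
        a.check_script()
        seg = a.oriented_read_segment(data.long_reads)
        assert cg.query_span(a.ops) == len(seg)


def test_denovo_aligner_recovers_unique_placements():
    cfg = _cfg(repeat_families=[], contig_gap_fraction=0.0,
               long_read=LongReadConfig(coverage=3, mean_length=2000,
                                        error_rate=0.05))
    genome, copies = simulate_genome(cfg)
    contigs, ctruth = simulate_contigs(genome, cfg, copies)
    reads, truth = simulate_long_reads(genome, cfg)
    alns = toy_align_denovo(reads, contigs)
    aligned_reads = {a.read_id for a in alns}
    assert len(aligned_reads) >= 0.7 * len(reads)
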