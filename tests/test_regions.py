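"""Region splitting: boundary merging, rules 1-2, unification properties."""

import numpy as np
import pytest

from lrcorrect import cigar as cg
from lrcorrect.alignments import FORWARD, RawAlignment
from lrcorrect.regions import (cluster_positions, collect_boundaries,
                               group_read_regions, split_contig_regions,
                               unify_regions)

from util import pairs_to_raw, random_alignment_set


def _aln(read_id, rs, re_, contig_id, cs, ce, ops=None, read_len=10_000,
         contig_len=10_000):
    ops = ops or [(ce - cs, "=")]
    return RawAlignment(read_id, read_len, rs, re_, contig_id, contig_len,
                        cs, ce, FORWARD, cg.identity(ops), ops)


# ---------------------------------------------------------------------------
# boundary clustering

def test_cluster_merges_within_delta():
    alns = [_aln("r1", 0, 200, "c", 100, 300),
            _aln("r2", 0, 198, "c", 102, 300)]
    b = collect_boundaries(alns, delta=4)
    assert b["c"] == [100, 300]


def test_cluster_delta_zero_is_identity():
    positions = [5, 6, 7, 100]
    snap = cluster_positions(positions, 0)
    assert snap == {p: p for p in positions}


def _closure_oracle(positions, delta):
    """Brute-force transitive closure of |a-b| < delta."""
    positions = sorted(set(positions))
    clusters = [[p] for p in positions]
    changed = True
    while changed:
        changed = False
        for i in range(len(clusters) - 1):
            if any(abs(a - b) < delta
                   for a in clusters[i] for b in clusters[i + 1]):
                clusters[i] += clusters.pop(i + 1)
                changed = True
                break
    return {p: min(c) for c in clusters for p in c}


def test_cluster_chain_collapses_like_transitive_closure():
    positions = [0, 3, 6, 9]
    assert cluster_positions(positions, 4) == _closure_oracle(positions, 4)
    assert set(cluster_positions(positions, 4).values()) == {0}


def test_cluster_random_vs_closure_oracle():
    rng = np.random.default_rng(11)
    for _ in range(100):
        pts = rng.integers(0, 200, size=int(rng.integers(2, 15))).tolist()
        delta = int(rng.integers(0, 9))
        assert cluster_positions(pts, delta) == _closure_oracle(pts, delta)


# ---------------------------------------------------------------------------
# rule 1 (contig splitting)

def contig_intervals(region_set, cid):
    return [(r.start, r.end) for r in region_set.regions(cid)]


def test_overlapping_hits_split_into_three():
    alns = [_aln("r1", 0, 200, "c", 100, 300),
            _aln("r2", 0, 200, "c", 200, 400)]
    rs = split_contig_regions(alns, delta=4)
    assert contig_intervals(rs, "c") == [(100, 200), (200, 300), (300, 400)]


def test_contained_hit_partitions_outer():
    alns = [_aln("r1", 0, 300, "c", 100, 400),
            _aln("r2", 0, 100, "c", 200, 300)]
    rs = split_contig_regions(alns, delta=4)
    assert contig_intervals(rs, "c") == [(100, 200), (200, 300), (300, 400)]


def test_single_hit_unsplit():
    alns = [_aln("r1", 0, 200, "c", 100, 300)]
    rs = split_contig_regions(alns, delta=4)
    assert contig_intervals(rs, "c") == [(100, 300)]


# ---------------------------------------------------------------------------
# rule 2 (read splitting via script projection)

def test_read_region_split_at_projected_contig_boundary():
    # gap-free alignment: projected read boundary = contig offset exactly
    alns = [_aln("r1", 0, 200, "c", 100, 300),
            _aln("r2", 0, 200, "c", 200, 400)]
    _rs, pairs = unify_regions(alns, delta=4)
    r1 = sorted([p for p in pairs if p.read_id == "r1"],
                key=lambda p: p.read_start)
    assert [(p.read_start, p.read_end) for p in r1] == [(0, 100), (100, 200)]
    assert [(p.contig_start, p.contig_end) for p in r1] == \
        [(100, 200), (200, 300)]


def test_no_internal_boundary_single_pair():
    alns = [_aln("r1", 0, 200, "c", 100, 300)]
    _rs, pairs = unify_regions(alns, delta=4)
    assert len(pairs) == 1
    p = pairs[0]
    assert (p.read_start, p.read_end, p.contig_start, p.contig_end) == \
        (0, 200, 100, 300)


def test_boundary_inside_insertion_goes_to_following_piece():
    # contig cut at 150 falls right at an insertion run in r1's script
    ops = [(50, "="), (5, "I"), (150, "=")]
    alns = [_aln("r1", 0, 205, "c", 100, 300, ops=ops),
            _aln("r2", 0, 150, "c", 150, 300)]
    _rs, pairs = unify_regions(alns, delta=4)
    r1 = sorted([p for p in pairs if p.read_id == "r1"],
                key=lambda p: p.read_start)
    assert [(p.contig_start, p.contig_end) for p in r1] == \
        [(100, 150), (150, 300)]
    # the inserted bases belong to the second piece
    assert r1[0].ops == [(50, "=")]
    assert r1[1].ops == [(5, "I"), (150, "=")]


# ---------------------------------------------------------------------------
# property suite (randomized)

def _union(intervals):
    merged = set()
    for s, e in intervals:
        merged.update(range(s, e))
    return merged


@pytest.mark.parametrize("delta", [0, 4, 10])
@pytest.mark.parametrize("indels", [False, True])
def test_splitting_properties_randomized(delta, indels):
    rng = np.random.default_rng(100 + delta)
    for trial in range(25):
        alns = random_alignment_set(rng, n_alns=8, indels=indels)
        if not alns:
            continue
        region_set, pairs = unify_regions(alns, delta)
        _check_splitting_invariants(alns, region_set, pairs, delta,
                                    exact_coverage=not indels)


def _check_splitting_invariants(alns, region_set, pairs, delta,
                                exact_coverage):
    # unification: intersecting contig regions are identical
    for cid in region_set.sequences():
        regs = region_set.regions(cid)
        for a, b in zip(regs, regs[1:]):
            assert a.end <= b.start or (a.start, a.end) == (b.start, b.end)

    # coverage conservation: split regions fill the (snapped) aligned
    # territory; with indels, pure-deletion slivers may be dropped
    from lrcorrect.regions import cluster_positions as _cp
    per_contig_orig = {}
    for a in alns:
        per_contig_orig.setdefault(a.contig_id, []).append(
            (a.contig_start, a.contig_end))
    for cid, ivs in per_contig_orig.items():
        snap = _cp([p for iv in ivs for p in iv], delta)
        orig_union = _union([(snap[s], max(snap[e], snap[s] + 1))
                             for s, e in ivs])
        split_union = _union([(r.start, r.end)
                              for r in region_set.regions(cid)])
        assert split_union <= orig_union | set(
            range(min(orig_union, default=0), max(orig_union, default=0)))
        missing = orig_union - split_union
        if exact_coverage:
            assert not missing
        else:
            total_dels = sum(n for a in alns if a.contig_id == cid
                             for n, op in a.ops if op == "D")
            assert len(missing) <= total_dels + 2 * delta * len(ivs)

    # edit-script preservation: when no piece of an alignment was dropped,
    # concatenating the sub-scripts reproduces the original script
    by_aln = {}
    for p in pairs:
        by_aln.setdefault(p.aln_id, []).append(p)
    for aln_id, sub in by_aln.items():
        a = alns[aln_id]
        sub = sorted(sub, key=lambda p: p.contig_start)
        covered = sum(p.contig_end - p.contig_start for p in sub)
        snapped_span = covered  # pieces tile the snapped interval when none dropped
        if snapped_span == a.contig_end - a.contig_start:
            flat = [o for p in sub for o in p.ops]
            if cg.query_span(flat) == cg.query_span(a.ops):
                assert cg.merge_runs(flat) == cg.merge_runs(a.ops)

    # idempotence: splitting its own output changes nothing
    read_lens = {a.read_id: a.read_len for a in alns}
    contig_lens = {a.contig_id: a.contig_len for a in alns}
    again_rs, again_pairs = unify_regions(
        pairs_to_raw(pairs, read_lens, contig_lens), delta)
    key = lambda p: (p.read_id, p.read_start, p.read_end, p.contig_id,
                     p.contig_start, p.contig_end, p.orientation)
    assert sorted(map(key, again_pairs)) == sorted(map(key, pairs))


# ---------------------------------------------------------------------------
# grouping

def test_group_read_regions_orders_and_groups_candidates():
    alns = [_aln("r1", 0, 200, "c1", 100, 300),
            _aln("r1", 200, 400, "c2", 0, 200),
            _aln("r1", 0, 200, "c3", 500, 700)]  # rival candidate
    _rs, pairs = unify_regions(alns, delta=4)
    ladder = group_read_regions(pairs)["r1"]
    assert [iv for iv, _c in ladder] == [(0, 200), (200, 400)]
    assert len(ladder[0][1]) == 2
    assert len(ladder[1][1]) == 1
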