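"""Minimum-weight-path DP, sequence emission, repeat flagging."""

import numpy as np
import pytest

from lrcorrect.alignments import FORWARD, REVERSE
from lrcorrect.correction import (correct_all, correct_read,
                                  flag_repeat_corrected, min_weight_path)
from lrcorrect.graph import ACCURATE, ORDINARY, ContigGraph, build_graph
from lrcorrect.regions import AlignedPair, group_read_regions
from lrcorrect.seqio import SequenceStore, revcomp

from util import brute_force_best, brute_force_paths, random_dp_instance


def _pair(read_id, rs, re_, cid, cs, ce, orientation=FORWARD, ident=0.9,
          aln_id=0):
    return AlignedPair(read_id=read_id, contig_id=cid, read_start=rs,
                       read_end=re_, contig_start=cs, contig_end=ce,
                       orientation=orientation, identity=ident,
                       ops=[(ce - cs, "M")], aln_id=aln_id)


# ---------------------------------------------------------------------------
# DP vs brute force

def test_single_region_single_candidate():
    table, graph = random_dp_instance(np.random.default_rng(0),
                                      max_regions=1, max_cands=1)
    chosen, weight, gaps = min_weight_path(table, graph)
    assert len(chosen) == 1 and weight == 0.0 and gaps == [False]


@pytest.mark.parametrize("tie_heavy", [False, True])
def test_dp_matches_brute_force_enumeration(tie_heavy):
    rng = np.random.default_rng(42 if tie_heavy else 43)
    checked = 0
    for _ in range(150):
        table, graph = random_dp_instance(rng, tie_heavy=tie_heavy)
        oracle = brute_force_best(table, graph)
        chosen, weight, gaps = min_weight_path(table, graph)
        assert not any(gaps)  # instance guarantees a full path
        assert oracle is not None
        assert weight == pytest.approx(oracle[0])
        if tie_heavy:
            ids = sum(p.identity for p in chosen)
            assert ids == pytest.approx(oracle[1])
        checked += 1
    assert checked == 150


def test_adding_a_candidate_never_worsens_optimum():
    rng = np.random.default_rng(9)
    for _ in range(50):
        table, graph = random_dp_instance(rng)
        _c, w1, _g = min_weight_path(table, graph)
        # add a fresh candidate connected to everything with weight 0
        i = int(rng.integers(0, len(table)))
        iv, cands = table[i]
        extra = _pair("r", iv[0], iv[1], "cx", 0, iv[1] - iv[0],
                      ident=0.5, aln_id=99)
        graph.add_vertex(graph.vertex_key(extra))
        for neighbor_region in (i - 1, i + 1):
            if 0 <= neighbor_region < len(table):
                for p in table[neighbor_region][1]:
                    graph._edge(graph.vertex_key(p),
                                graph.vertex_key(extra)).support = 10**6
        table[i] = (iv, cands + [extra])
        _c2, w2, _g2 = min_weight_path(table, graph)
        assert w2 <= w1 + 1e-9


def test_dp_visits_every_region_despite_cheaper_global_shortcut():
    """A graph-global shortest path from the first to the last vertex that
    skips the middle region must not be taken: one candidate per region."""
    graph = ContigGraph(ORDINARY, 10.0)
    a = _pair("r", 0, 100, "cA", 0, 100, aln_id=0)
    m1 = _pair("r", 100, 200, "cM", 0, 100, ident=0.9, aln_id=0)
    m2 = _pair("r", 100, 200, "cN", 0, 100, ident=0.8, aln_id=1)
    b = _pair("r", 200, 300, "cB", 0, 100, aln_id=0)
    for p in (a, m1, m2, b):
        graph.add_vertex(graph.vertex_key(p))
    # direct A-B edge is free, but it would skip the middle region
    graph._edge(graph.vertex_key(a), graph.vertex_key(b)).adjacency = True
    graph._edge(graph.vertex_key(a), graph.vertex_key(m1)).support = 5  # w=5
    graph._edge(graph.vertex_key(m1), graph.vertex_key(b)).support = 5
    graph._edge(graph.vertex_key(a), graph.vertex_key(m2)).support = 2  # w=8
    graph._edge(graph.vertex_key(m2), graph.vertex_key(b)).support = 2
    table = [((0, 100), [a]), ((100, 200), [m1, m2]), ((200, 300), [b])]
    chosen, weight, _g = min_weight_path(table, graph)
    assert len(chosen) == 3
    assert chosen[1] is m1
    assert weight == pytest.approx(10.0)


def test_dead_end_reseeds_with_gap_transition():
    graph = ContigGraph(ORDINARY, 10.0)
    a = _pair("r", 0, 100, "cA", 0, 100)
    b = _pair("r", 100, 200, "cB", 0, 100)
    for p in (a, b):
        graph.add_vertex(graph.vertex_key(p))
    table = [((0, 100), [a]), ((100, 200), [b])]  # no edge at all
    chosen, weight, gaps = min_weight_path(table, graph)
    assert [p.contig_id for p in chosen] == ["cA", "cB"]
    assert gaps == [False, True]
    assert weight == pytest.approx(10.0)  # one gap penalty of C0


# ---------------------------------------------------------------------------
# sequence emission

def test_full_cover_forward_replaced_by_contig_sequence():
    contigs = SequenceStore({"c1": "ACGTACGTAC"})
    p = _pair("r", 0, 10, "c1", 0, 10)
    table = [((0, 10), [p])]
    res = correct_read("ACGAACGTAC", table, [p], contigs, read_id="r")
    assert res.sequence == "ACGTACGTAC"
    assert res.labels == "C" * 10


def test_reverse_candidate_substitutes_revcomp():
    contigs = SequenceStore({"c1": "ACGTACGTAC"})
    p = _pair("r", 0, 10, "c1", 0, 10, orientation=REVERSE)
    table = [((0, 10), [p])]
    res = correct_read("TTTTTTTTTT", table, [p], contigs, read_id="r")
    assert res.sequence == revcomp("ACGTACGTAC")


def test_unaligned_gap_copied_verbatim():
    contigs = SequenceStore({"c1": "A" * 100, "c2": "G" * 100})
    p1 = _pair("r", 0, 100, "c1", 0, 100, aln_id=0)
    p2 = _pair("r", 150, 250, "c2", 0, 100, aln_id=1)
    table = [((0, 100), [p1]), ((150, 250), [p2])]
    read = "C" * 100 + "T" * 50 + "C" * 100
    res = correct_read(read, table, [p1, p2], contigs, read_id="r")
    assert res.sequence == "A" * 100 + "T" * 50 + "G" * 100
    assert res.labels == "C" * 100 + "U" * 50 + "C" * 100


def test_missing_contig_raises():
    contigs = SequenceStore({"other": "ACGT"})
    p = _pair("r", 0, 4, "c1", 0, 4)
    with pytest.raises(KeyError, match="c1"):
        correct_read("ACGT", [((0, 4), [p])], [p], contigs)


# ---------------------------------------------------------------------------
# repeat flagging

def _result_for(pairs, graph, read, contigs):
    table = [((p.read_start, p.read_end), [p]) for p in pairs]
    res = correct_read(read, table, pairs, contigs, read_id="r")
    return flag_repeat_corrected(res, graph)


def test_adjacent_same_contig_steps_not_flagged():
    contigs = SequenceStore({"c1": "A" * 200})
    pairs = [_pair("r", 0, 100, "c1", 0, 100, aln_id=0),
             _pair("r", 100, 200, "c1", 100, 200, aln_id=0)]
    graph = build_graph(pairs, mode=ORDINARY, c0=2.0)
    res = _result_for(pairs, graph, "G" * 200, contigs)
    assert res.n_repeat_flagged == 0
    assert "R" not in res.labels


def test_cross_contig_support_steps_both_flagged():
    contigs = SequenceStore({"c1": "A" * 100, "c3": "G" * 100})
    pairs = [_pair("r", 0, 100, "c1", 0, 100, aln_id=0),
             _pair("r", 100, 200, "c3", 0, 100, aln_id=1)]
    graph = build_graph(pairs, mode=ORDINARY, c0=2.0)
    res = _result_for(pairs, graph, "T" * 200, contigs)
    assert res.n_repeat_flagged == 2
    assert res.labels == "R" * 200


def test_steps_separated_by_read_gap_not_flagged():
    contigs = SequenceStore({"c1": "A" * 100, "c3": "G" * 100})
    pairs = [_pair("r", 0, 100, "c1", 0, 100, aln_id=0),
             _pair("r", 500, 600, "c3", 0, 100, aln_id=1)]
    graph = build_graph(pairs, mode=ORDINARY, c0=2.0)
    res = _result_for(pairs, graph, "T" * 600, contigs)
    assert res.n_repeat_flagged == 0


# ---------------------------------------------------------------------------
# end-to-end properties on simulated data

def test_every_aligned_read_gets_a_finite_path(small_sim):
    from lrcorrect.regions import unify_regions
    from lrcorrect.graph import estimate_coverage
    _rs, pairs = unify_regions(small_sim.alignments)
    graph = build_graph(pairs, mode=ACCURATE)
    tables = group_read_regions(pairs)
    results = correct_all(small_sim.long_reads, small_sim.contigs, pairs, graph)
    by_id = {r.read_id: r for r in results}
    for read_id, ladder in tables.items():
        res = by_id[read_id]
        assert len(res.steps) == len(ladder)
        assert res.total_weight < float("inf")
        # labels cover the corrected sequence exactly
        assert len(res.labels) == len(res.sequence)
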