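"""Shared test helpers: random fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np

from lrcorrect import cigar as cg
from lrcorrect.alignments import FORWARD, REVERSE, RawAlignment
from lrcorrect.graph import ACCURATE, ContigGraph
from lrcorrect.regions import AlignedPair

BASES = "ACGT"


# ---------------------------------------------------------------------------
# random edit scripts / alignments

def random_ops(rng: np.random.Generator, target_len: int,
               indels: bool = True) -> cg.Ops:
    """Random edit script consuming exactly ``target_len`` target bases."""
    ops: cg.Ops = []
    t = 0
    while t < target_len:
        r = rng.random()
        if not indels or r < 0.75:
            n = min(int(rng.integers(1, 30)), target_len - t)
            ops.append((n, "=" if rng.random() < 0.9 else "X"))
            t += n
        elif r < 0.88:
            ops.append((int(rng.integers(1, 6)), "I"))
        else:
            n = min(int(rng.integers(1, 6)), target_len - t)
            ops.append((n, "D"))
            t += n
    if indels and rng.random() < 0.2:
        ops.append((int(rng.integers(1, 4)), "I"))
    return cg.merge_runs(ops)


def random_alignment_set(rng: np.random.Generator, n_alns: int = 8,
                         n_contigs: int = 2, n_reads: int = 4,
                         contig_len: int = 2000, read_len: int = 1500,
                         indels: bool = True) -> list[RawAlignment]:
    """Random mutually-overlapping alignments on a small coordinate space."""
    out = []
    for _ in range(n_alns):
        cid = f"c{rng.integers(0, n_contigs)}"
        rid = f"r{rng.integers(0, n_reads)}"
        t_span = int(rng.integers(100, 700))
        cs = int(rng.integers(0, contig_len - t_span))
        ops = random_ops(rng, t_span, indels)
        q_span = cg.query_span(ops)
        if q_span < 1 or q_span > read_len:
            continue
        rs = int(rng.integers(0, read_len - q_span + 1))
        orientation = FORWARD if rng.random() < 0.5 else REVERSE
        out.append(RawAlignment(
            read_id=rid, read_len=read_len, read_start=rs, read_end=rs + q_span,
            contig_id=cid, contig_len=contig_len, contig_start=cs,
            contig_end=cs + t_span, orientation=orientation,
            identity=cg.identity(ops), ops=ops))
    return out


def pairs_to_raw(pairs: list[AlignedPair],
                 read_lens: dict[str, int],
                 contig_lens: dict[str, int]) -> list[RawAlignment]:
    """Re-express split pairs as alignments (for idempotence checks)."""
    return [RawAlignment(
        read_id=p.read_id, read_len=read_lens[p.read_id],
        read_start=p.read_start, read_end=p.read_end,
        contig_id=p.contig_id, contig_len=contig_lens[p.contig_id],
        contig_start=p.contig_start, contig_end=p.contig_end,
        orientation=p.orientation, identity=p.identity, ops=p.ops)
        for p in pairs]


# ---------------------------------------------------------------------------
# DP instances and brute-force path oracle

def random_dp_instance(rng: np.random.Generator, max_regions: int = 6,
                       max_cands: int = 4, tie_heavy: bool = False):
    """Random candidate table + graph with a guaranteed full path.

    Weights are arbitrary non-negative integers realized through edge
    support counts; candidate 0 of consecutive regions is always connected
    so at least one full path exists (mirroring the read's own chain).
    """
    n = int(rng.integers(1, max_regions + 1))
    c0 = 50.0
    graph = ContigGraph(ACCURATE, c0)
    table = []
    pos = 0
    for i in range(n):
        m = int(rng.integers(1, max_cands + 1))
        cands = []
        for j in range(m):
            span = 10
            cs = 1000 * i + 20 * j
            ident = (round(float(rng.choice([0.8, 0.9])), 3) if tie_heavy
                     else round(float(rng.uniform(0.7, 1.0)), 6))
            p = AlignedPair(
                read_id="r", contig_id=f"c{j}", read_start=pos,
                read_end=pos + span, contig_start=cs, contig_end=cs + span,
                orientation=FORWARD, identity=ident, ops=[(span, "=")],
                aln_id=j)
            cands.append(p)
            graph.add_vertex(graph.vertex_key(p))
        table.append(((pos, pos + span), cands))
        pos += span
    weight_pool = [0, 1, 2] if tie_heavy else list(range(0, 12))
    for i in range(n - 1):
        for j, pj in enumerate(table[i][1]):
            for k, pk in enumerate(table[i + 1][1]):
                if j == 0 and k == 0:
                    connect = True
                else:
                    connect = rng.random() < 0.6
                if not connect:
                    continue
                w = float(rng.choice(weight_pool))
                u, v = graph.vertex_key(pj), graph.vertex_key(pk)
                graph._edge(u, v).support = int(c0 - w)
    return table, graph


def brute_force_paths(table, graph):
    """Exhaustive enumeration of all full candidate paths with finite weight.

    Yields (weight, identity_sum, choice_indices).
    """
    n = len(table)

    def rec(i, prev, w, ids, choice):
        if i == n:
            yield (w, ids, tuple(choice))
            return
        for j, p in enumerate(table[i][1]):
            v = graph.vertex_key(p)
            if i > 0:
                u = graph.vertex_key(prev)
                if u == v or not graph.has_edge(u, v):
                    continue
                step = graph.weight(u, v)
            else:
                step = 0.0
            choice.append(j)
            yield from rec(i + 1, p, w + step, ids + p.identity, choice)
            choice.pop()

    return list(rec(0, None, 0.0, 0.0, []))


def brute_force_best(table, graph):
    """(min weight, max identity sum among weight-minimal paths) or None."""
    paths = brute_force_paths(table, graph)
    if not paths:
        return None
    wmin = min(p[0] for p in paths)
    best_ids = max(p[1] for p in paths if abs(p[0] - wmin) < 1e-9)
    return wmin, best_ids
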