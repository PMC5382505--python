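"""Per-read correction: minimum-weight path DP over candidate contig regions.

For one read with split regions ``i = 1..n``, each with candidate aligned
contig regions ``j = 1..m_i``, the DP

    T(1, j)   = 0
    T(i+1, k) = min_j { T(i, j) + W_jk }     (edge (v_ij, v_{i+1,k}) exists)

finds the path of minimum total edge weight that visits exactly one
candidate per region.  A global shortest-path search is *not* applicable:
the path is constrained to the read's own region ladder, so a graph-global
shortest route that skipped a region would not describe the read.  Ties on
total weight are broken by the largest sum of candidate alignment
identities, then lexicographically for determinism.

The winning candidates then replace the read regions base-for-base
(reverse-complemented for reverse hits); unaligned head/tail/gap segments
are copied through unchanged.  Consecutive path steps whose contig regions
are distant (different contigs, or same contig, separated, with no
adjacency edge) were likely corrected with a similar repeat and are flagged
``repeat_corrected`` for the refinement stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .graph import ContigGraph, VKey
from .regions import DEFAULT_DELTA, AlignedPair, group_read_regions
from .seqio import SequenceStore, revcomp

# per-base provenance labels
LBL_CORRECTED = "C"
LBL_UNCORRECTED = "U"
LBL_REPEAT = "R"

#: ladder region with its candidate alignments
CandidateTable = list[tuple[tuple[int, int], list[AlignedPair]]]


@dataclass
class PathStep:
    region: tuple[int, int]          # read interval (forward strand)
    pair: AlignedPair                # winning candidate
    out_start: int = -1              # interval in the corrected sequence
    out_end: int = -1
    gap_transition: bool = False     # reached through a DP re-seed
    repeat_flagged: bool = False


@dataclass
class CorrectionResult:
    read_id: str
    steps: list[PathStep]
    sequence: str
    labels: str
    total_weight: float = 0.0

    def __post_init__(self):
        if len(self.sequence) != len(self.labels):
            raise ValueError("labels must cover the corrected sequence exactly")

    @property
    def n_repeat_flagged(self) -> int:
        return sum(s.repeat_flagged for s in self.steps)

    def base_counts(self) -> dict[str, int]:
        return {lbl: self.labels.count(lbl)
                for lbl in (LBL_CORRECTED, LBL_UNCORRECTED, LBL_REPEAT)}


# ---------------------------------------------------------------------------
# DP

def min_weight_path(table: CandidateTable, graph: ContigGraph,
                    ) -> tuple[list[AlignedPair], float, list[bool]]:
    """Minimum-total-weight choice of one candidate per read region.

    Returns (chosen pairs, total weight, per-step gap-transition flags).
    When no graph edge joins any candidate of two consecutive regions the DP
    re-seeds with a gap transition of penalty C0, so a full path always
    exists.
    """
    if not table:
        return [], 0.0, []
    n = len(table)
    INF = math.inf
    # state: (weight, -identity_sum); parent index; gap flag
    costs: list[list[tuple[float, float]]] = []
    parents: list[list[int]] = []
    gaps: list[list[bool]] = []

    first = table[0][1]
    costs.append([(0.0, -p.identity) for p in first])
    parents.append([-1] * len(first))
    gaps.append([False] * len(first))

    for i in range(1, n):
        prev_cands = table[i - 1][1]
        cands = table[i][1]
        row_cost: list[tuple[float, float]] = []
        row_par: list[int] = []
        for k, pk in enumerate(cands):
            vk = graph.vertex_key(pk)
            best = (INF, INF)
            best_j = -1
            for j, pj in enumerate(prev_cands):
                if costs[i - 1][j][0] == INF:
                    continue
                vj = graph.vertex_key(pj)
                if vj == vk or not graph.has_edge(vj, vk):
                    continue
                w = 0.0 if vj == vk else graph.weight(vj, vk)
                cand = (costs[i - 1][j][0] + w,
                        costs[i - 1][j][1] - pk.identity)
                if cand < best:
                    best, best_j = cand, j
            row_cost.append(best)
            row_par.append(best_j)
        if all(c[0] == INF for c in row_cost):
            # DP dead end: re-seed from the best previous state
            best_j = min(range(len(prev_cands)), key=lambda j: costs[i - 1][j])
            base = costs[i - 1][best_j]
            row_cost = [(base[0] + graph.c0, base[1] - p.identity) for p in cands]
            row_par = [best_j] * len(cands)
            row_gap = [True] * len(cands)
        else:
            row_gap = [False] * len(cands)
        costs.append(row_cost)
        parents.append(row_par)
        gaps.append(row_gap)

    last = min(range(len(table[-1][1])), key=lambda k: costs[-1][k])
    total = costs[-1][last][0]
    chosen: list[AlignedPair] = []
    gap_flags: list[bool] = []
    k = last
    for i in range(n - 1, -1, -1):
        chosen.append(table[i][1][k])
        gap_flags.append(gaps[i][k])
        k = parents[i][k]
    chosen.reverse()
    gap_flags.reverse()
    return chosen, total, gap_flags


# ---------------------------------------------------------------------------
# sequence emission

def correct_read(read_seq: str, table: CandidateTable,
                 chosen: list[AlignedPair], contigs: SequenceStore,
                 total_weight: float = 0.0,
                 gap_flags: list[bool] | None = None,
                 read_id: str = "") -> CorrectionResult:
    """Replace each read region with its winning contig region sequence.

    Unaligned head/tail segments and gaps between regions are copied
    verbatim and labeled uncorrected.
    """
    gap_flags = gap_flags or [False] * len(chosen)
    parts: list[str] = []
    labels: list[str] = []
    steps: list[PathStep] = []
    pos = 0
    out = 0
    for ((rs, re_), _cands), pair, gap in zip(table, chosen, gap_flags):
        rs = max(rs, pos)  # ladder may overlap by <= delta
        re_ = max(re_, rs)
        if rs > pos:
            seg = read_seq[pos:rs]
            parts.append(seg)
            labels.append(LBL_UNCORRECTED * len(seg))
            out += len(seg)
        if pair.contig_id not in contigs:
            raise KeyError(f"contig {pair.contig_id!r} missing from store")
        repl = contigs.seq(pair.contig_id)[pair.contig_start:pair.contig_end]
        if pair.orientation == "reverse":
            repl = revcomp(repl)
        parts.append(repl)
        labels.append(LBL_CORRECTED * len(repl))
        steps.append(PathStep(region=(rs, re_), pair=pair,
                              out_start=out, out_end=out + len(repl),
                              gap_transition=gap))
        out += len(repl)
        pos = re_
    if pos < len(read_seq):
        seg = read_seq[pos:]
        parts.append(seg)
        labels.append(LBL_UNCORRECTED * len(seg))
    return CorrectionResult(read_id=read_id, steps=steps,
                            sequence="".join(parts), labels="".join(labels),
                            total_weight=total_weight)


# ---------------------------------------------------------------------------
# similar-repeat flagging

def flag_repeat_corrected(result: CorrectionResult, graph: ContigGraph,
                          distant_span: int = 0,
                          delta: int = DEFAULT_DELTA) -> CorrectionResult:
    """Label regions corrected with *distant* contig regions as
    repeat-corrected.

    Two consecutive path steps are distant when their contig regions lie on
    different contigs, or on the same contig separated by more than
    ``distant_span`` bases with no adjacency edge between the chosen
    vertices.  Both steps of a distant pair are flagged; steps separated by
    an unaligned read gap larger than ``delta`` are not adjacent and do not
    trigger the rule.
    """
    labels = list(result.labels)
    for a, b in zip(result.steps, result.steps[1:]):
        read_gap = b.region[0] - a.region[1]
        if read_gap > delta:
            continue
        if not _distant(a.pair, b.pair, graph, distant_span):
            continue
        for step in (a, b):
            step.repeat_flagged = True
            for i in range(step.out_start, step.out_end):
                labels[i] = LBL_REPEAT
    result.labels = "".join(labels)
    return result


def _distant(p1: AlignedPair, p2: AlignedPair, graph: ContigGraph,
             distant_span: int) -> bool:
    if p1.contig_id != p2.contig_id:
        return True
    gap = max(p1.contig_start, p2.contig_start) - \
        min(p1.contig_end, p2.contig_end)
    if gap <= distant_span:
        return False
    u, v = graph.vertex_key(p1), graph.vertex_key(p2)
    data = graph.edge_data(u, v)
    return not (data is not None and data.adjacency)


# ---------------------------------------------------------------------------
# driver

def correct_all(reads: SequenceStore, contigs: SequenceStore,
                pairs: list[AlignedPair], graph: ContigGraph,
                delta: int = DEFAULT_DELTA,
                distant_span: int = 0) -> list[CorrectionResult]:
    """Correct every read in the store (store order).

    Reads with no alignments pass through uncorrected.
    """
    tables = group_read_regions(pairs, delta)
    results: list[CorrectionResult] = []
    for read_id, seq in reads.items():
        table = tables.get(read_id, [])
        if not table:
            results.append(CorrectionResult(
                read_id=read_id, steps=[], sequence=seq,
                labels=LBL_UNCORRECTED * len(seq)))
            continue
        chosen, weight, gap_flags = min_weight_path(table, graph)
        res = correct_read(seq, table, chosen, contigs, weight,
                           gap_flags, read_id)
        flag_repeat_corrected(res, graph, distant_span, delta)
        results.append(res)
    return results
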