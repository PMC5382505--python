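"""The weighted contig graph.

Vertices are the unified aligned contig regions (two per region in accurate
mode, one per orientation).  Edges come from two sources:

* **adjacency**: two regions abutting in the same initial contig are joined
  with weight 0 (per orientation in accurate mode);
* **long-read support**: every pair of adjacent regions of one read whose
  candidates are mutually compatible contributes one support count ``C`` to
  the edge between their contig-region vertices; such edges get weight
  ``max(C0 - C, 0)`` where ``C0`` is the expected long-read coverage on the
  contigs.

A candidate pair is *compatible* — and counts toward ``C`` — when the two
candidates come from the same original alignment, or from two alignments
that do not overlap on the read by more than the boundary tolerance.
Alternative (overlapping) alignments of the same read territory are rival
interpretations, not a chain, and contribute no adjacency evidence; this is
what lets genuine long-read support separate a true region from its similar
repeat, whose hit covers the same read bases as the true one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .alignments import FORWARD, REVERSE
from .regions import DEFAULT_DELTA, AlignedPair, group_read_regions

ORDINARY = "ordinary"
ACCURATE = "accurate"

#: vertex key: (contig_id, start, end, orientation)
VKey = tuple[str, int, int, str]


class GraphIntegrityError(RuntimeError):
    """The pair list violates the splitting contract (overlapping regions)."""


@dataclass
class EdgeData:
    support: int = 0
    adjacency: bool = False


class ContigGraph:
    def __init__(self, mode: str, c0: float, delta: int = DEFAULT_DELTA):
        if mode not in (ORDINARY, ACCURATE):
            raise ValueError(f"unknown graph mode {mode!r}")
        self.mode = mode
        self.c0 = float(c0)
        self.delta = delta
        self.vertices: set[VKey] = set()
        self._edges: dict[tuple[VKey, VKey], EdgeData] = {}

    # -- vertex helpers ----------------------------------------------------
    def vertex_key(self, pair: AlignedPair) -> VKey:
        orient = pair.orientation if self.mode == ACCURATE else FORWARD
        return (pair.contig_id, pair.contig_start, pair.contig_end, orient)

    def add_vertex(self, key: VKey) -> None:
        self.vertices.add(key)

    # -- edge helpers ------------------------------------------------------
    @staticmethod
    def _ekey(u: VKey, v: VKey) -> tuple[VKey, VKey]:
        return (u, v) if u <= v else (v, u)

    def _edge(self, u: VKey, v: VKey) -> EdgeData:
        return self._edges.setdefault(self._ekey(u, v), EdgeData())

    def has_edge(self, u: VKey, v: VKey) -> bool:
        return self._ekey(u, v) in self._edges

    def edge_data(self, u: VKey, v: VKey) -> EdgeData | None:
        return self._edges.get(self._ekey(u, v))

    def weight(self, u: VKey, v: VKey) -> float:
        """Edge weight: 0 for contig-adjacent regions, else max(C0 - C, 0)."""
        data = self._edges[self._ekey(u, v)]
        if data.adjacency:
            return 0.0
        return max(self.c0 - data.support, 0.0)

    def edges(self):
        for (u, v), data in sorted(self._edges.items()):
            yield u, v, data

    def n_edges(self) -> int:
        return len(self._edges)

    # -- debug dump --------------------------------------------------------
    def write_edge_list(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("u\tv\tsupport\tadjacency\tweight\n")
            for u, v, data in self.edges():
                fh.write(f"{_vstr(u)}\t{_vstr(v)}\t{data.support}\t"
                         f"{int(data.adjacency)}\t{self.weight(u, v):g}\n")

    # -- collapse (accurate -> ordinary view) -------------------------------
    def collapse(self) -> "ContigGraph":
        """Ordinary-mode view: merge orientation vertices, sum supports."""
        g = ContigGraph(ORDINARY, self.c0, self.delta)
        for (c, s, e, _o) in self.vertices:
            g.add_vertex((c, s, e, FORWARD))
        for u, v, data in self.edges():
            cu = (u[0], u[1], u[2], FORWARD)
            cv = (v[0], v[1], v[2], FORWARD)
            if cu == cv:
                continue
            d = g._edge(cu, cv)
            d.support += data.support
            d.adjacency = d.adjacency or data.adjacency
        return g


def _vstr(v: VKey) -> str:
    return f"{v[0]}:{v[1]}-{v[2]}({'+' if v[3] == FORWARD else '-'})"


# ---------------------------------------------------------------------------
# coverage estimation

def estimate_coverage(pairs: list[AlignedPair],
                      contig_lengths: dict[str, int] | None = None) -> float:
    """Expected long-read coverage C0 on the aligned part of the contigs.

    Mean per-base depth over covered contig bases: total aligned contig-region
    span divided by the size of the union of aligned contig intervals.
    ``contig_lengths`` is accepted for interface symmetry but not needed.
    """
    if not pairs:
        raise ValueError(
            "cannot estimate long-read coverage without alignments; "
            "supply the expected coverage manually (-coverage)")
    total = 0
    per_contig: dict[str, list[tuple[int, int]]] = {}
    for p in pairs:
        total += p.contig_end - p.contig_start
        per_contig.setdefault(p.contig_id, []).append((p.contig_start, p.contig_end))
    union = 0
    for ivs in per_contig.values():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s > cur_e:
                union += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        union += cur_e - cur_s
    return total / union


# ---------------------------------------------------------------------------
# graph construction

def build_graph(pairs: list[AlignedPair], mode: str = ACCURATE,
                c0: float | None = None, delta: int = DEFAULT_DELTA) -> ContigGraph:
    """Build the weighted contig graph from unified aligned pairs."""
    if c0 is None:
        c0 = estimate_coverage(pairs)
    graph = ContigGraph(mode, c0, delta)

    regions = _unique_regions_checked(pairs)
    orientations = (FORWARD, REVERSE) if mode == ACCURATE else (FORWARD,)
    for (contig_id, start, end) in regions:
        for o in orientations:
            graph.add_vertex((contig_id, start, end, o))

    # adjacency edges: abutting split regions of one contig, same orientation
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for (contig_id, start, end) in regions:
        by_contig.setdefault(contig_id, []).append((start, end))
    for contig_id, ivs in by_contig.items():
        ivs.sort()
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if e1 == s2:
                for o in orientations:
                    graph._edge((contig_id, s1, e1, o),
                                (contig_id, s2, e2, o)).adjacency = True

    # support edges from adjacent read regions
    grouped = group_read_regions(pairs, delta)
    aln_spans = _alignment_spans(pairs)
    for read_id in sorted(grouped):
        ladder = grouped[read_id]
        seen: set[tuple[VKey, VKey]] = set()
        for (_iv1, cands1), (_iv2, cands2) in zip(ladder, ladder[1:]):
            for p1 in cands1:
                for p2 in cands2:
                    if not _compatible(p1, p2, aln_spans, delta):
                        continue
                    u, v = graph.vertex_key(p1), graph.vertex_key(p2)
                    if u == v:
                        continue
                    ekey = graph._ekey(u, v)
                    if ekey in seen:
                        continue  # one read contributes at most 1 per edge
                    seen.add(ekey)
                    graph._edge(u, v).support += 1
    return graph


def _unique_regions_checked(pairs: list[AlignedPair]) -> list[tuple[str, int, int]]:
    regions = sorted({(p.contig_id, p.contig_start, p.contig_end) for p in pairs})
    prev = None
    for contig_id, start, end in regions:
        if prev is not None and prev[0] == contig_id and start < prev[2] \
                and (start, end) != (prev[1], prev[2]):
            raise GraphIntegrityError(
                f"overlapping non-identical contig regions "
                f"{contig_id}:{prev[1]}-{prev[2]} and {contig_id}:{start}-{end}; "
                f"pairs must come from region splitting")
        prev = (contig_id, start, end)
    return regions


def _alignment_spans(pairs: list[AlignedPair]) -> dict[tuple[str, int], tuple[int, int]]:
    spans: dict[tuple[str, int], tuple[int, int]] = {}
    for p in pairs:
        key = (p.read_id, p.aln_id)
        s, e = spans.get(key, (p.read_start, p.read_end))
        spans[key] = (min(s, p.read_start), max(e, p.read_end))
    return spans


def _compatible(p1: AlignedPair, p2: AlignedPair,
                aln_spans: dict, delta: int) -> bool:
    if p1.aln_id == p2.aln_id:
        return True
    s1, e1 = aln_spans[(p1.read_id, p1.aln_id)]
    s2, e2 = aln_spans[(p2.read_id, p2.aln_id)]
    return min(e1, e2) - max(s1, s2) <= delta
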