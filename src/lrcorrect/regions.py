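"""Splitting of aligned contig regions and long-read regions.

Every alignment couples an interval of a read to an interval of a contig.
Before graph construction all reads must align to one *unified* set of
contig regions: wherever two aligned contig intervals partially overlap (or
one contains the other) both are split at each other's boundaries, and the
read intervals are split correspondingly by projecting the cut positions
through the alignments' edit scripts.  Boundaries closer than a tolerance
``delta`` (default 4 bp) are considered the same position and merged by
single-linkage clustering; the smallest position of a cluster is its
canonical representative.

Cut positions propagate: a cut on a contig induces a cut on every read
aligned across it, which in turn induces cuts on *other* contigs those reads
align to (e.g. a similar-repeat copy).  :func:`unify_regions` therefore
iterates boundary collection and projection to a fixpoint before slicing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import cigar as cg
from .alignments import FORWARD, REVERSE, RawAlignment

CONTIG = "contig"
LONG_READ = "long_read"

DEFAULT_DELTA = 4


@dataclass(frozen=True, order=True)
class Region:
    seq_id: str
    start: int
    end: int
    kind: str = CONTIG

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty region {self.seq_id}:{self.start}-{self.end}")

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class AlignedPair:
    """One (split) long-read region aligned to one unified contig region."""

    read_id: str
    contig_id: str
    read_start: int
    read_end: int
    contig_start: int
    contig_end: int
    orientation: str
    identity: float
    ops: cg.Ops = field(repr=False)
    aln_id: int = -1  # index of the originating RawAlignment

    @property
    def read_region(self) -> Region:
        return Region(self.read_id, self.read_start, self.read_end, LONG_READ)

    @property
    def contig_region(self) -> Region:
        return Region(self.contig_id, self.contig_start, self.contig_end, CONTIG)

    @property
    def read_span(self) -> int:
        return self.read_end - self.read_start


class RegionSet:
    """Per-sequence sorted, non-overlapping regions with tolerance delta."""

    def __init__(self, delta: int = DEFAULT_DELTA):
        self.delta = delta
        self._regions: dict[str, list[Region]] = {}

    def add(self, region: Region) -> None:
        self._regions.setdefault(region.seq_id, []).append(region)

    def finalize(self) -> "RegionSet":
        for seq_id, regs in self._regions.items():
            self._regions[seq_id] = sorted(set(regs), key=lambda r: (r.start, r.end))
        return self

    def regions(self, seq_id: str) -> list[Region]:
        return self._regions.get(seq_id, [])

    def sequences(self) -> list[str]:
        return sorted(self._regions)

    def all_regions(self) -> list[Region]:
        return [r for s in self.sequences() for r in self.regions(s)]

    def __len__(self) -> int:
        return sum(len(v) for v in self._regions.values())


# ---------------------------------------------------------------------------
# boundary clustering

def cluster_positions(positions, delta: int) -> dict[int, int]:
    """Single-linkage clustering of positions under ``|a-b| < delta``.

    Returns a mapping position → canonical representative (the smallest
    member of its cluster).  With ``delta=0`` every position maps to itself.
    """
    out: dict[int, int] = {}
    rep = None
    prev = None
    for p in sorted(set(positions)):
        if rep is None or p - prev >= delta:
            rep = p
        out[p] = rep
        prev = p
    return out


def collect_boundaries(alignments: list[RawAlignment], delta: int) -> dict[str, list[int]]:
    """Canonical boundary positions per contig from alignment endpoints."""
    if delta < 0:
        raise ValueError("delta must be >= 0")
    per_contig: dict[str, set[int]] = {}
    for a in alignments:
        s = per_contig.setdefault(a.contig_id, set())
        s.add(a.contig_start)
        s.add(a.contig_end)
    return {c: sorted(set(cluster_positions(p, delta).values()))
            for c, p in per_contig.items()}


# ---------------------------------------------------------------------------
# coordinate projection helpers

def _fwd_to_oriented(a: RawAlignment, pos: int) -> int:
    """Forward-read position → query offset in the alignment's script."""
    if a.orientation == FORWARD:
        return pos - a.read_start
    return a.read_end - pos


def _oriented_to_fwd(a: RawAlignment, q: int) -> int:
    if a.orientation == FORWARD:
        return a.read_start + q
    return a.read_end - q


def project_contig_cuts_to_read(a: RawAlignment, cuts: list[int]) -> list[int]:
    """Map contig positions (inside the aligned interval) to forward-read
    positions through the edit script."""
    rel = [c - a.contig_start for c in sorted(cuts)]
    qs = cg.project_target_to_query(a.ops, rel)
    return [_oriented_to_fwd(a, q) for q in qs]


def project_read_cuts_to_contig(a: RawAlignment, cuts: list[int]) -> list[int]:
    """Map forward-read positions (inside the aligned interval) to contig
    positions through the edit script."""
    rel = sorted(_fwd_to_oriented(a, p) for p in cuts)
    ts = cg.project_query_to_target(a.ops, rel)
    return [a.contig_start + t for t in ts]


# ---------------------------------------------------------------------------
# unification driver

class _Boundaries:
    """Mutable per-sequence boundary position sets with δ-canonicalization."""

    def __init__(self, delta: int):
        self.delta = delta
        self.positions: dict[str, set[int]] = {}
        self._snap: dict[str, dict[int, int]] = {}

    def add(self, seq_id: str, pos: int) -> None:
        self.positions.setdefault(seq_id, set()).add(pos)

    def canonicalize(self) -> dict[str, tuple[int, ...]]:
        self._snap = {s: cluster_positions(p, self.delta)
                      for s, p in self.positions.items()}
        return {s: tuple(sorted(set(m.values()))) for s, m in self._snap.items()}

    def snap(self, seq_id: str, pos: int) -> int:
        return self._snap.get(seq_id, {}).get(pos, pos)

    def reps_inside(self, seq_id: str, lo: int, hi: int) -> list[int]:
        """Canonical representatives strictly between snap(lo) and snap(hi)."""
        lo_r, hi_r = self.snap(seq_id, lo), self.snap(seq_id, hi)
        snap = self._snap.get(seq_id, {})
        reps = sorted(set(snap.values()))
        return [r for r in reps if lo_r < r < hi_r]


# With delta=0 and overlapping opposite-orientation alignments of one read,
# indel-shifted cut positions can cascade one base per round before the
# boundary set saturates; the cap is generous for that worst case (typical
# delta=4 data converges in < 10 rounds).
_MAX_ROUNDS = 2000
_OUTER_ROUNDS = 50


def unify_regions(alignments: list[RawAlignment], delta: int = DEFAULT_DELTA,
                  ) -> tuple[RegionSet, list[AlignedPair]]:
    """Split all alignments against each other into a unified region set.

    Returns the contig :class:`RegionSet` and the list of
    :class:`AlignedPair` (one read region ↔ one contig region each).
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")

    def seed(points: list[tuple[str, int, str, int]]) -> tuple[_Boundaries, _Boundaries]:
        contig_b = _Boundaries(delta)
        read_b = _Boundaries(delta)
        for cid, cpos, rid, rpos in points:
            contig_b.add(cid, cpos)
            read_b.add(rid, rpos)
        return contig_b, read_b

    def converge(contig_b: _Boundaries, read_b: _Boundaries, chunks) -> None:
        prev = None
        for _ in range(_MAX_ROUNDS):
            state = (contig_b.canonicalize(), read_b.canonicalize())
            if state == prev:
                return
            prev = state
            for a in chunks:
                c_cuts = contig_b.reps_inside(a.contig_id, a.contig_start,
                                              a.contig_end)
                for p in project_contig_cuts_to_read(a, c_cuts):
                    if a.read_start < p < a.read_end:
                        read_b.add(a.read_id, p)
                r_cuts = read_b.reps_inside(a.read_id, a.read_start, a.read_end)
                # reps_inside uses snapped endpoints; keep only cuts inside
                # the raw interval so projection stays within the script
                r_cuts = [p for p in r_cuts if a.read_start < p < a.read_end]
                for p in project_read_cuts_to_contig(a, r_cuts):
                    if a.contig_start < p < a.contig_end:
                        contig_b.add(a.contig_id, p)

    # The boundary sets grow during convergence; δ-clusters over the full
    # grown set can chain further than clusters over the emitted pair
    # endpoints alone, so a single pass is not a fixpoint of its own
    # output.  Apply the splitting repeatedly — re-seeding the boundaries
    # from the current pieces and re-slicing them — until the pieces are
    # stable; the returned pairs are then idempotent under re-splitting.
    chunks: list = list(alignments)
    ids = list(range(len(alignments)))
    pairs: list[AlignedPair] = []
    prev_key = None
    for _outer in range(_OUTER_ROUNDS):
        points = [(a.contig_id, a.contig_start, a.read_id, a.read_start)
                  for a in chunks] + \
                 [(a.contig_id, a.contig_end, a.read_id, a.read_end)
                  for a in chunks]
        contig_b, read_b = seed(points)
        converge(contig_b, read_b, chunks)
        pairs = []
        for a, aln_id in zip(chunks, ids):
            pairs.extend(_slice_alignment(a, aln_id, contig_b))
        key = tuple(sorted((p.read_id, p.read_start, p.read_end, p.contig_id,
                            p.contig_start, p.contig_end) for p in pairs))
        if key == prev_key:
            break
        prev_key = key
        chunks = list(pairs)
        ids = [p.aln_id for p in pairs]
    region_set = RegionSet(delta)
    seen: set[tuple[str, int, int]] = set()
    for p in pairs:
        key = (p.contig_id, p.contig_start, p.contig_end)
        if key not in seen:
            seen.add(key)
            region_set.add(p.contig_region)
    return region_set.finalize(), pairs


def _fit_ops_to_target(ops: cg.Ops, pad_front: int, trim_back: int) -> cg.Ops:
    """Pad the script with ``pad_front`` leading deletions and remove the
    last ``trim_back`` target columns (any insertions beyond the new end
    are dropped with them)."""
    out = list(ops)
    removed = 0
    while out and removed < trim_back:
        n, op = out.pop()
        if op not in cg.OPS_TARGET:
            continue
        excess = n - (trim_back - removed)
        if excess > 0:
            out.append((excess, op))
            removed = trim_back
        else:
            removed += n
    if pad_front:
        out.insert(0, (pad_front, "D"))
    return cg.merge_runs(out)


def _slice_alignment(a: RawAlignment, aln_id: int,
                     contig_b: _Boundaries) -> list[AlignedPair]:
    cuts = contig_b.reps_inside(a.contig_id, a.contig_start, a.contig_end)
    rel = [c - a.contig_start for c in cuts]
    segments = cg.slice_by_target(a.ops, rel)
    out: list[AlignedPair] = []
    for q0, q1, t0, t1, sub in segments:
        if q1 - q0 < 1:
            continue  # sliver: no read bases in this piece
        # snap the piece's contig endpoints to canonical representatives
        # (moves < delta; interior cut points are representatives already)
        # and refit the script so pair coordinates stay exactly consistent
        raw_cs = a.contig_start + t0
        raw_ce = a.contig_start + t1
        cs = contig_b.snap(a.contig_id, raw_cs)
        ce = contig_b.snap(a.contig_id, raw_ce)
        if ce - cs < 1:
            continue
        fitted = _fit_ops_to_target(sub, raw_cs - cs, raw_ce - ce)
        qspan = cg.query_span(fitted)
        if qspan < 1:
            continue
        if a.orientation == FORWARD:
            r0 = a.read_start + q0
            r1 = r0 + qspan
        else:
            r1 = a.read_end - q0
            r0 = r1 - qspan
        out.append(AlignedPair(
            read_id=a.read_id, contig_id=a.contig_id,
            read_start=r0, read_end=r1, contig_start=cs, contig_end=ce,
            orientation=a.orientation, identity=cg.identity(fitted),
            ops=fitted, aln_id=aln_id))
    return out


# ---------------------------------------------------------------------------
# spec-surface wrappers

def split_contig_regions(alignments: list[RawAlignment],
                         delta: int = DEFAULT_DELTA) -> RegionSet:
    """Unified set of split contig regions (rule 1, with containment)."""
    region_set, _ = unify_regions(alignments, delta)
    return region_set


def split_long_read_regions(alignments: list[RawAlignment],
                            delta: int = DEFAULT_DELTA) -> list[AlignedPair]:
    """Split read regions against the unified contig regions (rule 2)."""
    _, pairs = unify_regions(alignments, delta)
    return pairs


# ---------------------------------------------------------------------------
# read-region grouping (candidate sets per region)

def group_read_regions(pairs: list[AlignedPair], delta: int = DEFAULT_DELTA,
                       ) -> dict[str, list[tuple[tuple[int, int], list[AlignedPair]]]]:
    """Group each read's pairs into ordered regions with candidate lists.

    Pairs whose read intervals agree within ``delta`` at both ends are
    alternative candidates for the same region (single-linkage on the
    sorted intervals; the representative interval is the group's first).
    Groups overlapping an already-accepted group by more than ``delta``
    cannot be placed on the non-overlapping region ladder and are dropped
    (defensive; does not occur on split output in practice).
    """
    by_read: dict[str, list[AlignedPair]] = {}
    for p in pairs:
        by_read.setdefault(p.read_id, []).append(p)
    out: dict[str, list[tuple[tuple[int, int], list[AlignedPair]]]] = {}
    for read_id, plist in by_read.items():
        plist.sort(key=lambda p: (p.read_start, p.read_end, p.contig_id,
                                  p.contig_start, p.orientation))
        groups: list[tuple[tuple[int, int], list[AlignedPair]]] = []
        for p in plist:
            if groups:
                (gs, ge), members = groups[-1]
                if abs(p.read_start - gs) < max(delta, 1) \
                        and abs(p.read_end - ge) < max(delta, 1):
                    members.append(p)
                    continue
            groups.append(((p.read_start, p.read_end), [p]))
        ladder: list[tuple[tuple[int, int], list[AlignedPair]]] = []
        prev_end = None
        for iv, members in groups:
            if prev_end is not None and iv[0] < prev_end - delta:
                continue
            cands = sorted(members,
                           key=lambda p: (p.contig_id, p.contig_start,
                                          p.orientation, -p.identity))
            ladder.append((iv, cands))
            prev_end = iv[1]
        out[read_id] = ladder
    return out
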