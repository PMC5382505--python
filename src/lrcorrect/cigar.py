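"""Edit-script (extended-CIGAR) primitives.

An edit script records the base-level correspondence of one alignment as a
run-length list of operations between a *query* (the long-read segment,
oriented to match the target's forward strand) and a *target* (the contig
segment on its forward strand):

    ``=``  match        (advances query and target)
    ``X``  mismatch     (advances query and target)
    ``I``  insertion    (bases present in the query only)
    ``D``  deletion     (bases present in the target only)

Scripts are held as ``[(length, op), ...]`` and serialized as extended CIGAR
strings (``"120=1X3I2D"``).  All functions here are pure coordinate/counting
arithmetic; no alignment is ever computed in this module.
"""

from __future__ import annotations

import re

_CIG_RE = re.compile(r"(\d+)([=XIDM])")

OPS_QUERY = frozenset("=XIM")   # ops that advance the query
OPS_TARGET = frozenset("=XDM")  # ops that advance the target

Ops = list[tuple[int, str]]


def parse_cigar(text: str) -> Ops:
    """Parse an extended CIGAR string into ``[(length, op), ...]``.

    ``M`` (alignment match, base unknown) is accepted on input; callers that
    need =/X resolution must reclassify it against the sequences.
    """
    ops: Ops = []
    pos = 0
    for m in _CIG_RE.finditer(text):
        if m.start() != pos:
            raise ValueError(f"malformed CIGAR near offset {pos}: {text!r}")
        n = int(m.group(1))
        if n <= 0:
            raise ValueError(f"non-positive CIGAR run in {text!r}")
        ops.append((n, m.group(2)))
        pos = m.end()
    if pos != len(text):
        raise ValueError(f"malformed CIGAR near offset {pos}: {text!r}")
    return ops


def cigar_string(ops: Ops) -> str:
    return "".join(f"{n}{op}" for n, op in ops)


def merge_runs(ops: Ops) -> Ops:
    """Coalesce adjacent runs of the same op; drop zero-length runs."""
    out: Ops = []
    for n, op in ops:
        if n == 0:
            continue
        if out and out[-1][1] == op:
            out[-1] = (out[-1][0] + n, op)
        else:
            out.append((n, op))
    return out


def query_span(ops: Ops) -> int:
    return sum(n for n, op in ops if op in OPS_QUERY)


def target_span(ops: Ops) -> int:
    return sum(n for n, op in ops if op in OPS_TARGET)


def identity(ops: Ops) -> float:
    """Blast-style identity: matches / alignment columns.

    ``M`` runs count as matches (callers should reclassify when sequences
    are available).
    """
    cols = sum(n for n, _ in ops)
    if cols == 0:
        return 0.0
    eq = sum(n for n, op in ops if op in "=M")
    return eq / cols


def classify_m(ops: Ops, query: str, target: str) -> Ops:
    """Resolve ``M`` runs into ``=``/``X`` using the two sequences."""
    out: Ops = []
    q = t = 0
    for n, op in ops:
        if op == "M":
            for i in range(n):
                op2 = "=" if query[q + i] == target[t + i] else "X"
                out.append((1, op2))
            q += n
            t += n
        else:
            out.append((n, op))
            if op in OPS_QUERY:
                q += n
            if op in OPS_TARGET:
                t += n
    return merge_runs(out)


def check_consistency(ops: Ops, query_len: int, target_len: int) -> None:
    """Raise ``ValueError`` if the script does not span the two segments."""
    qs, ts = query_span(ops), target_span(ops)
    if qs != query_len or ts != target_len:
        raise ValueError(
            f"edit script spans ({qs}, {ts}) but segments are "
            f"({query_len}, {target_len}) long"
        )


def apply_script(ops: Ops, query: str) -> None:
    """Sanity helper: verify the query length only (target bases unknown)."""
    if query_span(ops) != len(query):
        raise ValueError("edit script inconsistent with query length")


def slice_by_target(ops: Ops, cuts: list[int]) -> list[tuple[int, int, int, int, Ops]]:
    """Split a script at target-relative positions ``cuts``.

    Returns ``[(q0, q1, t0, t1, sub_ops), ...]`` covering the whole script,
    one entry per segment between consecutive cuts.  Cuts must be strictly
    increasing and strictly inside ``(0, target_span)``.  An insertion run
    sitting exactly on a cut is assigned to the *following* segment, so a
    boundary never splits inserted bases between two regions.
    """
    tlen = target_span(ops)
    for a, b in zip(cuts, cuts[1:]):
        if a >= b:
            raise ValueError("cuts must be strictly increasing")
    if cuts and (cuts[0] <= 0 or cuts[-1] >= tlen):
        raise ValueError("cuts must be strictly inside the target span")

    segments: list[tuple[int, int, int, int, Ops]] = []
    cur: Ops = []
    q0 = t0 = 0
    cq = ct = 0
    ci = 0
    for n, op in ops:
        while n > 0:
            if ci < len(cuts) and ct == cuts[ci]:
                segments.append((q0, cq, t0, ct, merge_runs(cur)))
                cur, q0, t0 = [], cq, ct
                ci += 1
                continue
            if op in OPS_TARGET:
                room = cuts[ci] - ct if ci < len(cuts) else n
                take = min(n, room)
            else:  # insertion: no target advance, cannot straddle a cut
                take = n
            cur.append((take, op))
            if op in OPS_QUERY:
                cq += take
            if op in OPS_TARGET:
                ct += take
            n -= take
    # flush trailing cut markers hit exactly at an op boundary
    while ci < len(cuts) and ct == cuts[ci]:  # pragma: no cover - defensive
        segments.append((q0, cq, t0, ct, merge_runs(cur)))
        cur, q0, t0 = [], cq, ct
        ci += 1
    segments.append((q0, cq, t0, ct, merge_runs(cur)))
    return segments


def project_target_to_query(ops: Ops, positions: list[int]) -> list[int]:
    """Map sorted target-relative positions to query-relative positions.

    The projected point is the query offset when the target first reaches the
    position — i.e. *before* consuming any insertion run that follows, and at
    the single query point spanned by a deletion run.
    """
    out: list[int] = []
    it = iter(positions)
    want = next(it, None)
    cq = ct = 0
    for n, op in ops:
        while want is not None and want <= ct:
            out.append(cq)
            want = next(it, None)
        if want is None:
            break
        if op in OPS_TARGET and ct < want <= ct + n:
            adv = want - ct
            out.append(cq + (adv if op in OPS_QUERY else 0))
            # continue scanning further positions inside this same run
            while True:
                want = next(it, None)
                if want is None or want > ct + n:
                    break
                adv = want - ct
                out.append(cq + (adv if op in OPS_QUERY else 0))
        if op in OPS_QUERY:
            cq += n
        if op in OPS_TARGET:
            ct += n
    while want is not None:
        out.append(cq)
        want = next(it, None)
    return out


def project_query_to_target(ops: Ops, positions: list[int]) -> list[int]:
    """Map sorted query-relative positions to target-relative positions."""
    flipped = [(n, _flip(op)) for n, op in ops]
    return project_target_to_query(flipped, positions)


def _flip(op: str) -> str:
    if op == "I":
        return "D"
    if op == "D":
        return "I"
    return op


def from_aligned_strings(q_aln: str, t_aln: str, gap: str = "-") -> Ops:
    """Build an edit script from two gapped aligned strings."""
    if len(q_aln) != len(t_aln):
        raise ValueError("aligned strings differ in length")
    ops: Ops = []
    for qc, tc in zip(q_aln, t_aln):
        if qc == gap and tc == gap:
            raise ValueError("double-gap column in aligned strings")
        if qc == gap:
            op = "D"
        elif tc == gap:
            op = "I"
        elif qc == tc:
            op = "="
        else:
            op = "X"
        ops.append((1, op))
    return merge_runs(ops)


def to_aligned_strings(ops: Ops, query: str, target: str, gap: str = "-") -> tuple[str, str]:
    """Render an edit script as two gapped aligned strings."""
    check_consistency(ops, len(query), len(target))
    qa: list[str] = []
    ta: list[str] = []
    q = t = 0
    for n, op in ops:
        if op in ("=", "X", "M"):
            qa.append(query[q:q + n])
            ta.append(target[t:t + n])
            q += n
            t += n
        elif op == "I":
            qa.append(query[q:q + n])
            ta.append(gap * n)
            q += n
        else:
            qa.append(gap * n)
            ta.append(target[t:t + n])
            t += n
    return "".join(qa), "".join(ta)
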