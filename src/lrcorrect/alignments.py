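"""Ingestion of long-read-to-contig alignments (BLASR m5, SAM, PAF).

All records are normalized to one internal convention:

* coordinates are 0-based half-open on the **forward strand** of both the
  read and the contig;
* ``orientation`` says whether the read aligns to the contig's forward
  (``"forward"``) or reverse (``"reverse"``) strand;
* the edit script (:mod:`lrcorrect.cigar` ops) is written along the
  alignment direction: its query side is the read segment *as oriented to
  match the contig forward strand* (i.e. reverse-complemented for reverse
  hits), its target side is ``contig[contig_start:contig_end]``.

Identity is blast-style: matches / (matches + mismatches + ins + del).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pysam

from . import cigar as cg
from .seqio import SequenceStore, revcomp

FORWARD = "forward"
REVERSE = "reverse"

#: default minimum read-span of a kept alignment (ordinary mode)
MIN_ALN_LEN_ORDINARY = 15
#: repeat-free mode drops all small alignments below this span
MIN_ALN_LEN_REPEAT_FREE = 300


class AlignmentParseError(ValueError):
    """A record could not be parsed; carries the 1-based line number."""

    def __init__(self, path, line_no: int, msg: str):
        super().__init__(f"{path}:{line_no}: {msg}")
        self.line_no = line_no


@dataclass
class RawAlignment:
    read_id: str
    read_len: int
    read_start: int
    read_end: int
    contig_id: str
    contig_len: int
    contig_start: int
    contig_end: int
    orientation: str
    identity: float
    ops: cg.Ops = field(repr=False)

    def __post_init__(self):
        if not (0 <= self.read_start < self.read_end <= self.read_len):
            raise ValueError(
                f"bad read interval [{self.read_start},{self.read_end}) "
                f"for {self.read_id} (len {self.read_len})")
        if not (0 <= self.contig_start < self.contig_end <= self.contig_len):
            raise ValueError(
                f"bad contig interval [{self.contig_start},{self.contig_end}) "
                f"for {self.contig_id} (len {self.contig_len})")
        if self.orientation not in (FORWARD, REVERSE):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity {self.identity} outside [0,1]")

    @property
    def read_span(self) -> int:
        return self.read_end - self.read_start

    @property
    def contig_span(self) -> int:
        return self.contig_end - self.contig_start

    def check_script(self) -> None:
        """Verify the edit script spans both aligned segments exactly."""
        cg.check_consistency(self.ops, self.read_span, self.contig_span)

    def oriented_read_segment(self, store: SequenceStore) -> str:
        """The read segment as the script's query (revcomp for reverse hits)."""
        seg = store.seq(self.read_id)[self.read_start:self.read_end]
        return revcomp(seg) if self.orientation == REVERSE else seg


# ---------------------------------------------------------------------------
# readers

def read_alignments(path: str | Path, fmt: str,
                    reads: SequenceStore | None = None,
                    contigs: SequenceStore | None = None) -> list[RawAlignment]:
    """Read alignments from *path* in the named dialect (``m5``/``sam``/``paf``).

    Optional sequence stores allow ``M`` CIGAR runs to be reclassified into
    ``=``/``X``; without them, ``M`` is kept and treated as match for
    coordinate purposes (identity then falls back to NM or column counts).
    """
    fmt = fmt.lower()
    if fmt == "paf":
        return _read_paf(path)
    if fmt == "m5":
        return _read_m5(path)
    if fmt == "sam":
        return _read_sam(path, reads, contigs)
    raise ValueError(f"unknown alignment format {fmt!r} (expected m5, sam or paf)")


def _read_paf(path: str | Path) -> list[RawAlignment]:
    out: list[RawAlignment] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise AlignmentParseError(path, line_no, "PAF line has <12 columns")
            try:
                qname, qlen, qs, qe, strand, tname, tlen, ts, te, nmatch, alnlen = (
                    fields[0], int(fields[1]), int(fields[2]), int(fields[3]),
                    fields[4], fields[5], int(fields[6]), int(fields[7]),
                    int(fields[8]), int(fields[9]), int(fields[10]))
            except ValueError as e:
                raise AlignmentParseError(path, line_no, f"bad PAF field: {e}") from None
            if strand not in "+-":
                raise AlignmentParseError(path, line_no, f"bad strand {strand!r}")
            ops: cg.Ops | None = None
            for tag in fields[12:]:
                if tag.startswith("cg:Z:"):
                    try:
                        ops = cg.parse_cigar(tag[5:])
                    except ValueError as e:
                        raise AlignmentParseError(path, line_no, str(e)) from None
            if ops is None:
                # gapless placeholder script; only usable when spans agree
                if qe - qs != te - ts:
                    raise AlignmentParseError(
                        path, line_no, "PAF record lacks cg:Z tag and spans differ")
                ops = [(qe - qs, "M")]
                ident = nmatch / alnlen if alnlen else 0.0
            else:
                ident = cg.identity(ops)
            orientation = FORWARD if strand == "+" else REVERSE
            try:
                aln = RawAlignment(qname, qlen, qs, qe, tname, tlen, ts, te,
                                   orientation, ident, ops)
                aln.check_script()
            except ValueError as e:
                raise AlignmentParseError(path, line_no, str(e)) from None
            out.append(aln)
    return out


def _read_m5(path: str | Path) -> list[RawAlignment]:
    """BLASR ``-m 5``-style whitespace-separated records.

    Column layout: qName qLength qStart qEnd qStrand tName tLength tStart
    tEnd tStrand score numMatch numMismatch numIns numDel mapQV qAlignedSeq
    matchPattern tAlignedSeq.  Minus-strand records are normalized so that
    target coordinates are on the target's forward strand and the gapped
    query string is the reverse-complemented read segment (the original
    aligner's reverse-strand coordinate quirk is not reproduced).
    """
    out: list[RawAlignment] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            if not line.strip():
                continue
            f = line.split()
            if len(f) != 19:
                raise AlignmentParseError(path, line_no,
                                          f"m5 record has {len(f)} columns, expected 19")
            try:
                qname, qlen, qs, qe = f[0], int(f[1]), int(f[2]), int(f[3])
                tname, tlen, ts, te, tstrand = f[5], int(f[6]), int(f[7]), int(f[8]), f[9]
                q_aln, t_aln = f[16], f[18]
            except ValueError as e:
                raise AlignmentParseError(path, line_no, f"bad m5 field: {e}") from None
            if tstrand not in "+-":
                raise AlignmentParseError(path, line_no, f"bad tStrand {tstrand!r}")
            try:
                ops = cg.from_aligned_strings(q_aln, t_aln)
            except ValueError as e:
                raise AlignmentParseError(path, line_no, str(e)) from None
            orientation = FORWARD if tstrand == "+" else REVERSE
            try:
                aln = RawAlignment(qname, qlen, qs, qe, tname, tlen, ts, te,
                                   orientation, cg.identity(ops), ops)
                aln.check_script()
            except ValueError as e:
                raise AlignmentParseError(path, line_no, str(e)) from None
            out.append(aln)
    return out


def _read_sam(path: str | Path, reads: SequenceStore | None,
              contigs: SequenceStore | None) -> list[RawAlignment]:
    out: list[RawAlignment] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            ops, lead_clip, tail_clip = _sam_ops(rec)
            if not ops:
                continue
            read_len = rec.infer_read_length()
            if read_len is None:
                read_len = cg.query_span(ops) + lead_clip + tail_clip
            # stored-orientation coords -> forward-read-strand coords
            o_start = lead_clip
            o_end = read_len - tail_clip
            if rec.is_reverse:
                read_start, read_end = read_len - o_end, read_len - o_start
                orientation = REVERSE
            else:
                read_start, read_end = o_start, o_end
                orientation = FORWARD
            tname = rec.reference_name
            tlen = sam.get_reference_length(tname)
            ts, te = rec.reference_start, rec.reference_end
            qseq = rec.query_alignment_sequence  # stored orientation, no clips
            if contigs is not None and tname in contigs and qseq:
                tseg = contigs.seq(tname)[ts:te]
                ops = cg.classify_m(ops, qseq.upper(), tseg)
                ident = cg.identity(ops)
            else:
                ident = _sam_identity(rec, ops)
            aln = RawAlignment(rec.query_name, read_len, read_start, read_end,
                               tname, tlen, ts, te, orientation, ident, ops)
            aln.check_script()
            out.append(aln)
    return out


def _sam_ops(rec) -> tuple[cg.Ops, int, int]:
    """CIGAR → internal ops plus leading/trailing clip lengths (H+S)."""
    table = {0: "M", 1: "I", 2: "D", 7: "=", 8: "X"}
    ops: cg.Ops = []
    lead = tail = 0
    seen_core = False
    for code, n in rec.cigartuples or []:
        if code in (4, 5):  # S, H
            if seen_core:
                tail += n
            else:
                lead += n
        elif code in table:
            ops.append((n, table[code]))
            seen_core = True
        elif code in (3,):  # N: treat reference skip as deletion run
            ops.append((n, "D"))
            seen_core = True
        # P (6) ignored
    return cg.merge_runs(ops), lead, tail


def _sam_identity(rec, ops: cg.Ops) -> float:
    cols = sum(n for n, _ in ops)
    if cols == 0:
        return 0.0
    n_m = sum(n for n, op in ops if op in "M=")
    n_x = sum(n for n, op in ops if op == "X")
    n_indel = sum(n for n, op in ops if op in "ID")
    if rec.has_tag("NM"):
        nm = rec.get_tag("NM")
        n_sub = max(nm - n_indel, 0)
        matches = max(n_m - max(n_sub - n_x, 0), 0)
        return matches / cols
    return n_m / cols


# ---------------------------------------------------------------------------
# writer (round-trip format)

def write_paf(alignments: list[RawAlignment], path: str | Path) -> None:
    """Write alignments as PAF with a ``cg:Z:`` extended-CIGAR tag."""
    with open(path, "w") as fh:
        for a in alignments:
            cols = sum(n for n, _ in a.ops)
            nmatch = round(a.identity * cols)
            strand = "+" if a.orientation == FORWARD else "-"
            fh.write("\t".join(map(str, [
                a.read_id, a.read_len, a.read_start, a.read_end, strand,
                a.contig_id, a.contig_len, a.contig_start, a.contig_end,
                nmatch, cols, 255, f"cg:Z:{cg.cigar_string(a.ops)}",
            ])) + "\n")


# ---------------------------------------------------------------------------
# filtering

def filter_alignments(alignments: list[RawAlignment],
                      min_len: int | None = None,
                      repeat_free: bool = False,
                      min_identity: float = 0.0) -> list[RawAlignment]:
    """Drop alignments shorter than ``min_len`` read bases.

    ``min_len`` defaults to 300 in repeat-free mode (small alignments are the
    similar-repeat hits that mode refuses to use) and 15 otherwise.
    """
    if min_len is None:
        min_len = MIN_ALN_LEN_REPEAT_FREE if repeat_free else MIN_ALN_LEN_ORDINARY
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return [a for a in alignments
            if a.read_span >= min_len and a.identity >= min_identity]
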