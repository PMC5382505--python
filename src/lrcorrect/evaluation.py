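"""Split-read error-correction evaluation.

Given the initial reads, the corrected split reads (whose names carry the
initial read id as ``<read_id>.<n>``) and per-read truth sequences, counts
per-base correction outcomes:

* **TP** — initial error now matching the truth (corrected error);
* **FP** — initially correct base now wrong (falsely converted);
* **FN** — initial error still wrong (uncorrected error);
* **TN** — initially correct base still correct.

Because errors are uniformly distributed along a read, totals over the
*output* bases extrapolate to the initial reads through the throughput
``TH`` (output bases / initial bases):

    EI = (TP + FN) / TH          estimated initial errors
    CI = (TN + FP) / TH          estimated initial correct bases
    CD = CI - (TN + FP)          correct bases among the discarded bases

    sensitivity = TP / EI
    specificity = (TN + CD) / CI
    gain        = (TP - FP) / EI

Both the initial and the corrected classification of a read against its
truth sequence use the same edit-distance alignment (edlib, target-infix
mode), so a null corrector (output = input) yields exactly
sensitivity = gain = 0 and specificity = 1.

Indel convention: a truth base deleted in the output counts FP if it was
initially correct and FN if it was an initial error; output bases with no
truth counterpart count FP, except where they persist initial insertions
(FN) — surplus initial insertions that disappeared count TP.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import edlib

from . import cigar as cg
from .seqio import SequenceStore, revcomp

_ST_CORRECT = 0
_ST_ERROR = 1


class EvaluationError(RuntimeError):
    pass


@dataclass
class EvalCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    th: float = 1.0

    @property
    def ei(self) -> float:
        return (self.tp + self.fn) / self.th if self.th > 0 else 0.0

    @property
    def ci(self) -> float:
        return (self.tn + self.fp) / self.th if self.th > 0 else 0.0

    @property
    def cd(self) -> float:
        return self.ci - (self.tn + self.fp)

    @property
    def sensitivity(self) -> float:
        return self.tp / self.ei if self.ei > 0 else 0.0

    @property
    def specificity(self) -> float:
        return (self.tn + self.cd) / self.ci if self.ci > 0 else 1.0

    @property
    def gain(self) -> float:
        return (self.tp - self.fp) / self.ei if self.ei > 0 else 0.0

    def as_dict(self) -> dict:
        return {
            "TP": self.tp, "FP": self.fp, "FN": self.fn, "TN": self.tn,
            "TH": self.th, "EI": self.ei, "CI": self.ci, "CD": self.cd,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "gain": self.gain,
        }


def derived_metrics(tp: int, fp: int, fn: int, tn: int, th: float) -> EvalCounts:
    """Wrap raw confusion counts with the TH-extrapolated estimators."""
    if th <= 0:
        raise ValueError("throughput must be > 0 to derive metrics")
    return EvalCounts(tp=tp, fp=fp, fn=fn, tn=tn, th=th)


def throughput(initial_reads, output_reads) -> float:
    """Output bases over initial bases; arguments are (id, seq) iterables."""
    init = _total_bases(initial_reads)
    out = _total_bases(output_reads)
    if init <= 0:
        raise ValueError("initial reads contain no bases")
    return out / init


def _total_bases(reads) -> int:
    if isinstance(reads, SequenceStore):
        return sum(len(s) for _i, s in reads.items())
    return sum(len(seq) for _id, seq in reads)


# ---------------------------------------------------------------------------
# truth table

@dataclass
class TruthRecord:
    read_id: str
    genome_id: str
    start: int
    end: int
    strand: str  # '+'/'-'
    error_script: str = "*"


class TruthTable:
    """Per-read true genome interval (and optional generative error script)."""

    def __init__(self, records: dict[str, TruthRecord], genome: SequenceStore):
        self.records = records
        self.genome = genome

    @classmethod
    def from_file(cls, path: str | Path, genome: SequenceStore) -> "TruthTable":
        records: dict[str, TruthRecord] = {}
        with open(path) as fh:
            reader = csv.reader(fh, delimiter="\t")
            for row in reader:
                if not row or row[0].startswith("#"):
                    continue
                read_id, genome_id, start, end, strand = row[:5]
                script = row[5] if len(row) > 5 else "*"
                records[read_id] = TruthRecord(read_id, genome_id, int(start),
                                               int(end), strand, script)
        return cls(records, genome)

    def __contains__(self, read_id: str) -> bool:
        return read_id in self.records

    def truth_seq(self, read_id: str) -> str:
        """Error-free sequence of the read (oriented as the read)."""
        rec = self.records[read_id]
        seg = self.genome.seq(rec.genome_id)[rec.start:rec.end]
        return revcomp(seg) if rec.strand == "-" else seg


# ---------------------------------------------------------------------------
# per-base confusion counting

def _classify(seq: str, truth: str) -> tuple[int, int, dict, dict, dict]:
    """Align ``seq`` into ``truth`` (infix) and classify truth positions.

    Returns (t0, t1, states, insertions, matches) where states maps truth
    position -> ``_ST_CORRECT``/``_ST_ERROR``/"deleted", insertions maps
    truth junction -> inserted-base count, and matches marks positions where
    the aligned base agrees with the truth.
    """
    res = edlib.align(seq, truth, mode="HW", task="path")
    t0, t1_incl = res["locations"][0]
    if t0 is None:
        t0 = 0
    ops = cg.parse_cigar(res["cigar"])
    states: dict[int, str] = {}
    ins: dict[int, int] = {}
    t = t0
    q = 0
    for n, op in ops:
        if op == "=":
            for i in range(n):
                states[t + i] = "match"
            t += n
            q += n
        elif op == "X":
            for i in range(n):
                states[t + i] = "mismatch"
            t += n
            q += n
        elif op == "D":
            for i in range(n):
                states[t + i] = "deleted"
            t += n
        elif op == "I":
            ins[t] = ins.get(t, 0) + n
            q += n
    return t0, t, states, ins, {}


class _ReadTruthCache:
    """Initial-read classification against truth, computed once per read."""

    def __init__(self):
        self._cache: dict[str, tuple] = {}

    def get(self, read_id: str, initial_seq: str, truth_seq: str):
        if read_id not in self._cache:
            t0, t1, states, ins, _ = _classify(initial_seq, truth_seq)
            init_state = {}
            for t, st in states.items():
                init_state[t] = _ST_CORRECT if st == "match" else _ST_ERROR
            # truth positions the initial alignment never reached are errors
            # of the deleted kind at the read edges; they fall outside any
            # output span that the initial read itself could produce
            self._cache[read_id] = (init_state, ins, (t0, t1))
        return self._cache[read_id]


def confusion_counts(split_reads, initial: SequenceStore,
                     truth: TruthTable) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) over the output bases of the split reads.

    ``split_reads`` is an iterable of ``(name, seq)`` with names of the form
    ``<read_id>.<n>`` (or a bare read id).  Raises
    :class:`EvaluationError` when a name cannot be traced to an initial
    read — the correspondence is required.
    """
    cache = _ReadTruthCache()
    tp = fp = fn = tn = 0
    for name, seq in split_reads:
        read_id = _origin(name, initial)
        if read_id is None:
            raise EvaluationError(
                f"split read {name!r} has no origin among the initial reads; "
                f"correspondence information is required")
        if read_id not in truth:
            raise EvaluationError(f"no truth interval for read {read_id!r}")
        truth_seq = truth.truth_seq(read_id)
        init_state, init_ins, _span = cache.get(
            read_id, initial.seq(read_id), truth_seq)
        t0, t1, states, s_ins, _ = _classify(seq, truth_seq)
        for t in range(t0, t1):
            st = states.get(t)
            init = init_state.get(t, _ST_ERROR)
            if st == "match":
                if init == _ST_ERROR:
                    tp += 1
                else:
                    tn += 1
            elif st in ("mismatch", "deleted"):
                if init == _ST_ERROR:
                    fn += 1
                else:
                    fp += 1
        for j in range(t0, t1):  # junction before truth base j
            a = init_ins.get(j, 0)
            b = s_ins.get(j, 0)
            if a or b:
                tp += max(a - b, 0)
                fn += min(a, b)
                fp += max(b - a, 0)
    return tp, fp, fn, tn


def _origin(name: str, initial: SequenceStore) -> str | None:
    if name in initial:
        return name
    stem, _, suffix = name.rpartition(".")
    if stem and suffix.isdigit() and stem in initial:
        return stem
    return None


def evaluate_split_reads(initial: SequenceStore, split_reads,
                         truth: TruthTable) -> EvalCounts:
    """End-to-end evaluation: confusion counts plus TH-derived estimators."""
    split_reads = list(split_reads)
    th = throughput(initial, split_reads)
    if th == 0:
        return EvalCounts(0, 0, 0, 0, th=1.0)  # empty output: nothing to score
    tp, fp, fn, tn = confusion_counts(split_reads, initial, truth)
    return derived_metrics(tp, fp, fn, tn, th)


def split_identity(split_reads, initial: SequenceStore,
                   truth: TruthTable) -> float:
    """Aggregate identity of split reads to their truth substrings.

    1 - (total edit distance / total aligned columns), infix alignment.
    """
    dist = 0
    cols = 0
    for name, seq in split_reads:
        read_id = _origin(name, initial)
        if read_id is None:
            raise EvaluationError(f"split read {name!r} has no origin")
        t = truth.truth_seq(read_id)
        res = edlib.align(seq, t, mode="HW")
        dist += res["editDistance"]
        cols += len(seq)
    if cols == 0:
        return 0.0
    return 1.0 - dist / cols


# ---------------------------------------------------------------------------
# reference-alignment mode (real data; not on the synthetic test path)

def alignment_stats_from_sam(path: str | Path) -> dict:
    """Alignment ratio / identity / genome fraction from a reads-vs-genome SAM.

    For corrected reads aligned to a reference with an external aligner.
    """
    import pysam

    aligned = 0
    total = 0
    matches = 0
    columns = 0
    covered: dict[str, set] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        lengths = dict(zip(sam.references or (), sam.lengths or ()))
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary:
                continue
            qlen = rec.query_length or rec.infer_read_length() or 0
            total += qlen
            if rec.is_unmapped:
                continue
            aligned += rec.query_alignment_length
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            cols = sum(n for op, n in (rec.cigartuples or [])
                       if op in (0, 1, 2, 7, 8))
            matches += cols - nm
            columns += cols
            covered.setdefault(rec.reference_name, set()).update(
                range(rec.reference_start, rec.reference_end))
    genome_size = sum(lengths.values())
    return {
        "alignment_ratio": aligned / total if total else 0.0,
        "alignment_identity": matches / columns if columns else 0.0,
        "genome_fraction": (sum(len(s) for s in covered.values()) / genome_size
                            if genome_size else 0.0),
    }
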