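"""Short-read refinement of similar-repeat-corrected regions.

A region corrected with a similar repeat carries the repeat's divergent
bases.  The initial short reads — which cover the true genome region — can
rewrite those bases: within each flagged region (plus a margin of k-1
bases) the refiner re-threads the sequence through the solid k-mer spectrum
of the short reads, anchored on solid k-mers in the flanking corrected
sequence.

Because the similar repeat itself is part of the genome, its k-mers are
also solid; the spectrum alone cannot always tell the true region from the
repeat wherever the two copies share a full k-mer window.  The search is
therefore run with two branch preferences (follow the current sequence /
avoid it), and the completed solid path closest to the *original read
bases* — an unbiased, if noisy, witness of the true region — is kept.

The refiner is pluggable: the internal spectrum refiner needs no external
software; an external LoRDEC-style binary can be substituted for real data.
Only bases inside flagged windows are ever modified.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import edlib

from .correction import LBL_CORRECTED, LBL_REPEAT, CorrectionResult
from .seqio import SequenceStore, read_sequences, revcomp, write_fasta

DEFAULT_K = 25
DEFAULT_SOLID = 2
#: branching events explored per region search before giving up
BRANCH_LIMIT = 200


class KmerSpectrum:
    """Canonical k-mer counts from the initial short reads."""

    def __init__(self, k: int = DEFAULT_K, solid_threshold: int = DEFAULT_SOLID):
        if k < 3 or k % 2 == 0:
            raise ValueError("k must be an odd integer >= 3")
        if solid_threshold < 1:
            raise ValueError("solidity threshold must be >= 1")
        self.k = k
        self.solid_threshold = solid_threshold
        self._counts: dict[str, int] = {}

    @classmethod
    def from_reads(cls, reads, k: int = DEFAULT_K,
                   solid_threshold: int = DEFAULT_SOLID) -> "KmerSpectrum":
        """Count k-mers from an iterable of sequences (or a SequenceStore)."""
        spec = cls(k, solid_threshold)
        if isinstance(reads, SequenceStore):
            reads = (seq for _id, seq in reads.items())
        for seq in reads:
            spec.add_sequence(seq)
        return spec

    @classmethod
    def from_file(cls, path: str | Path, k: int = DEFAULT_K,
                  solid_threshold: int = DEFAULT_SOLID) -> "KmerSpectrum":
        return cls.from_reads((s for _i, s in read_sequences(path)),
                              k, solid_threshold)

    def add_sequence(self, seq: str) -> None:
        k = self.k
        seq = seq.upper()
        counts = self._counts
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            if "N" in kmer:
                continue
            kmer = canonical(kmer)
            counts[kmer] = counts.get(kmer, 0) + 1

    def count(self, kmer: str) -> int:
        return self._counts.get(canonical(kmer), 0)

    def is_solid(self, kmer: str) -> bool:
        return self.count(kmer) >= self.solid_threshold

    def solid_fraction(self, seq: str) -> float:
        """Fraction of the sequence's k-mers that are solid (1.0 if too short)."""
        n = len(seq) - self.k + 1
        if n <= 0:
            return 1.0
        return sum(self.is_solid(seq[i:i + self.k]) for i in range(n)) / n

    def __len__(self) -> int:
        return len(self._counts)


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


# ---------------------------------------------------------------------------
# solid-path search

def _search(spectrum: KmerSpectrum, left_anchor: str, right_anchor: str,
            guide: str, max_extra: int, follow_guide: bool,
            branch_limit: int) -> list[str]:
    """Depth-first solid-k-mer walk from left_anchor to right_anchor.

    Extends base-by-base; at branch points the guide base is tried first
    (``follow_guide``) or last.  Returns the completed fillers (bases
    between the anchors, right anchor excluded) found within the branch
    budget.
    """
    k = spectrum.k
    max_len = len(guide) + len(right_anchor) + max_extra
    min_len = max(len(guide) + len(right_anchor) - max_extra, len(right_anchor))
    stack: list[str] = [""]
    branches = 0
    found: list[str] = []
    while stack:
        built = stack.pop()
        if len(built) >= min_len and built.endswith(right_anchor):
            found.append(built[:-len(right_anchor)])
            if len(found) >= 25:
                break
            continue
        if len(built) >= max_len:
            continue
        cur = (left_anchor + built)[-(k - 1):]
        exts = [b for b in "ACGT" if spectrum.is_solid(cur + b)]
        if not exts:
            continue
        if len(exts) > 1:
            branches += 1
            if branches > branch_limit:
                if found:
                    break
                continue
        pos = len(built)
        prefer = guide[pos] if pos < len(guide) else None
        # stack order: last pushed is explored first
        first_last = (lambda b: b == prefer) if follow_guide else (lambda b: b != prefer)
        for b in sorted(exts, key=first_last):
            stack.append(built + b)
    return found


def _bridge(spectrum: KmerSpectrum, left_anchor: str, right_anchor: str,
            guide: str, witness: str | None, max_extra: int,
            branch_limit: int = BRANCH_LIMIT) -> str | None:
    """Best solid filler between the anchors, or None.

    Candidates from both search directions are ranked by edit distance to
    ``witness`` (the original read bases for the region) when available,
    else to ``guide``.
    """
    cands: list[str] = []
    for follow in (True, False):
        cands.extend(_search(spectrum, left_anchor, right_anchor, guide,
                             max_extra, follow, branch_limit))
    if not cands:
        return None
    ref = witness if witness else guide
    seen: set[str] = set()
    best, best_d = None, None
    for c in cands:
        if c in seen:
            continue
        seen.add(c)
        d = edlib.align(c, ref, mode="HW" if witness else "NW")["editDistance"]
        if best_d is None or d < best_d:
            best, best_d = c, d
    return best


@dataclass
class RefineStats:
    regions_seen: int = 0
    regions_refined: int = 0
    bases_rewritten: int = 0


# ---------------------------------------------------------------------------
# region refinement

def refine_regions(results: list[CorrectionResult],
                   short_reads=None,
                   k: int = DEFAULT_K,
                   mode: str = "ordinary",
                   spectrum: KmerSpectrum | None = None,
                   solid_threshold: int = DEFAULT_SOLID,
                   reads: SequenceStore | None = None,
                   refiner: str = "internal",
                   lordec_bin: str = "lordec-correct",
                   ) -> tuple[list[CorrectionResult], RefineStats]:
    """Re-correct repeat-corrected regions with the initial short reads.

    In repeat-free mode this stage is skipped and the results are returned
    unchanged.  Only bases labeled repeat-corrected, plus a margin of k-1
    bases on each side, may be modified; refined bases are relabeled
    corrected.  ``reads`` (the initial long reads) sharpens path selection
    inside refined regions but is optional.
    """
    stats = RefineStats()
    if mode == "repeat-free":
        return results, stats
    if refiner == "lordec":
        return _refine_external(results, short_reads, k, lordec_bin, stats)
    if refiner != "internal":
        raise ValueError(f"unknown refiner {refiner!r}")
    if spectrum is None:
        if short_reads is None:
            raise ValueError("internal refiner needs short reads or a spectrum")
        spectrum = KmerSpectrum.from_reads(short_reads, k, solid_threshold)
    for res in results:
        _refine_one(res, spectrum, stats, reads)
    return results, stats


def _flagged_runs(labels: str) -> list[tuple[int, int]]:
    runs = []
    i = 0
    n = len(labels)
    while i < n:
        if labels[i] == LBL_REPEAT:
            j = i
            while j < n and labels[j] == LBL_REPEAT:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def _witness_segment(res: CorrectionResult, reads: SequenceStore | None,
                     run: tuple[int, int], margin: int) -> str | None:
    """Original read bases underlying an output run (plus margin)."""
    if reads is None or res.read_id not in reads:
        return None
    lo = hi = None
    for step in res.steps:
        if step.out_end <= run[0] or step.out_start >= run[1]:
            continue
        s, e = step.region
        lo = s if lo is None else min(lo, s)
        hi = e if hi is None else max(hi, e)
    if lo is None:
        return None
    seq = reads.seq(res.read_id)
    return seq[max(lo - margin, 0):min(hi + margin, len(seq))]


def _refine_one(res: CorrectionResult, spectrum: KmerSpectrum,
                stats: RefineStats, reads: SequenceStore | None = None) -> None:
    k = spectrum.k
    seq, labels = res.sequence, res.labels
    edits: list[tuple[int, int, str, int, int]] = []
    last_end = 0
    for start, end in _flagged_runs(labels):
        stats.regions_seen += 1
        w0 = max(start - (k - 1), 0, last_end)
        w1 = min(end + (k - 1), len(seq))
        la = _last_solid(spectrum, seq, w0, start)
        ra = _first_solid(spectrum, seq, end, w1)
        if la is None or ra is None:
            continue
        s, e = la[0] + k, ra[0]
        if e < s:
            continue
        guide = seq[s:e]
        witness = _witness_segment(res, reads, (start, end), k)
        mid = _bridge(spectrum, la[1], ra[1], guide, witness,
                      max_extra=max(10, len(guide) // 5))
        if mid is None:
            continue
        edits.append((s, e, mid, start, end))
        last_end = e
        stats.regions_refined += 1
        if mid != guide:
            stats.bases_rewritten += edlib.align(mid, guide)["editDistance"]
    for s, e, mid, start, end in reversed(edits):
        seq = seq[:s] + mid + seq[e:]
        pre = min(s, start)
        labels = (labels[:pre] + LBL_CORRECTED * max(s - start, 0)
                  + LBL_CORRECTED * len(mid) + labels[e:])
    res.sequence = seq
    res.labels = labels


def _last_solid(spectrum: KmerSpectrum, seq: str, lo: int, hi: int):
    """Rightmost solid k-mer starting in [lo, hi); (pos, kmer) or None."""
    k = spectrum.k
    for pos in range(min(hi, len(seq) - k) - 1, lo - 1, -1):
        kmer = seq[pos:pos + k]
        if spectrum.is_solid(kmer):
            return pos, kmer
    return None


def _first_solid(spectrum: KmerSpectrum, seq: str, lo: int, hi: int):
    """Leftmost solid k-mer starting in [lo, hi); (pos, kmer) or None."""
    k = spectrum.k
    for pos in range(lo, min(hi, len(seq) - k + 1)):
        kmer = seq[pos:pos + k]
        if spectrum.is_solid(kmer):
            return pos, kmer
    return None


# ---------------------------------------------------------------------------
# external refiner

def _refine_external(results, short_reads, k, binary, stats):
    """Shell out to a LoRDEC-style binary on the flagged subsequences."""
    if shutil.which(binary) is None:
        raise RuntimeError(
            f"external refiner binary {binary!r} not found on PATH; "
            f"use --refiner internal for the built-in spectrum refiner")
    with tempfile.TemporaryDirectory() as tmp:
        tmpdir = Path(tmp)
        sub: list[tuple[str, str]] = []
        index: dict[str, tuple[int, int, int]] = {}
        for ri, res in enumerate(results):
            for j, (s, e) in enumerate(_flagged_runs(res.labels)):
                name = f"region_{ri}_{j}"
                sub.append((name, res.sequence[s:e]))
                index[name] = (ri, s, e)
        if not sub:
            return results, stats
        write_fasta(tmpdir / "regions.fa", sub)
        write_fasta(tmpdir / "short.fa",
                    ((f"s{i}", s) for i, s in enumerate(short_reads)))
        out_fa = tmpdir / "refined.fa"
        subprocess.run(
            [binary, "-k", str(k), "-2", str(tmpdir / "short.fa"),
             "-i", str(tmpdir / "regions.fa"), "-o", str(out_fa)],
            check=True, capture_output=True)
        refined = dict(read_sequences(out_fa))
        per_result: dict[int, list[tuple[int, int, str]]] = {}
        for name, (ri, s, e) in index.items():
            if name in refined:
                per_result.setdefault(ri, []).append((s, e, refined[name]))
        for ri, pieces in per_result.items():
            res = results[ri]
            seq, lbl = res.sequence, res.labels
            for s, e, new in sorted(pieces, reverse=True):
                seq = seq[:s] + new + seq[e:]
                lbl = lbl[:s] + LBL_CORRECTED * len(new) + lbl[e:]
                stats.regions_refined += 1
            stats.regions_seen += len(pieces)
            res.sequence, res.labels = seq, lbl
    return results, stats
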