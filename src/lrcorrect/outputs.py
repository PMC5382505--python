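"""The three corrected outputs: full, trimmed and split reads.

* **full** — every input read, corrected regions substituted, uncorrected
  spans (head, tail, interior gaps) retained verbatim;
* **trimmed** — head and tail uncorrected spans removed, interior
  uncorrected spans kept; reads with no corrected bases are omitted;
* **split** — each maximal corrected run emitted as its own record, named
  ``<read_id>.<n>`` so downstream evaluation can map a piece back to its
  initial read; runs shorter than ``min_piece`` (default 100 bp) dropped.

Repeat-corrected bases — refined or not — count as corrected here: they
were corrected with a (possibly similar-repeat) contig region and belong to
the output, unlike bases no contig region ever covered.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterator

from .correction import LBL_UNCORRECTED, CorrectionResult
from .seqio import write_fasta

DEFAULT_MIN_PIECE = 100
FASTA_WIDTH = 80


def _corrected_runs(labels: str) -> list[tuple[int, int]]:
    """Maximal runs of non-uncorrected labels."""
    runs = []
    i, n = 0, len(labels)
    while i < n:
        if labels[i] != LBL_UNCORRECTED:
            j = i
            while j < n and labels[j] != LBL_UNCORRECTED:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def full_records(results: list[CorrectionResult]) -> Iterator[tuple[str, str]]:
    for res in results:
        yield res.read_id, res.sequence


def trimmed_records(results: list[CorrectionResult]) -> Iterator[tuple[str, str]]:
    for res in results:
        runs = _corrected_runs(res.labels)
        if not runs:
            continue
        start, end = runs[0][0], runs[-1][1]
        yield res.read_id, res.sequence[start:end]


def split_records(results: list[CorrectionResult],
                  min_piece: int = DEFAULT_MIN_PIECE) -> Iterator[tuple[str, str]]:
    for res in results:
        n = 0
        for start, end in _corrected_runs(res.labels):
            if end - start < min_piece:
                continue
            yield f"{res.read_id}.{n}", res.sequence[start:end]
            n += 1


def write_full(results: list[CorrectionResult], path: str | Path) -> int:
    return write_fasta(path, full_records(results), FASTA_WIDTH)


def write_trimmed(results: list[CorrectionResult], path: str | Path) -> int:
    return write_fasta(path, trimmed_records(results), FASTA_WIDTH)


def write_split(results: list[CorrectionResult], path: str | Path,
                min_piece: int = DEFAULT_MIN_PIECE) -> int:
    return write_fasta(path, split_records(results, min_piece), FASTA_WIDTH)


def write_correction_log(results: list[CorrectionResult], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["read_id", "n_regions", "total_weight",
                    "n_repeat_flagged", "corrected_bases", "uncorrected_bases"])
        for res in results:
            counts = res.base_counts()
            w.writerow([res.read_id, len(res.steps), f"{res.total_weight:g}",
                        res.n_repeat_flagged,
                        counts["C"] + counts["R"], counts["U"]])
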