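"""Sequence containers and FASTA/FASTQ I/O (gzip-aware, Biopython-backed)."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _sniff_format(path: str | Path) -> str:
    name = Path(path).name
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith((".fq", ".fastq")):
        return "fastq"
    return "fasta"


def read_sequences(path: str | Path, fmt: str | None = None) -> Iterator[tuple[str, str]]:
    """Yield ``(id, uppercase sequence)`` from a FASTA/FASTQ file."""
    fmt = fmt or _sniff_format(path)
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            yield rec.id, str(rec.seq).upper()


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 80) -> int:
    """Write records as FASTA with fixed line width; returns record count."""
    n = 0
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
            n += 1
    return n


class SequenceStore:
    """id → uppercase DNA sequence, with length lookups.

    Long reads and contigs are kept in separate stores so id collisions
    between the two namespaces cannot corrupt a correction run.
    """

    def __init__(self, sequences: dict[str, str] | None = None):
        self._seqs: dict[str, str] = {}
        if sequences:
            for name, seq in sequences.items():
                self.add(name, seq)

    @classmethod
    def from_file(cls, path: str | Path, fmt: str | None = None) -> "SequenceStore":
        store = cls()
        for name, seq in read_sequences(path, fmt):
            store.add(name, seq)
        return store

    def add(self, name: str, seq: str) -> None:
        seq = seq.upper()
        if not seq:
            raise ValueError(f"empty sequence for id {name!r}")
        if name in self._seqs:
            raise ValueError(f"duplicate sequence id {name!r}")
        self._seqs[name] = seq

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __len__(self) -> int:
        return len(self._seqs)

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def seq(self, name: str) -> str:
        try:
            return self._seqs[name]
        except KeyError:
            raise KeyError(f"sequence id {name!r} not in store") from None

    def length(self, name: str) -> int:
        return len(self.seq(name))

    def items(self) -> Iterator[tuple[str, str]]:
        return iter(self._seqs.items())
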