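"""Synthetic data with the statistical structure hybrid correction assumes.

The generator emulates a short+long read hybrid sequencing project at desk
scale: a random genome carrying families of similar repeats (copies a few
percent divergent — close enough that one copy can stand in for another as
a correction template), short-read contigs with coverage gaps (one repeat
copy per family can be dropped entirely, creating the lack-of-reference
situation the correction must rescue), long reads with ~15% indel-dominated
errors uniformly distributed along the read, and accurate short reads.

Ground truth (genome interval, strand and error script per read; genome
interval per contig; repeat copy coordinates) is recorded so tests can
score corrections base-by-base without any external aligner.  The bundled
truth-guided aligner emits, for every read region, its true contig region
*and* the sufficiently similar repeat copies — the multi-candidate input
the contig graph and DP are there to disambiguate.  A small de-novo
seed-and-extend aligner is included for data without truth; it is
best-effort only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np

from . import cigar as cg
from .alignments import FORWARD, REVERSE, RawAlignment, write_paf
from .evaluation import TruthRecord, TruthTable
from .seqio import SequenceStore, revcomp, write_fasta

BASES = "ACGT"


@dataclass
class RepeatFamily:
    copy_number: int = 2
    unit_length: int = 1000
    divergence: float = 0.04  # pairwise difference between copies (<0.15)


@dataclass
class LongReadConfig:
    coverage: float = 20.0
    mean_length: int = 8000
    min_length: int = 1000
    error_rate: float = 0.15
    # indel-dominated split of errors: insertion / deletion / substitution
    ins_frac: float = 0.45
    del_frac: float = 0.40


@dataclass
class ShortReadConfig:
    coverage: float = 40.0
    length: int = 100
    error_rate: float = 0.005


@dataclass
class SimulationConfig:
    genome_length: int = 100_000
    repeat_families: list[RepeatFamily] = field(
        default_factory=lambda: [RepeatFamily()])
    contig_gap_fraction: float = 0.05
    drop_repeat_copy: bool = True
    long_read: LongReadConfig = field(default_factory=LongReadConfig)
    short_read: ShortReadConfig = field(default_factory=ShortReadConfig)
    seed: int = 0

    def __post_init__(self):
        for fam in self.repeat_families:
            if not 0 <= fam.divergence < 0.15:
                raise ValueError("similar repeats must diverge by < 15%")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "repeat_families" in d:
            d["repeat_families"] = [RepeatFamily(**f) for f in d["repeat_families"]]
        if "long_read" in d:
            d["long_read"] = LongReadConfig(**d["long_read"])
        if "short_read" in d:
            d["short_read"] = ShortReadConfig(**d["short_read"])
        return cls(**d)


@dataclass
class RepeatCopy:
    family: int
    copy: int
    start: int
    end: int


@dataclass
class ContigTruth:
    contig_id: str
    start: int
    end: int


GENOME_ID = "genome"


# ---------------------------------------------------------------------------
# genome

def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _mutate_subs(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        alt = [b for b in BASES if b != arr[i]]
        arr[i] = alt[rng.integers(0, 3)]
    return "".join(arr)


def simulate_genome(config: SimulationConfig,
                    rng: np.random.Generator | None = None,
                    ) -> tuple[str, list[RepeatCopy]]:
    """Random genome with planted similar-repeat families.

    Copies of one family are mutated independently from a common unit at
    half the family divergence, so any two copies differ by approximately
    the configured pairwise divergence.  Copies are placed non-overlapping
    with generous separation.
    """
    rng = rng or np.random.default_rng(config.seed)
    genome = list(_random_dna(rng, config.genome_length))
    copies: list[RepeatCopy] = []
    taken: list[tuple[int, int]] = []
    min_sep = 3000
    for fi, fam in enumerate(config.repeat_families):
        unit = _random_dna(rng, fam.unit_length)
        for ci in range(fam.copy_number):
            for _attempt in range(1000):
                start = int(rng.integers(
                    min_sep, config.genome_length - fam.unit_length - min_sep))
                end = start + fam.unit_length
                if all(start - min_sep >= e or end + min_sep <= s
                       for s, e in taken):
                    break
            else:  # pragma: no cover - config error
                raise RuntimeError("could not place repeat copies; "
                                   "genome too small for the repeat layout")
            taken.append((start, end))
            mutated = _mutate_subs(rng, unit, fam.divergence / 2.0)
            genome[start:end] = list(mutated)
            copies.append(RepeatCopy(fi, ci, start, end))
    copies.sort(key=lambda c: c.start)
    return "".join(genome), copies


def write_repeats_bed(copies: list[RepeatCopy], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in copies:
            fh.write(f"{GENOME_ID}\t{c.start}\t{c.end}\tfamily{c.family}.copy{c.copy}\n")


# ---------------------------------------------------------------------------
# contigs

def simulate_contigs(genome: str, config: SimulationConfig,
                     copies: list[RepeatCopy],
                     rng: np.random.Generator | None = None,
                     min_contig: int = 200,
                     ) -> tuple[SequenceStore, list[ContigTruth]]:
    """Cut the genome into contigs with coverage gaps.

    When ``drop_repeat_copy`` is set, the last copy of each repeat family is
    removed wholesale (its true region is then absent from the contigs and
    reads over it must be rescued through the surviving copy).  Additional
    gaps totaling ``contig_gap_fraction`` of the genome are placed uniformly
    in the remaining (unique) sequence.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    L = len(genome)
    gaps: list[tuple[int, int]] = []
    if config.drop_repeat_copy:
        by_family: dict[int, list[RepeatCopy]] = {}
        for c in copies:
            by_family.setdefault(c.family, []).append(c)
        for fam_copies in by_family.values():
            if len(fam_copies) >= 2:
                victim = max(fam_copies, key=lambda c: c.copy)
                gaps.append((victim.start, victim.end))
    target_gap = int(config.contig_gap_fraction * L)
    placed = 0
    forbidden = [(c.start, c.end) for c in copies] + list(gaps)
    attempts = 0
    while placed < target_gap and attempts < 10_000:
        attempts += 1
        size = int(rng.integers(100, 1001))
        start = int(rng.integers(0, L - size))
        end = start + size
        if any(start < e and s < end for s, e in forbidden + gaps):
            continue
        gaps.append((start, end))
        placed += size
    gaps.sort()
    contigs = SequenceStore()
    truth: list[ContigTruth] = []
    pos = 0
    idx = 0
    for s, e in gaps + [(L, L)]:
        if s - pos >= min_contig:
            cid = f"contig{idx}"
            contigs.add(cid, genome[pos:s])
            truth.append(ContigTruth(cid, pos, s))
            idx += 1
        pos = max(pos, e)
    return contigs, truth


# ---------------------------------------------------------------------------
# long reads

def simulate_long_reads(genome: str, config: SimulationConfig,
                        rng: np.random.Generator | None = None,
                        ) -> tuple[SequenceStore, TruthTable]:
    """Noisy long reads with per-read truth intervals and error scripts.

    Per truth base, an error occurs with the configured rate; errors are
    insertions, deletions or substitutions in the configured (indel
    dominated) proportions.  Roughly half the reads are
    reverse-complemented.  The recorded error script is the edit script of
    the read (query) against its oriented truth segment (target).
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    lr = config.long_read
    L = len(genome)
    n_reads = max(1, round(lr.coverage * L / lr.mean_length))
    reads = SequenceStore()
    records: dict[str, TruthRecord] = {}
    for i in range(n_reads):
        length = int(rng.normal(lr.mean_length, 0.2 * lr.mean_length))
        length = max(lr.min_length, min(length, L))
        start = int(rng.integers(0, L - length + 1))
        end = start + length
        strand = "-" if rng.random() < 0.5 else "+"
        template = genome[start:end]
        if strand == "-":
            template = revcomp(template)
        seq, ops = _apply_errors(template, lr, rng)
        rid = f"read{i:04d}"
        reads.add(rid, seq)
        records[rid] = TruthRecord(rid, GENOME_ID, start, end, strand,
                                   cg.cigar_string(ops))
    genome_store = SequenceStore({GENOME_ID: genome})
    return reads, TruthTable(records, genome_store)


def _apply_errors(template: str, lr: LongReadConfig,
                  rng: np.random.Generator) -> tuple[str, cg.Ops]:
    n = len(template)
    if lr.error_rate <= 0:
        return template, cg.merge_runs([(n, "=")])
    err = rng.random(n) < lr.error_rate
    kinds = rng.random(n)
    ins_bases = rng.integers(0, 4, size=n)
    sub_bases = rng.integers(0, 3, size=n)
    out: list[str] = []
    ops: cg.Ops = []
    p_ins, p_del = lr.ins_frac, lr.ins_frac + lr.del_frac
    for i, base in enumerate(template):
        if not err[i]:
            out.append(base)
            ops.append((1, "="))
            continue
        k = kinds[i]
        if k < p_ins:
            out.append(BASES[ins_bases[i]])
            ops.append((1, "I"))
            out.append(base)
            ops.append((1, "="))
        elif k < p_del:
            ops.append((1, "D"))
        else:
            alt = [b for b in BASES if b != base][sub_bases[i]]
            out.append(alt)
            ops.append((1, "X"))
    return "".join(out), cg.merge_runs(ops)


# ---------------------------------------------------------------------------
# short reads

def simulate_short_reads(genome: str, config: SimulationConfig,
                         rng: np.random.Generator | None = None,
                         ) -> list[tuple[str, str]]:
    """Accurate short reads (substitution errors only), both strands."""
    rng = rng or np.random.default_rng(config.seed + 3)
    sr = config.short_read
    L = len(genome)
    n_reads = max(1, round(sr.coverage * L / sr.length))
    out: list[tuple[str, str]] = []
    starts = rng.integers(0, L - sr.length + 1, size=n_reads)
    strands = rng.random(n_reads) < 0.5
    for i in range(n_reads):
        seq = genome[starts[i]:starts[i] + sr.length]
        if strands[i]:
            seq = revcomp(seq)
        seq = _mutate_subs(rng, seq, sr.error_rate)
        out.append((f"sr{i:06d}", seq))
    return out


# ---------------------------------------------------------------------------
# truth-guided toy aligner

MIN_PIECE = 30


def toy_align(reads: SequenceStore, contigs: SequenceStore,
              truth: TruthTable, contig_truth: list[ContigTruth],
              copies: list[RepeatCopy],
              identity_floor: float = 0.70) -> list[RawAlignment]:
    """Emit the true alignment of each read region to contig territory plus
    alignments to sufficiently similar repeat copies elsewhere in the
    contigs.

    Candidate intervals come from the recorded truth; the base-level edit
    scripts are recomputed with an edit-distance routine, so the emitted
    alignments are what an ideal sensitive aligner would report.
    """
    out: list[RawAlignment] = []
    for read_id, read_seq in reads.items():
        rec = truth.records[read_id]
        gs, ge = rec.start, rec.end
        ops = cg.parse_cigar(rec.error_script)
        targets: list[tuple[int, int, str, int]] = []  # genome iv -> contig
        for ct in contig_truth:
            ov_s, ov_e = max(gs, ct.start), min(ge, ct.end)
            if ov_e - ov_s >= MIN_PIECE:
                targets.append((ov_s, ov_e, ct.contig_id, ct.start))
        # similar-repeat hits: the homologous interval of every *other* copy
        for c in copies:
            ov_s, ov_e = max(gs, c.start), min(ge, c.end)
            if ov_e - ov_s < MIN_PIECE:
                continue
            for other in copies:
                if other.family != c.family or other.copy == c.copy:
                    continue
                hs = other.start + (ov_s - c.start)
                he = other.start + (ov_e - c.start)
                for ct in contig_truth:
                    ps, pe = max(hs, ct.start), min(he, ct.end)
                    if pe - ps < MIN_PIECE:
                        continue
                    # map back to the read's own genome interval
                    rs_g = c.start + (ps - other.start)
                    re_g = c.start + (pe - other.start)
                    targets.append((rs_g, re_g, ct.contig_id, ct.start,
                                    ps - rs_g))
        for tgt in targets:
            g0, g1, contig_id, ct_start = tgt[0], tgt[1], tgt[2], tgt[3]
            shift = tgt[4] if len(tgt) > 4 else 0
            aln = _emit_alignment(read_id, read_seq, rec, ops, g0, g1,
                                  contig_id, ct_start, shift, contigs,
                                  identity_floor)
            if aln is not None:
                out.append(aln)
    out.sort(key=lambda a: (a.read_id, a.read_start, a.contig_id,
                            a.contig_start))
    return out


def _emit_alignment(read_id: str, read_seq: str, rec: TruthRecord,
                    ops: cg.Ops, g0: int, g1: int, contig_id: str,
                    ct_start: int, shift: int, contigs: SequenceStore,
                    identity_floor: float) -> RawAlignment | None:
    gs, ge = rec.start, rec.end
    # genome positions -> oriented-template offsets -> read positions
    if rec.strand == "+":
        t0, t1 = g0 - gs, g1 - gs
    else:
        t0, t1 = ge - g1, ge - g0
    q0, q1 = cg.project_target_to_query(ops, [t0, t1])
    if q1 - q0 < MIN_PIECE:
        return None
    # the error script's query is the read as stored, so q0/q1 are already
    # forward-read-strand coordinates
    rs, re_ = q0, q1
    seg = read_seq[rs:re_]
    orientation = FORWARD if rec.strand == "+" else REVERSE
    if orientation == REVERSE:
        seg = revcomp(seg)
    cs = g0 + shift - ct_start
    ce = g1 + shift - ct_start
    tseg = contigs.seq(contig_id)[cs:ce]
    res = edlib.align(seg, tseg, mode="NW", task="path")
    aln_ops = cg.parse_cigar(res["cigar"])
    ident = cg.identity(aln_ops)
    if ident < identity_floor:
        return None
    return RawAlignment(
        read_id=read_id, read_len=len(read_seq), read_start=rs, read_end=re_,
        contig_id=contig_id, contig_len=contigs.length(contig_id),
        contig_start=cs, contig_end=ce, orientation=orientation,
        identity=ident, ops=aln_ops)


# ---------------------------------------------------------------------------
# de-novo toy aligner (best-effort; for fixtures without truth)

def toy_align_denovo(reads: SequenceStore, contigs: SequenceStore,
                     k: int = 13, min_seeds: int = 3,
                     identity_floor: float = 0.70,
                     band: int = 150) -> list[RawAlignment]:
    """k-mer seeding + diagonal clustering + edit-distance extension."""
    index: dict[str, list[tuple[str, int]]] = {}
    for cid, seq in contigs.items():
        for i in range(0, len(seq) - k + 1):
            index.setdefault(seq[i:i + k], []).append((cid, i))
    out: list[RawAlignment] = []
    for read_id, read_seq in reads.items():
        for orient, oriented in ((FORWARD, read_seq),
                                 (REVERSE, revcomp(read_seq))):
            hits: dict[tuple[str, int], list[tuple[int, int]]] = {}
            for i in range(0, len(oriented) - k + 1, 5):
                for cid, cpos in index.get(oriented[i:i + k], ()):
                    diag = (cpos - i) // band
                    hits.setdefault((cid, diag), []).append((i, cpos))
            for (cid, _diag), seeds in hits.items():
                if len(seeds) < min_seeds:
                    continue
                q_lo = min(s[0] for s in seeds)
                q_hi = max(s[0] for s in seeds) + k
                c_lo = min(s[1] for s in seeds)
                c_hi = max(s[1] for s in seeds) + k
                seg = oriented[q_lo:q_hi]
                tseg = contigs.seq(cid)[c_lo:c_hi]
                if not seg or not tseg:
                    continue
                res = edlib.align(seg, tseg, mode="NW", task="path")
                ops = cg.parse_cigar(res["cigar"])
                ident = cg.identity(ops)
                if ident < identity_floor:
                    continue
                if orient == FORWARD:
                    rs, re_ = q_lo, q_hi
                else:
                    rs, re_ = len(read_seq) - q_hi, len(read_seq) - q_lo
                out.append(RawAlignment(
                    read_id=read_id, read_len=len(read_seq),
                    read_start=rs, read_end=re_, contig_id=cid,
                    contig_len=contigs.length(cid), contig_start=c_lo,
                    contig_end=c_hi, orientation=orient, identity=ident,
                    ops=ops))
    out.sort(key=lambda a: (a.read_id, a.read_start, a.contig_id,
                            a.contig_start))
    return out


# ---------------------------------------------------------------------------
# one-call fixture

@dataclass
class SimulatedData:
    config: SimulationConfig
    genome: str
    repeats: list[RepeatCopy]
    contigs: SequenceStore
    contig_truth: list[ContigTruth]
    long_reads: SequenceStore
    truth: TruthTable
    short_reads: list[tuple[str, str]]
    alignments: list[RawAlignment]


def simulate_all(config: SimulationConfig) -> SimulatedData:
    """Generate a full study fixture, deterministic under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    genome, copies = simulate_genome(config, rng)
    contigs, contig_truth = simulate_contigs(genome, config, copies, rng)
    long_reads, truth = simulate_long_reads(genome, config, rng)
    short_reads = simulate_short_reads(genome, config, rng)
    alignments = toy_align(long_reads, contigs, truth, contig_truth, copies)
    return SimulatedData(config, genome, copies, contigs, contig_truth,
                         long_reads, truth, short_reads, alignments)


def write_all(data: SimulatedData, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "genome.fa", [(GENOME_ID, data.genome)])
    write_repeats_bed(data.repeats, outdir / "repeats.bed")
    write_fasta(outdir / "contigs.fa", data.contigs.items())
    write_fasta(outdir / "long_reads.fa", data.long_reads.items())
    write_fasta(outdir / "short_reads.fa", data.short_reads)
    with open(outdir / "truth.tsv", "w") as fh:
        for rec in data.truth.records.values():
            fh.write(f"{rec.read_id}\t{rec.genome_id}\t{rec.start}\t"
                     f"{rec.end}\t{rec.strand}\t{rec.error_script}\n")
    write_paf(data.alignments, outdir / "alignments.paf")
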