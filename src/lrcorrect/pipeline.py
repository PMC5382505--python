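"""End-to-end correction pipeline: ingest → split → graph → DP → refine."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .alignments import RawAlignment, filter_alignments
from .correction import CorrectionResult, correct_all
from .graph import ACCURATE, ORDINARY, ContigGraph, build_graph, estimate_coverage
from .refine import DEFAULT_K, DEFAULT_SOLID, RefineStats, refine_regions
from .regions import DEFAULT_DELTA, unify_regions
from .seqio import SequenceStore

log = logging.getLogger(__name__)

MODE_ORDINARY = "ordinary"
MODE_REPEAT_FREE = "repeat-free"


@dataclass
class PipelineOptions:
    mode: str = MODE_ORDINARY
    accurate: bool = True          # orientation-resolved graph (default on)
    delta: int = DEFAULT_DELTA     # boundary merge tolerance (bp)
    coverage: float | None = None  # C0 override; estimated when None
    min_aln_len: int | None = None
    min_identity: float = 0.0
    distant_span: int = 0
    kmer: int = DEFAULT_K
    solid_threshold: int = DEFAULT_SOLID
    refiner: str = "internal"


@dataclass
class PipelineReport:
    n_alignments_in: int = 0
    n_alignments_kept: int = 0
    n_pairs: int = 0
    n_contig_regions: int = 0
    c0: float = 0.0
    n_vertices: int = 0
    n_edges: int = 0
    n_reads: int = 0
    n_reads_corrected: int = 0
    n_repeat_flagged_reads: int = 0
    refine: RefineStats = field(default_factory=RefineStats)


def run_correction(reads: SequenceStore, contigs: SequenceStore,
                   alignments: list[RawAlignment],
                   options: PipelineOptions | None = None,
                   short_reads=None,
                   ) -> tuple[list[CorrectionResult], ContigGraph, PipelineReport]:
    """Correct every read; returns results, the contig graph and counters."""
    opt = options or PipelineOptions()
    if opt.mode not in (MODE_ORDINARY, MODE_REPEAT_FREE):
        raise ValueError(f"unknown mode {opt.mode!r}")
    report = PipelineReport(n_alignments_in=len(alignments),
                            n_reads=len(reads))

    kept = filter_alignments(alignments, min_len=opt.min_aln_len,
                             repeat_free=(opt.mode == MODE_REPEAT_FREE),
                             min_identity=opt.min_identity)
    report.n_alignments_kept = len(kept)
    log.info("alignments: %d in, %d after length/identity filter",
             len(alignments), len(kept))

    region_set, pairs = unify_regions(kept, opt.delta)
    report.n_pairs = len(pairs)
    report.n_contig_regions = len(region_set)
    log.info("splitting: %d aligned pairs over %d unified contig regions",
             len(pairs), len(region_set))

    c0 = opt.coverage if opt.coverage is not None else estimate_coverage(pairs)
    mode = ACCURATE if opt.accurate else ORDINARY
    graph = build_graph(pairs, mode=mode, c0=c0, delta=opt.delta)
    report.c0 = c0
    report.n_vertices = len(graph.vertices)
    report.n_edges = graph.n_edges()
    log.info("graph: %d vertices, %d edges, C0=%.2f (%s mode)",
             report.n_vertices, report.n_edges, c0, mode)

    results = correct_all(reads, contigs, pairs, graph,
                          delta=opt.delta, distant_span=opt.distant_span)
    report.n_reads_corrected = sum(1 for r in results if r.steps)
    report.n_repeat_flagged_reads = sum(
        1 for r in results if r.n_repeat_flagged)
    log.info("correction: %d/%d reads corrected, %d with repeat-flagged regions",
             report.n_reads_corrected, len(results),
             report.n_repeat_flagged_reads)

    if opt.mode == MODE_ORDINARY and short_reads is not None:
        results, refine_stats = refine_regions(
            results, short_reads=short_reads, k=opt.kmer, mode=opt.mode,
            solid_threshold=opt.solid_threshold, reads=reads,
            refiner=opt.refiner)
        report.refine = refine_stats
        log.info("refinement: %d/%d flagged regions re-threaded",
                 refine_stats.regions_refined, refine_stats.regions_seen)
    return results, graph, report
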