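# Methods

This note documents the model implemented by `lrcorrect`, the choices made
where the method leaves room, and what the synthetic studies do and do not
demonstrate.

## Model and assumptions

The corrector assumes a short+long read hybrid project: accurate short
reads (assembled into contigs/scaffolds) and noisy long reads from the same
sample. Long-read errors are assumed approximately uniform along the read
and indel-dominated; this uniformity is what licenses the throughput-based
extrapolation in the evaluation estimators (`EI = (TP+FN)/TH` etc.).
Similar repeats are genome regions differing by less than 15% from a read
region's true region; at a read error rate near 15%, an alignment to such a
repeat is about as good as one to the true region, which is why a
permissive identity floor recovers candidates for regions whose true
region is absent from the contigs.

## Region unification

The splitting rules are stated pairwise (two overlapping aligned contig
intervals are cut at each other's boundaries; read intervals follow through
the edit scripts), but on real inputs cuts propagate: a contig cut induces
read cuts on every read aligned across it, and those induce cuts on *other*
contigs via each read's other alignments (notably similar-repeat copies).
`unify_regions` therefore iterates boundary collection, δ-merging
(single-linkage, smallest member as representative) and projection to a
fixpoint, then slices every alignment at the canonical cut positions.

Two details matter for exactness:

* Pair coordinates are kept exactly consistent with their edit scripts:
  when a piece's outer endpoints are snapped (< δ movement) to canonical
  representatives, the script is refitted (leading-deletion padding,
  trailing-column trimming) rather than left stale.
* A single splitting pass is not a fixpoint of its own output: δ-clusters
  computed over the full grown boundary set can chain further than clusters
  over the emitted endpoints alone. The driver therefore re-applies the
  splitting to its own output until the emitted pairs stabilise, which
  makes the published result exactly idempotent under re-splitting. With
  δ = 0 and heavily overlapping opposite-orientation alignments the inner
  propagation can cascade one base per round before saturating; the round
  caps are sized for that worst case.

Boundary projection places a cut that lands against a read-insertion run at
the start of the run, so inserted bases are never divided between two
regions. Sub-pairs left with no read bases are dropped.

## Graph construction and support counting

Vertices are the unified contig regions, doubled per orientation in
accurate mode (default). Adjacency edges (weight 0) join abutting split
regions of one contig with the same orientation on both endpoints —
traversing a contig in one direction preserves orientation. Support edges
get `max(C0 − C, 0)`.

How a multi-candidate region contributes to `C` is the one genuinely open
point of the weighting. Counting *every* candidate combination of two
adjacent read regions would give the true junction and the repeat junction
identical support (every read with a repeat hit increments both), leaving
the long-read-support idea with nothing to decide. `lrcorrect` counts a
candidate pair (j, k) of adjacent regions only when j and k come from the
same original alignment, or from two alignments that do not overlap on the
read beyond δ. Overlapping alignments of one read are rival
interpretations of the same territory, not a chain; a similar-repeat hit
covers the same read bases as the true-region hit and so never generates
adjacency evidence of its own. A read contributes at most one count per
edge. Each read's own chain thereby always creates its edges, which keeps
the read's observed alignment chain feasible in the DP.

`C0` is estimated as total aligned contig-region bases over the union of
aligned contig intervals (mean depth over covered bases), overridable with
`-coverage`.

## Correction DP

`T(1,j) = 0` for every first-region candidate (the recurrence only defines
transitions; a uniform zero start is the neutral completion). Transitions
exist only along graph edges. The objective is lexicographic: minimise
total weight, then maximise the sum of candidate alignment identities
(both additive, so the DP stays exact); any remaining tie falls to the
lexicographically smallest vertex key at each step, making results
deterministic. If no edge joins any candidates of two consecutive regions
(possible only when a degenerate sliver was dropped during splitting), the
DP re-seeds from the best previous state with a gap penalty of `C0`, so
exactly one candidate per region is always chosen — a global shortest path
that skipped a read region would not describe the read.

Consecutive chosen steps whose contig regions are distant — different
contigs, or the same contig with a gap above `--distant-span` (default 0)
and no adjacency edge — are flagged repeat-corrected, the conservative
reading of "distant" given that no threshold is stated anywhere. Steps
separated on the read by more than δ unaligned bases are not adjacent and
trigger no flag. Note this flags genuine cross-contig junctions too; for
those the subsequent refinement is a cheap no-op confirmation.

## Refinement

Only bases labeled repeat-corrected, plus a k−1 margin, may change. Within
each flagged run the refiner finds the nearest solid k-mer (k = 25, count
≥ 2 in the canonicalised short-read spectrum) on each side and searches a
solid-k-mer path between the anchors, extending base by base with bounded
branching. "Branching" is counted as branch events (positions with more
than one solid extension), not total extensions — a 1 kb region needs over
a thousand linear extensions, so a budget counted in nodes would forbid
exactly the regions the stage exists for; the budget is 200 branch events
per search.

Because the similar repeat is itself part of the genome, its k-mers are
solid too; wherever the two copies share a full (k−1)-window the graph
walk can switch copies, and the spectrum alone cannot arbitrate. The
search is therefore run twice (branch preference following / avoiding the
current sequence) and the completed path closest in edit distance to the
*original read bases* for the region — a noisy but unbiased witness of the
true copy — is spliced in. Successfully refined bases are relabeled
corrected; failed searches leave sequence and flag untouched, visible
downstream. Repeat-free mode skips the stage entirely (and drops
alignments under 300 bp up front, so similar repeats are not used at all).

The refiner is pluggable: an external LoRDEC-style binary can be invoked
per flagged region instead of the internal spectrum refiner; per-region
splicing honours the guarantee that unflagged bases are never modified.

## Outputs

Repeat-corrected bases that survive refinement un-rewritten still count as
corrected for trimming and splitting: they were corrected with a contig
region (just a similar one) and measurably sit near the true sequence,
unlike bases no contig region ever covered. FASTA is written at 80
columns; split pieces are `<read>.<n>` so evaluation can trace a piece to
its initial read.

## Evaluation conventions

Initial-error positions are derived by aligning the initial read to its
truth sequence with the same edit-distance routine (edlib, target-infix
mode) used for the corrected pieces, not by replaying the generative error
script: alignment-level ambiguity (e.g. clustered errors re-explained as
indels) then cancels between the two classifications, and a null corrector
scores exactly sensitivity = gain = 0, specificity = 1. Indels: a deleted
truth base counts FP if initially correct and FN if initially an error;
output insertions count FP except where they persist initial insertions
(FN); removed initial insertions count TP. Junction bookkeeping uses each
piece's leading junction so adjacent pieces never double-count.

A reference-alignment mode (`alignment_stats_from_sam`) computes alignment
ratio / identity / genome fraction from a reads-vs-genome SAM for real
data; it is not on the synthetic test path.

## Synthetic studies

The generator plants repeat families as copies independently mutated from
a common unit at half the family divergence (pairwise difference ≈ the
configured divergence, substitutions only), drops the last copy of each
family from the contigs plus ~5% of unique sequence as uniform gaps, and
draws reads with per-base errors split 45/40/15 insertion/deletion/
substitution — an indel-dominated mix typical of the platform, configurable.
Half the reads are reverse-complemented. Short reads carry 0.5%
substitution errors at 40×.

The default study conditions: 100 kb genome, one 2-copy 1 kb family at 4%
divergence, 20× long reads of mean 8 kb at 15% error. The truth-guided
aligner emits the true alignment of every read region plus hits to every
sufficiently similar repeat copy present in the contigs (identity floor
0.70) with edlib-computed edit scripts — the multi-candidate tables the
graph and DP must disambiguate. A de-novo k-mer seed-and-extend aligner
exists for fixtures without truth; it is best-effort and not used in the
acceptance studies.

What passing these studies shows: the splitting, weighting, DP, rescue and
refinement machinery behave as specified under realistic error structure.
What they do not show: performance under real aligner artefacts (chimeric
hits, clipped repeats, mapping-quality quirks), non-uniform error profiles,
heterozygosity, or genome scales where memory and speed dominate; the
per-base Python/edlib pipeline is built for method fidelity at study
scale, not for production genome sizes.

## Known limitations

* Single-linkage δ-merging is order-free but can chain boundaries across
  more than δ in dense regions; the fixpoint driver makes the result
  stable, not chain-free.
* The internal refiner handles substitution-divergent repeats well; highly
  indel-divergent repeats enlarge the search space and more often hit the
  branch budget (the region then keeps its repeat-derived sequence and its
  flag).
* Support counting assumes alignments of one read that overlap on the read
  are alternatives; a genuinely duplicated read segment (e.g. a chimeric
  read) would be under-counted, by design.
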