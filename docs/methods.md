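# Methods

This note documents the models, algorithms and numerical choices behind
`concatseq`, and what its synthetic benchmarks do and do not show about
real sequencing data.

## The problem

16S rRNA gene amplicon profiling reads a marker region with paired-end
reads (R1 forward, R2 reverse). When the amplicon is short enough, the
two reads overlap at their 3' ends and can be *merged* into the full
amplicon sequence; pairs that fail to merge are conventionally
discarded, which deletes long-amplicon organisms from the profile.
*Concatenation* keeps those pairs by appending the reverse-complemented
R2 directly to R1. The resulting artificial sequence duplicates the
overlap (if any) or omits the unsequenced middle, so it is only useful
if the downstream classifier tolerates that structure — which is exactly
the trade-off this package makes measurable.

## Read preparation

**Primer removal.** Primers are located with banded edit-distance
alignment (edlib, infix mode) with IUPAC degeneracies declared as
character equalities. A match is accepted up to
`floor(max_error_rate × primer_length)` errors, mismatches and indels
counted equally; the default rate is 0.10. The prefix through the match
is removed. Among co-optimal alignments the leftmost occurrence wins,
and at that position the span closest to the primer length (the
no-indel interpretation) — a convention needed because banded alignment
reports several co-optimal end points on repetitive primers. Reads
without a match are passed through and flagged rather than dropped.
When a 3' trimming regime is active it runs *before* primer removal.

**Length trimming (`L`).** The library's per-position median Phred
score is computed (per-position score histograms; even-count medians
are the mean of the two middle values — a convention this package fixes
because quality-plot tools rarely state one). Moving 5'→3', the first
position at which the median falls below Q20 is the retained length,
*including* that first below-threshold base; if the median never dips,
all bases are kept (length 0 = no trim). Explicit per-mate lengths can
override the derived ones (`TrimSpec`), mirroring how published
analyses occasionally pin trim positions for comparability with earlier
studies. Every read of the library is cut at the same position, which
keeps identical template sequences identical after trimming.

**Quality trimming (`Q`).** Each read is trimmed individually at the 3'
end by the partial-sum algorithm used by BWA and cutadapt: scanning
from the 3' end, accumulate `threshold − q_i` and cut at the position
where the running sum is maximal and positive. Ties resolve to the
longest retained prefix (trim least). The test suite checks this
against a brute-force search over all suffix cut points. Reads may be
emptied; zero-length reads stay in the stream and are removed by the
minimum-length-1 rule at filtering/writing time.

## Joining

**Overlap model.** Merging considers every ungapped offset that aligns
the 3' end of R1 with the 5' end of the reverse-complemented R2,
including full containment, with overlap ≥ `min_overlap` (default
20 bp, the conventional minimum for paired 16S merging). Each offset is
scored `matches − mismatches`; the best score wins and ties resolve to
the longest overlap (shortest assembly), so error-free pairs always
reconstruct the true amplicon when it is repeat-free. The winner is
rejected if its overlap identity falls below `min_overlap_identity`
(default 0.9). The published comparisons delegate merging to an
external assembler "with default parameters"; the scoring, identity
threshold and consensus rules here are this package's own contract,
chosen for determinism and oracle-testability rather than
bit-compatibility with any particular assembler. The offset scan exits
early once no remaining (shorter) overlap could beat the incumbent
score, which makes merging linear in practice for overlapping pairs.

**Consensus.** In the overlap, the base with the higher Phred score
wins (R1 on ties); consensus quality is `min(q1 + q2, 93)` where the
bases agree and `|q1 − q2|` where they disagree.

**Concatenation.** `R1 + revcomp(R2)` with qualities concatenated and
reversed accordingly; no spacer, no overlap detection, no loss. `Bp`
emits the merge result when merging succeeds and the concatenation
otherwise, so exactly one joined read leaves per input pair; `Cs`
concatenates unconditionally.

## Variants

Reads are filtered in the order: truncate at the first base with
quality ≤ `truncQ` (default 2); drop if shorter than `min_length`
(default 1); drop if more than `maxN` ambiguous bases (default 0); drop
if expected errors `EE = Σ 10^(−Q/10)` exceed `maxEE` (default 2).
Dereplication then collapses identical sequences into variants
identified by the MD5 of the sequence — a deliberately simple,
reproducible stand-in for denoised amplicon sequence variants.
Denoising and chimera removal are external-tool internals and out of
scope; the simulator compensates by keeping error rates low enough that
exact variants dominate, which means the variant *counts* here are
optimistic relative to a denoiser on noisy real data, while the
presence/absence genus sets the evaluation uses are robust to that.

Abundance filtering removes variants whose proportional abundance is
*strictly below* the threshold (ties survive), with the proportion
computed against the pre-filter total so the operation is
order-independent and monotone across a threshold sweep
(`0, 0.01%, 0.05%, 0.1%, 0.5%, 1%`). Phix-spike removal is not
implemented: synthetic and mock amplicon data contain none, and
supporting it would require bundling a genome.

## Evaluation

Lineages arrive as semicolon strings in Greengenes (`k__…g__`), SILVA
(`D_0__…D_5__`) or plain positional dialects. Genus names are
standardized before scoring: a genus is *unknown* when empty, equal to
its family name, containing any digit (the operationalization of
"strain numbers" in curation practice), or containing any of a fixed
ambiguous-token list (`UCG`, `NK`, `group`, `of`, `soil`, `clade`,
`env`, `genus`, `candidatus`, `species`, `subsp`, `subgroup`, `subsec`,
`marine`, `lineage`, `metagenome`, `mitochondria`, `R1`, `chloroplast`,
`Incertae`, `NA`) as a case-insensitive whole word — word-boundary
matching so that e.g. `R1` or `of` never fire inside legitimate names.
A user-supplied synonym map then renames aliases (e.g.
`Escherichia-Shigella → Escherichia`) to the mock's nomenclature.
Standardization is idempotent at the genus-name level. Non-bacterial
kingdoms are dropped (case-insensitive), `unknown` never enters the
detected set, and detection is presence/absence (set semantics).

`precision = TP/(TP+FP)` (defined 0 when nothing is detected),
`recall = TP/(TP+FN)` (at least one expected genus is required),
`F = 2PR/(P+R)` (0 when both are 0). Genus comparison is
case-insensitive exact matching after standardization; no fuzzy
matching. Shannon diversity uses the natural log (`H = −Σ p ln p`) and
Pielou's evenness `J = H/ln S`, with `J = 1` by convention for a
single-genus community.

## The simulator

The simulator defines the study conditions under which the package's
claims are tested:

- **References.** One amplicon per genus: a uniform-random core flanked
  by the 515F/806R primer sites (degenerate positions instantiated per
  genus), rejection-sampled so all pairwise identities (global edit
  distance) stay below 80%. Random cores rather than real 16S
  sequences keep the repository download-free and guarantee the toy
  classifier's separability; a real reference FASTA can be supplied to
  the comparison tools instead. Genus names are synthetic and
  digit-free so they survive nomenclature standardization.
- **Composition.** Balanced mocks are uniform; unbalanced mocks follow
  a geometric series (`∝ skew^rank`, default skew 0.5), a simple stand-in
  for vendors' staircase designs. Optional contaminants sit at a trace
  abundance (default 0.004%, the regime abundance thresholds are meant
  to clean up). Read counts are allocated by largest-remainder rounding
  of the composition — a mock community *is* a fixed composition, and
  deterministic allocation keeps the truth sharp; contaminants always
  receive at least one read. Read order is then shuffled.
- **Reads.** R1 is the template's first `read_length` bases, R2 the
  first `read_length` bases of the reverse complement, so pairs overlap
  iff the template is shorter than twice the read length. Per-position
  quality follows `Q(p) = q_start − (q_start − q_end)(p/read_length)^s`
  (defaults 38 → 23, shape 3, matching the late-cycle decay of 2×250
  MiSeq libraries) with R2 lowered by 4, emulating the R1/R2 quality
  asymmetry of the platform. Substitutions are drawn per base at
  `10^(−Q/10)` to a uniformly random other base; indels are not
  simulated (substitutions dominate MiSeq error and suffice to exercise
  expected-error filtering and merge mismatch handling). An explicit
  switch disables substitutions for oracle tests that require
  error-free reads. One seeded generator drives everything.
- **Toy classifier.** A variant found verbatim in a reference (either
  strand) takes that genus; otherwise genera are ranked by k-mer cosine
  similarity (k = 8), scoring each variant both whole and as the mean
  of its two halves so concatenated variants — whose halves match the
  reference even though the junction does not — are recovered. Below a
  0.7 similarity floor the variant is left genus-less and scores as
  unknown. This stands in for database-backed naive-Bayes
  classification, which needs trained reference classifiers and is out
  of scope.

What the simulator does **not** emulate: chimeras, indel errors,
length variation within a genus, real 16S sequence similarity
structure, and database-vs-database disagreements. Passing benchmarks
therefore demonstrate the correctness and the structural claims of the
read-preparation machinery (conservation, rescue of non-overlapping
pairs, threshold behaviour), not classifier accuracy on real
communities.

## Pipelines

Codes combine `{N, L, Q}` trimming with `{Mp, Bp, Cs, R1, R2}` joining;
quality trimming is not combined with single-end modes. Codes ending in
`Md` (merging inside the external denoiser) are recognised and rejected
with an explanation rather than imitated. Stage order is: 3' trim →
primer removal → join → filter → dereplicate, with every stage counted
in a `StageReport` that reconciles input to output. `L` derives its
trim lengths from the input library's quality profile unless explicit
lengths are given. Runs are deterministic for fixed inputs, and the
benchmark table (`compare_pipelines`) emits one long-format row per
pipeline × mock × threshold plus mean rows across mocks.

## Problem sizes

The shipped tests and the acceptance script use 300–4,000 pairs for
pipeline-level checks, 10,000 pairs for the conservation count, and
50,000 pairs for the contaminant-threshold experiment (the smallest
library in which a 0.004% contaminant is still guaranteed reads while
sitting strictly below the 0.01% threshold). These sizes make every
claim measurable in seconds on one CPU while leaving the mechanisms
identical at larger depth.

## Known limitations

- Exact dereplication inflates variant counts on noisy data relative
  to a denoiser; evaluations here are presence/absence at genus level,
  which absorbs most of that.
- The merge consensus and identity threshold are this package's
  contract, not a reimplementation of any specific assembler.
- Single-sample thresholding only: the abundance threshold applies per
  table (per mock per pipeline), not per constituent sample.
- The toy classifier's similarity floor (0.7) is tuned for the
  simulator's <80%-identity references; real 16S genera are far more
  similar and need a real classifier.
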