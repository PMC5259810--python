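# Methods

This note documents the models and procedures implemented in `ssutag`,
the tunable parameters and their defaults, what the synthetic-data
generator does and does not emulate, and the numerical choices made
where the design was genuinely open.

## Detection model

A recognition profile detects the conserved 23-nt recognition sequence
(RS) flanking one SSU hypervariable region.  Detection is two-staged:

1. **Probe prefilter.**  A degenerate IUPAC pattern over the most
   conserved run of ≥ 8 columns inside the RS window.  A position on a
   read is a candidate when the pattern matches with at most
   `probe_mismatches` mismatches (default 1; `None` disables the
   prefilter).  Bases enter the degenerate code when their training
   frequency is ≥ 5%; a position admitting all four bases collapses to
   `N`.  The prefilter is purely an accelerator: with the budget
   removed, scan results equal the exhaustive PSSM scan, and at default
   settings its measured sensitivity cost on default synthetic data is
   below 1%.
2. **PSSM confirmation.**  Additive log-odds score, base 2, against a
   uniform background with pseudocount 0.5:
   `M[i][b] = log2((c_ib + 0.5) / (N_i + 2) / 0.25)`, where `N_i`
   counts non-gap bases at window position `i`.  All-gap positions
   score zero; `N` in a read scores the column minimum (worst case).
   A site is confirmed when the window score reaches the profile
   threshold.

Both read orientations are scanned.  Profiles are stored *anchored*:
the PSSM reads the RS so that the tag always lies immediately 3' of it
in scan orientation.  For an upstream-side RS this equals gene sense;
for a downstream-side RS it is the reverse complement of gene sense.
This makes tag extraction orientation-free, guarantees that the long
sequence always begins with the tag, and lets forward and reverse reads
of the same locus aggregate to the same tag string.  When several
profiles for one region hit a read, only the highest-scoring site is
kept (ties: lexicographic profile id, then forward orientation, then
leftmost position).

## Profile training

* **Window placement.**  The nominal RS window is the 23 columns
  immediately flanking the region's alignment interval; a ±5-column
  search selects the placement minimizing mean column entropy (gaps
  excluded from denominators; all-gap columns count 2 bits).  Ties
  prefer the nominal placement.  Construction fails when the best
  window's mean entropy exceeds `max_mean_entropy` (default 1.5 bits) —
  a flank that diverged that far is not a usable recognition site.
* **Threshold calibration.**  The threshold comes from a sensitivity
  sweep over training-site scores, with three refinements that matter
  in practice:
  * *Leave-one-out scoring.*  Scoring a sequence against a matrix whose
    counts include that sequence is optimistically biased — about half
    a bit per rare base — which at n = 400 inflated apparent training
    sensitivity by several points and produced thresholds that
    over-shot on unseen data.  The sweep therefore uses scores with the
    sequence's own counts removed.
  * *Recognizable sites only.*  Training sites scoring below 0 bits
    (worse than background odds, e.g. a divergent clade with its own
    flank) are excluded from the sweep; otherwise a handful of such
    sequences drags the quantile threshold toward zero and the profile
    stops discriminating.  Divergent clades are instead served by
    supplementary profiles (below).  `training_sensitivity` in profile
    metadata is reported over recognizable sites, alongside
    `detectable_fraction`.
  * *Cluster-aware placement.*  True-site scores cluster by the number
    of diverged positions (each costs ~5–9 bits), so a raw quantile can
    land inside a cluster and split it, making the threshold unstable
    across training samples.  After the sweep finds the largest
    threshold retaining ≥ `target_sensitivity` of the (leave-one-out,
    recognizable) scores, the threshold relaxes down to the middle of
    the first score gap of ≥ 2 bits, i.e. between clusters.  Training
    sensitivity can only increase in this step.

  The default `target_sensitivity` is 0.98 rather than the 0.95 design
  goal itself: with a few hundred training sequences an exact-95%
  quantile makes sensitivity on unseen sequences a coin flip around
  95%, while the specificity budget (≤ 2×10⁻⁶ false positives per
  80-nt fragment) retains orders of magnitude of headroom at the lower
  threshold, so the margin is essentially free.
* **Supplementary taxon-specific profiles.**  After the universal
  profile is built, any phylum whose members miss its threshold at a
  rate above `miss_rate` (default 5%) and that has ≥ 2 members gets a
  profile trained on that phylum alone (`scope` = phylum label).  This
  is the same machinery applied to a taxon subset.

## Tag quantification and the error model

Per sample and tag: `n` = reads containing the tag; `npos` = distinct
RS offsets on reads in reported orientation (read literally as "number
of different locations of the tag on their source reads"; a large `n`
with small `npos` is the PCR-duplicate signature); the three most
abundant 60-nt long variants are tracked, ties broken lexicographically.
Paired-end mates count as independent observations by default; an
optional flag collapses same-tag observations sharing a read name.

`fp` estimates the abundance a tag would show *if it were absent*, from
single sequencing errors in its 1-nt neighbours: each observed
neighbour contributes `E = n × e/3`, with `e` the per-position mean of
the Phred-implied error probabilities over all observations in the
sample (FASTA input falls back to a configurable constant, default
0.001 — the Q30 filtering level).  Only observed neighbours contribute;
multiple-error paths are neglected, which the per-base Q30 gate
justifies.  `fp` is reported, never subtracted: the package does not
denoise or merge tags.

The generative validation inverts this model: simulating reads from a
single tag at per-base error `e`, a specific 1-nt variant arises when
its position erred to that base *and* no other tag base erred, i.e.
`Binomial(n_detected, (e/3)(1−e)^(L−1))`.  At the scale used
(10⁶ reads) the `(1−e)^(L−1)` factor is a 0.6σ effect and is kept; tag
errors are independent of RS detection, so the binomial `n` is the
number of reads that actually yielded an observation.

## Annotation and concordance

The reference index is built by scanning each unaligned reference
sequence exactly like a read (no quality gate), keying tags and long
sequences to `(seq_id, lineage)`.  Annotation looks the long sequence
up first (longer context is more specific; the `use` field records
which succeeded), then walks kingdom→species taking the modal label at
each rank among matching sequences.  Labels are emitted while the modal
fraction is ≥ `min_confidence` (default 0.5) and the mode is unique;
ties stop the walk, leaving deeper ranks unannotated.  Empty labels are
treated as missing and excluded from denominators.  `confidence` at the
emitted rank coincides by construction with the tag's *concordance* at
that rank (modal-label fraction among its reference sequences);
concordance histograms use the exact bin {1} first, then [0.95, 1),
[0.90, 0.95), …

## Synthetic data generator

References are laid out as 10 conserved and 9 variable blocks
(defaults: 30 nt and 50 nt), mirroring the SSU gene's alternating
architecture; the trivial equal-length layout doubles as the alignment.
Conserved blocks are a master template mutated independently per taxon
at `conserved_mut_rate` (default 1% — recognition-site windows in real
SSU data are near-universally conserved, which is what makes universal
primers and universal profiles possible).  Variable blocks evolve down
the lineage tree, one substitution round per rank step at
`variable_diversity` (default 10% per edge), so sequence similarity
tracks taxonomic relatedness.  Lineages are 7-rank paths from recursive
splitting by configurable branching factors, species unique per taxon.

Reads are sampled uniformly along the references with abundance
weighting, substitution errors i.i.d. at `per_base_error`, and a
constant Phred string consistent with the simulated rate
(Q = −10·log₁₀ e), so quality-gate behaviour is meaningfully testable.
Half the reads are reverse-complemented.  A faux-read mode emits
fixed-length non-overlapping (or random-composition) non-SSU fragments
for false-positive estimation.

What the generator does **not** emulate: indels and chimeras, rRNA
secondary-structure covariation, platform-specific quality profiles
(quality varies per position and read in real data), copy-number
variation, and real phylogenetic rate heterogeneity.  Passing tests
therefore demonstrate correctness of the algorithms under the stated
generative assumptions, not performance on any real dataset; in
particular the substitution-only error model matches the package's own
quantification model by construction.

## Problem sizes and numerical choices

The validation experiments use: 400 training + 200 held-out references
for sensitivity; 10⁷ random 80-nt fragments for the false-positive
rate; 10⁶ covering reads at e = 0.001 for the error model; a 20-taxon
error-free community (geometric abundances, ratio 0.85) for end-to-end
recovery and abundance correlation.  All randomness flows from a single
integer seed through `numpy.random.default_rng`; identical seeds give
byte-identical outputs (BIOM files carry a fixed date string for this
reason).  Alignment columns are 0-based half-open throughout.  Tags
containing `N` are discarded; a malformed read (quality length
mismatch) is rejected and counted, never fatal.  Scan accounting
satisfies `reads_in = reads_hit + reads_no_hit` and
`observations = hits − length_filtered − quality_filtered`.

## Known limitations

* Universal profiles are as good as their training alignment; heavily
  gapped or mis-annotated region boundaries degrade the window search
  (the ±5 shift absorbs small misplacements only).
* The error model considers substitutions at Hamming distance 1 only;
  indel-induced artifacts are invisible to it.
* Majority-vote annotation has no lowest-common-ancestor fallback: a
  50/50 split at a rank leaves the tag unannotated at and below it.
* `merge_samples` on mate *tables* sums `npos` (capped at `n`) because
  offsets are no longer available at table level; the CLI pools mate
  observations before aggregation and computes `npos` exactly.
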