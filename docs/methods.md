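# Methods

## Split-read realignment

The unit of evidence is the mapped-unmapped read pair (MUR): a pair in
which the first-pass mapper placed exactly one mate.  The mapped mate
anchors a realignment window of `window` (default 5,000) bp —
downstream of a forward-strand anchor, upstream of a reverse-strand
one, clipped at chromosome ends rather than dropped.  Assuming an FR
library, the unmapped mate is reverse-complemented into reference
orientation for a forward anchor and used as-is for a reverse anchor.
Anchors may carry mismatches and may be multiply placed; a multi-placed
anchor spawns one window per placement.  Pairs whose every anchor
placement lies inside the optional BED mask (intended for centromeres
and similar repeat sinks) are discarded.

### Alignment model

The mate is aligned inside the window with an exact affine-gap local
dynamic program (three matrices: aligned, gap-in-read, gap-in-
reference) in O(mn).  Scores: match +5, mismatch −4 (the NUC4.2
nucleotide values reduced to match/mismatch; anything outside A/C/G/T,
including N, scores as a mismatch), gap open −10, gap extension 0.
The zero extension cost is what lets a single gap run span an
arbitrarily long deletion for one fixed opening charge; it also makes
each row of the gap-in-read matrix a running maximum, which is how the
DP is vectorised.

Local alignments begin and end with an aligned column: an alignment
that started or ended inside a gap could be trimmed at no cost, and a
signature must be bracketed by aligned fragments anyway.  Every
co-optimal traceback is enumerated (fixed predecessor order: aligned,
gap-in-read, gap-in-reference, so output order is deterministic) and
deduplicated.  A read with more than `max_alignments` (default 10)
co-optimal placements is dropped as unalignably ambiguous; strictly
suboptimal alignments are not enumerated.

### Near-best filtering

An alignment is kept while its accumulated penalty

    4 · n_mismatch + 10 · n_gap_open ≤ 30

(the absolute values of the mismatch and gap-open scores against the
`max_penalty` budget).  This single budget admits up to 7 mismatches
or up to 3 gap openings, or mixtures in between.  The budget, not a
score-offset-from-optimum rule, is used because the two formulations
disagree under this matrix and only the budget reproduces both quoted
tolerances simultaneously.

### Signatures and candidates

A run of ≥ `min_gap_run` (default 2) consecutive gap columns is an
indel signature — gap-in-read runs are deletions (length = reference
bases spanned), gap-in-reference runs are insertions (length = read
bases, with the inserted sequence recorded).  Both flanking read
fragments must be ≥ `min_fragment` (default 8) bp; shorter fragments
align promiscuously and carry no placement information.  Signatures
are lifted to reference coordinates and grouped by exact location:
(chrom, kind, start, length), plus the inserted sequence for
insertions.  A group becomes a candidate when it is supported by at
least `min_support` (default 2) **distinct read ids** — the same read
seen through several co-optimal alignments or anchor placements counts
once.  Candidate length filters default to [2, 5,000] bp; the upper
bound is the window size, which caps detectable deletion length.

## Feature vectors

Deletions get 17 features in four groups, insertions the 13 of groups
2–4 (coverage inside a zero-width insertion point is undefined), and
`f1` is the support count alone.  Read-uniqueness calls: a first-pass
read is a UMR iff the mapper reported a single placement with mapping
quality ≥ 1, else an N-UMR; placements are grouped per physical read
(query name **and** mate number — both mates share the SAM qname).

1. Within-deletion coverage: `n_umr_within`, `n_numr_within`,
   `frac_zero_umr_within` (fraction of deleted positions with zero UMR
   depth), `ratio_umr_within_to_flank`
   (= n_umr_within / (1 + mean of up/down UMR counts)).
2. Flank coverage over `flank` (default 60, roughly one read length)
   bp on each side: `n_umr_up`, `n_umr_down`, `n_numr_up`,
   `n_numr_down`.
3. Single-position-variant concordance between the two passes within
   the candidate ± flank.  First-pass SPVs are positions where ≥ 2
   reads overlap and a strict majority carries the same non-reference
   allele; short first-pass indels are expanded position-wise (each
   deleted base as `(pos, "-")`, an insertion as `(pos, "+")`).
   Split-read SPVs are the mismatch columns and length-1 gap columns
   of the candidate's supporting alignments.  Features:
   `n_spv_concordant` (same position and allele), `n_spv_first_only`,
   `n_spv_split_only`, `n_spv_discordant` (same position, different
   allele), `frac_concordant` (concordant / union, 0 on empty union).
4. General: `indel_length`, `n_support`,
   `n_distinct_anchor_positions`, `mean_penalty` (mean accumulated
   alignment penalty of the supporting split reads).

The itemisation within the four groups is this package's own
committed enumeration; the group structure and counts (4+4+5+4 = 17,
17 − 4 = 13) are fixed and versioned with the feature-table format.

## Classifier

A soft-margin linear C-SVM (libsvm via scikit-learn's `SVC`) on
features min–max normalised to [0, 1].  Normalisation bounds are fit
on training data only; prediction-time values outside the bounds are
clipped, and constant training columns map to 0.  Decision value
w·x + b, with 0 classified positive.  Defaults when not
cross-validated: C = 10 for deletions, C = 0.10 for insertions.

Metrics: AUC via the Mann–Whitney rank statistic with ties averaged;
Spec-Sens-BEP as the true-positive rate at the threshold-sweep point
minimising |TPR − TNR| (lower threshold on ties — finite samples
rarely achieve exact equality).

Model selection is a repeated nested stratified cross-validation:
outer k-fold (defaults: k = 10 deletions, k = 5 insertions; 100
repeats), inner k-fold on each outer training set choosing C from the
decade grid 10⁻⁵…10⁵ by maximal mean inner BEP (largest C on ties);
the model is refit on the outer training set with the chosen C, outer
test scores are pooled per repeat into one AUC and one BEP, and the
report carries mean ± sd over repeats.  Pooling (rather than per-fold
averaging) keeps the estimate defined on insertion-sized corpora where
a single fold may hold only a handful of examples.  One integer seed
drives all fold shuffling.  libsvm iterations are capped at 10,000 per
fit: at extreme C on label-noise data the solver creeps toward an
interior optimum indefinitely without materially changing the decision
function.

## Cohort stage

Per-strain positive calls are merged within (chrom, kind, length)
groups by single-linkage chaining of starts within `merge_shift`
(default 10) bp; the representative start is the member median.  The
indel matrix encodes +1 (carried deletion), −1 (carried insertion), 0
(absent) over non-private indels (frequency ≥ 2); columns are mean-
centred (no variance scaling) and the strain covariance eigen-
decomposed via SVD.  Explained-variance fractions are eigenvalues over
the trace and sum to one.

Whole-gene loss: a deletion spanning an entire gene qualifies iff
≥ 90 % of the positions inside the deletion have zero UMR depth and
≥ 90 % of the positions of each deletion-length-sized flank are UMR-
covered (thresholds apply proportionally to flanks clipped at
chromosome ends).  Frame effect: an indel overlapping a CDS interval
is in-frame iff length mod 3 = 0, else a frameshift; non-overlapping
indels are non-coding.  Each indel is judged alone, ignoring possible
compensating variants nearby.

## Synthetic data

`simdata` generates the study conditions end to end: a uniform random
chromosome (default 100 kb); implanted non-overlapping variants ≥ 100
bp apart and away from the ends (defaults: 20 deletions of 30–1,000
bp, 10 insertions of 2–5 bp); FR paired-end reads at 20× with 2 × 50
bp reads and Gaussian insert length 300 ± 30 truncated at twice the
read length; optional per-base substitution errors (default 0).  The
first-pass mapper emulator aligns each read only at its truth-
projected reference position and declares it mapped iff that alignment
has ≤ 4 differences (mismatches + gap columns + edge-clipped inserted
bases) of which ≤ 3 are gaps.  Reads straddling a deletion junction or
an insertion of ≥ 4 bp therefore become unmapped, and their mapped
partners form the MUR set; insertions of 2–3 bp remain mappable as
short gap cigars and are invisible to the split-read stage by
construction — recovery claims for insertions refer to the detectable
(≥ 4 bp) ones.

An optional duplicated segment (copy diverged at 2 %/base by default)
produces the failure modes the classifier exists for: reads from
either copy are reported with both placements (N-UMRs), and a
multi-placed anchor near an implanted deletion inside one copy spawns
a window at the other copy where the junction reads cross-align into a
shifted decoy candidate.  With identical copies such decoys would be
feature-identical mirror images of the true call and irreducibly
unclassifiable; divergence — the realistic case for segmental
duplications — lets first-pass reads map uniquely to their own copy,
so coverage and penalty features expose the decoy.

Truth labeling marks a candidate +1 iff it matches an implanted
variant in kind and length with |Δstart| ≤ 10 bp (standing in for
wet-lab validation).  What the emulation leaves out — base-quality
models, PCR duplicates, chimeric fragments, a genome-wide mapping
search, heterozygosity — bounds what green tests show: they establish
algorithmic correctness and the mechanics of the classification gain,
not calibrated performance on real libraries.

Two auxiliary generators serve the classifier and cohort benchmarks:
a balanced Gaussian set whose first feature is shifted 2 SD between
classes (plus one nuisance feature: the Bayes-optimal AUC of a
univariate 2-SD shift is Φ(√2) ≈ 0.921, and every extra noise
dimension eats into what a finite-sample learner can recover, so the
benchmark stays near its ceiling while still requiring the learner to
ignore an uninformative column), and a two-population indel matrix
(50 strains × 500 non-private indels, population-specific carrier
rates 0.8 vs 0.05) for the PCA separation check.

## Problem sizes and numerics

The test suite and the acceptance script run simulations of 30–100 kb
at 20× — sizes chosen so every benchmark recomputes from scratch in
minutes on one CPU while still containing every mechanism (junction
reads, multi-placements, decoys, both variant kinds).  Alignment-
engine correctness is checked against independently written scalar DP
oracles and, on tiny instances, true exhaustive path enumeration;
metric implementations against O(n²) sweep oracles to 1e-12; PCA
against an explicit covariance eigen-decomposition to 1e-8.  Ties are
broken deterministically throughout (traceback operator order,
lower-threshold BEP, largest-C selection), and a fixed seed makes the
whole pipeline byte-reproducible.

## Known limitations

- Deletions are capped at the window size; long insertions are
  intrinsically penalised by the local alignment model (each inserted
  base forgoes a match), so insertion recovery is limited to a few bp
  at 50 bp reads.
- No genotyping: candidates are presence calls, not genotypes, and
  heterozygous variants are not modelled.
- The SPV features are base-quality-blind and the pileups are not
  mapping-quality weighted.
- The first-pass emulator does not perform a genome-wide search, so
  mapping artefacts outside duplicated segments are not represented.
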