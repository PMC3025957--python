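# Methods

## The question and the statistic

Tandem duplications of large mtDNA fragments make mitochondrial
recombination observable: if recombination (gene conversion) is frequent,
the two copies of the duplicated fragment within an individual are
homogenized and stay near-identical, while the same fragment still diverges
normally *between* individuals. The package quantifies this with two mean
p-distances over any region of a joint alignment of all 2N copies
(N individuals x copies I/II):

* `pi_dupl` — mean p-distance between copy I and copy II within each
  individual (paralogue diversity), averaged over individuals;
* `pi_ind` — mean p-distance between individuals within the same copy
  (orthologue diversity), pooled over copies I and II. Per-copy means are
  also reported, since pooling over copies is a choice: with strong
  conversion the two per-copy values are nearly identical anyway, and
  exposing both makes either reading checkable.

Under concerted evolution `pi_dupl << pi_ind`; a tract exempt from
conversion shows the reverse (`pi_dupl >> pi_ind`). In hornbill-like mt
genomes that exempt tract sits centrally in control-region domain I and is
interpreted as the Replication Fork Barrier (RFB): a site where replication
halts and leaves a free 3' strand end, which both promotes strand exchange
nearby and excludes the barrier region itself from homogenization.

p-distances use pairwise deletion (columns where either row has a gap are
skipped for that pair). An undefined distance (no comparable columns) is an
error, never silently 0. IUPAC ambiguity codes are retained and count as
differences against any other symbol — conservative for diversity
statistics. Polymorphic-site tallies include gap columns (a contiguous run
of gap columns counts as one indel position), but p-distances exclude them;
this is the only reading under which a tract can be reported both as "N
polymorphic sites including k indels" and with a gap-free p-distance.

## Pipeline stages

1. **Duplication detection** (`duplication_detect`). Exact 20-mer
   self-matches in tandem orientation (offset >= `min_len`, default 1000)
   are clustered by diagonal (band 50). The best cluster's outermost seed
   pairs anchor the local homology offsets at the left and right ends of
   the repeat; boundaries are extended outward while a 30-base running
   identity window stays >= `min_identity` (default 0.9), tolerating local
   dips up to one window length, then trimmed to a clean 4-base match run
   so chance matches in flanking sequence cannot creep in. Anchoring the
   two ends separately makes detection robust to copies of unequal length
   (indels, repeat-copy-number differences). Ties between equal-scoring
   clusters go to the smaller start coordinate. The full O(n^2) dot-plot is
   reserved for the test oracle.

2. **Alignment** (`align`). A Gotoh affine-gap global aligner (match +1,
   mismatch -2, gap open -5, gap extend -1; a length-L gap costs
   `open + L*extend`) with fixed traceback preference diagonal > up > left.
   The scores are conventional DNA values and configurable; at the <5%
   divergences involved the alignment is essentially forced. The joint
   alignment aligns every copy to a designated reference and projects onto
   reference columns; insertions relative to the reference open shared,
   left-aligned columns. Variable-copy-number repeat arrays can be masked
   out per copy before alignment, because columnwise homology is
   meaningless under length heteroplasmy.

3. **Site classification and RFB call** (`conversion_scan`). Every column
   is classed invariant / paralogue-variable / orthologue-variable / both /
   indel. Candidate tracts are runs of paralogue-variable (or both) sites,
   merging runs separated by <= `merge_gap` (30) columns; the run with the
   most such sites wins (others are reported as secondary calls) and is
   returned only if it has >= `min_paralog_sites` (3) sites and the
   diversity pattern is the RFB one (`pi_dupl > pi_ind` inside, not in the
   flanks). Boundaries are the outermost paralogue-variable sites, not
   window edges — the tract is delimited by sites, so its printed length is
   comparable to site-delimited lengths.

4. **Permutation test** (`conversion_contrast_test`). The homogenization
   contrast `pi_ind - pi_dupl` is compared against a null in which copy-II
   rows are re-paired with random individuals;
   `p = (1 + #{null >= observed}) / (n_perm + 1)`. The statistic is
   oriented so that a *large* value means paralogues are more similar than
   orthologues, i.e., conversion; with the opposite orientation the upper
   tail would be insensitive to conversion under this null (ancestral
   paralogue divergence is shared across individuals, so re-pairing barely
   changes `pi_dupl` inside the RFB). Apply it to the converted flanks.

5. **Trees** (`trees`). Neighbor-joining (scikit-bio) on p-distance
   matrices, labels sorted for determinism, negative branch estimates
   clamped to zero and flagged; an all-zero matrix yields a flagged star
   tree. NJ on p-distances stands in for likelihood trees deliberately: the
   readout is only which leaves cluster, and at near-identity divergence
   that is distance-determined. The classifier calls `paralog_clustered`
   when every individual's two copies form a cherry or sit at zero
   patristic distance (zero-length cherries count as clustered regardless
   of rotation, since many copies are literally identical), and
   `ortholog_clustered` when the copy-I and copy-II leaf sets form the two
   sides of a bipartition; anything else is `mixed`.

6. **Repeat arrays** (`repeat_analysis`). The period maximizes mean base
   identity between `seq[i]` and `seq[i+p]` (shift autocorrelation) over
   [10, 200]; multiples of the true period score alike up to sampling
   noise, so the smallest period within 0.03 of the maximum is returned,
   and identity < 0.6 means "not repetitive". Arrays are cut every period
   from a phase chosen by inter-slice identity (near-ties go to phase 0 —
   for a pure tandem array every phase scores alike and clones start at
   unit 1) or from an anchor motif; subsequent unit boundaries are refined
   by aligning candidate cuts (period +/-15%) against the first unit, so
   unit variants of slightly different length are cut correctly. Unit
   types are exact-sequence groups by default (each distinct sequence is a
   type, matching how printed type counts are derived); positional classes
   are B (only first), E (only last), BE (only sole unit of single-unit
   arrays), M (never first or last), with U for types violating the
   partition, which is not total for arbitrary data. Copy-number spectra
   count complete units per clone; ties for the dominant number go to the
   smaller count and are flagged.

## The simulator

`synthetic_data` generates datasets with exactly the structure the
statistics assume, plus ground truth for every event.

* **Genealogy**: a star — each individual descends independently from one
  ancestor. The sampled individuals are unstructured population samples
  and every statistic here only needs independent lineages; a coalescent
  adds nothing testable.
* **Ancestral RFB divergence** (`rfb_divergence`, default 0.24/site): the
  duplicates' divergence inside the RFB is ancestral and therefore shared
  across individuals — that is precisely why orthologues stay similar
  across individuals inside the tract while paralogues differ. A star
  radiation alone cannot produce `pi_dupl >> pi_ind`; the pre-radiation
  divergence is applied to the ancestor's copy-II tract. 0.24 is chosen so
  total expected paralogue divergence (ancestral + 2*mu*generations of
  post-radiation drift) is ~0.255, the level observed in the motivating
  system.
* **Per-generation events, in fixed order**: substitutions (rate `mu` per
  site, default 2.5e-4), small indels (1-3 bp, rate `indel_rate` = 0.01
  per copy per generation, confined to the RFB — outside it conversion
  would erase them and they would only jitter coordinates), then with
  probability `conversion_prob` (default 1: conversion every generation) a
  whole-tract conversion copying one copy's non-RFB portion over the
  other's, both flanks in one event, direction random. The
  mutate-then-convert order matters and is asserted in tests: with
  `conversion_prob = 1` the final conversion erases even the last
  generation's mutations, so paralogue diversity outside the RFB is
  *exactly* zero. (Under convert-then-mutate it would instead be the
  final-generation residue 2*mu*L.)
* **Defaults mirror the study geometry**: 6 individuals; a 1,930 bp
  duplicate with the 159 bp RFB placed after 1,368 bp; mu*generations =
  0.01 so that orthologue diversity is ~0.02; a 113 bp control-region
  repeat with copy numbers 1-10 (starting at the typical 9; CRII: 1-8,
  starting at 6) and a second 34 bp A-rich repeat (47% A on the heavy
  strand, single unit type). The carrier genome is 9,000 bp before
  duplication (~10.9 kb emitted) — enough flanking context for detection
  while keeping the 20-seed suites fast; the duplicate itself, where all
  statistics live, is full size.
* **Repeat clones**: per individual and region, each clone's copy number
  performs a +/-1 slippage walk (`slip_prob` = 0.05/generation) clamped to
  `copy_range`; arrays are composed as B + M... + E (a dedicated BE type
  for single-unit arrays), emulating the observed positional structure.
* **Ground truth**: ancestor, full event log (replaying it over the
  ancestor must reproduce every emitted sequence byte-for-byte — a tested
  invariant), RFB intervals in copy and genome coordinates, per-clone unit
  lists and copy numbers.

### What the simulator does not emulate

Unit types within a region share one length; real repeat-unit types can
spread over ~111-123 bp. Length-varying units break fixed-shift
autocorrelation (the period becomes ill-defined), so period recovery is
validated on equal-length arrays while the boundary-refinement path of
`decompose_array` is exercised separately on hand-planted variable-length
arrays. Also not modelled: selection, within-individual heteroplasmy of the
non-repeat sequence, minicircle-mediated rearrangements, gene-order
evolution, and sequencing error. Passing tests therefore demonstrate
correct recovery of the duplication/conversion/RFB structure under clean
star-genealogy data, not robustness to annotation errors or messy reads.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open internally; reports are 1-based
  inclusive; BED stays 0-based. Round-tripping is the identity.
* Aligner tie-breaks: diagonal > up > left during traceback; equal-scoring
  seed clusters: smaller start; NJ: lexicographic label order; dominant
  copy number: smaller value, flagged.
* `p_distance` with no comparable columns raises; `call_rfb` returns "no
  call" (None) rather than an error when no qualifying tract exists;
  detection distinguishes "no duplication" (None) from an
  overlapping/inverted best match (error).
* The permutation test returns exactly 1.0 for degenerate (all-identical)
  intervals and is bounded below by `1/(n_perm+1)`.
* All randomness in the simulator flows from a single `numpy` Generator
  seeded by `SimConfig.seed`; identical seeds give byte-identical outputs.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the full pipeline over 20
simulated datasets of the default geometry (about 10.9 kb per genome, 12
copies of ~1.93 kb in each joint alignment, 108 repeat clones per dataset),
100 random alignments of up to 12 rows x 2,000 columns against brute-force
oracles, and 500 random short-string pairs against an exhaustive alignment
oracle. These sizes keep a complete run in minutes on one CPU while leaving
every statistic estimable to the tolerances asserted.
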