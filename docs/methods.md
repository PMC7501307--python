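# Methods

## Model

A classification here is a set of *f* binary features over an alphabet
of *n* residues such that the concatenated membership bits give every
residue a distinct *f*-bit code. For the canonical alphabet (*n* = 20,
AAindex I-line order `A R N D C Q E G H I L K M F P S T W Y V`) the
minimum is *f* = 5, since 2⁴ < 20 ≤ 2⁵; 12 of the 32 codes then remain
empty. Features enter as numeric indices (one real value per residue),
and a feature contributes a binary split only through a *realizable
cut*: a boundary between two strictly different adjacent sorted values.
Residues with equal values can never be separated, so ties always stay
on one side.

Conventions fixed throughout:

- bit 0 = low side, bit 1 = high side; the split rule is
  `low iff value <= threshold` with the threshold stored as the largest
  low-side value;
- within a solution, separations are kept in canonical order (ascending
  accession, then cut size), and solutions are unordered sets — the f!
  ordered tree layouts of a solution are a presentation choice;
- the median is the usual sample median (mean of the two middle order
  statistics for even n). The median separation puts residues *equal*
  to the median in the low set, so tied medians can give splits more
  unbalanced than 10/10.

## Separation scoring

For one feature, score(c) = #{c′ ≠ c : gap(c′) < gap(c)}, counting
strictly, over the feature's *complete* realizable cut set — before any
size filtering or top-k selection. This is the only universe in which
the maximum score for 20 distinct values is 18 (19 cuts total), which
anchors the cumulative-score ceiling 5 × 18 = 90. Equal-gap cuts share
a score. Median separations are scored the same way, so cumulative
scores are comparable across median and cuts modes.

## Pool construction

- **median mode**: one median separation per feature; features whose
  values all fall on one side (e.g. constants) are skipped with a
  warning.
- **cuts mode**: per feature, all realizable cuts are enumerated and
  scored, cuts with either side larger than 2^(f−1) (i.e. cut size
  outside [4, 16] for n = 20) are discarded — such cuts can never be
  part of a minimal solution — and the k largest-gap survivors are kept
  (ties: higher score, then smaller cut size). The default k = 3
  matches the common demonstration setting; k = 2 (and any other k) is
  a flag. Afterwards the pool is deduplicated **pool-wide**: among
  separations with identical membership vectors only the
  highest-scoring one survives (ties: smallest accession, then smallest
  cut size). Deduplication is deliberately *not* applied in median
  mode: families of closely related indices (six volume-like, three
  hydrophobicity-like) are expected to contribute alternative solutions
  there, and collapsing identical median splits would hide them.
- `include_median` optionally force-adds each feature's median cut to a
  cuts-mode pool; off by default, since nothing in the scoring favors
  the median once arbitrary cut points are allowed.

## Search

Depth-first backtracking over the pool in canonical order, implemented
with an explicit stack (depth never exceeds f; the stack keeps pools of
hundreds of separations safe). Each step refines the current partition
by one separation and applies the **capacity criterion**: after n
features every cell must hold ≤ 2^(f−n) residues. The criterion is a
necessary condition satisfied by every prefix of every solution in
every order, so pruning is sound; this is verified in the tests by
exhaustive-subset comparison (`brute_force_solutions`, guarded to
C(|pool|, f) ≤ 10⁷) on randomized pools. Choosing pool indices in
increasing order emits each unordered solution exactly once. By default
at most one separation per feature joins a branch
(`distinct_features`); the flag allows two cuts of the same feature,
which can be jointly non-redundant (the nested 6/8/6 pattern). A
completed depth-f partition with ≤ 1 residue per cell is a solution —
"≤", not "=", since 2^f − n cells stay empty. Output is sorted by
descending cumulative score, then canonical key, so runs are
reproducible without seeds.

## Redundancy profiling

`redundancy_profile` deletes one residue *before* pool construction:
medians, cut points, gaps and scores are all recomputed on the reduced
alphabet, and uniqueness means ≤ 1 residue per cell out of 19. The
reported quantity is count(19-residue search) − count(full search). A
subtlety worth stating: with distinct values the median of 19 values
always puts 10 residues in the low set, so a deletion shifts at least
one median split, and a shifted split can in principle collide two
codes that only differed on that feature. The count difference is
therefore not clamped and is guaranteed non-negative only when the pool
is stable under deletion — e.g. dominant-gap cuts whose membership (on
the surviving residues) is unchanged, which is the regime the planted
generator produces and the tests assert. On real median-mode data the
difference is expected, but not proven, to be non-negative.

## Niche assessment

A candidate amino acid is coded per solution by the canonical threshold
rule (`low iff value <= threshold`); the thresholds learned from the 20
canonical residues are never re-fit to the candidate. Solutions for
which the candidate lacks a value for some feature (secondary-structure
propensities are typically unmeasurable for non-canonical amino acids)
are skipped and counted separately rather than guessed. The
empty-niche count — how often the candidate's code is unoccupied —
is the diversity measure; each code is empty or occupied by exactly one
residue, never more.

## Synthetic data

`generate_planted_table` is the ground-truth generator used by tests
and the acceptance script. It samples n distinct f-bit codes, then
realizes bit-plane i as feature `PLANT0i`: bit-0 residues take distinct
values in [0, 0.9], bit-1 residues in [2.0, 2.9] (evenly spaced within
a band, randomly assigned, rounded to 6 decimals). The ≥ 1.1 band gap
strictly dominates every within-band gap, so the planted cut is the
top-gap cut with score n−2. By default codes are drawn as complement
pairs, which balances every bit-plane at n/2 — making the planted cut
simultaneously the median cut, so planted designs are recoverable in
both modes; unbalanced sampling (capacity bounds only) is a flag. Noise
features are n−2 exactly tied values plus two low outliers: their only
realizable cuts have side sizes 1 and 2, which the size filter rejects
(requiring n ≥ 2^(f−1) + 3 when noise is requested), and their median
split is degenerate, so noise can never enter a solution — noise
ineligibility comes from the size filter rather than vector collisions,
because colliding vectors would simply be deduplicated away and would
not exercise the search.

With k = 1 the cuts-mode pool is exactly the f planted cuts and the
search returns exactly the planted solution; with k ≥ 2 the extra
near-gap cuts can combine into additional valid solutions, but the
planted set always carries the strictly maximal cumulative score. Tests
assert exact recovery at k = 1 and top rank at k = 3.

What the generator does **not** emulate: the value distributions,
inter-feature correlations, and tie patterns of real physicochemical
indices. Passing tests therefore demonstrate algorithmic correctness
(pruning soundness, canonicalization, scoring, format fidelity), not
that any particular real feature set admits a solution; database-level
results require supplying an AAindex1 file (see README).

`generate_random_table` draws i.i.d. uniform values rounded to 6
decimals (re-sampled until distinct), then overwrites a `tie_fraction`
share of entries per feature with copies of other entries, leaving
exactly n − round(tie_fraction · n) distinct values per feature.

## Numerical choices

- Values are parsed by exact decimal-to-binary conversion and written
  back as shortest round-trip `repr` text, so both file formats
  round-trip bit-for-bit; `NA` encodes an imputed-missing entry (value
  0, flagged) in both formats.
- Gap comparisons are strict floating-point comparisons; no tolerance
  is applied, so analytically equal gaps that differ in the last ulp
  are ranked by their float values. This only affects scores among
  near-tied cuts, never which cuts are realizable.
- Sorting residues within a feature breaks value ties by alphabet
  position, making every profile, cut enumeration and export
  deterministic.
- Curated-missing records (NA-imputed) are retained by default; the
  `missing` flags let a caller drop them explicitly.

## Problem sizes

The test suite and acceptance script run on 20-residue tables with
pools of ≤ ~24 separations, 100 random pools for the oracle-equivalence
check, 100 planted designs for recovery, and 3 tables × 21 searches for
redundancy profiling — a few seconds in total. These sizes were chosen
because the oracle (exhaustive C(12, 5) enumeration) is exact there;
the search itself handles pools of hundreds of separations.

## Known limitations

- Redundancy monotonicity is conditional (see above); the package
  reports raw count differences.
- No optimization of tree-layer ordering to keep chemically similar
  residues together as long as possible; exports take any requested
  permutation.
- Adjective labelling requires a user-supplied accession → (adjective,
  side) map; the package does not infer which side of a split deserves
  which name.
- AAindex C-line correlation listings are parsed as metadata only;
  correlation coefficients are never recomputed or used.
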