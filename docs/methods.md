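# Methods

## Pipeline model

`binlink` deduplicates a single file of person records under a
privacy-preserving, distributable workflow. The stages are a linear state
machine — encode → stage → plan → split → match → merge → group — with the
invariant that every stage after *encode* operates only on privacy-preserved
artifacts. The run report records which files each stage read, so this
boundary is asserted by a test rather than by convention. In a hybrid
deployment the boundary between *encode* and *stage* is the trust boundary:
everything past it could run on untrusted infrastructure. Here it is a
directory boundary.

Matching work is expressed as independent single-bin jobs that communicate
only via files. A worker pool runs at most `workers` jobs concurrently; each
job has a retry policy (default five attempts). Jobs that exceed the
configured timeout fail the run immediately with a resumable state file —
timed-out jobs are deliberately not retried, since a timeout usually
indicates a sizing problem rather than a transient fault.

## Encoding

* **Bloom filters** (first, middle, last name, address): the value is
  lowercased, stripped of non-alphanumerics, split into unpadded overlapping
  bigrams, and each bigram sets `num_hashes` = 30 positions in a
  `filter_length_bits` = 512 filter. Positions come from double hashing:
  two keyed SHA-256 digests h1, h2 of the token give h1 + i·h2 (mod 512)
  for i = 0..29. This has the same set-membership semantics as 30
  independent keyed hashes at 15× fewer digest computations; a bit-exact
  alternative scheme can be swapped in behind `bloom_encode`. Padding is a
  deliberate non-default: unpadded bigrams slightly de-emphasise word
  boundaries, and the choice is config-visible.
* **Exact digests** (DOB day, month, year, sex, postcode): HMAC-SHA-256 of
  the normalized value, salted with the field label so equal values in
  different fields never collide. One project-wide secret key is used.
  Missing values map to an explicit marker, never a digest.
* **Date of birth** is stored as three separate component digests, so the
  matcher can observe partial agreement (e.g. transposed day/month agree on
  the year). Postcode is digested rather than Bloom-encoded because it is
  short and structured; address is Bloom-encoded. Both choices are
  config-exposed.
* **Blocking keys** (first-name initial + last-name Soundex; DOB + sex) are
  assembled from raw values and digested at encode time, so staged files
  reveal neither initials nor phonetic codes. A record missing any component
  of a strategy simply gets no key for that strategy — a sentinel
  missing-value block would concentrate all incomplete records into one
  giant block.

The testable privacy property is deliberately modest: serialized encoded
artifacts share no alphabetic token (≥ 3 characters) with any raw name or
address value. Hardened resistance to frequency attacks on Bloom filters is
out of scope and should not be inferred from that property.

## Comparison and classification

Standard Fellegi–Sunter scoring. Field similarity is Dice overlap for Bloom
fields (the standard similarity for bigram Bloom filters in the
privacy-preserving linkage literature), digest equality (1/0) for exact
fields, and the fraction of agreeing components (0, ⅓, ⅔, 1) for the date
of birth. The weight for similarity s is

* log2(m/u) if s ≥ t_high,
* log2((1−m)/(1−u)) if s ≤ t_low,
* linear interpolation between the two on (t_low, t_high).

Defaults t_low = 0.6, t_high = 1.0. Interpolation exploits the graded Dice
similarity instead of thresholding it to binary; t_low = 0.6 sits below the
typical Dice value of a single-typo name variant (≈ 0.8–0.95) and above the
background similarity of unrelated names (≈ 0.2–0.5). Missing comparisons
contribute weight 0: absence of a field is treated as no evidence either
way.

Per-field m defaults (0.90–0.98) are a documented preset, highest for
date-of-birth and lowest for the error-prone middle-name and address
fields. u for exact fields is estimated from the data as the expected
random-pair agreement Σ f(f−1)/2 ÷ N(N−1)/2 over value frequencies, clamped
to [1e-6, 1−1e-6]; u for Bloom fields is a preset (frequency-based
estimation does not transfer directly to set similarity). Thresholds
default to T_p = 15 (emission) and T_m = 25 (match): under the default
specs a full agreement scores ≈ 51, a random pair sharing only the DOB+sex
block scores well below 0, and the 15–25 band holds weak potential matches
for review.

## Binning

Each block value of frequency f costs c = f(f−1)/2 comparisons
(deduplication is a self-join; the two-file Cartesian form f_A·f_B is
implemented but unused). Keys with c > M (the maximum desired per-bin
space) are discarded before planning; the alternative reading that compares
the raw *frequency* f against M is selectable (`discard_rule="frequency"`)
but not the default, since comparing a frequency to a comparison space is
unit-inconsistent and the purpose of the rule is to bound per-job load.
Bin count B = ⌈(ΣC − discarded)/M⌉ with a floor of one; ties in c are broken
by digest order; keys are dealt round-robin (largest first, returning to
bin 0). One global assignment covers both strategies, matching a single
split task. Default M = 5000 yields single-digit bin counts on fixtures of
a few thousand records.

Consequences, each a tested invariant:

* **Conservation**: Σ per-bin space + discarded space = Σ per-strategy
  totals, exactly, as integers.
* **Disjoint work**: no unordered pair is compared under the same strategy
  in two bins (a bin only generates candidates for keys assigned to it).
* **Bin-count invariance**: the merged, de-duplicated pairs table, scores
  and groups are identical for any bin count and identical to a
  single-process matcher over the same blocks.
* **Monotonicity**: decreasing M never decreases B *while the discarded set
  is unchanged*. Unconditional monotonicity does not hold: a smaller M can
  discard more keys, shrinking the remaining space faster than the divisor.

## Pairs table, grouping, analytics

Duplicate pairs (same unordered ids from different strategies) keep the
row with the maximal score, ties broken by strategy name; keep-first is
selectable for replaying historical runs. Grouping is plain transitive
closure (connected components at score ≥ T_m) with the smallest member id
as the group id. Analytics: pair count; score histogram over half-open bins
[x, x+w) anchored at the minimum score (counts sum to the pair count by
construction); range query lo ≤ score < hi. Pairwise quality metrics are
total functions: empty prediction sets have precision 1.0, empty truth sets
recall 1.0.

Scores are serialized with shortest-round-trip float formatting, so a pairs
file read back compares exactly equal to the in-memory result — this is
what makes "byte-identical across bin counts" a meaningful test.

## Synthetic data generator

The generator emulates a population-style administrative file: name fields
drawn from bundled Zipf-skewed frequency tables (≈ 50 given names, ≈ 48
surnames; middle names reuse the given-name pool), uniform dates of birth
over 1920–2005, an address grammar of number + street + type, and four-digit
postcodes. User-supplied `FrequencyTable`s replace the bundled ones for
realistic population frequencies.

Duplicates per entity default to a zipf(a=2) tail minus one, capped at 50 —
a heavy-tailed "zero to many thousands of duplicates" regime scaled to desk
size; with 600 entities this yields roughly 2,000 records. Geometric and
fixed counts are available.

Each duplicate is corrupted independently under a per-field error model
(rate + mixture over kinds: replace, truncate, misspell, delete, insert,
alternate name, set missing). The default preset sets rates deliberately
high (0.08–0.40 by field) to stress matching accuracy. Character-level
edits on date-of-birth and sex degrade to whole-value replacement so dates
always parse and sex stays categorical. Alternate names use a small bundled
nickname map and fall back to a misspelling when a name has no entry.

What the generator does *not* emulate: real population name frequencies and
their correlations (ethnicity, cohort effects), household structure shared
across entities, address standardisation noise, and temporal drift. Passing
tests therefore demonstrate the pipeline's structural properties
(conservation, invariance, determinism, privacy of the encoding) and its
behaviour under a controlled error model — not field accuracy on real data,
which depends on population-specific m/u calibration.

## Numerical and degenerate-input choices

* All randomness flows from one integer seed through `numpy` generators;
  fixed seed ⇒ byte-identical artifacts (gzip streams are written with
  mtime = 0).
* u estimates are clamped away from {0, 1} so weights stay finite; m ≤ u is
  rejected at construction.
* Dice similarity of two empty filters is defined as 0 (treated upstream as
  a missing comparison, since an all-zero filter means a missing field).
* Empty datasets run through the whole pipeline and produce an empty table,
  one empty bin, and zero groups.
* Deterministic orderings everywhere ties could occur: plan keys by
  (−space, digest, strategy), pairs by (id_a, id_b, strategy), groups by
  group id.

## Problem sizes

Default test and acceptance runs use 600-entity (≈ 2,000-record) fixtures
for pipeline-level checks and 30–300-entity fixtures for unit-level
oracles, with brute-force O(n²) comparisons as the independent oracle
wherever feasible. These sizes exercise every code path — multi-bin plans,
overlapping blocks, discarded keys, duplicate pairs — while keeping
brute-force verification exact.

## Known limitations

* Bloom-filter encodings are vulnerable to frequency-based
  cryptanalysis; this implementation targets honest-but-curious
  infrastructure, not adversarial attack resistance.
* m is user-supplied, not estimated (no EM on encoded data).
* Transitive closure can chain distinct entities through borderline pairs;
  alternative grouping strategies are out of scope.
* Load balance is block-level: a bin's space is balanced, but a single
  discarded-threshold-sized block still lands on one job.
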