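# Methods

This note documents the statistical definitions, parameter choices and
numerical conventions behind `deepcoral`, and what the synthetic-data
generator does and does not emulate.

## Alignment statistics

An alignment is a non-empty, equal-length set of upper-case rows over
{A,C,G,T, IUPAC ambiguity codes, `-`}; U is mapped to T at ingest and a
sidecar CSV carries per-sequence taxonomy, basin and depth (deflines are
too unstructured for these fields).

Site counting uses the conventional definitions: a column's state set is
the distinct unambiguous bases it contains; gaps and ambiguity codes
contribute no state. `gaps_as_state=True` adds `-` as a fifth state for
users who want indel-aware counts. Percentages of alignment length are
rounded half-up to the nearest integer (`floor(100·k/L + 0.5)`); this
rounding is what makes count/length/percentage triples in published marker
tables internally consistent, and is verified cell by cell in the test
suite. The de-gapped length range reports the shortest and longest rows
after removing gap characters.

Variable-site counts are additive under column-wise concatenation of
alignments over the same row ids; this is used as a test invariant.

## Haplotype collapsing

Haplotypes are identity classes of rows. The default `strict` policy is
literal string equality over all columns, so a sequence differing only by
an ambiguity code (or a gap) is a distinct haplotype. This is deliberately
the default: in real ribosomal (18S) datasets, strict counting yields more
haplotypes than the most variable mitochondrial marker precisely because
of ambiguous base calls, and that behaviour should be visible, not
silently removed. The `mask_ambiguity` policy compares two rows only on
columns where both carry a symbol in {A,C,G,T,-}, so ambiguity codes can
never separate haplotypes.

Masked equality is not transitive (A-R-G chains). The partition is
therefore built greedily in input order: each sequence joins the first
existing class whose *representative* (first member) it matches, otherwise
it founds a new class. Consequences: membership is exactly "matches the
representative", class indices are assigned in order of first appearance,
and the output is deterministic. For any input, strict class count ≥
masked class count, and for ambiguity-injected simulations the true
(pre-injection) count is bracketed between the two.

Richness tables count, per group (genus/family/species), the distinct
haplotypes overall and per ocean basin (a haplotype counts in every basin
where it has ≥ 1 member, so basin columns can sum to more than the total).
Specimens without a basin label contribute to totals only. Basin is always
an input label — never inferred from coordinates.

Trimming to a shared column window before collapsing (e.g. comparing only
a 5′ fragment) is the caller's responsibility via `Alignment.subset` /
column slicing of the input; the collapser itself requires the equal-length
invariant and compares all columns.

## Distances and the delimitation rule

Uncorrected p-distance uses pairwise deletion: per pair, only columns
where both symbols are unambiguous bases are compared; `p` is the fraction
of those that differ. Pairwise (not complete) deletion is the standard
convention for reporting "uncorrected p" and is robust to ragged sequence
ends. A pair with zero comparable columns raises an error in the scalar
API; in the matrix API the pair is flagged (`NaN`) and the rest of the
matrix is still produced. Internal values are proportions; display
rounding to two decimals of a percent happens only at output.

Transitions are A↔G and C↔T; tallies are pooled over all row pairs under
pairwise deletion, and the ti/tv ratio is undefined (flagged, not an
error) when no transversions are observed. Pooled pairwise tallies
approximate the realized substitution-event ratio only when divergence is
low (multiple hits hide events); the simulator records realized events
exactly, and the recovery test runs at 0.02 substitutions/site so the two
agree within sampling tolerance.

The family-delimitation rule uses two calibrated constants: the maximum
p-distance observed *within* any reference family (default 0.049) and the
minimum observed *between* families (default 0.038). Distances from a
candidate to a family's members that all sit at or below the inter-family
minimum are evidence the candidate belongs inside; all at or above the
intra-family maximum, evidence for a distinct family; otherwise the call
is explicitly `ambiguous` — the calibration thresholds overlap, so forcing
a binary call would manufacture certainty. The defaults come from a
reference calcaxonian dataset external to this package and are plain
configuration values; the calibration itself is not reproduced here.

## Biogeographic curation and depth profiles

Every record reduces to a point depth, the mean of its station interval
(point records are their own mean). The range rule excludes a record when
its interval exceeds half its mean depth, with strict inequality — a point
record can never be excluded by it. Manual exclusions (a shipped default
list carries two known-bad historical stations) are applied alongside and
take precedence in the report when both rules fire, so the accounting
identity `input = retained + range + manual` always holds, as does colony
conservation over retained records.

Genus depth summaries are Tukey five-number summaries (hinges = medians of
the lower/upper halves, halves sharing the middle element when n is odd),
not interpolated percentiles, matching classic box-and-whisker
construction; outliers lie beyond hinge ± 1.5 × inter-hinge spread. The
hinge code is hand-written (numpy offers only interpolated quantiles) and
tested against a brute-force sort-and-hinge oracle.

Species depth ranges are min/max of curated point depths by default;
`use_raw_extremes=True` spans raw station bounds instead, since published
range tables are ambiguous about which convention they use. The diversity
profile defaults to *range-through interval counting* over half-open 100-m
bins [b, b+100) from 0 to 4500 m: a species counts in every bin its closed
depth interval overlaps. A `point` mode counting presence at the 100-m
levels themselves is provided because the phrase "species found every
100 m" admits both readings; interval mode is the default because point
sampling misses species whose whole range falls between levels. Ranges
extending past the profile floor are counted in the terminal bin and
logged. Shallow-species counts use strict inequality (`depth_lo <
threshold`).

## Synthetic data

The sequence generator evolves a uniform-random root sequence along a
seeded pure-birth (Yule) tree (dendropy, birth rate 1.0 by default, leaves
relabelled `t1..tN`). Substitutions follow a two-parameter symmetric
process: per site and branch, the event count is Poisson with mean
`rate × branch length` (default 0.05 expected substitutions/site per unit
length — enough divergence to separate most leaves without saturating),
and each event is a transition with probability κ/(κ+2) (default κ = 2)
or one of two transversions. Simulating the jump chain event by event
means the realized transition/transversion counts — including multiple
hits — are recorded exactly and serve as the oracle for the pairwise
tallies. A two-parameter process suffices because every downstream
statistic only distinguishes identity/transition/transversion; a GTR
simulator would add parameters nothing consumes. Ambiguity injection
replaces a base with a random compatible IUPAC code, gap injection with
`-`, each per-symbol post hoc (defaults 0); the ground-truth haplotype
partition is recorded before injection.

The record generator draws per-genus point depths from truncated
log-normal laws (positive, right-skewed — the shape real depth
distributions show — truncated by resampling; default genus set spans a
depth generalist and several deep-water specialists at a 985-record
scale). A configurable fraction (default 0.35) of records are trawls with
half-width fraction f ∈ [0.02, 0.2] of their mean depth; forced
range-rule violators get f ∈ [0.3, 0.6] (the rule fires iff f > 0.25, so
both sides are strict by construction), and forced manual exclusions are
distinct records given ids `MANUAL-k`. Truth records every flag and the
realized per-species depth intervals of the retained records.

What the generator does **not** emulate: indel evolution (gaps are noise,
not history), among-site rate variation, rate variation among branches,
geographically structured sampling, duplicate museum records, or
correlation between genetic distance and depth. Passing tests therefore
demonstrate the correctness of the bookkeeping, counting and threshold
logic under controlled conditions — not that any biological conclusion
drawn from real data is right.

## Pipeline and determinism

`run_all` validates paths up front, runs each stage under a named log
scope, writes only delimited text, and records a SHA-256 per artifact in
`manifest.csv`; identical (config, inputs) reruns are byte-identical, which
the test suite asserts. Every excluded record and flagged pair is logged
individually, because exclusion decisions are exactly what a re-analysis
needs to audit. The acceptance script scales its simulations to run in
seconds (a 985-record database, alignments up to 105 × 5236, a 4000-column
ti/tv simulation); these sizes match the published tables where a table is
being recomputed and are otherwise chosen as the smallest that leave the
sampling tolerances comfortable.

## Known limitations

* Greedy masked collapsing depends on input order in the rare
  non-transitive configurations; representatives are stable, but a
  reordered input can shift class boundaries.
* Pooled ti/tv tallies understate the realized event ratio as divergence
  grows (multiple hits); no correction is attempted.
* The delimitation thresholds are external calibration constants, not
  estimated from the data at hand; the rule is a screening heuristic, not
  a species-delimitation model.
* Depth curation treats the interval mean as the best point estimate; for
  strongly asymmetric trawl intervals this biases point depths toward the
  interval center.
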