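# Methods

## Survey model

The unit of observation is a prescription: a deduplicated set of
standardized medicinal materials dispensed together. All statistics are
presence-based — repeated mentions of a material within one prescription
count once, so citation counts and pair supports are per-prescription
frequencies. Material names are standardized through a single-valued
synonym table before any counting; the normalized match policy folds
case, surrounding whitespace, internal whitespace runs, and diacritics,
and nothing fuzzier is ever applied silently (fuzzy matching, when
opted into, reports how each name matched).

Materials distinguished by processing or color variant (red vs. black
jujube, white peony, cooked rehmannia, cassia ramulus vs. cortex) are
distinct materials with a variant suffix in the id, because traditional
practice and the survey literature treat them as different drugs.

## Citation statistics and profiles

`RFC = FC / N` with `N` the number of prescriptions (not pharmacies).
The frequent-use filter `RFC >= cutoff` is inclusive, with the reference
cutoff 0.2; count thresholds for pairs and edges are strict (`> t`) by
default, with inclusive variants behind a flag. Because 18/90 must pass
a 0.2 cutoff exactly, float cutoffs are interpreted through their
shortest decimal form and compared as exact rationals; binary-float
comparison would fail the boundary.

Categorical profiles expose two counting conventions as an explicit
parameter:

* **per_material** — denominator = number of materials; each material
  counts once per category it carries. Proportions sum to 1 for
  single-valued variables (property, kingdom, family, part) and may sum
  to more than 1 for multi-valued ones (flavors, pharmacology tags).
* **per_token** — denominator = total mentions; proportions always sum
  to 1. Only defined for multi-valued variables.

Property percentages of the reference survey are per-material
(11/19 warm = 58%); flavor percentages are per-token (14/26 sweet =
54%). These conventions reproduce the published radar-chart figures and
are the defaults used by the pipeline report.

All internal arithmetic is exact — integer counts and rational
proportions. Rounding happens at one site: half-up to whole percent for
proportions and to two decimals for RFC display columns. Reports reuse
the display values computed for the CSVs, so a number never rounds
twice.

When a registry is transcribed from a published table that prints RFC
but no prescription-level data, citation counts are back-computed as
`round(RFC * N)`; for the packaged 19-material registry every
back-computed count re-displays to the printed two-decimal RFC, so the
transcription is self-consistent.

## Pair mining and the network

Support, confidence, and the network are computed by direct enumeration
over prescription sets — at survey scale (~90 transactions, ~81 items)
nothing faster is needed, and the exhaustive count is its own
specification. Only pairs are mined; higher-order itemsets are out of
scope. Confidence-1 rules are decided by `support == FC(antecedent)`.

The network restricts nodes to frequent materials by default (matching
how such surveys draw their core-component diagrams); an unrestricted
mode exists. Core ranking is a total order: descending citation count,
then descending weighted degree, then material id. The interpretation of
"distance from the center" in the original mining software is not
published; frequency-with-degree-tie-break is this package's documented
reading. All orderings in tables and rankings are totally specified, so
outputs are byte-stable across runs.

## Synthetic corpus generator

Each prescription is drawn by independent Bernoulli inclusion of every
material at its marginal probability; then each configured pair boost
`((a, b), u)` forces both members in with probability `u` (leaving the
independent draws otherwise), giving expected pair support
`n * (u + (1 - u) * p_a * p_b)`; finally implication rules `a -> b` are
applied as a closure, so no generated prescription ever violates one.
Implications run last — after the stochastic steps — because a boost
applied after them could insert an antecedent without its consequent.
One explicitly seeded generator drives all draws; the same seed yields a
byte-identical corpus.

Prescriptions that come out empty are redrawn, up to 100 attempts, then
the generator errors rather than silently patching the draw. The redraw
conditions the distribution on "at least one material", which inflates
marginals by a factor of roughly `1 / (1 - prod(1 - p))`. For the
reference configuration this is negligible (empty probability ~ e^-11),
but for small pools it is visible, and the calibration tests therefore
measure the Bernoulli mechanism with an always-present anchor material
in the pool; one test asserts the truncation effect itself.

The **reference configuration** emulates the aggregate shape of the
Taiwan galactagogue survey: 90 prescriptions; the 19 frequent materials
at their published RFC values as marginals; 62 background materials on a
truncated power-law grid `0.18 * i^-0.8` (floored at 1/90), chosen so
prescriptions average about 11 materials — realistic for multi-herb
decoctions — while every background marginal stays below the 0.2
cutoff. No pair couplings are planted: independence alone reproduces the
published top pair supports (90·0.93·0.86 ≈ 72 and 90·0.93·0.83 ≈ 69).
The generator spans independence through deterministic implication as
*test regimes*; it is not an estimate of the real survey's dependence
structure, whose prescription-level table was never deposited. Passing
tests therefore demonstrate correct counting, thresholding, and
recovery under a known inclusion model — not distributional fidelity to
the original data.

A consequence worth stating plainly: with marginals fixed at the
published values, the expected number of the 19 planted frequent
materials that clear the 0.2 filter in a 90-prescription replicate is
16.93 (sum of exact binomial tail probabilities, dominated by the seven
borderline marginals between 0.20 and 0.26), so recovery averages just
under 17 of 19 across seeds. The measured Monte-Carlo mean in this
package is ~16.8–16.9.

## Test design

Brute-force oracles (direct set-membership scans, exhaustive pair
enumeration, direct confidence-1 scans) are implemented independently in
the test suite and never share code with the mined paths. Miner/oracle
equivalence is checked exhaustively over every corpus of up to 3
prescriptions on 3 materials (343 corpora) and over seeded random
corpora spanning up to 6 prescriptions on 6 materials; the full 6×6
corpus space is astronomically large, so the exhaustive envelope was
fixed at 3×3 with randomized coverage beyond it. Stochastic checks use
fixed seeds and tolerances derived from binomial closed forms (3
standard errors), never tuned bands. Monte-Carlo sizes — 500 replicates
for frequent-material recovery, 1,000 for core-ranking stability at
n = 200, 100 for implication recovery — keep the whole suite under a
minute while leaving the standard error of each estimate an order of
magnitude below the margin being asserted.

## Known limitations

* Efficacy-class histograms (e.g. "tonics") depend on curation decisions
  that are not recoverable from published usage text by keyword rules;
  efficacy classes are accepted as curated tags only and are not an
  analysis surface.
* The pipeline reproduces the published mining *parameters*, not the
  original mining software's visual layout; network exports are
  deterministic GraphML/TSV with no force-directed geometry.
* Statistical significance of edges is deliberately absent — the method
  this package reproduces performs none.
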