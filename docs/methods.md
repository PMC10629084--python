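# Methods

This note documents the models and procedures implemented in
`labdigitize`, the defaults that matter, what the synthetic corpus does
and does not emulate, and the numerical choices made where the design was
genuinely open.

## Problem setting

The input is the product of an OCR engine applied to a scanned laboratory
test report: a list of recognized text items, each with a quadrilateral
detection box and a confidence, or equivalently pre-formed text lines.
The target output is a table with one row per test item and four fields —
LabName, LabResult, LabUnit, LabRefRange — plus the report time. The OCR
engine itself is out of scope; the package defines an adapter contract
(`register_ocr_engine`) so any engine producing text+box items can be
plugged in, and works from `box_json` or plain-line input otherwise.

Real reports are heterogeneous in exactly the ways that break naive
table parsers: repeated column groups (two or three items per physical
line), bilingual item names, dual results (a numeric value and a
qualitative call), swapped unit/reference-range order, and extra columns
(method, note) that are not extraction targets. OCR adds its own failure
modes: merged text items, split or misplaced lines, and character-level
confusions.

## Line formation

Boxes are clustered into lines by single-linkage on their vertical
centers (mean of the four quad-corner *y* values, which is robust to mild
skew). In one dimension single linkage reduces to sorting by center and
cutting where consecutive gaps exceed the tolerance; the implementation
does exactly that and is checked in tests against a brute-force
union-find over all pairs. The default tolerance is **0.5 × median box
height** on the page — scale-free across scan resolutions. Ties in line
ordering are broken by the left *x* of the first box so output is
deterministic. No de-skew is attempted: a page skewed by more than half a
box height across its width can still split a physical line, which
mirrors the known failure mode of geometric line grouping.

## Time detection

Three datetime dialects are recognized: `YYYY-MM-DD[ HH:MM[:SS]]`,
`YYYY/MM/DD[ HH:MM[:SS]]` and `YYYY年M月D日[ HH:MM]`. The earliest instant
wins; dates without a time-of-day compare at 00:00, and ties are broken
by line index. Two-digit years are rejected (they do not occur in report
headers and invite century ambiguity). No attempt is made to distinguish
collection vs. reporting vs. printing timestamps semantically — earliest
is the rule. Digits corrupted by OCR inside a date are not repaired; an
invalid calendar date is simply skipped.

## Headline position

The header is the first line matching keywords from **at least two**
distinct header roles (name/result/unit/range); requiring two roles stops
a stray "结果" in running text from being taken for the header. The end
line is the first subsequent line matching an endline keyword
(signature/notes: 检验者, 审核者, 备注, …). The keyword lists ship in
`data/keywords.yaml` with bilingual defaults and are fully configurable,
because endline vocabulary varies across hospitals. When no header
matches, the region falls back to the whole document with
`confident=False` and extraction proceeds anyway (recall over precision).

## Line normalization

With L̄ the mean length of non-empty lines, a current line of length
`c < short·L̄` absorbs its next line when `c + n1 ≤ max_merged·L̄`, and
additionally the next two when `n1 < fragment·L̄` and the three-way merge
still fits. Defaults `short=0.6`, `max_merged=1.25`, `fragment=0.3`
(config-exposed): they restore fragment-split lines without gluing two
genuine full lines, since two full lines sum to ≈2 L̄ ≫ 1.25 L̄. Empty
lines are transparent to candidate selection and removed at the end.

Two implementation decisions guarantee the contract invariants. Merge
passes repeat until a fixed point (each pass recomputes L̄), which makes
the operation **idempotent** by construction; termination is guaranteed
because every effective pass strictly reduces the line count. Merged
texts are joined with a single space, so the multiset and order of
non-whitespace characters are **conserved** exactly — verified by
property tests.

## Tokenization and features

Entity boundaries in Chinese fall between characters, so each CJK
character is its own token; Latin abbreviations and numbers are kept as
maximal letter/digit runs (decimal points bind inside digit context:
`4.5-9.8` → `4.5`, `-`, `9.8`); any other visible character is one
punctuation token. Per-token features: lowercased identity, word shape
(CJK→`c`, case-sensitive letters→`A`/`a`, digits→`d`), suffixes of length
1–3 for Latin runs, and a coarse lexical class plus flags (numeric,
slash, percent, comparator characters `<>-~`). The class stands in for a
part-of-speech tag — a true POS is ill-defined for isolated CJK
characters, and the tag's role here is purely to separate symbol-bearing
fields (units, ranges) from names and values. Context features are the
neighbors' intrinsic features within a ±2 window with begin/end-of-line
markers. Window and suffix lengths are parameters of
`EntityRecognizer`.

## The CRF

A linear-chain CRF over the 9-tag alphabet `{O} ∪ {B-,I-}×{4 categories}`
with emission weights on binary features, a transition matrix, and
start/end potentials. Training minimizes the penalized negative
log-likelihood with **elastic net**: the L2 term is handled directly and
the non-smooth L1 term exactly, by splitting every weight into positive
and negative parts bound-constrained at zero, which turns the objective
into a smooth box-constrained problem solvable by **L-BFGS-B**
(`scipy.optimize.minimize`). The gradient uses forward–backward marginals
and is validated against finite differences to ~1e-10 in development.
All recursions are vectorized across the padded batch of sequences, so
training on a few thousand lines takes on the order of a minute on one
CPU core. Defaults: `c1 = c2 = 0.1`, `max_iterations = 100`. Training is
deterministic given corpus order and hyperparameters; the feature
vocabulary is sorted before indexing for the same reason.

Sequences are single lines ("row-wise" processing): cross-line
transitions would couple unrelated items and preclude per-line layout
decisions. Decoding is Viterbi; predicted tag sequences are repaired
deterministically before span decoding (a dangling `I-c` becomes `B-c`),
a repair that is idempotent and leaves valid sequences untouched.

## Entity linking

Two adjacent same-category entities merge into one logical entity when
the gap between them is at most 2 characters containing only spaces or
parentheses: bilingual LabNames (the CJK half becomes the primary text,
the other script the linked alternate, regardless of order) and dual
LabResults (the second value becomes the alternate). Units and ranges
never link. The gap rule keeps genuine column gaps (≥2 spaces wide by
construction, usually much wider) from being swallowed — column gaps of
exactly two spaces between two same-category entities are the residual
ambiguity, and they do not occur in the generated layouts.

## Step detection and assembly

The column layout of each line is decided from its recognized entities
alone: *n* linked LabNames mean *n* column groups, cut at the start
offsets of the 2nd, 3rd… LabName. Cutting at LabName starts can never
split an entity, because entities are non-overlapping and each segment
starts exactly at one of them. Within a segment the first entity of each
category fills the record; extras and LabName-less segments are logged as
warnings rather than silently dropped. Records are emitted row-major
(left column group before right on the same physical line); a
`column_order="column_major"` switch re-sorts for sources known to fill
down each column first, since the text itself cannot reveal fill order. A
report-wide majority unit/range order is recorded as a diagnostic only —
field identity comes from the NER labels, not from column position, so
reordering is never needed. Layout is per line, letting a report mix
single- and multi-column lines.

## Rule-based baseline

The comparison arm types whitespace-delimited spans (split on runs of ≥2
spaces; single spaces bind) with character-class patterns: reference
ranges are comparator symbols with numbers, units contain `/`, `%` or
Latin letter combinations, results are unsigned numbers (decimal point
excepted, optional ↑/↓) or a short list of qualitative Chinese words,
names are spans containing CJK characters. Conflicts resolve
most-specific-first (RefRange > Unit > Result > Name) — otherwise
`3.5-9.5` would match the number rule. Untyped spans fall back to the
nearest header column's category by offset. The patterns live in
`data/rules.yaml`. The baseline is deliberately not tuned: it exists to
quantify what the learned model adds, and the expected (and observed)
ordering on noisy data is CRF above rules, driven mainly by the baseline
mistyping Latin name abbreviations as units and item numbers as results.

## Synthetic corpus and noise model

The generator fabricates the four-part document structure of real
reports — (1) title/test type and timestamps, (2) patient information,
(3) the result table, (4) signature and notes — over a bank of ~95
fabricated but format-realistic items (bilingual names, units such as
`10^9/L`, `mmol/L`, `%`; ranges using `-` and `<`; serology items with
dual numeric/qualitative results; urine items with qualitative results).
Five layout presets cover the documented variation: single-column
bilingual, single-column with dual results, single-column with extra
method/note columns and swapped unit/range order, double-column
bilingual, and triple-column plain. Values are drawn uniformly inside
the reference range, with 15% drawn up to ±20% outside and flagged ↑/↓
as real reports do. Column cells are padded so fields are separated by
at least two spaces, as box gaps render in text.

Noise is applied in a fixed order — adjacent-line swaps, line splits at
a space, text-item merges (a multi-space gap collapses), character
substitutions/deletions from a visual confusion map (0/O, 1/l, 5/S, …,
plus deletions reproducing the leading-digit-drop class `101.1 → 01.1`).
Every event is recorded with concrete indices in a noise log, so
replaying the log on the clean lines reproduces the noisy lines exactly
(a tested invariant); gold truth always refers to the clean report.
Default rates — `p_swap=0.03`, `p_split=0.05`, `p_merge=0.05`,
`p_char_sub=0.01` per opportunity — are the package's choice of a
moderately degraded scan: roughly one line-level event and a handful of
character errors per report, enough that the three error classes all
appear regularly without overwhelming the document structure. Real error
frequencies are not published for this document class; the rates are
config-exposed.

What the generator does **not** emulate: image-level effects (skew,
illumination, handwriting), OCR confidence correlated with visual
quality, hospital-specific header vocabularies beyond the shipped
keyword lists, and genuinely free-form layouts (e.g. results embedded in
prose). Passing tests therefore demonstrate correctness of the pipeline
mechanics and learnability of the layout conventions modeled here — not
performance on any particular hospital's scans, which depends on
annotated data from that distribution.

## Evaluation

Entity scoring: a prediction is correct when category and normalized
text (trimmed, internal whitespace collapsed) match a still-unmatched
gold entity of the same report; for LabName the Chinese portion
(maximal CJK subsequence) alone suffices, so the Latin half of a
bilingual name is not penalized. Matching is greedy in document order,
one-to-one per report and category. Because the match relation is an
equivalence on normalized keys, greedy matching attains the maximum
bipartite matching; tests verify this against
`scipy.optimize.linear_sum_assignment` on random small reports. Micro
aggregation (summed counts) is the headline "overall"; macro averages
are reported alongside and never conflated with it. When a report has
no gold and no predicted entities, metrics are reported as 1.0 with a
warning — perfect silence on an empty report is not an error. Raw rates
are kept internally; rounding to two decimals happens only at printing.

OCR scoring takes per-line lists of box texts and measures: character
accuracy (matched characters in an edit alignment of the concatenated
streams — `difflib.SequenceMatcher` — over gold characters), box
accuracy (gold boxes with an identical one-to-one predicted box, so a
merge costs both constituents), and line accuracy (gold lines reproduced
exactly), averaged into one overall score.

## Problem sizes

The shipped test suite trains its session recognizer on ~35 generated
reports (≈500 annotated lines) and the acceptance checks on ~130 reports
(≥2,000 lines, the size at which held-out clean F1 saturates at 1.0 in
this corpus); gold-consistency runs over 200 reports across all
templates; comparisons use 30-report test sets. These sizes were chosen
as the smallest at which the measured quantities are stable across
seeds.

## Known limitations

- Line formation trusts box geometry; heavy skew splits lines and no
  rectification is attempted.
- The linker cannot distinguish a bilingual pair from two same-category
  columns separated by exactly two spaces (not observed in the modeled
  layouts, but possible in the wild).
- The baseline's pattern inventory is the quoted character classes only;
  its absolute scores are not meaningful beyond the ordering comparison.
- The CRF sees one line at a time; a value orphaned onto its own line by
  OCR can only be recovered by line normalization, not by the model.
- Qualitative-only results written in non-listed vocabulary (e.g. rare
  words beyond 阴性/阳性/正常) reduce baseline recall and, if absent from
  training data, CRF recall as well.
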