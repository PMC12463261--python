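# Methods

## Scope and model of the problem

`mednorm` standardizes free-text medication names from spontaneous
adverse-reaction reports into concepts of a local drug vocabulary, then
quantifies what standardization does to signal detection. The package
runs entirely offline: the vocabulary tiers that a production pipeline
would query through remote terminology services (a core drug
nomenclature plus a broader fallback vocabulary for international
names) are represented as local TSV file sets, and all matching
intelligence is local and reproducible.

## Normalization

Raw names pass through a fixed rule pipeline: lowercase → accent
folding → removal of parenthesized/bracketed segments → delimiter
characters (`/ \ - + ,`) to spaces → residual punctuation stripped →
tokenization → removal of pure-number and number+unit tokens →
abbreviation expansion (once per token) → unwanted-term removal →
whitespace collapse. Numbers are stripped *before* abbreviation
expansion so dose fragments ("50/12.5") can never be expanded; the
full order was chosen to reproduce the worked examples shipped with the
demo vocabulary and is asserted by tests.

Decisions worth noting:

* **Accent folding** uses canonical (NFD) decomposition with combining
  marks dropped, applied globally, so French rule entries operate on
  folded text ("comprimé" ≡ "comprime"). Canonical rather than
  compatibility decomposition ensures folding never introduces
  whitespace.
* **Parenthetical removal**: reported names frequently carry reporter
  annotations in parentheses that are not part of the name; segments in
  `()[]{}` are dropped wholesale.
* **Unit tokens** are recognized from a closed list (mg, ml, mcg, g,
  ui, iu, %) including attached forms ("500mg") — a bounded, testable
  rule rather than a general quantity parser.
* The unwanted-terms list deliberately does **not** contain "plus":
  device and brand names legitimately contain it ("ACCU-CHEK AVIVA
  PLUS"), and the `+` delimiter already handles combination joins.
* Normalization is idempotent (property-tested) and can only shorten
  the delimiter-split token list, with one documented exception: a
  multi-word abbreviation expansion ("asa" → "acetylsalicylic acid").

The special-cases file maps verbatim terms (matched on the raw
lowercase string or its normalized form) directly to a standardized
target name or concept id; it is consulted before any vocabulary
matching, and its target name is authoritative for display (an entry
may deliberately standardize to a name such as "Paracetamol" that the
vocabulary holds only as a synonym).

## Matching

**Candidate generation.** Each vocabulary tier holds a token inverted
index over all normalized names (preferred + synonyms). Candidates for
a query are all concepts indexed under any query token, exactly or at
token edit distance 1. The edit-distance bridge is the local analogue
of lexical variant generation: it guarantees that a name corrupted by a
single character edit still reaches its source concept.

**Scoring.** `sim(a,b) = ½·J + ½·C` with `J` the Jaccard overlap of
token sets and `C = 1 − lev(a,b)/max(|a|,|b|)` the normalized
Levenshtein similarity (computed with edlib). The blend is symmetric,
bounded in [0,1], equals 1 iff the strings are equal, and handles the
two dominant error modes: token reordering/subsetting (J) and
within-token misspelling (C).

**Acceptance threshold.** Default 0.40. A single-character misspelling
of a one-token name of length L scores ½·(1 − 1/L) (token sets are
disjoint); for L = 9 ("metformn" vs "metformin") that is 0.4444, and
for the 5-letter worst case 0.40 exactly — so every single-edit typo on
names ≥ 5 letters is accepted, while unrelated multi-word device names
score far below (the demo device name scores < 0.2 against every demo
concept). Raising the threshold toward 0.5 makes single-edit typos of
single-token names unmatchable under this scorer; the default is the
highest round value that keeps them.

**Cascade.** Cache hit → special case → primary-tier best match
(accepted without further evaluation) → extended-tier best match whose
*preferred name* is re-matched against the primary tier (so a
fallback hit is always anchored to a primary concept) → unmatched.
Ties break by higher score, then shorter matched name, then lower
concept id — bit-stable outputs everywhere. On vocabularies where the
exhaustive maximum-similarity winner shares at least one token (exact
or edit-distance-1) with the query, the indexed search provably equals
exhaustive search; this equivalence is exercised on 1000+ corrupted
queries against a 200-concept vocabulary in the acceptance suite.

## Caching

One JSONL file per stage (`preprocess`, `match`, `enrich`), keyed on
the **raw** input string — never the normalized form, since rule
changes would silently alias keys; instead every record carries a
pipeline-version tag and mismatched versions read as misses. Negative
results are cached so failures are never re-queried. Appends are
durable after an fsync'd flush; a truncated final line (interrupted
write) is ignored on load, while a corrupt complete line raises a cache
error naming the tier. A cache hit reports stage `CACHE` for matched
names; the stage/status invariant keeps unmatched results at stage
`NONE`. All equivalence guarantees (resume after interruption, warm
rerun) are therefore stated over the stable fields: status, concept,
standardized name, score and normalized text.

## Enrichment

Ingredients come from `HAS_INGREDIENT` relations; an ingredient-type
concept is its own ingredient link. The generic name of a brand or
combination is its ingredient names joined with `" / "` in alphabetical
order (the vocabulary's own preferred name for a pre-coordinated
combination is separate and preserved in the mapping file). ATC codes
are taken at the product level when present and otherwise from the
ingredient concept(s) — the level ATC is typically linked at — without
ever overriding a product-level code; all codes are kept, sorted, at
the 4th (chemical subgroup) level in the shipped vocabularies. Missing
metadata yields empty fields and lowers the reported
ingredient/ATC success rates rather than raising errors.

## Signal statistics

The unit of analysis is the report: drugs and events are sets, so a
report contributes once per drug–event pair. From the 2×2 table
(a, b, c, d):

* `E = (a+b)(a+c)/n`, `IC = log₂((a+0.5)/(E+0.5))` (bits);
  `IC₀₂₅ = IC − 3.3(a+0.5)^−½ − 2(a+0.5)^−3/2`,
  `IC₉₇₅ = IC + 2.4(a+0.5)^−½ + 0.5(a+0.5)^−3/2`. These closed-form
  credibility bounds are the standard shrinkage-IC approximation used
  in disproportionality screening; `information_component` is the
  single place to swap in an exact posterior if desired.
* `ROR = ad/bc` with `CI₉₅ = exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))`,
  applying the Haldane–Anscombe +0.5 correction to every cell whenever
  any cell is zero (flagged in the result). Two or more empty margins
  are rejected as undefined.
* SDR flags: `IC₀₂₅ > 0` or `ROR` lower bound `> 1`.

`compare_aggregation` computes per-variant statistics on raw name keys
and aggregated statistics after canonical-key replacement. The shipped
fragmentation fixture (10 variants × 3 co-reports, drug margin 500,
event margin 2000, 100 000 reports) realizes the dilution effect
exactly: every variant has `IC₀₂₅ = −0.8470 < 0`, the aggregate
`IC₀₂₅ = 0.9290 > 0`.

## Validation metrics

Standard confusion-matrix statistics with Wilson score 95% intervals
(chosen because the score interval is the method that reproduces
published interval bounds exactly on the shipped validation block, and
is well-behaved at proportions near 1), Cohen's κ for inter-rater
agreement, and `recover_matrix`: exhaustive enumeration of all integer
(tp, fn) consistent with a validation design and rounded point
estimates. Rounding comparisons use half-up at 4 decimal places.
Recovery errors distinguish "no solution" from "ambiguous" and list the
candidates. On the shipped design (200 pairs; 101 predicted positive;
99 negative; printed precision/recall/specificity 0.9802/0.7734/0.9722)
the solution is unique — (tp, fp, fn, tn) = (99, 2, 29, 70) — and every
derived number (balanced accuracy 0.8728, MCC 0.7159, all six Wilson
bounds) follows from it. This computation is what
`scripts/acceptance.py` performs.

## Synthetic data

The generators emulate the heterogeneity classes seen in real report
data: single-character misspellings (the dominant class), case noise,
dose-strength suffixes from a fixed menu, dose-form words, French
terms, and combination joins. Per-name random streams are derived from
(seed, name), so every output is reproducible and independent of call
order. Vocabulary names are pronounceable words of ≥ 5 letters per
token — short enough to be realistic, long enough that a single edit
stays above the matching threshold. Report tables realize a requested
signal design exactly (co-occurrence count, margins, total), with drug
mentions distributed round-robin — not randomly — across variants so
per-variant counts are deterministic.

What the generators do **not** model: real marketed-name distributions,
multi-edit misspellings, natural-health products, truncations, or
ambiguous names shared between products. Passing the synthetic recovery
test (≥ 95% of single-edit-corrupted names recovered on a seeded
200-name vocabulary) therefore demonstrates the mechanics of the
cascade, not field performance on a national database, whose match
rates depend on vocabulary coverage and noise far beyond one edit.

## Problem sizes and numerical choices

The test and acceptance workloads use vocabularies of up to 200
concepts, ~1000 matcher queries and report tables of 100 000 rows —
sizes at which the exhaustive oracle comparisons that guarantee
correctness remain exact and fast. Scores and statistics are reported
at 4 decimal places (half-up); all orderings are total (score, name
length, concept id) so outputs are byte-stable across runs and
platforms.

## Known limitations

* Matching quality is bounded by vocabulary coverage; names absent from
  both tiers are unmatched by design, and no machine-learned or
  contextual disambiguation is attempted.
* The similarity blend is a local definition; a remote terminology
  service's internal matcher would rank some candidates differently.
* Only the local backend is implemented; the module surfaces
  (``best_match``, the cascade contract) are written so a remote
  backend could satisfy the same interface.
* French support is limited to folded-accent rule entries and curated
  special cases, not translation.
* The IC credibility bounds are a closed-form approximation, not a full
  posterior computation.
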