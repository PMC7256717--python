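# Methods

## Data model

A transaction is one study's acupoint prescription as an unordered,
duplicate-free set of canonical codes. Codes are normalized before anything
else touches them: uppercase, whitespace and leading zeros stripped, and
meridian-prefix aliases rewritten through a table shipped as data
(`data/aliases.csv`). The table covers the abbreviations that actually occur
in the clinical literature (`L → LU`, `DU → GV`, `RN/REN → CV`, `SJ → TE`,
`UB → BL`, …); users can pass their own mapping. Normalization is idempotent
and rejects tokens that do not reduce to the `[A-Z]{2,3}[0-9]+` shape, so a
malformed label fails loudly at parse time with its line number rather than
silently becoming a new "item".

The bundled fixture (`data/copd_rcts.basket`) is the 12-trial COPD
prescription table. With the `L → LU` aliasing its universe is exactly 27
acupoints; without it, the two Deering codes `L5`/`L7` would masquerade as a
28th and 29th item and every marginal involving LU5/LU7 would be wrong. That
consistency check (27 items, LU5/LU7 among the ten most frequent points) is
what pins the alias interpretation down, and it is recorded in the fixture's
tests rather than in prose only.

Three interchangeable file dialects (basket text, long CSV, binary incidence
matrix CSV) round-trip losslessly; the matrix reader accepts items as rows or
columns, auto-detected from the corner header token, and treats any cell
outside {0,1} as an error rather than truncating.

## Mining

`mine_frequent` is textbook level-wise Apriori: L1 from single-item counts;
candidates for level k+1 by joining frequent k-itemsets that share their
first k−1 items in canonical alphabetical order; pruning of any candidate
with an infrequent k-subset; counting by bitset subset tests (each
transaction is an integer mask over the universe). The intended scale —
tens-to-thousands of transactions, tens of items — makes Python integers as
bitsets entirely adequate; no FP-Growth-style alternative is needed or
provided.

Support and confidence thresholds are held as `fractions.Fraction` (floats
are converted through their decimal string, so `0.2` means exactly 1/5) and
compared inclusively in exact arithmetic. This is not pedantry: the
published-style thresholds sit exactly on data values (a rule with
confidence exactly 0.8 must be *retained*), and float comparison at such
boundaries is exactly where reimplementations drift.

`brute_force_frequent` enumerates every subset of the universe up to
`max_len` and counts supports directly. It shares nothing with the miner but
the result type, is guarded to ≤ 20 items, and exists purely as an oracle:
the test suite checks itemset-for-itemset equality against it on hundreds of
randomized databases.

## Rules and their metrics

Every frequent itemset Z is split into each antecedent/consequent partition
with `consequent_size` items on the right. All four metrics are exact
rationals of counts, so the identities `lift · expected_confidence =
confidence`, `confidence · supp(LHS) = supp(rule)`, and lift symmetry
between a rule and its reciprocal hold *exactly*, and the tests assert them
with `==`, not tolerances. Metrics are rendered as 7-decimal strings only at
the export boundary.

### Default structural convention

The defaults are `min_support = 0.2`, `min_confidence = 0.8`,
`consequent_size = 1`, `max_len = 5`, `min_antecedent_size = 0`. The two
structural choices deserve explanation, because the analysis ecosystem this
package interoperates with (R `arules`, which wraps Borgelt's apriori
implementation) makes exactly these choices and headline rule counts depend
on them:

- **`max_len = 5`**: Borgelt's miner defaults to at most five items per
  rule. On the bundled fixture the convention matters a lot — the data
  contain a 10-point combination shared by three trials, so every subset of
  it is frequent and the rule count grows steeply with `max_len` (64 rules
  at pairs only, 2444 at ≤ 5 items, 5008 unbounded).
- **`min_antecedent_size = 0`**: `arules`' `minlen = 1` admits rules with an
  empty antecedent, whose confidence is the consequent's marginal support.
  On the fixture exactly one item clears the 0.8 confidence bar that way
  (BL13, support 10/12), contributing the 2444th rule.

Under these defaults `mine --fixture` reproduces the published rule count
exactly; both knobs are ordinary parameters for anyone wanting a different
convention.

### Ranking and ties

`rank_rules` orders by support, then confidence, then lift (all descending),
then alphabetically — a total order, so output is deterministic. When the
k-th place is shared, the full metric-tie group can be requested alongside.
The published top-10 table for the fixture is a ranking of rules *between
individual acupoints*; it is reproduced by mining with `max_len = 2,
min_antecedent_size = 1`, where the ten qualifying rules are unambiguous as
a set (the full default ruleset would interleave composite
confidence-1.0 rules such as `{BL13,ST36} ⇒ {EXB1}` into the same support
tier).

### Grouped summary

The grouped-rules export partitions a rule set by identical consequent and
orders groups by their best member's support. Upstream visualization tools
cluster antecedents with an undocumented heuristic before grouping; this
package deliberately replaces that with the deterministic
consequent-partition, which supports the same interpretive claims (which
consequents attract the strongest rules, and from which antecedents) without
reverse-engineering a plotting library. Pixel-level figure reproduction is a
non-goal; every figure's underlying numbers are available as CSV/JSON.

## Synthetic generator

`PlantedModel` draws each transaction by including every planted core k
wholly with probability π_k and every universe item independently with
background probability p (p < min π_k; cores pairwise disjoint). Expected
core support is π + (1 − π)p^|C|. Defaults in the tests emulate the shape of
the real data: universes of ~20 items, 2000 transactions for calibration
runs, cores of 3 items with π = 0.4 over p = 0.1 background.

Two honest limitations. First, empty transactions are re-drawn to keep the
database valid, which conditions the item distribution on non-emptiness; the
closed-form support expectation is accurate only in regimes where empties
are rare (with the default p and universe size the empty probability is
≈ 0.1³⁰ per draw — negligible; at very sparse settings the conditioning
visibly inflates supports, and the test suite pins one such regime down).
Second, background items are independent Bernoulli draws: real prescriptions
have correlated "accessory" points, school-of-practice effects and
size-constrained baskets, none of which the generator emulates. Passing
recovery tests therefore demonstrate correctness of the mining machinery and
detection calibration under a known null — not that the thresholds are
clinically optimal for real prescription data.

The recovery criterion used in acceptance: a core with π − 3·SE above the
support threshold (SE = √(π(1−π)/N), N = 2000) must be detected in ≥ 95% of
50 seeded simulations; per-seed detection probability is ≈ Φ(3) ≈ 0.999, so
the margin is comfortable and failures indicate real defects, not noise.

## CLI

The CLI is a thin wiring layer: `mine` (full pipeline and all exports),
`freq` (frequency ranking only), `simulate` (model file → DB → recovery
report), `export` (dialect conversion). Diagnostics and the effective
parameter set go to stderr; data go to files; `--summary-json` prints a
machine-readable run summary. Precedence is explicit flags over config file
over defaults — the conventional reading, chosen deliberately so a config
file can define a study profile while any flag remains an override.

## Degenerate inputs and numerical notes

- Empty database or empty transaction: validation error, never silently
  dropped; duplicate codes within a prescription collapse with a logged
  warning (support is defined on presence).
- A support threshold above every item's support yields an empty result, not
  an error; rule generation on an empty itemset collection yields an empty
  rule set.
- All tie-breaks (candidate join order, ranking, group order) are canonical
  alphabetical, so every output is a pure function of the input set, not of
  input order.
- Mean lift in group summaries is the arithmetic mean of exact rationals;
  it is the one group statistic that is not order-statistics-based, and it
  stays a `Fraction` until rendered.
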