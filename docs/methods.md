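# Methods

## Data model and conventions

Tables are ordered collections of opaque text cells. Cells compare as exact
tokens: `29` and `29.0` are different values, and a hierarchy's level-0 keys
must match raw cells byte-for-byte. Numeric interpretation happens only
where an operation demands it (interval binning, the ordered earth-mover's
distance). Missing cells are kept as the empty-string token and form their
own equivalence key — merging them with any real value would overstate
anonymity. Row identity is positional: every row keeps its index in the
original input, so suppression reports can name exactly which input rows
were deleted.

An equivalence class is a maximal set of rows identical on every
quasi-identifier; the partition is computed in first-appearance order, which
makes every downstream choice (and hence the whole engine) deterministic.

## Hierarchies

A hierarchy is a chain of total mappings h₁…hₙ; level j must cover the whole
image of level j−1, and the chain composes to a single-valued map from raw
values to any level. Construction validates both properties, so a
mis-specified hierarchy fails at load time, not mid-search.

Serialization follows the ARX column convention (one row per raw value,
column j = its level-j generalization), plus two config shorthands:
`{type: interval, lower, upper, steps: [...]}` for numeric binning and
`{type: suppression}` for a single level mapping everything to `*`. Interval
bins are half-open `[a, b)` — left-closed, right-open — and the label is
rendered exactly as `[a, b)` with integer bounds printed without a decimal
point, so generalized tables can be compared byte-for-byte against published
ones. Consecutive interval steps must nest (each level-j bin lies inside one
level-j+1 bin); non-nesting step sequences are rejected as non-functional
rather than silently re-binned from the raw values.

`get_transformation` recovers the applied level per column as the unique
level whose image contains every observed value. If two levels' images
collide (e.g. `*` is the image of two levels), the lowest matching level
wins; this is an explicit tie-break, documented because the images are not
guaranteed disjoint in general.

## Privacy metrics

All sensitive-attribute metrics use natural logarithms. The global
distribution q is measured on the retained rows of the audited table — the
table as it would be published — not on any pre-suppression ancestor.
The entropy-ℓ report value is `floor(exp(min_EC H) + 1e-9)`: the tolerance
keeps `exp(ln 3)` from flooring to 2. The categorical earth-mover's distance
(equal ground distance) reduces to total variation, EMD = ½·Σ|p−q|; the
numeric variant orders the support and uses the normalized cumulative sum,
(1/(m−1))·Σᵢ|Σ_{j≤i}(p_j−q_j)|. The numeric variant is opt-in because most
sensitive attributes in practice are categorical, and applying an ordered
distance to category codes would be meaningless.

Satisfaction conventions: k-anonymity and the ℓ-family are "at least";
t-closeness and β-likeness are "at most"; δ-disclosure is strict
("achieved δ" is the supremum |ln(p/q)|, and a table satisfies the model for
any requirement strictly above it). The enhanced β-likeness criterion caps
each value's excess at min(β, −ln q); since no single achieved statistic is
standard for it, the report carries the same max-excess value as basic
β-likeness plus a feasibility flag that is false when some value's excess
exceeds −ln q (in which case no β can ever satisfy the enhanced model).
The reported recursive-(c,ℓ) value is the smallest integer c at ℓ equal to
the table's achieved ℓ-diversity, which always exists.

## The search engine

The lattice of transformation vectors is walked greedily: starting from all
zeros, the engine repeatedly checks whether deleting every violating
equivalence class fits the suppression budget, and if not generalizes one
more level on the quasi-identifier with the most distinct values in the
current table state (ties broken by schema QI order). Composite models run
two phases — k-anonymity first, then the sensitive-attribute criterion —
sharing a single budget, always measured against the original row count.

Two deliberate refinements:

- **Deletion runs to a fixpoint before committing.** Deleting classes
  changes the global distribution q, which can push previously satisfied
  classes into violation for the distribution-comparing models (t-closeness,
  δ-disclosure, β-likeness). The engine therefore simulates iterated
  whole-class deletion until stable and commits only if the total stays
  within budget; otherwise it generalizes. For plain k-anonymity one pass is
  already the fixpoint. A fixpoint that would delete every row is treated as
  infeasible: an empty table is not a meaningful anonymization and the
  auditor rejects empty input.
- **Exhaustive fallback.** The greedy path is a single trajectory through
  the lattice and is not complete for non-monotone criteria (a feasible
  node can sit off the trajectory). When the walk exhausts the lattice, the
  engine scans all nodes in a fixed order (total generalization, then
  lexicographic) before raising an unachievable-requirement error, so "no
  solution" genuinely means no lattice node plus in-budget suppression
  works. The error reports the best transformation found and its residual
  violation count. The fallback never triggers on instances the greedy
  solves, so typical runs stay linear in the lattice depth.

Suppression always deletes whole equivalence classes — partial deletion
would break the class semantics the metrics are defined on. The engine
contains no randomness: identical inputs produce byte-identical outputs.

The greedy heuristic reproduces the published hospital worked examples
(transformations [2,0,0] and [2,0,1]) but is not guaranteed to pick the same
vector as other tools on other data; only the satisfied requirement, the
budget bound and determinism are contractual.

## Synthetic data

`sdctab.fixtures.generate_synthetic` draws each column independently —
categorical values with given weights, uniform integers, or clipped
rounded-normal integers — fully determined by a seed. It emulates the shape
of microdata (small-cardinality quasi-identifiers, a categorical sensitive
attribute, tens to thousands of rows) but none of the correlation structure
of real populations; passing tests on it demonstrates the correctness of
the partitioning, metrics and search, not the utility or risk profile of
any real dataset. Test instances use tables of up to 50 rows for metric
cross-validation (where exhaustive re-computation is the oracle) and
lattices of at most a few dozen nodes for the completeness property (where
exhaustive lattice search is the oracle); these sizes make the oracles exact
rather than sampled.

## Limitations

- One sensitive attribute per run. Multiple sensitive attributes can be
  handled by iterating the engine — anonymize for the first, re-anonymize
  the result for the next (optionally moving the remaining sensitive columns
  into the quasi-identifier list) — but no automation is provided.
- No information-loss or utility metrics, and no optimal-lattice algorithms
  (Incognito/OLA/Mondrian-style); the search is the greedy-plus-fallback
  scheme above.
- CSV is the only table format; cells are never type-coerced on read.
- Re-identification risk models (prosecutor/journalist risk) are out of
  scope; the auditor reports achieved model parameters only.
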