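# Methods

## The descriptive model

A knowledge base is a taxon × descriptor matrix of categorical observations.
Each descriptor carries an ordered vocabulary of at least two state labels;
labels are opaque tokens — numeric-looking labels such as `"5"` or `"10–14"`
are categories, never parsed as numbers. A cell is exactly one of:

- a **non-empty state set** — several states record intraspecific
  polymorphism ("Black; Orange"), not uncertainty;
- **INAPPLICABLE** — the structure the descriptor refers to is absent in that
  taxon; a recorded, expected absence;
- **UNKNOWN** — nothing recorded.

Descriptors may depend on a parent descriptor with a set of *triggering
states*; the links must form a forest. A descriptor applies to a taxon iff it
has no dependency, or its parent applies and the taxon's parent cell is a
state set intersecting the triggering states. A polymorphic parent cell
triggers when **any** of its states does — validated against the packaged
matrix, where a species with marking type "Ovoid shape spot; Other" still has
line counts recorded even though only one of the two states triggers them.
An UNKNOWN or INAPPLICABLE parent cell never triggers.

The consistency check (`check_base`) reports completeness (a cell is complete
iff it is a state set or INAPPLICABLE — only UNKNOWN counts as missing,
so a fully coded base with structural absences scores 100 %), pairs of taxa
with cell-by-cell identical descriptions, and dependency violations (a state
set recorded where the descriptor does not apply, or INAPPLICABLE recorded
where it does).

## Comparison semantics

For one descriptor, a taxon pair is IDENTICAL (equal sets), OVERLAP (shared
but unequal), DISJOINT (no shared state — the descriptor fully discriminates
the pair), or NOT_COMPARABLE (either cell INAPPLICABLE or UNKNOWN). UNKNOWN
is treated exactly like INAPPLICABLE here: incompatibility cannot be asserted
from missing data.

The discriminatory-power index of a descriptor over *n* taxa is the number of
DISJOINT pairs divided by **all** `n(n−1)/2` unordered pairs, not-comparable
pairs included in the denominator. This convention reproduces both published
two-decimal worked values from their printed group sizes (65/2145 = 0.03;
120/2145 = 0.06); the alternative comparable-pairs denominator happens to
round identically for the second case (120/1891), so one convention had to be
fixed — the all-pairs form is the one implemented, and also the one that
penalises characters unobservable on part of the taxon set, which matches how
the index is used to order characters.

## Informative vs constant (group comparison)

Within a group, a descriptor is **informative** iff at least two members have
unequal cells, where INAPPLICABLE counts as a distinct value of its own and
UNKNOWN cells are excluded (they can never make a descriptor informative).
This deliberately differs from the DISJOINT rule above: informativeness asks
whether members *differ* (and "structure present" vs "structure absent" is a
difference), while the index asks whether a pair can be *told apart* by
observing the character. The packaged matrix pins both choices: two of its
rows are constant among the taxa to which they apply yet are classified
informative purely because two species lack the structure.

Group unions/intersections carry INAPPLICABLE through: the union flags it,
the intersection is the INAPPLICABLE marker when no member has states, and
empty when applicability is mixed.

The between-group variability table reports, per group: distinct species,
items (colour forms), informative descriptors, the same as a percentage of
all descriptors (rounded half-up to an integer), and divided by the item
count (rounded half-up to one decimal). Groups with one item have nothing to
compare and carry missing values; the TSV renderer additionally dashes every
single-*species* group, matching how such tables are conventionally printed
(a genus represented by one species is dashed even when two of its colour
forms are coded).

## Minimal diagnostic sets

"Sufficient subset" is interpreted as *identical covered-pair sets*, not
merely an equal count — stronger and deterministic. Pairs no descriptor
separates (e.g. species a base deliberately leaves undistinguished) are
excluded from the requirement rather than causing failure. Greedy adds the
descriptor covering the most uncovered pairs (ties: fewest states, then
lowest id). Exact runs branch-and-bound set cover seeded with the greedy
solution: branch on the coverers of the uncovered pair with fewest of them,
prune with `⌈uncovered / best-single-descriptor-coverage⌉`; refused above 22
descriptors by default (worst-case exponential).

## Single-access key induction

At a node with remaining taxa R (|R| ≥ 2), candidate descriptors must be
applicable to **and** known for every taxon in R, unused on the path, and not
give all of R the same cell. The candidate maximising the index restricted to
R wins (ties: fewer states, then lower id). One branch per state present in
at least one remaining cell; a polymorphic taxon follows every branch whose
state it possesses, so it can own several root-to-leaf paths. Recursion stops
at singletons (resolved leaves) or when no candidate separates R (unresolved
leaf — taxa that cannot be told apart under the applicable-to-all rule).
Descriptors never repeat along a path: after branching, a descriptor's
observed state is fixed, and re-splitting polymorphic taxa on it would trade
key readability for nothing.

Path statistics: a step is one internal node traversed; per taxon the number
of paths and shortest/longest/mean lengths; globally the mean over taxa of
the per-taxon means, plus ranges. The requirement that every candidate be
known and applicable for *all* remaining taxa is a design choice — it
guarantees every question on a path is observable for every taxon still in
play, at the price of sometimes leaving separable pairs unresolved when
coverage is patchy.

## Multi-access identification

A session accumulates observations (a state set per descriptor, or an
explicit INAPPLICABLE answer — "the structure is absent on my specimen").
A taxon mismatches an observation iff its cell is a state set disjoint from
the observed states, or applicability disagrees in either direction. UNKNOWN
cells never mismatch. With tolerance *k*, candidates are taxa with at most
*k* mismatching observations, ranked by mismatch count then name; *k* = 1
guarantees a single observation error cannot eliminate the true taxon.
Under polymorphism a non-empty intersection between observed and recorded
states counts as compatible. Candidate filtering is a pure function of the
choice set, so replay order is irrelevant. Remaining descriptors are ranked
by the index restricted to the current candidates, dropping those that
separate no candidate pair.

## Synthetic bases

The generator's defaults are the ladybird-base profile: 66 taxa, 21
descriptors with the published per-descriptor state counts (98 states, 2–12,
mean 4.67), a dependency forest hitting the published role counts (5
independent / 4 parents / 14 children / 2 both), polymorphism probability
0.15 per applicable cell (the published base reports no rate; roughly one
cell in seven polymorphic is in line with its printed six-species matrix),
no unknowns (the base is 100 % complete), and duplicate descriptions
resampled away (the base has none). Triggering sets have size 1, matching
presence/absence parents. All randomness flows from one `random.Random(seed)`
stream, so equal seeds give byte-identical bases.

Role assignment draws pure parents, parent-and-child, pure children and
independents from a shuffled id list; parent-and-child nodes attach only to
earlier parent-capable nodes (acyclic by construction), and children are
reassigned if some designated parent would otherwise end up childless.
Dependency targets that do not account for every descriptor leave the
remainder independent. Distinctness is enforced by redrawing only the
clashing rows, up to 100 retries, then raising an infeasibility error.

What the generator does **not** emulate: real state frequencies are not
uniform (wild colour morphs are strongly skewed), characters are correlated
(markings entail marking colours), and taxonomy is not random — so passing
tests show the algorithms are correct on structurally realistic matrices, not
that any biological conclusion transfers.

`generate_planted_kb` builds oracle bases with a known unique minimum
diagnostic set: one reference taxon plus one taxon per planted binary
descriptor differing on that descriptor alone, so each planted descriptor is
the sole separator of one pair.

## Numerical and formatting choices

- Printed-style roundings use half-up (`round_half_up`, via `decimal`), never
  banker's rounding: 16/21 → 76 %, 1/21 → 5 %, 13/4 → 3.3.
- Indices are kept at full float precision internally; rounding happens only
  in reports.
- All tie-breaks (greedy cover, key node choice, ranking) end on ascending
  descriptor id, making every pipeline stage deterministic.
- Degenerate inputs: an index over fewer than two taxa is an error; a key
  over an empty base is an error, over one taxon a single resolved leaf; an
  empty identification base yields an empty candidate list.
- CSV-matrix files cannot declare vocabularies, so reading one infers states
  from observed cells and waives the two-state minimum; JSON is the
  full-fidelity format and validates strictly.

## Fixture notes

The packaged matrix keeps the printed row order and labels; a sidecar maps
each row to the canonical descriptor numbering 1–21 used everywhere else.
The dependency map is reconstructed as the minimal forest consistent with
every "not applicable" cell in the matrix (3,4 ← 2=Present; 7,8,9,12,13,14,
15,16,19 ← 6=Present; 10,11 ← 9 ∈ {Regular dots, Ovoid shape spot}; 17,18 ←
16=Present); the full base's own map is not published, and the reconstruction
yields 4 independent / 4 parents / 15 children / 2 both — close to, but not
forced to match, the published 5/4/14/2, which the generator targets instead.
States never shown in the matrix (the complement of a constant
presence/absence character) are added to keep vocabularies legal; for binary
characters this reproduces the published state counts exactly.

The published full-base numbers that require the online 66-taxon matrix
(the complete index column, the 11-descriptor minimal set, the generated
key's mean 4.2 steps and 1.5 paths) are shipped as reference metadata only;
the corresponding machinery is validated by exhaustive-oracle property tests
on synthetic bases instead (exact-cover optimality on ≤ 8 descriptors by
full enumeration, key soundness/completeness and path statistics against an
independent path walk on 100 seeded bases, identification error tolerance
over seeded trials).

## Problem sizes

Oracle and property tests run on bases of 8–20 taxa and 5–8 descriptors
(hundreds of seeds), where exhaustive enumeration is itself cheap; the
ladybird profile (66 × 21) is exercised for structure, distinctness and
distribution checks. The full test suite completes in a few seconds.
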