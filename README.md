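# polyclave

Analytics and key generation for **multi-access (polyclave) identification
keys** built on categorical colour/pattern characters — the kind of knowledge
base behind interactive field-identification tools for groups like ladybirds
(Coleoptera, Coccinellidae).

A knowledge base couples a descriptive model with descriptions:

- **descriptors** (characters): finite state vocabularies, optionally
  *dependent* on a parent descriptor ("Shape of the scutellar spot" only
  exists when "Scutellar spot = Present"); the dependency links form a forest;
- **taxa**: species or intraspecific colour forms;
- **cells**: for each taxon × descriptor a non-empty state set (several
  states record intraspecific polymorphism), an explicit *inapplicable*
  marker, or *unknown*.

On top of that model the package computes:

| stage | what it does |
|---|---|
| `check_base` | completeness, duplicated descriptions, dependency violations |
| `compare_pair`, `xper_index`, `power_table` | pairwise outcomes and the discriminatory-power index |
| `minimal_descriptor_set` | smallest descriptor subset separating the same taxon pairs as the full set (greedy or certified-exact set cover) |
| `group_summary`, `variability_table` | within-genus union/intersection and informative-vs-constant classification; between-genus variability |
| `build_key`, `key_statistics`, `export_key` | greedy single-access key induction, per-taxon path statistics, text/DOT export |
| `start_session`, `apply_choice`, `next_descriptors` | multi-access identification with best-character ordering and error tolerance |
| `generate_kb`, `load_fixture` | synthetic bases with realistic structure; packaged reference fixtures |

## The core statistic

For one descriptor *d* and two taxa with state sets *S₁*, *S₂*, the pair is
**incompatible** (fully discriminated) when *S₁ ∩ S₂ = ∅*. Over a taxon set of
size *n* the discriminatory power of *d* is

```
index(d) = #{unordered pairs with disjoint state sets} / (n·(n−1)/2)
```

ranging from 0 (separates nothing) to 1 (separates every pair). Pairs that
cannot be compared on *d* (an inapplicable or unknown cell) count in the
denominator but never in the numerator: a 65-vs-1 binary split over 66 taxa
gives 65/2145 → **0.03**, and a 60-vs-2 split with 4 inapplicable taxa gives
120/2145 → **0.06**.

A **minimal diagnostic set** is a smallest descriptor subset whose covered
pair set (pairs separated by ≥ 1 member) equals the full set's — a set-cover
problem solved greedily or exactly with branch-and-bound.

## Worked example

The packaged fixture is the published six-species *Coccinella* comparison
matrix (6 taxa × 21 descriptors):

```python
>>> import polyclave as pc
>>> kb = pc.load_fixture("coccinella_table4")
>>> pc.check_base(kb).completeness        # every cell recorded
1.0
>>> len(pc.informative_descriptors(kb, kb.taxon_ids))
12
>>> sorted(pc.discriminating_descriptors(kb, "coccinella_septempunctata",
...                                      "coccinella_magnifica"))
[21]
```

Twelve of the 21 characters vary within the genus (the other nine are
constant and describe the genus itself), and the species pair
*C. septempunctata* / *C. magnifica* is separable by exactly one character —
number 21, the small white triangular underside marks. The power table ranks
characters by how many of the 15 species pairs they separate:

```python
>>> pc.power_table(kb).head(3)[["descriptor_id", "name", "index", "rank"]]
   descriptor_id                                     name     index  rank
0              8                Number of elytra markings  0.800000     1
1              9                  Type of elytra markings  0.533333     2
2             12  A spot in the first third of the elytra  0.533333     3
```

and three characters suffice to tell all six species apart:

```sh
$ polyclave minset --kb src/polyclave/data/coccinella_table4.json --method exact
{ ... "descriptors": [8, 11, 21], "size": 3, "certified_minimum": true ... }
```

The same analyses run from the shell: `polyclave check | stats | power |
minset | compare-group | build-key | identify | simulate` (see `--help`).

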