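# Methods

## The survey model

A survey is a flat table of citations: one row per (respondent, species,
part, use category, specific use), optionally carrying a pebble-technique
availability judgement (`very_abundant`, `abundant`, `not_abundant`,
`rare`, `very_rare`). Use categories are the six standard classes of
wildlife use: food, medicinal, cosmetic, traditional/cultural, artisanal
and commercial. Specific uses are free text; labels are canonicalized
(case-folded, whitespace-collapsed) before any distinct-count, so
"Grilled  Meat" and "grilled meat" are one use.

`N`, the citation-frequency denominator, is always derived from the
dataset at hand: the union of the respondent registry (interviewees
enrolled whether or not they cited anything — populated by the
generator) and the respondents appearing in records. It is never a
configuration constant, so subsetting a dataset automatically rescales
CF. Data read from a bare citation CSV has no registry; its N is the
number of distinct citing respondents.

## Counting reported use

`RUsp = ΣNCp` is computed as the number of **distinct**
(part, canonical specific use) combinations per species, deduplicated
across respondents. The alternative — counting every citation record —
forces RU ≥ ni, which published use tables contradict (heavily cited
species routinely show fewer reported uses than citers, e.g. a species
cited by 8 of 17 respondents with only 3 reported uses). Under the
deduplicated reading RU measures the breadth of a species' use
repertoire and is independent of interview volume, which also gives the
battery a clean scale-invariance: cloning every respondent changes no
index. The per-species record count remains an upper bound on RU and is
logged by the pipeline.

Consequences carried through the package:

- ΣNCp over parts ≤ records per species (equality only when no two
  records repeat a part-use).
- Adding a record never decreases a species' ni, RU or NSU
  (monotonicity), verified by property tests.

## The use-value denominator

By default `UVsp = 100·RUsp/ΣRU` with ΣRU summed over the species in
the dataset, so UV sums to exactly 100 (float tolerance 1e-9). The
packaged study fixture carries `reference_use_total = 185` in its
metadata because the source study normalized its UV column against a
base of 185 reported uses while the per-species uses reconstructed from
that same column sum to 193 (its printed UV column sums to 104.28%, not
100%). `compute_use_table(ds, ru_total=...)` accepts the recorded base
so the published values can be reproduced exactly; analyses of fresh
data should leave the default. NSU (distinct specific uses, the UDI
numerator) is deliberately kept separate from the count of distinct use
*categories* that feeds vulnerability parameter P2: the former is
free-text diversity (unbounded), the latter is bounded by six.

## Vulnerability scoring

P1 thresholds apply to the CF percentage (< 5 → 1, [5, 15) → 2,
≥ 15 → 3); P2 to the distinct use-category count (< 2 → 1, 2–3 → 2,
≥ 4 → 3); P3 to the modal availability category (very abundant or
abundant → 1, not abundant → 2, rare or very rare → 3 — the five field
categories surject onto the three levels, with "not abundant",
25%–50% availability, as the middle "scarce" level). The modal category
is summarized with a consensus value (modal share of judgements; ≥ 1/5
whenever a judgement exists). Ties break toward the scarcer category by
default — a precautionary conservation choice — configurable to
`more_abundant`. The modal category, not the consensus share, drives
P3; weighting by consensus is deliberately not applied.

`VI = (P1+P2+P3)/3` is carried as an exact rational (`fractions.
Fraction`), so the class boundaries — VI = 2 inclusive for moderately
vulnerable, VI = 2.5 inclusive for vulnerable — classify exactly, with
no float-boundary risk. All 27 parameter triples are enumerated in
tests against an independently stated hand rule. Species with no
availability judgement receive P1/P2 but are flagged `unscored` rather
than guessed at.

## The synthetic generator

`generate_survey` emulates the structure of a village-interview
bushmeat survey: each respondent cites each species independently with
a per-species probability; a citation reports 1–3 parts (default
distribution 0.7/0.2/0.1), each with a specific use drawn from a
six-category multinomial; one availability judgement is attached per
citation. Defaults mirror the study conditions: a 298-respondent pool,
food dominating the category mix at 0.68 (medicinal 0.14 and
traditional/cultural 0.09 the main secondary uses, matching the
reported predominance of wild-meat consumption), and availability
judgements centred on the middle of the abundance scale (0.10/0.25/
0.35/0.20/0.10) — a reserve perceived as neither pristine nor empty.
Sociodemographic attributes (gender, ethnicity, religion, age) are
generated from the study's published proportions as inert respondent
metadata; no index reads them. All randomness flows from one
`numpy.random.default_rng(seed)`; the same seed yields byte-identical
CSV output.

What the generator does **not** emulate: snowball-recruitment network
structure (respondents are independent), correlation between a species'
citation probability and its availability judgements, respondent-level
heterogeneity in knowledge, and seasonal effects. Passing tests on
generated data therefore demonstrate the correctness and calibration of
the index pipeline, not the field realism of any particular dataset.

## The deterministic study fixture

`table3_fixture` rebuilds a dataset behind a published 48-row
use-importance table by brute-force denominator search: 17 effective
respondents is the smallest N reproducing every printed CF at 2
decimals (printed CFs are the multiples of 100/17), 185 the smallest UV
base, and 3 the NSU maximum (printed UDIs are 33.33/66.67/100). Per
species, ni = round(CF·17/100) citers and RU = round(UV·185/100)
distinct part-uses spanning NSU = round(UDI·3/100) specific uses are
laid out deterministically (citers rotate through the 17-respondent
pool; the first citer reports every pair, the rest repeat the first
pair), giving 280 records. From these counts the pipeline reproduces
every printed CF, UV, UDI at 2 decimals and every printed IVIU within
±0.02 (in fact exactly at 2 decimals, full precision absorbing the
table's component rounding). Availability judgements are not published
per species; the fixture cycles the five categories so the
vulnerability stage is exercised, and its class counts are therefore
not a reproduction of the study's (the study's per-species P2/P3
inputs are unpublished).

The packaged taxonomy covers the 49 printed species rows. Counting
those rows gives 30 families, 43 genera and 6 classes; the source
text's own prose totals (31 families, 46 genera) do not match its
printed table, and the package reports what the rows contain. Per-family
counts that the prose and table agree on (Bovidae 5, Cercopithecidae 4,
Muridae 4) are asserted in tests. Red List categories are taken from a
local table, never an API; summary percentages are computed over the
package's own species count.

## Numerical and design choices

- All index arithmetic is full precision; 2-decimal rounding is applied
  only at serialization (CSV display), and `results.json` carries full
  precision. Published tables round components before summing, so
  composites can differ by ±0.01 from the sum of printed components;
  computing at full precision avoids baking that in.
- Ranking ties (equal IVIU) break lexicographically by species id, and
  every tabulation orders deterministically, so identical inputs yield
  byte-identical reports.
- Empty datasets are errors for every aggregate (no silent zero
  tables); an empty use-value denominator returns UV = 0 only for the
  scalar helper, logged as the empty-dataset convention.
- Problem sizes in tests: property suites run on datasets of ≤ 5
  respondents × ≤ 4 species against a brute-force recount oracle;
  generator calibration uses 500–2000 respondents (5000+ records) and
  60 seeded replicates for the law-of-large-numbers check — sizes at
  which binomial error is well inside the asserted ±1–3 point bands.

## Known limitations

- The citation-frequency denominator of a CSV-loaded survey counts only
  citing respondents; enrolled-but-silent interviewees must be supplied
  via the registry (the CSV format has no row for "cited nothing").
- The fixture's vulnerability classes and its use-typology shares are
  artifacts of its deterministic layout, not study results.
- Free-text specific-use canonicalization is lexical only; synonyms
  ("grilled meat" vs "roasted meat") count as distinct uses.
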