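# Methods

## Disease paths

Input is long-format: one (patient, visit date, code) row per diagnosis,
so a multi-diagnosis visit is several rows sharing patient and date. Codes
are truncated to the 3-digit ICD-9-CM base category (decimal suffix
stripped, left-zero-padded: "42" → "042"); supplementary-classification
codes (V01–V91, E000–E999, case-insensitive) are excluded, and codes that
are neither numeric nor V/E-prefixed are dropped with a logged count.
Cohort filters remove patients failing an active sex filter (patients with
unknown sex are dropped only when a filter is active) and patients older
than `max_age` (default 99 years) at the `reference_date` (default
2018-10-01). Patients with no birth date are retained: the age filter is
simply inapplicable to them, and dropping them would silently shrink
cohorts with patchy demographics.

Each patient's path is the sequence of *first occurrences*: each distinct
3-digit code is assigned to the date of its earliest record, and codes
sharing that date share a bucket. Duplicate same-day rows of a code
collapse to one event. Bucket dates strictly increase, every code appears
in exactly one bucket, and re-extracting paths from their own serialized
records is idempotent (tested).

## Network construction

Transitions are *bucket-bipartite*: every code of bucket t links to every
code of bucket t+1, with no intra-bucket and no skip edges. There is no
upper limit on the calendar gap between consecutive buckets. Because first
occurrences are unique, a patient contributes at most one event to any
ordered pair, so `w_ij` is a patient count. Node prevalence `N_i` is the
number of patients whose path contains i.

Each ordered pair (i, j) with w ≥ 1 gets a 2×2 table over the population
of all transition events: a = events i→j, b = i→other, c = other→j,
d = the rest. The one-sided Fisher exact p-value is the hypergeometric
tail P(X ≥ a) with margins fixed (alternative "greater": enrichment of
i preceding j), computed via `scipy.stats.hypergeom.sf`; the test suite
checks it against exact integer-arithmetic enumeration to 1e-12 for every
table with total count ≤ 50. φ is the Pearson association of the same
table, defined as 0 whenever a marginal is zero (association is undefined
there, and a neutral value avoids NaN propagation). An all-zero table has
p = 1.

Filters run in a fixed order, each recording its removal count in the
provenance report:

1. **Node prevalence** — nodes with N_i below the nearest-rank
   `node_percentile` (default 10th) percentile of the prevalence
   distribution are dropped with their incident edges. An
   `explicit_min_node` count can replace the percentile rule when a
   specific threshold is required.
2. **Pair count** — edges with w < `min_pair` (default 100 patients).
3. **Death codes** — edges incident in either direction to a code in
   `death_codes` (default {"798"}, sudden death cause unknown); such
   pairs are treated as recording artifacts rather than progression.
4. **Significance** — Benjamini–Hochberg over the family of edges that
   survived steps 1–3 (the family actually tested), keeping adjusted
   p < `alpha` (default 0.05). Running BH after the cleaning steps keeps
   the correction aligned with the hypotheses that remain of interest;
   the family size is reported so sensitivity checks are possible.

Filters are contractive and the per-stage counts sum exactly to
input − output (tested on a fully hand-checked 20-patient cohort).

## Centrality and fatality

* **K_w**: sum of edge weights over in- and out-edges — incoming plus
  outgoing patients.
* **PageRank**: weighted, directed, damping 0.85, uniform teleportation
  and uniform dangling redistribution; converged to 1e-12 in L1. Checked
  against dense power iteration to 1e-8.
* **Betweenness**: directed, normalized by (n−1)(n−2), with edge
  distance 1/w by default so heavy-traffic edges are short — consistent
  with the trajectory metric; an unweighted variant is available.
  Checked against exhaustive simple-path enumeration on small graphs.
* **Fatality**: fraction of patients dead within `horizon_years`
  (default 8) of their first diagnosis of a code. The denominator is
  restricted to patients observed for the full horizon (first diagnosis
  + horizon ≤ `data_end`) or dead within it; incompletely followed
  survivors would otherwise be indistinguishable from survivors and
  would dilute the estimate. Note the converse bias: deaths among
  recently diagnosed patients are counted while their surviving peers
  are not, so on cohorts whose diagnosis dates run to the end of
  follow-up the estimate sits above the per-disease death probability.
  Recovery tests therefore use cohorts whose diagnosis window ends a
  full horizon before `data_end`, where the estimator is unbiased.
* **Spearman** comparisons use average ranks for ties and drop pairs
  with missing fatality.

## Communities

The map-equation partition is computed by the Infomap algorithm as
implemented in `igraph` (two-level, directed, edge weights as flow, best
of `trials` = 10 optimizations). Determinism: igraph draws randomness
from Python's `random` module, which is re-seeded from the configured
seed on every call. Per-node flow is the stationary visit density of the
damped random walk (teleportation 0.15) — the same walk PageRank
measures — so module flow, labeling and PageRank are mutually consistent.

Modules with fewer than `community_min_size` (default 5) members are
dropped; survivors are labeled TDN1..TDNk by decreasing total member
flow, ties broken toward the larger community and then the smallest
member code, so labels are reproducible.

The chapter-entropy score of a community with n members is

    H = Σ_i −p_i log2(p_i) / log2(n)

with p_i the fraction of members in ICD-9 chapter i and the sum over
chapters present (0·log 0 = 0). The normalization uses community size n,
not chapter count, so H = 1 exactly when every member has its own
chapter; a singleton community is defined to have H = 0 (its
normalization 1/log2(1) is otherwise undefined, and one disease is
trivially homogeneous). The 17 top-level ICD-9-CM chapter ranges ship as
a versioned TSV (`tdnet/data/icd9_chapters.tsv`) and can be overridden.

## Trajectories

Edge weights are inverted to distances 1/w and minimum-cost directed
simple paths are extracted with Dijkstra (`networkx.all_shortest_paths`).
*All* co-optimal paths are returned in lexicographic order rather than an
arbitrary one: real networks tie, and keeping the full tie set makes
aggregation deterministic. Queries against a target set (explicit codes
or a chapter name resolved through the chapter map) skip unreachable
targets with a logged count rather than failing, since chapter-wide
queries routinely contain unreachable members. Aggregation counts, per
ordered pair, the number of trajectories using that step; it does not
count patients — the step multiplicity of a query is a property of the
network, not a cohort frequency. Trajectory queries run on the fully
filtered network, matching the pipeline order.

## Synthetic cohorts

The generator emulates the structure of an outpatient extract: per
patient, a geometric number of visits (mean `mean_visits` = 8, capped at
60) on distinct random dates in `date_range` (default 2002-01-01 to
2018-10-01); background diagnoses drawn uniformly from a configurable
code universe at `background_rate` = 0.6 per visit; codes rendered with a
random 4th–5th digit half the time; V/E supplementary codes inserted at
`ve_rate` = 0.05 per visit; ~2% female patients; births uniform
1930–1980. Planted structure:

* a **precedence pair** (i, j, excess) occupies two adjacent visits of a
  carrier (carrier probability 0.5), oriented i-first with probability
  (1 + excess)/2 — excess is exactly the expected asymmetry
  (w_ij − w_ji)/(w_ij + w_ji), which raw transition counts recover
  within binomial error (tested);
* a **disease block** (members, p_within) is entered by a patient with
  probability p_within, placing a shuffled run of 2..|block| members on
  consecutive visits — concentrated within-block flow with essentially
  no systematic between-block flow;
* the **death model** draws, after the first diagnosis of a triggering
  code, a death uniform in the following 8-year window with the stated
  probability (the earliest triggered death wins).

All sampling comes from one `numpy` generator seeded from the spec, so
output tables are byte-identical across runs and platforms.

What the generator does *not* model: realistic marginal prevalences,
age- or sex-dependent diagnosis rates, coding practice drift over time,
visits ceasing at death, or correlated comorbidity beyond the planted
blocks. Passing recovery tests therefore demonstrate that the pipeline
detects the planted mechanisms under EHR-like noise — not that it would
reproduce any particular health system's network.

Recovery at the default study conditions (validated in the test suite):
a pair planted at 0.9 excess in 2000-patient cohorts survives the full
filter cascade in ≥ 90% of 50 replicates; background-only cohorts retain
at most 5% of tested pairs after BH at α = 0.05 (in practice ~0); three
planted 5-disease blocks are recovered exactly by the map-equation stage.

## Numerical and interface choices

* Nearest-rank percentile for the prevalence threshold (the ceil(p·n/100)-th
  smallest value) — simple, exact on integer counts.
* BH adjustment delegates to `statsmodels.stats.multitest`; the tests
  cross-check a hand-written step-up.
* Unknown keys in a YAML run config are a fatal error naming the key.
* Every pipeline run writes `provenance.json`: package version, full
  parameter set, SHA-256 of the inputs, and in/out counts at every
  filter stage; deterministic stages are bit-identical across re-runs
  with the same config (tested).
* Problem sizes in the test suite (cohorts of 1–2 thousand patients,
  fixture graphs of ≤ 8 nodes, exhaustive Fisher enumeration to total
  count 50) were chosen as the smallest scales at which each property is
  sharply testable.

## Known limitations

* The 2×2 table is built over transition *events*, treating events as
  exchangeable across patients; a patient-level construction would
  condition differently. The event-level table directly tests the
  quantity the edge weight measures and is the package's default.
* Consecutive-bucket semantics mean an intervening first occurrence
  breaks an i→j transition; long-range precedence is deliberately not
  counted.
* The fixed-horizon fatality fraction is not a survival model; no
  censoring-adjusted estimator (Kaplan–Meier etc.) is provided.
* Hierarchical (multi-level) map-equation partitions are not exposed;
  the two-level partition is used throughout.
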