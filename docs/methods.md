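# Methods

## The exposure statistic

For an undirected simple graph with binary node attribute *x*, node *i*'s
exposure is E_i = Σ_{j∈N(i)} x_j / d(i). Conventions, all of which matter for
the summary tables:

- **Isolated nodes** have E_i = 0 and count as unexposed. Exposure is total:
  every node is either exposed (E_i > 0) or unexposed, so the two counts
  partition the network.
- **Self-attribute is ignored**: an antivaccine video's exposure is computed
  from its neighbors only. This is the standard NEM convention.
- **Weights**: the general weighted form Σ w_ij x_j / Σ w_ij is available via
  the `weight=` argument, but the pipeline runs unweighted — recommendation
  edges carry only a parallel-record multiplicity kept as provenance.
- **Summary**: mean and SD of the full exposure vector (sample SD, n−1
  denominator; both denominators round identically at the two-decimal report
  precision on the sparse vectors this analysis produces), exposed count and
  percentage, and the (min, max) of E_i over exposed nodes only — undefined
  when nothing is exposed.

A useful exact invariant used throughout the tests: Σ_i E_i·d(i) equals the
total degree of attribute-bearing nodes, on every graph.

## Graph construction and cleaning

Crawl output is a list of directed recommendation records. Analysis operates
on the cleaned undirected graph: reciprocal/parallel records collapse to one
edge (multiplicity kept as `weight`, smallest crawl depth kept as `depth`),
self-loops are dropped, and videos flagged as non-English are removed with
their incident edges *before* any analysis — network statistics, exposure and
odds ratios all see the filtered graph. Node ids are opaque, case-sensitive
strings. Stance recoding maps vaccine-related videos with raw misinformation
codes to `anti`, other vaccine-related videos to `pro`, everything else to
`none`; it is idempotent, so running the pipeline on already-recoded data
(including simulator output) changes nothing.

Supported formats: GraphML, GEXF, and a CSV pair (`<base>.edges.csv` with
`src,dst,depth,weight`; `<base>.nodes.csv` with `id` plus the annotation
columns). Booleans serialize as `true`/`false`; unknown columns are carried
through untouched; write∘read is the identity on nodes, edges and
annotations (property-tested on random networks for all three formats).
Unparseable annotation values default to unknown/False with a logged warning;
`strict=True` upgrades this to an error.

## Network statistics

- **Average degree** is 2E/N, unrounded; report layers round to one decimal.
- **Diameter** is the maximum finite shortest-path length. Crawled networks
  can be disconnected after cleaning, so the diameter is taken over the
  largest connected component; single nodes and edgeless graphs report 0.
- **Average clustering** is the mean local clustering coefficient with
  degree < 2 nodes contributing 0 (the convention of the common
  network-analysis tools); `count_low_degree=False` restricts the mean to
  degree ≥ 2 nodes, since published values do not always say which
  convention they used.

## Case-control odds ratios

The point estimate is ad/bc with no continuity correction: zero-cell tables
report 0 (ad = 0) or +∞ (bc = 0) rather than a Haldane-corrected finite
number, and the doubly degenerate table (both products zero) is an error.

Interval methods, in increasing order of fidelity to the conditional
distribution of the *a* cell given both margins (noncentral hypergeometric
with odds ratio ψ):

1. **Woolf**: exp(ln OR ± z·√(1/a+1/b+1/c+1/d)). Refuses zero cells.
2. **Cornfield approximation**: normal approximation to the conditional
   tails with a 0.5 continuity correction — the lower limit solves
   a − ½ = E_ψ(X) + z·√Var_ψ(X), the upper a + ½ = E_ψ(X) − z·√Var_ψ(X).
   Refuses tables whose *a* cell sits on its support boundary.
3. **Exact conditional** (default): equal-tail inversion — the lower limit
   solves P_ψ(X ≥ a) = α/2, the upper P_ψ(X ≤ a) = α/2, solved by Brent's
   method on log ψ against a vectorized log-space pmf. At the bottom of the
   support the lower limit is exactly 0 with a finite upper limit; at the top
   the upper limit is +∞. A mid-P variant (half weight on the observed
   table) is behind a flag; the equal-tail construction is the default
   because it is the conservative, commonly reported one.

The exact implementation is cross-checked in the tests against an
independent inversion built on `scipy.stats.nchypergeom_fisher` (agreement to
1e-6 relative), contains the conditional MLE on random tables, and covers a
fixed true ψ ∈ {1, 5} in ≥ 93% of 2000 seeded binomial-sampling replicates
at 50 per arm — equal-tail exact intervals are conservative, so realized
coverage sits above the nominal 95% as often as below.

## The crawl simulator

The generator emulates the data-collection design: `n_seeds` start videos
(6 for search scenarios — one screen of search hits; 16 and 8 for the
conspiracy and expert seed scenarios), branching 6 (the recommendations
visible on one screen), depth 3. Two mechanisms are deliberate
simplifications of an unobservable recommendation engine:

- **Re-attachment** (`reattach_prob` ρ): each recommendation points to a
  uniformly chosen existing video with probability ρ instead of a new one.
  This is the simplest stand-in for covisitation-driven overlap and is what
  shrinks the crawl from its theoretical maximum (1554 nodes for 6 seeds at
  depth 3) to realistic sizes, and what creates cycles and triangles. Preset
  ρ is solved from the closed-form expected size s·Σ_k (b(1−ρ))^k matched to
  each scenario's observed node count (roughly 0.37–0.55).
- **First-order category homophily**: a new video's category (provaccine,
  antivaccine, autism, accurate health, health misinformation, other — the
  partition implied by the annotation scheme) is drawn from H[parent]. Preset
  rows are the mixture λ·δ_parent + (1−λ)·π with π the scenario's observed
  composition and homophily weight λ = 0.2. This mixture makes π the exact
  stationary distribution, so search presets (whose start videos are drawn
  from π) match the target composition in expectation; seed presets start
  from antivaccine videos, which biases the realized antivaccine share
  upward by roughly λ·(levels near the seeds)/(total) ≈ 2 percentage points
  — an intended echo of seeding inside the antivaccine neighborhood. λ = 0.2
  keeps parent–child category persistence visible (P(anti|anti) ≈ 0.27 for
  the conspiracy preset vs. a 0.075 base rate) without collapsing the crawl
  into single-category trees.

What the simulator does **not** reproduce: the observed edge densities
(uniform re-attachment adds more edges per node than the deduplicated real
crawls, so simulated average degree runs near 4 instead of 2.4), the search
networks' high clustering (0.4-ish in the observed data, which uniform
re-attachment cannot produce), observed diameters, and any personalization
or view-history effects. Passing tests therefore demonstrate correctness of
the statistics and the faithfulness of the crawl *shape* (sizes, seed
counts, depth, composition, homophily), not a generative fit to the real
recommendation engine.

Everything is reproducible: one `numpy` Generator seeded from the config (or
an explicit override) drives seeds, categories, re-attachment and sources,
and identical configs serialize to byte-identical networks.

## Annotation-stage conventions

- **Krippendorff's α** (nominal) is computed from the coincidence matrix:
  each unit with m ≥ 2 ratings contributes its ordered value pairs with
  weight 1/(m−1); α = 1 − (n−1)·Σ_{c≠k} o_ck / (n² − Σ_c n_c²). Units with a
  single rating are ignored; fewer than two pairable units, or a single
  observed category (expected disagreement zero), is an error rather than a
  silent 1.0. Note one behavior worth knowing: a constant coder paired with
  a uniform random coder converges to α = −1/3, not 0 — observed
  disagreement (½) exceeds what the pooled marginals predict (⅜). The
  chance-level null is two *independent* random coders.
- **Systematic sampling**: interval k = round(1/fraction), seeded random
  start in [0, k), every k-th item; the sample size is within one of
  n·fraction (538 items at 10% yield 53 or 54 depending on the start).
- **Rounding**: printed percentages use half-up rounding (25/40 → 63%, not
  62%), integer precision for composition tables and one decimal for
  exposure tables. `pct` computes in `decimal` arithmetic to avoid binary
  ties.
- **Report bundle**: `run_report` recodes stances, then computes global
  statistics, composition (stance percentages relative to vaccine-related
  videos, health-accuracy percentages relative to health-related videos,
  source percentages relative to vaccine-related videos), exposure to
  antivaccine videos, and the eight-type odds-ratio table, and records every
  convention flag (CI method, rounding mode, clustering convention, SD
  denominator) in the bundle metadata so emitted numbers are auditable.
  Re-running on the same inputs is byte-identical.

## Problem sizes

Defaults keep everything desk-scale: preset networks are a few hundred
nodes; property suites use 200 random graphs of ≤ 60 nodes (plus 200-node
graphs for the brute-force equivalence check), 50 random tables for the
exact-CI oracle comparison, 2000 replicates per ψ for coverage, and 50
replicates for the composition check. The full test suite runs in well under
a minute on one CPU.
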