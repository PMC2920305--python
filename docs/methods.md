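# Methods

## The model

A *livelihood landscape* is a directed, weighted network over a fixed list
of occupational categories, built from household survey responses in which
each household lists the distinct activities it pursues for food or money
and ranks them by importance (rank 1 = primary). The default category list
has ten entries — fishing, selling marine products, tourism, farming, cash
crops, gleaning, salaried employment, the informal sector, other, and
`none` — and is fixed per study so that every network, at every aggregation
level (village, settlement type, country), has the same node set. This keeps
size-dependent statistics such as density and centralization comparable
across selections.

Construction, for a chosen set of households:

1. Every category is a node with a *primary counter* (households ranking it
   first) and a *secondary counter* (households ranking it second or lower).
2. A household with ranked portfolio (o₁, …, o_k) increments the primary
   counter of o₁, the secondary counters of o₂…o_k, and contributes one
   directed link o_i → o_j for **every** ordered pair i < j — k(k−1)/2 link
   contributions in total, not just adjacent ranks.
3. Link counts are normalized to weights by dividing by the originating
   node's **total** household count (primary + secondary):

       w(A→B) = n(A→B) / (primary(A) + secondary(A))

   i.e. the fraction of households engaged in A that also engage in B at a
   lower rank, bounded by 1. An alternative `origin_secondary` mode divides
   by the origin's secondary counter alone; its weights can exceed 1 (a
   warning is attached) and it is undefined when an origin has outgoing
   links but no secondary reports, which the package treats as an error.
   The `origin_total` default is the only choice under which the stated
   interpretation ("fraction of households …") and the unit upper bound
   both hold, which is why it is the default; the other mode is retained
   for fidelity experiments.

The `none` category is exclusive — it marks a household reporting no income
activity, cannot co-occur with a real occupation, and therefore contributes
a primary count but never a link. Whether `none` is in the node list at all
is a configuration choice (`CategorySet.without_none()`); the default list
includes it.

## Statistics

*Sectoral.* In-degree of an occupation is the sum of weights on incoming
links (how often it is taken on as a supplemental, lower-ranked activity);
out-degree is the sum on outgoing links (how often it outranks co-reported
activities). Isolates score zero.

*Systemic.* Binary statistics are computed after pruning links with weight
strictly below 0.05 (a weight of exactly 0.05 survives) and setting the
survivors to 1; weighted statistics always use the unpruned normalized
network.

- Density: links (binary) or summed weights (weighted) over n(n−1), the
  number of ordered node pairs on the fixed node set. Since the maximum
  weight is 1 the two variants share the denominator.
- Centralization (Freeman-style degree centralization):

      C_d = Σ_v [d* − d(v)] / [(n−1)(n−2)],   d(v) = (in(v) + out(v))/2

  where d* is the maximal symmetrized degree. The normalizer (n−1)(n−2) is
  the numerator attained by a perfect star (one hub bidirectionally linked
  to all spokes, no spoke–spoke links), so the binary statistic is exactly
  1 on the star — verified exhaustively on four-node digraphs — and 0 on
  any degree-regular network. In the weighted variant the denominator is
  additionally multiplied by the mean positive link weight; a weighted
  network with no links is assigned 0 (the mean weight is undefined there,
  and 0 is the natural limit). Degrees are symmetrized in the binary case
  too, keeping the binary and weighted variants structurally identical;
  only the symmetrized form preserves the star maximum for directed
  graphs.
- Mean occupations per household: arithmetic mean of portfolio sizes, with
  a `none` household counting as zero activities.

Degree and weight totals obey Σ in = Σ out = Σ w, and counters and raw link
counts are additive over disjoint household selections; both are enforced
by tests.

## Gradient analysis

`site_metrics_table` runs the full metrics pipeline per site under one
shared configuration and joins each site's development index (a unitless
PCA score over infrastructure items, supplied as a covariate) and
population density (persons per grid cell, natural-log-transformed exactly
once at join time; missing for sites the gridded population product cannot
resolve). `correlate_metrics` reports Spearman rank correlations (average
ranks for ties, pairwise deletion of missing values, large-sample t
p-values; a seeded permutation p-value is available for very small site
counts) of each systemic statistic against each covariate, flagging p <
0.05 and p < 0.10 separately. Rank correlation is the package's inferential
surface; regression-with-optimal-scaling model selection is out of scope.

## Synthetic data generator

The generator emulates the study design the method targets: a multi-site
survey (tens of sites, on the order of 25–150 households each) in which a
household draws k distinct activities and ranks them. Portfolios are drawn
by sequential conditional sampling without replacement: the first category
proportional to a prevalence vector, each later category proportional to
prevalence times the product of pairwise coupling multipliers with the
categories already chosen. Coupling 1 everywhere gives independence (the
two-draw pair probability has the closed form p_a·p_b/(1−p_a) +
p_b·p_a/(1−p_b), used as a Monte-Carlo oracle); very large coupling forces
near-certain co-occurrence, which surfaces downstream as link weights near
1. Ranking is by descending prevalence by default (the everyday activity is
usually the main one), or uniformly random. `none` households appear only
via an explicit probability, default 0.

Defaults: 100 households per site; portfolio-size distribution
{1: 0.40, 2: 0.45, 3: 0.10, 4: 0.05} (mean 1.8, mid-range for ranked
coastal livelihood surveys whose community means span roughly 1.1–2.5);
prevalence a coastal-economy mix dominated by fishing (0.28), farming
(0.22) and the informal sector (0.15). `specialization_gradient` builds a
ready-made multi-site design in which the single-activity share rises
linearly from 0.15 to 0.85 with a linearly increasing development index —
the configuration used to check that mean occupations, both densities and
centralization all fall along the gradient.

What the generator does **not** emulate: household sizes and per-individual
weighting, sampling weights, spatial or kin structure among households, and
any feedback between covariates and portfolio composition beyond the
monotone designs constructed in tests. Passing tests therefore show that
the pipeline recovers known generative structure, not that any particular
field system satisfies these assumptions.

Determinism: one community is byte-reproducible from its seed (identical
CSV on disk); a multi-site study derives each site's sub-seed from the
master seed and a CRC-32 of the site id, so site order is irrelevant. All
seeds stay below 2³¹.

## Drawing conventions

Maps are drawn from the pruned (≥ 0.05) weighted network with a seeded
Fruchterman–Reingold spring embedding, link weights acting as attraction
strengths; categories with no surviving links sit on a deterministic outer
ring. Node *area* (not radius) scales with primary + secondary counters to
avoid perceptual exaggeration; each node is a two-wedge pie whose shaded
fraction is primary/(primary+secondary); arrow width is linear in weight.
SVG is the reference output; the drawn encodings are also returned as data
(`RenderSpec`) so tests assert them directly. Spring layouts are only
reproducible given the seed — no bit-level match with any other embedder is
claimed, only the qualitative property that a uniformly linked node sits
nearer the layout centroid than a singly linked one (asserted as an average
over 20 seeds).

## Numerical and design choices

- Ranks must be contiguous integers 1..k; ties and gaps are rejected at
  read time (the construction needs a strict order).
- Duplicate categories within a household are data errors, rejected rather
  than deduplicated.
- Pruning uses strict `<`, exact threshold survives; raising the threshold
  can only remove links (monotonicity is tested).
- Density/centralization node count n defaults to the full fixed category
  list including isolates; `node_set="present"` restricts to reported
  categories for sensitivity analysis.
- Density needs n ≥ 2 and centralization n ≥ 3; both raise below that.
- Equality assertions in tests use 1e-9 relative tolerance; the builder
  itself is exact integer arithmetic until normalization.
- Problem sizes in tests (20,000-household calibration draws, 8-site × 120
  household gradient replicates, exhaustive four-node enumerations) were
  chosen so the whole suite completes in well under a minute while keeping
  3σ Monte-Carlo bounds tight.

## Known limitations

- The per-individual link normalization variant is not implemented; the
  household is the unit of analysis throughout.
- `origin_secondary` normalization is provided but unbounded and partially
  undefined; results computed under it are not comparable to the default.
- Empirical regression coefficients from field data cannot be reproduced
  without that data; the gradient analysis asserts directions on synthetic
  designs only.
- Layouts are qualitative; manual refinement of maps is out of scope.
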