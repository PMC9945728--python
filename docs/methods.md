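# Methods

## Data model

The unit of observation is a literature *association record*: one tick
species, at one life stage (larva / nymph / adult / unknown), reported on
one vertebrate family (belonging to an order), in one biogeographic realm,
with a weight counting citation events.  Host taxa are used at family and
order rank only; finer ranks in this literature are dominated by
misidentification and uneven reporting.  Taxon identifiers are opaque,
case-sensitive strings after whitespace trimming; no synonym resolution is
attempted — curation belongs upstream.  Duplicate rows (same species, stage,
family, realm) merge by summing weights; a family reported under two
different orders is an error, not a merge.

Networks are weighted bipartite graphs: tick nodes versus host nodes, edge
weight the summed citation count.  Realm networks use only records tagged
with that realm; cosmopolitan ("worldwide") species enter only the complete
network.  Tick nodes are species by default; a species×stage granularity is
available because stage-resolved feeding drives the cluster structure.
With `host_rank="both"` each record contributes one family-rank and one
order-rank edge; all matrix-based indices are nevertheless computed on the
family-rank columns only, because mixing ranks would count every
interaction twice.  "Links per species" always divides by distinct
*species*, whatever the node granularity.

## Index suite

All indices are computed from first principles on the family-rank
interaction matrix or on the graph itself:

- **NODF** on the binary (presence/absence) view: pairs of rows (and
  columns) with strictly decreasing fill contribute 100·overlap/fill of the
  sparser vector; equal fills contribute zero; normalised by the number of
  row plus column pairs.  Binary is the canonical definition and makes the
  index invariant to citation effort.
- **Fisher's α** treats the nonzero cells as "species" (S) and the total
  citation weight as "individuals" (N), solving S = α ln(1 + N/α) by
  bracketed root finding plus one Newton polish (residual < 1e−10).  N ≤ S
  is a divergence error, not a number.
- **Partner diversity** is the weight-weighted mean Shannon entropy of the
  tick rows (natural log); it is bounded by ln(number of host columns).
- **Functional complementarity** is the total branch length of the UPGMA
  (average-linkage) dendrogram over Euclidean distances between tick rows,
  with leaves at height zero — each merge at height *h* contributes
  (h − height of each child).  This is the `vegan::treeheight` bookkeeping
  used by the standard R implementation of the index.  UPGMA is run
  directly via the Lance–Williams update rather than through a generic
  linkage routine, because generic codes break distance ties by internal
  traversal order; here ties (pairs within 1e−9 of the current minimum
  distance) merge the lexicographically smallest cluster-id pair, with
  leaves numbered in lexical row order, so the dendrogram is reproducible
  across implementations.
- **Extinction slope**: host columns are removed one at a time in
  uniformly random order (100 seeded replicates); a tick is extinct when
  its last host is removed.  Pooled (proportion removed, proportion
  surviving) points are fitted with y = 1 − xᵃ by nonlinear least squares.
  Removal order is random rather than degree-ranked; a, the fitted
  exponent, is 1 in the no-redundancy limit (each tick one private host)
  and grows without bound as redundancy saturates.
- **Louvain modularity** maximises weighted Newman–Girvan Q at resolution
  1.0 on the bipartite graph treated as an ordinary weighted graph.  The
  greedy sweeps depend on node visit order, so the reported partition is
  the best of 10 seeded restarts and is floored at the single-module
  partition (Q = 0).  One-step Louvain values from interactive tools are
  not bit-reproducible; best-of-restarts is.
- **Betweenness** uses unweighted (hop-count) shortest paths,
  unnormalised, with fractional splitting over equal-length geodesics:
  citation counts measure sampling effort, not distance, so using them as
  path lengths would be semantically wrong.

## Phylogenetic diversity and the ontogenetic switch

Faith's PD of a host-family set is the branch length of the minimal subtree
spanning the tips.  `include_root=True` is the default — the subtree
includes the path from the set's MRCA to the root, so a singleton family
has its root-to-tip distance rather than zero — matching the dominant
convention of community-ecology implementations; the flag is exposed
because published per-species values depend on it.  Families present in
records but absent from the tree are excluded from both PD and richness and
tallied separately (`n_unplaced`), never silently dropped.  Stage-unknown
records participate in species-level networks but not in stage-resolved PD
or switch statistics.

The switch statistic for a molt is the relative change
(PD₂ − PD₁)/PD₁: 0 = no change, 1 = doubled, −0.5 = halved, bounded below
by −1.  A zero baseline yields NaN (missing), never 0, so "no data" cannot
masquerade as "no change".  The absolute difference is carried as a
secondary column.  Rates are scale-invariant in the tree's branch-length
units, which is essential because those units are arbitrary.

Stage-flow tables redistribute record mass between host orders across a
molt.  Literature records never pair an individual larva with the nymph it
became, so the coupling within a species is the independence
(outer-product) of the two stages' record distributions; species are
weighted by their record mass at the two stages and each table is
normalised to 1.  This coupling choice shapes the flow output and is the
main caveat when reading it.

## Co-occurrence

For two species with n_a and n_b of N host families, the shared count under
independent random placement is Hypergeometric(N, n_a, n_b).  Exact tails
classify the pair: positive if P(J ≥ j_obs) < α, negative if
P(J ≤ j_obs) < α (α = 0.05 default).  A non-significant pair is
*unclassifiable* when even the most extreme attainable overlap could not
reach α in either tail — the pair has too little power for any verdict —
and *random* otherwise.  No multiple-testing correction is applied, by
design; the classification is a per-pair screen, not a family-wise claim.

## Synthetic data

The generator emulates a literature compilation, not tick biology: species
are planted into modules; host families (and orders) are partitioned across
the same modules; each species/stage holds a pool of `hosts_per_pool = 6`
families sampled by a preference putting probability `module_affinity`
inside the module; a molt keeps the pool with probability 1 − σ
(`switch_sigma`) and redraws it otherwise; per-stage citation counts are
negative-binomial (mean `records_per_species_stage`, shape `dispersion`)
spread multinomially over the pool.  Realms are independent replicate
communities sharing species, modules and tree.  An `effort_bias` knob
multiplies one module's citation effort to probe robustness to survey
skew.  Defaults (250 species, 150 families, 30 orders, 6 modules, affinity
0.9, σ = 0.5, mean 8 records at dispersion 1) sketch a worldwide
single-genus compilation scaled to run in seconds.

What the generator does *not* emulate: real phylogenetic signal in host
use (families are exchangeable within a module), geographic structure
within realms, taxonomic error, or correlations between a species' range
and its survey effort.  Passing recovery tests therefore shows the
*pipeline* is correct and the planted parameters are identifiable — not
that real compilations satisfy these assumptions.

Identifiability of the switch intensity deserves a note: at literature-like
effort (mean 8 records, dispersion 1) the realized host sets of two stages
differ substantially by sampling alone even when they share a pool, and σ
is not recoverable from mean |rate|.  The recovery analyses therefore run
at saturating effort (mean 30, dispersion 5), the synthetic analogue of
restricting the switch statistic to well-documented species, which is also
how the statistic is meaningfully applied to real data.  At those settings
mean |rate| is strictly monotone over σ ∈ {0, 0.25, 0.5, 0.75, 1}
(500 species per cell) across seeds.

## Numerical choices and degenerate inputs

- Fisher's α: bracket (1e−9, 1e9), Brent to machine tolerance, one Newton
  step; residual < 1e−10 enforced by tests.
- Extinction fit: `curve_fit` with a ∈ [1e−6, 1e6], p0 = 1; a failed fit
  raises an error carrying the pooled curve.
- NODF needs at least 2 rows or 2 columns; functional complementarity at
  least 2 rows (identical rows give 0); empty networks after filtering are
  an explicit error, never a silent empty object.
- Missing branch lengths default to 0 (with a warning) so PD can never
  silently inflate; missing GraphML edge weights default to 1 (with a
  warning); GraphML files without a partition attribute are two-colored
  structurally and the inference is logged.
- All simulation, Louvain, and extinction randomness flows from explicit
  integer seeds; identical seeds give byte-identical outputs.

## Known limitations

- The pipeline measures association structure, not causation; citation
  weights conflate true association strength with survey effort (the
  generator's bias knob exists precisely to study this).
- Per-realm index values from a published compilation are reproducible
  only with that compilation's realm-tagged records; a network file alone
  does not carry realm membership.
- Louvain cluster counts on near-degenerate modularity landscapes can vary
  with the restart budget; the best-of-10 convention is part of the
  reported definition.
- The outer-product stage-flow coupling overstates mixing for species
  whose individuals are host-faithful across molts.
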