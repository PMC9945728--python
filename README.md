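# ixonet

Stage-resolved analysis of tick–host association networks.

Hard ticks of the genus *Ixodes* feed once per life stage (larva, nymph,
adult) and the literature records which vertebrate families each species and
stage has been found on, in which biogeographic realm, and how often.
`ixonet` turns such association tables into weighted bipartite parasite–host
networks and asks the questions ecologists ask of them: how modular and how
nested are the associations, how redundant is the host base, how robust is
the tick community to host loss, how phylogenetically broad is each species'
host spectrum, and how much does that spectrum shift between consecutive
life stages (the *ontogenetic switch*)?

## What it computes

For a bipartite network with tick set *X*, host set *Y* and citation-count
edge weights *a<sub>ij</sub>*:

- **Order / size / links per species** — node count, link count, links per
  distinct tick species.
- **Modularity and clusters** — Louvain maximisation of weighted
  Newman–Girvan *Q* (seeded, best of 10 restarts).
- **NODF** — nestedness by overlap and decreasing fill on the binary
  incidence matrix, 0–100.
- **Fisher's α** — the root of *S = α ln(1 + N/α)* with *S* the number of
  realized interactions and *N* the total citation weight.
- **Partner diversity** — Σ<sub>i</sub> A<sub>i</sub>H<sub>i</sub> / Σ<sub>i</sub> A<sub>i</sub>
  with H<sub>i</sub> the Shannon entropy of row *i* (natural log).
- **Functional complementarity** — total branch length of the UPGMA
  dendrogram over Euclidean distances between tick interaction profiles.
- **Extinction slope** — exponent *a* of *y = 1 − xᵃ* fitted to tick
  survival *y* under random sequential host removal *x* (100 replicates).
- **Compartments, weighted degree, betweenness** — components and node
  centralities (betweenness on unweighted shortest paths).
- **Faith's PD** — branch length of the minimal spanning subtree of each
  species/stage host-family set on a host phylogeny, with family richness.
- **Ontogenetic switch** — relative PD change (PD₂ − PD₁)/PD₁ across
  larva→nymph and nymph→adult molts, plus host-order stage-flow tables.
- **Co-occurrence** — exact hypergeometric classification of every species
  pair as positive / negative / random / unclassifiable.

A synthetic-data generator plants module structure, nestedness, switch
intensity and overdispersed citation effort so every stage of the pipeline
can be exercised and scored against known ground truth.

## Worked example

```python
from ixonet import SimulationConfig, build_network, generate_records, network_report

records, _ = generate_records(SimulationConfig(seed=1))
rep = network_report(build_network(records), seed=1, n_replicates=100)
for key, value in rep.to_dict().items():
    print(f"{key:>28}: {value:.4f}" if isinstance(value, float) else f"{key:>28}: {value}")
```

prints

```
                       order: 399
                        size: 1887
           links_per_species: 7.5783
                  n_clusters: 6
                        nodf: 5.3553
                fisher_alpha: 944.1056
             n_host_families: 150
  functional_complementarity: 2674.9796
           partner_diversity: 1.9523
            extinction_slope: 7.0177
              n_compartments: 1
                  modularity: 0.7333
```

— a connected community of 249 tick species on 150 host families whose six
Louvain clusters recover the six planted modules exactly; the low NODF and
high modularity say the associations are clustered rather than nested, and
the extinction exponent of ~7 says most species would survive random loss of
most host families.  `examples/` contains one short script per capability
(simulation, indices, PD, switch, co-occurrence, full pipeline), and the
same operations are exposed as a thin CLI
(`ixonet simulate|build|metrics|pd|switch|cooccur|run`).

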