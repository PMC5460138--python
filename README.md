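# neighbornet

Systems-level analysis of the *neighbourhood* of cancer-related proteins in
tissue-specific interactomes.

Most target-selection work in oncology looks at the proteins that are
themselves altered — mutated in a census of cancer genes, or differentially
expressed between normal and tumour tissue. `neighbornet` implements the
complementary, network-level view: it classifies every protein of a
tissue-specific signalling/PPI network into

* **cancer-related (CR)** — the coding gene is mutated in the given cancer
  type and/or binary-differentially expressed between the normal and cancer
  state;
* **first neighbour (FN)** — directly interacting with at least one CR
  protein without being CR itself;
* **unaffected (UA)** — everything else; with the **influencer** subset of
  UA proteins that have a *directed* interaction into a first neighbour
  (by default, a first neighbour of a differentially expressed CR protein).

and then quantifies, per class: topological centrality (degree `k`,
betweenness `b`, clustering coefficient `C`, all on the undirected,
unweighted, loop-free graph), internal connectivity (giant-component ratio
against a label-permutation null with Z-score), functional reach (the GO
biological-process terms first neighbours *add* beyond the CR proteins'
own annotation, with a one-sided binomial test), robustness (how often each
protein recurs as first neighbour of random seed sets), and druggability
(phase-4 / ≤ 500 nM IC50-Ki-Kd filters on a bioactivity table, with χ² and
binomial enrichment tests). Consensus influencers across several network
resources are counted by protein identity.

The statistics follow the field's standard conventions: two-sided Wilcoxon
rank-sum (exact enumeration for groups of ≤ 10, tie-corrected normal
approximation otherwise) and Kolmogorov–Smirnov tests for class
comparisons, with the whole network as control; binary differential
expression via the mean-minus-SD discretization rule
`τ = μ − σ` over the per-state mean expression of the network's genes.

A first-class synthetic-data module replaces the external resources
(mutation census, expression series, network databases, bioactivity
extracts) with generators that have the statistical structure the analysis
relies on — heavy-tailed degrees from preferential attachment, hub-biased
mutated seed sets, bimodal log-intensity expression with a controllable
on/off switching fraction, GO assignments and phase/potency mixtures — and
always emit the ground truth, so every stage is testable at desk scale.

## Worked example

```python
from neighbornet import (
    SyntheticConfig, generate_dataset, discretize,
    call_differential_expression, build_tissue_network,
    classify, with_influencers, compute_topology, giant_component_test,
)

cfg = SyntheticConfig(n_nodes=2000, rng_seed=7)
ds = generate_dataset(cfg)

disc = discretize(ds.profile, ds.interactome.nodes)   # tau = mu - sigma
de = call_differential_expression(disc)               # on/off switch genes
net = build_tissue_network(ds.interactome, disc)      # both-endpoints-present rule
c = with_influencers(net, classify(net, ds.mutated, de))

print(len(c.cancer_related), len(c.first_neighbour),
      len(c.unaffected), len(c.influencers))
# 212 744 530 144

topo = compute_topology(net)
print(topo.loc[sorted(c.mutated), "degree"].median(),
      topo.loc[sorted(c.first_neighbour), "degree"].median())
# 13.0 3.0
```

The tissue network keeps 1486 of the 2000 proteins (the rest are silent in
both states). The classes partition those 1486 nodes: 212 cancer-related
(33 mutated, 181 differentially expressed), 744 first neighbours, 530
unaffected, of which 144 are influencers. The median degree of mutated
proteins (13) far exceeds the network median — they were sampled with a
degree-squared bias, mirroring the reported topology of census-mutated
genes — while their first neighbours sit at the network median.

The same pipeline runs from the shell:

```bash
neighbornet simulate --n-nodes 2000 --seed 7 --out study/
neighbornet classify --edges study/edges.tsv --expr study/expression.tsv \
    --normal-cols N01,...,N10 --cancer-cols C01,...,C10 \
    --mutated study/mutations.txt --out classes.tsv
neighbornet drugs --bioactivity study/bioactivity.tsv --classes classes.tsv
```

or end-to-end over many resources and cancer types from one YAML file with
`neighbornet run-all --config run.yaml` (see `neighbornet --help` for all
subcommands: simulate, build-network, classify, topology, giant-component,
randomize, go-test, drugs, report, run-all).

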