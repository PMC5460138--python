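# Methods

This note records the models, conventions and design choices behind
`neighbornet`, in the order the pipeline applies them.

## Expression discretization and binary differential expression

Expression is treated as binary by design. For each gene the per-state
summary is the arithmetic mean of its (log-intensity) values over that
state's samples (`summary="median"` is available). The threshold is

> τ = μ − σ,

where μ and σ are computed over the pooled per-state summaries of the
genes of the network under study — two values per gene (normal and cancer)
enter one pool (`pooling="combined"`, the default). σ is the sample
standard deviation (n − 1 denominator; `sd="population"` available). A
gene is *not expressed* in a state iff its summary is strictly below τ;
ties and the degenerate σ = 0 case therefore land on the expressed side.
A gene is *differentially expressed* (DE) iff its call differs between
the two states — a gene expressed in both states is never DE, no matter
how large its fold change, and a gene silent in both states is simply
absent. This deliberately favours presence/absence switches over graded
overexpression.

Open conventions resolved here (both exposed as options): the pool for
(μ, σ) is the combined two-state pool rather than per-state pools, because
the analysis treats normal and cancer values as one intensity scale per
network; and per-state pooling (`pooling="per_state"`) gives each state
its own τ for sensitivity analysis.

## Tissue-specific network construction

An interaction is retained when both endpoints are present in at least one
tissue state (the *union* rule): a protein expressed only in cancer can
interact with one expressed only in normal tissue, because the analysis
studies a single combined tissue network in which the network effect of
presence/absence switches is visible. The conjunctive alternative
(`rule="per_state"`: both endpoints expressed in the *same* state) is
available, since the defining phrase is genuinely ambiguous between the
two readings. Genes of the network that the expression table does not
cover default to absent (strict policy, count logged);
`uncovered="expressed"` keeps them. The retained edge set is monotone in
the expressed gene set, never introduces edges, and an empty result is a
warning, not an error.

## Classification

CR = (mutated ∪ DE) ∩ network nodes; FN = one-step neighbourhood of CR
minus CR (a protein that is both CR and neighbour of another CR protein
counts only as CR); UA = the rest. Adjacency ignores edge direction —
direction annotations (present in signalling resources, absent in plain
PPI data) are consulted only for influencer detection: an influencer is a
UA protein with a directed edge into an FN protein, and by default that FN
must additionally touch a DE cancer-related protein, matching the two-step
drug-target use case; the looser variant is a flag. Mutated genes silent
in both states are not in the network and hence not classifiable; they are
logged. The partition property (pairwise disjoint, exhaustive,
influencers ⊆ UA) is asserted on every run.

Consensus influencers across resources are counted by protein identity: a
protein that targets different first neighbours in different resources
still accumulates one vote per resource; the default consensus threshold
is k = 3 resources.

## Topology metrics

Degree, betweenness and clustering coefficient are computed on the
undirected, unweighted, loop-free graph via igraph. Betweenness uses
unnormalized pair counts — for node v the sum over unordered pairs
(s, t), s ≠ t ≠ v, of σ_st(v)/σ_st; ranks (hence every rank-based test)
are invariant to the normalization, which is available as a flag.
Clustering is 0 by convention for degree < 2 (this affects class medians
and is therefore stated here). Class comparisons use the two-sided
Wilcoxon rank-sum and two-sample KS tests, each class against the whole
network (the class is a subset of its control, as in the reference
analysis) or against the unaffected class; significance stars follow the
0.05 / 0.01 / 0.001 scale. The rank-sum test enumerates all C(n+m, n)
assignments exactly when both groups have ≤ 10 members (midranks, so ties
are handled as a true permutation test) and otherwise uses the
tie-corrected normal approximation with continuity correction.

## Giant-component permutation test

For a node class of size k, the observed statistic is the fraction of the
class inside the largest connected component of the class-induced
subgraph. The null relabels the class 1000 times (N configurable, ≥ 100
recommended): a uniformly random k-subset of all network nodes is drawn
and its ratio recorded. Reported are Z = (r_obs − mean_null)/sd_null, the
upper-tail normal p, and the empirical p = (1 + #{null ≥ r_obs})/(N + 1).
When the null has zero spread (e.g. the class is the whole connected
graph) Z is undefined and only the empirical p is meaningful. The
empirical estimator is slightly conservative under heavy ties of the
discrete ratio; its size at α = 0.05 is verified by simulation (200 null
datasets) to stay within [0.02, 0.09]. Uniform relabelling is the default,
as the plain reading of label perturbation; a degree-stratified null
(`null="degree_stratified"`, sampling within degree deciles to match the
class's degree profile) is available for classes whose connectivity might
be explained by degree alone.

## Seed-randomization robustness

R = 100 times, a uniformly random seed set of the same size as the real CR
set is drawn and its first-neighbour set listed by the same one-step rule;
per-node occurrence counts (in [0, R]) are compared between the real FN,
UA and CR classes with rank-sum tests. On heavy-tailed graphs the real
first neighbours recur far more often than unaffected proteins — the
friendship-paradox property that makes FN membership largely a property of
the topology, not of the particular seed list.

## GO added reach

CR proteins are annotated first with their biological-process terms; FN
proteins then contribute only terms not already claimed (BP_added, always
disjoint from BP_cr by construction). By default terms are used exactly as
annotated — no propagation up the ontology DAG, matching direct use of an
association file; passing a term-to-parents mapping propagates
annotations to all ancestors first. The one-sided
binomial test uses k = |BP_added| successes in n = |BP_cr ∪ BP_added|
trials with expected probability |FN|/|network|; the trials universe is
the package's own choice (the natural universe for "added" terms) and is
configurable, since no canonical choice exists.

## Drug and compound filters

An *active compound* is a record with activity type in {IC50, Ki, Kd} and
potency ≤ 500 nM; a *drug* is an active compound whose maximum clinical
phase is 4. Records with other activity types are skipped with a log
entry. Counting per class is by unique compound — one drug hitting three
FN targets counts once for FN, and a compound with targets in two classes
counts in both (class drug pools genuinely overlap). Enrichment uses χ²
without Yates correction on the drugs vs non-drug-actives table of the two
classes, with a Fisher exact fallback when an expected cell is below 5,
plus a one-sided binomial test of a class's drug count against its share
of network nodes. Multi-cancer overlaps are exact Venn partitions
(counts per non-empty cancer subset; they sum to the union size).

## Synthetic data: what it emulates, and what it does not

The generators provide the structural premises the conclusions rest on,
with defaults chosen once as a realistic desk-scale study:

| knob | default | why |
|---|---|---|
| `n_nodes`, `attachment_edges` | 2000, 3 | preferential attachment ⇒ connected, heavy-tailed degrees (the property behind first-neighbour centrality); ~6000 edges is a desk-scale signalling resource |
| `n_seed_proteins` | 50 | census-style per-cancer mutation lists are tens of genes |
| `seed_centrality_bias` | 2 | mutated proteins are reported as high-degree; weight ∝ degree² concentrates seeds on hubs; 0 gives uniform seeds |
| `frac_de_genes` | 0.1 | fraction of genes switching on/off between states |
| `silent_fraction` | 0.3 | fraction of genes in the low mode; keeps τ between the modes |
| `expression_modes` | N(4, 1), N(9, 1) | log2-intensity-like bimodality (silent vs expressed), 5 mode-SDs apart |
| `n_samples_per_group` | 10 | small cohort per state |
| `directed_fraction` | 0.5 | mixes directed signalling with undirected PPI edges |
| `frac_phase4`, `potency_range_nM` | 0.2, 1–10⁴ (log-uniform) | phase/potency mixture straddling the 500 nM cutoff |

A configuration-model alternative with a power-law degree sequence is
available (`graph_model="configuration"`). Every generator is a pure
function of (config, seed), with one independent child stream per
generator, and ground truth (DE labels, seed list, per-state expression
truth) is always emitted.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: probe-level microarray structure, batch effects
and cohort heterogeneity, cancer-subtype structure, correlated GO
annotation (terms are assigned independently of topology, so the GO
added-reach test is exercised for correctness, not for enrichment — on
uniform annotations the binomial p is expectedly non-significant), and
correlated compound-target structure. The recovery experiments
(friendship paradox, two-strategy dichotomy, calibration, discretization
recovery) are statements about the method under these controlled
conditions, at the problem sizes given below.

## Numerical and procedural choices

* Thresholding is strict (`value < τ` ⇒ silent), so σ = 0 degenerates to
  everything expressed rather than everything silent.
* Undirected edges are stored once under a canonical endpoint ordering;
  duplicate rows collapse with a union of direction flags; self-loops are
  removed on ingestion (the protein is kept as a node) with a logged
  count.
* All empirical p-values use the (1 + hits)/(N + 1) estimator; all
  simulations derive per-replicate seeds from one master seed via
  independent child streams, so doubling a replicate count never reuses a
  stream.
* Exact rank-sum enumeration is capped at group sizes of 10
  (C(20, 10) ≈ 1.8·10⁵ assignments); beyond that the tie-corrected
  asymptotic path is used.
* Problem sizes of the validation experiments: 2000-node studies for the
  classification/recovery runs (100 replicates), 500-node graphs with 5%
  classes for the permutation-test calibration (200 datasets × 1000
  permutations) and power (100 datasets), 10 replicates for
  discretization recovery.

## Known limitations

* The pipeline is identifier-namespace agnostic; the mapping-table reader
  covers namespace translation, but no live mapping service is consulted.
* Binary DE discards graded fold-change information by design; genes
  moderately expressed in both states can never be DE.
* The influencer definition is one directed step into an FN protein;
  longer directed paths and edge signs (activation/inhibition) are out of
  scope.
* The giant-component null ignores degree when relabelling; for classes
  with extreme degree profiles a degree-preserving null would be stricter.
* GO analysis counts distinct terms; it does not weight by term depth or
  information content, and does not perform per-term enrichment.
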