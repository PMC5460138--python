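"""Synthetic benchmark data with the statistical structure the analysis assumes.

Every downstream stage of the pipeline (discretization, classification,
topology, GO reach, drug filtering) needs inputs whose structure matches
real resources: a heavy-tailed interactome, a degree-biased mutated seed
set, bimodal (expressed/silent) expression with a controllable fraction of
on/off switching genes, GO term assignments, and bioactivity records with
controllable clinical-phase and potency mixtures. These generators provide
that structure at desk scale and always emit the ground truth so recovery
is checkable.

Every generator is a pure function of ``(config, config.rng_seed)``:
each stage draws from its own child stream of the configured seed, so
regenerating one input never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import (
    BioactivityTable,
    ExpressionProfile,
    Interactome,
    write_bioactivity,
    write_edge_list,
    write_expression_matrix,
    write_gaf,
    write_gene_list,
)

# child-stream indices: one per generator, so streams never collide
_STREAM_GRAPH = 0
_STREAM_EXPRESSION = 1
_STREAM_MUTATIONS = 2
_STREAM_GO = 3
_STREAM_BIOACTIVITY = 4


@dataclass
class SyntheticConfig:
    """Knobs for the synthetic study; defaults are the reference conditions.

    The interactome grows by preferential attachment (heavy-tailed degrees,
    connected); mutated seeds are drawn with probability proportional to
    ``degree ** seed_centrality_bias`` (0 = uniform); expression is a
    two-mode Gaussian mixture on a log2-intensity scale, with
    ``frac_de_genes`` of genes switching mode between the normal and cancer
    state.
    """

    n_nodes: int = 2000
    attachment_edges: int = 3
    n_seed_proteins: int = 50
    seed_centrality_bias: float = 2.0
    frac_de_genes: float = 0.1
    silent_fraction: float = 0.3
    #: ((location, scale) silent, (location, scale) expressed) on log2 scale
    expression_modes: tuple[tuple[float, float], tuple[float, float]] = ((4.0, 1.0), (9.0, 1.0))
    n_samples_per_group: int = 10
    n_go_terms: int = 200
    go_terms_per_protein: tuple[int, int] = (1, 5)
    n_compounds: int = 500
    frac_phase4: float = 0.2
    potency_range_nM: tuple[float, float] = (1.0, 10_000.0)
    directed_fraction: float = 0.5
    graph_model: str = "preferential_attachment"  # or "configuration"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("frac_de_genes", "silent_fraction", "frac_phase4", "directed_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_nodes < self.attachment_edges + 1:
            raise ConfigError("n_nodes must exceed attachment_edges")
        if not 0 <= self.n_seed_proteins < self.n_nodes:
            raise ConfigError("n_seed_proteins must satisfy 0 <= n < n_nodes")
        if self.seed_centrality_bias < 0:
            raise ConfigError("seed_centrality_bias must be >= 0")
        (s_loc, s_sc), (e_loc, e_sc) = self.expression_modes
        if not e_loc > s_loc:
            raise ConfigError("expressed-mode location must exceed silent-mode location")
        if s_sc <= 0 or e_sc <= 0:
            raise ConfigError("expression mode scales must be positive")
        if self.n_samples_per_group < 1:
            raise ConfigError("n_samples_per_group must be >= 1")
        lo, hi = self.go_terms_per_protein
        if not 0 <= lo <= hi or hi > self.n_go_terms:
            raise ConfigError("go_terms_per_protein range invalid for n_go_terms")
        plo, phi = self.potency_range_nM
        if not 0 < plo <= phi:
            raise ConfigError("potency_range_nM must be positive and ordered")
        if self.graph_model not in ("preferential_attachment", "configuration"):
            raise ConfigError(f"unknown graph_model {self.graph_model!r}")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.rng_seed), stream])


def _node_name(i: int, width: int) -> str:
    return f"P{i:0{width}d}"


def generate_interactome(config: SyntheticConfig) -> Interactome:
    """Grow a connected, heavy-tailed interactome.

    Preferential attachment (default) gives the degree heterogeneity on
    which the friendship-paradox behaviour of first-neighbour selection
    rests; a configuration-model alternative with a power-law degree
    sequence is available for sensitivity checks. A configurable random
    fraction of edges carries a direction flag with random orientation
    (signalling resources are directed, PPI resources are not).
    """
    config.validate()
    rng = config.rng(_STREAM_GRAPH)
    if config.graph_model == "preferential_attachment":
        g = nx.barabasi_albert_graph(
            config.n_nodes, config.attachment_edges,
            seed=int(rng.integers(2**31)),
        )
    else:
        g = _configuration_graph(config, rng)
    width = max(4, len(str(config.n_nodes - 1)))
    relabel = {i: _node_name(i, width) for i in g.nodes}
    g = nx.relabel_nodes(g, relabel)

    net = Interactome(f"synthetic-{config.rng_seed}")
    edges = sorted(tuple(sorted(e)) for e in g.edges)
    flags = rng.random(len(edges)) < config.directed_fraction
    flips = rng.random(len(edges)) < 0.5
    for (u, v), directed, flip in zip(edges, flags, flips):
        if directed and flip:
            net.add_edge(v, u, directed=True)
        else:
            net.add_edge(u, v, directed=bool(directed))
    return net


def _configuration_graph(config: SyntheticConfig, rng: np.random.Generator) -> nx.Graph:
    """Configuration model with a truncated power-law degree sequence."""
    n = config.n_nodes
    kmin = config.attachment_edges
    seq = np.minimum(rng.zipf(2.5, size=n) + kmin - 1, n - 1)
    if seq.sum() % 2:
        seq[0] += 1
    g = nx.configuration_model(seq.tolist(), seed=int(rng.integers(2**31)))
    g = nx.Graph(g)  # collapse multi-edges
    g.remove_edges_from(nx.selfloop_edges(g))
    giant = max(nx.connected_components(g), key=len)
    return nx.convert_node_labels_to_integers(g.subgraph(giant).copy())


def generate_expression(
    config: SyntheticConfig, interactome: Interactome
) -> tuple[ExpressionProfile, pd.DataFrame]:
    """Draw bimodal expression for every network gene, plus ground truth.

    Each gene is either silent or expressed in each state; a fraction
    ``frac_de_genes`` of genes (chosen independently per gene) switches mode
    between states, in a random direction. Per-sample values are Gaussian
    around the state's mode location. Returns the profile and a truth table
    with columns ``gene, is_de_truth, expressed_normal, expressed_cancer``.
    """
    config.validate()
    rng = config.rng(_STREAM_EXPRESSION)
    genes = sorted(interactome.nodes)
    n = len(genes)
    (s_loc, s_sc), (e_loc, e_sc) = config.expression_modes

    is_de = rng.random(n) < config.frac_de_genes
    base_expressed = rng.random(n) >= config.silent_fraction
    # DE genes: expressed in exactly one state, direction random
    de_on_in_cancer = rng.random(n) < 0.5
    expressed_normal = np.where(is_de, ~de_on_in_cancer, base_expressed)
    expressed_cancer = np.where(is_de, de_on_in_cancer, base_expressed)

    m = config.n_samples_per_group
    loc_normal = np.where(expressed_normal, e_loc, s_loc)[:, None]
    sc_normal = np.where(expressed_normal, e_sc, s_sc)[:, None]
    loc_cancer = np.where(expressed_cancer, e_loc, s_loc)[:, None]
    sc_cancer = np.where(expressed_cancer, e_sc, s_sc)[:, None]
    vals_normal = rng.normal(loc_normal, sc_normal, size=(n, m))
    vals_cancer = rng.normal(loc_cancer, sc_cancer, size=(n, m))

    normal_cols = [f"N{j+1:02d}" for j in range(m)]
    cancer_cols = [f"C{j+1:02d}" for j in range(m)]
    values = pd.DataFrame(
        np.hstack([vals_normal, vals_cancer]), index=genes,
        columns=normal_cols + cancer_cols,
    )
    profile = ExpressionProfile(values, normal_cols, cancer_cols)
    truth = pd.DataFrame(
        {
            "gene": genes,
            "is_de_truth": is_de,
            "expressed_normal": expressed_normal,
            "expressed_cancer": expressed_cancer,
        }
    ).set_index("gene")
    return profile, truth


def generate_mutations(config: SyntheticConfig, interactome: Interactome) -> list[str]:
    """Sample ``n_seed_proteins`` distinct mutated genes.

    Sampling weight is ``degree ** seed_centrality_bias``: bias 0 gives a
    uniform draw, bias 2 concentrates seeds on hubs (the reported topology
    of census-mutated proteins).
    """
    config.validate()
    if config.n_seed_proteins > interactome.n_nodes():
        raise ConfigError("n_seed_proteins exceeds number of network nodes")
    if config.n_seed_proteins == 0:
        return []
    rng = config.rng(_STREAM_MUTATIONS)
    genes = sorted(interactome.nodes)
    degrees = np.array([interactome.graph.degree[g] for g in genes], dtype=float)
    weights = degrees ** config.seed_centrality_bias
    p = weights / weights.sum()
    chosen = rng.choice(len(genes), size=config.n_seed_proteins, replace=False, p=p)
    return [genes[i] for i in chosen]


def generate_go_annotations(
    config: SyntheticConfig,
    interactome: Interactome,
    proteins: list[str] | None = None,
    term_pool: list[str] | None = None,
) -> dict[str, set[str]]:
    """Assign each protein between min and max biological-process terms.

    Term IDs are syntactically valid GO identifiers (``GO:%07d``). A custom
    ``term_pool`` / ``proteins`` restriction supports building annotation
    sets with controlled overlap between protein classes.
    """
    config.validate()
    rng = config.rng(_STREAM_GO)
    if term_pool is None:
        term_pool = [f"GO:{i:07d}" for i in range(config.n_go_terms)]
    if proteins is None:
        proteins = sorted(interactome.nodes)
    lo, hi = config.go_terms_per_protein
    annotations: dict[str, set[str]] = {}
    for protein in sorted(proteins):
        k = int(rng.integers(lo, hi + 1))
        if k == 0:
            continue
        terms = rng.choice(len(term_pool), size=min(k, len(term_pool)), replace=False)
        annotations[protein] = {term_pool[i] for i in terms}
    return annotations


def generate_bioactivity(config: SyntheticConfig, interactome: Interactome) -> BioactivityTable:
    """Draw compound-target bioactivity records.

    Each compound hits 1-3 targets with a shared clinical phase
    (phase 4 with probability ``frac_phase4``, else uniform on 1-3);
    potencies are log-uniform over ``potency_range_nM`` and the activity
    type is uniform over IC50/Ki/Kd.
    """
    config.validate()
    rng = config.rng(_STREAM_BIOACTIVITY)
    genes = sorted(interactome.nodes)
    rows = []
    lo, hi = config.potency_range_nM
    for i in range(config.n_compounds):
        compound = f"CMPD{i:05d}"
        phase = 4 if rng.random() < config.frac_phase4 else int(rng.integers(1, 4))
        n_targets = int(rng.integers(1, 4))
        targets = rng.choice(len(genes), size=min(n_targets, len(genes)), replace=False)
        for t in targets:
            value = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            rows.append(
                {
                    "compound_id": compound,
                    "target_id": genes[t],
                    "activity_type": str(rng.choice(["IC50", "Ki", "Kd"])),
                    "value_nM": value,
                    "max_phase": phase,
                    "indication_class": "",
                }
            )
    return BioactivityTable(pd.DataFrame(rows))


@dataclass
class SyntheticDataset:
    """One fully generated study: all inputs plus ground truth."""

    config: SyntheticConfig
    interactome: Interactome
    profile: ExpressionProfile
    truth: pd.DataFrame
    mutated: list[str]
    annotations: dict[str, set[str]] = field(default_factory=dict)
    bioactivity: BioactivityTable | None = None


def generate_dataset(config: SyntheticConfig, with_annotations: bool = True,
                     with_bioactivity: bool = True) -> SyntheticDataset:
    """Generate every input of one synthetic study from a single config."""
    net = generate_interactome(config)
    profile, truth = generate_expression(config, net)
    mutated = generate_mutations(config, net)
    annotations = generate_go_annotations(config, net) if with_annotations else {}
    bioactivity = generate_bioactivity(config, net) if with_bioactivity else None
    return SyntheticDataset(config, net, profile, truth, mutated, annotations, bioactivity)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write a dataset in the exact formats the readers consume.

    Also writes ``ground_truth.tsv`` (node, is_mutated, is_de_truth) so
    downstream recovery can be checked from files alone.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "edges": outdir / "edges.tsv",
        "expression": outdir / "expression.tsv",
        "mutations": outdir / "mutations.txt",
        "gaf": outdir / "annotations.gaf",
        "bioactivity": outdir / "bioactivity.tsv",
        "truth": outdir / "ground_truth.tsv",
    }
    write_edge_list(dataset.interactome, paths["edges"])
    write_expression_matrix(dataset.profile, paths["expression"])
    write_gene_list(dataset.mutated, paths["mutations"])
    if dataset.annotations:
        write_gaf(dataset.annotations, paths["gaf"])
    if dataset.bioactivity is not None:
        write_bioactivity(dataset.bioactivity, paths["bioactivity"])
    mutated = set(dataset.mutated)
    truth = dataset.truth.copy()
    truth.insert(0, "is_mutated", [g in mutated for g in truth.index])
    truth.to_csv(paths["truth"], sep="\t", index_label="node")
    return paths
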