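"""Generator contracts: structure, determinism, ground-truth consistency."""

from dataclasses import replace

import networkx as nx
import numpy as np
import pytest
from scipy import stats as sps

from neighbornet.errors import ConfigError
from neighbornet.synthetic import (
    SyntheticConfig,
    generate_bioactivity,
    generate_expression,
    generate_go_annotations,
    generate_interactome,
    generate_mutations,
)


class TestInteractome:
    def test_single_attachment_grows_a_tree(self):
        cfg = SyntheticConfig(n_nodes=10, attachment_edges=1, n_seed_proteins=3, rng_seed=1)
        net = generate_interactome(cfg)
        assert net.n_edges() == 9
        assert nx.is_tree(net.graph)
        assert net.n_self_loops_dropped == 0

    def test_same_seed_same_network(self):
        cfg = SyntheticConfig(n_nodes=50, attachment_edges=2, n_seed_proteins=5, rng_seed=3)
        a = generate_interactome(cfg)
        b = generate_interactome(cfg)
        assert a == b

    def test_different_seeds_differ(self):
        a = generate_interactome(SyntheticConfig(n_nodes=50, attachment_edges=2, n_seed_proteins=5, rng_seed=3))
        b = generate_interactome(SyntheticConfig(n_nodes=50, attachment_edges=2, n_seed_proteins=5, rng_seed=4))
        assert a != b

    @pytest.mark.parametrize("seed", range(20))
    def test_heavy_tailed_degrees(self, seed):
        cfg = SyntheticConfig(n_nodes=2000, attachment_edges=3, rng_seed=seed)
        net = generate_interactome(cfg)
        degrees = np.array([d for _, d in net.graph.degree])
        assert degrees.max() > 10 * np.median(degrees)

    def test_connected_and_loop_free(self):
        net = generate_interactome(SyntheticConfig(n_nodes=500, rng_seed=9))
        assert nx.is_connected(net.graph)
        assert nx.number_of_selfloops(net.graph) == 0

    def test_directed_fraction_controls_flags(self):
        cfg = SyntheticConfig(n_nodes=500, directed_fraction=0.0, rng_seed=2)
        assert not generate_interactome(cfg).directed_edges
        cfg = SyntheticConfig(n_nodes=500, directed_fraction=1.0, rng_seed=2)
        net = generate_interactome(cfg)
        assert len(net.directed_edges) == net.n_edges()

    def test_configuration_model_alternative(self):
        cfg = SyntheticConfig(n_nodes=500, graph_model="configuration", rng_seed=5)
        net = generate_interactome(cfg)
        assert nx.is_connected(net.graph)
        assert nx.number_of_selfloops(net.graph) == 0

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(n_nodes=3, attachment_edges=3)


class TestExpression:
    def test_no_switching_means_empty_de_truth(self, small_config):
        cfg = replace(small_config, frac_de_genes=0.0)
        net = generate_interactome(cfg)
        _, truth = generate_expression(cfg, net)
        assert not truth["is_de_truth"].any()

    def test_de_count_within_binomial_interval(self):
        cfg = SyntheticConfig(n_nodes=1000, frac_de_genes=0.1, rng_seed=21)
        net = generate_interactome(cfg)
        _, truth = generate_expression(cfg, net)
        k = int(truth["is_de_truth"].sum())
        lo, hi = sps.binom.ppf([0.005, 0.995], 1000, 0.1)
        assert lo <= k <= hi

    def test_de_genes_expressed_in_exactly_one_state(self, small_config):
        cfg = replace(small_config, frac_de_genes=0.3)
        net = generate_interactome(cfg)
        _, truth = generate_expression(cfg, net)
        de = truth[truth["is_de_truth"]]
        assert (de["expressed_normal"] != de["expressed_cancer"]).all()
        stable = truth[~truth["is_de_truth"]]
        assert (stable["expressed_normal"] == stable["expressed_cancer"]).all()

    def test_well_separated_modes_recovered_downstream(self):
        # tight modes: the mean-minus-SD rule should recover nearly all calls
        from neighbornet.construct import discretize

        accs = []
        for seed in range(10):
            cfg = SyntheticConfig(
                n_nodes=400, expression_modes=((2.0, 0.1), (10.0, 0.1)), rng_seed=seed
            )
            net = generate_interactome(cfg)
            profile, truth = generate_expression(cfg, net)
            disc = discretize(profile, net.nodes)
            calls = disc.calls.loc[truth.index]
            acc = (
                (calls["normal"] == truth["expressed_normal"]).sum()
                + (calls["cancer"] == truth["expressed_cancer"]).sum()
            ) / (2 * len(truth))
            accs.append(acc)
        assert min(accs) >= 0.95


class TestMutations:
    def test_unbiased_seeds_match_network_degree_distribution(self):
        cfg = SyntheticConfig(n_nodes=1000, n_seed_proteins=40,
                              seed_centrality_bias=0.0, rng_seed=31)
        net = generate_interactome(cfg)
        degrees = dict(net.graph.degree)
        pooled = []
        for i in range(50):
            seeds = generate_mutations(replace(cfg, rng_seed=1000 + i), net)
            pooled.extend(degrees[g] for g in seeds)
        p = sps.ks_2samp(pooled, list(degrees.values())).pvalue
        assert p > 0.01

    def test_biased_seeds_sit_on_hubs(self):
        cfg = SyntheticConfig(n_nodes=1000, n_seed_proteins=40,
                              seed_centrality_bias=2.0, rng_seed=32)
        net = generate_interactome(cfg)
        degrees = dict(net.graph.degree)
        net_median = np.median(list(degrees.values()))
        wins = 0
        for i in range(100):
            seeds = generate_mutations(replace(cfg, rng_seed=2000 + i), net)
            if np.median([degrees[g] for g in seeds]) > net_median:
                wins += 1
        assert wins >= 95

    def test_zero_seeds_is_empty(self, small_config):
        cfg = replace(small_config, n_seed_proteins=0)
        net = generate_interactome(cfg)
        assert generate_mutations(cfg, net) == []

    def test_seeds_distinct_and_in_network(self, small_config):
        net = generate_interactome(small_config)
        seeds = generate_mutations(small_config, net)
        assert len(seeds) == len(set(seeds)) == small_config.n_seed_proteins
        assert set(seeds) <= net.nodes


class TestGOAnnotations:
    def test_exactly_one_term_each(self, small_config):
        cfg = replace(small_config, go_terms_per_protein=(1, 1))
        net = generate_interactome(cfg)
        ann = generate_go_annotations(cfg, net)
        assert set(ann) == net.nodes
        assert all(len(terms) == 1 for terms in ann.values())

    def test_term_ids_within_configured_space(self, small_config):
        cfg = replace(small_config, n_go_terms=50)
        net = generate_interactome(cfg)
        ann = generate_go_annotations(cfg, net)
        all_terms = set().union(*ann.values())
        assert all_terms <= {f"GO:{i:07d}" for i in range(50)}

    def test_term_count_respects_range(self, small_config):
        cfg = replace(small_config, go_terms_per_protein=(2, 4))
        net = generate_interactome(cfg)
        ann = generate_go_annotations(cfg, net)
        assert all(2 <= len(t) <= 4 for t in ann.values())


class TestBioactivity:
    def test_all_phase4_when_fraction_is_one(self, small_config):
        cfg = replace(small_config, frac_phase4=1.0)
        net = generate_interactome(cfg)
        table = generate_bioactivity(cfg, net)
        assert (table.records["max_phase"] == 4).all()

    def test_weak_potencies_fail_downstream_filter(self, small_config):
        from neighbornet.functional_drug import filter_drugs

        cfg = replace(small_config, potency_range_nM=(600.0, 1000.0))
        net = generate_interactome(cfg)
        table = generate_bioactivity(cfg, net)
        drugs, compounds = filter_drugs(table)
        assert len(drugs) == 0 and len(compounds) == 0

    def test_phase4_count_within_binomial_interval(self):
        cfg = SyntheticConfig(n_nodes=300, n_compounds=500, frac_phase4=0.2, rng_seed=41)
        net = generate_interactome(cfg)
        table = generate_bioactivity(cfg, net)
        per_compound = table.records.groupby("compound_id")["max_phase"].first()
        k = int((per_compound == 4).sum())
        lo, hi = sps.binom.ppf([0.005, 0.995], 500, 0.2)
        assert lo <= k <= hi

    def test_potencies_inside_range(self, small_config):
        net = generate_interactome(small_config)
        table = generate_bioactivity(small_config, net)
        lo, hi = small_config.potency_range_nM
        assert table.records["value_nM"].between(lo, hi).all()
        assert set(table.records["activity_type"]) <= {"IC50", "Ki", "Kd"}
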