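"""Repeated synthetic studies: recovery, calibration and robustness rates.

These runners execute the full pipeline (generate -> discretize -> binary
DE -> tissue network -> classify -> topology) many times under controlled
generator conditions and summarize how often the qualitative findings are
recovered. They back both the validation suite and the reproduction
script; each takes an explicit seed and derives one child seed per
replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import networkx as nx
import numpy as np

from .classify import Classification, classify, first_neighbour_split
from .construct import TissueNetwork, build_tissue_network, call_differential_expression, discretize
from .synthetic import SyntheticConfig, generate_expression, generate_interactome, generate_mutations
from .topology import compute_topology, giant_component_test
from .stats import rank_sum_test


@dataclass
class StudyRun:
    """One synthetic study, carried through classification."""

    config: SyntheticConfig
    network: TissueNetwork
    classification: Classification
    truth: "object"
    disc: "object"


def run_study(config: SyntheticConfig) -> StudyRun:
    """Generate one dataset and run it through the pipeline's core stages."""
    interactome = generate_interactome(config)
    profile, truth = generate_expression(config, interactome)
    mutated = generate_mutations(config, interactome)
    disc = discretize(profile, interactome.nodes)
    de = call_differential_expression(disc)
    network = build_tissue_network(interactome, disc)
    classification = classify(network, mutated, de)
    return StudyRun(config, network, classification, truth, disc)


def _replicate_config(base: SyntheticConfig, seed: int, i: int) -> SyntheticConfig:
    return replace(base, rng_seed=int(np.random.default_rng([seed, i]).integers(2**31)))


def friendship_paradox_rate(
    base: SyntheticConfig, n_sims: int = 100, seed: int = 0
) -> float:
    """Fraction of studies where median first-neighbour degree >= network median.

    Run with ``seed_centrality_bias=0`` this is the friendship-paradox
    property itself: even uniformly chosen seeds have first neighbours at
    or above the network's median degree in a heavy-tailed graph.
    """
    hits = 0
    for i in range(n_sims):
        run = run_study(_replicate_config(base, seed, i))
        degrees = dict(run.network.graph.degree)
        fn = [degrees[v] for v in run.classification.first_neighbour]
        if not fn:
            continue
        if np.median(fn) >= np.median(list(degrees.values())):
            hits += 1
    return hits / n_sims


def fn_centrality_rejection_rate(
    base: SyntheticConfig, n_sims: int = 100, seed: int = 0, alpha: float = 0.05
) -> dict[str, float]:
    """How often FN vs UA differ significantly in degree and betweenness.

    Returns per-metric fractions of studies with two-sided rank-sum
    p < alpha, plus the fraction where both metrics reject at once.
    """
    hits = {"degree": 0, "betweenness": 0, "both": 0}
    for i in range(n_sims):
        run = run_study(_replicate_config(base, seed, i))
        topo = compute_topology(run.network)
        fn = sorted(run.classification.first_neighbour)
        ua = sorted(run.classification.unaffected)
        if len(fn) < 2 or len(ua) < 2:
            continue
        rejected = {}
        for metric in ("degree", "betweenness"):
            p = rank_sum_test(topo.loc[fn, metric], topo.loc[ua, metric]).p_value
            rejected[metric] = p < alpha
            hits[metric] += rejected[metric]
        hits["both"] += rejected["degree"] and rejected["betweenness"]
    return {k: v / n_sims for k, v in hits.items()}


def dichotomy_rate(
    base: SyntheticConfig, n_sims: int = 100, seed: int = 0
) -> dict[str, float]:
    """Recovery of the two-strategy pattern of mutated vs DE seeds.

    With hub-biased mutated seeds and unbiased DE genes, each study checks
    (a) median degree of first neighbours of DE proteins strictly exceeds
    the DE proteins' own median, and (b) mutated proteins' median degree is
    at least their first neighbours'. Returns the per-condition and joint
    fractions.
    """
    hits = {"de_fn_higher": 0, "mut_at_least_fn": 0, "both": 0}
    for i in range(n_sims):
        run = run_study(_replicate_config(base, seed, i))
        degrees = dict(run.network.graph.degree)
        fn_mut, fn_de = first_neighbour_split(run.classification, run.network)
        de_deg = [degrees[v] for v in run.classification.de]
        mut_deg = [degrees[v] for v in run.classification.mutated]
        if not (fn_de and fn_mut and de_deg and mut_deg):
            continue
        a = np.median([degrees[v] for v in fn_de]) > np.median(de_deg)
        b = np.median(mut_deg) >= np.median([degrees[v] for v in fn_mut])
        hits["de_fn_higher"] += a
        hits["mut_at_least_fn"] += b
        hits["both"] += a and b
    return {k: v / n_sims for k, v in hits.items()}


def gc_calibration_rate(
    n_datasets: int = 200,
    n_nodes: int = 500,
    attachment_edges: int = 3,
    class_fraction: float = 0.05,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Type-I error of the giant-component test under uniform random labels.

    For each dataset a fresh graph is grown, a uniformly random class of
    the given fraction is labelled, and the empirical permutation p is
    computed; returns the fraction of datasets with p < alpha. A
    calibrated test keeps this near alpha.
    """
    rejections = 0
    for i in range(n_datasets):
        rng = np.random.default_rng([seed, i])
        cfg = SyntheticConfig(
            n_nodes=n_nodes, attachment_edges=attachment_edges,
            rng_seed=int(rng.integers(2**31)),
        )
        net = generate_interactome(cfg)
        nodes = sorted(net.nodes)
        k = max(2, int(round(class_fraction * len(nodes))))
        members = [nodes[j] for j in rng.choice(len(nodes), size=k, replace=False)]
        res = giant_component_test(net, members, n_perm=n_perm, seed=rng)
        rejections += res.p_empirical < alpha
    return rejections / n_datasets


def gc_planted_detection_rate(
    n_datasets: int = 100,
    n_nodes: int = 500,
    attachment_edges: int = 3,
    class_fraction: float = 0.05,
    n_perm: int = 1000,
    z_threshold: float = 3.0,
    seed: int = 0,
) -> float:
    """Power against a planted connected module of the given size.

    The planted class is a breadth-first ball around a random node, hence
    connected by construction (observed ratio 1); returns the fraction of
    datasets with Z above the threshold.
    """
    detections = 0
    for i in range(n_datasets):
        rng = np.random.default_rng([seed, i])
        cfg = SyntheticConfig(
            n_nodes=n_nodes, attachment_edges=attachment_edges,
            rng_seed=int(rng.integers(2**31)),
        )
        net = generate_interactome(cfg)
        nodes = sorted(net.nodes)
        k = max(2, int(round(class_fraction * len(nodes))))
        start = nodes[int(rng.integers(len(nodes)))]
        members = [start]
        seen = {start}
        for _, v in nx.bfs_edges(net.graph, start):
            if v not in seen:
                members.append(v)
                seen.add(v)
            if len(members) == k:
                break
        res = giant_component_test(net, members, n_perm=n_perm, seed=rng)
        if np.isfinite(res.z) and res.z > z_threshold:
            detections += 1
    return detections / n_datasets


def discretization_recovery(
    base: SyntheticConfig, n_seeds: int = 10, seed: int = 0
) -> float:
    """Mean fraction of ground-truth on/off labels the mean-minus-SD rule recovers.

    Per study, every (gene, state) call is compared against the generator's
    truth; the mean accuracy across studies is returned.
    """
    accs = []
    for i in range(n_seeds):
        cfg = _replicate_config(base, seed, i)
        interactome = generate_interactome(cfg)
        profile, truth = generate_expression(cfg, interactome)
        disc = discretize(profile, interactome.nodes)
        calls = disc.calls.loc[truth.index]
        correct = (
            (calls["normal"] == truth["expressed_normal"]).sum()
            + (calls["cancer"] == truth["expressed_cancer"]).sum()
        )
        accs.append(correct / (2 * len(truth)))
    return float(np.mean(accs))
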