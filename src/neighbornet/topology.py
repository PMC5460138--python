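"""Node-level topology metrics, class comparisons and permutation tests.

All metrics are computed on the undirected, unweighted, loop-free graph:

* degree k — number of incident edges;
* betweenness b — for node v, the sum over unordered node pairs (s, t),
  s != t != v, of sigma_st(v) / sigma_st (unnormalized pair counts; ranks,
  and hence every rank-based comparison, are invariant to normalization);
* clustering coefficient C — fraction of a node's neighbour pairs that are
  themselves connected; 0 by convention for degree < 2.

The heavy lifting goes through python-igraph, which keeps the permutation
and randomization analyses (hundreds of betweenness evaluations) fast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import CLASS_LABELS, Classification
from .errors import ConfigError, DataError
from .stats import KSResult, RankSumResult, ks_test, rank_sum_test, significance_stars

logger = logging.getLogger(__name__)

METRICS = ("degree", "betweenness", "clustering")


def _as_nx(network) -> nx.Graph:
    if isinstance(network, nx.Graph):
        return network
    graph = getattr(network, "graph", None)
    if isinstance(graph, nx.Graph):
        return graph
    raise ConfigError(f"cannot interpret {type(network).__name__} as a graph")


def compute_topology(network, normalized: bool = False) -> pd.DataFrame:
    """Per-node degree, betweenness and clustering coefficient.

    Returns a node-indexed DataFrame with columns
    ``degree, betweenness, clustering``. ``normalized=True`` divides
    betweenness by (n-1)(n-2)/2, the number of pairs excluding the node.
    """
    graph = _as_nx(network)
    nodes = sorted(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    g = ig.Graph(
        n=len(nodes),
        edges=[(index[u], index[v]) for u, v in graph.edges],
        directed=False,
    )
    degree = g.degree()
    betweenness = g.betweenness(directed=False)
    clustering = g.transitivity_local_undirected(mode="zero")
    df = pd.DataFrame(
        {
            "degree": np.asarray(degree, dtype=int),
            "betweenness": np.asarray(betweenness, dtype=float),
            "clustering": np.asarray(clustering, dtype=float),
        },
        index=pd.Index(nodes, name="node"),
    )
    if normalized:
        n = len(nodes)
        scale = (n - 1) * (n - 2) / 2 if n > 2 else 1.0
        df["betweenness"] = df["betweenness"] / scale
    return df


@dataclass(frozen=True)
class ClassComparison:
    """One metric compared between a class and a control group."""

    class_a: str
    class_b: str
    metric: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    q1_a: float
    q3_a: float
    q1_b: float
    q3_b: float
    wilcoxon: RankSumResult
    ks: KSResult

    @property
    def stars(self) -> str:
        return significance_stars(self.wilcoxon.p_value)


def _quartiles(values: np.ndarray) -> tuple[float, float, float]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return float(q1), float(med), float(q3)


def compare_groups(values_a, values_b, class_a: str, class_b: str, metric: str,
                   alternative: str = "two-sided") -> ClassComparison:
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    q1a, meda, q3a = _quartiles(a)
    q1b, medb, q3b = _quartiles(b)
    return ClassComparison(
        class_a, class_b, metric, a.size, b.size, meda, medb,
        q1a, q3a, q1b, q3b,
        wilcoxon=rank_sum_test(a, b, alternative=alternative),
        ks=ks_test(a, b),
    )


def compare_classes(
    topology: pd.DataFrame,
    classification: Classification,
    control: str = "whole_network",
    metrics: Sequence[str] = METRICS,
    classes: Sequence[str] = CLASS_LABELS,
    alternative: str = "two-sided",
) -> list[ClassComparison]:
    """Each class against the control group, for each metric.

    ``control`` is ``whole_network`` (the class is compared against every
    node, itself included — the class is a subset of its control) or
    ``unaffected``. Groups smaller than 2 are skipped with a warning.
    """
    if control not in ("whole_network", "unaffected"):
        raise ConfigError(f"unknown control {control!r}")
    results = []
    for label in classes:
        members = sorted(classification.members(label))
        if control == "whole_network":
            ctrl_nodes = list(topology.index)
            ctrl_label = "whole_network"
        else:
            if label == "unaffected":
                continue
            ctrl_nodes = sorted(classification.unaffected)
            ctrl_label = "unaffected"
        if len(members) < 2 or len(ctrl_nodes) < 2:
            logger.warning("comparison %s vs %s skipped: group too small",
                           label, ctrl_label)
            continue
        for metric in metrics:
            if metric not in METRICS:
                raise ConfigError(f"unknown metric {metric!r}")
            results.append(
                compare_groups(
                    topology.loc[members, metric],
                    topology.loc[ctrl_nodes, metric],
                    label, ctrl_label, metric, alternative,
                )
            )
    return results


def comparisons_frame(comparisons: Iterable[ClassComparison]) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        rows.append(
            {
                "class": c.class_a, "control": c.class_b, "metric": c.metric,
                "n_class": c.n_a, "n_control": c.n_b,
                "median_class": c.median_a, "median_control": c.median_b,
                "q1_class": c.q1_a, "q3_class": c.q3_a,
                "q1_control": c.q1_b, "q3_control": c.q3_b,
                "wilcoxon_stat": c.wilcoxon.statistic,
                "wilcoxon_p": c.wilcoxon.p_value,
                "wilcoxon_method": c.wilcoxon.method,
                "ks_stat": c.ks.statistic, "ks_p": c.ks.p_value,
                "stars": c.stars,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# giant component permutation test
# ---------------------------------------------------------------------------

def _adjacency(graph: nx.Graph) -> dict[str, set[str]]:
    return {v: set(graph.neighbors(v)) for v in graph.nodes}


def giant_component_ratio(adjacency: Mapping[str, set], nodes: Iterable[str]) -> float:
    """|largest connected component of the induced subgraph| / |node set|."""
    pool = set(nodes)
    if not pool:
        raise DataError("empty node set")
    best = 0
    remaining = set(pool)
    while remaining:
        start = remaining.pop()
        comp = 1
        frontier = [start]
        seen = {start}
        while frontier:
            v = frontier.pop()
            for w in adjacency.get(v, ()) & remaining:
                remaining.discard(w)
                seen.add(w)
                comp += 1
                frontier.append(w)
        best = max(best, comp)
    return best / len(pool)


@dataclass
class PermutationResult:
    """Observed giant-component ratio against a label-permutation null."""

    label: str
    class_size: int
    r_obs: float
    null: np.ndarray = field(repr=False)
    mean_null: float = 0.0
    sd_null: float = 0.0
    z: float = float("nan")
    p_normal: float = float("nan")
    p_empirical: float = 1.0

    @property
    def n_perm(self) -> int:
        return len(self.null)


def _null_sampler(graph: nx.Graph, all_nodes: list, class_nodes: list, scheme: str):
    """Build the per-permutation node-subset sampler for the chosen null."""
    k = len(class_nodes)
    n = len(all_nodes)
    if scheme == "uniform":
        def draw(rng: np.random.Generator):
            idx = rng.choice(n, size=k, replace=False)
            return (all_nodes[j] for j in idx)
        return draw
    # degree-stratified: sample within degree deciles, matching the class's
    # per-decile membership counts
    degrees = np.array([graph.degree[v] for v in all_nodes], dtype=float)
    edges = np.quantile(degrees, np.linspace(0, 1, 11))
    bins = np.clip(np.searchsorted(edges, degrees, side="right") - 1, 0, 9)
    index = {v: i for i, v in enumerate(all_nodes)}
    pools = [np.flatnonzero(bins == b) for b in range(10)]
    class_counts = np.bincount([bins[index[v]] for v in class_nodes], minlength=10)

    def draw(rng: np.random.Generator):
        chosen = []
        for pool, c in zip(pools, class_counts):
            if c:
                chosen.extend(rng.choice(pool, size=int(c), replace=False))
        return (all_nodes[j] for j in chosen)

    return draw


def giant_component_test(
    network,
    class_nodes: Iterable[str],
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    label: str = "",
    null: str = "uniform",
) -> PermutationResult:
    """Is the class more internally connected than a random set of its size?

    The null relabels the class ``n_perm`` times: a random node subset of
    the same size is drawn from the whole network and its induced-subgraph
    giant-component ratio recorded. ``null="uniform"`` draws uniformly;
    ``null="degree_stratified"`` preserves the class's degree profile by
    sampling, within each degree decile, as many nodes as the class has
    there. Reported are the Z-score of the observed ratio against the
    null, its upper-tail normal p, and the empirical p
    ``(1 + #{null >= obs}) / (n_perm + 1)``. When the null has zero spread
    the Z-score is undefined (NaN) and only the empirical p is meaningful.
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    if null not in ("uniform", "degree_stratified"):
        raise ConfigError(f"unknown null scheme {null!r}")
    graph = _as_nx(network)
    adjacency = _adjacency(graph)
    all_nodes = sorted(graph.nodes)
    class_nodes = sorted(set(class_nodes))
    if not class_nodes:
        raise DataError("class is empty")
    missing = set(class_nodes) - set(all_nodes)
    if missing:
        raise DataError(f"class contains nodes outside the network: {sorted(missing)[:5]}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r_obs = giant_component_ratio(adjacency, class_nodes)
    k = len(class_nodes)
    draw = _null_sampler(graph, all_nodes, class_nodes, null)
    null_sample = np.empty(n_perm)
    for i in range(n_perm):
        null_sample[i] = giant_component_ratio(adjacency, draw(rng))
    mean_null = float(null_sample.mean())
    sd_null = float(null_sample.std(ddof=1)) if n_perm > 1 else 0.0
    if sd_null > 0:
        z = (r_obs - mean_null) / sd_null
        p_normal = float(sps.norm.sf(z))
    else:
        z = float("nan")
        p_normal = float("nan")
    p_emp = (1 + int((null_sample >= r_obs - 1e-12).sum())) / (n_perm + 1)
    return PermutationResult(label, k, r_obs, null_sample, mean_null, sd_null,
                             z, p_normal, p_emp)


# ---------------------------------------------------------------------------
# seed-randomization robustness analysis
# ---------------------------------------------------------------------------

@dataclass
class RandomizationResult:
    """First-neighbour occurrence counts across R random seed draws.

    ``occurrence[v]`` counts, out of R uniformly random seed sets of the
    same size as the real cancer-related set, how often v appeared in the
    derived first-neighbour set. ``comparisons`` holds rank-sum tests of
    those counts between the real classes (FN vs UA, FN vs CR).
    """

    R: int
    occurrence: dict[str, int]
    comparisons: dict[str, RankSumResult] = field(default_factory=dict)

    def counts(self, nodes: Iterable[str]) -> np.ndarray:
        return np.array([self.occurrence.get(v, 0) for v in sorted(set(nodes))])


def randomization_analysis(
    network,
    classification: Classification,
    R: int = 100,
    seed: int | np.random.Generator = 0,
) -> RandomizationResult:
    """How often would each protein be a first neighbour of a random seed set?

    Repeats R times: draw a uniform random node set of the real CR set's
    size, list its first neighbours by the classification rule (one-step
    adjacency minus the seed set itself), and accumulate per-node
    occurrence counts. R = 0 returns all-zero counts and no comparisons.
    """
    graph = _as_nx(network)
    nodes = sorted(graph.nodes)
    k = len(classification.cancer_related)
    if k < 1:
        raise DataError("cancer-related class is empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    occurrence = {v: 0 for v in nodes}
    adjacency = _adjacency(graph)
    for _ in range(R):
        idx = rng.choice(len(nodes), size=k, replace=False)
        seeds = {nodes[j] for j in idx}
        fn: set[str] = set()
        for s in seeds:
            fn |= adjacency[s]
        fn -= seeds
        for v in fn:
            occurrence[v] += 1
    result = RandomizationResult(R, occurrence)
    if R > 0:
        fn_counts = result.counts(classification.first_neighbour)
        ua_counts = result.counts(classification.unaffected)
        cr_counts = result.counts(classification.cancer_related)
        if fn_counts.size and ua_counts.size:
            result.comparisons["fn_vs_ua"] = rank_sum_test(fn_counts, ua_counts)
        if fn_counts.size and cr_counts.size:
            result.comparisons["fn_vs_cr"] = rank_sum_test(fn_counts, cr_counts)
    return result
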