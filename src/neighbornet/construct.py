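"""Tissue-specific network construction from discretized expression.

The expression contract is deliberately binary: a gene is *expressed* in a
state when its per-state summary value clears the threshold tau = mu - sigma,
where mu and sigma are taken over the pooled per-state summaries of all
network genes. A gene is differentially expressed (DE) when its on/off call
differs between the normal and cancer state — overexpression of a gene that
is on in both states does not count. The tissue network then keeps an
interaction when both endpoints are present in at least one state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .errors import ConfigError, DataError, DegenerateInputError
from .io import ExpressionProfile, Interactome

logger = logging.getLogger(__name__)

PRESENCE_LEVELS = ("both", "normal_only", "cancer_only", "absent")


@dataclass
class DiscretizationResult:
    """Per-gene, per-state on/off calls against the mean-minus-SD threshold.

    ``summaries`` and ``calls`` are gene-indexed frames with ``normal`` and
    ``cancer`` columns; ``calls`` holds booleans (True = expressed). In the
    default combined pooling a single (mu, sigma, tau) applies to both
    states; per-state pooling stores one threshold per state (tau then holds
    the normal-state value, ``tau_by_state`` both).
    """

    mu: float
    sigma: float
    tau: float
    summaries: pd.DataFrame
    calls: pd.DataFrame
    pooling: str = "combined"
    tau_by_state: dict[str, float] = field(default_factory=dict)

    def expressed_in_any_state(self) -> set[str]:
        return set(self.calls.index[self.calls.any(axis=1)])


def discretize(
    profile: ExpressionProfile,
    network_genes: set[str],
    summary: str = "mean",
    sd: str = "sample",
    pooling: str = "combined",
) -> DiscretizationResult:
    """Discretize expression of the network's genes into on/off calls.

    Parameters
    ----------
    profile
        Expression values split into normal and cancer sample groups.
    network_genes
        The gene universe of the interactome under study; mu and sigma are
        pooled over these genes only ("in the given network").
    summary
        Per-state per-gene summary across samples: ``mean`` (default) or
        ``median``.
    sd
        ``sample`` (n-1 denominator, default) or ``population``.
    pooling
        ``combined`` pools both states' summaries into one (mu, sigma);
        ``per_state`` computes a separate threshold per state.

    A gene is called *not expressed* in a state iff its summary value is
    strictly below tau = mu - sigma; ties sit on the expressed side, so a
    zero-variance pool leaves every gene expressed.
    """
    if summary not in ("mean", "median"):
        raise ConfigError(f"unknown summary {summary!r}")
    if sd not in ("sample", "population"):
        raise ConfigError(f"unknown sd convention {sd!r}")
    if pooling not in ("combined", "per_state"):
        raise ConfigError(f"unknown pooling {pooling!r}")
    genes = sorted(network_genes & profile.genes)
    if not genes:
        raise DataError("no overlap between network genes and expression profile")
    summaries = (profile.state_means() if summary == "mean" else profile.state_medians())
    summaries = summaries.loc[genes]
    ddof = 1 if sd == "sample" else 0

    if pooling == "combined":
        pool = summaries.to_numpy().ravel()
        if pool.size < 2:
            raise DegenerateInputError("need at least two pooled summary values for sigma")
        mu = float(pool.mean())
        sigma = float(pool.std(ddof=ddof))
        tau = mu - sigma
        calls = summaries >= tau  # not expressed iff value < tau (strict)
        return DiscretizationResult(mu, sigma, tau, summaries, calls, pooling)

    tau_by_state: dict[str, float] = {}
    calls = pd.DataFrame(index=summaries.index)
    for state in ("normal", "cancer"):
        col = summaries[state].to_numpy()
        if col.size < 2:
            raise DegenerateInputError("need at least two summary values for sigma")
        mu_s = float(col.mean())
        sigma_s = float(col.std(ddof=ddof))
        tau_by_state[state] = mu_s - sigma_s
        calls[state] = summaries[state] >= tau_by_state[state]
    first = tau_by_state["normal"]
    return DiscretizationResult(
        mu=float(summaries.to_numpy().mean()),
        sigma=float(summaries.to_numpy().std(ddof=ddof)),
        tau=first,
        summaries=summaries,
        calls=calls,
        pooling="per_state",
        tau_by_state=tau_by_state,
    )


def call_differential_expression(disc: DiscretizationResult) -> set[str]:
    """Genes whose on/off call differs between the two states.

    On in both states or off in both states is *not* DE — only an on/off
    switch between normal and cancer counts.
    """
    differs = disc.calls["normal"] != disc.calls["cancer"]
    return set(disc.calls.index[differs])


@dataclass
class TissueNetwork:
    """The interactome restricted to genes present in at least one state.

    ``presence`` maps every base-interactome node to one of
    ``both / normal_only / cancer_only / absent``; ``graph`` holds the
    retained edges only, and ``directed_edges`` the direction annotations
    among them.
    """

    base: Interactome
    graph: nx.Graph
    directed_edges: set[tuple[str, str]]
    presence: dict[str, str]

    @property
    def resource_name(self) -> str:
        return self.base.resource_name

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors(self, node: str) -> set[str]:
        return set(self.graph.neighbors(node))


def build_tissue_network(
    interactome: Interactome,
    disc: DiscretizationResult,
    uncovered: str = "absent",
    rule: str = "union",
) -> TissueNetwork:
    """Restrict the interactome to the tissue's expressed gene set.

    Parameters
    ----------
    uncovered
        Policy for network genes missing from the expression table:
        ``absent`` (strict, default; dropped with a logged count) or
        ``expressed`` (treated as on in both states).
    rule
        ``union`` (default): keep an edge when both endpoints are present
        in at least one state, not necessarily the same one. ``per_state``:
        keep an edge only if there is a single state in which both
        endpoints are expressed (the conjunctive reading).

    Nodes with retained presence but whose every edge is filtered remain in
    the graph as isolated nodes; an entirely empty result is a warning, not
    an error.
    """
    if uncovered not in ("absent", "expressed"):
        raise ConfigError(f"unknown uncovered policy {uncovered!r}")
    if rule not in ("union", "per_state"):
        raise ConfigError(f"unknown edge rule {rule!r}")

    calls = disc.calls
    presence: dict[str, str] = {}
    expressed_state: dict[str, tuple[bool, bool]] = {}
    n_uncovered = 0
    for node in interactome.graph.nodes:
        if node in calls.index:
            en = bool(calls.at[node, "normal"])
            ec = bool(calls.at[node, "cancer"])
        else:
            n_uncovered += 1
            en = ec = uncovered == "expressed"
        expressed_state[node] = (en, ec)
        if en and ec:
            presence[node] = "both"
        elif en:
            presence[node] = "normal_only"
        elif ec:
            presence[node] = "cancer_only"
        else:
            presence[node] = "absent"
    if n_uncovered:
        logger.info(
            "%s: %d network gene(s) not covered by expression data (policy=%s)",
            interactome.resource_name, n_uncovered, uncovered,
        )

    graph = nx.Graph()
    for node, level in presence.items():
        if level != "absent":
            graph.add_node(node)
    for u, v in interactome.graph.edges:
        un, uc = expressed_state[u]
        vn, vc = expressed_state[v]
        if rule == "union":
            keep = (un or uc) and (vn or vc)
        else:
            keep = (un and vn) or (uc and vc)
        if keep:
            graph.add_edge(u, v)
    directed = {
        (s, t) for (s, t) in interactome.directed_edges if graph.has_edge(s, t)
    }
    if graph.number_of_nodes() == 0:
        logger.warning("%s: tissue network is empty", interactome.resource_name)
    return TissueNetwork(interactome, graph, directed, presence)
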