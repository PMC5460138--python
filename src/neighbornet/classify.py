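"""Node classification: cancer-related, first neighbour, unaffected, influencer.

A protein is *cancer-related* (CR) when its gene is in the mutated list
and/or the binary-DE set; a *first neighbour* (FN) is any direct interactor
of a CR protein that is not itself CR — a protein that is both CR and a
neighbour of another CR protein counts only as CR. Everything else is
*unaffected* (UA). Adjacency ignores edge direction; direction is consulted
only for *influencers*: UA proteins with a directed interaction into a
first neighbour (by default, a first neighbour of a DE cancer-related
protein — the two-step drug-target rule).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .construct import TissueNetwork
from .errors import ConfigError, EmptySeedError

logger = logging.getLogger(__name__)

CLASS_LABELS = ("cancer_related", "first_neighbour", "unaffected")


@dataclass(frozen=True)
class Classification:
    """A total partition of the network's nodes into the three classes.

    ``mutated`` and ``de`` record the (non-exclusive) reason a CR node is
    cancer-related; both are subsets of ``cancer_related``. ``influencers``
    is a subset of ``unaffected`` and is empty until
    :func:`find_influencers` fills it.
    """

    cancer_related: frozenset[str]
    first_neighbour: frozenset[str]
    unaffected: frozenset[str]
    mutated: frozenset[str]
    de: frozenset[str]
    influencers: frozenset[str] = frozenset()
    resource_name: str = ""

    @property
    def n_nodes(self) -> int:
        return len(self.cancer_related) + len(self.first_neighbour) + len(self.unaffected)

    def label_of(self, node: str) -> str:
        if node in self.cancer_related:
            return "cancer_related"
        if node in self.first_neighbour:
            return "first_neighbour"
        if node in self.unaffected:
            return "unaffected"
        raise KeyError(node)

    def members(self, label: str) -> frozenset[str]:
        if label not in CLASS_LABELS:
            raise ConfigError(f"unknown class label {label!r}")
        return getattr(self, label)

    def validate(self, nodes: set[str]) -> None:
        """Assert the partition property over the given node universe."""
        union = self.cancer_related | self.first_neighbour | self.unaffected
        if union != nodes:
            raise AssertionError("classes do not cover the node set")
        if (self.cancer_related & self.first_neighbour
                or self.cancer_related & self.unaffected
                or self.first_neighbour & self.unaffected):
            raise AssertionError("classes are not pairwise disjoint")
        if not self.influencers <= self.unaffected:
            raise AssertionError("influencers must be unaffected proteins")


def classify(network: TissueNetwork, mutated: Iterable[str], de: Iterable[str]) -> Classification:
    """Partition the tissue network's nodes.

    ``mutated`` / ``de`` identifiers outside the network (e.g. census genes
    silent in both tissue states, hence absent from the network) are logged
    and ignored. Raises :class:`EmptySeedError` when no cancer-related
    protein is present at all.
    """
    nodes = network.nodes
    mutated = set(mutated)
    de = set(de)
    outside = (mutated | de) - nodes
    if outside:
        logger.info(
            "%s: %d mutated/DE gene(s) not present in the tissue network",
            network.resource_name, len(outside),
        )
    mutated &= nodes
    de &= nodes
    cancer_related = mutated | de
    if not cancer_related:
        raise EmptySeedError("no cancer-related protein in the network")
    first_neighbour = set()
    for cr in cancer_related:
        first_neighbour.update(network.graph.neighbors(cr))
    first_neighbour -= cancer_related
    unaffected = nodes - cancer_related - first_neighbour
    result = Classification(
        cancer_related=frozenset(cancer_related),
        first_neighbour=frozenset(first_neighbour),
        unaffected=frozenset(unaffected),
        mutated=frozenset(mutated),
        de=frozenset(de),
        resource_name=network.resource_name,
    )
    result.validate(nodes)
    return result


def find_influencers(
    network: TissueNetwork,
    classification: Classification,
    restrict_to_de_fn: bool = True,
) -> frozenset[str]:
    """Unaffected proteins with a directed interaction into a first neighbour.

    With ``restrict_to_de_fn`` (default) the targeted first neighbour must
    additionally be adjacent to a differentially expressed cancer-related
    protein — the variant relevant for the two-step drug-target strategy.
    """
    if not network.directed_edges:
        logger.warning("%s: no directed edges; influencer set is empty",
                       network.resource_name)
        return frozenset()
    fn = set(classification.first_neighbour)
    if restrict_to_de_fn:
        fn = {f for f in fn if network.neighbors(f) & classification.de}
    ua = classification.unaffected
    influencers = {
        s for (s, t) in network.directed_edges if s in ua and t in fn
    }
    return frozenset(influencers)


def with_influencers(
    network: TissueNetwork,
    classification: Classification,
    restrict_to_de_fn: bool = True,
) -> Classification:
    """Return a copy of ``classification`` with the influencer subset filled."""
    return replace(
        classification,
        influencers=find_influencers(network, classification, restrict_to_de_fn),
    )


def consensus_influencers(per_resource: Sequence[Iterable[str]], k: int) -> frozenset[str]:
    """Proteins identified as influencer in at least ``k`` resources.

    Counting is by protein identity: a protein that targets different first
    neighbours in different resources still accumulates one vote per
    resource.
    """
    if k < 1:
        raise ConfigError("k must be >= 1")
    if k > len(per_resource):
        raise ConfigError(f"k={k} exceeds the number of resources ({len(per_resource)})")
    votes: dict[str, int] = {}
    for influencers in per_resource:
        for p in set(influencers):
            votes[p] = votes.get(p, 0) + 1
    return frozenset(p for p, n in votes.items() if n >= k)


def first_neighbour_split(
    classification: Classification, network: TissueNetwork
) -> tuple[frozenset[str], frozenset[str]]:
    """Split first neighbours by the alteration type of their CR contact.

    Returns ``(FN_of_mutated, FN_of_de)``: adjacency to at least one
    mutated (resp. DE) cancer-related protein. The two sets may overlap —
    a neighbour of both a mutated and a DE protein belongs to both.
    """
    fn_mut = set()
    fn_de = set()
    for f in classification.first_neighbour:
        nbrs = network.neighbors(f)
        if nbrs & classification.mutated:
            fn_mut.add(f)
        if nbrs & classification.de:
            fn_de.add(f)
    return frozenset(fn_mut), frozenset(fn_de)


def classification_table(classification: Classification) -> "list[dict]":
    """Rows (node, class, is_mutated, is_de, is_influencer, resource) sorted by node."""
    rows = []
    for label in CLASS_LABELS:
        for node in classification.members(label):
            rows.append(
                {
                    "node": node,
                    "class": label,
                    "is_mutated": node in classification.mutated,
                    "is_de": node in classification.de,
                    "is_influencer": node in classification.influencers,
                    "resource": classification.resource_name,
                }
            )
    rows.sort(key=lambda r: r["node"])
    return rows
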