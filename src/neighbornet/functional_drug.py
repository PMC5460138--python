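"""Added GO biological-process reach of first neighbours, and drug filters.

The GO question is about *added* functional reach: cancer-related proteins
claim their biological-process terms first; first neighbours then
contribute only the terms not already claimed. A one-sided binomial test
asks whether that added share is larger than the first neighbours' share
of the network would predict. Terms are used exactly as annotated (no
ancestor propagation up the ontology).

The drug side applies the repurposing filters: an *active compound* has an
IC50/Ki/Kd at or below 500 nM against some target; a *drug* is an active
compound that reached clinical phase 4. Counting per class is by unique
compound: one drug hitting three first neighbours counts once for the
first-neighbour class, and a compound bridging two classes counts in both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .classify import Classification
from .errors import ConfigError, DataError
from .io import ACTIVITY_TYPES, BioactivityTable
from .stats import BinomialResult, Chi2Result, binomial_test, chi2_independence

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# GO added biological processes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AddedBPResult:
    """Terms of cancer-related proteins vs terms first neighbours add."""

    bp_cr: frozenset[str]
    bp_added: frozenset[str]

    def __post_init__(self) -> None:
        if self.bp_cr & self.bp_added:
            raise AssertionError("added terms must be disjoint from CR terms")

    @property
    def k(self) -> int:
        return len(self.bp_added)

    @property
    def n(self) -> int:
        return len(self.bp_cr | self.bp_added)


def _propagate(terms: set[str], parents: Mapping[str, Iterable[str]]) -> set[str]:
    """Close a term set under the is-a parent relation."""
    out = set(terms)
    frontier = list(terms)
    while frontier:
        for parent in parents.get(frontier.pop(), ()):
            if parent not in out:
                out.add(parent)
                frontier.append(parent)
    return out


def added_bps(
    annotations: Mapping[str, Iterable[str]],
    classification: Classification,
    ontology: Mapping[str, Iterable[str]] | None = None,
) -> AddedBPResult:
    """Annotate CR proteins first; FN proteins keep only the new terms.

    By default terms are used exactly as annotated. Passing ``ontology``
    (a term -> parent-terms mapping) propagates every annotation up the
    is-a hierarchy before the set algebra.
    """
    covered = set(annotations) & (
        set(classification.cancer_related) | set(classification.first_neighbour)
    )
    if not covered:
        raise DataError("annotations cover no classified protein")
    bp_cr: set[str] = set()
    for p in classification.cancer_related:
        bp_cr |= set(annotations.get(p, ()))
    if not bp_cr:
        logger.warning("no annotated cancer-related protein; BP_cr is empty")
    bp_fn: set[str] = set()
    for p in classification.first_neighbour:
        bp_fn |= set(annotations.get(p, ()))
    if ontology is not None:
        bp_cr = _propagate(bp_cr, ontology)
        bp_fn = _propagate(bp_fn, ontology)
    return AddedBPResult(frozenset(bp_cr), frozenset(bp_fn - bp_cr))


def added_bp_binomial_test(
    result: AddedBPResult, classification: Classification, network
) -> BinomialResult:
    """Do first neighbours add more terms than their network share predicts?

    One-sided (greater) binomial test of k = |BP_added| successes in
    n = |BP_cr u BP_added| trials, with expected success probability
    |FN| / |network nodes|.
    """
    n_nodes = network.n_nodes() if hasattr(network, "n_nodes") else len(network.nodes)
    if n_nodes == 0:
        raise DataError("empty network")
    if result.n == 0:
        raise DataError("no terms at all: binomial trials count is zero")
    p_expected = len(classification.first_neighbour) / n_nodes
    return binomial_test(result.k, result.n, p_expected, alternative="greater")


# ---------------------------------------------------------------------------
# drug / compound filtering and counting
# ---------------------------------------------------------------------------

def filter_drugs(
    bioactivity: BioactivityTable,
    potency_cutoff_nM: float = 500.0,
    phase_cutoff: int = 4,
    activity_types: Iterable[str] = ACTIVITY_TYPES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split bioactivity records into (drug records, active-compound records).

    Active compounds: activity type among IC50/Ki/Kd and potency at or
    below the cutoff. Drugs: the subset whose compound reached the phase
    cutoff. Records with an unknown activity type are skipped with a log
    entry. Drug records are always a subset of compound records.
    """
    if potency_cutoff_nM <= 0:
        raise ConfigError("potency cutoff must be positive")
    df = bioactivity.records
    known = df["activity_type"].isin(set(activity_types))
    if (~known).any():
        logger.info("skipped %d record(s) with unknown activity type", int((~known).sum()))
    compounds = df[known & (df["value_nM"] <= potency_cutoff_nM)].reset_index(drop=True)
    drugs = compounds[compounds["max_phase"] >= phase_cutoff].reset_index(drop=True)
    return drugs, compounds


@dataclass
class DrugCountResult:
    """Unique drug/compound counts per class with enrichment tests.

    ``contingency`` compares, between the two classes, drugs against
    non-drug active compounds ([[drugs_a, actives_a - drugs_a], [...b]]);
    a compound targeting both classes appears in both rows. The binomial
    test compares the first class's share of drugs against an expected
    fraction (by default the first class's share of network nodes).
    """

    classes: tuple[str, str]
    drugs: dict[str, frozenset[str]]
    compounds: dict[str, frozenset[str]]
    contingency: tuple | None = None
    chi2: Chi2Result | None = None
    binomial: BinomialResult | None = None

    def drug_count(self, label: str) -> int:
        return len(self.drugs[label])

    def compound_count(self, label: str) -> int:
        return len(self.compounds[label])


def _unique_compounds_by_class(
    records: pd.DataFrame, classification: Classification, classes: Iterable[str]
) -> dict[str, frozenset[str]]:
    out = {}
    for label in classes:
        members = classification.members(label)
        hits = records[records["target_id"].isin(members)]
        out[label] = frozenset(hits["compound_id"])
    return out


def count_by_class(
    drug_records: pd.DataFrame,
    compound_records: pd.DataFrame,
    classification: Classification,
    network=None,
    classes: tuple[str, str] = ("first_neighbour", "cancer_related"),
    expected_fraction: float | None = None,
) -> DrugCountResult:
    """Count unique drugs/compounds per class and test for enrichment.

    A compound contributes to a class iff at least one of its filtered
    targets is in that class; a compound with targets in both classes is
    counted in both (the classes' drug pools genuinely overlap). The chi2
    test compares the drug : non-drug-active ratio between the two
    classes; the binomial test compares the first class's drug count to
    ``expected_fraction`` (default: first class's share of network nodes
    when a network is given).
    """
    drugs = _unique_compounds_by_class(drug_records, classification, classes)
    compounds = _unique_compounds_by_class(compound_records, classification, classes)
    a, b = classes
    result = DrugCountResult(classes, drugs, compounds)
    table = [
        [len(drugs[a]), len(compounds[a]) - len(drugs[a])],
        [len(drugs[b]), len(compounds[b]) - len(drugs[b])],
    ]
    if all(sum(row) > 0 for row in table) and sum(col[0] + col[1] for col in zip(*table)) > 0:
        try:
            result.contingency = tuple(map(tuple, table))
            result.chi2 = chi2_independence(table)
        except ValueError:
            logger.warning("chi-squared test degenerate for table %s", table)
    total_drugs = len(drugs[a] | drugs[b])
    if expected_fraction is None and network is not None:
        n_nodes = network.n_nodes() if hasattr(network, "n_nodes") else len(network.nodes)
        expected_fraction = len(classification.members(a)) / n_nodes if n_nodes else None
    if expected_fraction is not None and total_drugs > 0:
        result.binomial = binomial_test(
            len(drugs[a]), total_drugs, expected_fraction, alternative="greater"
        )
    return result


# ---------------------------------------------------------------------------
# multi-cancer overlap (Venn partition)
# ---------------------------------------------------------------------------

def multi_cancer_overlap(per_cancer: Mapping[str, Iterable[str]]) -> dict[frozenset, int]:
    """Exact Venn partition counts over the cancer types.

    Returns, for every non-empty subset S of cancer types, the number of
    items present in exactly the cancers of S. Counts sum to the size of
    the union and are independent of mapping order.
    """
    if not per_cancer:
        raise DataError("no cancer types given")
    sets = {c: set(v) for c, v in per_cancer.items()}
    universe = set().union(*sets.values())
    partition: dict[frozenset, int] = {}
    for item in universe:
        region = frozenset(c for c, s in sets.items() if item in s)
        partition[region] = partition.get(region, 0) + 1
    return partition


def overlap_frame(partition: Mapping[frozenset, int]) -> pd.DataFrame:
    rows = [
        {"cancers": "+".join(sorted(region)), "n_cancers": len(region), "count": count}
        for region, count in partition.items()
    ]
    rows.sort(key=lambda r: (-r["n_cancers"], r["cancers"]))
    return pd.DataFrame(rows)
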