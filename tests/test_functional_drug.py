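"""GO added-reach computation, drug filters, per-class counts, Venn overlap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from neighbornet.classify import classify
from neighbornet.errors import DataError
from neighbornet.functional_drug import (
    added_bp_binomial_test,
    added_bps,
    count_by_class,
    filter_drugs,
    multi_cancer_overlap,
)
from neighbornet.io import BioactivityTable
from .conftest import tissue_from_edges
from .oracles import venn_partition_oracle


def _classification(edges, mutated, de=frozenset()):
    tn = tissue_from_edges(edges)
    return tn, classify(tn, mutated=set(mutated), de=set(de))


class TestAddedBPs:
    def test_first_neighbours_keep_only_new_terms(self):
        tn, c = _classification([("A", "B"), ("B", "C")], mutated={"A"})
        ann = {"A": {"b1", "b2"}, "B": {"b2", "b3"}}
        res = added_bps(ann, c)
        assert res.bp_cr == {"b1", "b2"}
        assert res.bp_added == {"b3"}
        assert res.k == 1 and res.n == 3

    def test_fn_terms_subset_of_cr_adds_nothing(self):
        tn, c = _classification([("A", "B")], mutated={"A"})
        res = added_bps({"A": {"b1", "b2"}, "B": {"b1"}}, c)
        assert res.k == 0

    def test_disjoint_pools_add_everything_used(self):
        # generator-style overlap control: FN pool disjoint from CR pool
        tn, c = _classification([("A", "B"), ("A", "C")], mutated={"A"})
        ann = {"A": {"cr1", "cr2"}, "B": {"fn1"}, "C": {"fn2", "fn3"}}
        res = added_bps(ann, c)
        assert res.bp_added == {"fn1", "fn2", "fn3"}

    def test_disjointness_always_holds(self):
        tn, c = _classification([("A", "B")], mutated={"A"})
        res = added_bps({"A": {"x"}, "B": {"x", "y"}}, c)
        assert not res.bp_cr & res.bp_added

    def test_ancestor_propagation_option(self):
        # b3 is-a b2 is-a b1: propagation pulls b2's ancestors into BP_cr
        tn, c = _classification([("A", "B")], mutated={"A"})
        ann = {"A": {"b2"}, "B": {"b3"}}
        ontology = {"b3": {"b2"}, "b2": {"b1"}}
        plain = added_bps(ann, c)
        assert plain.bp_added == {"b3"}
        propagated = added_bps(ann, c, ontology=ontology)
        assert propagated.bp_cr == {"b1", "b2"}
        assert propagated.bp_added == {"b3"}  # ancestors of b3 already claimed

    def test_uncovered_classification_rejected(self):
        tn, c = _classification([("A", "B")], mutated={"A"})
        with pytest.raises(DataError):
            added_bps({"ELSEWHERE": {"b"}}, c)

    def test_binomial_test_uses_fn_network_share(self):
        # 4-node path: CR={A}, FN={B}, UA={C,D}; p_expected = 1/4
        tn, c = _classification([("A", "B"), ("B", "C"), ("C", "D")], mutated={"A"})
        ann = {"A": {"b1"}, "B": {"b2", "b3"}}
        res = added_bps(ann, c)
        test = added_bp_binomial_test(res, c, tn)
        assert test.p_expected == pytest.approx(0.25)
        assert test.k == 2 and test.n == 3
        # one-sided exact: P(X >= 2), X ~ Bin(3, 1/4) = 10/64
        assert test.p_value == pytest.approx(10 / 64, abs=1e-12)


FIXTURE_ROWS = [
    # 20 hand-enumerated records: (compound, target, type, nM, phase)
    ("d01", "T1", "IC50", 400.0, 4),   # drug + compound
    ("d01", "T2", "Ki", 100.0, 4),     # same drug, second target
    ("d02", "T1", "Ki", 500.0, 4),     # boundary potency: kept
    ("d03", "T3", "Kd", 499.9, 4),     # drug + compound
    ("d04", "T4", "IC50", 501.0, 4),   # fails potency
    ("d05", "T5", "IC50", 600.0, 4),   # fails potency
    ("c06", "T1", "IC50", 400.0, 3),   # compound only (phase 3)
    ("c07", "T2", "Ki", 50.0, 2),      # compound only
    ("c08", "T3", "Kd", 450.0, 1),     # compound only
    ("c09", "T4", "IC50", 2000.0, 3),  # fails potency
    ("c10", "T5", "EC50", 10.0, 4),    # unknown activity type: skipped
    ("c11", "T1", "EC50", 10.0, 2),    # unknown activity type: skipped
    ("d12", "T6", "IC50", 30.0, 4),    # drug + compound
    ("c13", "T6", "Ki", 470.0, 0),     # compound only (preclinical)
    ("d14", "T7", "Kd", 90.0, 4),      # drug + compound
    ("c15", "T7", "IC50", 800.0, 3),   # fails potency
    ("c16", "T8", "Ki", 320.0, 3),     # compound only
    ("d17", "T8", "IC50", 10.0, 4),    # drug + compound
    ("c18", "T9", "Kd", 444.0, 2),     # compound only
    ("d19", "T9", "IC50", 5000.0, 4),  # fails potency
]


def fixture_table() -> BioactivityTable:
    return BioactivityTable(pd.DataFrame(
        FIXTURE_ROWS,
        columns=["compound_id", "target_id", "activity_type", "value_nM", "max_phase"],
    ))


class TestFilterDrugs:
    def test_hand_enumerated_fixture(self):
        drugs, compounds = filter_drugs(fixture_table())
        # hand enumeration: potency <= 500 with known type
        expected_compounds = {"d01", "d02", "d03", "c06", "c07", "c08",
                              "d12", "c13", "d14", "c16", "d17", "c18"}
        expected_drugs = {"d01", "d02", "d03", "d12", "d14", "d17"}
        assert set(compounds["compound_id"]) == expected_compounds
        assert set(drugs["compound_id"]) == expected_drugs

    def test_drugs_are_subset_of_compounds(self):
        drugs, compounds = filter_drugs(fixture_table())
        drug_rows = set(map(tuple, drugs[["compound_id", "target_id"]].itertuples(index=False)))
        compound_rows = set(map(tuple, compounds[["compound_id", "target_id"]].itertuples(index=False)))
        assert drug_rows <= compound_rows

    @pytest.mark.parametrize(
        "record,is_drug,is_compound",
        [
            (("c1", "t1", "IC50", 400.0, 4), True, True),
            (("c2", "t1", "IC50", 600.0, 4), False, False),
            (("c3", "t1", "Ki", 400.0, 3), False, True),
        ],
    )
    def test_single_record_contracts(self, record, is_drug, is_compound):
        table = BioactivityTable(pd.DataFrame(
            [record],
            columns=["compound_id", "target_id", "activity_type", "value_nM", "max_phase"],
        ))
        drugs, compounds = filter_drugs(table)
        assert (len(drugs) == 1) == is_drug
        assert (len(compounds) == 1) == is_compound


class TestCountByClass:
    def _setup(self):
        # star: A mutated CR; T1,T2 its FN; T3 unaffected
        edges = [("A", "T1"), ("A", "T2"), ("T2", "T3")]
        return _classification(edges, mutated={"A"})

    def test_one_drug_two_fn_targets_counts_once(self):
        tn, c = self._setup()
        records = pd.DataFrame(
            [("d1", "T1", "IC50", 10.0, 4), ("d1", "T2", "IC50", 20.0, 4)],
            columns=["compound_id", "target_id", "activity_type", "value_nM", "max_phase"],
        )
        res = count_by_class(records, records, c)
        assert res.drug_count("first_neighbour") == 1

    def test_compound_bridging_classes_counts_in_both(self):
        tn, c = self._setup()
        records = pd.DataFrame(
            [("d1", "A", "IC50", 10.0, 4), ("d1", "T1", "IC50", 20.0, 4)],
            columns=["compound_id", "target_id", "activity_type", "value_nM", "max_phase"],
        )
        res = count_by_class(records, records, c)
        assert res.drug_count("first_neighbour") == 1
        assert res.drug_count("cancer_related") == 1

    def test_binomial_against_network_share(self):
        tn, c = self._setup()
        records = pd.DataFrame(
            [("d1", "T1", "IC50", 10.0, 4), ("d2", "A", "Ki", 5.0, 4)],
            columns=["compound_id", "target_id", "activity_type", "value_nM", "max_phase"],
        )
        res = count_by_class(records, records, c, network=tn)
        assert res.binomial is not None
        assert res.binomial.p_expected == pytest.approx(2 / 4)  # |FN|/|V|


class TestMultiCancerOverlap:
    def test_identical_sets_concentrate_in_full_intersection(self):
        sets = {c: {"x", "y"} for c in ("colon", "breast", "liver", "lung")}
        partition = multi_cancer_overlap(sets)
        assert partition == {frozenset(sets): 2}

    def test_disjoint_sets_stay_in_singletons(self):
        sets = {"colon": {"a"}, "breast": {"b"}, "liver": {"c"}}
        partition = multi_cancer_overlap(sets)
        assert partition == {
            frozenset({"colon"}): 1, frozenset({"breast"}): 1, frozenset({"liver"}): 1,
        }

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_subset_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        universe = [f"i{k}" for k in range(30)]
        sets = {
            c: {x for x in universe if rng.random() < 0.4}
            for c in ("colon", "breast", "liver", "lung")
        }
        sets = {c: s for c, s in sets.items() if s} or {"colon": {"i0"}}
        assert multi_cancer_overlap(sets) == venn_partition_oracle(sets)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.dictionaries(
            st.sampled_from(["c1", "c2", "c3"]),
            st.sets(st.integers(0, 15)),
            min_size=1,
        )
    )
    def test_sum_consistency(self, sets):
        partition = multi_cancer_overlap(sets)
        assert sum(partition.values()) == len(set().union(*sets.values()))
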