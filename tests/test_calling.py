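"""Candidate-interactor classification: filters, rules and their algebra."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from baitcall.calling import (
    CallingParams,
    ControlRule,
    call_candidates,
    control_detected,
    filter_quality,
    presence_matrix,
    replicate_consistent,
    strip_decoys_contaminants,
)
from baitcall.io import ProteinGroupTable
from conftest import make_design, make_record, table_from_presence
from oracles import brute_force_candidates


class TestFilters:
    def test_quality_filter_is_strict(self):
        table = ProteinGroupTable(
            records=[
                make_record("A", {"S": 1.0}, q=0.001),
                make_record("B", {"S": 1.0}, q=0.01),  # exactly on the boundary
                make_record("C", {"S": 1.0}, q=0.5),
            ],
            sample_ids=["S"],
        )
        kept = filter_quality(table, 0.01)
        assert kept.ids() == ["A"]
        assert filter_quality(table, 1.0).ids() == ["A", "B", "C"]

    def test_all_records_above_threshold_yields_empty_table(self):
        table = ProteinGroupTable(
            records=[make_record(g, {"S": 1.0}, q=0.5) for g in "ABC"],
            sample_ids=["S"],
        )
        assert len(filter_quality(table, 0.01)) == 0

    def test_quality_filter_rejects_bad_threshold(self):
        table = ProteinGroupTable(records=[], sample_ids=["S"])
        with pytest.raises(ValueError):
            filter_quality(table, 0.0)

    def test_decoys_and_contaminants_stripped(self):
        table = ProteinGroupTable(
            records=[
                make_record("ok", {"S": 1.0}),
                make_record("rev", {"S": 1.0}, reverse=True),
                make_record("con", {"S": 1.0}, contaminant=True),
            ],
            sample_ids=["S"],
        )
        assert strip_decoys_contaminants(table).ids() == ["ok"]


class TestPresenceAndRules:
    def test_presence_matrix_matches_hand_truth_table(self, one_condition_design):
        design = one_condition_design
        table = ProteinGroupTable(
            records=[
                make_record("X", {s: 0.0 for s in design.sample_ids} | {"A_bait_1": 1e7}),
                make_record("Y", {s: 5.0 for s in design.sample_ids}),
            ],
            sample_ids=design.sample_ids,
        )
        matrix = presence_matrix(table, design)
        assert matrix.present("X", "A_bait_1") is True
        assert matrix.present("X", "A_bait_2") is False
        assert all(matrix.present("Y", s) for s in design.sample_ids)

    def test_design_sample_missing_from_table_is_named(self, one_condition_design):
        table = ProteinGroupTable(
            records=[make_record("X", {"other": 1.0})], sample_ids=["other"]
        )
        with pytest.raises(KeyError, match="A_bait_1"):
            presence_matrix(table, one_condition_design)

    def test_control_rules(self, one_condition_design):
        design = one_condition_design
        presence = {
            "in_one_ctrl": {"A_ctrl_1": True},
            "in_all_ctrl": {"A_ctrl_1": True, "A_ctrl_2": True, "A_ctrl_3": True},
            "never_in_ctrl": {"A_bait_1": True},
        }
        matrix = presence_matrix(table_from_presence(presence, design), design)
        any_hits = control_detected(matrix, design, "A", ControlRule.ANY_CONTROL_REPLICATE)
        assert any_hits == {"in_one_ctrl", "in_all_ctrl"}
        all_hits = control_detected(matrix, design, "A", ControlRule.ALL_CONTROL_REPLICATES)
        assert all_hits == {"in_all_ctrl"}

    def test_condition_without_controls_is_an_error(self):
        design = make_design(["A"], n_ctrl=0)
        table = table_from_presence({"X": {"A_bait_1": True}}, design)
        matrix = presence_matrix(table, design)
        with pytest.raises(ValueError, match="control"):
            control_detected(matrix, design, "A")

    def test_replicate_rules(self, one_condition_design):
        design = one_condition_design
        presence = {
            "three_of_three": {f"A_bait_{r}": True for r in (1, 2, 3)},
            "two_of_three": {f"A_bait_{r}": True for r in (1, 3)},
        }
        matrix = presence_matrix(table_from_presence(presence, design), design)
        assert replicate_consistent(matrix, design, "A", "all") == {"three_of_three"}
        assert replicate_consistent(matrix, design, "A", 2) == {
            "three_of_three",
            "two_of_three",
        }
        with pytest.raises(ValueError, match="exceeds"):
            replicate_consistent(matrix, design, "A", 4)


class TestCallCandidates:
    def test_hand_traced_toy_example(self, one_condition_design):
        design = one_condition_design
        baits = {f"A_bait_{r}": True for r in (1, 2, 3)}
        presence = {
            "bait": dict(baits),
            "interactor": dict(baits),
            "sticky": dict(baits) | {"A_ctrl_1": True, "A_ctrl_2": True},
            "dropout": {f"A_bait_{r}": True for r in (1, 2)},
        }
        table = table_from_presence(presence, design)
        candidates = call_candidates(table, design)
        assert candidates["A"] == {"bait", "interactor"}

    def test_everything_in_controls_gives_empty_set(self, one_condition_design):
        design = one_condition_design
        presence = {
            g: {s: True for s in design.sample_ids} for g in ("p1", "p2", "p3")
        }
        table = table_from_presence(presence, design)
        assert call_candidates(table, design)["A"] == frozenset()

    def test_flagged_rows_removed_before_binarization(self, one_condition_design):
        # the decoy is everywhere, including controls, but is stripped before
        # binarization: it is never called and never enters the subtraction
        design = one_condition_design
        records = [
            make_record("real", {s: 1.0 if "bait" in s else 0.0 for s in design.sample_ids}),
            make_record(
                "decoy",
                {s: 1.0 for s in design.sample_ids},
                reverse=True,
            ),
        ]
        table = ProteinGroupTable(records=records, sample_ids=design.sample_ids)
        assert call_candidates(table, design)["A"] == {"real"}


def random_instance(rng, n_proteins, conditions=("A", "B"), n_reps=3):
    design = make_design(list(conditions), n_bait=n_reps, n_ctrl=n_reps)
    records = []
    for i in range(n_proteins):
        intensities = {
            s: float(rng.integers(0, 3)) * 10.0 ** rng.integers(4, 8)
            for s in design.sample_ids
        }
        records.append(
            make_record(
                f"P{i}",
                intensities,
                q=float(rng.choice([0.001, 0.009, 0.01, 0.2])),
                reverse=bool(rng.random() < 0.15),
                contaminant=bool(rng.random() < 0.15),
            )
        )
    return ProteinGroupTable(records=records, sample_ids=design.sample_ids), design


class TestAgainstBruteForce:
    @pytest.mark.parametrize("min_reps,control_rule", [
        ("all", ControlRule.ANY_CONTROL_REPLICATE),
        (2, ControlRule.ANY_CONTROL_REPLICATE),
        ("all", ControlRule.ALL_CONTROL_REPLICATES),
    ])
    def test_matches_direct_evaluator_on_small_instances(self, min_reps, control_rule):
        rng = np.random.default_rng(20220)
        for _ in range(60):
            table, design = random_instance(rng, int(rng.integers(1, 13)))
            params = CallingParams(
                min_bait_replicates=min_reps, control_rule=control_rule
            )
            got = call_candidates(table, design, params)
            want = brute_force_candidates(
                table,
                design,
                min_reps=min_reps,
                control_any=control_rule is ControlRule.ANY_CONTROL_REPLICATE,
            )
            assert {c: set(s) for c, s in got.sets.items()} == want


class TestInvariants:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_monotonicity_in_q_and_replicate_rule(self, seed):
        rng = np.random.default_rng(seed)
        table, design = random_instance(rng, int(rng.integers(1, 13)))
        strict = call_candidates(table, design, CallingParams(q_max=0.005))
        loose = call_candidates(table, design, CallingParams(q_max=0.05))
        for condition in design.conditions:
            # lowering q_max never enlarges a candidate set
            assert strict[condition] <= loose[condition]
        all_rule = call_candidates(table, design, CallingParams(min_bait_replicates="all"))
        k_rule = call_candidates(table, design, CallingParams(min_bait_replicates=2))
        for condition in design.conditions:
            assert all_rule[condition] <= k_rule[condition]

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_candidates_disjoint_from_control_detections(self, seed):
        rng = np.random.default_rng(seed)
        table, design = random_instance(rng, int(rng.integers(1, 13)))
        params = CallingParams()
        candidates = call_candidates(table, design, params)
        filtered = strip_decoys_contaminants(filter_quality(table, params.q_max))
        matrix = presence_matrix(filtered, design)
        for condition in design.conditions:
            detected = control_detected(matrix, design, condition, params.control_rule)
            assert not candidates[condition] & detected

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        table, design = random_instance(rng, 10)
        baseline = call_candidates(table, design)
        shuffled_records = list(table.records)
        rng.shuffle(shuffled_records)
        shuffled_samples = list(table.sample_ids)
        rng.shuffle(shuffled_samples)
        shuffled = ProteinGroupTable(
            records=shuffled_records, sample_ids=shuffled_samples
        )
        assert call_candidates(shuffled, design).sets == baseline.sets
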