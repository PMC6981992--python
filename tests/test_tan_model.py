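"""Structure learning, CPT estimation, the joint, re-rooting, serialization."""
from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from accident_bn.catalog_io import CaseMatrix
from accident_bn.synthetic_data import GeneratorConfig, build_ground_truth, sample_cases
from accident_bn.tan_model import (
    CLASS_NODE,
    SmoothingPolicy,
    TanModel,
    conditional_mutual_information,
    estimate_cpts,
    fit_tan,
    joint_probability,
    learn_tan_structure,
    reroot,
)

from conftest import random_model


def make_matrix(columns: dict[str, list[int]], types: list[str]) -> CaseMatrix:
    index = pd.Index([f"A{i}" for i in range(len(types))], name="case_id")
    data = pd.DataFrame({c: [bool(v) for v in vals] for c, vals in columns.items()}, index=index)
    return CaseMatrix(data, pd.Series(types, index=index))


def cmi_oracle(matrix: CaseMatrix, i: str, j: str, alpha: float) -> float:
    """Plain-loop summation over the full class x 2 x 2 contingency table."""
    classes = sorted(set(matrix.accident_types))
    n = matrix.n_cases
    cells = {}
    for y in classes:
        for a in (0, 1):
            for b in (0, 1):
                mask = (
                    (matrix.accident_types == y)
                    & (matrix.data[i] == bool(a))
                    & (matrix.data[j] == bool(b))
                )
                cells[(y, a, b)] = int(mask.sum()) + alpha
    total = n + alpha * len(cells)
    value = 0.0
    for y in classes:
        p_y = sum(cells[(y, a, b)] for a in (0, 1) for b in (0, 1)) / total
        for a in (0, 1):
            for b in (0, 1):
                p = cells[(y, a, b)] / total
                if p == 0:
                    continue
                p_ay = sum(cells[(y, a, bb)] for bb in (0, 1)) / total
                p_by = sum(cells[(y, aa, b)] for aa in (0, 1)) / total
                value += p * math.log(p * p_y / (p_ay * p_by))
    return value


def all_assignments(model: TanModel):
    for y in model.class_states:
        for states in itertools.product((0, 1), repeat=len(model.features)):
            yield {CLASS_NODE: y, **dict(zip(model.features, states))}


class TestConditionalMutualInformation:
    def test_countwise_independence_is_zero_unsmoothed(self):
        # within each class the 2x2 table is [[25,25],[25,25]]
        cols = {"B1": [], "B2": []}
        types = []
        for t in "SCFL":
            for a, b in itertools.product((0, 1), repeat=2):
                cols["B1"] += [a] * 25
                cols["B2"] += [b] * 25
                types += [t] * 25
        matrix = make_matrix(cols, types)
        value = conditional_mutual_information(matrix, "B1", "B2", SmoothingPolicy(0.0))
        assert value == pytest.approx(0.0, abs=1e-12)

    def test_perfect_copy_gives_ln2(self):
        # balanced within each class and B2 == B1 deterministically
        cols = {"B1": [], "B2": []}
        types = []
        for t in "SCFL":
            cols["B1"] += [0] * 10 + [1] * 10
            cols["B2"] += [0] * 10 + [1] * 10
            types += [t] * 20
        matrix = make_matrix(cols, types)
        value = conditional_mutual_information(matrix, "B1", "B2", SmoothingPolicy(0.0))
        assert value == pytest.approx(math.log(2), abs=1e-12)

    @pytest.mark.parametrize("alpha", [0.0, 0.5, 1.0])
    def test_matches_plain_loop_oracle(self, alpha):
        rng = np.random.default_rng(11)
        cols = {
            "B1": rng.integers(0, 2, 120).tolist(),
            "B2": rng.integers(0, 2, 120).tolist(),
        }
        # correlate: copy B1 into B2 on a third of the rows
        cols["B2"][::3] = cols["B1"][::3]
        types = rng.choice(list("SCFL"), 120).tolist()
        matrix = make_matrix(cols, types)
        ours = conditional_mutual_information(matrix, "B1", "B2", SmoothingPolicy(alpha))
        assert ours == pytest.approx(cmi_oracle(matrix, "B1", "B2", alpha), abs=1e-12)

    @given(seed=st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_symmetric_in_its_arguments(self, seed):
        rng = np.random.default_rng(seed)
        cols = {
            "B1": rng.integers(0, 2, 60).tolist(),
            "B2": rng.integers(0, 2, 60).tolist(),
        }
        types = rng.choice(list("SCFL"), 60).tolist()
        matrix = make_matrix(cols, types)
        ij = conditional_mutual_information(matrix, "B1", "B2")
        ji = conditional_mutual_information(matrix, "B2", "B1")
        assert ij == pytest.approx(ji, abs=1e-12)
        assert ij >= 0

    def test_rejects_identical_arguments_and_empty_matrix(self):
        matrix = make_matrix({"B1": [1, 0], "B2": [0, 1]}, ["F", "S"])
        with pytest.raises(ValueError):
            conditional_mutual_information(matrix, "B1", "B1")
        empty = make_matrix({"B1": [], "B2": []}, [])
        with pytest.raises(ValueError):
            conditional_mutual_information(empty, "B1", "B2")


class TestStructureLearning:
    def test_three_behavior_tree_follows_pairwise_ordering(self):
        # B2 = B1 with one flip, B3 = B1 with two flips (different rows),
        # so CMI(1,2) > CMI(1,3) > CMI(2,3): Kruskal keeps edges 1-2 and 1-3.
        b1 = [0, 0, 0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1, 1, 1]
        b2 = list(b1)
        b2[0] ^= 1
        b3 = list(b1)
        b3[1] ^= 1
        b3[8] ^= 1
        matrix = make_matrix({"B1": b1, "B2": b2, "B3": b3}, ["F"] * 16)
        smoothing = SmoothingPolicy(0.5)
        c12 = conditional_mutual_information(matrix, "B1", "B2", smoothing)
        c13 = conditional_mutual_information(matrix, "B1", "B3", smoothing)
        c23 = conditional_mutual_information(matrix, "B2", "B3", smoothing)
        assert c12 > c13 > c23
        structure = learn_tan_structure(matrix, smoothing)
        assert set(structure.edge_weights) == {("B1", "B2"), ("B1", "B3")}
        assert structure.root == "B1"

    def test_two_behaviors_give_the_single_edge(self):
        matrix = make_matrix({"B1": [0, 1, 0, 1], "B2": [0, 0, 1, 1]}, ["F", "F", "S", "S"])
        structure = learn_tan_structure(matrix)
        assert set(structure.edge_weights) == {("B1", "B2")}

    def test_spanning_tree_has_m_minus_1_edges(self):
        truth = build_ground_truth(GeneratorConfig(seed=5, n_behaviors=9, planted=()))
        matrix = sample_cases(truth, 400, seed=6)
        structure = learn_tan_structure(matrix)
        assert len(structure.edge_weights) == len(structure.features) - 1
        roots = [f for f, p in structure.parents.items() if p is None]
        assert roots == [structure.root]

    def test_all_zero_cmi_still_yields_tree_deterministically(self):
        # constant columns: every pairwise CMI is 0; ties break by code order
        matrix = make_matrix(
            {"B1": [0] * 8, "B2": [0] * 8, "B3": [0] * 8}, ["F"] * 4 + ["S"] * 4
        )
        s1 = learn_tan_structure(matrix, SmoothingPolicy(0.0))
        s2 = learn_tan_structure(matrix, SmoothingPolicy(0.0))
        assert s1.parents == s2.parents
        assert len(s1.edge_weights) == 2

    def test_missing_class_dropped_with_warning(self):
        matrix = make_matrix({"B1": [0, 1, 1], "B2": [1, 0, 1]}, ["F", "F", "S"])
        with pytest.warns(UserWarning, match="C, L"):
            structure = learn_tan_structure(matrix)
        assert structure.class_states == ("S", "F")


class TestCptEstimation:
    def test_smoothed_class_prior_from_published_counts(self):
        types = ["F"] * 191 + ["C"] * 39 + ["S"] * 33 + ["L"] * 24
        rng = np.random.default_rng(0)
        matrix = make_matrix(
            {"B1": rng.integers(0, 2, 287).tolist(), "B2": rng.integers(0, 2, 287).tolist()},
            types,
        )
        model = fit_tan(matrix, SmoothingPolicy(0.5))
        prior = dict(zip(model.class_states, model.class_prior))
        assert prior["F"] == pytest.approx(0.6626, abs=5e-5)
        assert prior["C"] == pytest.approx(0.1367, abs=5e-5)
        assert prior["S"] == pytest.approx(0.1159, abs=5e-5)
        assert prior["L"] == pytest.approx(0.0848, abs=5e-5)

    def test_unsmoothed_zero_count_gives_zero_cell(self):
        matrix = make_matrix({"B1": [0, 1, 0, 1], "B2": [0, 0, 0, 0]}, ["F", "F", "S", "S"])
        model = fit_tan(matrix, SmoothingPolicy(0.0))
        # B2 never occurs: its Yes cells are exactly 0
        assert np.all(model.cpts["B2"].table[1] == 0)

    @pytest.mark.parametrize("alpha", [0.25, 0.5, 1.0])
    def test_smoothed_cells_strictly_inside_unit_interval(self, alpha):
        truth = build_ground_truth(GeneratorConfig(seed=2, n_behaviors=6, planted=()))
        matrix = sample_cases(truth, 150, seed=3)
        model = fit_tan(matrix, SmoothingPolicy(alpha))
        for cpt in model.cpts.values():
            assert np.all(cpt.table > 0) and np.all(cpt.table < 1)


class TestJoint:
    def test_joint_sums_to_one_on_six_feature_model(self):
        model = random_model(np.random.default_rng(4), 6)
        total = sum(joint_probability(model, a) for a in all_assignments(model))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_hand_built_two_feature_product(self):
        model = random_model(np.random.default_rng(9), 2)
        asg = {CLASS_NODE: "F", "B1": 1, "B2": 0}
        k = model.class_index("F")
        expected = (
            model.class_prior[k]
            * model.cpts["B1"].table[1, k]
            * model.cpts["B2"].table[0, k, 1]
        )
        assert joint_probability(model, asg) == pytest.approx(expected, rel=1e-12)

    def test_missing_variable_is_an_error(self):
        model = random_model(np.random.default_rng(9), 2)
        with pytest.raises(KeyError, match="B2"):
            joint_probability(model, {CLASS_NODE: "F", "B1": 1})

    def test_orientation_root_does_not_change_unsmoothed_joint(self):
        truth = build_ground_truth(GeneratorConfig(seed=12, n_behaviors=5, planted=()))
        matrix = sample_cases(truth, 300, seed=13)
        m_a = fit_tan(matrix, SmoothingPolicy(0.0), orientation_root="B1")
        m_b = fit_tan(matrix, SmoothingPolicy(0.0), orientation_root="B4")
        for asg in all_assignments(m_a):
            assert joint_probability(m_a, asg) == pytest.approx(
                joint_probability(m_b, asg), abs=1e-12
            )


class TestReroot:
    @pytest.fixture
    def model(self):
        truth = build_ground_truth(
            GeneratorConfig(seed=21, n_behaviors=5, planted=(("B3", "F", 0.3),))
        )
        matrix = sample_cases(truth, 500, seed=22)
        return fit_tan(matrix, SmoothingPolicy(0.5))

    def test_joint_unchanged_under_rerooting(self, model):
        for new_root in model.features:
            view = reroot(model, new_root)
            for asg in all_assignments(model):
                assert joint_probability(view.model, asg) == pytest.approx(
                    joint_probability(model, asg), abs=1e-9
                )

    def test_conditional_rows_normalized(self, model):
        view = reroot(model, "B3")
        sums = view.class_given_root.sum(axis=1)
        assert sums["Yes"] == pytest.approx(1.0, abs=1e-9)
        assert sums["No"] == pytest.approx(1.0, abs=1e-9)

    def test_reroot_at_current_root_is_identity(self, model):
        view = reroot(model, model.structure.root)
        assert view.model.structure.parents == model.structure.parents
        for node, cpt in model.cpts.items():
            np.testing.assert_allclose(view.model.cpts[node].table, cpt.table, atol=1e-12)

    def test_unknown_root_raises(self, model):
        with pytest.raises(KeyError, match="B99"):
            reroot(model, "B99")


class TestSerialization:
    def test_json_round_trip_is_exact(self, tmp_path):
        truth = build_ground_truth(
            GeneratorConfig(seed=31, n_behaviors=6, planted=(("B3", "F", 0.3),))
        )
        matrix = sample_cases(truth, 200, seed=32)
        model = fit_tan(matrix)
        path = tmp_path / "model.json"
        model.save(path)
        back = TanModel.load(path)
        assert back.structure.parents == model.structure.parents
        assert back.structure.class_states == model.class_states
        assert back.smoothing == model.smoothing
        for node in model.cpts:
            np.testing.assert_array_equal(back.cpts[node].table, model.cpts[node].table)
        # emitted decimal strings are stable
        assert back.to_json() == model.to_json()


class TestParameterRecovery:
    def test_cells_converge_to_truth(self):
        """Cell-wise error shrinks with n and is below 0.02 at n=20,000."""
        # few cells and balanced states so every CPT cell sees thousands of
        # samples at the larger n (per-cell standard error ~0.007)
        truth = build_ground_truth(
            GeneratorConfig(
                seed=41,
                n_behaviors=3,
                class_probs={"S": 0.5, "F": 0.5},
                base_rate=0.5,
                parent_coupling=0.2,
                planted=(),
            )
        )
        errors = {}
        for n in (2_000, 20_000):
            matrix = sample_cases(truth, n, seed=42)
            fitted = estimate_cpts(matrix, truth.model.structure, SmoothingPolicy(0.5))
            errors[n] = max(
                float(np.max(np.abs(fitted.cpts[node].table - truth.model.cpts[node].table)))
                for node in truth.model.cpts
            )
        assert errors[20_000] < 0.02
        assert errors[20_000] < errors[2_000]
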