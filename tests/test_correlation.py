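import numpy as np
import pytest
import sympy as sp

from linident import (
    ExperimentCondition,
    build_model,
    builtin_example,
    coefficient_system,
    minimal_datasets,
    nullspace_basis,
    random_model,
    required_datasets,
    sensitivity_columns,
    stacked_rank_check,
)
from linident.correlation import analyze_condition, numeric_rank

x10, x20, x30, u10 = sp.symbols("x10 x20 x30 u10")


def _analysis(model, cond, **kw):
    return analyze_condition(model, cond, **kw)


class TestCoefficientSystem:
    def test_chain_model_reduces_to_four_equations(self, ex2):
        """With generic x0 and input, the system is rank 3 on 3 unknowns
        (the published four equations contain one dependency)."""
        model, _, _ = ex2
        cond = ExperimentCondition((x10, x20, x30), (u10,))
        cols = sensitivity_columns(model, cond, input_mode="generic")
        system = coefficient_system(cols)
        assert system.n_p == 3
        rng = np.random.default_rng(0)
        B = system.evaluate(system.random_assignment(rng))
        assert numeric_rank(B) == 3  # alpha = 0 forced

    def test_single_column_one_state(self):
        m = build_model({"states": ["x"], "outputs": ["y"], "A": [["-p"]], "C": [["1"]]})
        cols = sensitivity_columns(m, ExperimentCondition((x10,), ()))
        system = coefficient_system(cols)
        assert system.n_p == 1
        assert any(any(c != 0 for c in row) for row in system.rows)

    def test_mammillary_zero_x20_x30_reduces_to_five_equations(self, ex3):
        model, _, _ = ex3
        cond = ExperimentCondition((x10, 0, 0), (u10,))
        cols = sensitivity_columns(model, cond)
        system = coefficient_system(cols)
        rng = np.random.default_rng(1)
        B = system.evaluate(system.random_assignment(rng))
        assert numeric_rank(B) == 5  # 5 independent constraints on 6 unknowns

    def test_rows_contain_no_laplace_variable(self, ex1):
        from linident.model import s

        model, conds, _ = ex1
        cols = sensitivity_columns(model, conds[0].generic(model))
        system = coefficient_system(cols)
        assert all(s not in e.free_symbols for row in system.rows for e in row)


class TestNullspace:
    def test_two_compartment_structural_relation(self, ex1):
        """x10 != 0, x20 = 0: single relation (1, -1, p3/p2, -p3/p2, 0)."""
        model, conds, _ = ex1
        cols = sensitivity_columns(model, conds[0].generic(model))
        basis = nullspace_basis(coefficient_system(cols))
        p2, p3 = sp.symbols("p2 p3")
        assert len(basis) == 1
        expected = (1, -1, p3 / p2, -p3 / p2, 0)
        assert all(sp.cancel(a - b) == 0 for a, b in zip(basis[0].entries, expected))

    def test_mammillary_structural_relation(self, ex3):
        """x20 = x30 = 0: the six-parameter relation with ratio entries."""
        model, conds, _ = ex3
        cols = sensitivity_columns(model, conds[0].generic(model))
        basis = nullspace_basis(coefficient_system(cols))
        p21, p31, p12, p13 = sp.symbols("p21 p31 p12 p13")
        assert len(basis) == 1
        expected = (1, -1, -p12 / p21, p13 / p31, p12 / p21, -p13 / p31)
        assert all(sp.cancel(a - b) == 0 for a, b in zip(basis[0].entries, expected))

    def test_chain_model_with_full_excitation_empty_basis(self, ex2):
        model, _, _ = ex2
        cond = ExperimentCondition((x10, x20, x30), (u10,))
        cols = sensitivity_columns(model, cond, input_mode="generic")
        assert nullspace_basis(coefficient_system(cols)) == []

    def test_normalized_leading_entries(self, ex4):
        model, conds, _ = ex4
        cols = sensitivity_columns(model, conds[0].generic(model))
        basis = nullspace_basis(coefficient_system(cols))
        for v in basis:
            lead = min(v.support)
            assert v.entries[lead] == 1

    def test_rank_nullity_over_random_draws(self, ex1, ex3):
        """rank(beta at random values) + dim(nullspace) = n_p, 20 draws."""
        rng = np.random.default_rng(99)
        for model, conds, _ in (ex1, ex3):
            cols = sensitivity_columns(model, conds[0].generic(model))
            system = coefficient_system(cols)
            k = len(nullspace_basis(system))
            for _ in range(10):
                B = system.evaluate(system.random_assignment(rng))
                assert numeric_rank(B) + k == system.n_p

    def test_basis_annihilates_system_numerically(self, ex1):
        model, conds, _ = ex1
        cols = sensitivity_columns(model, conds[0].generic(model))
        system = coefficient_system(cols)
        (vec,) = nullspace_basis(system)
        rng = np.random.default_rng(3)
        assignment = system.random_assignment(rng)
        B = system.evaluate(assignment)
        v = vec.evaluate(
            {k: v for k, v in assignment.items() if k in vec.free_symbols}
        )
        assert np.abs(B @ v).max() < 1e-10 * max(np.abs(B).max(), 1.0)


class TestClassification:
    def test_structural_case_two_compartment(self, ex1):
        model, conds, _ = ex1
        _, _, rep = _analysis(model, conds[0])
        assert rep.status[sp.Symbol("V")] == "identifiable"
        for name in ("p1", "p2", "p3", "p4"):
            assert rep.status[sp.Symbol(name)] == "structurally-nonidentifiable"

    def test_practical_case_two_compartment(self, ex1):
        model, conds, _ = ex1
        _, _, rep = _analysis(model, conds[2])
        assert rep.group_kinds == ("practical",)
        assert rep.n_max == 4 and rep.equations_per_dataset == 2 and rep.n_d == 2

    def test_case2_p3_identifiable_with_known_volume(self, ex1_rates):
        model, conds, _ = ex1_rates
        _, _, rep = _analysis(model, conds[1])
        assert rep.status[sp.Symbol("p3")] == "identifiable"
        (group,) = rep.groups
        assert group == frozenset(sp.symbols("p1 p2 p4"))
        # relation proportional to (p4-p1-p2, p1+p2-p3-p4, 0, p3)
        (vec,) = rep.basis
        p1, p2, p3, p4 = sp.symbols("p1 p2 p3 p4")
        ref = (p4 - p1 - p2, p1 + p2 - p3 - p4, sp.Integer(0), p3)
        ratios = {
            sp.cancel(e / r) for e, r in zip(vec.entries, ref) if r != 0
        }
        assert len(ratios) == 1

    def test_insulin_receptor_outputs(self):
        expected = {
            "y1": {"p21p", "p51", "p12", "p32"},
            "y2": {"p21p", "p51", "p12", "p32"},  # same relation as y1
            "y3": set(),
        }
        for out, nonident in expected.items():
            model, conds, _ = builtin_example(5, outputs=(out,))
            _, _, rep = _analysis(model, conds[0])
            assert {str(p) for p in rep.nonidentifiable} == nonident

    def test_full_observation_identifies_everything(self, ex1, ex4):
        """Replacing C with the identity empties the nullspace."""
        for model, conds, _ in (ex1, ex4):
            spec = model.to_dict()
            n = model.n_x
            spec["outputs"] = [f"y{i+1}" for i in range(n)]
            spec["C"] = [["1" if i == j else "0" for j in range(n)] for i in range(n)]
            spec["D"] = [["0"] * model.n_u for _ in range(n)]
            # direct observation replaces any scaled output, so parameters
            # that only lived in C (the volume V) leave the model
            spec.pop("params", None)
            full = build_model(spec)
            _, _, rep = _analysis(full, conds[0])
            assert rep.groups == ()

    def test_monotonicity_of_information(self, ex1):
        """The stacked two-condition system constrains at least as much as
        either single condition: its numeric nullspace is contained in
        each single-condition nullspace."""
        model, conds, _ = ex1
        rank1, full1 = stacked_rank_check(
            model, [conds[2]], sp.symbols("p1 p2 p3 p4"), seed=1
        )
        rank2, full2 = stacked_rank_check(
            model, [conds[2], conds[3]], sp.symbols("p1 p2 p3 p4"), seed=1
        )
        assert rank2 >= rank1
        assert not full1 and full2


class TestDatasetCounts:
    def test_required_datasets_practical(self, ex1):
        model, conds, _ = ex1
        _, _, rep = _analysis(model, conds[2])
        assert required_datasets(rep) == 2

    def test_required_datasets_empty_basis(self, ex2):
        model, conds, _ = ex2
        _, _, rep = _analysis(model, conds[1])
        assert required_datasets(rep) == 0

    def test_minimal_datasets_four_compartment(self, ex4):
        """n_max from the u-only analysis over 12 equations per dataset:
        one enriched dataset suffices."""
        model, conds, _ = ex4
        assert minimal_datasets(model, conds[0]) == 1

    def test_minimal_datasets_mammillary(self, ex3):
        model, conds, _ = ex3
        assert minimal_datasets(model, conds[0]) == 2

    def test_minimal_datasets_nothing_to_remedy(self, ex2):
        model, conds, _ = ex2
        assert minimal_datasets(model, conds[1]) == 0


class TestStackedRank:
    def test_two_compartment_needs_two_conditions(self, ex1):
        model, conds, _ = ex1
        group = sp.symbols("p1 p2 p3 p4")
        rank1, full1 = stacked_rank_check(model, [conds[2]], group)
        assert (rank1, full1) == (3, False)
        rank2, full2 = stacked_rank_check(model, [conds[2], conds[3]], group)
        assert (rank2, full2) == (4, True)

    def test_mammillary_two_enriched_conditions(self, ex3):
        model, conds, _ = ex3
        rank, full = stacked_rank_check(model, [conds[1], conds[1]], model.params)
        assert full and rank == 6


class TestRandomModels:
    @pytest.mark.parametrize("seed", range(5))
    def test_rank_nullity_random_models(self, seed):
        model, _ = random_model(3, 1, seed=seed)
        cond = ExperimentCondition((1.0,) + (0.0,) * (model.n_x - 1), (1.0,) * model.n_u)
        cols, system, rep = _analysis(model, cond)
        rng = np.random.default_rng(seed + 1000)
        B = system.evaluate(system.random_assignment(rng))
        assert numeric_rank(B) + len(rep.basis) == model.n_p
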