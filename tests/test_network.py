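"""Reaction registry, constraint matrix loading and feasibility checks."""

import numpy as np
import pandas as pd
import pytest

from fibrenmf.containers import SchemaError
from fibrenmf.network import (
    ConstraintMatrix,
    NetworkError,
    build_chain_constraints,
    build_completeness_constraints,
    check_feasibility,
    load_constraint_matrix,
    load_reaction_table,
    write_constraint_matrix,
)


def _write_registry(tmp_path, rows, mets):
    reg = tmp_path / "reg.tsv"
    met = tmp_path / "met.tsv"
    pd.DataFrame(rows, columns=["aft_id", "kind", "members", "substrate", "product", "module"]).to_csv(
        reg, sep="\t", index=False
    )
    pd.DataFrame(mets, columns=["metabolite_id", "compartment"]).to_csv(met, sep="\t", index=False)
    return reg, met


class TestReactionRegistry:
    def test_reference_fixture_counts(self, ref_network):
        kinds = [a.kind for a in ref_network.afts]
        assert ref_network.n_features == 101
        assert kinds.count("KO-pathway") == 68
        assert kinds.count("GH") + kinds.count("PL") == 33

    def test_feature_order_is_file_order(self, ref_network):
        assert ref_network.aft_ids[:3] == ["AFT_1", "AFT_2", "AFT_3"]
        assert ref_network.aft_ids[-1] == "PL11"

    def test_empty_registry_errors(self, tmp_path):
        reg, met = _write_registry(tmp_path, [], [("A", "extracellular")])
        with pytest.raises((SchemaError, NetworkError)):
            load_reaction_table(reg, met)

    def test_duplicate_member_is_specificity_violation(self, tmp_path):
        rows = [
            ("AFT_1", "KO-pathway", "K01809", "A", "B", "m"),
            ("AFT_2", "KO-pathway", "K01809", "B", "A", "m"),
        ]
        reg, met = _write_registry(tmp_path, rows, [("A", "extracellular"), ("B", "extracellular")])
        with pytest.raises(NetworkError, match="specificity"):
            load_reaction_table(reg, met)

    def test_duplicate_aft_id_errors(self, tmp_path):
        rows = [
            ("AFT_1", "KO-pathway", "K1", "A", "B", "m"),
            ("AFT_1", "KO-pathway", "K2", "A", "B", "m"),
        ]
        reg, met = _write_registry(tmp_path, rows, [("A", "extracellular"), ("B", "extracellular")])
        with pytest.raises(NetworkError, match="duplicate"):
            load_reaction_table(reg, met)

    def test_unknown_metabolite_errors(self, tmp_path):
        rows = [("AFT_1", "KO-pathway", "K1", "A", "Z", "m")]
        reg, met = _write_registry(tmp_path, rows, [("A", "extracellular")])
        with pytest.raises(NetworkError, match="metabolite"):
            load_reaction_table(reg, met)


class TestConstraintLoading:
    def test_reference_constraint_dimensions_and_signs(self, ref_network, ref_F):
        assert ref_F.values.shape == (155, 101)
        assert all(np.any(r > 0) and np.any(r < 0) for r in ref_F.values)

    def test_column_permutation_invariance(self, tmp_path, toy_network, toy_F):
        path = tmp_path / "F.tsv"
        df = pd.DataFrame(toy_F.values, columns=toy_F.aft_order)
        df = df[list(reversed(toy_F.aft_order))]
        df.insert(0, "constraint_id", toy_F.row_ids)
        df.to_csv(path, sep="\t", index=False)
        loaded = load_constraint_matrix(path, toy_network)
        np.testing.assert_array_equal(loaded.values, toy_F.values)

    def test_one_signed_row_is_degenerate(self, tmp_path, toy_network):
        path = tmp_path / "F.tsv"
        df = pd.DataFrame(np.ones((1, toy_network.n_features)), columns=toy_network.aft_ids)
        df.insert(0, "constraint_id", ["bad"])
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(NetworkError, match="degenerate"):
            load_constraint_matrix(path, toy_network)

    def test_all_zero_row_errors(self, tmp_path, toy_network):
        path = tmp_path / "F.tsv"
        df = pd.DataFrame(np.zeros((1, toy_network.n_features)), columns=toy_network.aft_ids)
        df.insert(0, "constraint_id", ["zero"])
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(SchemaError, match="all-zero"):
            load_constraint_matrix(path, toy_network)

    def test_unknown_column_errors(self, tmp_path, toy_network):
        path = tmp_path / "F.tsv"
        df = pd.DataFrame([[1.0, -1.0]], columns=["AFT_a", "nope"])
        df.insert(0, "constraint_id", ["c"])
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(SchemaError, match="not in network"):
            load_constraint_matrix(path, toy_network)

    def test_round_trip(self, tmp_path, toy_network, toy_F):
        path = tmp_path / "F.tsv"
        write_constraint_matrix(toy_F, path)
        loaded = load_constraint_matrix(path, toy_network)
        np.testing.assert_array_equal(loaded.values, toy_F.values)
        assert loaded.aft_order == toy_F.aft_order


class TestChainConstraints:
    def test_linear_chain_single_row(self, toy_network):
        F = build_chain_constraints(toy_network)
        idx = {f: i for i, f in enumerate(F.aft_order)}
        # m2: consumer AFT_d, single producer AFT_c -> h_d <= h_c
        row = next(F.values[i] for i, rid in enumerate(F.row_ids) if rid == "chain:m2:AFT_d")
        assert row[idx["AFT_d"]] == 1.0 and row[idx["AFT_c"]] == -1.0
        assert np.count_nonzero(row) == 2

    def test_two_producers_one_row(self, toy_network):
        F = build_chain_constraints(toy_network)
        idx = {f: i for i, f in enumerate(F.aft_order)}
        row = next(F.values[i] for i, rid in enumerate(F.row_ids) if rid == "chain:m1:AFT_c")
        assert row[idx["AFT_c"]] == 1.0
        assert row[idx["AFT_a"]] == -1.0 and row[idx["AFT_b"]] == -1.0
        assert np.count_nonzero(row) == 3

    def test_extracellular_only_network_gives_no_rows(self, toy_network):
        from fibrenmf.network import AftEntry, MetabolicNetwork

        net = MetabolicNetwork(
            metabolites={"A": "extracellular", "B": "extracellular"},
            afts=[AftEntry("x", "KO-pathway", ["K1"], "A", "B", "m")],
        )
        assert build_chain_constraints(net).n_constraints == 0

    def test_consumer_without_producer_is_infeasible(self):
        from fibrenmf.network import AftEntry, MetabolicNetwork

        net = MetabolicNetwork(
            metabolites={"m": "intracellular", "B": "extracellular"},
            afts=[AftEntry("x", "KO-pathway", ["K1"], "m", "B", "m")],
        )
        with pytest.raises(NetworkError, match="consumed but never produced"):
            build_chain_constraints(net)

    def test_generated_rows_always_mix_signs(self, ref_network):
        for F in (build_chain_constraints(ref_network), build_completeness_constraints(ref_network)):
            assert all(np.any(r > 0) and np.any(r < 0) for r in F.values)


class TestFeasibility:
    def test_zero_profiles_feasible(self, toy_F):
        rep = check_feasibility(np.zeros((2, toy_F.values.shape[1])), toy_F, tol=1e-8)
        assert rep.all_feasible and np.all(rep.max_violation == 0)

    def test_direct_violation_value(self):
        F = ConstraintMatrix(np.array([[-1.0, 1.0]]), ["a", "b"])
        rep = check_feasibility(np.array([[1.0, 2.0]]), F, tol=1e-8)
        assert rep.max_violation[0] == pytest.approx(1.0)
        assert not rep.all_feasible
        rep2 = check_feasibility(np.array([[2.0, 1.0]]), F, tol=1e-8)
        assert rep2.all_feasible and rep2.max_violation[0] == pytest.approx(-1.0)

    def test_dimension_mismatch_errors(self, toy_F):
        with pytest.raises(ValueError, match="features"):
            check_feasibility(np.zeros((1, 3)), toy_F)
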