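import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pnd import (
    Network,
    build_multiplex,
    by_length_profile,
    classify_pair,
    decompose,
    edgewise_networks,
    pair_atoms,
    pair_gain,
)
from pnd.pairwise import CLASS_REDUNDANT, CLASS_SYNERGISTIC, CLASS_UNREACHABLE

from _oracles import brute_classify, brute_decompose
from conftest import random_multiplex

INF = float("inf")


class TestClassifyPair:
    @pytest.mark.parametrize("lA,lB,lAB,expected", [
        (3, 2, 2, "unique:B"),
        (2, 3, 2, "unique:A"),
        (2, 2, 2, "redundant"),
        (3, INF, 2, "synergistic"),
        (1, 1, 1, "redundant"),
        (1, INF, 1, "unique:A"),
        (INF, INF, INF, "unreachable"),
        (INF, INF, 2, "synergistic"),
    ])
    def test_conditions(self, lA, lB, lAB, expected):
        assert classify_pair(lA, lB, lAB) == expected

    def test_contract_violation(self):
        with pytest.raises(ValueError, match="exceeds"):
            classify_pair(2, 2, 3)

    def test_direct_edges_never_synergistic(self):
        # a length-1 joint path needs the edge in some layer
        for lA, lB in [(1, 1), (1, 5), (4, 1), (1, INF)]:
            assert classify_pair(lA, lB, 1) != "synergistic"


class TestPairAtoms:
    def test_worked_example_pair(self):
        a = pair_atoms(1 / 3, 0.0, 1 / 2)
        assert a.r == 0.0
        assert a.u == (1 / 3, 0.0)
        assert a.s == pytest.approx(1 / 6, abs=1e-15)

    def test_identical_layers_all_redundant(self):
        a = pair_atoms(0.25, 0.25, 0.25)
        assert (a.r, a.u, a.s) == (0.25, (0.0, 0.0), 0.0)

    def test_direct_edge_dominates(self):
        a = pair_atoms(1.0, 0.5, 1.0)
        assert a.r == 0.5 and a.u == (0.5, 0.0) and a.s == 0.0

    def test_contract_violation(self):
        with pytest.raises(ValueError, match="below"):
            pair_atoms(0.5, 0.5, 0.25)

    @given(st.integers(1, 20), st.integers(0, 20), st.integers(1, 20))
    @settings(derandomize=True, max_examples=200)
    def test_atoms_nonnegative_and_conserve(self, la, lb, lab):
        """Atoms from any consistent length triple are >=0 and sum to f_joint."""
        fa = 1 / la
        fb = 0.0 if lb == 0 else 1 / lb
        fab = max(1 / lab, fa, fb)
        a = pair_atoms(fa, fb, fab)
        assert a.r >= 0 and a.s >= 0 and all(u >= 0 for u in a.u)
        assert min(a.u) == 0.0  # one layer always has zero unique atom
        assert a.r + sum(a.u) + a.s == pytest.approx(fab, abs=1e-12)


class TestDecompose:
    def test_worked_example_exact(self, worked_multiplex):
        res = decompose(worked_multiplex)
        assert res.R == pytest.approx(1 / 6, abs=1e-15)
        assert res.U["A"] == pytest.approx(5 / 9, abs=1e-15)
        assert res.U["B"] == pytest.approx(1 / 6, abs=1e-15)
        assert res.S == pytest.approx(1 / 36, abs=1e-15)
        assert res.class_counts["synergistic"] == 1
        assert res.class_counts["unique:A"] == 3
        assert res.class_counts["unique:B"] == 2
        assert res.class_counts["redundant"] == 0

    def test_identical_layers(self):
        g = Network("1234", [("1", "2"), ("2", "3"), ("3", "4")])
        res = decompose(build_multiplex([g, g]))
        assert res.S == 0.0 and all(u == 0.0 for u in res.U.values())
        assert res.R == pytest.approx(res.F_joint)

    def test_nested_layers(self):
        small = Network("123", [("1", "2")])
        big = Network("123", [("1", "2"), ("2", "3")])
        res = decompose(build_multiplex([small, big], names=["A", "B"]))
        assert res.U["A"] == 0.0 and res.S == 0.0

    def test_rejects_three_layers(self):
        g = Network("12", [("1", "2")])
        m = build_multiplex([g, g, g])
        with pytest.raises(ValueError, match="lattice"):
            decompose(m)

    def test_matches_brute_force_on_many_small_multiplexes(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            n = int(rng.integers(3, 7))
            m = random_multiplex(n, 2, rng, p=rng.uniform(0.15, 0.7))
            res = decompose(m)
            oracle = brute_decompose(list(m.node_ids), m.layers[0], m.layers[1])
            assert res.R == pytest.approx(oracle["R"], abs=1e-12)
            assert res.U[m.layer_names[0]] == pytest.approx(oracle["U_A"], abs=1e-12)
            assert res.U[m.layer_names[1]] == pytest.approx(oracle["U_B"], abs=1e-12)
            assert res.S == pytest.approx(oracle["S"], abs=1e-12)
            assert res.F_joint == pytest.approx(oracle["F"], abs=1e-12)

    def test_conservation_identity(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            m = random_multiplex(int(rng.integers(3, 10)), 2, rng)
            res = decompose(m)
            assert res.R + sum(res.U.values()) + res.S == pytest.approx(
                res.F_joint, abs=1e-12)

    def test_layer_swap_symmetry(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            m = random_multiplex(6, 2, rng)
            swapped = build_multiplex([m.layer(1), m.layer(0)], names=["L1", "L0"])
            a, b = decompose(m), decompose(swapped)
            assert a.R == pytest.approx(b.R, abs=1e-12)
            assert a.S == pytest.approx(b.S, abs=1e-12)
            assert a.U["L0"] == pytest.approx(b.U["L0"], abs=1e-12)
            assert a.U["L1"] == pytest.approx(b.U["L1"], abs=1e-12)

    def test_class_agrees_with_atom_route(self):
        """The length-based and atom-based routes to the label coincide."""
        rng = np.random.default_rng(9)
        for _ in range(50):
            m = random_multiplex(int(rng.integers(3, 8)), 2, rng)
            res = decompose(m)
            names = res.layer_names
            for _, row in res.per_pair.iterrows():
                if row["class"] == CLASS_UNREACHABLE:
                    continue
                if row["s"] > 1e-12:
                    via_atoms = CLASS_SYNERGISTIC
                elif row[f"u_{names[0]}"] > 1e-12:
                    via_atoms = f"unique:{names[0]}"
                elif row[f"u_{names[1]}"] > 1e-12:
                    via_atoms = f"unique:{names[1]}"
                else:
                    via_atoms = CLASS_REDUNDANT
                assert row["class"] == via_atoms
                # cross-check with the independent classifier
                assert row["class"] == brute_classify(
                    row["l_A"], row["l_B"], row["l_joint"]).replace(
                        "unique:A", f"unique:{names[0]}").replace(
                        "unique:B", f"unique:{names[1]}")

    def test_unreachable_pairs_have_zero_atoms(self):
        a = Network("abcd", [("a", "b")])
        b = Network("abcd", [("a", "b"), ("c", "d")])
        res = decompose(build_multiplex([a, b]))
        row = res.per_pair[(res.per_pair["node_u"] == "a")
                           & (res.per_pair["node_v"] == "c")].iloc[0]
        assert row["class"] == CLASS_UNREACHABLE
        assert row["r"] == row["s"] == 0.0
        assert res.class_counts[CLASS_UNREACHABLE] > 0
        # unreachable excluded from proportions by default, included on demand
        assert CLASS_UNREACHABLE not in res.class_proportions()
        assert sum(res.class_proportions(include_unreachable=True).values()) == pytest.approx(1.0)


class TestLengthProfile:
    def test_length_one_row_has_no_synergy(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            m = random_multiplex(6, 2, rng)
            prof = by_length_profile(decompose(m))
            if 1.0 in prof.index:
                assert prof.loc[1.0, CLASS_SYNERGISTIC] == 0.0

    def test_rows_sum_to_one_and_match_oracle(self, worked_multiplex):
        prof = by_length_profile(decompose(worked_multiplex))
        assert np.allclose(prof.sum(axis=1), 1.0)
        # joint lengths: five pairs at length 1, one (the synergistic 1-4) at 2
        assert set(prof.index) == {1.0, 2.0}
        assert prof.loc[1.0, "unique:A"] == pytest.approx(3 / 5)
        assert prof.loc[1.0, "unique:B"] == pytest.approx(2 / 5)
        assert prof.loc[2.0, CLASS_SYNERGISTIC] == 1.0

    def test_single_length_profile(self):
        a = Network("12", [("1", "2")])
        prof = by_length_profile(decompose(build_multiplex([a, a])))
        assert len(prof) == 1


class TestGainAndEdgewise:
    def test_gains(self, worked_multiplex):
        res = decompose(worked_multiplex)
        assert pair_gain(res, ("1", "4")) == 1.0  # 3 steps in A vs 2 joint
        assert pair_gain(res, ("4", "1")) == 1.0  # order-insensitive
        # unique pair with the other layer disconnected: infinite gain
        assert math.isinf(pair_gain(res, ("1", "2")))
        with pytest.raises(KeyError):
            pair_gain(res, ("1", "99"))

    def test_redundant_pairs_gain_zero(self):
        g = Network("123", [("1", "2"), ("2", "3")])
        res = decompose(build_multiplex([g, g]))
        assert (res.per_pair["gain"] == 0.0).all()

    def test_edgewise_partition(self, worked_multiplex):
        res = decompose(worked_multiplex)
        nets = edgewise_networks(res)
        assert nets[CLASS_SYNERGISTIC].edges == frozenset({("1", "4")})
        all_edges = [e for g in nets.values() for e in g.edges]
        assert len(all_edges) == len(set(all_edges)) == 6  # a partition

    def test_identical_layers_only_redundant(self):
        g = Network("123", [("1", "2"), ("2", "3")])
        nets = edgewise_networks(decompose(build_multiplex([g, g], names=["A", "B"])))
        assert nets["unique:A"].n_edges == 0
        assert nets["unique:B"].n_edges == 0
        assert nets[CLASS_SYNERGISTIC].n_edges == 0
        assert nets[CLASS_REDUNDANT].n_edges == 3
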