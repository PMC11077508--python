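import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pnd import (
    Antichain,
    Network,
    build_multiplex,
    decompose,
    decompose_lattice,
    enumerate_antichains,
    joint_network,
    lattice_leq,
    redundancy_function,
    verify_axioms,
)
from pnd.graphcore import global_utility
from pnd.lattice import dominant_character_general, per_pair_atoms

from _oracles import brute_antichains, brute_lattice_atoms, brute_leq
from conftest import random_multiplex


def antichain(elements, n=2):
    return Antichain([frozenset(e) for e in elements], n)


class TestAntichainType:
    def test_rejects_comparable_elements(self):
        with pytest.raises(ValueError, match="incomparable"):
            antichain([{0}, {0, 1}])

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            antichain([])
        with pytest.raises(ValueError, match="nonempty"):
            antichain([set()])


class TestEnumeration:
    @pytest.mark.parametrize("n,count", [(1, 1), (2, 4), (3, 18), (4, 166)])
    def test_counts_follow_dedekind_numbers(self, n, count):
        assert len(enumerate_antichains(n)) == count

    def test_two_layer_antichains_explicit(self):
        got = {a.canonical() for a in enumerate_antichains(2)}
        assert got == {(((0,), (1,))), ((0,),), ((1,),), ((0, 1),)}

    def test_matches_brute_force_enumeration(self):
        for n in (2, 3):
            ours = {frozenset(a.elements) for a in enumerate_antichains(n)}
            brute = set(brute_antichains(n))
            assert ours == brute

    def test_large_n_guarded(self):
        with pytest.raises(ValueError, match="cap"):
            enumerate_antichains(5)

    def test_canonical_order_is_linear_extension(self):
        nodes = enumerate_antichains(3)
        for i, a in enumerate(nodes):
            for j in range(i + 1, len(nodes)):
                assert not lattice_leq(nodes[j], a) or not lattice_leq(a, nodes[j])


class TestOrder:
    def test_examples(self):
        bottom = antichain([{0}, {1}])
        assert lattice_leq(bottom, antichain([{0}]))
        assert not lattice_leq(antichain([{0}]), antichain([{1}]))
        assert lattice_leq(bottom, antichain([{0, 1}]))
        assert lattice_leq(antichain([{0}]), antichain([{0, 1}]))

    def test_matches_brute_definition(self):
        nodes = enumerate_antichains(3)
        for a in nodes:
            for b in nodes:
                assert lattice_leq(a, b) == brute_leq(a.elements, b.elements)

    @given(st.data())
    @settings(derandomize=True, max_examples=100)
    def test_partial_order_properties(self, data):
        nodes = enumerate_antichains(3)
        a = data.draw(st.sampled_from(nodes))
        b = data.draw(st.sampled_from(nodes))
        c = data.draw(st.sampled_from(nodes))
        assert lattice_leq(a, a)
        if lattice_leq(a, b) and lattice_leq(b, a):
            assert a.elements == b.elements
        if lattice_leq(a, b) and lattice_leq(b, c):
            assert lattice_leq(a, c)


class TestRedundancyFunction:
    def test_worked_example_values(self, worked_multiplex):
        m = worked_multiplex
        assert redundancy_function(m, antichain([{0}, {1}])) == pytest.approx(1 / 6, abs=1e-15)
        assert redundancy_function(m, antichain([{0, 1}])) == pytest.approx(11 / 12, abs=1e-15)
        # self-intersection
        assert redundancy_function(m, antichain([{0}])) == pytest.approx(13 / 18, abs=1e-15)

    def test_deterministic_equality_with_nested_edge_sets(self):
        small = Network("123", [("1", "2")])
        big = Network("123", [("1", "2"), ("2", "3")])
        m = build_multiplex([small, big])
        # layer 0's edges are contained in layer 1's: intersecting with the
        # superset layer changes nothing
        v1 = redundancy_function(m, antichain([{0}]))
        v2 = redundancy_function(m, antichain([{0}, {1}]))
        assert v1 == pytest.approx(v2, abs=1e-15)
        # and the joint {0,1} equals layer 1 itself
        v3 = redundancy_function(m, antichain([{0, 1}]))
        assert v3 == pytest.approx(redundancy_function(m, antichain([{1}])), abs=1e-15)


class TestMoebius:
    def test_worked_example_atoms(self, worked_multiplex):
        lat = decompose_lattice(worked_multiplex)
        atoms = lat.atoms_by_antichain()
        assert atoms[((0,), (1,))] == pytest.approx(1 / 6, abs=1e-15)
        assert atoms[((0,),)] == pytest.approx(5 / 9, abs=1e-15)
        assert atoms[((1,),)] == pytest.approx(1 / 6, abs=1e-15)
        assert atoms[((0, 1),)] == pytest.approx(1 / 36, abs=1e-15)

    def test_identical_layers_only_bottom_atom(self):
        g = Network("123", [("1", "2"), ("2", "3")])
        lat = decompose_lattice(build_multiplex([g, g]))
        atoms = lat.atoms_by_antichain()
        assert atoms[((0,), (1,))] == pytest.approx(global_utility(g))
        assert atoms[((0,),)] == pytest.approx(0.0, abs=1e-15)
        assert atoms[((0, 1),)] == pytest.approx(0.0, abs=1e-15)

    def test_reduces_to_pairwise_for_two_layers(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            m = random_multiplex(int(rng.integers(3, 8)), 2, rng)
            lat = decompose_lattice(m)
            atoms = lat.atoms_by_antichain()
            res = decompose(m)
            assert atoms[((0,), (1,))] == pytest.approx(res.R, abs=1e-12)
            assert atoms[((0,),)] == pytest.approx(res.U[m.layer_names[0]], abs=1e-12)
            assert atoms[((1,),)] == pytest.approx(res.U[m.layer_names[1]], abs=1e-12)
            assert atoms[((0, 1),)] == pytest.approx(res.S, abs=1e-12)

    def test_matches_brute_force_three_layers(self):
        rng = np.random.default_rng(22)
        for _ in range(20):
            m = random_multiplex(5, 3, rng)
            lat = decompose_lattice(m)
            brute = brute_lattice_atoms(list(m.node_ids), [list(e) for e in m.layers])
            for i, node in enumerate(lat.nodes):
                assert lat.f_atom[i] == pytest.approx(
                    brute[frozenset(node.elements)], abs=1e-12)

    def test_reconstruction_and_total(self):
        rng = np.random.default_rng(23)
        for n_layers in (2, 3):
            for _ in range(25):
                m = random_multiplex(6, n_layers, rng)
                lat = decompose_lattice(m)
                # Moebius reconstruction at every node
                for i in range(len(lat.nodes)):
                    below = lat.leq[:, i]
                    assert lat.f_atom[below].sum() == pytest.approx(
                        lat.f_cap[i], abs=1e-12)
                assert lat.f_atom.sum() == pytest.approx(
                    global_utility(joint_network(m)), abs=1e-12)

    def test_atom_nonnegativity(self):
        rng = np.random.default_rng(24)
        for n_layers in (2, 3):
            for _ in range(50):
                m = random_multiplex(int(rng.integers(3, 8)), n_layers, rng)
                lat = decompose_lattice(m)
                assert (lat.f_atom >= -1e-12).all()

    def test_relabeling_invariance(self):
        """Permuting layers permutes atoms through the induced antichain map."""
        rng = np.random.default_rng(25)
        m = random_multiplex(6, 3, rng)
        perm = [2, 0, 1]
        permuted = build_multiplex([m.layer(i) for i in perm],
                                   names=[m.layer_names[i] for i in perm])
        lat = decompose_lattice(m)
        lat_p = decompose_lattice(permuted)
        atoms = lat.atoms_by_antichain()
        atoms_p = lat_p.atoms_by_antichain()
        inv = {orig: new for new, orig in enumerate(perm)}
        for key, val in atoms.items():
            mapped = tuple(sorted(tuple(sorted(inv[i] for i in a)) for a in key))
            assert atoms_p[mapped] == pytest.approx(val, abs=1e-12)


class TestDominantCharacter:
    def test_worked_example_pairs(self, worked_multiplex):
        m = worked_multiplex
        lat, atoms = per_pair_atoms(m)
        idx = {v: i for i, v in enumerate(m.node_ids)}

        def character(u, v):
            profile = atoms[:, idx[u], idx[v]]
            return dominant_character_general(lat, profile)

        top, _ = character("1", "4")
        assert top.canonical() == ((0, 1),)  # synergistic
        ub, _ = character("1", "3")
        assert ub.canonical() == ((1,),)  # unique to layer 2

    def test_unreachable_pair_has_no_character(self):
        a = Network("abcd", [("a", "b")])
        b = Network("abcd", [("a", "b"), ("c", "d")])
        m = build_multiplex([a, b])
        lat, atoms = per_pair_atoms(m)
        idx = {v: i for i, v in enumerate(m.node_ids)}
        char, amb = dominant_character_general(lat, atoms[:, idx["a"], idx["c"]])
        assert char is None and amb == []

    def test_unique_for_two_layers_everywhere(self):
        rng = np.random.default_rng(26)
        for _ in range(20):
            m = random_multiplex(6, 2, rng)
            lat, atoms = per_pair_atoms(m)
            n = m.n_nodes
            for i in range(n):
                for j in range(i + 1, n):
                    char, ambiguous = dominant_character_general(lat, atoms[:, i, j])
                    assert ambiguous == []  # never ambiguous for N=2


class TestAxioms:
    def test_random_multiplexes_pass_all_axioms(self):
        rng = np.random.default_rng(27)
        for n_layers in (2, 3):
            for _ in range(10):
                m = random_multiplex(6, n_layers, rng)
                report = verify_axioms(m)
                assert max(report.values()) <= 1e-12, report
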