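"""Cleavable-bond matching, cutting, clique enumeration, fragmentation."""

import itertools
import random

import networkx as nx
import pytest

from molblocks.chem_io import canonical_smiles, heavy_atom_count
from molblocks.fragmenter import (
    CompatibilityGraph,
    build_compatibility_graph,
    cut_bonds,
    fragment_extensive,
    fragment_library,
    fragment_single,
    match_cleavable_bonds,
    maximal_cliques,
)
from molblocks.fixtures import GOLDEN_MOLECULES, brute_force_fragmenter

from conftest import record


class TestMatchCleavableBonds:
    def test_single_ester_bond(self, ethyl_acetate, ester_rule):
        (cb,) = match_cleavable_bonds(ethyl_acetate, ester_rule)
        mol = ethyl_acetate.mol
        a1, a2 = cb.atom_pair
        assert mol.GetAtomWithIdx(a1).GetSymbol() == "O"
        assert mol.GetAtomWithIdx(a2).GetSymbol() == "C"
        assert mol.GetBondBetweenAtoms(a1, a2).GetIdx() == cb.bond_index

    def test_no_match_gives_empty_list(self, ester_rule):
        assert match_cleavable_bonds(record("CCCC"), ester_rule) == []

    def test_two_ester_bonds(self, diethyl_succinate, ester_rule):
        bonds = match_cleavable_bonds(diethyl_succinate, ester_rule)
        assert len(bonds) == 2
        assert len({b.bond_index for b in bonds}) == 2

    def test_symmetric_matches_counted_once(self, rules):
        # both C-O bonds of the ether match, each in two orientations
        bonds = match_cleavable_bonds(record("CCOCC"), rules)
        assert len(bonds) == 2

    def test_ring_bonds_excluded(self, rules):
        # tetrahydrofuran: every C-O bond matching the ether rule is cyclic
        assert match_cleavable_bonds(record("C1CCOC1"), rules) == []

    def test_ordered_by_bond_index(self, rules):
        bonds = match_cleavable_bonds(record("CCOC(=O)CCC(=O)NC"), rules)
        assert [b.bond_index for b in bonds] == sorted(
            b.bond_index for b in bonds
        )


class TestCutBonds:
    def test_ester_cut_products(self, ethyl_acetate, ester_rule):
        bonds = match_cleavable_bonds(ethyl_acetate, ester_rule)
        frags = cut_bonds(ethyl_acetate, bonds)
        assert {canonical_smiles(f) for f in frags} == {"CC(=O)O", "CC"}

    def test_empty_cut_returns_whole_molecule(self, ethyl_acetate):
        (frag,) = cut_bonds(ethyl_acetate, [])
        assert canonical_smiles(frag) == canonical_smiles(ethyl_acetate.mol)

    def test_double_cut_component_count(self, diethyl_succinate, ester_rule):
        bonds = match_cleavable_bonds(diethyl_succinate, ester_rule)
        frags = cut_bonds(diethyl_succinate, bonds)
        assert len(frags) == 3  # |bonds| + 1
        smiles = sorted(canonical_smiles(f) for f in frags)
        assert smiles == ["CC", "CC", "O=C(O)CCC(=O)O"]

    def test_heavy_atoms_conserved(self, diethyl_succinate, ester_rule):
        bonds = match_cleavable_bonds(diethyl_succinate, ester_rule)
        frags = cut_bonds(diethyl_succinate, bonds)
        assert sum(heavy_atom_count(f) for f in frags) == heavy_atom_count(
            diethyl_succinate.mol
        )

    def test_ring_bond_cut_rejected(self):
        from molblocks.fragmenter import CleavableBond

        mol = record("C1CCOC1")
        ring_bond = CleavableBond(bond_index=0, atom_pair=(0, 1), rule_name="x")
        with pytest.raises(ValueError, match="ring"):
            cut_bonds(mol, [ring_bond])


class TestCompatibilityGraph:
    def test_succinate_min2_two_nodes_one_edge(self, diethyl_succinate,
                                               ester_rule):
        bonds = match_cleavable_bonds(diethyl_succinate, ester_rule)
        g = build_compatibility_graph(diethyl_succinate, bonds, min_size=2)
        assert len(g.nodes) == 2
        assert g.edges == {frozenset({0, 1})}

    def test_succinate_min3_solo_infeasible(self, diethyl_succinate,
                                            ester_rule):
        # each solo cut strands a 2-atom ethyl fragment
        bonds = match_cleavable_bonds(diethyl_succinate, ester_rule)
        g = build_compatibility_graph(diethyl_succinate, bonds, min_size=3)
        assert g.nodes == []

    def test_single_bond_single_node_no_edges(self, ethyl_acetate, ester_rule):
        bonds = match_cleavable_bonds(ethyl_acetate, ester_rule)
        g = build_compatibility_graph(ethyl_acetate, bonds, min_size=1)
        assert len(g.nodes) == 1 and g.edges == set()

    def test_multiple_rules_same_bond_one_node(self, ethyl_acetate, rules):
        from molblocks.chem_io import _compile_rule

        extra = _compile_rule("ester_dup", "[O;$(OC=O):1][CX4:2]", "test")
        bonds = match_cleavable_bonds(ethyl_acetate, rules + [extra])
        assert len(bonds) == 2  # two (bond, rule) pairs...
        g = build_compatibility_graph(ethyl_acetate, bonds, min_size=1)
        assert len(g.nodes) == 1  # ...but one graph node


def graph_from_edges(n, edges):
    return CompatibilityGraph(
        nodes=list(range(n)),  # node payload is irrelevant to the algorithm
        edges={frozenset(e) for e in edges},
    )


def brute_force_cliques(n, edges):
    edge_set = {frozenset(e) for e in edges}
    cliques = [
        set(sub)
        for r in range(1, n + 1)
        for sub in itertools.combinations(range(n), r)
        if all(frozenset(p) in edge_set
               for p in itertools.combinations(sub, 2))
    ]
    return {
        frozenset(c) for c in cliques
        if not any(set(c) < o for o in cliques)
    }


class TestMaximalCliques:
    def test_triangle_is_one_clique(self):
        g = graph_from_edges(3, [(0, 1), (1, 2), (0, 2)])
        assert maximal_cliques(g) == [frozenset({0, 1, 2})]

    def test_path_graph(self):
        g = graph_from_edges(3, [(0, 1), (1, 2)])
        assert maximal_cliques(g) == [frozenset({0, 1}), frozenset({1, 2})]

    def test_isolated_nodes_are_singleton_cliques(self):
        g = graph_from_edges(3, [])
        assert maximal_cliques(g) == [
            frozenset({0}), frozenset({1}), frozenset({2})
        ]

    def test_empty_graph(self):
        assert maximal_cliques(graph_from_edges(0, [])) == []

    def test_matches_brute_force_and_networkx_on_random_graphs(self):
        rng = random.Random(20240301)
        for trial in range(120):
            n = rng.randint(1, 10)
            p = rng.choice([0.2, 0.5, 0.8])
            edges = [
                e for e in itertools.combinations(range(n), 2)
                if rng.random() < p
            ]
            g = graph_from_edges(n, edges)
            ours = {frozenset(c) for c in maximal_cliques(g)}
            assert ours == brute_force_cliques(n, edges), f"trial {trial}"
            nxg = nx.Graph()
            nxg.add_nodes_from(range(n))
            nxg.add_edges_from(edges)
            assert ours == {frozenset(c) for c in nx.find_cliques(nxg)}

    def test_deterministic_order(self):
        edges = [(0, 1), (1, 2), (2, 3), (0, 3)]
        g = graph_from_edges(4, edges)
        assert maximal_cliques(g) == maximal_cliques(g)
        assert maximal_cliques(g) == sorted(
            maximal_cliques(g), key=lambda c: tuple(sorted(c))
        )


class TestFragmentExtensive:
    def test_succinate_min2(self, diethyl_succinate, ester_rule):
        result = fragment_extensive(diethyl_succinate, ester_rule, 2)
        assert result.fragments == {"CC", "O=C(O)CCC(=O)O"}

    def test_lone_bond_not_solo_feasible_gives_empty_set(self, ethyl_acetate,
                                                         ester_rule):
        assert fragment_extensive(ethyl_acetate, ester_rule, 4).fragments == set()

    def test_ethyl_acetate_min2(self, ethyl_acetate, ester_rule):
        assert fragment_extensive(ethyl_acetate, ester_rule, 2).fragments == {
            "CC(=O)O", "CC"
        }

    def test_golden_library(self, golden, rules):
        expected = {g.id: g.extensive_min2 for g in GOLDEN_MOLECULES}
        for rec in golden:
            got = fragment_extensive(rec, rules, 2).fragments
            assert got == set(expected[rec.id]), rec.id

    def test_min_size_must_be_positive(self, ethyl_acetate, ester_rule):
        with pytest.raises(ValueError):
            fragment_extensive(ethyl_acetate, ester_rule, 0)


class TestFragmentSingle:
    def test_succinate_same_as_extensive(self, diethyl_succinate, ester_rule):
        single = fragment_single(diethyl_succinate, ester_rule, 2)
        assert single.fragments == {"CC", "O=C(O)CCC(=O)O"}

    def test_no_matches_empty_set(self, rules):
        assert fragment_single(record("CCCC"), rules, 1).fragments == set()

    def test_subset_of_extensive_on_golden(self, golden, rules):
        for rec in golden:
            for min_size in (1, 2, 3, 4):
                single = fragment_single(rec, rules, min_size).fragments
                extensive = fragment_extensive(rec, rules, min_size).fragments
                assert single <= extensive, (rec.id, min_size)


class TestFragmentationProperties:
    def test_conservation_on_every_clique_cut(self, golden, rules):
        for rec in golden:
            parent_atoms = heavy_atom_count(rec.mol)
            candidates = match_cleavable_bonds(rec, rules)
            g = build_compatibility_graph(rec, candidates, min_size=2)
            for clique in maximal_cliques(g):
                frags = cut_bonds(rec, [g.nodes[i] for i in clique])
                assert sum(heavy_atom_count(f) for f in frags) == parent_atoms

    def test_size_guarantee(self, golden, rules):
        from rdkit import Chem

        for rec in golden:
            for min_size in (1, 2, 3, 4, 5):
                for frag in fragment_extensive(rec, rules, min_size).fragments:
                    assert heavy_atom_count(
                        Chem.MolFromSmiles(frag)
                    ) >= min_size

    def test_monotone_filtering_per_cut_set(self, golden, rules):
        """For a fixed clique cut, raising min_size only removes fragments."""
        for rec in golden:
            candidates = match_cleavable_bonds(rec, rules)
            g = build_compatibility_graph(rec, candidates, min_size=1)
            for clique in maximal_cliques(g):
                frags = cut_bonds(rec, [g.nodes[i] for i in clique])
                previous = None
                for min_size in (1, 2, 3, 4, 5, 6):
                    current = {
                        canonical_smiles(f) for f in frags
                        if heavy_atom_count(f) >= min_size
                    }
                    if previous is not None:
                        assert current <= previous, (rec.id, min_size)
                    previous = current

    def test_result_sets_are_not_nested_across_min_size(self, rules):
        """Raising min_size can remove compatibility edges, so smaller
        maximal cliques produce coarser fragments never seen at the lower
        threshold.  Pin the diethyl ether counterexample: whole-result
        monotonicity is a known non-property of clique-based cutting."""
        ether = record("CCOCC", "diethyl_ether")
        at_1 = fragment_extensive(ether, rules, 1).fragments
        at_2 = fragment_extensive(ether, rules, 2).fragments
        assert at_1 == {"CC", "O"}
        assert at_2 == {"CC", "CCO"}
        assert not at_2 <= at_1

    def test_extensive_matches_brute_force_oracle(self, golden, rules):
        """The clique route equals exhaustive cut-set enumeration, except
        on the pathological molecule where a pairwise-compatible triple is
        jointly undersized; there every oracle-only fragment must strictly
        contain the post-filtered undersized core."""
        from rdkit import Chem

        patho = {g.id for g in GOLDEN_MOLECULES if g.pathological}
        for rec in golden:
            for min_size in (1, 2, 3, 4):
                extensive = fragment_extensive(rec, rules, min_size).fragments
                brute = brute_force_fragmenter(rec, rules, min_size)
                if rec.id not in patho:
                    assert extensive == brute, (rec.id, min_size)
                else:
                    assert extensive <= brute, (rec.id, min_size)
                    for extra in brute - extensive:
                        # coarser than some extensive fragment: the extra
                        # piece still holds the undersized core
                        n = heavy_atom_count(Chem.MolFromSmiles(extra))
                        assert n >= min_size
                        assert all(
                            n > heavy_atom_count(Chem.MolFromSmiles(f))
                            for f in extensive
                        ) or extensive == set()


class TestFragmentLibrary:
    def test_row_per_molecule_in_order(self, golden, rules):
        table = fragment_library(golden, rules, 2, extensive=True)
        assert [row.molecule_id for row in table] == [r.id for r in golden]

    def test_oversized_threshold_gives_empty_rows(self, golden, rules):
        table = fragment_library(golden, rules, 99, extensive=True)
        assert all(row.fragments == frozenset() for row in table)

    def test_empty_library_rejected(self, rules):
        with pytest.raises(ValueError):
            fragment_library([], rules, 2)
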