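"""Core growth, the disambiguation cascade, and the two-molecule route."""

import pytest

from mucha import (
    AlignConfig,
    Atom,
    AtomString,
    Bond,
    MoleculeGraph,
    SeedAlignment,
    align,
    align_pairwise_stop,
    extend_core,
    find_lcas,
    random_molecule,
    select_representative,
)
from mucha.corealign import disambiguate


def _core_label_multiset(aln, mol):
    return sorted(mol.label(c.cells[mol.id]) for c in aln.core_columns())


class TestExtendCore:
    def test_fixture_pair_core_content(self, c00482, c05855):
        aln = align_pairwise_stop([c00482, c05855])
        assert len(aln.core_columns()) == 10
        # 6 ring atoms, 3 side-chain carbons, and the para oxygen of each
        assert {c.cells["C00482"] for c in aln.core_columns()} == {
            1, 2, 3, 4, 5, 6, 7, 11, 14, 9,
        }
        assert {c.cells["C05855"] for c in aln.core_columns()} == {
            1, 2, 3, 4, 5, 6, 7, 9, 11, 8,
        }
        # the para oxygen is matched at species level across O1a / O2a
        para = next(c for c in aln.core_columns() if c.cells["C00482"] == 9)
        assert para.cells["C05855"] == 8
        assert c00482.label(9) == "O1a" and c05855.label(8) == "O2a"

    def test_identical_molecules_align_fully(self):
        mol = random_molecule(5, n_atoms=11)
        twin = mol.relabel({i: i for i in mol.atom_indices}, id="TWIN")
        aln = align_pairwise_stop([mol, twin])
        assert len(aln.core_columns()) == len(mol)  # 100% atom coverage
        aln.validate()

    def test_seed_only_fixpoint(self):
        # both molecules are exactly the seed path: nothing to extend
        atoms = [Atom(1, "C1b", "C"), Atom(2, "C1b", "C"), Atom(3, "O1a", "O")]
        bonds = [Bond(1, 2), Bond(2, 3)]
        a = MoleculeGraph("A", atoms, bonds)
        b = MoleculeGraph("B", atoms, bonds)
        sets = find_lcas([a, b])
        seed = select_representative([a, b], sets)
        aln = extend_core([a, b], seed)
        assert len(aln.core_columns()) == 3

    def test_growth_is_monotone_and_conflict_free(self, c00482, c05855):
        aln = align_pairwise_stop([c00482, c05855])
        aln.validate()
        seed_cols = [c for c in aln.columns if c.provenance == "seed"]
        assert len(seed_cols) == 4  # promotion never removes seed columns

    def test_core_size_invariant_under_renumbering(self, c00482, c05855):
        base = len(align_pairwise_stop([c00482, c05855]).core_columns())
        for offset in (1, 3):
            n = len(c05855)
            perm = {i: (i + offset - 1) % n + 1 for i in c05855.atom_indices}
            renum = c05855.relabel(perm, id="C05855")
            moved = len(align_pairwise_stop([c00482, renum]).core_columns())
            assert moved == base


class TestDisambiguate:
    def test_ring_membership_splits_first(self):
        # ring carbon vs chain carbon, same species, same anchor distances
        ring = MoleculeGraph(
            "R",
            [Atom(i, "C1x", "C") for i in range(1, 4)],
            [Bond(1, 2), Bond(2, 3), Bond(3, 1)],
        )
        chain = MoleculeGraph(
            "S",
            [Atom(i, "C1x", "C") for i in range(1, 4)],
            [Bond(1, 2), Bond(2, 3)],
        )
        by_id = {"R": ring, "S": chain}
        cols = disambiguate(by_id, {"R": [1, 2], "S": [1, 2]})
        # ring atoms have 2 ring bonds, chain atoms 0: no subgroup spans both
        assert cols == []

    def test_class_then_full_label_refinement(self):
        mols = {}
        for mid in ("A", "B"):
            atoms = [
                Atom(1, "C1a", "C"),
                Atom(2, "C8y", "C"),
                Atom(3, "C8x", "C"),
                Atom(4, "O1a", "O"),
            ]
            bonds = [Bond(1, 2), Bond(1, 3), Bond(3, 4)]
            mols[mid] = MoleculeGraph(mid, atoms, bonds)
        cols = disambiguate(mols, {"A": [2, 3], "B": [2, 3]})
        # same species and ring counts; full-label split pairs 2<->2, 3<->3
        assert sorted(tuple(sorted(c.items())) for c, _ in cols) == [
            (("A", 2), ("B", 2)),
            (("A", 3), ("B", 3)),
        ]

    def test_symmetric_candidates_paired_by_index_order(self):
        benzene = MoleculeGraph(
            "X",
            [Atom(i, "C8x", "C") for i in range(1, 7)],
            [Bond(1, 2), Bond(2, 3), Bond(3, 4), Bond(4, 5), Bond(5, 6), Bond(6, 1)],
        )
        twin = benzene.relabel({i: i for i in benzene.atom_indices}, id="Y")
        by_id = {"X": benzene, "Y": twin}
        cols = disambiguate(by_id, {"X": [2, 6], "Y": [2, 6]})
        assert [(c[0], c[1]) for c in cols] == [
            ({"X": 2, "Y": 2}, "index-order"),
            ({"X": 6, "Y": 6}, "index-order"),
        ]

    def test_unequal_multiplicities_rejected(self):
        mol_a = MoleculeGraph(
            "A",
            [Atom(1, "C1a", "C"), Atom(2, "O1a", "O"), Atom(3, "O1a", "O")],
            [Bond(1, 2), Bond(1, 3)],
        )
        mol_b = MoleculeGraph(
            "B",
            [Atom(1, "C1a", "C"), Atom(2, "O1a", "O")],
            [Bond(1, 2)],
        )
        cols = disambiguate({"A": mol_a, "B": mol_b}, {"A": [2, 3], "B": [2]})
        assert cols == []


class TestRouting:
    def test_two_molecule_query_is_core_only(self, c00482, c05855):
        aln, groups = align([c00482, c05855])
        assert groups == []
        assert all(c.role == "core" for c in aln.columns)

    def test_three_molecule_query_runs_branch_stage(self, panel):
        aln, groups = align(panel)
        assert any(c.role == "branch" for c in aln.columns)
        assert groups

    def test_wrong_arity_rejected(self, panel):
        with pytest.raises(ValueError):
            align_pairwise_stop(panel)
        with pytest.raises(ValueError):
            align([panel[0]])
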