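"""Longest-common-string search and representative selection."""

import pytest

from mucha import (
    AlignConfig,
    Atom,
    AtomString,
    Bond,
    MoleculeGraph,
    canonical_orientation,
    find_lcas,
    random_molecule,
    select_representative,
    string_key,
)

from conftest import oracle_lcas


class TestCanonicalOrientation:
    def test_collapses_mirror(self, c00482):
        s = AtomString("C00482", (11, 7, 1, 2))
        assert canonical_orientation(c00482, s) == canonical_orientation(
            c00482, s.reverse()
        )

    def test_idempotent(self, c00482):
        s = AtomString("C00482", (2, 1, 7, 11))
        once = canonical_orientation(c00482, s)
        assert canonical_orientation(c00482, once) == once

    def test_palindromic_labels_tie_broken_by_indices(self, c00482):
        s = AtomString("C00482", (3, 4, 5))  # C8y-C8y-C8y
        assert canonical_orientation(c00482, s).atoms == (3, 4, 5)

    def test_mirror_strings_share_key(self, c00482):
        s = AtomString("C00482", (11, 7, 1, 2))
        assert string_key(c00482, s) == string_key(c00482, s.reverse())


class TestFindLcas:
    def test_fixture_pair_has_two_symmetric_instances(self, c00482, c05855):
        sets = find_lcas([c00482, c05855])
        assert len(sets) == 1
        cs = sets[0]
        assert cs.key[0] == ("C2b", "C2b", "C8y", "C8x")
        assert {m: len(v) for m, v in cs.instances.items()} == {
            "C00482": 2,
            "C05855": 2,
        }

    def test_disjoint_label_sets_give_empty_result(self):
        a = MoleculeGraph("A", [Atom(1, "C1a", "C"), Atom(2, "C1b", "C")], [Bond(1, 2)])
        b = MoleculeGraph("B", [Atom(1, "O1a", "O"), Atom(2, "O2a", "O")], [Bond(1, 2)])
        assert find_lcas([a, b]) == []

    def test_single_molecule_rejected(self, c00482):
        with pytest.raises(ValueError):
            find_lcas([c00482])

    def test_two_copies_recover_longest_unique_path(self):
        mol = random_molecule(11, n_atoms=9)
        twin = mol.relabel({i: i for i in mol.atom_indices}, id="TWIN")
        sets = find_lcas([mol, twin])
        expected = oracle_lcas([mol, twin])
        assert {cs.key for cs in sets} == set(expected)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        a = random_molecule(2 * seed, n_atoms=4 + seed % 9, ring_prob=0.1)
        b = random_molecule(2 * seed + 1, n_atoms=4 + seed % 9, ring_prob=0.1)
        got = find_lcas([a, b])
        expected = oracle_lcas([a, b])
        assert {cs.key for cs in got} == set(expected)
        for cs in got:
            for mid, insts in cs.instances.items():
                assert {min(s.atoms, s.atoms[::-1]) for s in insts} == expected[cs.key][mid]

    def test_invariant_under_input_order_and_renumbering(self, c00482, c05855):
        ref = find_lcas([c00482, c05855])
        flipped = find_lcas([c05855, c00482])
        assert {cs.key for cs in ref} == {cs.key for cs in flipped}
        n = len(c05855)
        perm = {i: n + 1 - i for i in c05855.atom_indices}
        renum = c05855.relabel(perm, id="C05855")
        again = find_lcas([c00482, renum])
        assert {cs.key for cs in again} == {cs.key for cs in ref}
        # instance atoms map through the permutation
        for cs in again:
            got = {min(s.atoms, s.atoms[::-1]) for s in cs.instances["C05855"]}
            want = {
                min(t := tuple(perm[a] for a in s.atoms), t[::-1])
                for s in ref[0].instances["C05855"]
            }
            assert got == want

    def test_prefixes_of_common_strings_are_common(self, c00482, c05855):
        # monotonicity that justifies the level-wise search: every prefix of a
        # common string has its key somewhere in every other molecule
        from conftest import all_simple_paths

        sets = find_lcas([c00482, c05855])
        for cs in sets:
            for s in cs.instances["C00482"]:
                for cut in range(1, len(s.atoms)):
                    prefix_key = string_key(c00482, AtomString("C00482", s.atoms[:cut]))
                    other_keys = {
                        string_key(c05855, AtomString("C05855", p))
                        for p in all_simple_paths(c05855)
                        if len(p) == cut
                    }
                    assert prefix_key in other_keys


def _two_armed(mol_id: str, center: str, extra: str) -> MoleculeGraph:
    """Center atom with two C1b-O1a arms; ``extra`` breaks the arm symmetry."""
    atoms = [
        Atom(1, center, center[0]),
        Atom(2, "C1b", "C"),
        Atom(3, "O1a", "O"),
        Atom(4, "C1b", "C"),
        Atom(5, "O1a", "O"),
        Atom(6, extra, extra[0]),
    ]
    bonds = [Bond(1, 2), Bond(2, 3), Bond(1, 4), Bond(4, 5), Bond(2, 6)]
    return MoleculeGraph(mol_id, atoms, bonds)


class TestSelectRepresentative:
    def test_single_instance_returned_unchanged(self):
        a = MoleculeGraph(
            "A",
            [Atom(1, "O1a", "O"), Atom(2, "C1b", "C"), Atom(3, "C1a", "C")],
            [Bond(1, 2), Bond(2, 3)],
        )
        b = MoleculeGraph(
            "B",
            [Atom(1, "O1a", "O"), Atom(2, "C1b", "C"), Atom(3, "N1a", "N")],
            [Bond(1, 2), Bond(2, 3)],
        )
        sets = find_lcas([a, b])
        seed = select_representative([a, b], sets)
        assert seed.key[0] == ("C1b", "O1a")
        assert {m: s.atoms for m, s in seed.strings.items()} == {
            "A": (2, 1),
            "B": (2, 1),
        }

    def test_symmetric_instances_score_equally(self, c00482, c05855):
        (cs,) = find_lcas([c00482, c05855])
        import itertools

        from mucha import string_decaf_score

        scores = set()
        for sa, sb in itertools.product(cs.instances["C00482"], cs.instances["C05855"]):
            scores.add(round(string_decaf_score(c00482, sa, c05855, sb), 9))
        assert len(scores) == 1  # any choice is equally good

    def test_ga_attains_exhaustive_optimum(self):
        # three molecules with two seed instances each: 2 x 2 x 2 combinations
        mols = [
            _two_armed("M0", "C1y", "N1a"),
            _two_armed("M1", "C1x", "S2a"),
            _two_armed("M2", "C2b", "O2a"),
        ]
        sets = find_lcas(mols)
        assert {m: len(v) for m, v in sets[0].instances.items()} == {
            "M0": 2, "M1": 2, "M2": 2,
        }
        exhaustive = select_representative(mols, sets, AlignConfig(exhaustive_limit=10**9))
        for ga_seed in (0, 1, 2):
            ga = select_representative(
                mols, sets, AlignConfig(seed=ga_seed, exhaustive_limit=0)
            )
            assert ga.objective == pytest.approx(exhaustive.objective)

    def test_empty_input_rejected(self, c00482, c05855):
        with pytest.raises(ValueError):
            select_representative([c00482, c05855], [])
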