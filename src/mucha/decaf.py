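"""Distance-embedded common atom fingerprints (DECAF) and atom similarity.

Every atom gets a fingerprint counting, for each shortest-path distance
``d`` reachable from it, how many atoms of each KEGG *atom class* sit at
that distance.  The fingerprint of atom ``i`` is the multiset of keys
``(d, class)`` with occurrence numbers ``n[i, k, d]``; the ``d = 0`` entry
is the atom's own class with count 1, and the walk ends at the atom's
eccentricity (when breadth-first search runs out of molecule).

Two atoms are compared by the down-weighted overlap of their fingerprints::

    score(i, j) = sum_d  [ sum_k min(n[i,k,d], n[j,k,d]) ] / (d + 1)

so agreement close to the atom counts more than agreement far away.
Scores are memoized: each (molecule, atom) pair is computed once and then
served from a hash table.
"""

from __future__ import annotations

from .chemgraph import Level, MoleculeGraph
from .dmaid import AtomString

__all__ = ["build_decaf", "decaf_score", "string_decaf_score", "ScoreCache"]

# fingerprint: {(distance, atom-class token): occurrence count}
Decaf = dict[tuple[int, str], int]


def build_decaf(mol: MoleculeGraph, atom_index: int) -> Decaf:
    """Fingerprint of one atom: counts of atom classes per shortest-path distance.

    Every atom of the molecule lands in exactly one bucket, so the total
    fingerprint mass equals the molecule's atom count.
    """
    mol.atom(atom_index)
    fp: Decaf = {}
    for j, d in mol.distances()[atom_index].items():
        key = (d, mol.label(j, Level.CLASS))
        fp[key] = fp.get(key, 0) + 1
    return fp


def decaf_score(fa: Decaf, fb: Decaf) -> float:
    """Per-distance min-overlap of two fingerprints, down-weighted by 1/(d+1)."""
    score = 0.0
    for key, na in fa.items():
        nb = fb.get(key)
        if nb is not None:
            score += min(na, nb) / (key[0] + 1)
    return score


class ScoreCache:
    """Memo table for atom-atom DECAF scores, keyed by unordered atom pairs.

    Fingerprints are built lazily per molecule and scores stored under the
    sorted ((molecule_id, atom), (molecule_id, atom)) key, so repeated
    queries are dictionary lookups.
    """

    def __init__(self) -> None:
        self._fingerprints: dict[tuple[str, int], Decaf] = {}
        self._scores: dict[tuple[tuple[str, int], tuple[str, int]], float] = {}

    def fingerprint(self, mol: MoleculeGraph, atom_index: int) -> Decaf:
        key = (mol.id, atom_index)
        fp = self._fingerprints.get(key)
        if fp is None:
            fp = build_decaf(mol, atom_index)
            self._fingerprints[key] = fp
        return fp

    def score(self, mol_a: MoleculeGraph, a: int, mol_b: MoleculeGraph, b: int) -> float:
        ka, kb = (mol_a.id, a), (mol_b.id, b)
        key = (ka, kb) if ka <= kb else (kb, ka)
        cached = self._scores.get(key)
        if cached is None:
            cached = decaf_score(self.fingerprint(mol_a, a), self.fingerprint(mol_b, b))
            self._scores[key] = cached
        return cached


def string_decaf_score(
    mol_a: MoleculeGraph,
    sa: AtomString,
    mol_b: MoleculeGraph,
    sb: AtomString,
    cache: ScoreCache | None = None,
) -> float:
    """Position-wise sum of atom-atom DECAF scores between equal-length strings."""
    if len(sa) != len(sb):
        raise ValueError(f"string length mismatch: {len(sa)} vs {len(sb)}")
    if cache is None:
        cache = ScoreCache()
    return sum(
        cache.score(mol_a, a, mol_b, b) for a, b in zip(sa.atoms, sb.atoms)
    )
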