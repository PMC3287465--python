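"""Distance-matrix atom identifiers (DMAIDs) for atom strings.

An *atom string* is a simple path in one molecule.  Its **self-DMAID** is
the square matrix of whole-molecule shortest-path distances between the
string's atoms, rows and columns in string order; two strings in different
molecules occupy topologically identical positions iff their label
sequences and self-DMAIDs agree entry-wise.  The **anchored DMAID** is the
(generally rectangular) matrix of distances from a string's atoms to the
atoms of an anchor string, and encodes *where* the string sits relative to
an already-aligned substructure.

Distances are always measured in the whole molecule, never in the subgraph
induced by the string: in a six-membered ring the two ends of a
five-atom string are 2 bonds apart through the sixth ring atom, and that
shortcut is part of the positional identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chemgraph import Level, MoleculeGraph

__all__ = ["AtomString", "self_dmaid", "anchored_dmaid", "dmaid_equal"]


@dataclass(frozen=True)
class AtomString:
    """A simple path of atoms in one molecule (consecutive atoms bonded)."""

    molecule_id: str
    atoms: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.atoms) < 1:
            raise ValueError("atom string must contain at least one atom")
        if len(set(self.atoms)) != len(self.atoms):
            raise ValueError(f"atom string has repeated atoms: {self.atoms}")

    def __len__(self) -> int:
        return len(self.atoms)

    def reverse(self) -> "AtomString":
        return AtomString(self.molecule_id, self.atoms[::-1])

    def labels(self, mol: MoleculeGraph, level: Level = Level.FULL) -> tuple[str, ...]:
        return tuple(mol.label(a, level) for a in self.atoms)

    def validate(self, mol: MoleculeGraph) -> None:
        """Check membership and path-ness against the owning molecule."""
        if mol.id != self.molecule_id:
            raise ValueError(f"string belongs to {self.molecule_id}, not {mol.id}")
        for a in self.atoms:
            mol.atom(a)
        for a, b in zip(self.atoms, self.atoms[1:]):
            if not mol.has_bond(a, b):
                raise ValueError(f"{mol.id}: atoms {a} and {b} are not bonded")


def _distance_block(
    mol: MoleculeGraph, rows: Sequence[int], cols: Sequence[int]
) -> np.ndarray:
    d = mol.distances()
    return np.array([[d[r][c] for c in cols] for r in rows], dtype=int)


def self_dmaid(mol: MoleculeGraph, string: AtomString) -> np.ndarray:
    """Square matrix of whole-molecule distances among the string's atoms."""
    string.validate(mol)
    return _distance_block(mol, string.atoms, string.atoms)


def anchored_dmaid(
    mol: MoleculeGraph, string: AtomString, anchor: AtomString
) -> np.ndarray:
    """|string| x |anchor| matrix of distances from string atoms to anchor atoms."""
    string.validate(mol)
    anchor.validate(mol)
    return _distance_block(mol, string.atoms, anchor.atoms)


def dmaid_equal(a: np.ndarray, b: np.ndarray) -> bool:
    """Entry-wise equality with shape check; no permutation search.

    Row/column order is fixed by string order, so topological identity of
    two strings reduces to plain matrix equality.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    return a.shape == b.shape and bool(np.array_equal(a, b))
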