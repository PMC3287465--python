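"""Molecular graph data model, KCF I/O, and distance/ring machinery.

Molecules are hydrogen-suppressed labeled graphs in the KEGG KCF
representation: vertices are heavy atoms carrying a hierarchical KEGG atom
type (e.g. ``C8y``: species ``C``, atom class ``C8``, full type ``C8y``),
edges carry bond orders.  Every downstream stage of the alignment consumes
only three things from this module: the atom labels at one of the three
hierarchy levels, all-pairs shortest-path distances (bond counts), and
per-atom counts of ring bonds.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx

__all__ = [
    "Level",
    "Atom",
    "Bond",
    "MoleculeGraph",
    "KCFParseError",
    "label_at_level",
    "parse_kcf",
    "write_kcf",
    "all_pairs_distances",
    "ring_bond_count",
]

_LABEL_RE = re.compile(r"^[A-Z][0-9A-Za-z]{1,3}$")


class Level(enum.Enum):
    """Hierarchy level of a KEGG atom label."""

    SPECIES = 1  # first letter, the element (C, N, O, ...)
    CLASS = 2    # first two letters, the orbital environment (C8, O2, ...)
    FULL = 3     # full type including neighbor context (C8y, O2a, ...)


def label_at_level(label: str, level: Level) -> str:
    """Truncate a KEGG atom label to the requested hierarchy level.

    The species is a prefix of the class, which is a prefix of the full
    label, so truncation is plain string slicing.
    """
    if not label:
        raise ValueError("empty KEGG atom label")
    if level is Level.SPECIES:
        return label[:1]
    if level is Level.CLASS:
        return label[:2]
    return label


@dataclass(frozen=True)
class Atom:
    """One heavy atom: 1-based KCF index, KEGG label, element symbol."""

    index: int
    label: str
    element: str
    x: float = 0.0
    y: float = 0.0

    def __post_init__(self) -> None:
        if not _LABEL_RE.match(self.label):
            raise ValueError(f"malformed KEGG atom label {self.label!r}")
        if self.element != label_at_level(self.label, Level.SPECIES):
            raise ValueError(
                f"element {self.element!r} does not match label {self.label!r}"
            )


@dataclass(frozen=True)
class Bond:
    """Undirected bond between two atom indices with an integer order."""

    a: int
    b: int
    order: int = 1

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError(f"self-bond on atom {self.a}")
        if self.order < 1:
            raise ValueError(f"bond order must be >= 1, got {self.order}")

    @property
    def pair(self) -> tuple[int, int]:
        return (self.a, self.b) if self.a < self.b else (self.b, self.a)


class KCFParseError(ValueError):
    """Raised for malformed KCF input; carries entry id and line number."""

    def __init__(self, message: str, entry: str | None = None, line: int | None = None):
        loc = []
        if entry:
            loc.append(f"entry {entry}")
        if line is not None:
            loc.append(f"line {line}")
        super().__init__(f"{message} ({', '.join(loc)})" if loc else message)
        self.entry = entry
        self.line = line


class MoleculeGraph:
    """A connected hydrogen-suppressed molecule with KEGG-typed atoms.

    Parameters
    ----------
    id
        Compound identifier (e.g. a KEGG Compound ID such as ``C00482``).
    atoms, bonds
        Atom and bond records; atom indices must be unique, bonds must
        reference existing atoms, and the resulting graph must be a single
        connected component (all distance machinery assumes finiteness).
    """

    def __init__(self, id: str, atoms: Iterable[Atom], bonds: Iterable[Bond]):
        self.id = id
        self._atoms: dict[int, Atom] = {}
        for atom in atoms:
            if atom.index in self._atoms:
                raise KCFParseError(f"duplicate atom index {atom.index}", entry=id)
            self._atoms[atom.index] = atom
        if not self._atoms:
            raise KCFParseError("molecule has no atoms", entry=id)
        self._bonds: list[Bond] = []
        seen_pairs: set[tuple[int, int]] = set()
        for bond in bonds:
            for end in (bond.a, bond.b):
                if end not in self._atoms:
                    raise KCFParseError(
                        f"bond references missing atom {end}", entry=id
                    )
            if bond.pair in seen_pairs:
                raise KCFParseError(f"duplicate bond {bond.pair}", entry=id)
            seen_pairs.add(bond.pair)
            self._bonds.append(bond)

        g = nx.Graph()
        g.add_nodes_from(self._atoms)
        g.add_edges_from((b.a, b.b) for b in self._bonds)
        if not nx.is_connected(g):
            raise KCFParseError("molecule graph is disconnected", entry=id)
        self._graph = g
        self._distances: dict[int, dict[int, int]] | None = None
        self._ring_bonds: dict[int, int] | None = None

    # -- basic accessors ---------------------------------------------------

    @property
    def atoms(self) -> Sequence[Atom]:
        return tuple(self._atoms[i] for i in sorted(self._atoms))

    @property
    def bonds(self) -> Sequence[Bond]:
        return tuple(self._bonds)

    @property
    def atom_indices(self) -> tuple[int, ...]:
        return tuple(sorted(self._atoms))

    def __len__(self) -> int:
        return len(self._atoms)

    def atom(self, index: int) -> Atom:
        try:
            return self._atoms[index]
        except KeyError:
            raise KeyError(f"{self.id}: no atom with index {index}") from None

    def label(self, index: int, level: Level = Level.FULL) -> str:
        return label_at_level(self.atom(index).label, level)

    def neighbors(self, index: int) -> tuple[int, ...]:
        self.atom(index)
        return tuple(sorted(self._graph.neighbors(index)))

    def has_bond(self, a: int, b: int) -> bool:
        return self._graph.has_edge(a, b)

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    # -- distances and rings -----------------------------------------------

    def distances(self) -> Mapping[int, Mapping[int, int]]:
        """All-pairs shortest-path bond counts, BFS-exact, computed once."""
        if self._distances is None:
            self._distances = {
                src: dict(dists)
                for src, dists in nx.all_pairs_shortest_path_length(self._graph)
            }
        return self._distances

    def distance(self, a: int, b: int) -> int:
        self.atom(a)
        self.atom(b)
        return self.distances()[a][b]

    def eccentricity(self, index: int) -> int:
        return max(self.distances()[index].values())

    def ring_bond_count(self, index: int) -> int:
        """Number of bonds at this atom that lie on at least one cycle.

        A bond is a ring bond iff it is not a bridge of the graph.
        """
        self.atom(index)
        if self._ring_bonds is None:
            bridges = set(frozenset(e) for e in nx.bridges(self._graph))
            counts = dict.fromkeys(self._atoms, 0)
            for bond in self._bonds:
                if frozenset(bond.pair) not in bridges:
                    counts[bond.a] += 1
                    counts[bond.b] += 1
            self._ring_bonds = counts
        return self._ring_bonds[index]

    # -- misc ---------------------------------------------------------------

    def relabel(self, mapping: Mapping[int, int], id: str | None = None) -> "MoleculeGraph":
        """Return a copy with atom indices renumbered through ``mapping``."""
        atoms = [
            Atom(mapping[a.index], a.label, a.element, a.x, a.y) for a in self.atoms
        ]
        bonds = [Bond(mapping[b.a], mapping[b.b], b.order) for b in self._bonds]
        return MoleculeGraph(id or self.id, atoms, bonds)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MoleculeGraph):
            return NotImplemented
        return (
            self.id == other.id
            and self.atoms == other.atoms
            and set(b.pair + (b.order,) for b in self._bonds)
            == set(b.pair + (b.order,) for b in other._bonds)
        )

    def __repr__(self) -> str:
        return f"MoleculeGraph({self.id!r}, {len(self)} atoms, {len(self._bonds)} bonds)"


# -- module-level functional surface ---------------------------------------

def all_pairs_distances(mol: MoleculeGraph) -> Mapping[int, Mapping[int, int]]:
    """Whole-molecule shortest-path distance matrix (cached on the molecule)."""
    return mol.distances()


def ring_bond_count(mol: MoleculeGraph, atom_index: int) -> int:
    return mol.ring_bond_count(atom_index)


# -- KCF I/O ----------------------------------------------------------------

def parse_kcf(text: str) -> list[MoleculeGraph]:
    """Parse a KCF document (one or more ``///``-terminated entries).

    Accepted dialect (whitespace-delimited, fixed-column tolerant)::

        ENTRY       C00482    Compound
        ATOM        16
                    1  C8y C 0.0 0.0
                    ...
        BOND        16
                    1  1 2 2
                    ...
        ///
    """
    mols: list[MoleculeGraph] = []
    lines = text.splitlines()
    i, n = 0, len(lines)
    while i < n:
        # skip blank lines, comments, and entry separators between entries
        stripped = lines[i].strip()
        if not stripped or stripped == "///" or stripped.startswith("#"):
            i += 1
            continue
        fields = lines[i].split()
        if fields[0] != "ENTRY" or len(fields) < 2:
            raise KCFParseError(f"expected ENTRY line, got {lines[i]!r}", line=i + 1)
        entry_id = fields[1]
        i += 1
        atoms: list[Atom] = []
        bonds: list[Bond] = []
        saw_atom = saw_bond = False
        while i < n and lines[i].strip() != "///":
            fields = lines[i].split()
            if not fields:
                i += 1
                continue
            if fields[0] == "ATOM":
                saw_atom = True
                try:
                    count = int(fields[1])
                except (IndexError, ValueError):
                    raise KCFParseError("malformed ATOM count", entry_id, i + 1)
                for k in range(count):
                    i += 1
                    if i >= n:
                        raise KCFParseError("truncated ATOM block", entry_id, i)
                    f = lines[i].split()
                    if len(f) < 3:
                        raise KCFParseError(
                            f"malformed ATOM line {lines[i]!r}", entry_id, i + 1
                        )
                    try:
                        idx = int(f[0])
                        x = float(f[3]) if len(f) > 3 else 0.0
                        y = float(f[4]) if len(f) > 4 else 0.0
                        atoms.append(Atom(idx, f[1], f[2], x, y))
                    except ValueError as exc:
                        raise KCFParseError(str(exc), entry_id, i + 1) from exc
                i += 1
            elif fields[0] == "BOND":
                saw_bond = True
                try:
                    count = int(fields[1])
                except (IndexError, ValueError):
                    raise KCFParseError("malformed BOND count", entry_id, i + 1)
                for k in range(count):
                    i += 1
                    if i >= n:
                        raise KCFParseError("truncated BOND block", entry_id, i)
                    f = lines[i].split()
                    if len(f) < 3:
                        raise KCFParseError(
                            f"malformed BOND line {lines[i]!r}", entry_id, i + 1
                        )
                    try:
                        order = int(f[3]) if len(f) > 3 else 1
                        bonds.append(Bond(int(f[1]), int(f[2]), order))
                    except ValueError as exc:
                        raise KCFParseError(str(exc), entry_id, i + 1) from exc
                i += 1
            else:
                # unknown block line (e.g. continuation of a header) — skip
                i += 1
        if i < n:
            i += 1  # consume ///
        if not saw_atom or not saw_bond:
            raise KCFParseError("entry lacks ATOM or BOND block", entry_id)
        mols.append(MoleculeGraph(entry_id, atoms, bonds))
    if not mols:
        raise KCFParseError("no KCF entries found in input")
    return mols


def write_kcf(mols: MoleculeGraph | Iterable[MoleculeGraph]) -> str:
    """Serialize molecules to KCF text; inverse of :func:`parse_kcf`."""
    if isinstance(mols, MoleculeGraph):
        mols = [mols]
    out: list[str] = []
    for mol in mols:
        out.append(f"ENTRY       {mol.id}    Compound")
        out.append(f"ATOM        {len(mol)}")
        for atom in mol.atoms:
            out.append(
                f"            {atom.index:<4d}{atom.label:<5s}{atom.element:<3s}"
                f"{atom.x:>9.4f} {atom.y:>9.4f}"
            )
        out.append(f"BOND        {len(mol.bonds)}")
        for k, bond in enumerate(mol.bonds, 1):
            out.append(f"            {k:<4d}{bond.a:>4d}{bond.b:>4d} {bond.order}")
        out.append("///")
    return "\n".join(out) + "\n"
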