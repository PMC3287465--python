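"""Stage 2: grow the seed alignment into the shared core substructure.

The seed strings are already aligned position-by-position.  Extension then
repeats a simple frontier step: collect the atoms adjacent to the current
core in each molecule, group them by *atom species* together with their
anchored DMAID against the current core columns, and promote a group to a
new core column when it names exactly one atom in every query molecule.
Groups that are still ambiguous go through a disambiguation cascade —
ring-bond counts, then atom classes, then full KEGG atom types, and as a
last resort (pure topological symmetry) pairing by ascending atom index.
Growth is monotone and stops at a fixpoint, so the core is one connected
substructure per molecule, grown out of a path seed.

With exactly two query molecules the pipeline stops after this stage; the
branch stage only exists to find substructures shared by *subsets* of a
larger query.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

from .chemgraph import Level, MoleculeGraph
from .config import AlignConfig
from .decaf import ScoreCache
from .lcas import SeedAlignment, find_lcas, select_representative

__all__ = [
    "CORE",
    "BRANCH",
    "AlignmentColumn",
    "MultipleAlignment",
    "extend_core",
    "disambiguate",
    "align_pairwise_stop",
]

CORE = "core"
BRANCH = "branch"


@dataclass(frozen=True)
class AlignmentColumn:
    """One atom-atom mapping: molecule id -> atom index, plus its role."""

    cells: dict[str, int] = field(hash=False)
    role: str = CORE
    group: int | None = None
    provenance: str = ""

    def atoms(self) -> set[tuple[str, int]]:
        return {(m, a) for m, a in self.cells.items()}


@dataclass
class MultipleAlignment:
    """Ordered alignment columns over a fixed set of query molecules."""

    molecules: tuple[MoleculeGraph, ...]
    columns: list[AlignmentColumn]
    config: AlignConfig = field(default_factory=AlignConfig)

    @property
    def molecule_ids(self) -> tuple[str, ...]:
        return tuple(m.id for m in self.molecules)

    def core_columns(self) -> list[AlignmentColumn]:
        return [c for c in self.columns if c.role == CORE]

    def branch_columns(self) -> list[AlignmentColumn]:
        return [c for c in self.columns if c.role == BRANCH]

    def used_atoms(self, mol_id: str) -> set[int]:
        return {c.cells[mol_id] for c in self.columns if mol_id in c.cells}

    def validate(self) -> None:
        """Assert global conflict-freeness and core completeness."""
        ids = set(self.molecule_ids)
        seen: set[tuple[str, int]] = set()
        for col in self.columns:
            if col.role == CORE and set(col.cells) != ids:
                raise AssertionError("core column missing a molecule")
            for cell in col.atoms():
                if cell in seen:
                    raise AssertionError(f"atom {cell} appears in two columns")
                seen.add(cell)


def _anchor_vector(mol: MoleculeGraph, atom: int, core_atoms: Sequence[int]) -> tuple[int, ...]:
    """Anchored DMAID of a single atom against the core columns, in column order."""
    d = mol.distances()[atom]
    return tuple(d[c] for c in core_atoms)


# disambiguation stages, applied cumulatively in this order
_STAGES: list[tuple[str, Callable[[MoleculeGraph, int], object]]] = [
    ("ring-bonds", lambda mol, a: mol.ring_bond_count(a)),
    ("atom-class", lambda mol, a: mol.label(a, Level.CLASS)),
    ("kegg-atom", lambda mol, a: mol.label(a, Level.FULL)),
]


def disambiguate(
    by_id: dict[str, MoleculeGraph],
    group: dict[str, list[int]],
    provenance: str = "extension",
) -> list[tuple[dict[str, int], str]]:
    """Resolve a (species, anchored-DMAID) group into one-atom-per-molecule columns.

    Applies, in order: ring-bond counts, atom classes, full KEGG atom
    types, and finally index-order pairing; stops at the first stage that
    makes each (sub)group unambiguous.  Subgroups that stop spanning every
    member molecule, or end with unequal candidate counts, are dropped.
    """
    return _cascade(by_id, group, 0, provenance)


def _cascade(
    by_id: dict[str, MoleculeGraph],
    group: dict[str, list[int]],
    stage: int,
    provenance: str,
) -> list[tuple[dict[str, int], str]]:
    if all(len(v) == 1 for v in group.values()):
        return [({m: v[0] for m, v in group.items()}, provenance)]
    if stage >= len(_STAGES):
        counts = {len(v) for v in group.values()}
        if len(counts) != 1:
            return []  # unequal multiplicities: conservative rejection
        width = counts.pop()
        return [
            ({m: sorted(v)[i] for m, v in group.items()}, "index-order")
            for i in range(width)
        ]
    name, keyf = _STAGES[stage]
    members = set(group)
    sub: dict[object, dict[str, list[int]]] = {}
    for mol_id, atoms in group.items():
        mol = by_id[mol_id]
        for a in atoms:
            sub.setdefault(keyf(mol, a), {}).setdefault(mol_id, []).append(a)
    out: list[tuple[dict[str, int], str]] = []
    refined = len(sub) > 1
    for sk in sorted(sub, key=repr):
        g2 = sub[sk]
        if set(g2) == members:
            out.extend(_cascade(by_id, g2, stage + 1, name if refined else provenance))
        # subgroups missing a molecule are dropped from the core
    return out


def extend_core(
    mols: Sequence[MoleculeGraph],
    seed: SeedAlignment,
    cfg: AlignConfig | None = None,
) -> MultipleAlignment:
    """Iterative frontier growth of the core from the seed alignment.

    Each pass re-anchors candidates against the *current* core (anchored
    DMAID columns follow core-column creation order), promotes every group
    that resolves to one atom per molecule, and terminates when a pass
    adds nothing.
    """
    cfg = cfg or AlignConfig()
    by_id = {m.id: m for m in mols}
    ids = set(by_id)
    if set(seed.strings) != ids:
        raise ValueError("seed alignment does not cover the query molecules")

    columns = [
        AlignmentColumn(cells=col, role=CORE, provenance="seed")
        for col in seed.columns()
    ]
    used: dict[str, set[int]] = {
        m: {c.cells[m] for c in columns} for m in ids
    }

    while True:
        core_atoms = {m: [c.cells[m] for c in columns] for m in ids}
        # frontier: atoms adjacent to the core, not yet aligned
        groups: dict[tuple[str, tuple[int, ...]], dict[str, list[int]]] = {}
        for mol_id in ids:
            mol = by_id[mol_id]
            frontier = sorted(
                {
                    nb
                    for a in core_atoms[mol_id]
                    for nb in mol.neighbors(a)
                    if nb not in used[mol_id]
                }
            )
            for atom in frontier:
                key = (
                    mol.label(atom, Level.SPECIES),
                    _anchor_vector(mol, atom, core_atoms[mol_id]),
                )
                groups.setdefault(key, {}).setdefault(mol_id, []).append(atom)

        added = False
        for key in sorted(groups):
            group = groups[key]
            if set(group) != ids:
                continue  # some molecule lacks this neighborhood: discard
            # drop candidates claimed earlier in this same pass
            group = {
                m: [a for a in atoms if a not in used[m]]
                for m, atoms in group.items()
            }
            if any(not atoms for atoms in group.values()):
                continue
            for cells, prov in disambiguate(by_id, group):
                columns.append(AlignmentColumn(cells=cells, role=CORE, provenance=prov))
                for m, a in cells.items():
                    used[m].add(a)
                added = True
        if not added:
            break

    aln = MultipleAlignment(tuple(mols), columns, cfg)
    aln.validate()
    return aln


def align_pairwise_stop(
    mols: Sequence[MoleculeGraph],
    cfg: AlignConfig | None = None,
    cache: ScoreCache | None = None,
) -> MultipleAlignment:
    """Two-molecule alignment: seed, extend the core, and stop.

    With only two molecules the branch stage is skipped entirely and the
    core atom-atom mapping is the final output.
    """
    if len(mols) != 2:
        raise ValueError("align_pairwise_stop requires exactly two molecules")
    cfg = cfg or AlignConfig()
    cache = cache or ScoreCache()
    sets = find_lcas(mols)
    if not sets:
        return MultipleAlignment(tuple(mols), [], cfg)
    seed = select_representative(mols, sets, cfg, cache)
    return extend_core(mols, seed, cfg)
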