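"""Stage 3: position-aware branch substructures ("building blocks").

After the core is frozen, the atoms outside it are searched for *short
common atom strings* (SCAS): simple paths over non-core atoms that agree,
across at least ``min_support`` molecules, on their atom-species sequence
and on their anchored DMAID against the core columns.  Matching is
deliberately looser than the seed stage (species-level labels instead of
full KEGG atoms) because branch groups model substituents transferred as a
unit, whose internal typing may drift between molecules; the anchored
DMAID still pins the attachment position, so chemically identical residues
hanging at different core positions are kept apart.

Each SCAS is grown sideways with the same grouping machinery as the core
(restricted to its member molecules and to non-core atoms).  Because SCAS
are found independently they may claim the same atom; a randomized greedy
pass — random column order, accept-if-disjoint, best of ``restarts``
shuffles by total aligned atoms — resolves the conflicts.  Surviving
columns that are mutually adjacent in every member molecule are merged
into one branch group.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Sequence

from .chemgraph import Level, MoleculeGraph
from .config import AlignConfig
from .corealign import (
    BRANCH,
    CORE,
    AlignmentColumn,
    MultipleAlignment,
    disambiguate,
)
from .dmaid import AtomString

__all__ = [
    "ScasSeed",
    "BranchGroup",
    "find_scas",
    "extend_branch",
    "remove_conflicts",
    "group_branches",
    "branch_stage",
]

# (species label sequence, anchored-DMAID rows vs core) — branch string identity
ScasKey = tuple[tuple[str, ...], tuple[tuple[int, ...], ...]]


@dataclass(frozen=True)
class ScasSeed:
    """One matched branch string across its member molecules."""

    key: ScasKey
    strings: dict[str, AtomString] = field(hash=False)

    @property
    def members(self) -> tuple[str, ...]:
        return tuple(sorted(self.strings))

    def columns(self) -> list[dict[str, int]]:
        return [
            {m: s.atoms[p] for m, s in self.strings.items()}
            for p in range(len(self.key[0]))
        ]


@dataclass(frozen=True)
class BranchGroup:
    """A building block: adjacent branch columns sharing one member set."""

    group_id: int
    members: tuple[str, ...]
    columns: tuple[AlignmentColumn, ...] = field(hash=False)

    @property
    def n_atoms(self) -> int:
        return sum(len(c.cells) for c in self.columns)


def _directed_key(
    mol: MoleculeGraph, s: AtomString, core_atoms: Sequence[int]
) -> ScasKey:
    d = mol.distances()
    rows = tuple(tuple(d[a][c] for c in core_atoms) for a in s.atoms)
    return (s.labels(mol, Level.SPECIES), rows)


def _canonical_key(mol, s, core_atoms) -> ScasKey:
    return min(
        _directed_key(mol, s, core_atoms),
        _directed_key(mol, s.reverse(), core_atoms),
    )


def _oriented(mol, s, key, core_atoms) -> AtomString:
    fwd = _directed_key(mol, s, core_atoms)
    rev = _directed_key(mol, s.reverse(), core_atoms)
    if fwd == key and rev == key:
        return min(s, s.reverse(), key=lambda t: t.atoms)
    return s if fwd == key else s.reverse()


def find_scas(
    mols: Sequence[MoleculeGraph],
    core: MultipleAlignment,
    cfg: AlignConfig | None = None,
) -> list[ScasSeed]:
    """Level-wise search for branch seed strings over non-core atoms.

    A string identity is kept while at least ``cfg.min_support`` molecules
    contain it; it is emitted once no one-atom extension preserves its
    member-molecule set, so a long string shared by few molecules and its
    shorter, more widely shared parent can both seed branches.  Identities
    with several instances in one molecule are paired in ascending
    atom-index order, one instance set per rank.
    """
    cfg = cfg or AlignConfig()
    by_id = {m.id: m for m in mols}
    core_atoms = {
        mid: [c.cells[mid] for c in core.core_columns()] for mid in by_id
    }
    non_core = {
        mid: [a for a in by_id[mid].atom_indices if a not in set(core_atoms[mid])]
        for mid in by_id
    }

    current: dict[str, list[AtomString]] = {
        mid: [AtomString(mid, (a,)) for a in atoms] for mid, atoms in non_core.items()
    }
    keyed = _filter_support(by_id, current, core_atoms, cfg.min_support)
    emitted: dict[ScasKey, dict[str, set[AtomString]]] = {}
    while keyed:
        extended_keys: set[ScasKey] = set()
        children: dict[str, list[tuple[ScasKey, AtomString]]] = {mid: [] for mid in by_id}
        for key, per_mol in keyed.items():
            for mid, strings in per_mol.items():
                mol = by_id[mid]
                blocked = set(core_atoms[mid])
                for s in strings:
                    tail = s.atoms[-1]
                    for nb in mol.neighbors(tail):
                        if nb not in s.atoms and nb not in blocked:
                            children[mid].append(
                                (key, AtomString(mid, s.atoms + (nb,)))
                            )
        child_strings = {mid: [s for _, s in pairs] for mid, pairs in children.items()}
        child_keyed = _filter_support(by_id, child_strings, core_atoms, cfg.min_support)
        # a parent key is superseded only by a child covering the same members
        surviving = {
            mid: {s.atoms for ck in child_keyed.values() for s in ck.get(mid, ())}
            for mid in by_id
        }
        for mid, pairs in children.items():
            for parent_key, child in pairs:
                if child.atoms in surviving[mid]:
                    ck = _canonical_key(by_id[mid], child, core_atoms[mid])
                    if set(child_keyed[ck]) >= set(keyed[parent_key]):
                        extended_keys.add(parent_key)
        for key, per_mol in keyed.items():
            if key not in extended_keys:
                tgt = emitted.setdefault(key, {})
                for mid, strings in per_mol.items():
                    tgt.setdefault(mid, set()).update(strings)
        keyed = child_keyed

    seeds: list[ScasSeed] = []
    for key in sorted(emitted):
        per_mol = {
            mid: sorted(strings, key=lambda s: s.atoms)
            for mid, strings in emitted[key].items()
        }
        width = max(len(v) for v in per_mol.values())
        for i in range(width):
            members = {mid: v[i] for mid, v in per_mol.items() if len(v) > i}
            if len(members) >= cfg.min_support:
                seeds.append(ScasSeed(key, members))
    return seeds


def _filter_support(
    by_id: dict[str, MoleculeGraph],
    strings: dict[str, list[AtomString]],
    core_atoms: dict[str, list[int]],
    min_support: int,
) -> dict[ScasKey, dict[str, set[AtomString]]]:
    table: dict[ScasKey, dict[str, set[AtomString]]] = {}
    for mid, ss in strings.items():
        mol = by_id[mid]
        for s in ss:
            key = _canonical_key(mol, s, core_atoms[mid])
            table.setdefault(key, {}).setdefault(mid, set()).add(
                _oriented(mol, s, key, core_atoms[mid])
            )
    return {k: v for k, v in table.items() if len(v) >= min_support}


def extend_branch(
    mols: Sequence[MoleculeGraph],
    core: MultipleAlignment,
    seed: ScasSeed,
    cfg: AlignConfig | None = None,
) -> list[AlignmentColumn]:
    """Grow one SCAS into a branch substructure candidate.

    Same frontier machinery as the core extension, but restricted to the
    seed's member molecules and to non-core atoms; candidates are anchored
    against the core columns plus the branch columns grown so far.
    """
    cfg = cfg or AlignConfig()
    by_id = {m.id: m for m in mols if m.id in seed.strings}
    members = set(by_id)
    core_atoms = {
        mid: [c.cells[mid] for c in core.core_columns()] for mid in members
    }
    columns = [
        AlignmentColumn(cells=col, role=BRANCH, provenance="scas")
        for col in seed.columns()
    ]
    used = {mid: set(core_atoms[mid]) for mid in members}
    for col in columns:
        for mid, a in col.cells.items():
            used[mid].add(a)

    while True:
        anchor = {
            mid: core_atoms[mid] + [c.cells[mid] for c in columns] for mid in members
        }
        groups: dict[tuple[str, tuple[int, ...]], dict[str, list[int]]] = {}
        for mid in members:
            mol = by_id[mid]
            branch_atoms = [c.cells[mid] for c in columns]
            frontier = sorted(
                {
                    nb
                    for a in branch_atoms
                    for nb in mol.neighbors(a)
                    if nb not in used[mid]
                }
            )
            d = mol.distances()
            for atom in frontier:
                key = (
                    mol.label(atom, Level.SPECIES),
                    tuple(d[atom][c] for c in anchor[mid]),
                )
                groups.setdefault(key, {}).setdefault(mid, []).append(atom)
        added = False
        for key in sorted(groups):
            group = groups[key]
            if set(group) != members:
                continue
            group = {m: [a for a in v if a not in used[m]] for m, v in group.items()}
            if any(not v for v in group.values()):
                continue
            for cells, prov in disambiguate(by_id, group):
                columns.append(
                    AlignmentColumn(cells=cells, role=BRANCH, provenance=prov)
                )
                for m, a in cells.items():
                    used[m].add(a)
                added = True
        if not added:
            break
    return columns


def remove_conflicts(
    columns: Sequence[AlignmentColumn],
    restarts: int = 20,
    rng: random.Random | None = None,
) -> list[AlignmentColumn]:
    """Randomized greedy selection of mutually disjoint columns.

    Per restart: shuffle the columns, then accept each column unless it
    shares an atom with one already accepted; score a restart by the total
    number of atoms accepted and return the best of ``restarts`` shuffles.
    Deterministic under a fixed ``rng``.
    """
    rng = rng or random.Random(0)
    cols = list(columns)
    best: list[AlignmentColumn] | None = None
    best_score = -1
    for _ in range(max(1, restarts)):
        order = cols[:]
        rng.shuffle(order)
        taken: list[AlignmentColumn] = []
        occupied: set[tuple[str, int]] = set()
        for col in order:
            cells = col.atoms()
            if cells & occupied:
                continue
            taken.append(col)
            occupied |= cells
        score = sum(len(c.cells) for c in taken)
        if score > best_score:
            best, best_score = taken, score
    assert best is not None
    # restore deterministic order for downstream grouping
    index = {id(c): i for i, c in enumerate(cols)}
    return sorted(best, key=lambda c: index[id(c)])


def group_branches(
    mols: Sequence[MoleculeGraph], columns: Sequence[AlignmentColumn]
) -> tuple[list[AlignmentColumn], list[BranchGroup]]:
    """Merge adjacent conflict-free branch columns into building blocks.

    Two columns join one group when they cover the same member molecules
    and their atoms are bonded in every one of them; connected components
    of that relation are the groups.  Ids are assigned deterministically
    by (descending size, lexical cell order).
    """
    by_id = {m.id: m for m in mols}
    cols = list(columns)
    n = len(cols)
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = cols[i], cols[j]
            if set(a.cells) != set(b.cells):
                continue
            if all(
                by_id[mid].has_bond(a.cells[mid], b.cells[mid]) for mid in a.cells
            ):
                adj[i].add(j)
                adj[j].add(i)
    # connected components
    comp: dict[int, int] = {}
    for start in range(n):
        if start in comp:
            continue
        stack, cid = [start], start
        while stack:
            v = stack.pop()
            if v in comp:
                continue
            comp[v] = cid
            stack.extend(adj[v] - comp.keys())
    groups_raw: dict[int, list[int]] = {}
    for i, cid in comp.items():
        groups_raw.setdefault(cid, []).append(i)

    def signature(idxs: list[int]):
        cells = sorted(
            tuple(sorted(cols[i].cells.items())) for i in idxs
        )
        return (-sum(len(cols[i].cells) for i in idxs), cells)

    ordered = sorted(groups_raw.values(), key=signature)
    out_cols: list[AlignmentColumn] = []
    groups: list[BranchGroup] = []
    for gid, idxs in enumerate(ordered, start=1):
        gcols = tuple(
            AlignmentColumn(cols[i].cells, BRANCH, gid, cols[i].provenance)
            for i in sorted(idxs)
        )
        out_cols.extend(gcols)
        groups.append(
            BranchGroup(gid, tuple(sorted(gcols[0].cells)), gcols)
        )
    return out_cols, groups


def branch_stage(
    mols: Sequence[MoleculeGraph],
    core: MultipleAlignment,
    cfg: AlignConfig | None = None,
) -> tuple[MultipleAlignment, list[BranchGroup]]:
    """Full branch stage: SCAS search, extension, conflict removal, grouping."""
    cfg = cfg or AlignConfig()
    seeds = find_scas(mols, core, cfg)
    candidates: list[AlignmentColumn] = []
    for seed in seeds:
        candidates.extend(extend_branch(mols, core, seed, cfg))
    rng = random.Random(cfg.seed)
    kept = remove_conflicts(candidates, cfg.conflict_restarts, rng)
    branch_cols, groups = group_branches(mols, kept)
    aln = MultipleAlignment(
        tuple(mols), core.core_columns() + branch_cols, cfg
    )
    aln.validate()
    return aln, groups
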