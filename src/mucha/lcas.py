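"""Longest common atom strings (LCAS): the seed of the multiple alignment.

Stage 1 of the alignment finds the longest atom string — a simple path —
that occurs in *every* query molecule with the same full KEGG label
sequence and the same self-DMAID.  The search is level-wise, mirroring a
breadth-first queue: every atom starts as a length-1 string; strings whose
identity key is missing from any molecule are discarded; survivors are
extended by one bonded neighbor of their terminal atom; the last level
with survivors holds the LCAS.  Because every direction of a common string
is itself generated from its own (also common) prefixes, terminal-only
extension loses nothing, and mirror traversals are collapsed into one
canonical string.

When a molecule holds several maximal strings, one *representative* per
molecule is chosen to maximize the summed pairwise DECAF similarity of
the aligned positions — exhaustively when the combination count is small,
otherwise with a seeded genetic algorithm.
"""

from __future__ import annotations

import itertools
import math
import random
from dataclasses import dataclass, field
from typing import Sequence

from .chemgraph import Level, MoleculeGraph
from .config import AlignConfig
from .decaf import ScoreCache, string_decaf_score
from .dmaid import AtomString, self_dmaid

__all__ = [
    "StringKey",
    "CommonStringSet",
    "SeedAlignment",
    "canonical_orientation",
    "string_key",
    "find_lcas",
    "select_representative",
]

# (label sequence, self-DMAID rows) — hashable topological identity of a string
StringKey = tuple[tuple[str, ...], tuple[tuple[int, ...], ...]]


def _directed_key(mol: MoleculeGraph, s: AtomString) -> StringKey:
    return (s.labels(mol), tuple(map(tuple, self_dmaid(mol, s))))


def string_key(mol: MoleculeGraph, s: AtomString) -> StringKey:
    """Orientation-independent identity key: labels + self-DMAID.

    The smaller of the two directed (labels, DMAID) pairs is used, so the
    key is comparable across molecules regardless of traversal direction
    or local atom numbering.
    """
    return min(_directed_key(mol, s), _directed_key(mol, s.reverse()))


def canonical_orientation(mol: MoleculeGraph, s: AtomString) -> AtomString:
    """Return ``s`` or its reversal, whichever compares smaller.

    Comparison is on the (full-label sequence, atom-index sequence) pair;
    idempotent, and identical for a string and its mirror.
    """
    r = s.reverse()
    return min(s, r, key=lambda t: (t.labels(mol), t.atoms))


def _oriented_for_key(mol: MoleculeGraph, s: AtomString, key: StringKey) -> AtomString:
    """Orient an instance so its directed key equals the canonical key."""
    fwd, rev = _directed_key(mol, s), _directed_key(mol, s.reverse())
    if fwd == key and rev == key:
        return canonical_orientation(mol, s)  # palindromic key: index tie-break
    return s if fwd == key else s.reverse()


@dataclass(frozen=True)
class CommonStringSet:
    """All instances of one string identity across the query molecules."""

    key: StringKey
    instances: dict[str, tuple[AtomString, ...]] = field(hash=False)

    @property
    def length(self) -> int:
        return len(self.key[0])


@dataclass(frozen=True)
class SeedAlignment:
    """One chosen string per molecule, all sharing one StringKey.

    Column ``p`` of the seed alignment maps molecule ``m`` to
    ``strings[m].atoms[p]``.
    """

    key: StringKey
    strings: dict[str, AtomString] = field(hash=False)
    objective: float = 0.0

    @property
    def length(self) -> int:
        return len(self.key[0])

    def columns(self) -> list[dict[str, int]]:
        return [
            {m: s.atoms[p] for m, s in self.strings.items()}
            for p in range(self.length)
        ]


def find_lcas(mols: Sequence[MoleculeGraph]) -> list[CommonStringSet]:
    """Level-wise search for the longest strings common to all molecules.

    Returns every maximal-length common string identity with its instances
    per molecule (canonically oriented, mirrors collapsed); empty when the
    molecules share no atom label at all.
    """
    if len(mols) < 2:
        raise ValueError("need at least two molecules to align")
    ids = [m.id for m in mols]
    if len(set(ids)) != len(ids):
        raise ValueError("molecule ids must be unique within a query")

    # level 1: every atom is a directed length-1 string
    directed: dict[str, list[AtomString]] = {
        m.id: [AtomString(m.id, (a,)) for a in m.atom_indices] for m in mols
    }
    by_id = {m.id: m for m in mols}

    survivors = _filter_common(by_id, directed)
    if not survivors:
        return []
    last = survivors
    while True:
        nxt: dict[str, list[AtomString]] = {m.id: [] for m in mols}
        for mol_id, strings in last.items():
            mol = by_id[mol_id]
            for s in strings:
                tail = s.atoms[-1]
                for nb in mol.neighbors(tail):
                    if nb not in s.atoms:
                        nxt[mol_id].append(AtomString(mol_id, s.atoms + (nb,)))
        longer = _filter_common(by_id, nxt)
        if not longer:
            break
        last = longer

    return _group(by_id, last)


def _filter_common(
    by_id: dict[str, MoleculeGraph], directed: dict[str, list[AtomString]]
) -> dict[str, list[AtomString]]:
    """Keep directed strings whose identity key occurs in every molecule."""
    keys_per_mol: dict[str, set[StringKey]] = {}
    keyed: dict[str, list[tuple[StringKey, AtomString]]] = {}
    for mol_id, strings in directed.items():
        mol = by_id[mol_id]
        pairs = [(string_key(mol, s), s) for s in strings]
        keyed[mol_id] = pairs
        keys_per_mol[mol_id] = {k for k, _ in pairs}
    common = set.intersection(*keys_per_mol.values()) if keys_per_mol else set()
    if not common:
        return {}
    return {
        mol_id: [s for k, s in pairs if k in common]
        for mol_id, pairs in keyed.items()
    }


def _group(
    by_id: dict[str, MoleculeGraph], survivors: dict[str, list[AtomString]]
) -> list[CommonStringSet]:
    """Group surviving directed strings by key, dedup mirrors, orient canonically."""
    table: dict[StringKey, dict[str, set[AtomString]]] = {}
    for mol_id, strings in survivors.items():
        mol = by_id[mol_id]
        for s in strings:
            key = string_key(mol, s)
            table.setdefault(key, {}).setdefault(mol_id, set()).add(
                _oriented_for_key(mol, s, key)
            )
    return [
        CommonStringSet(
            key, {m: tuple(sorted(insts, key=lambda s: s.atoms)) for m, insts in per_mol.items()}
        )
        for key, per_mol in sorted(table.items())
    ]


# -- representative selection ----------------------------------------------

def _objective(
    mols: dict[str, MoleculeGraph],
    choice: dict[str, AtomString],
    cache: ScoreCache,
) -> float:
    ids = sorted(choice)
    return sum(
        string_decaf_score(mols[a], choice[a], mols[b], choice[b], cache)
        for a, b in itertools.combinations(ids, 2)
    )


def select_representative(
    mols: Sequence[MoleculeGraph],
    sets: Sequence[CommonStringSet],
    cfg: AlignConfig | None = None,
    cache: ScoreCache | None = None,
) -> SeedAlignment:
    """Pick one string per molecule maximizing summed pairwise DECAF score.

    Each candidate identity (StringKey) is optimized separately — a seed
    alignment must share a single key — and the best-scoring key wins.
    Searches exhaustively while the combination count stays within
    ``cfg.exhaustive_limit``, else runs a seeded genetic algorithm.
    """
    if not sets:
        raise ValueError("no common strings to select a representative from")
    cfg = cfg or AlignConfig()
    cache = cache or ScoreCache()
    by_id = {m.id: m for m in mols}

    best: SeedAlignment | None = None
    for cs in sorted(sets, key=lambda c: c.key):
        mol_ids = sorted(cs.instances)
        options = [cs.instances[m] for m in mol_ids]
        n_combo = math.prod(len(o) for o in options)
        if n_combo <= cfg.exhaustive_limit:
            pick, score = _exhaustive(by_id, mol_ids, options, cache)
        else:
            pick, score = _genetic(by_id, mol_ids, options, cfg, cache)
        cand = SeedAlignment(cs.key, dict(zip(mol_ids, pick)), score)
        if best is None or cand.objective > best.objective:
            best = cand
    assert best is not None
    return best


def _exhaustive(by_id, mol_ids, options, cache):
    best_pick, best_score = None, -math.inf
    for combo in itertools.product(*options):
        choice = dict(zip(mol_ids, combo))
        score = _objective(by_id, choice, cache)
        if score > best_score:
            best_pick, best_score = combo, score
    return best_pick, best_score


def _genetic(by_id, mol_ids, options, cfg: AlignConfig, cache):
    """Tournament-selection GA over per-molecule instance indices."""
    rng = random.Random(cfg.seed)
    n_genes = len(options)
    sizes = [len(o) for o in options]

    def fitness(ind: tuple[int, ...]) -> float:
        choice = {m: options[g][i] for g, (m, i) in enumerate(zip(mol_ids, ind))}
        return _objective(by_id, choice, cache)

    pop = [
        tuple(rng.randrange(s) for s in sizes) for _ in range(cfg.ga_population)
    ]
    scored = sorted(((fitness(i), i) for i in pop), reverse=True)
    for _ in range(cfg.ga_generations):
        nxt = [ind for _, ind in scored[: cfg.ga_elitism]]
        while len(nxt) < cfg.ga_population:
            pa = _tournament(scored, rng, cfg.ga_tournament)
            pb = _tournament(scored, rng, cfg.ga_tournament)
            if n_genes > 1 and rng.random() < cfg.ga_crossover:
                cut = rng.randrange(1, n_genes)
                child = pa[:cut] + pb[cut:]
            else:
                child = pa
            child = tuple(
                rng.randrange(sizes[g]) if rng.random() < cfg.ga_mutation else c
                for g, c in enumerate(child)
            )
            nxt.append(child)
        scored = sorted(((fitness(i), i) for i in nxt), reverse=True)
    best_score, best_ind = scored[0]
    pick = tuple(options[g][i] for g, i in enumerate(best_ind))
    return pick, best_score


def _tournament(scored, rng: random.Random, k: int):
    contenders = [scored[rng.randrange(len(scored))] for _ in range(k)]
    return max(contenders)[1]
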