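"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately avoid the package's own machinery: distances come
from scipy's Floyd–Warshall on a dense adjacency matrix, and common-string
search is a brute-force enumeration of all simple paths.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.sparse.csgraph import floyd_warshall

from mucha import (
    MoleculeGraph,
    monolignol_panel,
    p_coumaryl_alcohol_glucoside,
    sinapic_acid,
)


@pytest.fixture(scope="session")
def c00482() -> MoleculeGraph:
    return sinapic_acid()


@pytest.fixture(scope="session")
def c05855() -> MoleculeGraph:
    return p_coumaryl_alcohol_glucoside()


@pytest.fixture(scope="session")
def panel() -> list[MoleculeGraph]:
    return monolignol_panel()


# -- oracles ----------------------------------------------------------------

def fw_distances(mol: MoleculeGraph) -> dict[int, dict[int, int]]:
    """All-pairs shortest paths by Floyd–Warshall (independent of BFS path)."""
    idx = list(mol.atom_indices)
    pos = {a: k for k, a in enumerate(idx)}
    adj = np.zeros((len(idx), len(idx)))
    for b in mol.bonds:
        adj[pos[b.a], pos[b.b]] = adj[pos[b.b], pos[b.a]] = 1
    dm = floyd_warshall(adj, directed=False, unweighted=True)
    return {
        a: {b: int(dm[pos[a], pos[b]]) for b in idx} for a in idx
    }


def all_simple_paths(mol: MoleculeGraph) -> list[tuple[int, ...]]:
    """Every simple path (length >= 1) in the molecule, by DFS from each atom."""
    paths: list[tuple[int, ...]] = []

    def grow(path: tuple[int, ...]) -> None:
        paths.append(path)
        for nb in mol.neighbors(path[-1]):
            if nb not in path:
                grow(path + (nb,))

    for a in mol.atom_indices:
        grow((a,))
    return paths


def oracle_string_key(mol: MoleculeGraph, path: tuple[int, ...], dists):
    """Orientation-minimal (labels, self-DMAID) identity, computed from scratch."""

    def directed(p):
        labels = tuple(mol.atom(a).label for a in p)
        dmaid = tuple(tuple(dists[a][b] for b in p) for a in p)
        return (labels, dmaid)

    return min(directed(path), directed(path[::-1]))


def oracle_lcas(mols: list[MoleculeGraph]) -> dict:
    """Brute-force longest-common-string search over all simple paths.

    Returns {key: {mol_id: set of canonical instance atom tuples}} for the
    maximal common length (empty dict when nothing is shared).
    """
    per_mol: list[dict] = []
    for mol in mols:
        dists = fw_distances(mol)
        table: dict = {}
        for path in all_simple_paths(mol):
            key = oracle_string_key(mol, path, dists)
            table.setdefault(key, set()).add(min(path, path[::-1]))
        per_mol.append(table)
    common = set(per_mol[0])
    for t in per_mol[1:]:
        common &= set(t)
    if not common:
        return {}
    top = max(len(k[0]) for k in common)
    return {
        key: {m.id: per_mol[i][key] for i, m in enumerate(mols)}
        for key in common
        if len(key[0]) == top
    }


def greedy_score(columns, order: tuple[int, ...]) -> int:
    """Greedy accept-if-disjoint score of one explicit column ordering."""
    occupied: set = set()
    score = 0
    for i in order:
        cells = set(columns[i].cells.items())
        if cells & occupied:
            continue
        occupied |= cells
        score += len(cells)
    return score


def best_ordering_score(columns) -> int:
    """Exhaustive maximum of the greedy score over all column orderings."""
    n = len(columns)
    return max(
        greedy_score(columns, order) for order in itertools.permutations(range(n))
    )
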