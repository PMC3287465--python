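"""Top-level driver: seed, core, and (for three or more molecules) branches."""

from __future__ import annotations

from typing import Sequence

from .branchalign import BranchGroup, branch_stage
from .chemgraph import MoleculeGraph
from .config import AlignConfig
from .corealign import MultipleAlignment, extend_core
from .decaf import ScoreCache
from .lcas import find_lcas, select_representative

__all__ = ["align"]


def align(
    mols: Sequence[MoleculeGraph], cfg: AlignConfig | None = None
) -> tuple[MultipleAlignment, list[BranchGroup]]:
    """Multiple chemical alignment of two or more molecules.

    Finds the longest common atom strings, selects one representative per
    molecule, grows the shared core, and — when the query holds more than
    two molecules — searches the remaining atoms for branch substructures.
    Returns the alignment together with its branch groups (always empty
    for a two-molecule query, whose output is the core mapping alone).
    """
    cfg = cfg or AlignConfig()
    if len(mols) < 2:
        raise ValueError("need at least two molecules to align")
    cache = ScoreCache()
    sets = find_lcas(mols)
    if not sets:
        return MultipleAlignment(tuple(mols), [], cfg), []
    seed = select_representative(mols, sets, cfg, cache)
    core = extend_core(mols, seed, cfg)
    if len(mols) == 2:
        return core, []
    return branch_stage(mols, core, cfg)
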