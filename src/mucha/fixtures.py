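"""Hand-encoded example molecules and a random-molecule generator.

The named fixtures are phenylpropanoids encoded as KCF text under
``mucha/data/``: sinapic acid (C00482), p-coumaryl alcohol 4-O-glucoside
(C05855), and the monolignol panel (p-coumaryl, coniferyl and sinapyl
alcohols).  Their numbering puts the six benzene-ring atoms first, with
the side-chain-bearing ring carbon as atom 1 and ring atoms 1-5 following
the characteristic ring label strings (``C8y-C8x-C8y-C8y-C8y`` for sinapic
acid, ``C8y-C8x-C8x-C8y-C8x`` for the glucoside); substituent labels
follow common KEGG atom-typing conventions and are annotated in the KCF
files themselves so they can be audited or amended without touching code.

``random_molecule`` produces connected, seeded random graphs with
KEGG-like labels for property tests; it makes no attempt at valence
realism.
"""

from __future__ import annotations

import random
from importlib import resources

from .chemgraph import Atom, Bond, Level, MoleculeGraph, parse_kcf

__all__ = [
    "sinapic_acid",
    "p_coumaryl_alcohol_glucoside",
    "monolignol_panel",
    "random_molecule",
    "fixture_kcf_text",
    "DEFAULT_LABEL_ALPHABET",
]

DEFAULT_LABEL_ALPHABET: tuple[str, ...] = (
    "C1a", "C1b", "C1x", "C1y", "C2b", "C8x", "C8y", "C6a",
    "O1a", "O2a", "O2x", "N1a", "N1b", "S2a",
)


def fixture_kcf_text(name: str) -> str:
    """Raw KCF text of a shipped fixture file (e.g. ``"C00482"``)."""
    return (resources.files("mucha.data") / f"{name}.kcf").read_text()


def sinapic_acid() -> MoleculeGraph:
    """Sinapic acid (KEGG C00482): 16 heavy atoms, one benzene ring."""
    return parse_kcf(fixture_kcf_text("C00482"))[0]


def p_coumaryl_alcohol_glucoside() -> MoleculeGraph:
    """p-Coumaryl alcohol 4-O-glucoside (KEGG C05855): 22 heavy atoms."""
    return parse_kcf(fixture_kcf_text("C05855"))[0]


def monolignol_panel() -> list[MoleculeGraph]:
    """p-Coumaryl, coniferyl and sinapyl alcohols (0, 1 and 2 methoxys)."""
    return parse_kcf(fixture_kcf_text("monolignols"))


def random_molecule(
    seed: int,
    n_atoms: int = 10,
    ring_prob: float = 0.15,
    label_alphabet: tuple[str, ...] = DEFAULT_LABEL_ALPHABET,
) -> MoleculeGraph:
    """Connected random molecule: random spanning tree plus ring-closing edges.

    Deterministic per ``seed``; each non-tree atom pair closes a ring with
    probability ``ring_prob``.  Labels are drawn uniformly from
    ``label_alphabet``; elements follow the label's first letter.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    if not 0.0 <= ring_prob <= 1.0:
        raise ValueError("ring_prob must be in [0, 1]")
    if not label_alphabet:
        raise ValueError("label alphabet must be non-empty")
    rng = random.Random(seed)
    atoms = []
    for i in range(1, n_atoms + 1):
        label = rng.choice(label_alphabet)
        atoms.append(Atom(i, label, label[0]))
    bonds = [Bond(rng.randrange(1, i), i) for i in range(2, n_atoms + 1)]
    present = {b.pair for b in bonds}
    for a in range(1, n_atoms + 1):
        for b in range(a + 1, n_atoms + 1):
            if (a, b) not in present and rng.random() < ring_prob:
                bonds.append(Bond(a, b))
                present.add((a, b))
    return MoleculeGraph(f"R{seed:05d}", atoms, bonds)
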