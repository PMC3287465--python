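"""Alignment rendering (text / TSV / JSON) and the ``mucha`` command line.

The text form resembles a sequence alignment: one banner row per block
(``CORE`` first, then branch groups ``B1``, ``B2``, ... in id order), one
row per molecule, fixed-width cells ``atomIndex:KEGGlabel`` with ``-`` for
molecules outside a branch group.  The JSON form is the machine-facing
ground truth; text and TSV are views of the same column structure, and
the text form parses back losslessly.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from typing import Sequence

import click

from .chemgraph import KCFParseError, MoleculeGraph, parse_kcf, write_kcf
from .config import AlignConfig
from .corealign import BRANCH, CORE, AlignmentColumn, MultipleAlignment
from .fixtures import random_molecule
from .pipeline import align

__all__ = [
    "render_text",
    "parse_text",
    "render_tsv",
    "render_json",
    "atom_groups_tsv",
    "cli_main",
]

log = logging.getLogger("mucha")


def _blocks(aln: MultipleAlignment) -> list[tuple[str, list[AlignmentColumn]]]:
    blocks: list[tuple[str, list[AlignmentColumn]]] = [("CORE", aln.core_columns())]
    by_group: dict[int, list[AlignmentColumn]] = {}
    for col in aln.branch_columns():
        by_group.setdefault(col.group or 0, []).append(col)
    for gid in sorted(by_group):
        blocks.append((f"B{gid}", by_group[gid]))
    return blocks


def render_text(aln: MultipleAlignment) -> str:
    """Sequence-alignment-like text document; round-trips via parse_text."""
    mols = aln.molecule_ids
    lines = [
        "# mucha alignment",
        "# molecules: " + " ".join(f"{m.id}({len(m)})" for m in aln.molecules),
        "# config: "
        + " ".join(f"{k}={v}" for k, v in aln.config.to_dict().items()),
    ]
    by_id = {m.id: m for m in aln.molecules}
    name_w = max((len(m) for m in mols), default=0) + 2
    for banner, cols in _blocks(aln):
        if banner != "CORE" and not cols:
            continue
        lines.append(banner)
        if not cols:
            continue
        cells = {
            mid: [
                f"{c.cells[mid]}:{by_id[mid].label(c.cells[mid])}"
                if mid in c.cells
                else "-"
                for c in cols
            ]
            for mid in mols
        }
        width = max(len(v) for row in cells.values() for v in row) + 1
        for mid in mols:
            lines.append(
                mid.ljust(name_w) + "".join(v.ljust(width) for v in cells[mid])
            )
    return "\n".join(lines) + "\n"


def parse_text(text: str) -> list[tuple[str, int | None, dict[str, int]]]:
    """Recover the column structure from a rendered text document.

    Returns one ``(role, group, cells)`` triple per column, in document
    order, where ``cells`` maps molecule id to atom index.
    """
    columns: list[tuple[str, int | None, dict[str, int]]] = []
    block: list[tuple[str, list[str]]] = []
    role, group = CORE, None

    def flush() -> None:
        if not block:
            return
        n_cols = len(block[0][1])
        for mid, row in block:
            if len(row) != n_cols:
                raise ValueError(f"ragged alignment row for {mid}")
        for p in range(n_cols):
            cells = {
                mid: int(row[p].split(":", 1)[0])
                for mid, row in block
                if row[p] != "-"
            }
            columns.append((role, group, cells))
        block.clear()

    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        if line.strip() == "CORE":
            flush()
            role, group = CORE, None
        elif line.strip().startswith("B") and line.strip()[1:].isdigit():
            flush()
            role, group = BRANCH, int(line.strip()[1:])
        else:
            fields = line.split()
            block.append((fields[0], fields[1:]))
    flush()
    return columns


def render_tsv(aln: MultipleAlignment) -> str:
    """One row per column: role, group, then the atom per molecule."""
    mols = aln.molecule_ids
    lines = ["\t".join(("role", "group") + mols)]
    for col in aln.columns:
        lines.append(
            "\t".join(
                [col.role, "" if col.group is None else str(col.group)]
                + [str(col.cells.get(m, "")) for m in mols]
            )
        )
    return "\n".join(lines) + "\n"


def render_json(aln: MultipleAlignment) -> str:
    doc = {
        "molecules": [
            {"id": m.id, "atoms": len(m), "bonds": len(m.bonds)}
            for m in aln.molecules
        ],
        "columns": [
            {
                "role": c.role,
                "group": c.group,
                "cells": c.cells,
                "provenance": c.provenance,
            }
            for c in aln.columns
        ],
        "config": aln.config.to_dict(),
    }
    return json.dumps(doc, indent=1, sort_keys=True) + "\n"


def atom_groups_tsv(aln: MultipleAlignment) -> str:
    """Per-atom group-id table (``molecule  atom  group``) for colorizing.

    Group ``core`` covers core columns, ``B<n>`` the branch groups, ``-``
    the unaligned atoms.
    """
    assignment: dict[tuple[str, int], str] = {}
    for col in aln.columns:
        tag = "core" if col.role == CORE else f"B{col.group}"
        for mid, a in col.cells.items():
            assignment[(mid, a)] = tag
    lines = ["molecule\tatom\tgroup"]
    for mol in aln.molecules:
        for a in mol.atom_indices:
            lines.append(f"{mol.id}\t{a}\t{assignment.get((mol.id, a), '-')}")
    return "\n".join(lines) + "\n"


# -- CLI --------------------------------------------------------------------

_RENDERERS = {"text": render_text, "tsv": render_tsv, "json": render_json}


@click.group()
@click.option(
    "--log-level",
    default="WARNING",
    show_default=True,
    type=click.Choice(["DEBUG", "INFO", "WARNING", "ERROR"], case_sensitive=False),
)
def cli_main(log_level: str) -> None:
    """Multiple chemical alignment of KEGG-typed molecular graphs."""
    logging.basicConfig(level=getattr(logging, log_level.upper()), stream=sys.stderr)


@cli_main.command("align")
@click.argument("files", nargs=-1, required=True, type=click.Path(exists=True))
@click.option("-o", "--output", type=click.Path(), default=None, help="Output path (default stdout).")
@click.option("--format", "fmt", default="text", show_default=True, type=click.Choice(sorted(_RENDERERS)))
@click.option("--seed", default=0, show_default=True, type=int)
@click.option("--min-support", default=2, show_default=True, type=int)
@click.option("--restarts", default=20, show_default=True, type=int)
@click.option("--ga-population", default=50, show_default=True, type=int)
@click.option("--ga-generations", default=100, show_default=True, type=int)
@click.option("--atom-groups", type=click.Path(), default=None, help="Also write a per-atom group-id TSV here.")
def cli_align(files, output, fmt, seed, min_support, restarts, ga_population, ga_generations, atom_groups):
    """Align the molecules in the given KCF FILES (multi-entry files allowed)."""
    cfg = AlignConfig(
        seed=seed,
        min_support=min_support,
        conflict_restarts=restarts,
        ga_population=ga_population,
        ga_generations=ga_generations,
    )
    mols: list[MoleculeGraph] = []
    for path in files:
        try:
            with open(path) as fh:
                mols.extend(parse_kcf(fh.read()))
        except (OSError, KCFParseError) as exc:
            raise click.UsageError(f"{path}: {exc}")
    if len(mols) < 2:
        raise click.UsageError("need at least two molecules to align")
    t0 = time.perf_counter()
    aln, groups = align(mols, cfg)
    log.info(
        "aligned %d molecules: %d core columns, %d branch columns, %d groups (%.3fs)",
        len(mols),
        len(aln.core_columns()),
        len(aln.branch_columns()),
        len(groups),
        time.perf_counter() - t0,
    )
    doc = _RENDERERS[fmt](aln)
    if output:
        with open(output, "w") as fh:
            fh.write(doc)
    else:
        click.echo(doc, nl=False)
    if atom_groups:
        with open(atom_groups, "w") as fh:
            fh.write(atom_groups_tsv(aln))


@cli_main.command("synth")
@click.option("--seed", default=0, show_default=True, type=int)
@click.option("--n-atoms", default=10, show_default=True, type=int)
@click.option("--ring-prob", default=0.15, show_default=True, type=float)
@click.option("--count", default=1, show_default=True, type=int)
@click.option("-o", "--output", type=click.Path(), default=None)
def cli_synth(seed, n_atoms, ring_prob, count, output):
    """Generate seeded random molecules as KCF text."""
    try:
        mols = [
            random_molecule(seed + k, n_atoms=n_atoms, ring_prob=ring_prob)
            for k in range(count)
        ]
    except ValueError as exc:
        raise click.UsageError(str(exc))
    doc = write_kcf(mols)
    if output:
        with open(output, "w") as fh:
            fh.write(doc)
    else:
        click.echo(doc, nl=False)
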