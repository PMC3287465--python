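# mucha — multiple chemical alignment for metabolic building blocks

`mucha` aligns two or more small molecules atom-by-atom, the way a multiple
sequence alignment aligns residues. Given a set of metabolites as
hydrogen-suppressed molecular graphs with KEGG atom types (KCF format), it
finds

* the **core substructure** shared by *all* query molecules, as one
  globally consistent atom-atom mapping, and
* the **branch substructures** ("building blocks") shared by *subsets* of
  the molecules, each pinned to the core position where it is attached.

Metabolites that descend from one biosynthetic pathway share a core and
differ by building blocks added one enzymatic step at a time (methoxy
groups, sugar residues, acyl chains, ...). Position-aware building blocks
therefore narrow the search space for the biosynthesis of orphan
metabolites — the intended audience is metabolomics / pathway-prediction
work, not pharmacophore modeling: atoms are matched by their metabolic
equivalence (KEGG atom-type hierarchy), never by electrostatics.

## Method

A molecule is a connected graph `G(V, E)` whose vertices carry hierarchical
KEGG atom labels (full type `C8y` ⊃ atom class `C8` ⊃ species `C`); edges
carry bond orders (parsed, but never used for matching — chemical
environment lives in the labels). Distance `d(i, j)` is the shortest-path
bond count. Three devices drive the alignment:

* **DMAID** (distance-matrix atom identifier). An *atom string* is a simple
  path; its *self-DMAID* is the matrix `[d(s_i, s_j)]` over the string's
  atoms (whole-molecule distances), and its *anchored DMAID* against an
  anchor string `t` is `[d(s_i, t_j)]`. Two strings in different molecules
  occupy the same topological position iff labels and matrices agree
  entry-wise.
* **DECAF** (distance-embedded common atom fingerprint). Per atom `i`,
  counts `n_{i,k,d}` of atoms of class `k` at distance `d`. Atom similarity
  is `Σ_d [Σ_k min(n_{i,k,d}, n_{j,k,d})] / (d+1)`.
* **Seed and extend.** Stage 1 finds the longest common atom strings
  (LCAS: identical full labels + self-DMAID in every molecule) by a
  level-wise queue search, picking one representative per molecule by the
  DECAF objective (exhaustively, or by a seeded genetic algorithm when the
  combination count explodes). Stage 2 grows the seed: frontier atoms are
  grouped by (species, anchored DMAID vs. the current core) and promoted to
  core columns once unique per molecule, with a disambiguation cascade —
  ring-bond counts, atom classes, full types, atom-index order — for
  symmetric cases. Two-molecule queries stop here. Stage 3 repeats the idea
  on the leftover atoms with species-level labels and DMAIDs anchored to the
  core (SCAS), requiring only `min_support ≥ 2` molecules, then removes
  conflicting columns by a randomized greedy pass (best of 20 shuffles by
  total aligned atoms) and merges adjacent columns into building blocks.

## Worked example

The two bundled phenylpropanoids — sinapic acid (`C00482`, 16 heavy atoms)
and p-coumaryl alcohol 4-O-glucoside (`C05855`, 22 heavy atoms) — share a
benzene ring with a three-carbon side chain. Their ring label strings
differ (`C8y-C8x-C8y-C8y-C8y` vs `C8y-C8x-C8x-C8y-C8x`), so the LCAS is the
four-atom string `C2b-C2b-C8y-C8x` (two symmetric instances per molecule):

```python
>>> from mucha import sinapic_acid, p_coumaryl_alcohol_glucoside, build_decaf, decaf_score
>>> a, b = sinapic_acid(), p_coumaryl_alcohol_glucoside()
>>> [a.distance(1, j) for j in (1, 2, 3, 4, 5)]   # self-DMAID row of the ring string
[0, 1, 2, 3, 2]
>>> fa = build_decaf(a, 1)    # fingerprint of the side-chain-bearing ring carbon
>>> len(fa)
11
>>> decaf_score(fa, build_decaf(b, 1))            # 1/1 + 3/2 + 3/3 + 1/4 + 1/5
3.95
```

The score sums the shared class counts per distance shell: both atoms see
two ring carbons + one vinyl carbon at distances 1 and 2, one shared ring
carbon at distance 3, and one shared hydroxyl-type oxygen at distance 4.

Aligning the pair (`mucha align a.kcf b.kcf`, or `align([a, b])` in
Python) prints a core-only mapping of 10 columns — the 6 ring atoms, the
3 side-chain carbons (`C6a` carboxyl matched to `C1b` alcohol at species
level), and the para oxygen (`O1a` hydroxyl matched to `O2a` glycosidic
ether at species level):

```
CORE
C00482  11:C2b 7:C2b  1:C8y  2:C8x  14:C6a 6:C8x  3:C8y  5:C8y  4:C8y  9:O1a
C05855  9:C2b  7:C2b  1:C8y  2:C8x  11:C1b 6:C8x  3:C8x  5:C8x  4:C8y  8:O2a
```

The methoxy and carboxyl oxygens of sinapic acid and the glucose residue
stay unaligned: they are the building blocks that distinguish the two
molecules. With three or more molecules (try the bundled monolignol
panel) those appear as `B1`, `B2`, ... branch blocks with gap cells for
non-member molecules.

## Command line

```sh
mucha align panel.kcf --format json --seed 7 -o out.json --atom-groups groups.tsv
mucha synth --seed 3 --n-atoms 10        # seeded random test molecules
```

Outputs are byte-identical for identical inputs and config (including
seed). `--atom-groups` writes a `molecule  atom  group` TSV for coloring
structures with any external drawing tool.

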