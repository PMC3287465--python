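# Methods

This note records the model behind `mucha`, the parameters that matter,
the numerical and design choices made where the procedure was genuinely
open, and what the bundled fixtures and synthetic molecules do and do not
exercise.

## Data model

Molecules are connected, hydrogen-suppressed graphs. Atom labels are
treated as *opaque hierarchical tokens* with three levels — species (first
character), atom class (first two), full type — and no attempt is made to
derive KEGG atom types from raw connectivity: labels must arrive in the
KCF input (an optional typed-SDF path was considered and dropped; typing
is a separate, non-trivial problem). Bond orders are parsed and preserved
for round-tripping but take no part in matching: the matching rules
compare only labels and distances, and the orbital/neighborhood context
that bond orders would add is already encoded in the label hierarchy.

Disconnected input is rejected rather than split: every identifier in the
method is built from whole-molecule shortest-path distances and must be
finite. Atom indices are 1-based as in KCF and are preserved verbatim.

All-pairs distances are computed once per molecule by breadth-first search
and cached; "ring bond" means a non-bridge edge (it lies on at least one
cycle), computed by a standard bridge-finding pass and cached likewise.

## DMAID

A string's self-DMAID uses **whole-molecule** distances restricted to the
string's atoms, not distances in the path itself: in a six-membered ring
the ends of a five-atom string are 2 bonds apart through the sixth atom,
and that shortcut distinguishes a ring arc from an open chain of the same
labels. Matrix comparison is entry-wise under the string's own order; no
permutation search is ever attempted (that would be a graph-isomorphism
problem smuggled in through the back door). Anchored DMAIDs inherit the
anchor's column order, so comparability across molecules requires a shared
anchor orientation — the aligned core columns provide exactly that.

## DECAF

The fingerprint buckets every atom of the molecule by (distance,
destination atom class), including the distance-0 self entry, so the
total mass equals the atom count — a conservation law the tests assert on
random molecules. Keys are (distance, class) pairs with occurrence
counts, not full backward path strings: per-destination-class counting is
what makes the score's per-distance overlap `Σ_k min(n_i, n_j)` well
defined, and it reproduces both worked quantities of the bundled fixture
pair (the 11-entry fingerprint and the 3.95 score with terms 1/1, 3/2,
3/3, 1/4, 1/5). The per-layer denominator is `d + 1`, read directly off
that worked sum. Distances appearing in only one fingerprint contribute
nothing (`min` with an absent count is 0). Scores are memoized per
unordered atom pair; the cache is transparency-tested against direct
recomputation.

## Seed strings (LCAS)

Strings are simple paths — repeated atoms would break both "path" and the
squareness of the self-DMAID. The string identity key is the pair (full
label sequence, self-DMAID), made orientation-free by taking the smaller
of the two directed (labels, matrix) pairs. This direction-minimal key —
rather than an orientation fixed by molecule-local atom indices — is what
keeps keys comparable across molecules even for palindromic label
sequences; instance-level duplicates (a path and its mirror) are still
collapsed by the documented (labels, atom-index) tie-break.

The level-wise search extends surviving strings at the terminal atom
only. That suffices: every prefix *and* suffix of a string common to all
molecules is itself common (its instances are sub-paths of the common
instances, with restricted matrices), so each direction of every common
string is reachable through its own chain of surviving prefixes. The
brute-force equivalence test (exhaustive simple-path enumeration on random
pairs) pins this argument down.

Representative selection maximizes the summed pairwise string DECAF score.
When several maximal-length identities exist, each is optimized separately
and the best identity wins — a seed alignment must share a single
identity, so a "global" search across mixed identities would produce an
invalid seed. Exhaustive search runs while the per-identity combination
count is at most `exhaustive_limit` (default 10 000, a few milliseconds of
scoring); beyond that a seeded genetic algorithm takes over: population
50, 100 generations, tournament size 3, one-point crossover rate 0.9,
per-gene mutation rate 0.1, elitism 1. These GA values are conventional
textbook settings — the selection landscape here is small and flat — and
all are overridable through `AlignConfig`.

## Core extension

Frontier atoms are grouped by (species, anchored DMAID against the
current core). Re-anchoring against the **full current core** at every
pass, not the original seed only, is an interpretive choice: the growing
core is the natural anchor, it is strictly more discriminative, and it is
what lets ring positions that start out symmetric become distinguishable
as soon as any symmetry-breaking column lands. Species-level matching at
this stage is what allows chemically drifted but positionally equivalent
atoms (carboxyl `C6a` vs alcohol `C1b`; hydroxyl `O1a` vs glycosidic
`O2a`) into the core.

The disambiguation cascade runs ring-bond counts → atom classes → full
KEGG types → ascending atom-index pairing, stopping at the first stage
where every refined subgroup is unambiguous; uniqueness is judged *after*
the cascade (the cascade exists to create it). Index-order pairing is the
honest last resort for true topological symmetry — it can permute cells
under renumbering, but never changes the column count, which is the
property the tests assert. Two conservative rules apply: a refined
subgroup that stops spanning every molecule is dropped, and a group that
finishes the cascade with unequal candidate counts per molecule is
rejected rather than force-paired. Processing order (sorted group keys,
columns in creation order) makes the stage fully deterministic. Growth is
monotone — promotion never removes a column — so termination within |V|
passes is immediate.

## Branch stage

SCAS search mirrors the seed search with three deliberate differences:
species-level labels (branch blocks model transferred groups whose
internal typing drifts more than their skeleton), anchoring against the
frozen core (which pins attachment position and keeps identical residues
at different positions apart), and a support threshold of `min_support`
molecules (default 2 — the weakest floor at which "common" means
anything) instead of all. A string identity is emitted as a seed when no
one-atom extension preserves its member set at the support threshold, so
a short widely-shared string and its longer narrowly-shared extension can
both compete. Identities with several instances in one molecule are
paired rank-by-rank in ascending atom-index order, the same last-resort
rule as the core cascade; ranks that fall below `min_support` members are
dropped (this is why a doubly-methoxylated ring aligns one methoxy with a
singly-methoxylated partner and leaves the other unmatched).

Each seed is grown with the core-extension machinery restricted to its
member molecules and non-core atoms, anchored against core plus the
branch columns grown so far. Branches may chain off other branches'
atoms; they never cross into the core, which is frozen after stage 2.

Conflict removal reproduces the randomized greedy procedure: shuffle the
candidate columns, accept each unless it shares an atom with an accepted
one, score by total atoms accepted, keep the best of `conflict_restarts`
shuffles (default 20). This is a heuristic, not an optimal
weighted-independent-set solver; the tests characterize it against the
exhaustive-ordering optimum on small crafted instances (attainment rate
printed, and high). All randomness flows from `AlignConfig.seed`, so
outputs are byte-reproducible.

Surviving columns merge into a building block when they cover the same
member molecules and are bonded in every one of them; group ids are
assigned by descending size then lexical order.

## Fixtures and synthetic data

The named fixtures are hand-encoded phenylpropanoids: sinapic acid
(16 heavy atoms), p-coumaryl alcohol 4-O-glucoside (22), and the
monolignol panel (p-coumaryl / coniferyl / sinapyl alcohols, 0/1/2
methoxy groups). Ring atoms are numbered 1–6 with the side-chain-bearing
carbon as atom 1, matching the positions that the worked quantities pin;
substituent labels follow common KEGG conventions and are annotated line
by line in the KCF sources for audit. The glucose-residue labels affect
no pinned quantity (everything pinned lives within distance 4 of atom 1
or on the ring) but are flagged in the data file comments.

`random_molecule` draws a random spanning tree plus ring-closing edges
(probability 0.15 per extra pair by default) with labels sampled from a
KEGG-like alphabet. It emulates the *graph-theoretic* shape of KCF input
— connected, sparse, ring-bearing, hierarchically labeled — and none of
its chemistry: no valence constraints, no label-environment consistency.
Property tests on it therefore establish algorithmic correctness
(oracle equivalence, conservation, invariances), not chemical validity of
alignments; the fixture molecules carry that weight.

Test and characterization problem sizes — oracle equivalence on 100
random pairs of up to 12 atoms, conflict-removal attainment over 100
seeded trials on 6-column instances — are chosen so exhaustive oracles
(all simple paths; all column orderings) stay exact.

## Known limitations

* The alignment is a greedy heuristic; it carries no maximum-common-
  substructure guarantee, and oracle checks are exact only at fixture
  scale.
* Index-order pairing resolves true symmetry arbitrarily (consistently,
  but not canonically): cell assignments under symmetry are reproducible,
  not meaningful.
* Species-level branch matching can merge chemically distinct residues
  that share a skeleton and position; raise the matching bar by aligning
  fewer, closer molecules if that matters.
* No stereochemistry, aromatic perception, charge handling, or automatic
  atom typing; structurally diverse query sets degrade gracefully into
  small cores but the output is then not biologically informative.
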