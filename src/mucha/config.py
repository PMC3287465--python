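"""Pipeline configuration shared by the alignment stages."""

from __future__ import annotations

from dataclasses import dataclass, asdict


@dataclass
class AlignConfig:
    """Tunable parameters of the multiple chemical alignment.

    Attributes
    ----------
    seed
        Master seed for every randomized step (representative selection by
        genetic algorithm, conflict-removal restarts); identical inputs and
        config produce byte-identical outputs.
    exhaustive_limit
        Representative seed-string selection enumerates all per-molecule
        combinations when their product is at most this; above it, a seeded
        genetic algorithm searches instead.
    ga_population, ga_generations, ga_tournament, ga_crossover, ga_mutation,
    ga_elitism
        Genetic-algorithm knobs for representative selection.
    min_support
        Minimum number of member molecules for a branch substructure.
    conflict_restarts
        Random restarts of greedy conflict removal among branch columns.
    """

    seed: int = 0
    exhaustive_limit: int = 10_000
    ga_population: int = 50
    ga_generations: int = 100
    ga_tournament: int = 3
    ga_crossover: float = 0.9
    ga_mutation: float = 0.1
    ga_elitism: int = 1
    min_support: int = 2
    conflict_restarts: int = 20

    def to_dict(self) -> dict:
        return asdict(self)
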