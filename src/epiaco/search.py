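"""Full colony search: iteration loop, candidate memory, exhaustive oracle.

Each iteration every ant proposes a K-SNP combination, the combinations are
scored by Svalue, the per-iteration ranking is cut at the inflection point of
its descending score curve, and the survivors are merged into a memory of
candidate solutions carried across iterations. Pheromones are then updated
with an extra reward for SNPs belonging to current candidates. The final
memory, ranked by Svalue, is the search result.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .colony import AcoParams, ColonyState, construct_combination, update_pheromones
from .scoring import CombinationScore, score_combination
from .simulate import GenotypeDataset

__all__ = [
    "CandidateMemory",
    "SearchResult",
    "find_inflection",
    "update_memory",
    "run_epiaco",
    "brute_force_scan",
    "random_search",
]


def _rank(solutions: list[CombinationScore]) -> list[CombinationScore]:
    """Descending by svalue; ties broken by ascending index tuple."""
    return sorted(solutions, key=lambda s: (-s.svalue, s.snps))


def _dedupe(solutions: list[CombinationScore]) -> list[CombinationScore]:
    seen: set[tuple[int, ...]] = set()
    out = []
    for s in solutions:
        if s.snps not in seen:
            seen.add(s.snps)
            out.append(s)
    return out


@dataclass
class CandidateMemory:
    """Top candidate combinations retained across iterations.

    Kept unique by SNP tuple and sorted descending by svalue (ties by
    ascending tuple). ``capacity`` optionally caps the length after each
    update; by default the inflection-point cut is the only limit.
    """

    solutions: list[CombinationScore] = field(default_factory=list)
    capacity: int | None = None

    def __post_init__(self) -> None:
        self.solutions = _rank(_dedupe(self.solutions))
        if self.capacity is not None:
            self.solutions = self.solutions[: self.capacity]

    @property
    def best(self) -> CombinationScore | None:
        return self.solutions[0] if self.solutions else None

    def combinations(self) -> set[tuple[int, ...]]:
        return {s.snps for s in self.solutions}

    def __len__(self) -> int:
        return len(self.solutions)


def find_inflection(scores: list[float] | np.ndarray) -> int:
    """Rank count f at the inflection of a descending score curve.

    With 1-based ranks g, f is the g in {3..m} maximizing the second
    difference (score_g - score_{g-1}) - (score_{g-1} - score_{g-2}); ties
    take the smallest g. Fewer than 3 scores: f is the list length (0 for an
    empty list).
    """
    s = np.asarray(scores, dtype=float)
    if s.size < 3:
        return int(s.size)
    if np.any(np.diff(s) > 1e-9):
        raise ValueError("scores must be sorted in descending order")
    second = np.diff(s, n=2)  # second[g-3] for g = 3..m
    return int(np.argmax(second)) + 3


def update_memory(
    memory: CandidateMemory, iteration_solutions: list[CombinationScore]
) -> CandidateMemory:
    """Merge an iteration's solutions into the candidate memory.

    The iteration's unique solutions are ranked and cut at their inflection
    point; the survivors are unioned with the previous memory, the merged
    list is re-ranked and cut at its own inflection point. The best svalue
    can therefore never decrease across iterations.
    """
    ranked = _rank(_dedupe(iteration_solutions))
    f = find_inflection([s.svalue for s in ranked])
    merged = _rank(_dedupe(memory.solutions + ranked[:f]))
    f2 = find_inflection([s.svalue for s in merged])
    return CandidateMemory(solutions=merged[:f2], capacity=memory.capacity)


@dataclass
class SearchResult:
    """Outcome of one colony run."""

    candidates: CandidateMemory
    #: per-iteration records: best svalue in memory and memory size
    history: list[dict]
    params: AcoParams
    seed: int

    @property
    def top(self) -> CombinationScore | None:
        return self.candidates.best


def run_epiaco(
    dataset: GenotypeDataset,
    params: AcoParams,
    memory_capacity: int | None = None,
) -> SearchResult:
    """Run the full colony search on a dataset.

    Pheromones start at tau0 and the heuristic vector at 1 for every SNP.
    Scores are cached per combination within the run, so re-proposed
    combinations cost nothing to re-evaluate. Deterministic given
    ``params.seed``.
    """
    if dataset.n_snps < params.order:
        raise ValueError(
            f"dataset has {dataset.n_snps} SNPs, fewer than order {params.order}"
        )
    rng = np.random.default_rng(params.seed)
    state = ColonyState.initial(dataset.n_snps, params)
    memory = CandidateMemory(capacity=memory_capacity)
    cache: dict[tuple[int, ...], CombinationScore] = {}
    history: list[dict] = []

    for t in range(1, params.n_iterations + 1):
        state.iteration = t
        ant_solutions: list[CombinationScore] = []
        for _ in range(params.n_ants):
            combo = construct_combination(state, rng)
            score = cache.get(combo)
            if score is None:
                score = score_combination(dataset, combo)
                cache[combo] = score
            ant_solutions.append(score)
        # memory update precedes the pheromone update so the candidate
        # reward sees this iteration's candidates
        memory = update_memory(memory, ant_solutions)
        scale = 1.0
        if params.deposit_normalization != "none":
            best = max(s.svalue for s in ant_solutions)
            scale = best if best > 0.0 else 1.0
            if params.deposit_normalization == "colony":
                scale *= params.n_ants
        state.tau = update_pheromones(
            state, ant_solutions, memory.combinations(), scale=scale
        )
        history.append(
            {
                "iteration": t,
                "best_svalue": memory.best.svalue if memory.best else 0.0,
                "memory_size": len(memory),
            }
        )
    return SearchResult(
        candidates=memory, history=history, params=params, seed=params.seed
    )


def brute_force_scan(
    dataset: GenotypeDataset,
    order: int = 2,
    max_combinations: int = 200_000,
) -> list[CombinationScore]:
    """Score every K-combination exhaustively; descending Svalue ranking.

    The independent oracle for the colony search. Refuses instances whose
    combination count exceeds ``max_combinations``.
    """
    from math import comb

    total = comb(dataset.n_snps, order)
    if total > max_combinations:
        raise ValueError(
            f"{total} combinations exceed the exhaustive-scan cap "
            f"{max_combinations}"
        )
    scores = [
        score_combination(dataset, snps)
        for snps in itertools.combinations(range(dataset.n_snps), order)
    ]
    return _rank(scores)


def random_search(
    dataset: GenotypeDataset,
    order: int,
    n_evaluations: int,
    seed: int = 0,
) -> list[CombinationScore]:
    """Uniform random sampling baseline at a fixed evaluation budget.

    Samples ``n_evaluations`` K-combinations uniformly (with replacement
    across draws, deduplicated for scoring) and returns the descending
    Svalue ranking of the distinct combinations seen.
    """
    rng = np.random.default_rng(seed)
    seen: dict[tuple[int, ...], CombinationScore] = {}
    for _ in range(n_evaluations):
        combo = tuple(
            sorted(int(i) for i in rng.choice(dataset.n_snps, order, replace=False))
        )
        if combo not in seen:
            seen[combo] = score_combination(dataset, combo)
    return _rank(list(seen.values()))
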