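"""Ant-colony engine: pheromone state, path selection, pheromone updates.

Each ant builds a K-SNP combination one SNP at a time. For every choice a
fresh uniform draw q is compared to the threshold q0 = t / T (current over
total iterations): q <= q0 uses the probabilistic rule (roulette wheel over
pheromone^alpha * heuristic^beta), otherwise the stochastic rule (uniform
over the half of the SNPs with the lowest pheromones). Early iterations are
therefore exploration-heavy; by the final iteration every choice is
probabilistic. Pheromones evaporate at rate rho each iteration and are
reinforced by the Svalue of every combination an ant evaluated, with an
extra reward (factor xi) for combinations that made it into the candidate
memory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .scoring import CombinationScore

__all__ = [
    "AcoParams",
    "ColonyState",
    "q_threshold",
    "select_probabilistic",
    "select_stochastic",
    "construct_combination",
    "update_pheromones",
]


@dataclass(frozen=True)
class AcoParams:
    """Colony parameters.

    Defaults follow the benchmark settings: 200 ants, 25 iterations,
    evaporation rho = 0.2, candidate reward xi = 0.3, and unit pheromone,
    heuristic, alpha and beta.
    """

    n_ants: int = 200
    n_iterations: int = 25
    order: int = 2
    alpha: float = 1.0
    beta: float = 1.0
    rho: float = 0.2
    xi: float = 0.3
    tau0: float = 1.0
    seed: int = 0
    #: if True, one q draw decides the rule for a whole combination instead
    #: of one draw per SNP choice
    single_q_per_ant: bool = False
    #: deposit scaling: "colony" divides pheromone deposits by
    #: (n_ants * iteration-best Svalue) so the colony's total deposit per
    #: iteration stays on the tau0 scale regardless of sample size;
    #: "iteration_max" divides by the iteration-best Svalue only;
    #: "none" deposits raw Svalues
    deposit_normalization: str = "colony"

    def __post_init__(self) -> None:
        if self.n_ants < 3:
            raise ValueError("need at least 3 ants (inflection point needs 3 ranks)")
        if self.order < 2:
            raise ValueError("combination order must be at least 2")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if not 0.0 <= self.xi <= 1.0:
            raise ValueError("xi must lie in [0, 1]")
        if self.tau0 <= 0.0:
            raise ValueError("tau0 must be positive")
        if self.n_iterations < 1:
            raise ValueError("need at least one iteration")
        if self.deposit_normalization not in ("colony", "iteration_max", "none"):
            raise ValueError(
                "deposit_normalization must be 'colony', 'iteration_max' "
                "or 'none'"
            )


@dataclass
class ColonyState:
    """Mutable per-run colony state: pheromones, heuristic, iteration clock."""

    tau: np.ndarray
    eta: np.ndarray
    params: AcoParams
    iteration: int = 1

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.eta = np.asarray(self.eta, dtype=float)
        if self.tau.shape != self.eta.shape or self.tau.ndim != 1:
            raise ValueError("tau and eta must be 1-D vectors of equal length")
        if np.any(self.tau <= 0) or np.any(self.eta <= 0):
            raise ValueError("tau and eta must be strictly positive")
        if not 1 <= self.iteration <= self.params.n_iterations:
            raise ValueError(
                f"iteration {self.iteration} outside "
                f"[1, {self.params.n_iterations}]"
            )

    @classmethod
    def initial(cls, n_snps: int, params: AcoParams) -> "ColonyState":
        return cls(
            tau=np.full(n_snps, params.tau0),
            eta=np.ones(n_snps),
            params=params,
        )

    @property
    def n_snps(self) -> int:
        return self.tau.shape[0]

    def selection_weights(self) -> np.ndarray:
        """tau^alpha * eta^beta for every SNP (roulette-wheel weights)."""
        return self.tau ** self.params.alpha * self.eta ** self.params.beta

    def lower_half(self) -> np.ndarray:
        """Indices of the floor(n/2) SNPs with the lowest pheromones.

        The latter half of a descending pheromone sort; pheromone ties are
        broken by ascending SNP index.
        """
        n = self.n_snps
        order = np.argsort(-self.tau, kind="stable")
        return order[n - n // 2 :]


def q_threshold(iteration: int, total: int) -> float:
    """Exploitation threshold q0 = t / T (reaches 1 at the last iteration)."""
    if not 1 <= iteration <= total:
        raise ValueError(f"iteration {iteration} outside [1, {total}]")
    return iteration / total


def select_probabilistic(
    state: ColonyState,
    available: Sequence[int],
    rng: np.random.Generator,
    weights: np.ndarray | None = None,
) -> int:
    """Roulette-wheel draw: P(i) proportional to tau_i^alpha * eta_i^beta.

    ``weights`` may pass precomputed per-SNP weights to avoid recomputing
    them for every ant within an iteration.
    """
    available = np.asarray(available, dtype=np.intp)
    if available.size == 0:
        raise ValueError("no SNPs available for selection")
    if weights is None:
        weights = state.selection_weights()
    w = weights[available]
    return int(rng.choice(available, p=w / w.sum()))


def select_stochastic(
    state: ColonyState,
    available: Sequence[int],
    rng: np.random.Generator,
    lower_half: np.ndarray | None = None,
) -> int:
    """Uniform draw from the low-pheromone half of the SNPs.

    The pool is the floor(n/2) SNPs with the lowest pheromones, intersected
    with ``available``; if that intersection is empty the draw falls back to
    uniform over ``available``.
    """
    available = np.asarray(available, dtype=np.intp)
    if available.size == 0:
        raise ValueError("no SNPs available for selection")
    if lower_half is None:
        lower_half = state.lower_half()
    pool = available[np.isin(available, lower_half)]
    if pool.size == 0:
        pool = available
    return int(rng.choice(pool))


def construct_combination(
    state: ColonyState, rng: np.random.Generator
) -> tuple[int, ...]:
    """One ant's K-SNP combination, returned as a sorted index tuple.

    SNPs are chosen sequentially without replacement; each choice draws its
    own q against q0 = t / T to pick the selection rule (a single shared q
    per ant is available via ``AcoParams.single_q_per_ant``).
    """
    p = state.params
    if state.n_snps < p.order:
        raise ValueError("fewer SNPs than the combination order")
    q0 = q_threshold(state.iteration, p.n_iterations)
    weights = state.selection_weights()
    lower = state.lower_half()
    available = np.arange(state.n_snps)
    chosen: list[int] = []
    shared_q = rng.random() if p.single_q_per_ant else None
    for _ in range(p.order):
        q = shared_q if shared_q is not None else rng.random()
        if q <= q0:
            pick = select_probabilistic(state, available, rng, weights=weights)
        else:
            pick = select_stochastic(state, available, rng, lower_half=lower)
        chosen.append(pick)
        available = available[available != pick]
    return tuple(sorted(chosen))


def update_pheromones(
    state: ColonyState,
    ant_solutions: Iterable[CombinationScore],
    candidates: Iterable[tuple[int, ...]] | None,
    scale: float = 1.0,
) -> np.ndarray:
    """Next iteration's pheromone vector.

    tau_i(t+1) = (1 - rho) tau_i(t)
                 + sum over ants whose combination contains i of Svalue
                 + xi * Svalue for those of them whose combination is a
                   current candidate solution.

    ``ant_solutions`` is per-ant (a combination picked by two ants deposits
    twice); ``candidates`` is the set of candidate combinations after the
    memory update of this iteration. ``scale`` divides every deposit: the
    run loop passes the iteration's best Svalue so that reinforcement is
    expressed relative to the fitness scale of the dataset (the raw Svalue
    magnitude shrinks with sample size through its log-K2 denominator and
    would otherwise be negligible against tau0). Returns the new vector;
    the caller stores it and advances the iteration clock.
    """
    p = state.params
    if scale <= 0.0:
        raise ValueError("scale must be positive")
    candidate_set = set(candidates) if candidates is not None else set()
    tau = (1.0 - p.rho) * state.tau
    for sol in ant_solutions:
        bonus = 1.0 + p.xi if sol.snps in candidate_set else 1.0
        for i in sol.snps:
            tau[i] += bonus * sol.svalue / scale
    return tau
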