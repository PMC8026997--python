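"""Evolutionary dynamics: synchronous imitation with mutation on the ring.

One generation: every player's expected payoff is computed on the current
population, then all players simultaneously revise their type.  A player
mutates to a uniformly random type with probability ``mu`` (mutation preempts
imitation); otherwise it picks a model player — globally with probability
``a``, else among its ``n`` neighbours — and copies the model's type **iff**
the model's payoff is strictly greater than its own.  Ties never fire.

Random-draw discipline (bit-reproducibility contract): per generation the
generator is consumed in whole-population blocks, in this fixed order —
mutation coins (N uniforms), mutation types (N integers), adaptation-scope
coins (N uniforms), global model picks (N integers), local model picks
(N integers).  Every block is drawn regardless of which branch each player
takes, so a trial is a pure function of ``(params, generations, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    COOPERATES,
    ModelParams,
    Strategy,
    neighbor_indices,
    payoff_vector,
    validate_population,
)

__all__ = [
    "GenerationRecord",
    "TrialResult",
    "init_population",
    "choose_model",
    "adapt_step",
    "run_trial",
]


@dataclass(frozen=True)
class GenerationRecord:
    """Snapshot of the population at one generation (0 = initial state)."""

    generation: int
    strategies: np.ndarray
    strategy_counts: np.ndarray  # counts of CP, CN, DP, DN; sums to N

    @property
    def cooperation_rate(self) -> float:
        n = self.strategy_counts.sum()
        return float(self.strategy_counts[Strategy.CP] + self.strategy_counts[Strategy.CN]) / n

    @property
    def defector_rate(self) -> float:
        return 1.0 - self.cooperation_rate

    def fraction(self, strategy: Strategy) -> float:
        return float(self.strategy_counts[Strategy(strategy)]) / self.strategy_counts.sum()


def _record(generation: int, pop: np.ndarray) -> GenerationRecord:
    counts = np.bincount(pop, minlength=4)
    return GenerationRecord(generation, pop.copy(), counts)


@dataclass(frozen=True)
class TrialResult:
    """Full history of one trial: ``generations + 1`` records incl. the start."""

    params: ModelParams
    seed: int
    history: list[GenerationRecord] = field(repr=False)

    @property
    def final(self) -> GenerationRecord:
        return self.history[-1]

    def strategy_matrix(self) -> np.ndarray:
        """(generations+1) x N matrix of strategy codes, row 0 = initial state."""
        return np.stack([rec.strategies for rec in self.history])


def init_population(params: ModelParams, rng: np.random.Generator) -> np.ndarray:
    """Each position independently uniform over the four types."""
    return rng.integers(0, 4, size=params.N).astype(np.int8)


def choose_model(i: int, params: ModelParams, rng: np.random.Generator) -> int:
    """Pick the imitation model for player ``i``.

    With probability ``a`` the model is uniform over all ``N - 1`` other
    players; otherwise uniform over the ``n`` ring neighbours.  Never ``i``.
    """
    if rng.random() < params.a:
        j = int(rng.integers(0, params.N - 1))
        return j if j < i else j + 1
    return int(neighbor_indices(i, params)[rng.integers(0, params.n)])


def adapt_step(
    pop: np.ndarray, params: ModelParams, rng: np.random.Generator
) -> np.ndarray:
    """One synchronous generation; payoffs and model types frozen at entry."""
    pop = validate_population(pop, params)
    N, n = params.N, params.n
    pay = payoff_vector(pop, params)
    idx = np.arange(N)

    mutate = rng.random(N) < params.mu
    mut_type = rng.integers(0, 4, size=N).astype(np.int8)
    global_scope = rng.random(N) < params.a
    gpick = rng.integers(0, N - 1, size=N)
    gpick = np.where(gpick < idx, gpick, gpick + 1)  # uniform over others
    half = n // 2
    offsets = np.concatenate([np.arange(-half, 0), np.arange(1, half + 1)])
    lpick = (idx + offsets[rng.integers(0, n, size=N)]) % N

    model = np.where(global_scope, gpick, lpick)
    new = np.where(pay[model] > pay, pop[model], pop)
    new = np.where(mutate, mut_type, new)
    return new.astype(np.int8)


def run_trial(
    params: ModelParams,
    generations: int,
    seed: int,
    initial: np.ndarray | None = None,
) -> TrialResult:
    """Run one trial, recording the initial state and every generation after.

    ``initial`` overrides the uniform-random starting population (used for
    controlled experiments); the RNG stream is the same either way.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    rng = np.random.default_rng(seed)
    pop = (
        validate_population(initial, params)
        if initial is not None
        else init_population(params, rng)
    )
    history = [_record(0, pop)]
    for t in range(1, generations + 1):
        pop = adapt_step(pop, params, rng)
        history.append(_record(t, pop))
    return TrialResult(params=params, seed=seed, history=history)
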