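"""Core model: strategies, ring-lattice locality statistics and expected payoffs.

The model places ``N`` players on a ring (one-dimensional regular graph of
degree 2).  Each player holds one of four strategies combining a cooperation
flag and a peer-punishment flag.  Every generation each player's payoff is the
*expected* payoff of one public-goods round with ``n + 1`` participants plus
the expected punishment flows, with three locality weights:

``g``
    weight of the global cooperator ratio in the game payoff (0 = the game is
    played with the ``n`` ring neighbours only, 1 = with the whole population).
``p``
    probability that a punisher samples its ``n`` punishment targets globally
    rather than punishing its neighbourhood.
``a``
    probability that the imitation model is drawn globally (handled in
    :mod:`ringpgg.dynamics`).

Writing ``N_C``/``n_C`` for the global/local cooperator ratios around player
``i`` (self excluded) and ``N_P``/``n_P`` for the punisher ratios, the payoff
components are::

    pi_C = b * [n * (g*N_C + (1-g)*n_C) + 1] / (n+1) - c
    pi_D = b *  n * (g*N_C + (1-g)*n_C)      / (n+1)
    pi_P = s * [p * (1-N_C) + (1-p) * (1-n_C)]
    pi_F = f * [p * N_P     + (1-p) * n_P]

and the strategy totals are CP = pi_C - pi_P, CN = pi_C,
DP = pi_D - pi_P - pi_F, DN = pi_D - pi_F.

A Monte-Carlo oracle (:func:`mc_payoff_oracle`) samples actual interaction
realizations and is used to validate the closed-form expectations.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Strategy",
    "ModelParams",
    "LocalityStats",
    "PayoffComponents",
    "STRATEGY_NAMES",
    "COOPERATES",
    "PUNISHES",
    "neighbor_indices",
    "locality_stats",
    "pi_game",
    "pi_punish_cost",
    "pi_fine",
    "payoff_components",
    "payoff_vector",
    "mc_payoff_oracle",
    "population_from_string",
    "validate_population",
]


class Strategy(enum.IntEnum):
    """The four behavioural types: cooperate/defect x punish/not."""

    CP = 0  # cooperative punisher
    CN = 1  # cooperative non-punisher
    DP = 2  # non-cooperative punisher
    DN = 3  # non-cooperative non-punisher

    @property
    def cooperates(self) -> bool:
        return self in (Strategy.CP, Strategy.CN)

    @property
    def punishes(self) -> bool:
        return self in (Strategy.CP, Strategy.DP)


STRATEGY_NAMES = np.array(["CP", "CN", "DP", "DN"])
#: boolean lookup tables indexed by strategy code
COOPERATES = np.array([True, True, False, False])
PUNISHES = np.array([True, False, True, False])


@dataclass(frozen=True)
class ModelParams:
    """All model constants.

    Defaults are the reference configuration used throughout:
    ``(N, n) = (100, 4)``, ``(b, c, f, s) = (2, 1, 6, 3)``, ``mu = 0.01``.
    The locality triple ``(g, p, a)`` defaults to the fully local case.
    """

    N: int = 100
    n: int = 4
    b: float = 2.0
    c: float = 1.0
    f: float = 6.0
    s: float = 3.0
    g: float = 0.0
    p: float = 0.0
    a: float = 0.0
    mu: float = 0.01

    def __post_init__(self) -> None:
        if self.n % 2 != 0:
            raise ValueError(f"neighborhood size n must be even, got n={self.n}")
        if not (2 <= self.n < self.N):
            raise ValueError(f"require 2 <= n < N, got n={self.n}, N={self.N}")
        for name in ("b", "c", "f", "s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("g", "p", "a", "mu"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def replace(self, **kw) -> "ModelParams":
        from dataclasses import replace as _replace

        return _replace(self, **kw)


@dataclass(frozen=True)
class LocalityStats:
    """Cooperator/punisher ratios around one player at both scopes.

    Local ratios are over the player's ``n`` ring neighbours; global ratios
    are over the other ``N - 1`` players.  All values lie in [0, 1].
    """

    nC_local: float
    nP_local: float
    NC_global: float
    NP_global: float


@dataclass(frozen=True)
class PayoffComponents:
    """Breakdown of one player's expected payoff."""

    pi_game: float
    pi_punish_cost: float
    pi_fine: float
    total: float


def validate_population(pop: np.ndarray, params: ModelParams) -> np.ndarray:
    """Coerce ``pop`` to an int8 strategy-code array and check it."""
    pop = np.asarray(pop, dtype=np.int8)
    if pop.ndim != 1 or pop.shape[0] != params.N:
        raise ValueError(f"population must be a length-{params.N} vector")
    if pop.min() < 0 or pop.max() > 3:
        raise ValueError("population contains invalid strategy codes")
    return pop


def population_from_string(spec: str) -> np.ndarray:
    """Build a population from whitespace-separated strategy ids.

    Shorthand ``C``/``D`` map to the non-punishing types CN/DN, so the
    worked configuration ``"C C C C D D D"`` is a 7-player ring of CN and DN.
    """
    alias = {"C": "CN", "D": "DN"}
    codes = []
    for tok in spec.split():
        tok = alias.get(tok, tok)
        codes.append(Strategy[tok])
    return np.array(codes, dtype=np.int8)


def neighbor_indices(i: int, params: ModelParams) -> np.ndarray:
    """Positions of player ``i``'s ``n`` ring neighbours, ``n/2`` hops each way.

    Ordered ``(i - n/2, ..., i - 1, i + 1, ..., i + n/2)`` modulo ``N``;
    ``i`` itself is excluded.
    """
    if not (0 <= i < params.N):
        raise ValueError(f"player index {i} outside [0, {params.N})")
    half = params.n // 2
    offsets = np.concatenate([np.arange(-half, 0), np.arange(1, half + 1)])
    return (i + offsets) % params.N


def _ring_neighbor_sum(x: np.ndarray, n: int) -> np.ndarray:
    """For each position, the sum of ``x`` over the n/2-hop ring neighbourhood."""
    total = np.zeros_like(x, dtype=float)
    for k in range(1, n // 2 + 1):
        total += np.roll(x, k)
        total += np.roll(x, -k)
    return total


def locality_stats(pop: np.ndarray, i: int, params: ModelParams) -> LocalityStats:
    """Exact cooperator/punisher ratios around player ``i``."""
    pop = validate_population(pop, params)
    nbrs = neighbor_indices(i, params)
    coop = COOPERATES[pop]
    pun = PUNISHES[pop]
    return LocalityStats(
        nC_local=coop[nbrs].sum() / params.n,
        nP_local=pun[nbrs].sum() / params.n,
        NC_global=(coop.sum() - coop[i]) / (params.N - 1),
        NP_global=(pun.sum() - pun[i]) / (params.N - 1),
    )


def pi_game(stats: LocalityStats, params: ModelParams, cooperates: bool) -> float:
    """Expected public-goods payoff for one player.

    The pot share is ``b * (expected contributors) / (n + 1)``; a cooperator
    adds its own token (the ``+ 1``) and pays the cost ``c``.
    """
    mix = params.g * stats.NC_global + (1.0 - params.g) * stats.nC_local
    if cooperates:
        return params.b * (params.n * mix + 1.0) / (params.n + 1) - params.c
    return params.b * params.n * mix / (params.n + 1)


def pi_punish_cost(stats: LocalityStats, params: ModelParams) -> float:
    """Expected sanction cost borne by a punisher (defector ratio in scope x s)."""
    return params.s * (
        params.p * (1.0 - stats.NC_global) + (1.0 - params.p) * (1.0 - stats.nC_local)
    )


def pi_fine(stats: LocalityStats, params: ModelParams) -> float:
    """Expected fine borne by a defector (punisher ratio in scope x f)."""
    return params.f * (params.p * stats.NP_global + (1.0 - params.p) * stats.nP_local)


def payoff_components(
    strategy: Strategy, stats: LocalityStats, params: ModelParams
) -> PayoffComponents:
    """Assemble one player's expected payoff from its components."""
    strategy = Strategy(strategy)
    game = pi_game(stats, params, strategy.cooperates)
    cost = pi_punish_cost(stats, params) if strategy.punishes else 0.0
    fine = 0.0 if strategy.cooperates else pi_fine(stats, params)
    return PayoffComponents(
        pi_game=game, pi_punish_cost=cost, pi_fine=fine, total=game - cost - fine
    )


def payoff_vector(pop: np.ndarray, params: ModelParams) -> np.ndarray:
    """Expected payoff of every player, vectorised over the ring.

    Deterministic given ``(pop, params)``: payoffs are expectations, not
    sampled realizations.
    """
    pop = validate_population(pop, params)
    N, n = params.N, params.n
    coop = COOPERATES[pop]
    pun = PUNISHES[pop]

    nC = _ring_neighbor_sum(coop, n) / n
    nP = _ring_neighbor_sum(pun, n) / n
    NC = (coop.sum() - coop) / (N - 1)
    NP = (pun.sum() - pun) / (N - 1)

    mix = params.g * NC + (1.0 - params.g) * nC
    game = np.where(
        coop,
        params.b * (n * mix + 1.0) / (n + 1) - params.c,
        params.b * n * mix / (n + 1),
    )
    cost = params.s * (params.p * (1.0 - NC) + (1.0 - params.p) * (1.0 - nC))
    fine = params.f * (params.p * NP + (1.0 - params.p) * nP)
    return game - np.where(pun, cost, 0.0) - np.where(coop, 0.0, fine)


def mc_payoff_oracle(
    pop: np.ndarray,
    i: int,
    params: ModelParams,
    n_samples: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Monte-Carlo estimate of player ``i``'s per-round payoff.

    Samples ``n_samples`` independent realizations of one round and returns
    the empirical mean and its standard error.  Realization semantics:

    * **game** — each of the ``n`` co-player slots starts as one ring
      neighbour and is independently replaced, with probability ``g``, by a
      uniform draw from the other ``N - 1`` players; the pot pays
      ``b * contributors / (n + 1)`` with ``i`` contributing iff it cooperates.
    * **sanction** — if ``i`` punishes, its scope is its ``n`` neighbours, or
      (with probability ``p``) ``n`` distinct players drawn uniformly from the
      other ``N - 1``; it pays ``s / n`` per defector in scope.
    * **fine** — if ``i`` defects, each other punisher independently resolves
      its scope the same way and ``i`` pays ``f / n`` per punisher whose scope
      contains it.  A global scope contains ``i`` with probability
      ``n / (N - 1)`` (the exact marginal of an n-out-of-(N-1) distinct draw),
      which is how inclusion is sampled.

    With per-act amounts ``s/n`` and ``f/n`` the expectations of the three
    parts equal the closed-form components used by :func:`payoff_vector`.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    pop = validate_population(pop, params)
    N, n = params.N, params.n
    coop = COOPERATES[pop]
    pun = PUNISHES[pop]
    nbrs = neighbor_indices(i, params)
    others = np.delete(np.arange(N), i)

    payoff = np.zeros(n_samples)

    # (a) game
    global_slot = rng.random((n_samples, n)) < params.g
    global_draw = others[rng.integers(0, N - 1, size=(n_samples, n))]
    partners = np.where(global_slot, global_draw, nbrs[np.newaxis, :])
    contributors = coop[partners].sum(axis=1) + int(coop[i])
    payoff += params.b * contributors / (n + 1)
    if coop[i]:
        payoff -= params.c

    # (b) sanction cost
    if pun[i]:
        global_scope = rng.random(n_samples) < params.p
        n_def = np.full(n_samples, float((~coop[nbrs]).sum()))
        m = int(global_scope.sum())
        if m:
            # n distinct draws from the N-1 others via partial sort of uniforms
            u = rng.random((m, N - 1))
            pick = np.argpartition(u, n - 1, axis=1)[:, :n]
            n_def[global_scope] = (~coop[others[pick]]).sum(axis=1)
        payoff -= params.s / n * n_def

    # (c) fines from every other punisher
    if not coop[i]:
        punishers = np.flatnonzero(pun)
        punishers = punishers[punishers != i]
        if punishers.size:
            in_my_nbrs = np.isin(punishers, nbrs)  # ring symmetry: i in nbrs(j)
            scope_global = rng.random((n_samples, punishers.size)) < params.p
            incl_global = rng.random((n_samples, punishers.size)) < n / (N - 1)
            hit = np.where(scope_global, incl_global, in_my_nbrs[np.newaxis, :])
            payoff -= params.f / n * hit.sum(axis=1)

    mean = float(payoff.mean())
    se = float(payoff.std(ddof=1) / math.sqrt(n_samples)) if n_samples > 1 else 0.0
    return mean, se
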