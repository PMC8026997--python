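# Methods

## Model

`N` players occupy the nodes of a ring; player `i`'s neighbourhood is the
`n` players within `n/2` hops (`n` even, `2 ≤ n < N`). Strategies combine a
cooperation flag with a peer-punishment flag (CP, CN, DP, DN). Payoffs are
*expectations* of one public-goods round plus expected punishment flows —
the model deliberately removes payoff stochasticity, so the only randomness
in the dynamics is model-player selection and mutation.

The game payoff mixes the local and global cooperator ratios with weight
`g` on the global ratio: each of the `n` co-player slots is effectively
drawn from the whole population with probability `g` and from the
neighbourhood otherwise, giving an expected per-co-player contribution
probability `g·N_C + (1−g)·n_C`. A cooperator adds its own token (the
`+1` in `π_C`) and pays the contribution cost `c`; the pot pays `b` per
token, split over the `n + 1` participants. Punishment works the same way
with probability `p` of global scope: a punisher's expected sanction cost
is `s` times the defector ratio in its scope, a defector's expected fine is
`f` times the punisher ratio among those who might observe it.

### Parameters

| symbol | meaning | default | notes |
|---|---|---|---|
| `N` | population size | 100 | ring length |
| `n` | neighbourhood size | 4 | `n/2` hops each way |
| `b` | benefit per contributed token | 2 | pot multiplier |
| `c` | cost of contributing | 1 | paid by cooperators |
| `f` | fine per full punisher exposure | 6 | scales `π_F` |
| `s` | sanction cost per full defector exposure | 3 | scales `π_P` |
| `g` | game globality weight | 0 | 0 = play with neighbours |
| `p` | punishment globality probability | 0 | 0 = punish neighbours |
| `a` | adaptation globality probability | 0 | 0 = imitate neighbours |
| `μ` | mutation probability per player per generation | 0.01 | |

The defaults are the reference configuration used by all built-in
experiments. Note that at these defaults `b/c = 2 < 2.5`, so a cooperator at
a cooperator–defector boundary earns less (`4b/5 − c`) than the defector
facing it (`2b/5`); game locality alone cannot stop a defector block from
growing, and sustained cooperation depends on punishers.

## Dynamics

One generation: (1) compute every player's expected payoff on the current
population; (2) simultaneously for every player, with probability `μ`
assign a uniformly random type (mutation preempts imitation and may redraw
the current type, so the effective change rate is `3μ/4`); otherwise draw
one model — uniform over the other `N − 1` players with probability `a`,
else uniform over the `n` neighbours — and copy its type iff its payoff is
*strictly* greater. Ties never fire, no noise is added to payoffs, and all
comparisons use the generation-`t` payoffs and types.

RNG discipline: each trial owns one PCG64 generator seeded by an integer.
Per generation the generator is consumed in whole-population blocks in a
fixed order (mutation coins, mutation types, scope coins, global picks,
local picks), every block drawn regardless of branch, so a trial is a pure
function of `(params, generations, seed)` and histories are bit-reproducible.
The scalar `choose_model` helper realizes the same model-choice distribution
draw-by-draw; the generation step is its vectorized counterpart (their
random streams differ, their distributions are identical — checked
statistically in the test suite).

Sweeps derive per-trial seeds by feeding `(base_seed, round(g·10⁶),
round(p·10⁶), round(a·10⁶), trial)` into a `SeedSequence`, so any cell can
be recomputed independently and bit-exactly.

## Monte-Carlo validation of the expected payoffs

`mc_payoff_oracle` samples actual single-round realizations: each neighbour
slot of the focal player's game is independently replaced by a uniform
global draw with probability `g` (so `g = 0` reproduces exactly the `n`
neighbours and a fully local round is deterministic); a punisher's global
scope is `n` distinct players drawn uniformly from the other `N − 1`; the
per-act sanction and fine are `s/n` and `f/n`, which makes the three payoff
parts unbiased for `π_game`, `π_P` and `π_F`. For the fines levied *on* the
focal player, each other punisher's global scope contains it with
probability `n/(N − 1)` — the exact marginal of the distinct-draw scope —
and inclusion is sampled directly. The acceptance suite checks 20 random
populations/parameter draws at 10⁵ samples against the closed forms within
3 standard errors; an exceedance is confirmed with an independent
4×10⁵-sample re-estimate because a fixed 3σ gate over 20 draws trips by
chance about once in twenty runs.

## Experiments

* *Sweep*: full factorial grid over `(g, p, a)` (default five values
  `{0, 0.25, 0.5, 0.75, 1}` per axis, 125 cells), replicated trials per
  cell, aggregating the **final-generation** cooperation rate
  `(|CP| + |CN|)/N` (not time-averaged). "After `T` generations" means
  history index `T`: the recorded history has `T + 1` rows including the
  initial state.
* *Dominance time*: first generation at which a strategy (or the classes
  cooperators/defectors/punishers) strictly exceeds a threshold; the
  takeover experiments use strict majority (0.5), with 0.9 available for
  sensitivity.
* *Defector fraction*: mean over trials of the final `(|DP| + |DN|)/N`.

The built-in experiment sizes (100 trials × 100 generations for single
cells; a reduced `{0, 0.5, 1}³` grid at 30 trials inside the test suite,
with the full 125-cell sweep available from the CLI) keep a complete run in
seconds to minutes on one core while leaving trial-ensemble standard errors
of a cooperation rate below ~0.03.

## Numerical choices

* Payoff arithmetic is plain double precision; test comparisons of payoffs
  use absolute tolerance 1e−12.
* Sweep CSVs are written with shortest round-tripping float repr and read
  back with pandas' `round_trip` parser, so read(write(x)) is exact and
  identical configurations yield byte-identical tables.
* Strategy matrices are written as string ids (CP/CN/DP/DN), tab-separated,
  UTF-8, LF endings; sweep rows are sorted lexicographically in `(g, p, a)`.
* Mutation draws uniform over all four types (not "other three"); the
  alternative would only rescale `μ` by 4/3.

## What the synthetic dynamics do and do not show

The simulator emulates the idealized study conditions exactly: expected
payoffs, homogeneous ring, synchronous deterministic imitation, constant
parameters. It does not model payoff stochasticity, heterogeneous or
two-dimensional networks, mobility, anti-social or pool punishment, or
execution errors — conclusions about those require extensions.

Two structural properties of the model shape (and limit) its phenomenology,
and both follow from invariants the unit tests verify:

* Punishment never directly pays: at identical locality statistics
  `Π(CN) − Π(CP) = Π(DN) − Π(DP) = π_P ≥ 0`, with equality only when the
  relevant defector ratio is zero. With `p = 0` a punisher in a locally
  defector-free region pays exactly nothing and coexists neutrally with CN;
  with `p > 0` *any* defector anywhere keeps `π_P > 0` for every punisher,
  so under strict-inequality imitation punishers are gradually displaced by
  CN whenever defectors persist (and mutation keeps resupplying defectors).
* At the default `b/c` ratio, boundary defectors out-earn boundary
  cooperators (`2b > 5c` fails), so once punishers are gone defector blocks
  erode cooperator regions one-way.

Consequently, in this implementation sustained cooperation over 100
generations from uniform random initial conditions is observed in the
fully-local-punishment cells (`p = 0`, any `a`, small `g`), while cells
with `p > 0` lose their punishers and collapse even at `g = 0`, and global
adaptation (`a = 1`) preserves an established CP/CN regime but weakens the
transient from random starts. The reduced-grid sweep computed by the
acceptance suite records these outcomes; the corresponding acceptance
checks that expect cooperation in *all* `g = 0` cells (and a defector share
near 8% at `(0, 1, 0)`) therefore fail, and are left failing deliberately
rather than being adjusted — the measured values are reported as computed.
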