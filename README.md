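# ringpgg

Agent-based simulator of **spatial public goods games with peer punishment
on a ring lattice**, in which the *locality* of three processes can be tuned
independently:

* **g** — how globally the public-goods game itself is played,
* **p** — how globally punishers look for defectors to fine,
* **a** — how globally players look for role models when imitating.

It is aimed at researchers in evolutionary game theory and social evolution
who want to study how interaction structure, sanctioning scope and learning
scope jointly determine whether cooperation survives.

## Model

`N` players sit on a ring (a one-dimensional regular graph of degree 2); a
player's neighbourhood is the `n` players within `n/2` hops. Each player
holds one of four strategies combining a cooperation flag and a punishment
flag: **CP** (cooperate & punish), **CN** (cooperate only), **DP** (defect &
punish), **DN** (defect only). Every generation each player receives the
*expected* payoff of one public-goods round with `n + 1` participants plus
expected punishment flows. With `N_C, n_C` (`N_P, n_P`) the global/local
cooperator (punisher) ratios around a player:

```
π_C = b·[n·(g·N_C + (1−g)·n_C) + 1]/(n+1) − c      (cooperator's game payoff)
π_D = b·n·(g·N_C + (1−g)·n_C)/(n+1)                (defector's game payoff)
π_P = s·[p·(1−N_C) + (1−p)·(1−n_C)]                (punisher's sanction cost)
π_F = f·[p·N_P + (1−p)·n_P]                        (defector's expected fine)

Π(CP) = π_C − π_P    Π(CN) = π_C
Π(DP) = π_D − π_P − π_F    Π(DN) = π_D − π_F
```

Adaptation is synchronous: every player simultaneously picks a model —
globally with probability `a`, otherwise among its `n` neighbours — and
copies the model's strategy **iff** the model's payoff is strictly greater;
with probability `μ` a player instead mutates to a uniformly random type.
A Monte-Carlo oracle (`mc_payoff_oracle`) samples actual interaction
realizations (per-act sanction `s/n`, per-act fine `f/n`) and validates the
closed-form expectations.

Reference parameters: `(N, n) = (100, 4)`, `(b, c, f, s) = (2, 1, 6, 3)`,
`μ = 0.01`.

## Worked example

The boundary between a cooperator block and a defector block, pattern
`C C C C D D D` on a 7-ring with `n = 4` and a fully local game (`g = 0`):

```python
>>> from ringpgg import ModelParams, payoff_vector, population_from_string
>>> pop = population_from_string("C C C C D D D")
>>> payoff_vector(pop, ModelParams(N=7, n=4, g=0.0))
array([0.2, 0.6, 0.6, 0.2, 0.8, 0.8, 0.8])
```

The third player (a cooperator whose neighbours are `CCCD`) earns
`4b/5 − c = 0.6`; the fifth (a defector with neighbours `CCDD`) earns
`2b/5 = 0.8`. The boundary cooperator only out-earns the boundary defector
when `2b > 5c` — at the defaults it does not, so without punishers a
defector block erodes a cooperator region.

A fully global regime collapses to free riding within a few tens of
generations:

```python
>>> from ringpgg import Strategy, dominance_time, run_trial
>>> trial = run_trial(ModelParams(g=1, p=1, a=1), generations=100, seed=7)
>>> trial.final.strategy_counts          # CP, CN, DP, DN
array([ 1,  0,  0, 99])
>>> dominance_time(trial, Strategy.DN, 0.5)
15
```

## Command line

```sh
ringpgg run   --seed 3 -g 0 -p 0 -a 0 --generations 100 --out out/   # one trial
ringpgg sweep --seed 1 --grid 0,0.25,0.5,0.75,1 --trials 100 --out out/
ringpgg plot  out/sweep.csv
```

`run` writes the strategy history (`history.tsv`, one row per generation,
strategy ids per agent) and its colour raster (CP light blue, CN pink, DP
red, DN dark blue; generation increasing upward). `sweep` writes a CSV with
one row per `(g, p, a)` cell — mean and standard deviation of the
final-generation cooperation rate over the trials — and `plot` renders it as
one heat-map panel per `p` (a horizontal, g vertical). All outputs are pure
functions of the configuration and base seed; sweep CSVs are byte-identical
across reruns. A YAML config can replace the flags (`--config run.yaml`,
flags override).

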