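"""Factorial locality sweeps and per-trial regime statistics.

The headline experiment runs a grid over the locality triple ``(g, p, a)``
with replicated trials per cell and aggregates the final-generation
cooperation rate — the quantity the sweep heat maps display.  Helpers
compute dominance times (first generation a strategy or class exceeds a
threshold) and mean final defector fractions for single cells.
"""

from __future__ import annotations

from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dynamics import TrialResult, run_trial
from .model import ModelParams, Strategy

__all__ = [
    "DEFAULT_GRID_VALUES",
    "SWEEP_COLUMNS",
    "default_grid",
    "trial_seed",
    "run_cell",
    "run_sweep",
    "dominance_time",
    "defector_fraction_summary",
]

DEFAULT_GRID_VALUES: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)

SWEEP_COLUMNS = [
    "g",
    "p",
    "a",
    "trials",
    "generations",
    "mean_coop",
    "sd_coop",
    "mean_defector",
]

#: strategy classes accepted wherever a single strategy is (DP+DN etc.)
_CLASSES = {
    "cooperators": (Strategy.CP, Strategy.CN),
    "defectors": (Strategy.DP, Strategy.DN),
    "punishers": (Strategy.CP, Strategy.DP),
}


def default_grid(
    values: Sequence[float] = DEFAULT_GRID_VALUES,
) -> list[tuple[float, float, float]]:
    """Full factorial grid over (g, p, a); 125 cells at the default values."""
    return list(product(values, values, values))


def trial_seed(base_seed: int, g: float, p: float, a: float, trial: int) -> int:
    """Portable per-trial seed mixing (base_seed, cell, trial index).

    Locality values are scaled to integers at 1e-6 resolution and fed with
    the base seed and trial index into a ``SeedSequence`` entropy pool, so
    sweeps parallelize deterministically and cells can be recomputed alone.
    """
    key = [
        int(base_seed),
        int(round(g * 10**6)),
        int(round(p * 10**6)),
        int(round(a * 10**6)),
        int(trial),
    ]
    return int(np.random.SeedSequence(key).generate_state(1)[0])


def run_cell(
    cell: tuple[float, float, float],
    base: ModelParams,
    trials: int,
    generations: int,
    base_seed: int,
) -> list[TrialResult]:
    """Run all trials of one grid cell with its derived seeds."""
    g, p, a = cell
    params = base.replace(g=g, p=p, a=a)
    return [
        run_trial(params, generations, trial_seed(base_seed, g, p, a, t))
        for t in range(trials)
    ]


def run_sweep(
    grid: Iterable[tuple[float, float, float]],
    base: ModelParams = ModelParams(),
    trials: int = 100,
    generations: int = 100,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Replicated sweep over a (g, p, a) grid.

    Returns one row per unique cell, sorted lexicographically in (g, p, a),
    with the mean and standard deviation of the final-generation cooperation
    rate across trials and the complementary mean defector rate.
    """
    grid = sorted(set(grid))
    if not grid:
        raise ValueError("grid must contain at least one (g, p, a) cell")
    if trials < 1:
        raise ValueError("trials must be >= 1")
    rows = []
    for cell in grid:
        results = run_cell(cell, base, trials, generations, base_seed)
        coop = np.array([r.final.cooperation_rate for r in results])
        rows.append(
            {
                "g": cell[0],
                "p": cell[1],
                "a": cell[2],
                "trials": trials,
                "generations": generations,
                "mean_coop": coop.mean(),
                "sd_coop": coop.std(ddof=1) if trials > 1 else 0.0,
                "mean_defector": 1.0 - coop.mean(),
            }
        )
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def _class_fraction(rec, strategy) -> float:
    if isinstance(strategy, str) and strategy in _CLASSES:
        return sum(rec.fraction(s) for s in _CLASSES[strategy])
    return rec.fraction(Strategy[strategy] if isinstance(strategy, str) else strategy)


def dominance_time(
    trial: TrialResult, strategy, threshold: float = 0.5
) -> int | None:
    """First generation at which ``strategy`` (or a class) exceeds ``threshold``.

    ``strategy`` is a :class:`Strategy`, its name, or one of the classes
    ``"cooperators"``, ``"defectors"``, ``"punishers"``.  Returns ``None`` if
    the threshold is never strictly exceeded.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    for rec in trial.history:
        if _class_fraction(rec, strategy) > threshold:
            return rec.generation
    return None


def defector_fraction_summary(
    cell: tuple[float, float, float],
    base: ModelParams = ModelParams(),
    trials: int = 100,
    generations: int = 100,
    base_seed: int = 0,
) -> float:
    """Mean over trials of the final-generation non-cooperator fraction."""
    results = run_cell(cell, base, trials, generations, base_seed)
    return float(np.mean([r.final.defector_rate for r in results]))
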