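"""Tables and configuration: CSV sweep tables, TSV strategy histories, YAML config.

Dialect: comma-separated with header for sweep tables, tab-separated for
strategy matrices, UTF-8, LF line endings.  Strategies are written as their
string ids (CP/CN/DP/DN) for self-documentation.  Floats are written with
shortest round-tripping precision, so reading a table back reproduces the
in-memory values exactly and identical configs yield byte-identical files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .experiments import DEFAULT_GRID_VALUES, SWEEP_COLUMNS
from .model import STRATEGY_NAMES, ModelParams, Strategy
from .dynamics import TrialResult

__all__ = [
    "RunConfig",
    "write_sweep_csv",
    "read_sweep_csv",
    "write_history",
    "read_history",
    "load_config",
    "save_config",
]


@dataclass
class RunConfig:
    """Everything needed to reproduce a run: model, experiment, output."""

    params: ModelParams = field(default_factory=ModelParams)
    grid_values: tuple[float, ...] = DEFAULT_GRID_VALUES
    trials: int = 100
    generations: int = 100
    base_seed: int = 0
    outdir: str = "out"
    verbose: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_values"] = list(self.grid_values)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "params" in d:
            d["params"] = ModelParams(**d["params"])
        if "grid_values" in d:
            d["grid_values"] = tuple(d["grid_values"])
        return cls(**d)


def _open_write(path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    return path


def write_sweep_csv(sweep: pd.DataFrame, path) -> Path:
    """Write a sweep table; deterministic (g, p, a)-lexicographic row order."""
    path = _open_write(path)
    out = sweep.loc[:, SWEEP_COLUMNS].sort_values(["g", "p", "a"])
    try:
        out.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")
    except OSError as exc:
        raise OSError(f"cannot write sweep table to {path}: {exc}") from exc
    return path


def read_sweep_csv(path) -> pd.DataFrame:
    """Read a sweep table written by :func:`write_sweep_csv`."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(SWEEP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path} is not a sweep table; missing columns {missing}")
    return df.loc[:, SWEEP_COLUMNS]


def write_history(trial: TrialResult, path) -> Path:
    """Write the (generations+1) x N strategy-id matrix of one trial.

    Row 0 is the initial state; column j is agent j in ring order; values are
    the strategy ids CP/CN/DP/DN, tab-separated.
    """
    path = _open_write(path)
    matrix = STRATEGY_NAMES[trial.strategy_matrix()]
    try:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for row in matrix:
                fh.write("\t".join(row))
                fh.write("\n")
    except OSError as exc:
        raise OSError(f"cannot write history to {path}: {exc}") from exc
    return path


def read_history(path) -> np.ndarray:
    """Read a strategy-id matrix back as strategy codes."""
    code = {name: Strategy[name].value for name in STRATEGY_NAMES}
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            rows.append([code[tok] for tok in line.split()])
    return np.array(rows, dtype=np.int8)


def save_config(config: RunConfig, path) -> Path:
    path = _open_write(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    return path


def load_config(path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))
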