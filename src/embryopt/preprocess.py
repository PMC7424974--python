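"""Min-max scaling to [0, 1] and random train/test splitting.

Inputs and targets are scaled to the unit interval before model fitting;
predictions are mapped back to natural units (percent, embryos per explant)
before any error metric is computed, so reported RMSE/MAE are in natural
units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ScalingParams", "fit_scaler", "split"]


@dataclass(frozen=True)
class ScalingParams:
    """Per-variable observed minima and maxima, fitted on training data only."""

    minima: dict[str, float]
    maxima: dict[str, float]

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.minima)

    def _check(self, variables) -> None:
        unknown = [v for v in variables if v not in self.minima]
        if unknown:
            raise KeyError(f"variables not covered by scaler: {unknown}")

    def apply(self, table: pd.DataFrame | dict) -> pd.DataFrame:
        """Map each covered column linearly so that [min, max] -> [0, 1].

        Out-of-range values map linearly outside [0, 1]; no clipping.
        """
        table = pd.DataFrame(table)
        cols = [c for c in table.columns if c in self.minima]
        self._check(cols)
        out = table.copy()
        for c in cols:
            out[c] = (table[c] - self.minima[c]) / (self.maxima[c] - self.minima[c])
        return out

    def invert(self, scaled: pd.DataFrame | dict) -> pd.DataFrame:
        table = pd.DataFrame(scaled)
        cols = [c for c in table.columns if c in self.minima]
        self._check(cols)
        out = table.copy()
        for c in cols:
            out[c] = table[c] * (self.maxima[c] - self.minima[c]) + self.minima[c]
        return out

    def apply_array(self, x: np.ndarray, variables: list[str]) -> np.ndarray:
        """Array form of :meth:`apply` for named columns of ``x``."""
        self._check(variables)
        lo = np.array([self.minima[v] for v in variables])
        hi = np.array([self.maxima[v] for v in variables])
        return (np.asarray(x, float) - lo) / (hi - lo)

    def invert_array(self, x: np.ndarray, variables: list[str]) -> np.ndarray:
        self._check(variables)
        lo = np.array([self.minima[v] for v in variables])
        hi = np.array([self.maxima[v] for v in variables])
        return np.asarray(x, float) * (hi - lo) + lo

    def to_json(self) -> str:
        return json.dumps(
            {v: {"min": self.minima[v], "max": self.maxima[v]} for v in self.minima}
        )

    @classmethod
    def from_json(cls, doc: str) -> "ScalingParams":
        data = json.loads(doc)
        return cls(
            minima={v: d["min"] for v, d in data.items()},
            maxima={v: d["max"] for v, d in data.items()},
        )


def fit_scaler(table: pd.DataFrame, variables: list[str]) -> ScalingParams:
    """Observe per-variable min/max; reject constant (degenerate) variables."""
    minima, maxima = {}, {}
    for v in variables:
        col = table[v].to_numpy(float)
        if len(np.unique(col)) < 2:
            raise ValueError(f"variable {v!r} is constant; cannot min-max scale")
        minima[v], maxima[v] = float(col.min()), float(col.max())
    return ScalingParams(minima=minima, maxima=maxima)


def split(
    table: pd.DataFrame, train_fraction: float = 0.75, seed: int | np.random.Generator = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random row-level partition into train and test tables.

    ``|train| = round(train_fraction * N)``; replicates of one treatment may
    land in both partitions (no stratification).  Deterministic per seed.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(table)
    n_train = int(round(train_fraction * n))
    if n_train == 0 or n_train == n:
        raise ValueError(f"train_fraction {train_fraction} leaves an empty partition")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = table.iloc[np.sort(perm[:n_train])].reset_index(drop=True)
    test = table.iloc[np.sort(perm[n_train:])].reset_index(drop=True)
    return train, test
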