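"""Variable-importance ranking by remove-and-retrain sensitivity.

For each input, the model is retrained from scratch without that input
(re-tuned under the same grid and seed policy) and its RMSE over the full
replicate table is compared with the all-inputs baseline:

    VSE_j  = RMSE of the model with input j removed
    VSR_j  = VSE_j / baseline RMSE

A VSR near 1 marks an input the model class can do without; the larger the
ratio, the more important the input.  Inputs are ranked by descending VSR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import FACTOR_NAMES
from .metrics import rmse
from .mlp import LMConfig, tune_mlp
from .preprocess import fit_scaler
from .svr import SVRHyperGrid, fit_response, tune_svr

__all__ = ["SensitivityReport", "compute_sensitivity"]


@dataclass
class SensitivityReport:
    """Per-input sensitivity of one response model."""

    target_name: str
    model_family: str
    baseline_rmse: float
    inputs: tuple[str, ...]
    vse: dict[str, float]
    vsr: dict[str, float]
    rank: dict[str, int]  # 1 = most important

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "input": list(self.inputs),
                "vse": [self.vse[v] for v in self.inputs],
                "vsr": [self.vsr[v] for v in self.inputs],
                "rank": [self.rank[v] for v in self.inputs],
            }
        )


def _fit_family(
    table: pd.DataFrame,
    target_name: str,
    model_family: str,
    inputs: tuple[str, ...],
    svr_grid: SVRHyperGrid,
    mlp_config: LMConfig,
):
    """Tune and fit one model on the given inputs; returns the fitted model."""
    scaler = fit_scaler(table, list(inputs) + [target_name])
    if model_family == "svr":
        Xs = scaler.apply_array(table[list(inputs)].to_numpy(float), list(inputs))
        ys = scaler.apply_array(table[[target_name]].to_numpy(float), [target_name]).ravel()
        C, eps, gamma, _ = tune_svr(Xs, ys, svr_grid)
        return fit_response(
            table, target_name, scaler, C, eps, gamma, input_names=inputs
        )
    return tune_mlp(table, target_name, scaler, config=mlp_config, input_names=inputs)


def compute_sensitivity(
    table: pd.DataFrame,
    target_name: str,
    model_family: str = "svr",
    inputs: tuple[str, ...] = FACTOR_NAMES,
    svr_grid: SVRHyperGrid | None = None,
    mlp_config: LMConfig | None = None,
    mode: str = "retrain",
) -> SensitivityReport:
    """Remove-and-retrain sensitivity of one response over the full table.

    The baseline model uses all inputs; each reduced model is re-tuned and
    refitted on the remaining inputs, and all models are scored by RMSE on
    every row of ``table``.  ``mode="zero"`` instead keeps the full model
    and substitutes the removed input by its observed minimum (a cheaper,
    cruder probe, kept for comparison).  Ties in the ranking break by input
    order.
    """
    if model_family not in ("svr", "mlp"):
        raise ValueError(f"unknown model family {model_family!r}")
    if mode not in ("retrain", "zero"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(inputs) < 2:
        raise ValueError("need at least 2 inputs to compare removals")
    svr_grid = svr_grid if svr_grid is not None else SVRHyperGrid()
    mlp_config = mlp_config if mlp_config is not None else LMConfig()

    observed = table[target_name].to_numpy(float)
    baseline = _fit_family(table, target_name, model_family, tuple(inputs), svr_grid, mlp_config)
    baseline_rmse = rmse(observed, baseline.predict(table))
    if baseline_rmse == 0:
        raise ZeroDivisionError(
            "baseline RMSE is zero; sensitivity ratio undefined"
        )

    vse: dict[str, float] = {}
    for removed in inputs:
        if mode == "retrain":
            kept = tuple(v for v in inputs if v != removed)
            reduced = _fit_family(
                table, target_name, model_family, kept, svr_grid, mlp_config
            )
            pred = reduced.predict(table[list(kept)])
        else:
            probe = table.copy()
            probe[removed] = table[removed].min()
            pred = baseline.predict(probe)
        vse[removed] = rmse(observed, pred)

    vsr = {v: vse[v] / baseline_rmse for v in inputs}
    order = sorted(inputs, key=lambda v: (-vsr[v], inputs.index(v)))
    rank = {v: i + 1 for i, v in enumerate(order)}
    return SensitivityReport(
        target_name=target_name,
        model_family=model_family,
        baseline_rmse=baseline_rmse,
        inputs=tuple(inputs),
        vse=vse,
        vsr=vsr,
        rank=rank,
    )
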