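"""End-to-end study runner: data -> scaling/split -> SVR and MLP fits ->
metrics -> sensitivity -> NSGA-II optimization -> ideal-point selection.

A single integer seed drives every stochastic stage (replicate expansion,
splitting, cross-validation folds, weight initialization, the genetic
algorithm), so two runs with the same configuration are identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as perf
from .dataset import (
    FACTOR_NAMES,
    RESPONSE_NAMES,
    SurfaceConfig,
    expand_replicates,
    generate_surface,
    load_treatment_means,
    observed_ideal_point,
)
from .mlp import LMConfig, MLPModel, tune_mlp
from .moo import NSGAConfig, OptimizationResult, nsga2_optimize, select_ideal_point
from .preprocess import ScalingParams, fit_scaler, split
from .sensitivity import SensitivityReport, compute_sensitivity
from .svr import SVRHyperGrid, SVRModel, fit_response, tune_svr

__all__ = [
    "RunConfig",
    "StudyReport",
    "run_study",
    "compare_models",
    "sweep_model_metrics",
]

logger = logging.getLogger(__name__)

#: objectives maximized by the optimization stage
OPTIMIZED_RESPONSES = ("emb_pct", "num")


@dataclass
class RunConfig:
    """Configuration of one full study run."""

    seed: int = 0
    data: str = "bundled"  # "bundled", a CSV path, or "synthetic"
    surface: SurfaceConfig | None = None  # used when data == "synthetic"
    n_reps: int = 9
    train_fraction: float = 0.75
    svr_grid: SVRHyperGrid | None = None
    mlp_config: LMConfig | None = None
    nsga: NSGAConfig | None = None
    run_mlp: bool = True
    run_sensitivity: bool = True
    run_optimization: bool = True
    #: surrogates handed to the optimizer are refit on the full table by
    #: default; set False to optimize the train-partition models instead
    refit_on_full: bool = True
    out_dir: str | Path | None = None


@dataclass
class StudyReport:
    """Everything one run produces."""

    config: RunConfig
    replicates: pd.DataFrame
    scaler: ScalingParams
    metrics: pd.DataFrame  # model x response x partition rows
    svr_models: dict[str, SVRModel]
    mlp_models: dict[str, MLPModel]
    svr_hyperparams: dict[str, tuple[float, float, float]]
    sensitivity: dict[str, SensitivityReport]
    optimization: OptimizationResult | None
    seeds: dict[str, int]


def _stage_seeds(seed: int) -> dict[str, int]:
    """Independent per-stage substreams derived from the one run seed."""
    ss = np.random.SeedSequence(seed)
    names = ("expand", "split", "cv", "mlp", "nsga")
    children = ss.spawn(len(names))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, children)
    }


def run_study(config: RunConfig | None = None) -> StudyReport:
    """Execute the full modeling-and-optimization study.

    Stages: load or simulate the replicate table; split; min-max scale on
    the training partition; grid-tune and fit one SVR and one MLP per
    response; score R2/RMSE/MAE per partition in natural units; rank input
    importance for each response; run NSGA-II on the embryogenesis-rate and
    embryo-count surrogates and select the ideal-point compromise.
    """
    if config is None:
        config = RunConfig()
    seeds = _stage_seeds(config.seed)
    t_start = time.perf_counter()

    # --- data ---------------------------------------------------------------
    if config.data == "bundled":
        means = load_treatment_means()
        replicates = expand_replicates(means, config.n_reps, seed=seeds["expand"])
        ideal = observed_ideal_point(means)
    elif config.data == "synthetic":
        surface = config.surface if config.surface is not None else SurfaceConfig()
        replicates = generate_surface(surface, seed=seeds["expand"])
        ideal = np.array(
            [replicates[r].max() for r in OPTIMIZED_RESPONSES]
        )
    else:
        replicates = pd.read_csv(config.data)
        missing = (set(FACTOR_NAMES) | set(RESPONSE_NAMES)) - set(replicates.columns)
        if missing:
            raise ValueError(f"input CSV lacks columns {sorted(missing)}")
        ideal = np.array([replicates[r].max() for r in OPTIMIZED_RESPONSES])
    logger.info("stage=data rows=%d source=%s", len(replicates), config.data)

    train, test = split(replicates, config.train_fraction, seed=seeds["split"])
    scaler = fit_scaler(train, list(FACTOR_NAMES) + list(RESPONSE_NAMES))
    logger.info("stage=split train=%d test=%d", len(train), len(test))

    svr_grid = config.svr_grid if config.svr_grid is not None else SVRHyperGrid()
    svr_grid = SVRHyperGrid(
        C=svr_grid.C, epsilon=svr_grid.epsilon, gamma=svr_grid.gamma,
        k=svr_grid.k, seed=seeds["cv"], fold_max_iter=svr_grid.fold_max_iter,
    )
    mlp_config = config.mlp_config if config.mlp_config is not None else LMConfig()
    mlp_config = LMConfig(
        max_epochs=mlp_config.max_epochs, mu0=mlp_config.mu0,
        mu_increase=mlp_config.mu_increase, mu_decrease=mlp_config.mu_decrease,
        mu_max=mlp_config.mu_max, grad_tol=mlp_config.grad_tol,
        val_fraction=mlp_config.val_fraction, patience=mlp_config.patience,
        seed=seeds["mlp"], hidden_sizes=mlp_config.hidden_sizes,
    )

    # --- models and metrics -------------------------------------------------
    Xtr = scaler.apply_array(train[list(FACTOR_NAMES)].to_numpy(float), list(FACTOR_NAMES))
    rows = []
    svr_models: dict[str, SVRModel] = {}
    mlp_models: dict[str, MLPModel] = {}
    svr_hyper: dict[str, tuple[float, float, float]] = {}
    for resp in RESPONSE_NAMES:
        ytr = scaler.apply_array(train[[resp]].to_numpy(float), [resp]).ravel()
        t0 = time.perf_counter()
        C, eps, gamma, cv = tune_svr(Xtr, ytr, svr_grid)
        svr_hyper[resp] = (C, eps, gamma)
        svr_models[resp] = fit_response(train, resp, scaler, C, eps, gamma)
        logger.info(
            "stage=svr target=%s C=%g eps=%g gamma=%g cv_rmse=%.4f wall=%.1fs",
            resp, C, eps, gamma, cv, time.perf_counter() - t0,
        )
        models = {"svr": svr_models[resp]}
        if config.run_mlp:
            t0 = time.perf_counter()
            mlp_models[resp] = tune_mlp(train, resp, scaler, config=mlp_config)
            logger.info(
                "stage=mlp target=%s hidden=%d wall=%.1fs",
                resp, mlp_models[resp].hidden_size, time.perf_counter() - t0,
            )
            models["mlp"] = mlp_models[resp]
        for family, model in models.items():
            for part, table in (("train", train), ("test", test)):
                pred = model.predict(table)
                obs = table[resp].to_numpy(float)
                rows.append(
                    {
                        "model": family,
                        "response": resp,
                        "partition": part,
                        "r2": perf.r_squared(obs, pred),
                        "rmse": perf.rmse(obs, pred),
                        "mae": perf.mae(obs, pred),
                        "n": len(table),
                    }
                )
    metrics = pd.DataFrame(rows)

    # --- sensitivity --------------------------------------------------------
    sensitivity: dict[str, SensitivityReport] = {}
    if config.run_sensitivity:
        for resp in RESPONSE_NAMES:
            t0 = time.perf_counter()
            sensitivity[resp] = compute_sensitivity(
                replicates, resp, model_family="svr", svr_grid=svr_grid,
            )
            logger.info(
                "stage=sensitivity target=%s wall=%.1fs", resp, time.perf_counter() - t0
            )

    # --- optimization -------------------------------------------------------
    optimization = None
    if config.run_optimization:
        nsga = config.nsga if config.nsga is not None else NSGAConfig()
        nsga = NSGAConfig(
            population_size=nsga.population_size, generations=nsga.generations,
            crossover_rate=nsga.crossover_rate, mutation_rate=nsga.mutation_rate,
            selection_scheme=nsga.selection_scheme, sbx_eta=nsga.sbx_eta,
            mutation_eta=nsga.mutation_eta, bounds=nsga.bounds, seed=seeds["nsga"],
        )
        surrogate_table = replicates if config.refit_on_full else train
        surrogates = {
            resp: fit_response(surrogate_table, resp, scaler, *svr_hyper[resp])
            for resp in OPTIMIZED_RESPONSES
        }

        def objectives(X: np.ndarray) -> np.ndarray:
            return np.stack(
                [surrogates[r].predict(X) for r in OPTIMIZED_RESPONSES], axis=1
            )

        t0 = time.perf_counter()
        front_X, front_F = nsga2_optimize(objectives, nsga)
        optimization = select_ideal_point(front_X, front_F, ideal)
        logger.info(
            "stage=nsga front=%d selected=%s objectives=%s wall=%.1fs",
            len(front_X),
            np.round(optimization.selected_decision, 3).tolist(),
            np.round(optimization.selected_objectives, 3).tolist(),
            time.perf_counter() - t0,
        )

    report = StudyReport(
        config=config,
        replicates=replicates,
        scaler=scaler,
        metrics=metrics,
        svr_models=svr_models,
        mlp_models=mlp_models,
        svr_hyperparams=svr_hyper,
        sensitivity=sensitivity,
        optimization=optimization,
        seeds=seeds,
    )
    if config.out_dir is not None:
        _write_artifacts(report, Path(config.out_dir))
    logger.info("stage=done wall=%.1fs", time.perf_counter() - t_start)
    return report


def sweep_model_metrics(
    seeds,
    include_mlp: bool = True,
    base_config: RunConfig | None = None,
) -> pd.DataFrame:
    """Repeat the modeling stage over several run seeds.

    Each seed drives a fresh replicate expansion, split, tuning and fit; the
    returned frame is the concatenated per-run metrics with a ``seed``
    column, from which seed-median performance statistics are computed.
    """
    frames = []
    for seed in seeds:
        base = base_config if base_config is not None else RunConfig()
        cfg = RunConfig(
            seed=int(seed), data=base.data, surface=base.surface,
            n_reps=base.n_reps, train_fraction=base.train_fraction,
            svr_grid=base.svr_grid, mlp_config=base.mlp_config,
            run_mlp=include_mlp, run_sensitivity=False, run_optimization=False,
        )
        report = run_study(cfg)
        frame = report.metrics.copy()
        frame.insert(0, "seed", int(seed))
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def compare_models(report: StudyReport) -> pd.DataFrame:
    """Side-by-side SVR vs MLP table with a winner flag per cell.

    The better model has the greater R2 or the smaller RMSE/MAE; exact ties
    are flagged as such.
    """
    m = report.metrics
    if set(m["model"]) != {"svr", "mlp"}:
        raise ValueError("comparison requires both model families")
    rows = []
    higher_better = {"r2": True, "rmse": False, "mae": False}
    for (resp, part), grp in m.groupby(["response", "partition"], sort=False):
        svr_row = grp[grp["model"] == "svr"].iloc[0]
        mlp_row = grp[grp["model"] == "mlp"].iloc[0]
        for metric, hb in higher_better.items():
            a, b = float(svr_row[metric]), float(mlp_row[metric])
            if a == b:
                winner = "tie"
            elif (a > b) == hb:
                winner = "svr"
            else:
                winner = "mlp"
            rows.append(
                {
                    "response": resp,
                    "partition": part,
                    "metric": metric,
                    "svr": a,
                    "mlp": b,
                    "winner": winner,
                }
            )
    return pd.DataFrame(rows)


def _write_artifacts(report: StudyReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    report.replicates.to_csv(out_dir / "replicates.csv", index=False)
    report.metrics.to_csv(out_dir / "metrics.csv", index=False)
    for resp, sens in report.sensitivity.items():
        sens.to_frame().to_csv(out_dir / f"sensitivity_{resp}.csv", index=False)
    opt = report.optimization
    if opt is not None:
        front = pd.DataFrame(
            np.hstack([opt.front_decisions, opt.front_objectives]),
            columns=list(FACTOR_NAMES) + list(OPTIMIZED_RESPONSES),
        )
        front.to_csv(out_dir / "pareto_front.csv", index=False)
    summary = {
        "seed": report.config.seed,
        "stage_seeds": report.seeds,
        "svr_hyperparams": {
            k: {"C": v[0], "epsilon": v[1], "gamma": v[2]}
            for k, v in report.svr_hyperparams.items()
        },
        "scaler": json.loads(report.scaler.to_json()),
        "optimum": None
        if opt is None
        else {
            "decision": opt.selected_decision.tolist(),
            "objectives": opt.selected_objectives.tolist(),
            "ideal": opt.ideal.tolist(),
            "distance": opt.distance,
        },
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
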