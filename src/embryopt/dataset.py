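"""Factorial tissue-culture dataset: bundled treatment means, replicate
reconstruction, and synthetic response surfaces.

The bundled dataset is a 4 x 4 x 4 full factorial over three plant growth
regulators applied to chrysanthemum leaf explants -- 2,4-D (a synthetic
auxin), kinetin (a cytokinin) and sodium nitroprusside (a nitric-oxide
donor) -- with three responses per treatment: callogenesis rate (%),
embryogenesis rate (%) and somatic embryo count per explant.  The published
summary reports, per treatment, the mean and standard error over nine
replications.  Model fitting operates on replicate-level rows, which this
module reconstructs by exact moment matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "FACTOR_NAMES",
    "FACTOR_LEVELS",
    "RESPONSE_NAMES",
    "RESPONSE_BOUNDS",
    "SurfaceConfig",
    "load_treatment_means",
    "expand_replicates",
    "generate_surface",
    "summarize_replicates",
    "observed_ideal_point",
]

logger = logging.getLogger(__name__)

FACTOR_NAMES = ("d24_uM", "kin_uM", "snp_uM")
FACTOR_LEVELS = {
    "d24_uM": (0.0, 4.54, 9.09, 13.63),
    "kin_uM": (0.0, 4.65, 9.29, 13.94),
    "snp_uM": (0.0, 10.0, 20.0, 40.0),
}
RESPONSE_NAMES = ("cal_pct", "emb_pct", "num")
#: valid range per response (rates are percentages; counts are nonnegative)
RESPONSE_BOUNDS = {
    "cal_pct": (0.0, 100.0),
    "emb_pct": (0.0, 100.0),
    "num": (0.0, np.inf),
}
_MEAN_COLS = {"cal_pct": "cal_mean", "emb_pct": "emb_mean", "num": "num_mean"}
_SE_COLS = {"cal_pct": "cal_se", "emb_pct": "emb_se", "num": "num_se"}

_FIXTURE_NAME = "chrysanthemum_factorial.csv"


def load_treatment_means() -> pd.DataFrame:
    """Load the bundled 64-treatment factorial summary (mean +/- SE, n = 9).

    Returns a DataFrame with columns ``d24_uM, kin_uM, snp_uM`` and, per
    response, ``*_mean`` and ``*_se``.  Raises ``ValueError`` if the bundled
    file fails its structural checks (one row per factor combination, valid
    ranges).
    """
    ref = resources.files("embryopt.data").joinpath(_FIXTURE_NAME)
    with ref.open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh)

    expected_cols = list(FACTOR_NAMES) + [
        c for r in RESPONSE_NAMES for c in (_MEAN_COLS[r], _SE_COLS[r])
    ]
    if sorted(df.columns) != sorted(expected_cols):
        raise ValueError(f"corrupted dataset: columns {list(df.columns)}")
    if len(df) != 64:
        raise ValueError(f"corrupted dataset: {len(df)} rows, expected 64")
    for name in FACTOR_NAMES:
        levels = np.asarray(FACTOR_LEVELS[name])
        if not np.isin(df[name].to_numpy(), levels).all():
            raise ValueError(f"corrupted dataset: unexpected {name} level")
    combos = df[list(FACTOR_NAMES)].drop_duplicates()
    if len(combos) != 64:
        raise ValueError("corrupted dataset: duplicate factor combinations")
    stats = df[[c for c in expected_cols if c not in FACTOR_NAMES]]
    if (stats.to_numpy() < 0).any():
        raise ValueError("corrupted dataset: negative mean or SE")
    if (df[["cal_mean", "emb_mean"]].to_numpy() > 100).any():
        raise ValueError("corrupted dataset: rate mean above 100%")
    return df


def observed_ideal_point(means: pd.DataFrame | None = None) -> np.ndarray:
    """Best observed (embryogenesis rate %, embryo count) over all treatments.

    This is the ideal point the Pareto-front selection rule measures
    distances against.
    """
    if means is None:
        means = load_treatment_means()
    return np.array([means["emb_mean"].max(), means["num_mean"].max()])


def expand_replicates(
    means: pd.DataFrame, n_reps: int = 9, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Reconstruct replicate-level rows matching each printed mean and SE.

    For every treatment and response, ``n_reps`` pseudo-random normal draws
    are affinely standardized so that their sample mean equals the printed
    mean and their sample standard error (SD/sqrt(n), ddof=1) equals the
    printed SE, exactly.  Values are then clipped to the valid response range;
    where clipping binds, exact moment matching is impossible and the
    deviation is logged as a warning rather than silently re-projected.

    Returns a DataFrame with columns
    ``d24_uM, kin_uM, snp_uM, rep, cal_pct, emb_pct, num``.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 (standard error undefined)")
    se_cols = [c for c in means.columns if c.endswith("_se")]
    if not np.isfinite(means[se_cols].to_numpy()).all():
        raise ValueError("all standard errors must be finite")

    rng = np.random.default_rng(seed)
    rows = {name: np.repeat(means[name].to_numpy(), n_reps) for name in FACTOR_NAMES}
    rows["rep"] = np.tile(np.arange(1, n_reps + 1), len(means))

    for resp in RESPONSE_NAMES:
        mu = means[_MEAN_COLS[resp]].to_numpy(float)
        se = means[_SE_COLS[resp]].to_numpy(float)
        lo, hi = RESPONSE_BOUNDS[resp]
        out = np.empty((len(means), n_reps))
        for i in range(len(means)):
            out[i] = _match_moments(rng, n_reps, mu[i], se[i])
        clipped = np.clip(out, lo, hi)
        moved = clipped != out
        if moved.any():
            for i in np.nonzero(moved.any(axis=1))[0]:
                new_mu = clipped[i].mean()
                new_se = clipped[i].std(ddof=1) / np.sqrt(n_reps)
                logger.warning(
                    "clipping bound %s at (%g, %g, %g): mean %.2f -> %.4f, "
                    "SE %.2f -> %.4f",
                    resp,
                    means[FACTOR_NAMES[0]].iloc[i],
                    means[FACTOR_NAMES[1]].iloc[i],
                    means[FACTOR_NAMES[2]].iloc[i],
                    mu[i],
                    new_mu,
                    se[i],
                    new_se,
                )
        rows[resp] = clipped.ravel()

    return pd.DataFrame(rows)


def _match_moments(
    rng: np.random.Generator, n: int, mean: float, se: float
) -> np.ndarray:
    """n draws with sample mean exactly `mean` and sample SE exactly `se`."""
    if se == 0.0:
        return np.full(n, mean)
    z = rng.standard_normal(n)
    z = z - z.mean()
    sd = z.std(ddof=1)
    if sd < 1e-12:  # vanishing spread of the raw draws; redraw deterministically
        z = np.linspace(-1.0, 1.0, n)
        z = z - z.mean()
        sd = z.std(ddof=1)
    target_sd = se * np.sqrt(n)
    return mean + z * (target_sd / sd)


def summarize_replicates(replicates: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate rows back to per-treatment mean +/- SE.

    Inverse of :func:`expand_replicates` where clipping did not bind.
    """
    grouped = replicates.groupby(list(FACTOR_NAMES), sort=False)
    out = {}
    for resp in RESPONSE_NAMES:
        agg = grouped[resp].agg(["mean", "sem"])
        out[_MEAN_COLS[resp]] = agg["mean"]
        out[_SE_COLS[resp]] = agg["sem"]
    return pd.DataFrame(out).reset_index()


@dataclass
class SurfaceConfig:
    """Smooth Gaussian-peak response surfaces with additive noise.

    Each response is ``height * exp(-sum_j ((x_j - peak_j) / width_j)^2)``
    plus Gaussian noise, clipped to its valid range.  Defaults emulate the
    bundled factorial: same factor levels, nine replicates, peaks near the
    best observed treatment, heights at the observed maxima.
    """

    peak_location: tuple[float, float, float] = (9.09, 4.65, 20.0)
    widths: tuple[float, float, float] = (4.0, 5.0, 18.0)
    peak_heights: dict[str, float] = field(
        default_factory=lambda: {"cal_pct": 100.0, "emb_pct": 100.0, "num": 57.8}
    )
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"cal_pct": 5.0, "emb_pct": 5.0, "num": 1.0}
    )
    n_reps: int = 9
    factor_levels: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in FACTOR_LEVELS.items()}
    )

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.widths):
            raise ValueError("widths must be strictly positive")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValueError("noise_sd must be non-negative")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if any(len(v) == 0 for v in self.factor_levels.values()):
            raise ValueError("factor level lists must be non-empty")

    def response(self, X: np.ndarray, resp: str) -> np.ndarray:
        """Noiseless surface value at natural-unit inputs X (m, 3)."""
        X = np.atleast_2d(np.asarray(X, float))
        z = (X - np.asarray(self.peak_location)) / np.asarray(self.widths)
        return self.peak_heights[resp] * np.exp(-(z**2).sum(axis=1))


def generate_surface(config: SurfaceConfig, seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Full-factorial replicate table from a :class:`SurfaceConfig`.

    Deterministic for a fixed seed; same schema as :func:`expand_replicates`.
    """
    rng = np.random.default_rng(seed)
    grids = np.meshgrid(
        *[np.asarray(config.factor_levels[name], float) for name in FACTOR_NAMES],
        indexing="ij",
    )
    X = np.stack([g.ravel() for g in grids], axis=1)
    n_cells = len(X)
    rows = {
        name: np.repeat(X[:, j], config.n_reps)
        for j, name in enumerate(FACTOR_NAMES)
    }
    rows["rep"] = np.tile(np.arange(1, config.n_reps + 1), n_cells)
    for resp in RESPONSE_NAMES:
        clean = np.repeat(config.response(X, resp), config.n_reps)
        noisy = clean + rng.standard_normal(clean.shape) * config.noise_sd[resp]
        lo, hi = RESPONSE_BOUNDS[resp]
        rows[resp] = np.clip(noisy, lo, hi)
    return pd.DataFrame(rows)
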