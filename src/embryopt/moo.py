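"""NSGA-II multi-objective search over the three regulator concentrations,
with ideal-point selection of a single compromise from the Pareto front.

The search maximizes two surrogate-predicted responses (embryogenesis rate
and embryo count) over box bounds given by the experimental ranges.  The
generational loop is the standard elitist NSGA-II: fast non-dominated
sorting, crowding distance, simulated binary crossover and polynomial
mutation; parent selection defaults to a roulette wheel on fitness
1/(1 + rank), with the canonical crowded binary tournament available.

The final answer is the front member closest (Euclidean, in raw objective
units) to the ideal point -- the best observed value of each objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .dataset import FACTOR_LEVELS, FACTOR_NAMES

__all__ = [
    "NSGAConfig",
    "OptimizationResult",
    "fast_nondominated_sort",
    "crowding_distance",
    "nsga2_optimize",
    "select_ideal_point",
]

#: experimental concentration ranges, the default search box
DEFAULT_BOUNDS = tuple(
    (min(FACTOR_LEVELS[name]), max(FACTOR_LEVELS[name])) for name in FACTOR_NAMES
)


def fast_nondominated_sort(points: np.ndarray) -> list[np.ndarray]:
    """Deb's fast non-dominated sorting for maximization.

    ``a`` dominates ``b`` iff ``a >= b`` component-wise with at least one
    strict inequality.  Returns index arrays, best front first; every point
    appears in exactly one front.  Equal vectors do not dominate each other.
    """
    F = np.atleast_2d(np.asarray(points, float))
    n = len(F)
    if n == 0:
        return []
    ge = (F[:, None, :] >= F[None, :, :]).all(axis=2)
    gt = (F[:, None, :] > F[None, :, :]).any(axis=2)
    dominates = ge & gt  # dominates[i, j]: i dominates j
    n_dominators = dominates.sum(axis=0)
    fronts: list[np.ndarray] = []
    remaining = np.ones(n, dtype=bool)
    while remaining.any():
        front = remaining & (n_dominators == 0)
        if not front.any():  # unreachable for a valid dominance relation
            raise RuntimeError("cyclic dominance relation")
        idx = np.nonzero(front)[0]
        fronts.append(idx)
        remaining[idx] = False
        n_dominators = n_dominators - dominates[idx].sum(axis=0)
    return fronts


def crowding_distance(front: np.ndarray) -> np.ndarray:
    """NSGA-II crowding distance of each point within one front.

    Boundary points per objective get +inf; interior points accumulate the
    normalized span of their neighbours; objectives with zero range
    contribute nothing.
    """
    F = np.atleast_2d(np.asarray(front, float))
    n, m = F.shape
    d = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for j in range(m):
        order = np.argsort(F[:, j], kind="stable")
        span = F[order[-1], j] - F[order[0], j]
        d[order[0]] = d[order[-1]] = np.inf
        if span > 0:
            d[order[1:-1]] += (F[order[2:], j] - F[order[:-2], j]) / span
    return d


@dataclass
class NSGAConfig:
    """Search settings; the defaults follow the published run (population
    200, 1000 generations, crossover 0.7, per-gene mutation 0.5)."""

    population_size: int = 200
    generations: int = 1000
    crossover_rate: float = 0.7
    mutation_rate: float = 0.5
    selection_scheme: str = "roulette"  # or "crowded_tournament"
    sbx_eta: float = 20.0
    mutation_eta: float = 20.0
    bounds: tuple[tuple[float, float], ...] = DEFAULT_BOUNDS
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.crossover_rate <= 1 and 0 <= self.mutation_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if self.population_size < 4 or self.population_size % 2:
            raise ValueError("population must be even and >= 4")
        if self.selection_scheme not in ("roulette", "crowded_tournament"):
            raise ValueError(f"unknown selection scheme {self.selection_scheme!r}")
        for lo, hi in self.bounds:
            if not np.isfinite([lo, hi]).all() or hi <= lo:
                raise ValueError("bounds must be finite with hi > lo")


@dataclass
class OptimizationResult:
    """Pareto front plus the ideal-point-selected compromise."""

    front_decisions: np.ndarray  # (n_front, n_dec)
    front_objectives: np.ndarray  # (n_front, n_obj)
    selected_decision: np.ndarray
    selected_objectives: np.ndarray
    ideal: np.ndarray
    distance: float


def _sbx(
    parents: np.ndarray,
    rng: np.random.Generator,
    eta: float,
    rate: float,
    lo: np.ndarray,
    hi: np.ndarray,
) -> np.ndarray:
    """Simulated binary crossover on consecutive pairs (vectorized).

    Children are clipped to the box so the downstream bounded mutation
    operates on feasible points.
    """
    children = parents.copy()
    half = len(parents) // 2
    p1 = parents[:half]
    p2 = parents[half:]
    cross = rng.random(half) < rate
    u = rng.random(p1.shape)
    beta = np.where(
        u <= 0.5,
        (2.0 * u) ** (1.0 / (eta + 1.0)),
        (1.0 / (2.0 * (1.0 - u))) ** (1.0 / (eta + 1.0)),
    )
    c1 = 0.5 * ((1 + beta) * p1 + (1 - beta) * p2)
    c2 = 0.5 * ((1 - beta) * p1 + (1 + beta) * p2)
    children[:half][cross] = c1[cross]
    children[half:][cross] = c2[cross]
    return np.clip(children, lo, hi)


def _poly_mutation(
    X: np.ndarray,
    rng: np.random.Generator,
    eta: float,
    rate: float,
    lo: np.ndarray,
    hi: np.ndarray,
) -> np.ndarray:
    """Bounded polynomial mutation, applied per gene with probability rate."""
    span = hi - lo
    mask = rng.random(X.shape) < rate
    u = rng.random(X.shape)
    d1 = (X - lo) / span
    d2 = (hi - X) / span
    pw = 1.0 / (eta + 1.0)
    left = (2 * u + (1 - 2 * u) * (1 - d1) ** (eta + 1.0)) ** pw - 1.0
    right = 1.0 - (2 * (1 - u) + 2 * (u - 0.5) * (1 - d2) ** (eta + 1.0)) ** pw
    delta = np.where(u <= 0.5, left, right)
    out = X.copy()
    out[mask] = (X + delta * span)[mask]
    return np.clip(out, lo, hi)


def _rank_and_crowd(F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ranks = np.empty(len(F), dtype=int)
    crowd = np.empty(len(F))
    for r, idx in enumerate(fast_nondominated_sort(F)):
        ranks[idx] = r
        crowd[idx] = crowding_distance(F[idx])
    return ranks, crowd


def _select_parents(
    X: np.ndarray,
    ranks: np.ndarray,
    crowd: np.ndarray,
    rng: np.random.Generator,
    scheme: str,
) -> np.ndarray:
    n = len(X)
    if scheme == "roulette":
        fitness = 1.0 / (1.0 + ranks)
        p = fitness / fitness.sum()
        pick = rng.choice(n, size=n, replace=True, p=p)
        return X[pick]
    # crowded binary tournament: lower rank wins, ties by larger crowding
    a = rng.integers(0, n, size=n)
    b = rng.integers(0, n, size=n)
    better_a = (ranks[a] < ranks[b]) | ((ranks[a] == ranks[b]) & (crowd[a] >= crowd[b]))
    return X[np.where(better_a, a, b)]


def nsga2_optimize(
    objective_fn: Callable[[np.ndarray], np.ndarray],
    config: NSGAConfig | None = None,
    on_generation: Callable[[int, np.ndarray, np.ndarray], None] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Run the elitist NSGA-II loop; returns the final first front.

    ``objective_fn`` maps a (m, n_dec) decision batch to (m, n_obj)
    objective values, all maximized.  ``on_generation(gen, X, F)`` is called
    once per generation with the surviving population.  Deterministic per
    ``config.seed``.  Returns ``(decisions, objectives)`` of the rank-0
    front with near-duplicate decisions (within 1e-6) removed.
    """
    if config is None:
        config = NSGAConfig()
    rng = np.random.default_rng(config.seed)
    lo = np.array([b[0] for b in config.bounds])
    hi = np.array([b[1] for b in config.bounds])
    npop = config.population_size

    def evaluate(X: np.ndarray) -> np.ndarray:
        F = np.atleast_2d(np.asarray(objective_fn(X), float))
        if not np.isfinite(F).all():
            bad = np.nonzero(~np.isfinite(F).all(axis=1))[0][0]
            raise ValueError(f"objective returned non-finite value at {X[bad]}")
        return F

    X = lo + rng.random((npop, len(lo))) * (hi - lo)
    F = evaluate(X)
    ranks, crowd = _rank_and_crowd(F)
    for gen in range(config.generations):
        parents = _select_parents(X, ranks, crowd, rng, config.selection_scheme)
        children = _sbx(parents, rng, config.sbx_eta, config.crossover_rate, lo, hi)
        children = _poly_mutation(
            children, rng, config.mutation_eta, config.mutation_rate, lo, hi
        )
        Fc = evaluate(children)
        # elitist survival: parents + children reduced by rank, then crowding
        Xall = np.vstack([X, children])
        Fall = np.vstack([F, Fc])
        chosen: list[np.ndarray] = []
        count = 0
        for idx in fast_nondominated_sort(Fall):
            if count + len(idx) <= npop:
                chosen.append(idx)
                count += len(idx)
            else:
                cd = crowding_distance(Fall[idx])
                order = np.argsort(-cd, kind="stable")
                chosen.append(idx[order[: npop - count]])
                count = npop
            if count == npop:
                break
        keep = np.concatenate(chosen)
        X, F = Xall[keep], Fall[keep]
        ranks, crowd = _rank_and_crowd(F)
        if on_generation is not None:
            on_generation(gen, X, F)

    front = np.nonzero(ranks == 0)[0]
    Xf, Ff = X[front], F[front]
    # drop near-duplicate decision vectors
    order = np.lexsort(Xf.T[::-1])
    Xf, Ff = Xf[order], Ff[order]
    keep_mask = np.ones(len(Xf), dtype=bool)
    for i in range(1, len(Xf)):
        if np.all(np.abs(Xf[i] - Xf[i - 1]) <= 1e-6):
            keep_mask[i] = False
    return Xf[keep_mask], Ff[keep_mask]


def select_ideal_point(
    front_decisions: np.ndarray,
    front_objectives: np.ndarray,
    ideal: Sequence[float],
) -> OptimizationResult:
    """Pick the front member nearest the ideal point.

    Distance is plain Euclidean on the raw objective vector (percent and
    count mixed, deliberately unnormalized).  Ties break toward the lower
    first decision variable (2,4-D concentration).
    """
    Xf = np.atleast_2d(np.asarray(front_decisions, float))
    Ff = np.atleast_2d(np.asarray(front_objectives, float))
    if len(Ff) == 0:
        raise ValueError("empty front")
    ideal = np.asarray(ideal, float)
    dist = np.sqrt(((Ff - ideal) ** 2).sum(axis=1))
    order = np.lexsort((Xf[:, 0], dist))
    best = order[0]
    return OptimizationResult(
        front_decisions=Xf,
        front_objectives=Ff,
        selected_decision=Xf[best],
        selected_objectives=Ff[best],
        ideal=ideal,
        distance=float(dist[best]),
    )
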