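"""Epsilon-insensitive support vector regression with an RBF kernel.

The regressor is the kernel expansion ``y(x) = sum_i beta_i k(x, x_i) + b``
with ``beta_i = alpha_i - alpha_i^*`` the dual coefficients of the standard
epsilon-SVR dual problem:

    max  sum_i t_i beta_i - eps sum_i (alpha_i + alpha_i^*)
         - 1/2 sum_ij beta_i beta_j k(x_i, x_j)
    s.t. sum_i beta_i = 0,   0 <= alpha_i, alpha_i^* <= C

Training solves this dual with a maximal-violating-pair SMO sweep (the
LIBSVM working-set heuristic), jit-compiled with numba; the bias ``b`` is
recovered from the KKT conditions of free support vectors.  ``C`` uses the
conventional per-point parameterization (no 1/n factor); an objective with
the 1/n factor is identical after rescaling ``C``.

Hyperparameters (C, eps, gamma) are chosen by exhaustive grid search over
k-fold cross-validated RMSE, since no single choice is canonical for
factorial dose-response data.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .dataset import FACTOR_NAMES, RESPONSE_BOUNDS
from .preprocess import ScalingParams

__all__ = [
    "SVRModel",
    "SVRHyperGrid",
    "rbf_kernel",
    "fit_svr",
    "predict_svr",
    "tune_svr",
    "fit_response",
    "dual_objective",
    "kkt_residuals",
]

logger = logging.getLogger(__name__)

#: coefficients smaller than this (relative to C) are treated as zero
_SV_RTOL = 1e-10


def rbf_kernel(x: np.ndarray, z: np.ndarray, gamma: float) -> np.ndarray:
    """Gaussian kernel matrix ``exp(-gamma * ||x - z||^2)``.

    ``x`` (m, d) and ``z`` (p, d) give an (m, p) matrix; 1-D inputs are
    treated as single vectors and give scalars.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    x1 = np.atleast_2d(np.asarray(x, float))
    z1 = np.atleast_2d(np.asarray(z, float))
    sq = (
        (x1**2).sum(axis=1)[:, None]
        + (z1**2).sum(axis=1)[None, :]
        - 2.0 * x1 @ z1.T
    )
    k = np.exp(-gamma * np.maximum(sq, 0.0))
    if np.asarray(x).ndim == 1 and np.asarray(z).ndim == 1:
        return float(k[0, 0])
    return k


@njit(cache=False)
def _smo(K, t, C, eps, tol, max_iter, a_init):  # pragma: no cover - exercised via fit_svr
    """Second-order working-set SMO on the 2n-variable dual.

    Variables a[0:n] are alpha, a[n:2n] are alpha*; signs y = +1 / -1.
    Minimizes 1/2 a'Qa + p'a with Q_ij = y_i y_j K_ij, p = eps -/+ t.
    ``a_init`` warm-starts the solve (must satisfy box and equality).
    Returns (alpha, alpha_star, iterations, final KKT gap).
    """
    n = K.shape[0]
    m2 = 2 * n
    a = a_init.copy()
    G = np.empty(m2)
    g0 = K @ (a[:n] - a[n:])
    for i in range(n):
        G[i] = g0[i] + eps - t[i]
        G[n + i] = -g0[i] + eps + t[i]
    act = np.arange(m2)
    m_act = m2
    gap = np.inf
    it = 0
    since_shrink = 0
    while it < max_iter:
        # first index: maximal violator in the "up" set
        gmax = -np.inf
        gmin = np.inf
        wi = -1
        for p in range(m_act):
            s = act[p]
            if s < n:  # y = +1
                v = -G[s]
                if a[s] < C and v > gmax:
                    gmax = v
                    wi = s
                if a[s] > 0.0 and v < gmin:
                    gmin = v
            else:  # y = -1
                v = G[s]
                if a[s] > 0.0 and v > gmax:
                    gmax = v
                    wi = s
                if a[s] < C and v < gmin:
                    gmin = v
        gap = gmax - gmin
        if gap < tol or wi < 0:
            if m_act == m2:
                break
            # converged on the shrunk set: reconstruct the full gradient and
            # verify optimality over all variables before accepting
            g0 = K @ (a[:n] - a[n:])
            for i in range(n):
                G[i] = g0[i] + eps - t[i]
                G[n + i] = -g0[i] + eps + t[i]
            act = np.arange(m2)
            m_act = m2
            since_shrink = 0
            continue
        # periodically shrink bounded variables lying strictly outside the
        # current violating range; exactness is restored by the final
        # full-set verification above
        since_shrink += 1
        if since_shrink >= 1000 and m_act > 2:
            since_shrink = 0
            kept = 0
            for p in range(m_act):
                s = act[p]
                if s < n:
                    v = -G[s]
                    if a[s] <= 0.0:
                        drop = v < gmin  # in the up set only
                    elif a[s] >= C:
                        drop = v > gmax  # in the down set only
                    else:
                        drop = False
                else:
                    v = G[s]
                    if a[s] >= C:
                        drop = v < gmin
                    elif a[s] <= 0.0:
                        drop = v > gmax
                    else:
                        drop = False
                if not drop:
                    act[kept] = s
                    kept += 1
            m_act = kept
        yi = 1.0 if wi < n else -1.0
        ii = wi % n
        # second index: best second-order decrease among down-set candidates
        wj = -1
        best = 0.0
        for p in range(m_act):
            s = act[p]
            if s < n:
                if a[s] <= 0.0:
                    continue
                v = -G[s]
            else:
                if a[s] >= C:
                    continue
                v = G[s]
            diff = gmax - v
            if diff <= 0.0:
                continue
            jj_s = s % n
            # curvature along the feasible two-variable direction is the
            # plain data-space quantity K_ii + K_jj - 2 K_ij for any sign pair
            quad = K[ii, ii] + K[jj_s, jj_s] - 2.0 * K[ii, jj_s]
            if quad < 1e-12:
                quad = 1e-12
            gain = diff * diff / quad
            if gain > best:
                best = gain
                wj = s
        if wj < 0:
            break
        yj = 1.0 if wj < n else -1.0
        jj = wj % n
        quad = K[ii, ii] + K[jj, jj] - 2.0 * K[ii, jj]
        if quad < 1e-12:
            quad = 1e-12
        vj = -G[wj] if wj < n else G[wj]
        d = (gmax - vj) / quad
        # clip the step so both variables stay in [0, C]
        if yi > 0.0:
            lo_i, hi_i = -a[wi], C - a[wi]
        else:
            lo_i, hi_i = a[wi] - C, a[wi]
        if yj > 0.0:
            lo_j, hi_j = a[wj] - C, a[wj]
        else:
            lo_j, hi_j = -a[wj], C - a[wj]
        lo = lo_i if lo_i > lo_j else lo_j
        hi = hi_i if hi_i < hi_j else hi_j
        if d > hi:
            d = hi
        elif d < lo:
            d = lo
        dai = yi * d
        daj = -yj * d
        a[wi] += dai
        a[wj] += daj
        ci = yi * dai
        cj = yj * daj
        for p in range(m_act):
            s = act[p]
            if s < n:
                G[s] += ci * K[s, ii] + cj * K[s, jj]
            else:
                G[s] -= ci * K[s - n, ii] + cj * K[s - n, jj]
        it += 1
    return a[:n], a[n:], it, gap


@dataclass
class SVRModel:
    """A trained epsilon-SVR: support vectors, dual coefficients and bias.

    All stored coordinates and the bias live in scaled [0, 1] space; the
    attached :class:`ScalingParams` maps to and from natural units when the
    model was fitted through :func:`fit_response`.
    """

    sv_inputs: np.ndarray  # (n_sv, d) scaled support-vector coordinates
    dual_coefs: np.ndarray  # (n_sv,) alpha_i - alpha_i^*
    bias: float
    gamma: float
    C: float
    epsilon: float
    scaler: ScalingParams | None = None
    target_name: str | None = None
    input_names: tuple[str, ...] = FACTOR_NAMES
    # full-length diagnostics of the dual solution
    alpha: np.ndarray | None = None
    alpha_star: np.ndarray | None = None
    n_iter: int = 0
    kkt_gap: float = np.nan

    @property
    def n_support(self) -> int:
        return len(self.dual_coefs)

    def decision_function(self, X_scaled: np.ndarray) -> np.ndarray:
        """Kernel expansion in scaled space: sum_i beta_i k(x, x_i) + b."""
        X_scaled = np.atleast_2d(np.asarray(X_scaled, float))
        if X_scaled.shape[1] != self.sv_inputs.shape[1]:
            raise ValueError(
                f"expected {self.sv_inputs.shape[1]} input dims, got {X_scaled.shape[1]}"
            )
        if self.n_support == 0:
            return np.full(len(X_scaled), self.bias)
        K = rbf_kernel(X_scaled, self.sv_inputs, self.gamma)
        return K @ self.dual_coefs + self.bias

    def predict(self, X: np.ndarray | pd.DataFrame, clip: bool = False) -> np.ndarray:
        """Predict in natural target units from natural-unit inputs.

        Requires an attached scaler.  With ``clip=True`` rates are clipped to
        [0, 100] and counts to >= 0.
        """
        if self.scaler is None or self.target_name is None:
            raise ValueError("model has no scaler attached; use decision_function")
        if isinstance(X, pd.DataFrame):
            X = X[list(self.input_names)].to_numpy(float)
        Xs = self.scaler.apply_array(np.atleast_2d(X), list(self.input_names))
        ys = self.decision_function(Xs)
        y = self.scaler.invert_array(ys, [self.target_name] * 1)
        if clip:
            lo, hi = RESPONSE_BOUNDS[self.target_name]
            y = np.clip(y, lo, hi)
        return y

    def to_json(self) -> str:
        doc = {
            "C": self.C,
            "epsilon": self.epsilon,
            "gamma": self.gamma,
            "bias": self.bias,
            "target_name": self.target_name,
            "input_names": list(self.input_names),
            "sv_inputs": self.sv_inputs.tolist(),
            "dual_coefs": self.dual_coefs.tolist(),
            "scaler": None if self.scaler is None else json.loads(self.scaler.to_json()),
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, doc: str) -> "SVRModel":
        d = json.loads(doc)
        scaler = None
        if d["scaler"] is not None:
            scaler = ScalingParams(
                minima={v: s["min"] for v, s in d["scaler"].items()},
                maxima={v: s["max"] for v, s in d["scaler"].items()},
            )
        return cls(
            sv_inputs=np.asarray(d["sv_inputs"], float).reshape(-1, len(d["input_names"])),
            dual_coefs=np.asarray(d["dual_coefs"], float),
            bias=d["bias"],
            gamma=d["gamma"],
            C=d["C"],
            epsilon=d["epsilon"],
            scaler=scaler,
            target_name=d["target_name"],
            input_names=tuple(d["input_names"]),
        )


def fit_svr(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    epsilon: float,
    gamma: float,
    tol: float = 1e-6,
    max_iter: int = 20_000_000,
    scaler: ScalingParams | None = None,
    target_name: str | None = None,
    input_names: tuple[str, ...] = FACTOR_NAMES,
) -> SVRModel:
    """Train an epsilon-SVR on scaled inputs/targets by solving the dual.

    Raises ``RuntimeError`` carrying the final KKT gap if the SMO sweep does
    not reach ``tol`` within ``max_iter`` pair updates.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    if len(X) != len(y):
        raise ValueError("X and y must have the same number of rows")
    if len(y) < 2:
        raise ValueError("need at least 2 training rows")
    if C <= 0 or epsilon < 0:
        raise ValueError("require C > 0 and epsilon >= 0")
    if gamma <= 0:
        raise ValueError("gamma must be > 0")

    K = rbf_kernel(X, X, gamma)
    alpha, alpha_star, n_iter, gap = _smo(
        K, y, float(C), float(epsilon), float(tol), int(max_iter),
        np.zeros(2 * len(y)),
    )
    if gap >= tol and n_iter >= max_iter:
        raise RuntimeError(
            f"SMO did not converge: KKT gap {gap:.3e} after {n_iter} iterations"
        )
    beta = alpha - alpha_star

    # bias from KKT conditions of free support vectors, averaged
    g = K @ beta
    free_lo = (alpha > _SV_RTOL * C) & (alpha < C * (1 - _SV_RTOL))
    free_hi = (alpha_star > _SV_RTOL * C) & (alpha_star < C * (1 - _SV_RTOL))
    b_vals = np.concatenate(
        [(y - g - epsilon)[free_lo], (y - g + epsilon)[free_hi]]
    )
    if len(b_vals) > 0:
        bias = float(b_vals.mean())
    else:
        # feasible interval for b from the box-inactive KKT inequalities
        lb = np.concatenate(
            [(y - g - epsilon)[alpha < C * (1 - _SV_RTOL)],
             (y - g + epsilon)[alpha_star > _SV_RTOL * C]]
        )
        ub = np.concatenate(
            [(y - g + epsilon)[alpha_star < C * (1 - _SV_RTOL)],
             (y - g - epsilon)[alpha > _SV_RTOL * C]]
        )
        bias = float((lb.max() + ub.min()) / 2.0)
        logger.warning(
            "no free support vector; bias set to midpoint of feasible interval "
            "[%.6g, %.6g]", lb.max(), ub.min()
        )

    keep = np.abs(beta) > _SV_RTOL * C
    return SVRModel(
        sv_inputs=X[keep],
        dual_coefs=beta[keep],
        bias=bias,
        gamma=gamma,
        C=C,
        epsilon=epsilon,
        scaler=scaler,
        target_name=target_name,
        input_names=input_names,
        alpha=alpha,
        alpha_star=alpha_star,
        n_iter=n_iter,
        kkt_gap=gap,
    )


def predict_svr(model: SVRModel, X, clip: bool = False) -> np.ndarray:
    """Functional alias of :meth:`SVRModel.predict` (natural units)."""
    return model.predict(X, clip=clip)


def dual_objective(
    alpha: np.ndarray, alpha_star: np.ndarray, K: np.ndarray, t: np.ndarray, epsilon: float
) -> float:
    """Value of the dual maximization objective at (alpha, alpha*)."""
    beta = alpha - alpha_star
    return float(
        t @ beta - epsilon * (alpha + alpha_star).sum() - 0.5 * beta @ K @ beta
    )


def kkt_residuals(model: SVRModel, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-training-point KKT violation of the fitted dual solution.

    Zero (to solver tolerance) at optimality: interior points must sit inside
    the eps tube, free support vectors exactly on it, and bound ones on or
    outside it.
    """
    if model.alpha is None or model.alpha_star is None:
        raise ValueError("model lacks the full dual solution diagnostics")
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    f = model.decision_function(X)
    r = y - f  # residual; tube requires |r| <= eps
    a, a_s, C, eps = model.alpha, model.alpha_star, model.C, model.epsilon
    tol = _SV_RTOL * C
    res = np.zeros(len(y))
    interior = (a <= tol) & (a_s <= tol)
    res[interior] = np.maximum(0.0, np.abs(r[interior]) - eps)
    free = (a > tol) & (a < C - tol)
    res[free] = np.maximum(res[free], np.abs(r[free] - eps))
    bound = a >= C - tol
    res[bound] = np.maximum(res[bound], np.maximum(0.0, eps - r[bound]))
    free_s = (a_s > tol) & (a_s < C - tol)
    res[free_s] = np.maximum(res[free_s], np.abs(-r[free_s] - eps))
    bound_s = a_s >= C - tol
    res[bound_s] = np.maximum(res[bound_s], np.maximum(0.0, eps + r[bound_s]))
    return res


@dataclass
class SVRHyperGrid:
    """Candidate hyperparameters for exhaustive cross-validated search.

    The defaults span a coarse log grid; none of C, eps, gamma has a
    canonical value for this kind of dose-response data, so all are tuned.
    """

    C: tuple[float, ...] = (1.0, 10.0, 100.0, 1000.0)
    epsilon: tuple[float, ...] = (0.001, 0.01, 0.05, 0.1)
    gamma: tuple[float, ...] = (0.1, 0.5, 1.0, 2.0, 5.0)
    k: int = 5
    seed: int = 0
    #: SMO pair-update budget per fold fit during the search; a candidate
    #: whose fold solve exceeds it is dropped from the selection, since the
    #: model it scores is not the one a converged fit would produce.  Keeps
    #: the exhaustive search from sinking unbounded time into hopeless
    #: large-C/small-eps corners; final fits are run to full convergence.
    fold_max_iter: int = 50_000

    def __post_init__(self) -> None:
        if len(self.C) == 0 or len(self.epsilon) == 0 or len(self.gamma) == 0:
            raise ValueError("hyperparameter grid must be non-empty")
        if any(c <= 0 for c in self.C) or any(g <= 0 for g in self.gamma):
            raise ValueError("C and gamma candidates must be strictly positive")
        if any(e < 0 for e in self.epsilon):
            raise ValueError("epsilon candidates must be non-negative")


def tune_svr(
    X: np.ndarray,
    y: np.ndarray,
    grid: SVRHyperGrid | None = None,
    fold_tol: float = 1e-3,
) -> tuple[float, float, float, float]:
    """Exhaustive grid search minimizing mean k-fold CV RMSE (scaled units).

    Ties are broken toward smaller C, then larger epsilon (simpler, flatter
    models), then smaller gamma.  The fold assignment depends only on
    ``grid.seed``, so shuffling the candidate lists cannot change the
    selected triple.  Fold models use a looser SMO tolerance (``fold_tol``)
    than final fits; CV scores only rank candidates.

    Returns ``(C, epsilon, gamma, cv_rmse)``.
    """
    if grid is None:
        grid = SVRHyperGrid()
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    n = len(y)
    k = min(grid.k, n)
    rng = np.random.default_rng(grid.seed)
    folds = np.array_split(rng.permutation(n), k)

    sq_err: dict[tuple[float, float, float], float] = {
        (C, eps, gamma): 0.0
        for C, eps, gamma in itertools.product(grid.C, grid.epsilon, grid.gamma)
    }
    for gamma in grid.gamma:
        K = rbf_kernel(X, X, gamma)
        for te in folds:
            tr = np.setdiff1d(np.arange(n), te)
            Ktr = np.ascontiguousarray(K[np.ix_(tr, tr)])
            Kte = K[np.ix_(te, tr)]
            ytr = y[tr]
            for eps in sorted(grid.epsilon, reverse=True):
                # warm-start along the increasing-C path; the previous
                # solution stays feasible when the box only grows
                a0 = np.zeros(2 * len(tr))
                for C in sorted(grid.C):
                    alpha, alpha_star, n_it, _ = _smo(
                        Ktr, ytr, float(C), float(eps), float(fold_tol),
                        grid.fold_max_iter, a0,
                    )
                    a0 = np.concatenate([alpha, alpha_star])
                    if n_it >= grid.fold_max_iter:
                        sq_err[(C, eps, gamma)] = np.inf
                        continue
                    beta = alpha - alpha_star
                    g = Ktr @ beta
                    free = (
                        (alpha > _SV_RTOL * C) & (alpha < C * (1 - _SV_RTOL))
                    ) | (
                        (alpha_star > _SV_RTOL * C)
                        & (alpha_star < C * (1 - _SV_RTOL))
                    )
                    bvals = np.where(
                        alpha[free] > alpha_star[free],
                        (ytr - g - eps)[free],
                        (ytr - g + eps)[free],
                    )
                    b = bvals.mean() if len(bvals) else float(np.median(ytr - g))
                    pred = Kte @ beta + b
                    sq_err[(C, eps, gamma)] += float(((pred - y[te]) ** 2).sum())
    results = [
        (np.sqrt(sq / n), C, -eps, gamma)
        for (C, eps, gamma), sq in sq_err.items()
        if np.isfinite(sq)
    ]
    if not results:
        raise RuntimeError("no grid candidate converged within the fold budget")
    cv_rmse, C, neg_eps, gamma = min(results)
    return float(C), float(-neg_eps), float(gamma), float(cv_rmse)


def fit_response(
    train: pd.DataFrame,
    target_name: str,
    scaler: ScalingParams,
    C: float,
    epsilon: float,
    gamma: float,
    input_names: tuple[str, ...] = FACTOR_NAMES,
    tol: float = 1e-6,
) -> SVRModel:
    """Fit one response model on a replicate table, handling scaling."""
    Xs = scaler.apply_array(train[list(input_names)].to_numpy(float), list(input_names))
    ys = scaler.apply_array(
        train[[target_name]].to_numpy(float), [target_name]
    ).ravel()
    return fit_svr(
        Xs, ys, C, epsilon, gamma, tol=tol,
        scaler=scaler, target_name=target_name, input_names=input_names,
    )
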