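"""Average-weight and optimized-weight ensembles.

The optimized ensemble solves

    min_w  sqrt( (1/n) * sum_i (y_i - sum_j w_j yhat_ij)^2 )
    s.t.   sum_j w_j = 1
           w_j >= 0
           mse(w) - mse_j <= 0   for every base model j

i.e. the simplex-constrained stacking weights must dominate every base
learner on the training matrix.  The root is monotone, so the RMSE and MSE
formulations share their argmin; the root form keeps the objective on the
scale of the observations.  Feasibility is guaranteed: the vertex of the
training-best base model satisfies the dominance constraint with equality.

A step-lattice enumeration oracle (``grid_oracle_weights``) verifies the
solver on small instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

MSE_TOL = 1e-8
WEIGHT_CLIP = 1e-10
_EPS = 1e-18  # keeps the root differentiable at a perfect fit


class EnsembleConfigError(ValueError):
    pass


@dataclass
class EnsembleWeights:
    """Simplex weights over base models plus solver diagnostics."""

    model_names: list[str]
    weights: np.ndarray
    objective: float  # root-of-mean-square residual at the solution, Mg/ha
    converged: bool = True
    n_iter: int = 0
    active_constraints: list[str] = field(default_factory=list)
    method: str = "slsqp"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.model_names):
            raise EnsembleConfigError("weights/names length mismatch")

    def as_dict(self) -> dict:
        return {
            "models": list(self.model_names),
            "weights": [float(w) for w in self.weights],
            "objective": float(self.objective),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "active_constraints": list(self.active_constraints),
            "method": self.method,
        }


def matrix_from_frame(pm: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Split a prediction-matrix frame into (P, y, model_names)."""
    names = pm.attrs.get("models")
    if names is None:
        names = [c for c in pm.columns if c not in ("geoid", "year", "y_true")]
    return pm[list(names)].to_numpy(), pm["y_true"].to_numpy(), list(names)


def fit_average_weights(k: int, model_names: list[str] | None = None) -> EnsembleWeights:
    """Equal weights 1/k over the k base models."""
    if k < 1:
        raise EnsembleConfigError("need at least one base model")
    names = model_names if model_names is not None else [f"m{j + 1}" for j in range(k)]
    if len(names) != k:
        raise EnsembleConfigError("model_names length must equal k")
    return EnsembleWeights(
        model_names=names,
        weights=np.full(k, 1.0 / k),
        objective=float("nan"),
        method="average",
    )


def _mse(P: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    r = y - P @ w
    return float(r @ r) / len(y)


def optimize_weights(
    P: np.ndarray, y: np.ndarray, model_names: list[str] | None = None
) -> EnsembleWeights:
    """Solve the constrained stacking problem on a raw (n, k) matrix.

    Multi-started SLSQP from the equal-weight point and every simplex
    vertex; the best feasible solution wins.  If no start converges to a
    feasible point, the training-best vertex (always feasible) is returned
    with ``converged=False``.
    """
    P = np.asarray(P, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = P.shape
    if k < 2:
        raise EnsembleConfigError("optimized ensemble needs k >= 2 base models")
    if model_names is None:
        model_names = [f"m{j + 1}" for j in range(k)]

    A = P.T @ P / n
    b = P.T @ y / n
    c = float(y @ y) / n
    base_mse = np.array([_mse(P, y, e) for e in np.eye(k)])

    def q(w: np.ndarray) -> float:  # mean squared residual
        return float(w @ A @ w - 2.0 * b @ w + c)

    def f(w: np.ndarray) -> float:
        return np.sqrt(max(q(w), 0.0) + _EPS)

    def fgrad(w: np.ndarray) -> np.ndarray:
        return (A @ w - b) / f(w)

    constraints = [
        {"type": "eq", "fun": lambda w: w.sum() - 1.0, "jac": lambda w: np.ones(k)},
        {
            "type": "ineq",  # base_mse_j - mse(w) >= 0 for all j
            "fun": lambda w: base_mse - q(w),
            "jac": lambda w: -2.0 * np.tile(A @ w - b, (k, 1)),
        },
    ]
    bounds = [(0.0, 1.0)] * k

    starts = [np.full(k, 1.0 / k)] + [e for e in np.eye(k)]
    best: tuple[float, np.ndarray, int] | None = None
    for w0 in starts:
        res = minimize(
            f,
            w0,
            jac=fgrad,
            method="SLSQP",
            bounds=bounds,
            constraints=constraints,
            options={"maxiter": 200, "ftol": 1e-12},
        )
        w = np.clip(res.x, 0.0, None)
        s = w.sum()
        if s <= 0:
            continue
        w = w / s
        if not np.all(q(w) - base_mse <= MSE_TOL):
            continue
        cand = (f(w), w, int(res.nit))
        if best is None or cand[0] < best[0]:
            best = cand

    if best is None:  # always-feasible fallback: training-best vertex
        j = int(np.argmin(base_mse))
        w = np.zeros(k)
        w[j] = 1.0
        ew = EnsembleWeights(
            model_names=model_names,
            weights=w,
            objective=f(w),
            converged=False,
            n_iter=0,
            method="vertex-fallback",
        )
        ew.active_constraints = _active_constraints(w, q(w), base_mse, model_names)
        return ew

    obj, w, nit = best
    w[w < WEIGHT_CLIP] = 0.0
    w = w / w.sum()
    ew = EnsembleWeights(
        model_names=model_names,
        weights=w,
        objective=f(w),
        converged=True,
        n_iter=nit,
    )
    ew.active_constraints = _active_constraints(w, q(w), base_mse, model_names)
    return ew


def _active_constraints(
    w: np.ndarray, mse_w: float, base_mse: np.ndarray, names: list[str]
) -> list[str]:
    active = [f"nonneg:{names[j]}" for j in range(len(w)) if w[j] == 0.0]
    active += [
        f"dominance:{names[j]}"
        for j in range(len(w))
        if abs(base_mse[j] - mse_w) <= 1e-6
    ]
    return active


def fit_optimized_weights(pm: pd.DataFrame) -> EnsembleWeights:
    """Fit optimized weights on a training prediction-matrix frame."""
    P, y, names = matrix_from_frame(pm)
    return optimize_weights(P, y, names)


def grid_oracle_weights(
    pm: pd.DataFrame | tuple[np.ndarray, np.ndarray], step: float = 0.01
) -> EnsembleWeights:
    """Exhaustive step-lattice minimizer for verification (k <= 4 only).

    Enumerates every nonnegative weight vector on the lattice summing to 1,
    discards those violating the dominance constraint, and returns the best.
    """
    if isinstance(pm, tuple):
        P, y = pm
        names = [f"m{j + 1}" for j in range(P.shape[1])]
    else:
        P, y, names = matrix_from_frame(pm)
    P = np.asarray(P, dtype=float)
    y = np.asarray(y, dtype=float)
    k = P.shape[1]
    if k > 4:
        raise EnsembleConfigError("grid oracle limited to k <= 4")
    m = round(1.0 / step)
    if abs(m * step - 1.0) > 1e-9:
        raise EnsembleConfigError("step must divide 1")

    base_mse = np.array([_mse(P, y, e) for e in np.eye(k)])
    best_w, best_mse = None, np.inf
    for comp in itertools.combinations_with_replacement(range(k), m):
        counts = np.bincount(comp, minlength=k)
        w = counts / m
        mse_w = _mse(P, y, w)
        if np.any(mse_w - base_mse > MSE_TOL):
            continue
        if mse_w < best_mse:
            best_mse, best_w = mse_w, w
    assert best_w is not None  # vertices are always on the lattice and feasible
    ew = EnsembleWeights(
        model_names=names,
        weights=best_w,
        objective=float(np.sqrt(best_mse)),
        method=f"grid-{step}",
    )
    ew.active_constraints = _active_constraints(best_w, best_mse, base_mse, names)
    return ew


def predict_ensemble(weights: EnsembleWeights, pm: pd.DataFrame) -> np.ndarray:
    """Per-row inner product of the weights with the base predictions."""
    P, _, names = matrix_from_frame(pm)
    if len(weights.weights) != P.shape[1]:
        raise EnsembleConfigError(
            f"weight length {len(weights.weights)} != {P.shape[1]} prediction columns"
        )
    if names != weights.model_names:
        P = pm[list(weights.model_names)].to_numpy()
    return P @ weights.weights
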