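"""Sequential model-based (Bayesian) hyperparameter search.

A Gaussian-process surrogate over the unit hypercube with expected
improvement acquisition; integer and log-scaled dimensions are handled by
the space transforms.  Deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern

import warnings


@dataclass(frozen=True)
class Real:
    low: float
    high: float
    log: bool = False

    def to_unit(self, x: float) -> float:
        if self.log:
            return (math.log(x) - math.log(self.low)) / (
                math.log(self.high) - math.log(self.low)
            )
        return (x - self.low) / (self.high - self.low)

    def from_unit(self, u: float) -> float:
        if self.log:
            return math.exp(
                math.log(self.low) + u * (math.log(self.high) - math.log(self.low))
            )
        return self.low + u * (self.high - self.low)


@dataclass(frozen=True)
class Integer:
    low: int
    high: int

    def to_unit(self, x: int) -> float:
        return (x - self.low) / (self.high - self.low)

    def from_unit(self, u: float) -> int:
        return int(round(self.low + u * (self.high - self.low)))


def _decode(space: dict, u: np.ndarray) -> dict:
    return {name: dim.from_unit(float(ui)) for (name, dim), ui in zip(space.items(), u)}


def bayes_search(
    objective,
    space: dict,
    n_iter: int = 40,
    seed: int = 0,
    n_initial: int = 10,
    n_candidates: int = 256,
) -> tuple[dict, float, list[tuple[dict, float]]]:
    """Minimize ``objective(params)`` over ``space`` in ``n_iter`` evaluations.

    The first ``n_initial`` points are space-filling random draws; afterwards
    a Matern-5/2 GP is refit on all observations and the next point maximizes
    expected improvement over a random candidate pool.

    Returns (best_params, best_value, history).
    """
    if not space:
        raise ValueError("search space is empty")
    n_initial = min(n_initial, n_iter)
    rng = np.random.default_rng(seed)
    dims = len(space)

    U: list[np.ndarray] = []
    vals: list[float] = []
    history: list[tuple[dict, float]] = []

    def evaluate(u: np.ndarray) -> None:
        params = _decode(space, u)
        v = float(objective(params))
        U.append(u)
        vals.append(v)
        history.append((params, v))

    for _ in range(n_initial):
        evaluate(rng.random(dims))

    for _ in range(n_iter - n_initial):
        X = np.vstack(U)
        y = np.asarray(vals)
        y_mu, y_sd = y.mean(), y.std()
        y_norm = (y - y_mu) / y_sd if y_sd > 0 else y - y_mu
        gp = GaussianProcessRegressor(
            kernel=Matern(nu=2.5, length_scale_bounds=(1e-2, 1e2)),
            alpha=1e-6,
            normalize_y=False,
            random_state=int(rng.integers(2**31)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(X, y_norm)
        cand = rng.random((n_candidates, dims))
        mu, sd = gp.predict(cand, return_std=True)
        best = y_norm.min()
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (best - mu) / sd
            ei = (best - mu) * norm.cdf(z) + sd * norm.pdf(z)
        ei[sd <= 0] = 0.0
        evaluate(cand[int(np.argmax(ei))])

    i_best = int(np.argmin(vals))
    return _decode(space, U[i_best]), vals[i_best], history
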