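"""Sequential model-based (Bayesian) minimization with a GP surrogate.

A small fixed-budget optimizer used for hyperparameter tuning: after an
initial random design, a Gaussian-process regression surrogate (Matern 5/2
plus white noise) is fitted to the observed (configuration, objective)
pairs and the next configuration maximizes expected improvement over a
random candidate pool. The number of objective evaluations is exactly the
budget and the best *observed* configuration is returned. Dimensions may be
linear or log-scaled reals, log-scaled integers, or categorical; everything
is encoded into the unit cube for the surrogate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .exceptions import ConfigurationError


@dataclass
class Dimension:
    """One search-space axis.

    kind: 'float' (linear), 'log-float', 'log-int' or 'categorical'.
    """

    name: str
    kind: str
    low: float = 0.0
    high: float = 1.0
    choices: tuple = ()

    def decode(self, u: float):
        u = float(np.clip(u, 0.0, 1.0))
        if self.kind == "float":
            return self.low + u * (self.high - self.low)
        if self.kind == "log-float":
            return float(np.exp(np.log(self.low) + u * (np.log(self.high) - np.log(self.low))))
        if self.kind == "log-int":
            v = np.exp(np.log(self.low) + u * (np.log(self.high) - np.log(self.low)))
            return int(np.clip(round(v), self.low, self.high))
        if self.kind == "categorical":
            idx = min(int(u * len(self.choices)), len(self.choices) - 1)
            return self.choices[idx]
        raise ConfigurationError(f"unknown dimension kind {self.kind!r}")


def decode_point(space, u: np.ndarray) -> dict:
    return {dim.name: dim.decode(u[i]) for i, dim in enumerate(space)}


@dataclass
class OptimizationTrace:
    """Evaluated configurations, their objectives, and the best observed."""

    params: list
    values: list
    best_params: dict
    best_value: float

    @property
    def n_evaluations(self) -> int:
        return len(self.values)


def minimize(
    objective,
    space,
    budget: int = 15,
    seed: int = 0,
    n_initial: int | None = None,
    n_candidates: int = 256,
) -> OptimizationTrace:
    """Minimize ``objective(params_dict)`` with exactly ``budget`` evaluations."""
    if budget < 1:
        raise ConfigurationError("optimization budget must be >= 1")
    space = list(space)
    d = len(space)
    rng = np.random.default_rng(seed)
    if n_initial is None:
        n_initial = min(max(3, budget // 3), budget)

    U: list[np.ndarray] = []
    values: list[float] = []
    params_log: list[dict] = []

    def evaluate(u: np.ndarray) -> None:
        params = decode_point(space, u)
        U.append(u)
        params_log.append(params)
        values.append(float(objective(params)))

    for _ in range(min(n_initial, budget)):
        evaluate(rng.random(d))

    while len(values) < budget:
        X = np.vstack(U)
        y = np.asarray(values)
        kernel = ConstantKernel(1.0) * Matern(
            length_scale=np.full(d, 0.5), nu=2.5
        ) + WhiteKernel(noise_level=1e-6, noise_level_bounds=(1e-10, 1e-1))
        gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=True, random_state=int(seed) & 0x7FFFFFFF
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                gp.fit(X, y)
                cand = rng.random((n_candidates, d))
                mu, sigma = gp.predict(cand, return_std=True)
            sigma = np.maximum(sigma, 1e-12)
            best = y.min()
            z = (best - mu) / sigma
            ei = (best - mu) * norm.cdf(z) + sigma * norm.pdf(z)
            u_next = cand[int(np.argmax(ei))]
        except Exception:  # GP degeneracy: fall back to a random draw
            u_next = rng.random(d)
        evaluate(u_next)

    best_idx = int(np.argmin(values))
    return OptimizationTrace(
        params=params_log,
        values=values,
        best_params=params_log[best_idx],
        best_value=values[best_idx],
    )
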