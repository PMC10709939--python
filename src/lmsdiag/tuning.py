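"""Bayesian hyperparameter search over the per-family search spaces.

A compact Gaussian-process optimizer (Matern kernel, expected-improvement
acquisition) drives the search: a seeded batch of random trials first, then
EI-maximizing proposals drawn from random candidate sets.  Duplicate
configurations are never re-evaluated, so tiny discrete spaces are swept
exhaustively.  The objective is validation binary cross-entropy (minimized)
for the network and validation accuracy (maximized) for the SVM / RF / GB
baselines.

Search spaces are dictionaries of parameter specs::

    {"dropout_rate": ("float", 0.1, 0.7),
     "n_hidden_layers": ("int", 2, 8),
     "kernel": ("cat", ["linear", "rbf", "poly", "sigmoid"]),
     "C": ("logfloat", 1e-2, 1e2)}
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern

from .classifiers import DnnConfig, predict_proba, train_baseline, train_dnn

__all__ = [
    "DEFAULT_SEARCH_SPACES",
    "TuningResult",
    "bayesian_minimize",
    "tune",
]

# Network ranges follow the published tuning protocol; baseline ranges cover
# the parameters named for each family at their customary magnitudes.
DEFAULT_SEARCH_SPACES: dict[str, dict] = {
    "dnn": {
        "dropout_rate": ("float", 0.1, 0.7),
        "n_hidden_layers": ("int", 2, 8),
        "n_hidden_nodes": ("int", 2, 32),
        "batch_size": ("int", 8, 64),
        "epochs": ("int", 30, 200),
    },
    "svm": {
        "kernel": ("cat", ["linear", "rbf", "poly", "sigmoid"]),
        "C": ("logfloat", 1e-2, 1e2),
        "gamma": ("logfloat", 1e-4, 1e1),
    },
    "rf": {
        "n_estimators": ("int", 50, 500),
        "max_depth": ("int", 1, 16),
        "max_features": ("cat", ["sqrt", "log2", None]),
    },
    "gb": {
        "learning_rate": ("logfloat", 0.01, 0.3),
        "n_estimators": ("int", 50, 500),
        "max_depth": ("int", 1, 8),
        "max_features": ("cat", ["sqrt", "log2", None]),
    },
}

_N_CANDIDATES = 256


def _validate_space(space: Mapping) -> None:
    if not space:
        raise ValueError("search space is empty")
    for name, spec in space.items():
        kind = spec[0]
        if kind in ("float", "logfloat", "int"):
            _, lo, hi = spec
            if not lo <= hi:
                raise ValueError(f"{name}: low {lo} > high {hi}")
            if kind == "logfloat" and lo <= 0:
                raise ValueError(f"{name}: log-scale bounds must be positive")
        elif kind == "cat":
            if not spec[1]:
                raise ValueError(f"{name}: no choices")
        else:
            raise ValueError(f"{name}: unknown spec kind {kind!r}")


def _decode(space: Mapping, u: np.ndarray) -> dict:
    """Map a point of the unit cube to a concrete configuration."""
    config = {}
    for (name, spec), x in zip(space.items(), u):
        x = float(np.clip(x, 0.0, 1.0))
        kind = spec[0]
        if kind == "float":
            _, lo, hi = spec
            config[name] = lo + x * (hi - lo)
        elif kind == "logfloat":
            _, lo, hi = spec
            config[name] = float(np.exp(np.log(lo) + x * (np.log(hi) - np.log(lo))))
        elif kind == "int":
            _, lo, hi = spec
            config[name] = int(np.clip(round(lo + x * (hi - lo)), lo, hi))
        else:  # cat
            choices = spec[1]
            idx = min(int(x * len(choices)), len(choices) - 1)
            config[name] = choices[idx]
    return config


def _key(config: dict) -> tuple:
    return tuple(config[k] for k in sorted(config))


@dataclass
class TuningResult:
    best_config: dict
    best_value: float
    trials: list[tuple[dict, float]]


def bayesian_minimize(
    space: Mapping,
    objective: Callable[[dict], float],
    n_trials: int,
    seed: int = 0,
) -> TuningResult:
    """Minimize ``objective`` over ``space`` with GP expected improvement."""
    _validate_space(space)
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    dim = len(space)
    n_init = min(n_trials, max(4, n_trials // 4))

    tried: set[tuple] = set()
    X_obs: list[np.ndarray] = []
    y_obs: list[float] = []
    trials: list[tuple[dict, float]] = []

    def propose_random() -> tuple[np.ndarray, dict] | None:
        for _ in range(200):
            u = rng.random(dim)
            config = _decode(space, u)
            if _key(config) not in tried:
                return u, config
        return None

    def propose_ei() -> tuple[np.ndarray, dict] | None:
        gp = GaussianProcessRegressor(
            kernel=Matern(nu=2.5, length_scale=np.full(dim, 0.3)),
            alpha=1e-6, normalize_y=True, random_state=int(rng.integers(2**31)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(np.array(X_obs), np.array(y_obs))
        cand_u = rng.random((_N_CANDIDATES, dim))
        mu, sigma = gp.predict(cand_u, return_std=True)
        best = min(y_obs)
        sigma = np.maximum(sigma, 1e-12)
        z = (best - mu) / sigma
        ei = (best - mu) * norm.cdf(z) + sigma * norm.pdf(z)
        for idx in np.argsort(-ei):
            config = _decode(space, cand_u[idx])
            if _key(config) not in tried:
                return cand_u[idx], config
        return propose_random()

    for t in range(n_trials):
        proposal = propose_random() if t < n_init else propose_ei()
        if proposal is None:  # finite space exhausted
            break
        u, config = proposal
        value = float(objective(config))
        tried.add(_key(config))
        X_obs.append(u)
        y_obs.append(value)
        trials.append((config, value))

    best_idx = int(np.argmin(y_obs))
    return TuningResult(trials[best_idx][0], y_obs[best_idx], trials)


def _binary_cross_entropy(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(np.asarray(p, dtype=float), 1e-12, 1 - 1e-12)
    y = np.asarray(y, dtype=float)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def tune(
    family: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    n_trials: int = 25,
    seed: int = 0,
    search_space: Mapping | None = None,
) -> TuningResult:
    """Search a family's hyperparameter space against the validation split.

    Returns the best configuration found: lowest validation binary
    cross-entropy for ``dnn``, highest validation accuracy for the baselines
    (reported ``best_value`` is the minimized objective, i.e. negative
    accuracy for baselines).
    """
    space = DEFAULT_SEARCH_SPACES[family] if search_space is None else search_space
    if family not in DEFAULT_SEARCH_SPACES:
        raise ValueError(f"unknown classifier family {family!r}")
    y_val = np.asarray(y_val).astype(int).ravel()

    if family == "dnn":
        def objective(config: dict) -> float:
            model = train_dnn(X_train, y_train, DnnConfig(**config, seed=seed))
            return _binary_cross_entropy(y_val, predict_proba(model, X_val))
    else:
        def objective(config: dict) -> float:
            model = train_baseline(family, X_train, y_train, config, seed=seed)
            pred = (predict_proba(model, X_val) >= 0.5).astype(int)
            return -float(np.mean(pred == y_val))

    return bayesian_minimize(space, objective, n_trials=n_trials, seed=seed)
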