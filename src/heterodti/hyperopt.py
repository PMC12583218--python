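"""Gaussian-process Bayesian optimization with expected improvement.

The validation metric is modeled by a GP with a squared-exponential kernel
(per-dimension length scales fit by marginal likelihood).  Each iteration
scores a fresh uniform candidate set with the expected-improvement
acquisition and evaluates the argmax; failed objective evaluations are
recorded and excluded from the GP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

logger = logging.getLogger(__name__)

__all__ = ["SearchSpace", "expected_improvement", "bayesian_optimize"]


@dataclass
class SearchSpace:
    """Box-bounded search space; integer dimensions are rounded on sampling."""

    names: list[str]
    lower: np.ndarray
    upper: np.ndarray
    integer: np.ndarray  # bool per dimension

    @classmethod
    def from_dict(cls, space: dict) -> "SearchSpace":
        names, lo, hi, isint = [], [], [], []
        for name, (a, b) in space.items():
            names.append(name)
            lo.append(float(a))
            hi.append(float(b))
            isint.append(isinstance(a, int) and isinstance(b, int))
        return cls(names, np.array(lo), np.array(hi), np.array(isint))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        X = rng.uniform(self.lower, self.upper, size=(n, len(self.names)))
        X[:, self.integer] = np.round(X[:, self.integer])
        return X

    def to_config(self, x: np.ndarray) -> dict:
        return {
            name: (int(round(v)) if isint else float(v))
            for name, v, isint in zip(self.names, x, self.integer)
        }


def expected_improvement(mu, sigma, f_star) -> np.ndarray:
    """EI(x) = (mu - f*) Phi(z) + sigma phi(z) with z = (mu - f*) / sigma,
    for maximization; max(mu - f*, 0) in the noiseless sigma = 0 limit."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    improvement = mu - f_star
    out = np.maximum(improvement, 0.0)
    positive = sigma > 0
    z = np.divide(improvement, sigma, out=np.zeros_like(improvement + sigma),
                  where=positive)
    ei = improvement * norm.cdf(z) + sigma * norm.pdf(z)
    return np.where(positive, ei, out)


def bayesian_optimize(objective, search_space: dict, n_iter: int = 50,
                      seed: int = 0, n_initial: int = 5,
                      n_candidates: int = 1000) -> dict:
    """Maximize `objective(config dict) -> score` over a box-bounded space.

    Returns {"best_config", "best_score", "trace"} where the trace records
    every evaluated point (config, score or None on failure).
    """
    space = SearchSpace.from_dict(search_space)
    rng = np.random.default_rng(seed)
    X_obs: list[np.ndarray] = []
    y_obs: list[float] = []
    trace: list[dict] = []

    def evaluate(x: np.ndarray):
        cfg = space.to_config(x)
        try:
            score = float(objective(cfg))
        except Exception as exc:  # noqa: BLE001 - failures are data here
            logger.warning("objective failed at %s: %s", cfg, exc)
            trace.append({"config": cfg, "score": None})
            return
        trace.append({"config": cfg, "score": score})
        X_obs.append(x)
        y_obs.append(score)

    for x in space.sample(rng, n_initial):
        evaluate(x)

    width = space.upper - space.lower
    for _ in range(n_iter):
        if len(X_obs) >= 2:
            kernel = (ConstantKernel(1.0, (1e-3, 1e3))
                      * RBF(length_scale=width / 2,
                            length_scale_bounds=[(w * 1e-3, w * 1e2)
                                                 for w in width])
                      + WhiteKernel(1e-6, (1e-10, 1e-1)))
            gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                          n_restarts_optimizer=1,
                                          random_state=int(rng.integers(2**31)))
            gp.fit(np.asarray(X_obs), np.asarray(y_obs))
            candidates = space.sample(rng, n_candidates)
            mu, sigma = gp.predict(candidates, return_std=True)
            ei = expected_improvement(mu, sigma, max(y_obs))
            x_next = candidates[int(np.argmax(ei))]
        else:
            x_next = space.sample(rng, 1)[0]
        evaluate(x_next)

    if not y_obs:
        raise RuntimeError("every objective evaluation failed")
    best = int(np.argmax(y_obs))
    return {
        "best_config": space.to_config(X_obs[best]),
        "best_score": float(y_obs[best]),
        "trace": trace,
    }
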