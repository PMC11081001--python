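"""Gaussian-process Bayesian optimization over a bounded hyperparameter box.

Minimizes an arbitrary objective over the training hyperparameter box
(L2 regularization, section depth, momentum, learning rate) with a Matern
5/2 surrogate and expected-improvement acquisition. Decade-spanning
dimensions (learning rate, L2) are searched in log10 space; the integer
section depth is relaxed continuously and rounded at evaluation time.

The true study objective — validation error of a trained network — is a
GPU-scale computation; the module therefore takes any callable, and a
cheap analytic demo objective is shipped for exercising the loop.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.stats import qmc
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern

DEFAULT_MAX_TIME_S = 54_000.0  # published wall-clock stopping budget (15 h)


@dataclass(frozen=True)
class Dimension:
    """One box dimension; log10 dims are searched on a decade scale."""

    name: str
    low: float
    high: float
    log10: bool = False
    integer: bool = False

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"{self.name}: lower bound must be below upper")
        if self.log10 and self.low <= 0:
            raise ValueError(f"{self.name}: log10 dimension needs positive bounds")

    def to_unit(self, value: float) -> float:
        lo, hi = self._transformed_bounds()
        v = np.log10(value) if self.log10 else value
        return (v - lo) / (hi - lo)

    def from_unit(self, u: float) -> float:
        lo, hi = self._transformed_bounds()
        v = lo + u * (hi - lo)
        if self.log10:
            v = 10.0**v
        if self.integer:
            v = int(round(v))
        return float(v) if not self.integer else v

    def _transformed_bounds(self) -> tuple[float, float]:
        if self.log10:
            return np.log10(self.low), np.log10(self.high)
        return self.low, self.high


@dataclass
class HyperparameterSpace:
    """Named box of dimensions; points are dicts name -> value."""

    dims: list[Dimension]

    def __post_init__(self) -> None:
        if not self.dims:
            raise ValueError("space needs at least one dimension")
        names = [d.name for d in self.dims]
        if len(set(names)) != len(names):
            raise ValueError("dimension names must be unique")

    @classmethod
    def default(cls) -> "HyperparameterSpace":
        """The published training box."""
        return cls(
            [
                Dimension("l2", 1e-10, 1e-2, log10=True),
                Dimension("depth", 1, 3, integer=True),
                Dimension("momentum", 0.7, 0.98),
                Dimension("lr", 1e-4, 1.0, log10=True),
            ]
        )

    def restrict(self, *names: str) -> "HyperparameterSpace":
        """Sub-box keeping only the named dimensions (order preserved)."""
        keep = [d for d in self.dims if d.name in names]
        if len(keep) != len(names):
            missing = set(names) - {d.name for d in keep}
            raise ValueError(f"unknown dimensions: {sorted(missing)}")
        return HyperparameterSpace(keep)

    @property
    def n_dims(self) -> int:
        return len(self.dims)

    def from_unit(self, u: np.ndarray) -> dict[str, float]:
        return {d.name: d.from_unit(ui) for d, ui in zip(self.dims, u)}

    def contains(self, point: dict[str, float]) -> bool:
        return all(d.low <= point[d.name] <= d.high for d in self.dims)


@dataclass
class BoTrace:
    """Ordered evaluation history of one optimization run."""

    points: list[dict[str, float]] = field(default_factory=list)
    values: list[float] = field(default_factory=list)
    stop_reason: str = "max_evals"

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.values))

    @property
    def best_point(self) -> dict[str, float]:
        return self.points[self.best_index]

    @property
    def best_value(self) -> float:
        return float(self.values[self.best_index])

    def running_minimum(self) -> np.ndarray:
        return np.minimum.accumulate(np.asarray(self.values, dtype=float))


def sample_space(space: HyperparameterSpace, n: int, seed: int) -> list[dict[str, float]]:
    """Latin-hypercube design in transformed coordinates, mapped to the box."""
    if n < 1:
        raise ValueError("n must be >= 1")
    sampler = qmc.LatinHypercube(d=space.n_dims, seed=seed)
    return [space.from_unit(row) for row in sampler.random(n)]


def _expected_improvement(mu: np.ndarray, sd: np.ndarray, best: float) -> np.ndarray:
    sd = np.maximum(sd, 1e-12)
    z = (best - mu) / sd
    return (best - mu) * stats.norm.cdf(z) + sd * stats.norm.pdf(z)


def run_bo(
    objective,
    space: HyperparameterSpace,
    max_evals: int = 25,
    max_time_s: float = DEFAULT_MAX_TIME_S,
    seed: int = 0,
    n_init: int = 5,
    n_candidates: int = 2048,
) -> BoTrace:
    """Sequential GP minimization; stops at max_evals or max_time_s.

    Latin-hypercube initialization, Matern 5/2 surrogate on the unit cube,
    expected improvement maximized over a fresh quasi-random candidate set
    each round. NaN objective values are recorded as +inf and excluded from
    the surrogate fit. Deterministic under seed for a deterministic
    objective.
    """
    if max_evals < n_init:
        raise ValueError("max_evals must be at least n_init")
    rng = np.random.default_rng(seed)
    start = time.monotonic()
    trace = BoTrace()
    unit_points: list[np.ndarray] = []

    def record(u: np.ndarray) -> None:
        point = space.from_unit(u)
        val = float(objective(point))
        if np.isnan(val):
            val = np.inf
        unit_points.append(u)
        trace.points.append(point)
        trace.values.append(val)

    init = qmc.LatinHypercube(d=space.n_dims, seed=seed).random(n_init)
    for u in init:
        if time.monotonic() - start > max_time_s:
            trace.stop_reason = "max_time"
            return trace
        record(u)

    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
        length_scale=np.full(space.n_dims, 0.3),
        length_scale_bounds=(1e-2, 1e2),
        nu=2.5,
    )
    while len(trace.values) < max_evals:
        if time.monotonic() - start > max_time_s:
            trace.stop_reason = "max_time"
            return trace
        x = np.array(unit_points)
        y = np.array(trace.values)
        finite = np.isfinite(y)
        if finite.sum() >= 2:
            gp = GaussianProcessRegressor(
                kernel=kernel,
                alpha=1e-10,
                normalize_y=True,
                n_restarts_optimizer=1,
                random_state=int(rng.integers(2**31 - 1)),
            )
            with warnings.catch_warnings():
                # hyperparameter MLE hitting a bound is harmless here
                warnings.simplefilter("ignore")
                gp.fit(x[finite], y[finite])
            cand = qmc.LatinHypercube(
                d=space.n_dims, seed=int(rng.integers(2**31 - 1))
            ).random(n_candidates)
            mu, sd = gp.predict(cand, return_std=True)
            ei = _expected_improvement(mu, sd, float(y[finite].min()))
            record(cand[int(np.argmax(ei))])
        else:  # surrogate unusable (too few finite observations)
            record(rng.uniform(size=space.n_dims))

    trace.stop_reason = "max_evals"
    return trace


def demo_quadratic(point: dict[str, float]) -> float:
    """Analytic demo objective: (log10 lr + 2)^2, minimized at lr = 0.01."""
    return float((np.log10(point["lr"]) + 2.0) ** 2)
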