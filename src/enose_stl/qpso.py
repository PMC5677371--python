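"""Quantum-behaved particle swarm optimization (QPSO).

Bound-constrained stochastic global minimizer.  Each particle is drawn
around a per-dimension attractor p = phi*pbest + (1-phi)*gbest via the
logarithmic jump

    x <- p +/- alpha_ce * |mbest - x| * ln(1/u),   u, phi ~ U(0,1)

where mbest is the mean of the personal bests and alpha_ce is a
contraction-expansion coefficient on a linearly decreasing schedule
(default 1.0 -> 0.5).  The swarm is pluggable so an enhanced variant can
be swapped in without touching callers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SwarmConfig:
    bounds: tuple[tuple[float, float], ...]
    n_particles: int = 30
    iterations: int = 300
    ce_start: float = 1.0  # contraction-expansion schedule endpoints
    ce_end: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("n_particles must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not self.bounds:
            raise ValueError("bounds must be nonempty")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError(f"each bound needs lo < hi, got ({lo}, {hi})")


@dataclass
class SwarmResult:
    best_position: np.ndarray
    best_value: float
    trace: np.ndarray  # best-so-far value after each iteration (non-increasing)

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"iter": np.arange(self.trace.size), "best_value": self.trace}
        )

    def write_trace(self, path: str | Path) -> None:
        self.trace_frame().to_csv(path, index=False)


def _evaluate(objective: Callable, X: np.ndarray) -> np.ndarray:
    values = np.array([float(objective(x)) for x in X])
    if not np.all(np.isfinite(values)):
        bad = X[~np.isfinite(values)][0]
        raise ValueError(f"objective returned a non-finite value at {bad}")
    return values


def optimize(objective: Callable[[np.ndarray], float], config: SwarmConfig) -> SwarmResult:
    """Minimize ``objective`` over the box ``config.bounds``.

    Bit-reproducible given ``config.seed``; every evaluated position lies
    inside the bounds; the best-so-far trace is monotone non-increasing.
    """
    rng = np.random.default_rng(config.seed)
    lo = np.array([b[0] for b in config.bounds])
    hi = np.array([b[1] for b in config.bounds])
    n, d = config.n_particles, lo.size

    X = rng.uniform(lo, hi, size=(n, d))
    values = _evaluate(objective, X)
    pbest = X.copy()
    pvalues = values.copy()
    g = int(np.argmin(pvalues))
    gbest, gvalue = pbest[g].copy(), float(pvalues[g])

    trace = np.empty(config.iterations)
    for it in range(config.iterations):
        frac = it / max(config.iterations - 1, 1)
        ce = config.ce_start + (config.ce_end - config.ce_start) * frac
        mbest = pbest.mean(axis=0)

        phi = rng.uniform(size=(n, d))
        u = 1.0 - rng.uniform(size=(n, d))  # in (0, 1], keeps ln(1/u) finite
        sign = np.where(rng.uniform(size=(n, d)) < 0.5, 1.0, -1.0)
        p = phi * pbest + (1.0 - phi) * gbest
        X = p + sign * ce * np.abs(mbest - X) * np.log(1.0 / u)
        X = np.clip(X, lo, hi)

        values = _evaluate(objective, X)
        improved = values < pvalues
        pbest[improved] = X[improved]
        pvalues[improved] = values[improved]
        g = int(np.argmin(pvalues))
        if pvalues[g] < gvalue:
            gbest, gvalue = pbest[g].copy(), float(pvalues[g])
        trace[it] = gvalue
    return SwarmResult(best_position=gbest, best_value=gvalue, trace=trace)
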