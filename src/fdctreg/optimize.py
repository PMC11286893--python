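"""Gradient ascent with a windowed convergence test.

The update rule is plain gradient ascent,

    p_{n+1} = p_n + learning_rate * S * g(p_n),

where g is the central finite-difference gradient (per-parameter steps) and
S a diagonal parameter-scale matrix that puts rotations (radians) and
translations (mm) on comparable physical footing.  Iteration stops when the
spread (max - min) of the objective over the last ``convergence_window``
values drops below ``convergence_min``, or at ``max_iterations``.  The best
iterate seen is returned, not necessarily the last.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["OptimizerConfig", "OptimizationTrace", "ascend"]


@dataclass
class OptimizerConfig:
    learning_rate: float = 1.0
    max_iterations: int = 100
    convergence_min: float = 1e-6
    convergence_window: int = 10
    fd_step_rotation: float = 1e-3   # radians
    fd_step_translation: float = 0.1  # mm
    parameter_scales: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.max_iterations <= 0:
            raise ValueError("learning_rate and max_iterations must be positive")
        if self.convergence_min <= 0 or self.convergence_window <= 0:
            raise ValueError("convergence settings must be positive")
        if self.convergence_window > self.max_iterations:
            raise ValueError("convergence_window cannot exceed max_iterations")
        if self.fd_step_rotation <= 0 or self.fd_step_translation <= 0:
            raise ValueError("finite-difference steps must be positive")


@dataclass
class OptimizationTrace:
    """Per-iteration record of an ascent run."""

    params: list = field(default_factory=list)
    values: list = field(default_factory=list)
    stop_reason: str = "max_iterations"


def _fd_steps(n: int, cfg: OptimizerConfig) -> np.ndarray:
    # 6-parameter rigid convention: first 3 entries rotations, rest translations
    if n == 6:
        return np.array([cfg.fd_step_rotation] * 3 + [cfg.fd_step_translation] * 3)
    return np.full(n, cfg.fd_step_translation)


def _gradient(objective: Callable, p: np.ndarray, steps: np.ndarray, f0: float) -> np.ndarray:
    g = np.zeros_like(p)
    for k, h in enumerate(steps):
        e = np.zeros_like(p)
        e[k] = h
        fp = objective(p + e)
        fm = objective(p - e)
        if np.isfinite(fp) and np.isfinite(fm):
            g[k] = (fp - fm) / (2.0 * h)
        elif np.isfinite(fp):
            g[k] = (fp - f0) / h
        elif np.isfinite(fm):
            g[k] = (f0 - fm) / h
        # both sides non-finite: leave this component at zero
    return g


def ascend(objective: Callable[[np.ndarray], float], p0,
           cfg: OptimizerConfig) -> tuple[np.ndarray, OptimizationTrace]:
    """Maximize ``objective`` from ``p0``; returns (best params, trace)."""
    p = np.asarray(p0, dtype=float).copy()
    f = float(objective(p))
    if not np.isfinite(f):
        raise ValueError("objective is not finite at the starting point")

    scales = (np.ones_like(p) if cfg.parameter_scales is None
              else np.asarray(cfg.parameter_scales, dtype=float))
    steps = _fd_steps(len(p), cfg)

    trace = OptimizationTrace(params=[p.copy()], values=[f])
    best_p, best_f = p.copy(), f
    window: list[float] = []  # post-update objective values

    for _ in range(cfg.max_iterations):
        g = _gradient(objective, p, steps, f)
        step = cfg.learning_rate * scales * g
        # halving backtrack if the step lands on a non-finite objective
        f_new = np.nan
        for _ in range(11):
            p_new = p + step
            f_new = float(objective(p_new))
            if np.isfinite(f_new):
                break
            step = step / 2.0
        if not np.isfinite(f_new):
            trace.stop_reason = "failure"
            break
        p, f = p_new, f_new
        trace.params.append(p.copy())
        trace.values.append(f)
        if f > best_f:
            best_p, best_f = p.copy(), f
        window.append(f)
        if len(window) >= cfg.convergence_window:
            recent = window[-cfg.convergence_window:]
            if max(recent) - min(recent) < cfg.convergence_min:
                trace.stop_reason = "converged"
                break

    return best_p, trace
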