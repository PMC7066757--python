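"""Robbins-Monro adaptive stochastic gradient descent.

Each iteration takes a step along a stochastic gradient estimate with a
decaying gain gamma(k) = a / (A + k)^alpha.  The maximal iteration count is
the only stop criterion, so runtime is fully predictable.  The gain
numerator ``a`` is typically auto-scaled by the caller so the first step
moves image points by about one voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ASGDResult", "asgd_minimize", "gain"]

DEFAULT_ALPHA = 0.602
DEFAULT_A = 50.0


def gain(k: int, a: float, A: float = DEFAULT_A, alpha: float = DEFAULT_ALPHA) -> float:
    """Step size gamma(k) = a / (A + k)^alpha, strictly decreasing for alpha > 0."""
    return a / (A + k) ** alpha


@dataclass
class ASGDResult:
    x: np.ndarray
    trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    iterations: int = 0


def asgd_minimize(
    cost_and_gradient,
    x0: np.ndarray,
    max_iterations: int,
    a: float = 1.0,
    A: float = DEFAULT_A,
    alpha: float = DEFAULT_ALPHA,
) -> ASGDResult:
    """Minimize a stochastic cost by Robbins-Monro iteration.

    ``cost_and_gradient(x, k)`` must return ``(cost, grad)`` where ``grad`` is
    a stochastic estimate of the cost gradient at ``x`` for iteration ``k``.
    Runs exactly ``max_iterations`` steps; ``max_iterations = 0`` returns
    ``x0`` untouched.  Raises on a non-finite gradient, naming the iteration.
    """
    x = np.asarray(x0, dtype=float).copy()
    trace = np.empty(max_iterations)
    for k in range(max_iterations):
        cost, grad = cost_and_gradient(x, k)
        grad = np.asarray(grad, dtype=float)
        if not np.all(np.isfinite(grad)):
            raise FloatingPointError(f"non-finite gradient at iteration {k}")
        trace[k] = cost
        x -= gain(k, a, A, alpha) * grad
    return ASGDResult(x=x, trace=trace, iterations=max_iterations)
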