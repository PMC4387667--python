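"""Orthant-Wise Limited-memory Quasi-Newton minimization.

Minimizes f(w) = loss(w) + sum_i c_i |w_i| where loss is smooth and the
per-coordinate weights c_i >= 0 may be zero (unpenalized coordinates).
The implementation follows the standard OWL-QN recipe: an L-BFGS two-loop
direction computed from smooth-gradient differences, steered by the
pseudo-gradient of the nonsmooth objective, with the search constrained to
the orthant of the current iterate and a projected backtracking line search.
Penalized coordinates can land exactly at zero, which is what produces
sparse solutions.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Callable, List, Tuple

import numpy as np


@dataclass
class OwlqnProblem:
    """One L1-penalized minimization instance.

    ``smooth_value_and_grad(w)`` must return (loss, gradient) of the smooth
    part only; ``l1_weight`` holds the per-coordinate penalty c_i.
    """

    dim: int
    smooth_value_and_grad: Callable[[np.ndarray], Tuple[float, np.ndarray]]
    l1_weight: np.ndarray
    init: np.ndarray
    memory: int = 10
    max_iter: int = 500
    tol_rel: float = 1e-6

    def __post_init__(self) -> None:
        self.l1_weight = np.broadcast_to(
            np.asarray(self.l1_weight, dtype=float), (self.dim,)).copy()
        self.init = np.asarray(self.init, dtype=float).copy()
        if (self.l1_weight < 0).any():
            raise ValueError("l1 weights must be nonnegative")
        if self.memory < 1:
            raise ValueError("memory must be >= 1")
        if self.init.shape != (self.dim,):
            raise ValueError("init has wrong dimension")


@dataclass
class OwlqnResult:
    x: np.ndarray
    trace: List[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0


def _pseudo_gradient(w: np.ndarray, g: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Directional derivative surrogate of loss + c|w| at w.

    At w_i = 0 the right derivative is used if negative, the left if
    positive, else 0 (the point is a local minimum along that axis).
    """
    pg = np.where(w > 0, g + c, np.where(w < 0, g - c, 0.0))
    at_zero = w == 0
    right = g + c
    left = g - c
    pg = np.where(at_zero & (right < 0), right, pg)
    pg = np.where(at_zero & (left > 0), left, pg)
    return pg


def owlqn_minimize(problem: OwlqnProblem) -> OwlqnResult:
    """Run OWL-QN; the objective trace over iterations is nonincreasing.

    Returns the best iterate with ``converged=False`` if the line search
    stalls before the relative-change tolerance is met.
    """
    c = problem.l1_weight
    w = problem.init.copy()
    loss, g = problem.smooth_value_and_grad(w)
    if not np.isfinite(loss):
        raise ValueError("smooth loss is non-finite at the starting point")
    f = loss + float(c @ np.abs(w))
    trace = [f]
    s_hist: deque = deque(maxlen=problem.memory)
    y_hist: deque = deque(maxlen=problem.memory)
    rho_hist: deque = deque(maxlen=problem.memory)
    converged = False
    it = 0

    for it in range(1, problem.max_iter + 1):
        pg = _pseudo_gradient(w, g, c)
        if np.max(np.abs(pg)) < 1e-12:
            converged = True
            break

        # L-BFGS two-loop on the pseudo-gradient
        d = -pg.copy()
        if s_hist:
            alphas = []
            for s, y, rho in zip(reversed(s_hist), reversed(y_hist),
                                 reversed(rho_hist)):
                a = rho * (s @ d)
                alphas.append(a)
                d -= a * y
            s_last, y_last = s_hist[-1], y_hist[-1]
            d *= (s_last @ y_last) / (y_last @ y_last)
            for (s, y, rho), a in zip(zip(s_hist, y_hist, rho_hist),
                                      reversed(alphas)):
                b = rho * (y @ d)
                d += (a - b) * s
        # keep only components strictly sign-aligned with steepest descent
        d[d * pg >= 0] = 0.0

        # orthant of the current point (sign of -pg where w is zero)
        xi = np.sign(w)
        xi[xi == 0] = np.sign(-pg)[xi == 0]

        step = 1.0 if s_hist else 1.0 / max(np.linalg.norm(pg), 1.0)
        accepted = False
        for _ in range(60):
            w_new = w + step * d
            w_new[w_new * xi < 0] = 0.0      # orthant projection
            loss_new, g_new = problem.smooth_value_and_grad(w_new)
            f_new = loss_new + float(c @ np.abs(w_new))
            if np.isfinite(f_new) and f_new <= f + 1e-4 * float(pg @ (w_new - w)):
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break

        s_vec = w_new - w
        y_vec = g_new - g
        sy = float(s_vec @ y_vec)
        if sy > 1e-10:
            s_hist.append(s_vec)
            y_hist.append(y_vec)
            rho_hist.append(1.0 / sy)

        rel = abs(f - f_new) / max(abs(f_new), 1.0)
        w, g, f = w_new, g_new, f_new
        trace.append(f)
        if rel < problem.tol_rel:
            converged = True
            break

    return OwlqnResult(x=w, trace=trace, converged=converged, n_iter=it)
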