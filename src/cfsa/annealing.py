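"""Simulated-annealing primitives and the refinement loop.

Works on the same continuous positions as the cuttlefish moves: a
neighbour perturbs every component by an independent uniform draw on
[-step, step] (clamped to bounds), the perturbed mask is re-decoded and
scored, and a Metropolis rule decides acceptance on the cost scale
``cost = -fitness`` (so improvements are always accepted).  The
temperature follows a geometric schedule ``t <- t * alpha``, one cooling
step per iteration.  The refinement returns the best solution ever
visited, not the final accepted state, so it can never return something
worse than its input.

Note on the acceptance rule: the uphill branch is the standard
Metropolis probability ``exp(-dc/t)``; a positive exponent would exceed
one and not be a probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .search_space import Bounds, Solution, clip_to_bounds, decode_mask

__all__ = ["SAParams", "cool", "acceptance_probability", "neighbour", "sa_refine"]


@dataclass(frozen=True)
class SAParams:
    """Annealing hyperparameters.

    Defaults are the reference values: initial temperature 9, cooling
    rate 0.95, 100 iterations, neighbourhood half-width 0.1.
    """

    t0: float = 9.0
    alpha: float = 0.95
    n_iter: int = 100
    step: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t0 <= 0:
            raise ValueError("t0 must be positive")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.n_iter < 0:
            raise ValueError("n_iter must be >= 0")
        if self.step <= 0:
            raise ValueError("step must be positive")


def cool(t: float, alpha: float) -> float:
    """One geometric cooling step: returns ``t * alpha``."""
    if t <= 0:
        raise ValueError("temperature must be positive")
    return t * alpha


def acceptance_probability(delta_c: float, t: float) -> float:
    """Metropolis acceptance probability for a cost change ``delta_c``.

    Returns 1 for ``delta_c <= 0`` (improvement or tie) and
    ``exp(-delta_c / t)`` otherwise.  ``delta_c`` is candidate cost
    minus current cost with ``cost = -fitness``.
    """
    if t <= 0:
        raise ValueError("temperature must be positive")
    if delta_c <= 0:
        return 1.0
    return math.exp(-delta_c / t)


def neighbour(
    current: np.ndarray,
    bounds: Bounds,
    step: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Perturb each component by an independent U(-step, step) draw, then clamp."""
    current = np.asarray(current, dtype=float)
    draw = rng.uniform(-step, step, size=current.shape)
    return clip_to_bounds(current + draw, bounds)


def sa_refine(
    start: Solution,
    params: SAParams,
    fitness_fn: Callable[[np.ndarray], float],
    bounds: Bounds,
    rng: np.random.Generator,
    threshold: float = 0.5,
) -> Solution:
    """Refine ``start`` by simulated annealing; return the best-ever visit.

    ``start`` must already be evaluated.  With ``n_iter == 0`` the input
    is returned unchanged and the random stream is untouched.
    """
    if start.fitness is None:
        raise ValueError("start solution must be evaluated before refinement")
    if params.n_iter == 0:
        return start

    current_pos = start.position.copy()
    current_fit = start.fitness
    best = start.copy()
    t = params.t0
    for it in range(params.n_iter):
        cand_pos = neighbour(current_pos, bounds, params.step, rng)
        cand_mask = decode_mask(cand_pos, threshold)
        try:
            cand_fit = fitness_fn(cand_mask)
        except Exception as exc:  # pragma: no cover - defensive context
            raise RuntimeError(f"fitness evaluation failed at SA iteration {it}") from exc
        delta_c = (-cand_fit) - (-current_fit)
        if delta_c <= 0 or rng.random() < acceptance_probability(delta_c, t):
            current_pos, current_fit = cand_pos, cand_fit
            if cand_fit > best.fitness:
                best = Solution(
                    position=cand_pos.copy(),
                    mask=cand_mask.copy(),
                    fitness=cand_fit,
                    provenance="sa_refined",
                )
        t = cool(t, params.alpha)
    return best
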