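"""Cuttlefish-algorithm population machinery.

The cuttlefish algorithm (CFA) is a population metaheuristic that mimics
the colour-changing skin of cuttlefish.  Three cell layers
(chromatophores, iridophores, leucophores) give rise to six update
"cases", organised into four groups of the population:

* G1 (cases 1-2): stretch/shrink — reflection scales the member's own
  position by a random coefficient R, visibility pulls toward the best
  with V fixed at 1:  ``new = R*x + (best - x)``.
* G2 (cases 3-4): mirror — reflection is the best itself (R = 1),
  visibility is scaled:  ``new = best + V*(best - x)``.
* G3 (case 5): local search around the best against the scalar average
  of its components (AVtop):  ``new = best + V*(best - av_top)``.
* G4 (case 6): random environmental matching — a fresh uniform draw.

R and V are sampled uniformly on [r2, r1] and [v2, v1]; every new
position is clamped into bounds and re-decoded into a feature mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional

import numpy as np

from .search_space import Bounds, Solution, clip_to_bounds, decode_mask

__all__ = [
    "CFAParams",
    "Population",
    "init_population",
    "sample_R",
    "sample_V",
    "case12_update",
    "case34_update",
    "case5_update",
    "case6_update",
    "compute_av_top",
]

N_GROUPS = 4


@dataclass(frozen=True)
class CFAParams:
    """Population-level hyperparameters.

    Defaults are the reference values: r1=0.5, r2=-2 (reflection range),
    v1=1, v2=-1 (visibility range).  ``n_pop`` must be at least 4 so all
    four groups are non-empty.
    """

    n_pop: int = 20
    r1: float = 0.5
    r2: float = -2.0
    v1: float = 1.0
    v2: float = -1.0
    max_iter: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pop < N_GROUPS:
            raise ValueError(f"population size must be >= {N_GROUPS} (got {self.n_pop})")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class Population:
    """Four ordered groups, the global best, and the AVtop scalar."""

    groups: List[List[Solution]]
    best: Solution
    av_top: float

    def members(self) -> List[Solution]:
        return [m for g in self.groups for m in g]

    @property
    def size(self) -> int:
        return sum(len(g) for g in self.groups)


def sample_R(r1: float, r2: float, u: float) -> float:
    """Reflection coefficient: ``u*(r1 - r2) + r2`` for ``u ~ U(0, 1)``."""
    return u * (r1 - r2) + r2


def sample_V(v1: float, v2: float, u: float) -> float:
    """Visibility coefficient: ``u*(v1 - v2) + v2`` for ``u ~ U(0, 1)``."""
    return u * (v1 - v2) + v2


def _uniform_position(bounds: Bounds, rng: np.random.Generator) -> np.ndarray:
    # points[j] = random*(upper - lower) + lower, i.i.d. per dimension
    return rng.random(bounds.d) * bounds.span + bounds.lower


def init_population(
    bounds: Bounds,
    params: CFAParams,
    rng: np.random.Generator,
    fitness_fn: Callable[[np.ndarray], float],
    threshold: float = 0.5,
) -> Population:
    """Draw N uniform solutions, evaluate all, split round-robin into 4 groups.

    Member ``i`` joins group ``i % 4``, so remainders land in the
    earliest groups and group sizes differ by at most one.  The global
    best is the member with the highest fitness (first index on ties).
    """
    members: List[Solution] = []
    for _ in range(params.n_pop):
        sol = Solution.from_position(
            _uniform_position(bounds, rng), bounds, threshold, provenance="init"
        )
        sol.fitness = fitness_fn(sol.mask)
        members.append(sol)

    groups: List[List[Solution]] = [[] for _ in range(N_GROUPS)]
    for i, sol in enumerate(members):
        groups[i % N_GROUPS].append(sol)

    best = max(members, key=lambda s: s.fitness).copy()
    return Population(groups=groups, best=best, av_top=compute_av_top(best))


def compute_av_top(best: Solution) -> float:
    """Scalar mean of the best solution's position components (AVtop)."""
    if best.position.size < 1:
        raise ValueError("best solution must have at least one component")
    return float(np.mean(best.position))


def _new_solution(
    raw: np.ndarray, bounds: Bounds, threshold: float, provenance: str
) -> Solution:
    return Solution.from_position(raw, bounds, threshold, provenance=provenance)


def case12_update(
    member: Solution,
    best: Solution,
    R: float,
    bounds: Bounds,
    threshold: float = 0.5,
) -> Solution:
    """G1 stretch/shrink move: ``new_j = R*x_j + (best_j - x_j)`` (V = 1)."""
    if member.position.shape != best.position.shape:
        raise ValueError("member and best must share dimension")
    raw = R * member.position + (best.position - member.position)
    return _new_solution(raw, bounds, threshold, "case12")


def case34_update(
    member: Solution,
    best: Solution,
    V: float,
    bounds: Bounds,
    threshold: float = 0.5,
) -> Solution:
    """G2 mirror move: ``new_j = best_j + V*(best_j - x_j)`` (R = 1)."""
    if member.position.shape != best.position.shape:
        raise ValueError("member and best must share dimension")
    raw = best.position + V * (best.position - member.position)
    return _new_solution(raw, bounds, threshold, "case34")


def case5_update(
    best: Solution,
    av_top: float,
    V: float,
    bounds: Bounds,
    threshold: float = 0.5,
) -> Solution:
    """G3 move around the best: ``new_j = best_j + V*(best_j - av_top)``."""
    if not np.isfinite(av_top):
        raise ValueError("av_top must be finite")
    raw = best.position + V * (best.position - av_top)
    return _new_solution(raw, bounds, threshold, "case5")


def case6_update(
    bounds: Bounds,
    rng: np.random.Generator,
    threshold: float = 0.5,
) -> Solution:
    """G4 random-matching move: a fresh uniform solution."""
    return _new_solution(_uniform_position(bounds, rng), bounds, threshold, "case6")
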