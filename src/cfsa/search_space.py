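"""Continuous encoding of feature subsets and binary-mask decoding.

A candidate feature subset is represented as a point in a bounded box
``[lower, upper]^d`` (one coordinate per candidate feature).  Both the
cuttlefish population moves and the annealing neighbourhood operate on
this continuous position; the subset actually scored by the wrapper
objective is obtained by thresholding each coordinate.  A repair rule
guarantees the decoded subset is never empty, because a wrapper fitness
over zero features is undefined.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["Bounds", "Solution", "decode_mask", "clip_to_bounds"]

#: Provenance labels a Solution may carry.
PROVENANCES = ("init", "case12", "case34", "case5", "case6", "sa_refined", "oracle")


@dataclass(frozen=True)
class Bounds:
    """Per-dimension box constraints of the continuous search space.

    Parameters
    ----------
    lower, upper
        Scalar limits applied to every dimension; ``lower < upper``.
    d
        Number of dimensions, i.e. the number of candidate features.
    """

    lower: float = 0.0
    upper: float = 1.0
    d: int = 1

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"lower must be < upper (got {self.lower}, {self.upper})")
        if self.d < 1:
            raise ValueError(f"d must be >= 1 (got {self.d})")

    @property
    def span(self) -> float:
        return self.upper - self.lower

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)


def clip_to_bounds(position: np.ndarray, bounds: Bounds) -> np.ndarray:
    """Clamp each component of ``position`` into ``[lower, upper]``.

    Idempotent; component order preserved.  Returns a new array.
    """
    position = np.asarray(position, dtype=float)
    return np.clip(position, bounds.lower, bounds.upper)


def decode_mask(position: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a continuous position into a boolean feature mask.

    ``mask[j]`` is True iff ``position[j] > threshold``.  If no component
    exceeds the threshold, the single largest component is forced on
    (ties break to the lowest index), so the mask is never all-False.
    """
    position = np.asarray(position, dtype=float)
    if position.ndim != 1 or position.size == 0:
        raise ValueError("position must be a non-empty 1-D vector")
    mask = position > threshold
    if not mask.any():
        mask = np.zeros(position.size, dtype=bool)
        mask[int(np.argmax(position))] = True  # argmax ties -> lowest index
    return mask


@dataclass
class Solution:
    """A candidate feature subset: continuous position + decoded mask.

    ``fitness`` is None until the wrapper objective has scored the mask.
    """

    position: np.ndarray
    mask: np.ndarray
    fitness: Optional[float] = None
    provenance: str = "init"

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.position.shape != self.mask.shape:
            raise ValueError("position and mask must share shape")
        if not self.mask.any():
            raise ValueError("mask must select at least one feature")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @classmethod
    def from_position(
        cls,
        position: np.ndarray,
        bounds: Bounds,
        threshold: float = 0.5,
        provenance: str = "init",
    ) -> "Solution":
        """Clip a raw position to bounds, decode its mask, and wrap it."""
        if not bounds.lower < threshold < bounds.upper:
            raise ValueError(
                f"threshold {threshold} must lie strictly inside "
                f"({bounds.lower}, {bounds.upper})"
            )
        pos = clip_to_bounds(position, bounds)
        if pos.size != bounds.d:
            raise ValueError(f"position has {pos.size} components, bounds expect {bounds.d}")
        return cls(position=pos, mask=decode_mask(pos, threshold), provenance=provenance)

    def copy(self) -> "Solution":
        return Solution(
            position=self.position.copy(),
            mask=self.mask.copy(),
            fitness=self.fitness,
            provenance=self.provenance,
        )

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())

    def mask_key(self) -> str:
        """Bit-string key of the mask, for memoisation."""
        return "".join("1" if b else "0" for b in self.mask)
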