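"""The hybrid optimizer: cuttlefish outer loop with embedded annealing.

One outer iteration processes the four population groups:

* S1 — stretch/shrink move toward the best (cases 1-2);
* S2 — mirror move (cases 3-4), then simulated-annealing refinement of
  the proposal; the better of the two is kept;
* S3 — local move around the best vs. AVtop (case 5), then the same
  SA refinement + better-of-two merge;
* S4 — fresh uniform re-draws (case 6).

Replacement is greedy: a proposal replaces the group member it was
derived from only when strictly fitter.  The global best is updated
whenever any evaluated solution exceeds it, so the best-so-far fitness
trace is non-decreasing by construction.  All randomness flows from one
seed through named substreams (init / cuttlefish moves / annealing), and
every fitness evaluation goes through a run-scoped memoising cache.

:func:`exhaustive_search` enumerates every non-empty mask with the
identical objective and serves as a certification oracle for small d.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Callable, List, Optional

import numpy as np

from .annealing import SAParams, sa_refine
from .cuttlefish import (
    CFAParams,
    Population,
    case6_update,
    case12_update,
    case34_update,
    case5_update,
    compute_av_top,
    init_population,
    sample_R,
    sample_V,
)
from .data_io import Dataset
from .fitness import FitnessCache, FitnessSpec
from .search_space import Bounds, Solution

__all__ = ["HybridRunResult", "run_hybrid", "exhaustive_search"]


@dataclass
class HybridRunResult:
    """Outcome of one optimizer run, sufficient to reproduce it."""

    best_solution: Solution
    selected_feature_names: List[str]
    history: List[dict]
    config_echo: dict
    seed: int
    n_evaluations: int
    cache_hits: int

    def to_manifest(self) -> dict:
        """JSON-serialisable run manifest (bit-for-bit reproducibility record)."""
        return {
            "config": self.config_echo,
            "seed": self.seed,
            "selected_features": self.selected_feature_names,
            "selected_mask": [bool(b) for b in self.best_solution.mask],
            "best_fitness": self.best_solution.fitness,
            "best_position": [float(x) for x in self.best_solution.position],
            "n_evaluations": self.n_evaluations,
            "cache_hits": self.cache_hits,
            "history": self.history,
        }

    def write_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_manifest(), fh, indent=2)


def _validate_dataset(dataset: Dataset) -> None:
    if dataset.n_features < 2:
        raise ValueError("need at least 2 candidate features")
    if np.unique(dataset.target).size < 2:
        raise ValueError("need at least 2 target classes")


def _config_echo(cfa, sa, fitness_spec, bounds, threshold, mode) -> dict:
    return {
        "cfa": vars(cfa).copy(),
        "sa": vars(sa).copy(),
        "fitness": {
            "classifier": fitness_spec.classifier,
            "classifier_params": dict(fitness_spec.classifier_params),
            "cv_folds": fitness_spec.cv_folds,
            "cv_seed": fitness_spec.cv_seed,
            "penalty_weight": fitness_spec.penalty_weight,
        },
        "bounds": {"lower": bounds.lower, "upper": bounds.upper, "d": bounds.d},
        "threshold": threshold,
        "mode": mode,
    }


def run_hybrid(
    dataset: Dataset,
    cfa: CFAParams,
    sa: SAParams,
    fitness_spec: FitnessSpec,
    bounds: Optional[Bounds] = None,
    seed: int = 0,
    threshold: float = 0.5,
    mode: str = "hybrid",
    cache: Optional[FitnessCache] = None,
) -> HybridRunResult:
    """Run the hybrid (or plain cuttlefish) feature selector.

    ``mode`` is ``"hybrid"`` (annealing refinement in S2/S3) or
    ``"cfa"`` (no refinement anywhere; equivalent to ``sa.n_iter == 0``).
    Deterministic given ``seed`` and the spec's ``cv_seed``.
    """
    if mode not in ("hybrid", "cfa"):
        raise ValueError("mode must be 'hybrid' or 'cfa'")
    _validate_dataset(dataset)
    if bounds is None:
        bounds = Bounds(0.0, 1.0, dataset.n_features)
    if bounds.d != dataset.n_features:
        raise ValueError("bounds dimension must equal the dataset feature count")

    if cache is None:
        cache = FitnessCache(dataset, fitness_spec)
    elif cache.dataset is not dataset or cache.spec != fitness_spec:
        raise ValueError("fitness cache is bound to a different dataset/spec")
    fitness_fn = cache.get_or_compute

    ss = np.random.SeedSequence(seed)
    rng_init, rng_moves, rng_sa = (np.random.default_rng(s) for s in ss.spawn(3))

    pop = init_population(bounds, cfa, rng_init, fitness_fn, threshold)
    best = pop.best
    sa_active = mode == "hybrid" and sa.n_iter > 0

    history: List[dict] = []
    for it in range(1, cfa.max_iter + 1):
        pop.av_top = compute_av_top(best)
        replacements = {"S1": 0, "S2": 0, "S3": 0, "S4": 0}

        for g, group in enumerate(pop.groups):
            for i, member in enumerate(group):
                if g == 0:
                    R = sample_R(cfa.r1, cfa.r2, rng_moves.random())
                    cand = case12_update(member, best, R, bounds, threshold)
                elif g == 1:
                    V = sample_V(cfa.v1, cfa.v2, rng_moves.random())
                    cand = case34_update(member, best, V, bounds, threshold)
                elif g == 2:
                    V = sample_V(cfa.v1, cfa.v2, rng_moves.random())
                    cand = case5_update(best, pop.av_top, V, bounds, threshold)
                else:
                    cand = case6_update(bounds, rng_moves, threshold)
                cand.fitness = fitness_fn(cand.mask)
                if cand.fitness > best.fitness:
                    best = cand.copy()

                if sa_active and g in (1, 2):
                    refined = sa_refine(cand, sa, fitness_fn, bounds, rng_sa, threshold)
                    if refined.fitness > best.fitness:
                        best = refined.copy()
                    if refined.fitness > cand.fitness:
                        cand = refined  # better of proposal vs refinement

                if cand.fitness > member.fitness:  # greedy replacement
                    group[i] = cand
                    replacements[f"S{g + 1}"] += 1

        history.append(
            {
                "iteration": it,
                "best_fitness": best.fitness,
                "replacements": replacements,
                "n_evaluations": cache.n_evaluations,
            }
        )

    pop.best = best
    names = [n for n, b in zip(dataset.feature_names, best.mask) if b]
    return HybridRunResult(
        best_solution=best.copy(),
        selected_feature_names=names,
        history=history,
        config_echo=_config_echo(cfa, sa, fitness_spec, bounds, threshold, mode),
        seed=seed,
        n_evaluations=cache.n_evaluations,
        cache_hits=cache.hits,
    )


def exhaustive_search(
    dataset: Dataset,
    fitness_spec: FitnessSpec,
    max_d: int = 15,
    cache: Optional[FitnessCache] = None,
) -> Solution:
    """Certify the optimum by scoring all 2^d - 1 non-empty masks.

    Ties break to fewer selected features, then to the lexicographically
    smallest mask (False < True, component order).  Refuses d > max_d.
    """
    _validate_dataset(dataset)
    d = dataset.n_features
    if d > max_d:
        raise ValueError(
            f"exhaustive search over d={d} features exceeds the guard bound max_d={max_d}"
        )
    if cache is None:
        cache = FitnessCache(dataset, fitness_spec)

    best_mask: Optional[np.ndarray] = None
    best_fit = -np.inf
    for bits in itertools.product((False, True), repeat=d):
        mask = np.array(bits, dtype=bool)
        if not mask.any():
            continue
        fit = cache.get_or_compute(mask)
        if fit > best_fit:
            better = True
        elif fit == best_fit and best_mask is not None:
            better = (mask.sum(), tuple(mask)) < (best_mask.sum(), tuple(best_mask))
        else:
            better = False
        if better:
            best_mask, best_fit = mask, fit

    assert best_mask is not None
    # synthetic position consistent with a 0.5 decode threshold on [0, 1]
    sol = Solution(position=np.where(best_mask, 1.0, 0.0), mask=best_mask, provenance="oracle")
    sol.fitness = best_fit
    return sol


def full_mask_table(dataset: Dataset, fitness_spec: FitnessSpec, max_d: int = 15):
    """Fitness of every non-empty mask, as (mask-string, n_selected, fitness) rows."""
    _validate_dataset(dataset)
    d = dataset.n_features
    if d > max_d:
        raise ValueError(f"d={d} exceeds guard bound max_d={max_d}")
    cache = FitnessCache(dataset, fitness_spec)
    rows = []
    for bits in itertools.product((False, True), repeat=d):
        mask = np.array(bits, dtype=bool)
        if not mask.any():
            continue
        rows.append(
            {
                "mask": "".join("1" if b else "0" for b in mask),
                "n_selected": int(mask.sum()),
                "fitness": cache.get_or_compute(mask),
            }
        )
    return rows
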