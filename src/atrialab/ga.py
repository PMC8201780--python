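"""Genetic-algorithm estimation of channel parameters from clamp data.

A real-coded GA with truncation ("simple select") parent sampling,
self-adaptive simulated binary crossover (SBX) and gaussian mutation.  The
fitness of a candidate parameter set is the weighted sum of per-dataset
root-mean-square errors between its simulated clamp observables and the
target records.  With elitism at zero the per-generation best may
fluctuate; the best-ever individual is tracked separately and is
non-increasing by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clamp import ClampDataset, predict_quantity
from .params import MutationParameterSet, PARAM_NAMES, SHIFT_PARAMS

__all__ = [
    "GAConfig",
    "FitResult",
    "fitness_wrmse",
    "sbx_crossover",
    "adapt_eta",
    "gaussian_mutation",
    "evolve",
    "default_bounds",
]

#: sampling bounds: wide enough to contain every fitted value
SCALE_BOUNDS = (0.05, 20.0)
SHIFT_BOUNDS = (-80.0, 80.0)


def default_bounds(names: list[str]) -> np.ndarray:
    """(k, 2) per-parameter sampling bounds."""
    out = np.empty((len(names), 2))
    for i, n in enumerate(names):
        out[i] = SHIFT_BOUNDS if n in SHIFT_PARAMS else SCALE_BOUNDS
    return out


@dataclass(frozen=True)
class GAConfig:
    population: int = 1000
    generations: int = 20
    mutation_rate: float = 0.9
    elitism: float = 0.0
    eta0: float = 2.0            # initial SBX distribution index
    parent_fraction: float = 0.15  # top fraction forming the parent pool
    sigma_fraction: float = 0.4   # gaussian mutation sd as fraction of |value|
    sigma_final: float = 0.001    # annealed sd fraction at the last generation
    seed: int = 0

    def __post_init__(self):
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation rate must be in [0, 1]")
        if not 0.0 <= self.elitism < 1.0:
            raise ValueError("elitism must be in [0, 1)")


@dataclass
class FitResult:
    best: MutationParameterSet
    best_score: float
    trace: np.ndarray            # per-generation best score
    best_trace: np.ndarray       # best-ever score, non-increasing
    seed: int
    config: GAConfig
    free_names: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"generation": np.arange(len(self.trace)),
                             "gen_best": self.trace,
                             "best_ever": self.best_trace})


# ---------------------------------------------------------------------------
# Fitness
# ---------------------------------------------------------------------------

def fitness_wrmse(params: MutationParameterSet, datasets: list[ClampDataset],
                  weights: list[float] | None = None,
                  protocols: dict | None = None) -> float:
    """Weighted sum of per-dataset RMSEs between simulation and targets.

    ``score = sum_d w_d * RMSE_d`` with ``RMSE_d`` the record-weight-
    weighted RMSE of raw residuals.  Dataset weights default to
    ``1 / mean(uncertainty^2)`` so quantities measured in different units
    contribute on comparable scales.  Zero iff the simulation matches every
    weighted record exactly; deterministic; invariant to record order.
    """
    return _score_prepared(params, _prepare_targets(datasets, weights, protocols))


def _prepare_targets(datasets, weights=None, protocols=None):
    """Extract (channel, quantity) target arrays once for fast re-scoring."""
    if not datasets:
        raise ValueError("need at least one dataset")
    if weights is not None and len(weights) != len(datasets):
        raise ValueError("one weight per dataset required")
    prepared = []
    for d_idx, ds in enumerate(datasets):
        for (channel, quantity), g in ds.groups():
            v = g["voltage_mV"].to_numpy()
            val = g["value"].to_numpy()
            w = g["weight"].to_numpy()
            if weights is not None:
                w_d = weights[d_idx]
            else:
                # uncertainty normalisation keeps pA/pF, ms and normalised
                # quantities on comparable (relative-error) scales
                w_d = 1.0 / math.sqrt(float(np.mean(g["uncertainty"].to_numpy() ** 2)))
            proto = (protocols or {}).get((channel, quantity),
                     getattr(ds, "protocol", None))
            prepared.append((channel, quantity, v, val, w, w_d, proto))
    return prepared


def _score_prepared(params, prepared) -> float:
    score = 0.0
    for channel, quantity, v, val, w, w_d, proto in prepared:
        sim = predict_quantity(params, channel, quantity, v, proto)
        if np.any(~np.isfinite(sim)):
            raise ValueError(
                f"simulation undefined for {channel}/{quantity} records")
        r = sim - val
        wsum = float(np.sum(w))
        if wsum == 0:
            continue
        score += w_d * np.sqrt(float(np.sum(w * r * r)) / wsum)
    return float(score)


# ---------------------------------------------------------------------------
# Operators
# ---------------------------------------------------------------------------

def sbx_crossover(parent1: np.ndarray, parent2: np.ndarray, eta: float,
                  rng: np.random.Generator,
                  parent_scores: tuple[float, float] | None = None,
                  child_scores: tuple[float, float] | None = None):
    """Simulated binary crossover; mean-preserving per coordinate.

    Returns ``(child1, child2, eta)``.  When both parent and child scores
    are supplied the distribution index is adapted: contracted (larger eta,
    children closer to parents) when the children outperform the parents,
    expanded otherwise; see :func:`adapt_eta`.
    """
    p1 = np.asarray(parent1, dtype=float)
    p2 = np.asarray(parent2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("parents must have the same dimension")
    u = rng.random(p1.shape)
    beta = np.where(u <= 0.5,
                    (2.0 * u) ** (1.0 / (eta + 1.0)),
                    (1.0 / (2.0 * (1.0 - u))) ** (1.0 / (eta + 1.0)))
    c1 = 0.5 * ((1.0 + beta) * p1 + (1.0 - beta) * p2)
    c2 = 0.5 * ((1.0 - beta) * p1 + (1.0 + beta) * p2)
    if parent_scores is not None and child_scores is not None:
        eta = adapt_eta(eta, parent_scores, child_scores)
    return c1, c2, eta


def adapt_eta(eta: float, parent_scores, child_scores,
              factor: float = 1.5, lo: float = 0.5, hi: float = 100.0) -> float:
    """Self-adaptation of the SBX distribution index.

    Children better than parents -> exploit (contract the spread, eta *
    factor); worse -> explore (expand, eta / factor).  Clamped to [lo, hi].
    """
    if min(child_scores) < min(parent_scores):
        eta = eta * factor
    else:
        eta = eta / factor
    return float(np.clip(eta, lo, hi))


def gaussian_mutation(individual: np.ndarray, rate: float,
                      sigma: np.ndarray | float,
                      bounds: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-coordinate gaussian perturbation with probability ``rate``.

    Mutated coordinates are clipped to their sampling bounds (which encode
    the positivity constraints of scale/slope parameters).
    """
    x = np.asarray(individual, dtype=float).copy()
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), x.shape)
    if np.any(sigma < 0):
        raise ValueError("sigma must be >= 0")
    hit = rng.random(x.shape) < rate
    x[hit] += rng.normal(0.0, 1.0, size=int(hit.sum())) * sigma[hit]
    return np.clip(x, bounds[:, 0], bounds[:, 1])


# ---------------------------------------------------------------------------
# Main loop
# ---------------------------------------------------------------------------

def _make_params(free_names, values, base: MutationParameterSet | None):
    d = (base or MutationParameterSet()).to_dict()
    d.pop("label")
    d.update({n: float(v) for n, v in zip(free_names, values)})
    return MutationParameterSet(**d, label="fit")


def evolve(config: GAConfig, free_names: list[str],
           datasets: list[ClampDataset],
           bounds: np.ndarray | None = None,
           base: MutationParameterSet | None = None,
           weights: list[float] | None = None,
           protocols: dict | None = None,
           fitness=None) -> FitResult:
    """Run the GA over the free parameters and return the best-ever fit.

    The initial population is drawn uniformly within the sampling bounds;
    each generation is scored, sorted, and parents are drawn uniformly with
    replacement from the top ``parent_fraction``; SBX then gaussian
    mutation produce the next generation.  Fully reproducible from the
    seed.  ``fitness`` may be overridden (e.g. analytic test functions).
    """
    for n in free_names:
        if n not in PARAM_NAMES:
            raise KeyError(f"unknown free parameter {n!r}")
    if not free_names:
        raise ValueError("free-parameter list must be non-empty")
    if fitness is None:
        if not datasets:
            raise ValueError("datasets required")
        prepared = _prepare_targets(datasets, weights, protocols)

        def fitness(vec):
            return _score_prepared(_make_params(free_names, vec, base), prepared)

    k = len(free_names)
    if bounds is None:
        bounds = default_bounds(free_names)
    bounds = np.asarray(bounds, dtype=float)
    rng = np.random.default_rng(config.seed)
    pop = rng.uniform(bounds[:, 0], bounds[:, 1], size=(config.population, k))

    trace = np.empty(config.generations)
    best_trace = np.empty(config.generations)
    best_vec = None
    best_score = np.inf
    eta = config.eta0
    n_elite = int(np.floor(config.elitism * config.population))
    pool_size = max(2, int(round(config.parent_fraction * config.population)))
    prev_best = None

    for gen in range(config.generations):
        scores = np.array([fitness(ind) for ind in pop])
        if not np.any(np.isfinite(scores)):
            raise RuntimeError(f"generation {gen}: no individual has finite fitness")
        order = np.argsort(scores)
        trace[gen] = scores[order[0]]
        if scores[order[0]] < best_score:
            best_score = float(scores[order[0]])
            best_vec = pop[order[0]].copy()
        best_trace[gen] = best_score
        # self-adaptive SBX: contract the spread while generations improve,
        # expand it when they stall
        if prev_best is not None:
            eta = adapt_eta(eta, (prev_best, prev_best),
                            (scores[order[0]], scores[order[0]]))
        prev_best = float(scores[order[0]])
        if gen == config.generations - 1:
            break

        # annealed mutation scale: broad exploration early, refinement late
        frac = gen / max(config.generations - 2, 1)
        sig_frac = config.sigma_fraction * (
            (config.sigma_final / config.sigma_fraction) ** frac)
        pool = order[:pool_size]
        children = []
        elite = [pop[i].copy() for i in order[:n_elite]]
        while len(children) < config.population - n_elite:
            i, j = rng.choice(pool, size=2, replace=True)
            c1, c2, _ = sbx_crossover(pop[i], pop[j], eta, rng)
            for c in (c1, c2):
                sig = sig_frac * np.maximum(np.abs(c), 0.01)
                c = gaussian_mutation(c, config.mutation_rate, sig, bounds, rng)
                children.append(c)
        pop = np.array(elite + children[: config.population - n_elite])

    return FitResult(best=_make_params(free_names, best_vec, base),
                     best_score=best_score, trace=trace,
                     best_trace=best_trace, seed=config.seed,
                     config=config, free_names=list(free_names))
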