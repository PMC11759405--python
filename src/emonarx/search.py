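"""Integer lag-structure search and sequential forward feature selection.

With one exogenous feature only 3 integer parameters (n_y, n_u, n_k) exist
and the 11^3 grid is searched exhaustively.  With 2 or 3 features (5 or 7
parameters) a genetic algorithm over integer chromosomes takes over:
tournament selection, uniform crossover, random-reset mutation and elitism,
capped at 200 x (parameter count) generations with a stall rule (mean
absolute change of the best fitness over 50 generations below 1e-6).

Feature combinations are grown greedily: the best single feature is always
accepted, and an extension is kept only if it raises the selection score by
at least 0.01 (the score is a mean cross-validated correlation supplied by
the caller).  No accepted feature is ever revisited or removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .narx import DEFAULT_BOUNDS, LagSpec

__all__ = ["GaConfig", "GenerationRecord", "SelectionTrace", "SelectionStage",
           "exhaustive_lag_search", "ga_lag_search",
           "forward_feature_selection"]

#: Minimum score improvement for accepting an additional feature.
SELECTION_DELTA = 0.01
GENERATIONS_PER_PARAM = 200


@dataclass(frozen=True)
class GaConfig:
    population: int = 50
    crossover_prob: float = 0.8
    mutation_prob: float = 0.1
    elite: int = 2
    tournament: int = 3
    max_generations: int | None = None   # None -> 200 x parameter count
    stall_window: int = 50
    stall_tol: float = 1e-6
    constraint_tol: float = 1e-3

    def __post_init__(self):
        if not (0 <= self.crossover_prob <= 1 and 0 <= self.mutation_prob <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.population < 2 or self.elite >= self.population:
            raise ValueError("population must exceed the elite count")

    def generations_for(self, n_params: int) -> int:
        if self.max_generations is not None:
            return self.max_generations
        return GENERATIONS_PER_PARAM * n_params


@dataclass(frozen=True)
class GenerationRecord:
    generation: int
    best: float
    mean: float
    std: float
    constraint_violation: float = 0.0   # always 0 under integer encoding


@dataclass(frozen=True)
class SelectionStage:
    feature: str
    spec: LagSpec | None
    score: float


@dataclass
class SelectionTrace:
    stages: list[SelectionStage] = field(default_factory=list)
    stop_reason: str = ""

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(s.feature for s in self.stages)

    @property
    def final_score(self) -> float:
        return self.stages[-1].score

    @property
    def final_spec(self) -> LagSpec | None:
        return self.stages[-1].spec


def _safe_eval(evaluator, spec, failures: list) -> float:
    try:
        v = float(evaluator(spec))
        return v if np.isfinite(v) else -np.inf
    except Exception as exc:  # noqa: BLE001 - failures score -inf, logged
        failures.append((spec, repr(exc)))
        return -np.inf


def exhaustive_lag_search(
    evaluator: Callable[[LagSpec], float],
    feature: str | Sequence[str],
    bounds: tuple[int, int] = DEFAULT_BOUNDS,
) -> tuple[LagSpec, float]:
    """Evaluate every (n_y, n_u, n_k) on the grid for a single feature.

    Deterministic; ties are broken toward the lexicographically smallest
    (n_y, n_u, n_k).  Evaluator failures score -inf.
    """
    if not isinstance(feature, str):
        (feature,) = feature
    lo, hi = bounds
    failures: list = []
    best_spec, best_score = None, -np.inf
    for n_y in range(lo, hi + 1):
        for n_u in range(lo, hi + 1):
            for n_k in range(lo, hi + 1):
                spec = LagSpec(n_y, (feature,), (n_u,), (n_k,), bounds=bounds)
                score = _safe_eval(evaluator, spec, failures)
                if score > best_score:
                    best_spec, best_score = spec, score
    if best_spec is None:
        best_spec = LagSpec(lo, (feature,), (lo,), (lo,), bounds=bounds)
    return best_spec, best_score


def ga_lag_search(
    evaluator: Callable[[LagSpec], float],
    features: Sequence[str],
    config: GaConfig = GaConfig(),
    bounds: tuple[int, int] = DEFAULT_BOUNDS,
    seed: int | None = 0,
) -> tuple[LagSpec, float, list[GenerationRecord]]:
    """Genetic search over the integer chromosome
    (n_y, n_u1, n_k1[, n_u2, n_k2[, n_u3, n_k3]]).

    Fully seeded; repeated calls with the same seed produce an identical
    generation log.  Returns the best-ever individual, its score, and the
    per-generation log.
    """
    features = tuple(features)
    n_params = 1 + 2 * len(features)
    lo, hi = bounds
    rng = np.random.default_rng(seed)
    cfg = config
    max_gen = cfg.generations_for(n_params)
    failures: list = []
    cache: dict[tuple[int, ...], float] = {}

    def fitness(chrom: np.ndarray) -> float:
        key = tuple(int(v) for v in chrom)
        if key not in cache:
            spec = LagSpec.from_vector(key, features, bounds=bounds)
            cache[key] = _safe_eval(evaluator, spec, failures)
        return cache[key]

    pop = rng.integers(lo, hi + 1, size=(cfg.population, n_params))
    fits = np.array([fitness(c) for c in pop])
    best_idx = int(np.argmax(fits))
    best_chrom, best_fit = pop[best_idx].copy(), float(fits[best_idx])
    log: list[GenerationRecord] = []
    best_history = [best_fit]

    for gen in range(1, max_gen + 1):
        order = np.argsort(fits)[::-1]
        new_pop = [pop[i].copy() for i in order[:cfg.elite]]
        while len(new_pop) < cfg.population:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, cfg.population, cfg.tournament)
                parents.append(pop[contenders[np.argmax(fits[contenders])]])
            p1, p2 = parents
            if rng.random() < cfg.crossover_prob:
                mask = rng.random(n_params) < 0.5
                child = np.where(mask, p1, p2)
            else:
                child = p1.copy()
            mut = rng.random(n_params) < cfg.mutation_prob
            if mut.any():
                child = child.copy()
                child[mut] = rng.integers(lo, hi + 1, int(mut.sum()))
            new_pop.append(child)
        pop = np.vstack(new_pop)
        fits = np.array([fitness(c) for c in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best_chrom = pop[gen_best].copy()
        best_history.append(best_fit)
        finite = fits[np.isfinite(fits)]
        log.append(GenerationRecord(
            generation=gen, best=best_fit,
            mean=float(finite.mean()) if finite.size else -np.inf,
            std=float(finite.std()) if finite.size else 0.0))
        if len(best_history) > cfg.stall_window:
            recent = np.diff(best_history[-(cfg.stall_window + 1):])
            if np.mean(np.abs(recent)) < cfg.stall_tol:
                break
    spec = LagSpec.from_vector(best_chrom, features, bounds=bounds)
    return spec, best_fit, log


def forward_feature_selection(
    candidates: Sequence[str],
    stage_evaluator: Callable[[tuple[str, ...]], tuple[LagSpec | None, float]],
    delta: float = SELECTION_DELTA,
    max_k: int | None = 3,
) -> SelectionTrace:
    """Greedy sequential forward selection.

    ``stage_evaluator(features)`` returns the best (spec, score) for that
    feature combination — an exhaustive or GA lag search for the NARX
    model, a plain refit for the window regression.  Stage 1 always accepts
    the best single feature; stage k+1 accepts the best extension only if it
    improves the incumbent score by at least ``delta``.  Candidate ties are
    broken by the order of ``candidates`` (the canonical feature order).
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate set")
    trace = SelectionTrace()
    selected: tuple[str, ...] = ()
    incumbent = -np.inf
    while True:
        remaining = [c for c in candidates if c not in selected]
        if not remaining:
            trace.stop_reason = "candidates exhausted"
            break
        best = None
        for cand in remaining:
            spec, score = stage_evaluator(selected + (cand,))
            if best is None or score > best[2]:
                best = (cand, spec, score)
        cand, spec, score = best
        if selected and score < incumbent + delta:
            trace.stop_reason = f"Δr < {delta}"
            break
        selected = selected + (cand,)
        incumbent = score
        trace.stages.append(SelectionStage(feature=cand, spec=spec,
                                           score=score))
        if max_k is not None and len(selected) >= max_k:
            trace.stop_reason = "max features"
            break
    return trace
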