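"""Genetic algorithm for questionnaire item selection.

A candidate short form is a binary mask over the items.  The GA
minimizes

    cost(mask) = I * k + sum_i w_i * (1 - R_i^2)

where ``k`` is the total number of retained items, ``I`` a fixed item
cost, and ``R_i^2`` the in-sample OLS R-squared of subscale *i*'s
long-form score (keyed mean of ALL its items) regressed on the retained
item scores.  By default each subscale is regressed on its *own*
retained items, which is what makes a per-subscale retention cap
meaningful; regression on all retained items is available via
``regression_mode="all"``.

The evolutionary loop is a classical generational binary GA: linear-rank
selection, single-point crossover, independent per-bit mutation, elitism
and a feasibility *repair* step that randomly deselects excess items in
any subscale exceeding ``k_max``.  Repair (rather than a penalty term)
guarantees every evaluated individual is feasible.

R-squared values are computed from precomputed covariance blocks, so a
fitness evaluation costs a handful of tiny linear solves regardless of
the number of respondents.

``exhaustive_search`` enumerates every feasible mask on small instances
(<= 20 items) and serves as a ground-truth oracle for the heuristic.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from shortform.scale_model import ScaleSpec, apply_keying, score_subscales, validate_response_matrix

__all__ = [
    "GAConfig",
    "GASolution",
    "FitnessContext",
    "subscale_r2",
    "compute_cost",
    "repair_mask",
    "evolve",
    "exhaustive_search",
]


@dataclass
class GAConfig:
    """GA run parameters.

    Defaults follow common practice for scale abbreviation: item cost
    0.05, population 200, 200 generations, at most 5 items kept per
    subscale, crossover probability 0.8, mutation probability 0.1,
    top 5% elitism.
    """

    item_cost: float = 0.05
    weights: Sequence[float] | None = None  # one per subscale; None => all 1
    population_size: int = 200
    generations: int = 200
    p_crossover: float = 0.8
    p_mutation: float = 0.1
    elite_fraction: float = 0.05
    k_max: int | None = 5
    seed: int = 0
    regression_mode: str = "subscale"  # or "all"
    stall_generations: int | None = None  # optional early stop, off by default

    def validate(self, n_subscales: int | None = None) -> None:
        if self.item_cost < 0:
            raise ValueError("item_cost must be nonnegative")
        for name in ("p_crossover", "p_mutation"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.elite_fraction > 0 and self.elite_fraction * self.population_size < 1:
            raise ValueError(
                "elite_fraction * population_size must be >= 1 when elitism is active"
            )
        if self.k_max is not None and self.k_max < 1:
            raise ValueError("k_max must be >= 1 (or None for unconstrained)")
        if self.regression_mode not in ("subscale", "all"):
            raise ValueError(f"unknown regression_mode {self.regression_mode!r}")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if (w <= 0).any():
                raise ValueError("subscale weights must be positive")
            if n_subscales is not None and len(w) != n_subscales:
                raise ValueError(
                    f"{len(w)} weights given for {n_subscales} subscales"
                )

    def weight_vector(self, n_subscales: int) -> np.ndarray:
        if self.weights is None:
            return np.ones(n_subscales)
        return np.asarray(self.weights, dtype=float)

    def to_dict(self) -> dict:
        return {
            "item_cost": self.item_cost,
            "weights": None if self.weights is None else list(map(float, self.weights)),
            "population_size": self.population_size,
            "generations": self.generations,
            "p_crossover": self.p_crossover,
            "p_mutation": self.p_mutation,
            "elite_fraction": self.elite_fraction,
            "k_max": self.k_max,
            "seed": self.seed,
            "regression_mode": self.regression_mode,
            "stall_generations": self.stall_generations,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GAConfig":
        return cls(**d)


class FitnessContext:
    """Complete-case data plus everything precomputed for fast fitness.

    Parameters
    ----------
    responses :
        Response matrix with NO missing cells (use an imputed copy when
        the design is planned-missing).
    spec :
        The instrument structure.

    Notes
    -----
    The regression target for subscale *i* is the keyed mean of ALL of
    that subscale's items, computed once here.  Covariances between each
    subscale's items and its target are cached so that the R-squared of
    any item subset reduces to solving a system no larger than the
    subscale.
    """

    def __init__(self, responses: pd.DataFrame, spec: ScaleSpec):
        validate_response_matrix(responses, spec)
        keyed = apply_keying(responses, spec)
        if keyed.isna().any().any():
            n_bad = int(keyed.isna().any(axis=1).sum())
            raise ValueError(
                f"fitness context requires complete data; {n_bad} respondents "
                "have missing cells (impute first)"
            )
        self.spec = spec
        self.n_respondents = len(keyed)
        self.item_ids = list(spec.item_ids)
        self._item_pos = {iid: j for j, iid in enumerate(self.item_ids)}
        X = keyed.to_numpy(dtype=float)
        targets = score_subscales(responses, spec)  # keyed mean of all items
        T = targets.to_numpy(dtype=float)
        self.target_scores = targets

        for i, sub in enumerate(spec.subscales):
            if np.var(T[:, i]) == 0:
                raise ValueError(
                    f"subscale {sub!r} target score has zero variance; "
                    "the data cannot support a regression-based fitness"
                )

        # full covariance of [items | targets]; ddof irrelevant for R^2
        full = np.cov(np.hstack([X, T]), rowvar=False, ddof=1)
        L = spec.n_items
        self._cov_items = full[:L, :L]
        self._cov_item_target = full[:L, L:]
        self._var_target = np.diag(full[L:, L:]).copy()
        self.subscale_item_pos = {
            sub: spec.subscale_indices(sub) for sub in spec.subscales
        }

    def r2(self, subscale_index: int, predictor_pos: np.ndarray) -> float:
        """In-sample OLS R^2 of one subscale target on the given item columns."""
        if predictor_pos.size == 0:
            return 0.0
        Sxx = self._cov_items[np.ix_(predictor_pos, predictor_pos)]
        sxy = self._cov_item_target[predictor_pos, subscale_index]
        # minimum-norm solution keeps R^2 well-defined for collinear items
        beta, *_ = np.linalg.lstsq(Sxx, sxy, rcond=None)
        r2 = float(sxy @ beta) / self._var_target[subscale_index]
        return float(min(max(r2, 0.0), 1.0))


def subscale_r2(
    context: FitnessContext,
    subscale_id: str,
    predictor_items: Sequence[str],
) -> float:
    """R^2 of a subscale's long-form score on a set of retained items.

    The empty predictor set yields 0 (intercept-only model).
    """
    spec = context.spec
    if subscale_id not in spec.subscales:
        raise KeyError(f"unknown subscale {subscale_id!r}")
    pos = []
    for iid in predictor_items:
        if iid not in context._item_pos:
            raise KeyError(f"predictor item {iid!r} not in context")
        pos.append(context._item_pos[iid])
    return context.r2(spec.subscales.index(subscale_id), np.array(sorted(pos), dtype=int))


def _mask_r2_vector(mask: np.ndarray, context: FitnessContext, mode: str) -> np.ndarray:
    spec = context.spec
    retained = np.flatnonzero(mask)
    out = np.empty(spec.n_subscales)
    for i, sub in enumerate(spec.subscales):
        if mode == "subscale":
            pos = context.subscale_item_pos[sub]
            pos = pos[mask[pos].astype(bool)]
        else:
            pos = retained
        out[i] = context.r2(i, pos)
    return out


def compute_cost(mask: np.ndarray, context: FitnessContext, config: GAConfig) -> float:
    """Evaluate the item-cost / variance-loss objective for one mask."""
    mask = np.asarray(mask)
    if mask.shape != (context.spec.n_items,):
        raise ValueError(
            f"mask length {mask.shape} does not match item count {context.spec.n_items}"
        )
    w = config.weight_vector(context.spec.n_subscales)
    r2 = _mask_r2_vector(mask, context, config.regression_mode)
    k = int(mask.sum())
    return float(config.item_cost * k + np.sum(w * (1.0 - r2)))


def repair_mask(
    mask: np.ndarray,
    spec: ScaleSpec,
    k_max: int | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Randomly deselect excess items so every subscale keeps <= k_max.

    Compliant masks are returned unchanged (as a copy); repaired masks
    retain a random k_max-subset of the previously retained items.
    """
    mask = np.asarray(mask).astype(np.int8).copy()
    if k_max is None:
        return mask
    for sub in spec.subscales:
        pos = spec.subscale_indices(sub)
        kept = pos[mask[pos] == 1]
        excess = len(kept) - k_max
        if excess > 0:
            drop = rng.choice(kept, size=excess, replace=False)
            mask[drop] = 0
    return mask


@dataclass
class GASolution:
    """Best-ever mask from one GA run plus its audit trail."""

    mask: np.ndarray
    cost: float
    r2: dict  # subscale id -> R^2 of the best mask
    history: pd.DataFrame  # per generation: best_cost, mean_cost, n_items, mean_r2
    config: GAConfig
    seed: int
    item_ids: list = field(default_factory=list)
    dataset_label: str | None = None

    @property
    def retained_items(self) -> list:
        return [iid for iid, m in zip(self.item_ids, self.mask) if m]

    def retained_by_subscale(self, spec: ScaleSpec) -> dict:
        kept = set(self.retained_items)
        return {s: [i for i in spec.items_in_subscale(s) if i in kept]
                for s in spec.subscales}

    def to_dict(self) -> dict:
        return {
            "item_ids": list(self.item_ids),
            "retained_items": self.retained_items,
            "cost": self.cost,
            "r2": {k: float(v) for k, v in self.r2.items()},
            "seed": self.seed,
            "dataset_label": self.dataset_label,
            "config": self.config.to_dict(),
            "history": {c: [float(v) for v in self.history[c]] for c in self.history.columns},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "GASolution":
        item_ids = list(d["item_ids"])
        retained = set(d["retained_items"])
        mask = np.array([1 if i in retained else 0 for i in item_ids], dtype=np.int8)
        return cls(
            mask=mask,
            cost=float(d["cost"]),
            r2=dict(d["r2"]),
            history=pd.DataFrame(d["history"]),
            config=GAConfig.from_dict(d["config"]),
            seed=int(d["seed"]),
            item_ids=item_ids,
            dataset_label=d.get("dataset_label"),
        )

    @classmethod
    def from_json(cls, path) -> "GASolution":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _rank_selection_probs(costs: np.ndarray) -> np.ndarray:
    """Linear-rank selection: probability proportional to rank (best = N)."""
    order = np.argsort(np.argsort(costs))  # 0 = lowest cost
    ranks = len(costs) - order  # best gets N, worst gets 1
    return ranks / ranks.sum()


def evolve(
    context: FitnessContext,
    config: GAConfig,
    dataset_label: str | None = None,
    on_generation=None,
) -> GASolution:
    """Run the generational GA and return the best-ever solution.

    Fully reproducible from ``config.seed``.  With elitism active the
    per-generation best cost is non-increasing.  Cost ties keep the
    incumbent best, so the reported solution is the first mask that
    attained the minimum.
    """
    spec = context.spec
    config.validate(spec.n_subscales)
    rng = np.random.default_rng(config.seed)
    L = spec.n_items
    N = config.population_size
    w = config.weight_vector(spec.n_subscales)
    elite_n = max(1, int(round(config.elite_fraction * N))) if config.elite_fraction > 0 else 0

    cache: dict[bytes, float] = {}

    def cost_of(mask: np.ndarray) -> float:
        key = mask.tobytes()
        c = cache.get(key)
        if c is None:
            r2 = _mask_r2_vector(mask, context, config.regression_mode)
            c = float(config.item_cost * mask.sum() + np.sum(w * (1.0 - r2)))
            cache[key] = c
        return c

    # Bernoulli(0.5) initialization, then repair to feasibility
    pop = rng.integers(0, 2, size=(N, L), dtype=np.int8)
    pop = np.array([repair_mask(ind, spec, config.k_max, rng) for ind in pop])
    costs = np.array([cost_of(ind) for ind in pop])

    best_idx = int(np.argmin(costs))
    best_mask = pop[best_idx].copy()
    best_cost = float(costs[best_idx])

    hist = {"best_cost": [], "mean_cost": [], "n_items": [], "mean_r2": []}

    def record() -> None:
        hist["best_cost"].append(best_cost)
        hist["mean_cost"].append(float(costs.mean()))
        hist["n_items"].append(int(best_mask.sum()))
        hist["mean_r2"].append(
            float(_mask_r2_vector(best_mask, context, config.regression_mode).mean())
        )

    record()  # generation 0 = initial population
    if on_generation is not None:
        on_generation(0, pop, costs)
    stall = 0
    for _gen in range(config.generations):
        order = np.argsort(costs, kind="stable")
        elites = pop[order[:elite_n]].copy() if elite_n else np.empty((0, L), dtype=np.int8)

        probs = _rank_selection_probs(costs)
        n_children = N - elite_n
        children = []
        while len(children) < n_children:
            i, j = rng.choice(N, size=2, p=probs)
            p1, p2 = pop[i].copy(), pop[j].copy()
            if rng.random() < config.p_crossover and L > 1:
                pt = int(rng.integers(1, L))
                p1[pt:], p2[pt:] = pop[j][pt:], pop[i][pt:]
            for child in (p1, p2):
                flips = rng.random(L) < config.p_mutation
                child ^= flips.astype(np.int8)
                child = repair_mask(child, spec, config.k_max, rng)
                if len(children) < n_children:
                    children.append(child)
        pop = np.vstack([elites, np.array(children, dtype=np.int8)])
        costs = np.array([cost_of(ind) for ind in pop])

        gen_best = int(np.argmin(costs))
        if costs[gen_best] < best_cost:  # strict: ties keep the incumbent
            best_cost = float(costs[gen_best])
            best_mask = pop[gen_best].copy()
            stall = 0
        else:
            stall += 1
        record()
        if on_generation is not None:
            on_generation(_gen + 1, pop, costs)
        if config.stall_generations is not None and stall >= config.stall_generations:
            break

    r2_vec = _mask_r2_vector(best_mask, context, config.regression_mode)
    return GASolution(
        mask=best_mask,
        cost=best_cost,
        r2={s: float(v) for s, v in zip(spec.subscales, r2_vec)},
        history=pd.DataFrame(hist),
        config=config,
        seed=config.seed,
        item_ids=list(spec.item_ids),
        dataset_label=dataset_label,
    )


def exhaustive_search(
    context: FitnessContext,
    config: GAConfig,
    max_items: int = 20,
) -> tuple[np.ndarray, float]:
    """Enumerate every feasible mask and return the global optimum.

    Guarded to small instances: the search space is exponential in the
    item count.  Ties are broken by fewer retained items, then by
    lexicographic mask order, so the result is unique and deterministic.
    """
    spec = context.spec
    config.validate(spec.n_subscales)
    if spec.n_items > max_items:
        raise ValueError(
            f"exhaustive search refused: {spec.n_items} items > limit {max_items}"
        )
    if config.regression_mode != "subscale":
        raise NotImplementedError("exhaustive_search supports regression_mode='subscale'")
    w = config.weight_vector(spec.n_subscales)

    # per-subscale: every feasible subset with its cost contribution
    per_sub: list[list[tuple[float, tuple[int, ...]]]] = []
    for i, sub in enumerate(spec.subscales):
        pos = context.subscale_item_pos[sub]
        cap = len(pos) if config.k_max is None else min(config.k_max, len(pos))
        options = []
        for size in range(cap + 1):
            for subset in itertools.combinations(pos, size):
                r2 = context.r2(i, np.array(subset, dtype=int))
                options.append(
                    (config.item_cost * size + w[i] * (1.0 - r2), subset)
                )
        per_sub.append(options)

    # the objective is additive over subscales, so total costs for the
    # full product of per-subscale subsets can be built by broadcasting
    sizes = [len(opts) for opts in per_sub]
    total = np.zeros(1)
    for opts, _size in zip(per_sub, sizes):
        costs_i = np.array([c for c, _ in opts])
        total = (total[:, None] + costs_i[None, :]).ravel()

    min_cost = float(total.min())
    ties = np.flatnonzero(total <= min_cost + 1e-9)

    L = spec.n_items
    best_key = None
    best_mask = None
    for flat in ties:
        combo = np.unravel_index(flat, sizes)
        mask = np.zeros(L, dtype=np.int8)
        for opts, j in zip(per_sub, combo):
            mask[list(opts[j][1])] = 1
        key = (int(mask.sum()), tuple(mask))
        if best_key is None or key < best_key:
            best_key = key
            best_mask = mask
    return best_mask, min_cost
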