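import itertools

import numpy as np
import pandas as pd
import pytest

from shortform.ga_engine import (
    FitnessContext,
    GAConfig,
    compute_cost,
    evolve,
    exhaustive_search,
    repair_mask,
    subscale_r2,
)
from shortform.scale_model import ItemSpec, ScaleSpec, apply_keying, score_subscales

from conftest import make_random_instance


def _ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    """Independent normal-equations R^2 oracle (intercept included)."""
    from sklearn.linear_model import LinearRegression

    model = LinearRegression().fit(X, y)
    return float(model.score(X, y))


@pytest.fixture
def small_instance():
    spec, responses = make_random_instance(seed=7, n_items_range=(8, 8), n_respondents=120)
    return spec, responses, FitnessContext(responses, spec)


class TestSubscaleR2:
    def test_all_items_explain_target_exactly(self, small_instance):
        spec, _, ctx = small_instance
        for sub in spec.subscales:
            r2 = subscale_r2(ctx, sub, spec.items_in_subscale(sub))
            assert r2 == pytest.approx(1.0, abs=1e-10)

    def test_empty_predictor_set_is_zero(self, small_instance):
        spec, _, ctx = small_instance
        assert subscale_r2(ctx, spec.subscales[0], []) == 0.0

    def test_matches_independent_ols(self, small_instance):
        spec, responses, ctx = small_instance
        keyed = apply_keying(responses, spec)
        targets = score_subscales(responses, spec)
        for sub in spec.subscales:
            ids = spec.items_in_subscale(sub)
            subset = ids[: max(2, len(ids) // 2)]
            expected = _ols_r2(targets[sub].to_numpy(), keyed[subset].to_numpy())
            assert subscale_r2(ctx, sub, subset) == pytest.approx(expected, abs=1e-9)

    def test_duplicate_predictor_columns_still_defined(self, small_instance):
        """Collinear predictors fall back to the minimum-norm solution."""
        spec, responses, _ = small_instance
        dup = responses.copy()
        first_sub = spec.subscales[0]
        ids = spec.items_in_subscale(first_sub)
        dup[ids[1]] = dup[ids[0]]  # perfect collinearity
        ctx = FitnessContext(dup, spec)
        r2 = subscale_r2(ctx, first_sub, ids[:2])
        solo = subscale_r2(ctx, first_sub, ids[:1])
        assert r2 == pytest.approx(solo, abs=1e-9)

    def test_unknown_predictor_rejected(self, small_instance):
        spec, _, ctx = small_instance
        with pytest.raises(KeyError):
            subscale_r2(ctx, spec.subscales[0], ["nope"])

    def test_monotone_in_predictor_set(self):
        """Adding an own-subscale item never decreases in-sample R^2."""
        for seed in range(5):
            spec, responses = make_random_instance(seed=seed, n_items_range=(8, 12))
            ctx = FitnessContext(responses, spec)
            rng = np.random.default_rng(seed)
            for sub in spec.subscales:
                ids = spec.items_in_subscale(sub)
                perm = list(rng.permutation(ids))
                r2s = [subscale_r2(ctx, sub, perm[: j + 1]) for j in range(len(perm))]
                assert all(b >= a - 1e-10 for a, b in zip(r2s, r2s[1:]))


class TestComputeCost:
    def test_item_cost_term_only(self):
        """Retaining all of 30 items in 6 x 5-item subscales: every
        R^2 is exactly 1, so cost reduces to I*k = 0.05*30."""
        items = [ItemSpec(f"s{s}i{j}", f"s{s}") for s in range(6) for j in range(5)]
        spec = ScaleSpec(items=items, response_min=1, response_max=6)
        rng = np.random.default_rng(0)
        responses = pd.DataFrame(
            rng.integers(1, 7, size=(40, 30)), columns=spec.item_ids
        )
        ctx = FitnessContext(responses, spec)
        cost = compute_cost(np.ones(30, dtype=int), ctx, GAConfig(item_cost=0.05))
        assert cost == pytest.approx(1.5, abs=1e-9)

    def test_empty_mask_full_penalty(self, small_instance):
        spec, _, ctx = small_instance
        cost = compute_cost(np.zeros(spec.n_items, dtype=int), ctx, GAConfig())
        assert cost == pytest.approx(spec.n_subscales, abs=1e-12)

    def test_matches_independent_computation(self, small_instance):
        """Double-entry bookkeeping: cost recomputed from scratch with
        sklearn OLS and the cost formula written out by hand."""
        spec, responses, ctx = small_instance
        rng = np.random.default_rng(3)
        mask = rng.integers(0, 2, size=spec.n_items)
        config = GAConfig(item_cost=0.07, weights=[1.5] * spec.n_subscales)
        keyed = apply_keying(responses, spec)
        targets = score_subscales(responses, spec)
        expected = 0.07 * mask.sum()
        for sub in spec.subscales:
            ids = spec.items_in_subscale(sub)
            idx = spec.subscale_indices(sub)
            kept = [i for i, j in zip(ids, idx) if mask[j]]
            r2 = _ols_r2(targets[sub].to_numpy(), keyed[kept].to_numpy()) if kept else 0.0
            expected += 1.5 * (1 - r2)
        assert compute_cost(mask, ctx, config) == pytest.approx(expected, abs=1e-9)

    def test_all_weights_closed_form(self, small_instance):
        """With every R^2 forced to 0 (empty mask) cost = I*k + s."""
        spec, _, ctx = small_instance
        cfg = GAConfig(item_cost=0.2)
        empty = np.zeros(spec.n_items, dtype=int)
        assert compute_cost(empty, ctx, cfg) == pytest.approx(spec.n_subscales)


class TestRepair:
    def test_compliant_mask_unchanged(self, toy_spec):
        mask = np.array([1, 0, 1, 1])
        out = repair_mask(mask, toy_spec, k_max=2, rng=np.random.default_rng(0))
        np.testing.assert_array_equal(out, mask)

    def test_excess_randomly_deselected_subset(self):
        items = [ItemSpec(f"i{j}", "S") for j in range(10)]
        spec = ScaleSpec(items=items)
        mask = np.array([1] * 7 + [0] * 3)
        out = repair_mask(mask, spec, k_max=5, rng=np.random.default_rng(1))
        assert out.sum() == 5
        assert np.all(mask[out == 1] == 1)  # repaired set is a subset

    def test_deterministic_under_seed(self):
        items = [ItemSpec(f"i{j}", "S") for j in range(10)]
        spec = ScaleSpec(items=items)
        mask = np.ones(10, dtype=int)
        a = repair_mask(mask, spec, 4, np.random.default_rng(42))
        b = repair_mask(mask, spec, 4, np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)


class TestEvolve:
    def test_closed_population_fixed_point(self, small_instance):
        """No crossover, no mutation: the best initial mask survives."""
        spec, _, ctx = small_instance
        cfg = GAConfig(
            population_size=20, generations=15, p_crossover=0.0, p_mutation=0.0,
            k_max=None, seed=5, elite_fraction=0.1,
        )
        sol = evolve(ctx, cfg)
        assert sol.history["best_cost"].iloc[0] == pytest.approx(sol.cost)

    def test_history_non_increasing_and_cost_reproducible(self, small_instance):
        spec, _, ctx = small_instance
        cfg = GAConfig(population_size=40, generations=30, k_max=3, seed=11)
        sol = evolve(ctx, cfg)
        assert (np.diff(sol.history["best_cost"]) <= 1e-12).all()
        assert compute_cost(sol.mask, ctx, cfg) == pytest.approx(sol.cost, abs=1e-12)

    def test_constraint_satisfied(self, small_instance):
        spec, _, ctx = small_instance
        cfg = GAConfig(population_size=30, generations=20, k_max=2, seed=2)
        sol = evolve(ctx, cfg)
        for sub in spec.subscales:
            idx = spec.subscale_indices(sub)
            assert sol.mask[idx].sum() <= 2

    def test_seed_determinism_bit_identical(self, small_instance):
        spec, _, ctx = small_instance
        cfg = GAConfig(population_size=30, generations=20, k_max=3, seed=9)
        a, b = evolve(ctx, cfg), evolve(ctx, cfg)
        np.testing.assert_array_equal(a.mask, b.mask)
        assert a.cost == b.cost
        pd.testing.assert_frame_equal(a.history, b.history)

    def test_zero_variance_target_named(self, toy_spec):
        resp = pd.DataFrame(
            {"a1": [3] * 10, "a2": [3] * 10, "a3": [4] * 10,
             "b1": list(np.tile([1, 2], 5))}
        )
        with pytest.raises(ValueError, match="'A'.*zero variance"):
            FitnessContext(resp, toy_spec)

    def test_zero_item_cost_unconstrained_keeps_everything(self):
        """With I=0 and no cap, R^2 monotonicity makes the full mask optimal."""
        spec, responses = make_random_instance(seed=21, n_items_range=(8, 10))
        ctx = FitnessContext(responses, spec)
        cfg = GAConfig(item_cost=0.0, k_max=None, population_size=40,
                       generations=40, seed=1)
        _, best_cost = exhaustive_search(ctx, cfg)
        full = np.ones(spec.n_items, dtype=int)
        assert compute_cost(full, ctx, cfg) == pytest.approx(best_cost, abs=1e-9)

    def test_solution_json_round_trip(self, small_instance, tmp_path):
        spec, _, ctx = small_instance
        sol = evolve(ctx, GAConfig(population_size=20, generations=10, k_max=3, seed=4))
        path = tmp_path / "sol.json"
        sol.to_json(path)
        loaded = type(sol).from_json(path)
        np.testing.assert_array_equal(loaded.mask, sol.mask)
        assert loaded.cost == pytest.approx(sol.cost)
        assert loaded.item_ids == sol.item_ids


class TestExhaustiveSearch:
    def _two_item_context(self, redundant: bool):
        spec = ScaleSpec(items=[ItemSpec("x1", "S"), ItemSpec("x2", "S")])
        rng = np.random.default_rng(0)
        x = rng.integers(1, 7, size=60)
        y = x if redundant else rng.integers(1, 7, size=60)
        responses = pd.DataFrame({"x1": x, "x2": y})
        return spec, FitnessContext(responses, spec)

    def test_huge_item_cost_prefers_empty_mask(self):
        spec, ctx = self._two_item_context(redundant=False)
        mask, cost = exhaustive_search(ctx, GAConfig(item_cost=10.0, k_max=None))
        assert mask.sum() == 0
        assert cost == pytest.approx(1.0)  # one subscale, w=1

    def test_redundant_item_dropped(self):
        spec, ctx = self._two_item_context(redundant=True)
        mask, cost = exhaustive_search(ctx, GAConfig(item_cost=0.05, k_max=None))
        assert mask.sum() == 1  # second copy adds I but no R^2

    def test_refuses_large_instances(self):
        spec, responses = make_random_instance(seed=0, n_items_range=(12, 14))
        ctx = FitnessContext(responses, spec)
        with pytest.raises(ValueError, match="refused"):
            exhaustive_search(ctx, GAConfig(), max_items=10)

    def test_matches_independent_enumeration(self):
        """Double-entry oracle: a literal loop over all 2^L masks with
        sklearn R^2 must find the same optimum cost."""
        spec, responses = make_random_instance(seed=13, n_items_range=(8, 8))
        ctx = FitnessContext(responses, spec)
        cfg = GAConfig(item_cost=0.05, k_max=2)
        mask, cost = exhaustive_search(ctx, cfg)

        keyed = apply_keying(responses, spec)
        targets = score_subscales(responses, spec)
        best = np.inf
        for bits in itertools.product([0, 1], repeat=spec.n_items):
            m = np.array(bits)
            feasible = all(
                m[spec.subscale_indices(s)].sum() <= 2 for s in spec.subscales
            )
            if not feasible:
                continue
            c = 0.05 * m.sum()
            for sub in spec.subscales:
                ids = spec.items_in_subscale(sub)
                idx = spec.subscale_indices(sub)
                kept = [i for i, j in zip(ids, idx) if m[j]]
                r2 = (
                    _ols_r2(targets[sub].to_numpy(), keyed[kept].to_numpy())
                    if kept else 0.0
                )
                c += 1 - r2
            best = min(best, c)
        assert cost == pytest.approx(best, abs=1e-8)
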