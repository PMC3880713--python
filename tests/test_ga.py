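import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rsmga import (
    GAConfig,
    QuadraticSurface,
    SweepSpec,
    certified_box_max,
    evolve,
    grid_oracle_max,
    parametric_sweep,
    published_surface,
)
from rsmga.ga import (
    bitwise_mutate,
    decode_chromosome,
    objective_transform,
    surface_objective,
    tournament_select,
    uniform_crossover,
)

BOUNDS5 = ((30.0, 40.0), (10.0, 14.0), (8.0, 12.0), (7.0, 9.0), (2.0, 4.0))


def small_config(**kw):
    defaults = dict(bounds=BOUNDS5, population_size=40, max_generations=60, seed=3)
    defaults.update(kw)
    return GAConfig(**defaults)


class TestConfig:
    def test_defaults_are_study_settings(self):
        cfg = GAConfig(bounds=BOUNDS5)
        assert (cfg.population_size, cfg.max_generations) == (210, 815)
        assert (cfg.crossover_prob, cfg.mutation_prob) == (0.5, 0.0015)
        assert cfg.tournament_size == 2
        assert cfg.chromosome_length == 50

    @pytest.mark.parametrize(
        "kw",
        [
            dict(population_size=1),
            dict(crossover_prob=1.5),
            dict(mutation_prob=-0.1),
            dict(tournament_size=0),
            dict(bits_per_variable=0),
            dict(bounds=((1.0, 1.0),)),
            dict(transform="log"),
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        base = dict(bounds=BOUNDS5)
        base.update(kw)
        with pytest.raises(ValueError):
            GAConfig(**base)


class TestDecode:
    def test_bound_endpoints(self):
        cfg = GAConfig(bounds=((30.0, 40.0),))
        assert decode_chromosome(np.zeros(10, dtype=np.uint8), cfg) == 30.0
        assert decode_chromosome(np.ones(10, dtype=np.uint8), cfg) == 40.0

    def test_linear_mapping_midpoint(self):
        cfg = GAConfig(bounds=((30.0, 40.0),))
        bits = np.zeros(10, dtype=np.uint8)
        bits[0] = 1  # MSB -> integer value 512
        assert decode_chromosome(bits, cfg)[0] == pytest.approx(35.0049, abs=5e-5)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            decode_chromosome(np.zeros(49, dtype=np.uint8), GAConfig(bounds=BOUNDS5))

    def test_population_decode_stays_in_bounds(self, rng):
        cfg = GAConfig(bounds=BOUNDS5)
        pop = rng.integers(0, 2, (64, 50), dtype=np.uint8)
        decoded = decode_chromosome(pop, cfg)
        lows, highs = np.array(BOUNDS5).T
        assert np.all(decoded >= lows) and np.all(decoded <= highs)


class TestTransform:
    def test_examples(self):
        assert objective_transform(3.5, "negate") == -3.5
        assert objective_transform(0.0, "inverse") == 1.0

    @given(st.tuples(st.floats(-0.9, 100), st.floats(-0.9, 100)))
    def test_both_modes_preserve_ranking(self, pair):
        a, b = pair
        if abs(a - b) < 1e-6 * (1 + abs(a)):
            return  # too close for a float-representable ranking
        hi, lo = max(a, b), min(a, b)
        for mode in ("negate", "inverse"):
            assert objective_transform(hi, mode) < objective_transform(lo, mode)

    def test_inverse_domain_error(self):
        with pytest.raises(ValueError):
            objective_transform(-1.5, "inverse")


class TestOperators:
    def test_tournament_returns_best_of_draws(self, rng):
        pop = np.array([[0, 0], [1, 1]], dtype=np.uint8)
        picks = [
            tuple(tournament_select(pop, np.array([5.0, 1.0]), 2, rng))
            for _ in range(50)
        ]
        # fitness 1.0 (the second member) should dominate heavily
        assert picks.count((1, 1)) > picks.count((0, 0))

    def test_tournament_selection_pressure_frequency(self, rng):
        # P(fitter wins a size-2 tournament) = 1 - (1/2)^2 = 0.75
        fitness = np.array([1.0, 2.0])
        draws = rng.integers(0, 2, size=(30000, 2))
        winners = draws[np.arange(30000), np.argmin(fitness[draws], axis=1)]
        assert np.mean(winners == 0) == pytest.approx(0.75, abs=0.01)

    def test_tournament_empty_population(self, rng):
        with pytest.raises(ValueError):
            tournament_select(np.empty((0, 4)), np.empty(0), 2, rng)

    @given(st.integers(0, 2**30))
    def test_crossover_conserves_positional_bit_multiset(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 2, 50, dtype=np.uint8)
        b = rng.integers(0, 2, 50, dtype=np.uint8)
        ca, cb = uniform_crossover(a, b, 0.8, rng)
        assert np.all(ca + cb == a + b)

    def test_crossover_pc_zero_is_identity(self, rng):
        a = rng.integers(0, 2, 50, dtype=np.uint8)
        b = rng.integers(0, 2, 50, dtype=np.uint8)
        ca, cb = uniform_crossover(a, b, 0.0, rng)
        assert np.array_equal(ca, a) and np.array_equal(cb, b)

    def test_crossover_identical_parents(self, rng):
        a = rng.integers(0, 2, 50, dtype=np.uint8)
        ca, cb = uniform_crossover(a, a.copy(), 1.0, rng)
        assert np.array_equal(ca, a) and np.array_equal(cb, a)

    def test_crossover_length_mismatch(self, rng):
        with pytest.raises(ValueError):
            uniform_crossover(np.zeros(5, np.uint8), np.zeros(6, np.uint8), 0.5, rng)

    def test_mutation_edge_rates(self, rng):
        bits = rng.integers(0, 2, 50, dtype=np.uint8)
        assert np.array_equal(bitwise_mutate(bits, 0.0, rng), bits)
        assert np.array_equal(bitwise_mutate(bits, 1.0, rng), 1 - bits)

    def test_mutation_mean_flip_count(self, rng):
        # 50 bits at Pm=0.0015 -> 0.075 expected flips per string
        pop = np.zeros((100000, 50), dtype=np.uint8)
        flipped = bitwise_mutate(pop, 0.0015, rng)
        assert flipped.sum(axis=1).mean() == pytest.approx(0.075, abs=0.006)


class TestEvolve:
    def test_seeded_runs_are_bit_identical(self, space, surface):
        cfg = small_config()
        r1 = evolve(cfg, surface, space)
        r2 = evolve(cfg, surface, space)
        assert np.array_equal(r1.best_bits, r2.best_bits)
        assert r1.best_objective == r2.best_objective
        assert r1.history.equals(r2.history)

    def test_elitist_best_history_is_monotone(self, space, surface):
        res = evolve(small_config(), surface, space)
        assert np.all(np.diff(res.history["best"]) >= 0)

    def test_best_stays_in_bounds(self, space, surface):
        res = evolve(small_config(), surface, space)
        lows, highs = np.array(BOUNDS5).T
        assert np.all(res.best_decoded >= lows)
        assert np.all(res.best_decoded <= highs)

    def test_never_beats_certified_oracle(self, space, rng):
        import itertools as it

        surf = QuadraticSurface(
            float(rng.normal(3, 1)),
            tuple(rng.normal(0, 0.5, 5)),
            tuple(rng.normal(-0.5, 0.5, 5)),
            {p: float(rng.normal(0, 0.3)) for p in it.combinations(range(5), 2)},
        )
        _, oracle = certified_box_max(surf)
        res = evolve(small_config(max_generations=120), surf, space)
        assert res.best_objective <= oracle + 1e-9

    def test_concave_surface_optimum_found_at_center(self, space):
        # separable concave bowl with interior argmax at the coded origin
        import itertools as it

        bowl = QuadraticSurface(
            5.0, (0.0,) * 5, (-1.0,) * 5,
            {p: 0.0 for p in it.combinations(range(5), 2)},
        )
        res = evolve(
            small_config(population_size=120, max_generations=300, seed=11),
            bowl, space,
        )
        coded_best = space.code(res.best_decoded)
        assert np.all(np.abs(coded_best) < 0.02)

    def test_surface_without_space_rejected(self, surface):
        with pytest.raises(ValueError):
            evolve(small_config(), surface)

    def test_study_budget_reaches_published_optimum(self, space, surface):
        cfg = GAConfig.for_space(space, seed=20)
        res = evolve(cfg, surface, space)
        _, oracle = certified_box_max(surface)
        assert res.best_objective <= oracle + 1e-9
        assert res.best_objective >= oracle - 0.02  # 10-bit discretization gap
        assert res.best_objective == pytest.approx(6.456375, abs=0.02)


class TestOracles:
    def test_negative_definite_diagonal_max_at_origin(self):
        import itertools as it

        surf = QuadraticSurface(
            4.2, (0.0,) * 5, (-1.0, -2.0, -0.5, -3.0, -1.5),
            {p: 0.0 for p in it.combinations(range(5), 2)},
        )
        pt, val = certified_box_max(surf)
        assert np.allclose(pt, 0.0)
        assert val == pytest.approx(4.2)

    def test_published_surface_certified_maximum(self, surface):
        pt, val = certified_box_max(surface)
        assert val == pytest.approx(6.4621, abs=5e-4)
        assert val >= 6.456375  # upper-bounds the study's reported optimum
        # optimum sits on the boundary: oil concentration and pH at facets
        assert pt[1] == 1.0 and pt[3] == 1.0

    def test_grid_oracle_agrees_with_certificate(self, surface):
        _, exact = certified_box_max(surface)
        _, approx = grid_oracle_max(surface, resolution=9)
        assert approx <= exact + 1e-9
        assert approx == pytest.approx(exact, abs=0.01)

    def test_grid_oracle_validation(self, surface):
        with pytest.raises(ValueError):
            grid_oracle_max(surface, resolution=1)


class TestSweep:
    def test_single_value_single_replicate(self, space, surface):
        cfg = small_config()
        spec = SweepSpec("max_generations", (60,), 1, cfg)
        table = parametric_sweep(spec, surface, space)
        assert len(table) == 1
        assert table["sd_best"].iloc[0] == 0.0

    def test_larger_population_dominates_on_average(self, space, surface):
        cfg = small_config(max_generations=40)
        spec = SweepSpec("population_size", (10, 210), 6, cfg)
        table = parametric_sweep(spec, surface, space).set_index("value")
        assert table.loc[210, "mean_best"] >= table.loc[10, "mean_best"]

    def test_invalid_sweep_values_rejected(self):
        cfg = small_config()
        with pytest.raises(ValueError):
            SweepSpec("mutation_prob", (0.5, 1.5), 2, cfg)
        with pytest.raises(ValueError):
            SweepSpec("inertia", (0.1,), 2, cfg)
        with pytest.raises(ValueError):
            SweepSpec("population_size", (10,), 0, cfg)

    def test_sweep_is_reproducible(self, space, surface):
        cfg = small_config(max_generations=30)
        spec = SweepSpec("mutation_prob", (0.001, 0.0031), 2, cfg)
        t1 = parametric_sweep(spec, surface, space)
        t2 = parametric_sweep(spec, surface, space)
        assert t1.equals(t2)
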