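"""Generator correctness: determinism, moment matching, planted structure."""

import numpy as np
import pytest

from geodetect import (
    FactorSpec,
    GaussianNoise,
    InteractionSpec,
    OutcomeModel,
    SynthConfig,
    ZoneLayout,
    compute_q,
    expected_q,
    generate,
    make_preset,
    planted_q_config,
    split_groups,
    stratify,
)
from geodetect.synthgen import solve_support_probs


class TestSpecs:
    def test_uncentered_effects_rejected(self):
        with pytest.raises(ValueError, match="centered"):
            FactorSpec("f", (1, 2), (0.5, 0.5), (0.0, 1.0))

    def test_non_simplex_rejected(self):
        with pytest.raises(ValueError, match="simplex"):
            FactorSpec("f", (1, 2), (0.6, 0.6), (0.0, 0.0))

    def test_uncentered_interaction_rejected(self):
        fa = FactorSpec("a", (1, 2), (0.5, 0.5), (0.0, 0.0))
        fb = FactorSpec("b", (1, 2), (0.5, 0.5), (0.0, 0.0))
        zones = ZoneLayout(((0.0, 0.0),), (0.1,), (1.0,))
        models = {"fatalities": OutcomeModel(GaussianNoise(1.0), 1.0)}
        bad = InteractionSpec("a", "b", ((1.0, 0.0), (0.0, 0.0)))
        with pytest.raises(ValueError, match="doubly centered"):
            SynthConfig(n_records=10, zones=zones, factors=(fa, fb),
                        models=models, interactions=(bad,))

    def test_config_json_round_trip(self):
        cfg = make_preset("shenzhen_like")
        again = SynthConfig.from_json(cfg.to_json())
        assert again == cfg
        cfg2 = make_preset("interaction_demo")
        assert SynthConfig.from_json(cfg2.to_json()) == cfg2


class TestMomentMatching:
    def test_exact_three_point_solution(self):
        p = solve_support_probs((1.0, 2.0, 5.0), 1.41, 1.055)
        x = np.array([1.0, 2.0, 5.0])
        assert p @ x == pytest.approx(1.41, abs=1e-10)
        assert p @ x**2 - 1.41**2 == pytest.approx(1.055**2, abs=1e-9)

    def test_integer_support_cannot_reach_printed_fatality_moments(self):
        # no integer-spaced distribution is this underdispersed at mean 0.48
        with pytest.raises(ValueError, match="infeasible"):
            solve_support_probs((0.0, 1.0, 2.0), 0.48, 0.301)

    def test_positive_support_matches_printed_fatality_moments(self):
        p = solve_support_probs((0.25, 0.5, 1.0), 0.48, 0.301)
        x = np.array([0.25, 0.5, 1.0])
        assert p @ x == pytest.approx(0.48, abs=1e-10)
        assert np.sqrt(p @ x**2 - 0.48**2) == pytest.approx(0.301, abs=1e-6)


class TestGenerate:
    def test_determinism_and_seed_sensitivity(self):
        cfg = make_preset("null")
        t1 = generate(cfg, seed=5)
        t2 = generate(cfg, seed=5)
        t3 = generate(cfg, seed=6)
        assert t1 == t2
        assert t1 != t3

    def test_no_planted_structure_q_near_zero(self):
        cfg = make_preset("null")
        table = generate(cfg, seed=1)
        y = table.outcome("fatalities")
        for name in table.factor_names:
            assert compute_q(y, stratify(table, name)).q < 0.03

    def test_shenzhen_like_shape(self, shenzhen_table):
        assert shenzhen_table.n == 3250
        assert len(shenzhen_table.factor_names) == 17
        assert len(shenzhen_table.coding["primary_cause"].categories) == 21

    def test_shenzhen_group_moments(self, shenzhen_table):
        g1, g2, _ = split_groups(shenzhen_table)
        fat = g1.outcome("fatalities")
        inj = g2.outcome("injuries")
        assert fat.mean() == pytest.approx(0.48, abs=0.03)
        assert fat.std() == pytest.approx(0.301, abs=0.03)
        assert inj.mean() == pytest.approx(1.41, abs=0.10)
        assert inj.std() == pytest.approx(1.055, abs=0.10)

    def test_zone_coordinates_cluster(self):
        table = generate(make_preset("spatial_demo"), seed=2)
        strat = stratify(table, "zones")
        coords = table.coords()[strat.index]
        labels = strat.labels.astype(str)
        within = np.mean([
            coords[labels == z].std(axis=0).mean()
            for z in np.unique(labels)
        ])
        assert within < coords.std(axis=0).mean() / 2


class TestExpectedQ:
    def test_symmetric_two_category(self):
        spec = FactorSpec("f", (1, 2), (0.5, 0.5), (-1.0, 1.0))
        assert expected_q(spec, 1.0) == pytest.approx(0.5)

    def test_zero_effects(self):
        spec = FactorSpec("f", (1, 2), (0.5, 0.5), (0.0, 0.0))
        assert expected_q(spec, 1.0) == 0.0

    def test_monte_carlo_oracle(self):
        """Closed form against q computed on a large simulated draw."""
        p = np.array([0.2, 0.8])
        a = np.array([-2.0, 0.5])
        a = a - p @ a
        spec = FactorSpec("f", (1, 2), tuple(p), tuple(a))
        target = expected_q(spec, 1.0)
        rng = np.random.default_rng(3)
        n = 10**6
        idx = rng.choice(2, size=n, p=p)
        y = a[idx] + rng.normal(size=n)
        q_hat = compute_q(y, idx.astype(str)).q
        assert q_hat == pytest.approx(target, abs=0.005)

    def test_invalid_noise_variance(self):
        spec = FactorSpec("f", (1, 2), (0.5, 0.5), (0.0, 0.0))
        with pytest.raises(ValueError):
            expected_q(spec, 0.0)


class TestPresets:
    def test_unknown_preset(self):
        with pytest.raises(ValueError, match="unknown preset"):
            make_preset("nope")

    def test_planted_q_config_hits_target(self):
        cfg = planted_q_config(0.4, 20000, seed=0)
        assert expected_q(cfg.factors[0], 1.0) == pytest.approx(0.4, abs=1e-12)
        table = generate(cfg)
        q = compute_q(table.outcome("fatalities"), stratify(table, "planted")).q
        assert q == pytest.approx(0.4, abs=0.02)

    def test_interaction_demo_marginals_powerless(self):
        table = generate(make_preset("interaction_demo"), seed=4)
        y = table.outcome("fatalities")
        assert compute_q(y, stratify(table, "factor_a")).q < 0.01
        assert compute_q(y, stratify(table, "factor_b")).q < 0.01
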