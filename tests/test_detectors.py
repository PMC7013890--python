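"""Unit and property tests for the four detectors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.base import clone

from geodetect import (
    ENHANCE_BI,
    ENHANCE_NONLINEAR,
    INDEPENDENT,
    INTERACTION_TYPES,
    WEAKEN_NONLINEAR,
    WEAKEN_SINGLE,
    EcologicalDetector,
    FactorDetector,
    InteractionDetector,
    RiskDetector,
    classify_interaction,
    compute_q,
    ecological_detector,
    explained_share,
    interaction_detector,
    overlay,
    q_significance,
    risk_detector,
    stratification_from_labels,
)


def strat(labels):
    return stratification_from_labels(labels)


class TestComputeQ:
    @pytest.mark.parametrize(
        "values, labels, q, sst, ssw",
        [
            ([1, 2, 3, 4], "AABB", 0.8, 5.0, 1.0),   # hand decomposition
            ([1, 2, 1, 2], "AABB", 0.0, 1.0, 1.0),   # equal stratum means
            ([5, 5, 9, 9], "AABB", 1.0, 16.0, 0.0),  # zero within variance
        ],
    )
    def test_hand_decompositions(self, values, labels, q, sst, ssw):
        res = compute_q(values, strat(list(labels)))
        assert res.q == pytest.approx(q, abs=1e-12)
        assert res.sst == pytest.approx(sst)
        assert res.ssw == pytest.approx(ssw)

    def test_constant_outcome_is_degenerate_zero(self):
        res = compute_q([3.0, 3.0, 3.0], strat(["A", "A", "B"]))
        assert res.q == 0.0 and res.degenerate

    def test_identity_and_bounds_random(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(4, 60)
            y = rng.normal(size=n)
            labels = rng.integers(0, rng.integers(2, 6), size=n).astype(str)
            res = compute_q(y, strat(labels))
            assert 0.0 <= res.q <= 1.0
            assert res.ssw <= res.sst + 1e-12
            if res.sst > 0:
                assert res.q == pytest.approx(1 - res.ssw / res.sst, abs=1e-12)
            assert sum(s.n for s in res.per_stratum) == res.n_used

    def test_anova_oracle_equivalence(self):
        """q must equal the between/total share of an independent one-way
        ANOVA decomposition computed from stratum means."""
        rng = np.random.default_rng(1)
        for _ in range(1000):
            n = int(rng.integers(4, 51))
            y = rng.normal(size=n)
            labels = rng.integers(0, rng.integers(2, 8), size=n).astype(str)
            grand = y.mean()
            ssb = sum(
                (y[labels == g]).size * (y[labels == g].mean() - grand) ** 2
                for g in np.unique(labels)
            )
            sst = float(((y - grand) ** 2).sum())
            assert compute_q(y, strat(labels)).q == pytest.approx(
                ssb / sst, abs=1e-10
            )

    def test_scale_and_shift_invariance(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=40)
        labels = rng.integers(0, 3, 40).astype(str)
        q0 = compute_q(y, strat(labels)).q
        assert compute_q(3.7 * y + 11, strat(labels)).q == pytest.approx(q0, abs=1e-10)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            compute_q([1.0, np.nan, 2.0], strat(list("ABA")))


def test_explained_share_is_percent_scale():
    assert explained_share(0.094) == pytest.approx(9.4)
    assert explained_share(0.12) == pytest.approx(12.0)


class TestQSignificance:
    def test_maximal_q_is_extremely_significant(self):
        y = np.repeat([0.0, 1.0], 50)
        labels = np.repeat(["A", "B"], 50)
        p = q_significance(y, strat(labels), n_perm=999, seed=0)
        assert p <= 0.001

    def test_degenerate_outcome_p_one(self):
        assert q_significance(np.ones(10), strat(["A"] * 5 + ["B"] * 5)) == 1.0

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=60)
        labels = rng.integers(0, 3, 60).astype(str)
        p1 = q_significance(y, strat(labels), seed=42)
        p2 = q_significance(y, strat(labels), seed=42)
        assert p1 == p2

    def test_analytic_cross_check_agrees_on_strong_effect(self):
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 3, 300)
        y = labels * 1.0 + rng.normal(size=300)
        s = strat(labels.astype(str))
        assert q_significance(y, s, method="permutation", seed=0) < 0.01
        assert q_significance(y, s, method="noncentral_f") < 0.01

    def test_planted_effect_has_power(self):
        from geodetect import generate, planted_q_config, stratify

        hits = 0
        for seed in range(20):
            table = generate(planted_q_config(0.3, 2000), seed=seed)
            p = q_significance(
                table.outcome("fatalities"), stratify(table, "planted"),
                seed=seed,
            )
            hits += p < 0.05
        assert hits == 20


class TestRiskDetector:
    def test_welch_oracle(self):
        """t and df must match scipy's independent Welch implementation."""
        a = np.array([0.0, 1.0, 1.0])
        b = np.array([3.0, 3.0, 4.0])
        comp = risk_detector(
            np.concatenate([a, b]), strat(["A"] * 3 + ["B"] * 3)
        )
        (pair,) = comp.pairs
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert pair.t_statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert pair.p_value == pytest.approx(ref.pvalue, abs=1e-12)
        assert pair.degrees_of_freedom == pytest.approx(ref.df, abs=1e-9)
        assert pair.significant

    def test_identical_strata_not_significant(self):
        y = [1, 2, 3, 1, 2, 3]
        comp = risk_detector(y, strat(["A"] * 3 + ["B"] * 3))
        (pair,) = comp.pairs
        assert pair.t_statistic == pytest.approx(0.0)
        assert not pair.significant

    def test_antisymmetry(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=30)
        labels = np.array(["A"] * 15 + ["B"] * 15)
        t_ab = risk_detector(y, strat(labels)).pairs[0].t_statistic
        swapped = np.where(labels == "A", "B", "A")
        t_ba = risk_detector(y, strat(swapped)).pairs[0].t_statistic
        assert t_ab == pytest.approx(-t_ba, abs=1e-12)

    def test_singleton_strata_excluded_from_pairs(self):
        y = [1.0, 2.0, 5.0, 1.5, 2.5]
        comp = risk_detector(y, strat(["A", "A", "B", "C", "C"]))
        involved = {p.stratum_a for p in comp.pairs} | {
            p.stratum_b for p in comp.pairs
        }
        assert "B" not in involved and len(comp.pairs) == 1

    def test_planted_ordering_recovered(self):
        from geodetect import generate, planted_q_config, stratify

        table = generate(planted_q_config(0.5, 4000, n_categories=3), seed=7)
        comp = risk_detector(
            table.outcome("fatalities"), stratify(table, "planted")
        )
        # planted effects increase with the category code, so the mean
        # ordering (hence the t sign) must follow the label ordering
        for pair in comp.pairs:
            assert (pair.stratum_a < pair.stratum_b) == (
                pair.t_statistic < 0
            )
            assert pair.significant


class TestEcologicalDetector:
    def test_identical_stratifications_give_f_one(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=50)
        labels = rng.integers(0, 4, 50).astype(str)
        res = ecological_detector(y, strat(labels), strat(labels))
        assert res.f_statistic == pytest.approx(1.0)
        assert res.dominant == "tie"

    def test_direct_arithmetic(self):
        """With equal n the F ratio reduces to SSW_a / SSW_b."""
        rng = np.random.default_rng(7)
        y = rng.normal(size=100)
        la = rng.integers(0, 4, 100).astype(str)
        lb = rng.integers(0, 4, 100).astype(str)
        res = ecological_detector(y, strat(la), strat(lb))
        expected = (100 * 99 * res.ssw_a) / (100 * 99 * res.ssw_b)
        assert res.f_statistic == pytest.approx(expected, abs=1e-12)

    def test_planted_factor_dominates_noise_factor(self):
        from geodetect import generate, planted_q_config, stratify

        table = generate(planted_q_config(0.5, 2000), seed=8)
        y = table.outcome("fatalities")
        rng = np.random.default_rng(9)
        noise_strat = strat(rng.integers(0, 5, 2000).astype(str))
        res = ecological_detector(y, stratify(table, "planted"), noise_strat)
        assert res.p_value < 0.05
        assert res.dominant == "planted"

    def test_zero_denominator_ssw_flagged_infinite(self):
        y = [0.0, 0.0, 1.0, 1.0]
        perfect = strat(["A", "A", "B", "B"])   # SSW = 0
        noisy = strat(["A", "B", "A", "B"])
        res = ecological_detector(y, noisy, perfect)
        assert np.isinf(res.f_statistic) and res.p_value == 0.0


class TestOverlay:
    def test_full_cross(self):
        o = overlay(strat(["a", "a", "b", "b"]), strat(["x", "y", "x", "y"]))
        assert o.n_strata == 4
        assert all(c == 1 for _, c in o.strata)

    def test_constant_second_factor_absorbed(self):
        a = ["a", "a", "b", "b"]
        o = overlay(strat(a), strat(["k"] * 4))
        assert o.n_strata == 2
        assert [c for _, c in o.strata] == [2, 2]

    def test_idempotence(self):
        labels = ["a", "b", "a", "c", "b"]
        o = overlay(strat(labels), strat(labels))
        assert o.n_strata == len(set(labels))
        rng = np.random.default_rng(10)
        y = rng.normal(size=5)
        assert compute_q(y, o).q == pytest.approx(
            compute_q(y, strat(labels)).q, abs=1e-12
        )


class TestClassifyInteraction:
    @pytest.mark.parametrize(
        "qa, qb, qab, expected",
        [
            (0.094, 0.042, 0.178, ENHANCE_NONLINEAR),
            (0.3, 0.2, 0.1, WEAKEN_NONLINEAR),
            (0.3, 0.2, 0.25, WEAKEN_SINGLE),
            (0.1, 0.2, 0.25, ENHANCE_BI),
            (0.1, 0.2, 0.30, INDEPENDENT),
            (0.1, 0.2, 0.35, ENHANCE_NONLINEAR),
        ],
    )
    def test_rule_table(self, qa, qb, qab, expected):
        assert classify_interaction(qa, qb, qab).type_label == expected

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            classify_interaction(1.2, 0.1, 0.5)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        st.floats(0, 1, allow_nan=False),
        st.floats(0, 1, allow_nan=False),
        st.floats(0, 1, allow_nan=False),
    )
    def test_total_and_deterministic(self, qa, qb, qab):
        first = classify_interaction(qa, qb, qab).type_label
        assert first in INTERACTION_TYPES
        assert classify_interaction(qa, qb, qab).type_label == first


class TestInteractionDetector:
    def test_overlay_never_weakens(self):
        """The overlay refines both factors, so q_ab >= max(q_a, q_b)."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(10, 80))
            y = rng.normal(size=n)
            la = rng.integers(0, 4, n).astype(str)
            lb = rng.integers(0, 3, n).astype(str)
            r = interaction_detector(y, strat(la), strat(lb))
            assert r.q_ab >= max(r.q_a, r.q_b) - 1e-12
            assert r.type_label not in (WEAKEN_NONLINEAR, WEAKEN_SINGLE)

    def test_redundant_second_factor(self):
        rng = np.random.default_rng(12)
        la = rng.integers(0, 3, 500)
        y = la * 2.0 + rng.normal(size=500)
        lb = np.zeros(500, dtype=int)     # constant: adds nothing
        r = interaction_detector(y, strat(la.astype(str)), strat(lb.astype(str)))
        assert r.q_ab == pytest.approx(r.q_a, abs=1e-12)
        # q_b == 0 puts the triple exactly on the Independent boundary
        assert r.type_label in (ENHANCE_BI, INDEPENDENT)

    def test_planted_cross_term_detected(self):
        from geodetect import generate, make_preset, stratify

        table = generate(make_preset("interaction_demo"), seed=13)
        r = interaction_detector(
            table.outcome("fatalities"),
            stratify(table, "factor_a"),
            stratify(table, "factor_b"),
        )
        assert r.type_label == ENHANCE_NONLINEAR
        assert r.q_ab > 0.2 and max(r.q_a, r.q_b) < 0.05


class TestEstimatorAPI:
    def test_factor_detector_fit_attributes(self):
        rng = np.random.default_rng(14)
        X = rng.integers(0, 3, 200).astype(str)
        y = (X == "2") * 1.0 + rng.normal(size=200)
        det = FactorDetector(random_state=0).fit(X, y)
        assert 0 <= det.q_ <= 1 and det.p_value_ < 0.05
        assert det.result_.n_used == 200

    def test_get_set_params_and_clone(self):
        det = FactorDetector(n_perm=199, random_state=3)
        params = det.get_params()
        assert params["n_perm"] == 199
        cloned = clone(det)
        assert cloned.get_params() == params
        cloned.set_params(n_perm=299)
        assert cloned.n_perm == 299 and det.n_perm == 199

    def test_two_column_estimators(self):
        rng = np.random.default_rng(15)
        a = rng.integers(0, 3, 300)
        b = rng.integers(0, 3, 300)
        y = a * 1.0 + rng.normal(size=300)
        X = np.column_stack([a.astype(str), b.astype(str)])
        eco = EcologicalDetector().fit(X, y)
        assert eco.dominant_ == "X1"
        inter = InteractionDetector().fit(X, y)
        assert inter.q_ab_ >= inter.q_a_ - 1e-12
        risk = RiskDetector().fit(a.astype(str), y)
        assert len(risk.comparison_.pairs) == 3
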