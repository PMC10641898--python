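import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from caimnet.stats import (
    binomial_ci_halfwidth,
    build_report,
    fisher_exact_2x2,
    fit_interaction_lm,
    rank_sum,
    signed_rank,
    simple_regression,
)


class TestBinomialCI:
    def test_printed_error_bars_reproduced(self):
        assert binomial_ci_halfwidth(0.301, 2530) == pytest.approx(1.8, abs=0.05)
        assert binomial_ci_halfwidth(0.0812, 301335) == pytest.approx(0.10, abs=0.005)

    def test_half_proportion_benchmark(self):
        assert binomial_ci_halfwidth(0.5, 100) == pytest.approx(9.8)

    def test_scales_as_inverse_sqrt_n(self):
        a = binomial_ci_halfwidth(0.3, 100)
        b = binomial_ci_halfwidth(0.3, 400)
        assert a / b == pytest.approx(2.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            binomial_ci_halfwidth(1.2, 10)
        with pytest.raises(ValueError):
            binomial_ci_halfwidth(0.5, 0)


def fisher_enumeration(table):
    """Exhaustive hypergeometric enumeration over all tables with the margins."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def p_of(a_):
        return (comb(r1, a_, exact=True) * comb(r2, c1 - a_, exact=True)
                / comb(n, c1, exact=True))

    p_obs = p_of(a)
    total = 0.0
    for a_ in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = p_of(a_)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return total


class TestFisherExact:
    def test_balanced_table_has_no_association(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_tiny_diagonal_table_by_enumeration(self):
        # 3 possible tables with these margins; the diagonal one has p=1/6
        # on each side, two-sided sum = 1/3
        assert fisher_exact_2x2([[2, 0], [0, 2]]) == pytest.approx(1 / 3)

    def test_matches_enumeration_on_random_tables(self, rng):
        for _ in range(25):
            t = rng.integers(0, 8, size=(2, 2))
            if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
                continue
            assert fisher_exact_2x2(t) == pytest.approx(fisher_enumeration(t))

    def test_invariant_under_row_and_column_swaps(self, rng):
        t = np.array([[7, 2], [3, 9]])
        p = fisher_exact_2x2(t)
        assert fisher_exact_2x2(t[::-1]) == pytest.approx(p)
        assert fisher_exact_2x2(t[:, ::-1]) == pytest.approx(p)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[0, 0], [3, 4]])


class TestRankTests:
    def test_identical_groups_not_different(self):
        x = np.arange(10.0)
        assert rank_sum(x, x) > 0.99

    def test_large_shift_strongly_detected(self, rng):
        x = rng.normal(0, 1, 20)
        assert rank_sum(x, x + 10.0) < 1e-3

    def test_symmetric_sample_not_different_from_zero(self):
        rng = np.random.default_rng(5)
        assert signed_rank(rng.normal(0, 1, 30)) > 0.05

    def test_shifted_sample_detected(self, rng):
        assert signed_rank(rng.normal(3, 1, 30)) < 1e-3


def grouped_data(rng, effect_behavior=0.0, effect_interaction=0.0, n=10):
    rows = []
    for genotype, behavior in itertools.product(("WT", "KO"), ("rest", "run")):
        mu = 0.0
        if behavior == "run":
            mu += effect_behavior
        if genotype == "KO" and behavior == "run":
            mu += effect_interaction
        for _ in range(n):
            rows.append({"genotype": genotype, "behavior": behavior,
                         "value": rng.normal(mu, 1.0)})
    return pd.DataFrame(rows)


class TestInteractionLM:
    def test_type_one_error_calibrated_under_null(self):
        rng = np.random.default_rng(77)
        hits = sum(
            fit_interaction_lm(grouped_data(rng)).deviance_p < 0.05
            for _ in range(400)
        )
        # binomial 99.9% band around 5% of 400
        assert 4 <= hits <= 41

    def test_behavior_main_effect_detected_with_power(self):
        # with treatment coding the behavior coefficient is estimated in
        # the reference genotype alone, so 20 sessions per cell give ~90%
        # power at a 1 SD planted effect
        rng = np.random.default_rng(78)
        hits = 0
        for _ in range(50):
            res = fit_interaction_lm(grouped_data(rng, effect_behavior=1.0, n=20))
            key = next(k for k in res.coef_p if "behavior" in k and ":" not in k)
            hits += res.model_significant and res.coef_p[key] < 0.05
        assert hits / 50 >= 0.80

    def test_planted_interaction_triggers_posthoc_in_right_genotype(self):
        rng = np.random.default_rng(79)
        found = 0
        for _ in range(20):
            res = fit_interaction_lm(
                grouped_data(rng, effect_interaction=2.5, n=12))
            if res.interaction_p is not None and res.interaction_p < 0.05:
                assert set(res.posthoc_p) == {"WT", "KO"}
                found += res.posthoc_p["KO"] < 0.05
        assert found >= 10  # the state difference shows up where planted

    def test_rank_deficient_design_rejected(self):
        df = pd.DataFrame({
            "genotype": ["WT"] * 4,
            "behavior": ["rest", "rest", "run", "run"],
            "value": [1.0, 2.0, 3.0, 4.0],
        })
        with pytest.raises(ValueError):
            fit_interaction_lm(df)


class TestSimpleRegression:
    def test_exact_line_recovered(self):
        x = np.arange(10.0)
        slope, intercept, p = simple_regression(x, 2 * x)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0, abs=1e-10)
        assert p < 1e-10

    def test_matches_normal_equations(self, rng):
        x = rng.normal(0, 1, 50)
        y = rng.normal(0, 1, 50)
        slope, intercept, _ = simple_regression(x, y)
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert intercept == pytest.approx(beta[0])
        assert slope == pytest.approx(beta[1])

    def test_null_slope_p_roughly_uniform(self):
        rng = np.random.default_rng(80)
        ps = [simple_regression(rng.normal(0, 1, 20), rng.normal(0, 1, 20))[2]
              for _ in range(300)]
        frac = np.mean(np.array(ps) < 0.05)
        assert 0.01 < frac < 0.10

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            simple_regression(np.ones(5), np.arange(5.0))


class TestBuildReport:
    def test_empty_input_is_safe(self):
        rep = build_report([])
        assert rep["n_sessions"] == 0

    def test_two_group_study_matches_recomputation(self):
        rng = np.random.default_rng(81)
        sessions = []
        for group, mu in (("WT", 2.0), ("KO", 2.2)):
            for _ in range(6):
                sessions.append({
                    "group": group,
                    "event_rate_rest": float(rng.normal(mu, 0.3)),
                    "event_rate_run": float(rng.normal(mu + 1.0, 0.3)),
                    "n_cells": 100,
                    "n_modulated": int(rng.integers(20, 35)),
                    "centrality_difference": float(rng.normal(0.03, 0.01)),
                })
        rep = build_report(sessions)
        wt = [s for s in sessions if s["group"] == "WT"]
        assert rep["groups"]["WT"]["event_rate_rest"]["mean"] == pytest.approx(
            np.mean([s["event_rate_rest"] for s in wt]))
        n_mod = sum(s["n_modulated"] for s in wt)
        assert rep["groups"]["WT"]["modulated_percent"]["value"] == pytest.approx(
            100 * n_mod / 600)
        assert "event_rate_lm" in rep["tests"]
        assert rep["multiple_testing_correction"] == "none"

    def test_deterministic_given_fixed_inputs(self):
        sessions = [{"group": "WT", "event_rate_rest": 1.5,
                     "event_rate_run": 2.5, "n_cells": 50, "n_modulated": 10}]
        assert build_report(sessions) == build_report(sessions)
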