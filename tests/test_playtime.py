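"""Tests for playtime normalization, the regression battery, and slopes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shakebox import (
    DataError,
    DegenerateDesignError,
    GeneratorConfig,
    condition_mean_correlation,
    fit_accuracy_regression,
    fit_playtime_regression,
    generate_exploration_trials,
    individual_slopes,
    normalize_playtimes,
)
from shakebox.playtime import trial_dprime


def make_trials(playtimes_by_child, pairs=((9, 8), (8, 6), (8, 1), (6, 3))):
    """Hand-built trial table: one row per child x contrast."""
    rows = []
    for child, plays in playtimes_by_child.items():
        for j, ((a, b), p) in enumerate(zip(pairs, plays)):
            rows.append(
                {
                    "child_id": child,
                    "experiment": "toy",
                    "trial_order": j + 1,
                    "n_a": a,
                    "n_b": b,
                    "hidden": a,
                    "playtime_s": float(p),
                    "response_count": a,
                    "correct": True,
                }
            )
    return pd.DataFrame(rows)


class TestNormalization:
    def test_uniform_play_gives_ones(self):
        norm = normalize_playtimes(make_trials({"c1": [10, 10, 10, 10]}))
        assert np.allclose(norm["normalized_playtime"], 1.0)

    def test_proportional_values(self):
        norm = normalize_playtimes(make_trials({"c1": [10, 20, 30, 40]}))
        assert np.allclose(norm["normalized_playtime"], [0.4, 0.8, 1.2, 1.6])

    def test_per_child_mean_is_one(self, default_norm):
        means = default_norm.groupby("child_id")["normalized_playtime"].mean()
        assert np.allclose(means, 1.0, atol=1e-12)
        sums = default_norm.groupby("child_id")["normalized_playtime"].sum()
        assert np.allclose(sums, 4.0, atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, scale):
        """Multiplying one child's raw playtimes by any positive constant
        leaves their normalized values unchanged."""
        base = make_trials({"c1": [5, 9, 13, 3], "c2": [1, 2, 3, 4]})
        scaled = base.copy()
        mask = scaled["child_id"] == "c1"
        scaled.loc[mask, "playtime_s"] *= scale
        a = normalize_playtimes(base)["normalized_playtime"].to_numpy()
        b = normalize_playtimes(scaled)["normalized_playtime"].to_numpy()
        assert np.allclose(a, b, rtol=1e-9)

    def test_zero_total_child_excluded_with_warning(self):
        trials = make_trials({"c1": [0, 0, 0, 0], "c2": [1, 2, 3, 4]})
        with pytest.warns(UserWarning, match="zero total playtime"):
            norm = normalize_playtimes(trials)
        assert set(norm["child_id"]) == {"c2"}

    def test_negative_playtime_rejected(self):
        with pytest.raises(DataError):
            normalize_playtimes(make_trials({"c1": [1, 2, -3, 4]}))


class TestPlaytimeRegression:
    def test_noiseless_recovery_is_exact(self):
        cfg = GeneratorConfig(
            seed=3, playtime_slope_theta=0.3, noise_sd=0.0, child_sd=0.0
        )
        norm = normalize_playtimes(generate_exploration_trials(cfg))
        fit = fit_playtime_regression(norm, "neg_dprime")
        assert fit.beta == pytest.approx(0.3, abs=1e-10)

    def test_default_recovery_within_published_interval(self, default_norm):
        fit = fit_playtime_regression(default_norm, "neg_dprime")
        assert 0.18 <= fit.beta <= 0.30
        assert fit.clustering == "child"
        assert fit.n_children == 96

    def test_content_null_ci_covers_zero_across_seeds(self):
        hits = 0
        for seed in range(20):
            norm = normalize_playtimes(
                generate_exploration_trials(GeneratorConfig(seed=seed))
            )
            fit = fit_playtime_regression(norm, "hidden_count")
            hits += fit.ci_low <= 0.0 <= fit.ci_high
        assert hits >= 17

    def test_clustered_slope_equals_brute_force_normal_equations(self):
        """On a small toy table the point estimate must equal the
        hand-computed least-squares slope (clustering only changes SEs)."""
        trials = make_trials(
            {"c1": [5, 9, 13, 3], "c2": [4, 4, 6, 2], "c3": [1, 2, 3, 4]}
        )
        norm = normalize_playtimes(trials)
        x = -trial_dprime(norm)
        y = norm["normalized_playtime"].to_numpy()
        xc = x - x.mean()
        slope_oracle = float(xc @ (y - y.mean()) / (xc @ xc))
        fit = fit_playtime_regression(norm, "neg_dprime")
        assert fit.beta == pytest.approx(slope_oracle, abs=1e-12)

    def test_constant_predictor_rejected(self):
        trials = make_trials(
            {"c1": [1, 2, 3, 4], "c2": [2, 2, 2, 2]},
            pairs=((8, 2), (8, 2), (8, 2), (8, 2)),
        )
        norm = normalize_playtimes(trials)
        with pytest.raises(DegenerateDesignError):
            fit_playtime_regression(norm, "neg_dprime")

    def test_single_child_flagged_not_fatal(self):
        norm = normalize_playtimes(make_trials({"c1": [5, 9, 13, 3]}))
        with pytest.warns(UserWarning, match="clustered SEs unavailable"):
            fit = fit_playtime_regression(norm, "neg_dprime")
        assert fit.clustering == "none"
        assert "unavailable" in fit.notes

    def test_mixed_estimator_agrees_roughly(self, default_norm):
        ols = fit_playtime_regression(default_norm, "neg_dprime")
        mixed = fit_playtime_regression(default_norm, "neg_dprime", estimator="mixed")
        assert mixed.beta == pytest.approx(ols.beta, abs=0.02)

    def test_log_playtime_scale_effect_is_positive(self, default_norm):
        fit = fit_playtime_regression(
            default_norm, "neg_dprime", playtime_scale="log"
        )
        assert fit.beta > 0


class TestAccuracyRegression:
    def test_recovers_generating_slope(self):
        cfg = GeneratorConfig(seed=21, n_children_per_experiment=300)
        trials = generate_exploration_trials(cfg)
        fit = fit_accuracy_regression(trials)
        assert fit.converged
        assert fit.beta == pytest.approx(1.12, rel=0.2)

    def test_constant_dprime_rejected(self):
        trials = make_trials(
            {"c1": [1, 2, 3, 4], "c2": [2, 3, 1, 1]},
            pairs=((8, 2), (8, 2), (8, 2), (8, 2)),
        )
        with pytest.raises(DegenerateDesignError):
            fit_accuracy_regression(trials)

    def test_perfect_separation_flagged_not_raised(self):
        trials = make_trials({"c1": [1, 2, 3, 4], "c2": [2, 3, 1, 1]})
        trials["correct"] = True
        fit = fit_accuracy_regression(trials)
        assert not fit.converged
        assert "separation" in fit.notes
        assert np.isnan(fit.beta)


class TestConditionMeanCorrelation:
    def test_noiseless_correlation_is_one(self, noiseless_norm):
        fit = condition_mean_correlation(noiseless_norm)
        assert fit.beta == pytest.approx(1.0, abs=1e-9)

    def test_default_correlation_strong(self, default_norm):
        fit = condition_mean_correlation(default_norm)
        assert fit.beta >= 0.9
        assert fit.n_obs == 16

    def test_constant_playtimes_rejected(self):
        trials = make_trials({"c1": [3, 3, 3, 3], "c2": [7, 7, 7, 7]})
        norm = normalize_playtimes(trials)
        with pytest.raises(DegenerateDesignError):
            condition_mean_correlation(norm)


class TestIndividualSlopes:
    def test_noiseless_everyone_follows_model(self, noiseless_norm):
        summary = individual_slopes(noiseless_norm)
        assert summary.k_positive == summary.n == 96
        assert summary.proportion == 1.0

    def test_counting_known_signs(self):
        # c1, c2 play longer on harder contrasts; c3 does the reverse
        trials = make_trials(
            {"c1": [4, 3, 1, 2], "c2": [5, 4, 2, 3], "c3": [1, 2, 5, 4]}
        )
        norm = normalize_playtimes(trials)
        summary = individual_slopes(norm)
        assert summary.k_positive == 2
        assert summary.n == 3
        assert summary.proportion == pytest.approx(2 / 3)

    def test_default_majority_follow_model(self, default_norm):
        summary = individual_slopes(default_norm)
        assert summary.proportion >= 0.7

    def test_constant_dprime_child_excluded(self):
        trials = pd.concat(
            [
                make_trials({"c1": [4, 3, 1, 2]}),
                make_trials(
                    {"c2": [1, 2, 3, 4]},
                    pairs=((8, 2), (8, 2), (8, 2), (8, 2)),
                ),
            ],
            ignore_index=True,
        )
        norm = normalize_playtimes(trials)
        with pytest.warns(UserWarning, match="constant d'"):
            summary = individual_slopes(norm)
        assert summary.n == 1

    def test_exact_ci_method_available(self, default_norm):
        summary = individual_slopes(default_norm, ci_method="exact_binomial")
        assert 0.0 <= summary.ci_low <= summary.proportion <= summary.ci_high <= 1.0
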