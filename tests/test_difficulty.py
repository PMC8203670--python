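"""Unit and property tests for the discriminability models."""

import math
from itertools import combinations

import pytest

from shakebox import (
    Contrast,
    DifficultyParams,
    InvalidParameterError,
    abs_diff,
    accuracy_2afc,
    dprime,
    neg_ratio,
    rank_contrasts,
    score,
)
from shakebox.difficulty import read_contrasts_csv, write_contrasts_csv
from shakebox.exceptions import ConfigurationError


def C(a, b):
    return Contrast(n_a=a, n_b=b, hidden=a)


class TestDprime:
    @pytest.mark.parametrize(
        "a, b, sigma, expected",
        [
            (5, 5, 1.0, 0.0),
            (8, 2, 1.0, math.log(4)),
            (2, 8, 1.0, math.log(4)),
            (9, 3, 2.0, math.log(3) / 2),
        ],
    )
    def test_log_ratio_values(self, a, b, sigma, expected):
        d = dprime(C(a, b), DifficultyParams(sigma=sigma))
        assert d.model_name == "dprime"
        assert d.value == pytest.approx(expected, abs=1e-12)

    def test_symmetry_exhaustive(self):
        """d'(a,b) == d'(b,a) for all pairs of counts 1..20."""
        for a in range(1, 21):
            for b in range(1, 21):
                assert dprime(C(a, b)).value == dprime(C(b, a)).value

    def test_weber_scale_invariance(self):
        """Scaling both counts by an integer k leaves d' unchanged exactly."""
        for a, b in combinations(range(1, 10), 2):
            base = dprime(C(a, b)).value
            for k in (2, 3, 7):
                assert dprime(C(k * a, k * b)).value == base

    def test_independent_of_hidden_side(self):
        lhs = dprime(Contrast(n_a=8, n_b=2, hidden=8))
        rhs = dprime(Contrast(n_a=8, n_b=2, hidden=2))
        assert lhs.value == rhs.value

    def test_invalid_inputs(self):
        with pytest.raises(InvalidParameterError):
            Contrast(n_a=0, n_b=2, hidden=2)
        with pytest.raises(InvalidParameterError):
            Contrast(n_a=3, n_b=2, hidden=5)
        with pytest.raises(InvalidParameterError):
            DifficultyParams(sigma=0.0)
        with pytest.raises(InvalidParameterError):
            DifficultyParams(sigma=-1.0)


class TestHeuristics:
    @pytest.mark.parametrize(
        "a, b, expected", [(8, 2, 6.0), (8, 6, 2.0), (4, 4, 0.0)]
    )
    def test_abs_diff(self, a, b, expected):
        assert abs_diff(C(a, b)).value == expected

    @pytest.mark.parametrize(
        "a, b, expected", [(8, 2, -0.25), (8, 6, -0.75), (4, 4, -1.0)]
    )
    def test_neg_ratio(self, a, b, expected):
        assert neg_ratio(C(a, b)).value == pytest.approx(expected, abs=1e-12)

    def test_identical_pair_is_hardest_under_every_model(self):
        same = C(4, 4)
        others = [C(a, b) for a, b in combinations(range(1, 10), 2)]
        for model in ("dprime", "abs_diff", "neg_ratio"):
            worst = score(same, model).value
            assert all(score(c, model).value > worst for c in others)


class TestAccuracy2AFC:
    def test_chance_at_zero(self):
        assert accuracy_2afc(0.0) == 0.5

    def test_derived_value(self):
        # independent oracle: Phi(d'/sqrt2) = (1 + erf(d'/2)) / 2
        d = 1.3863
        expected = 0.5 * (1.0 + math.erf(d / 2.0))
        assert accuracy_2afc(d) == pytest.approx(expected, abs=1e-12)
        assert accuracy_2afc(d) == pytest.approx(0.8365, abs=5e-4)

    def test_strictly_increasing_and_bounded(self):
        grid = [0.0, 0.1, 0.5, 1.0, 2.0, 4.0, 8.0]
        vals = [accuracy_2afc(d) for d in grid]
        assert all(lo < hi for lo, hi in zip(vals, vals[1:]))
        assert all(0.5 <= v < 1.0 for v in vals)
        assert accuracy_2afc(40.0) == pytest.approx(1.0, abs=1e-12)

    def test_accepts_score_and_rejects_negative(self):
        assert accuracy_2afc(dprime(C(8, 2))) > 0.8
        with pytest.raises(InvalidParameterError):
            accuracy_2afc(-0.1)


class TestRanking:
    def test_easiest_first(self):
        ranked = rank_contrasts([C(8, 6), C(8, 2)], "dprime")
        assert [c.key for c in ranked] == [(8, 2), (8, 6)]

    def test_models_disagree_on_difference_vs_ratio(self):
        pair = [C(9, 5), C(2, 1)]
        by_diff = rank_contrasts(pair, "abs_diff")
        by_dprime = rank_contrasts(pair, "dprime")
        assert [c.key for c in by_diff] == [(9, 5), (2, 1)]
        assert [c.key for c in by_dprime] == [(2, 1), (9, 5)]

    def test_dprime_and_neg_ratio_order_identically_over_all_pairs(self):
        contrasts = [C(a, b) for a, b in combinations(range(1, 10), 2)]
        by_d = [c.key for c in rank_contrasts(contrasts, "dprime")]
        by_r = [c.key for c in rank_contrasts(contrasts, "neg_ratio")]
        assert by_d == by_r

    def test_tie_break_is_deterministic(self):
        # 2:1 and 4:2 have identical d'; smaller max count wins
        ranked = rank_contrasts([C(4, 2), C(2, 1)], "dprime")
        assert [c.key for c in ranked] == [(2, 1), (4, 2)]

    def test_errors(self):
        with pytest.raises(ConfigurationError):
            rank_contrasts([C(2, 1)], "not_a_model")
        with pytest.raises(InvalidParameterError):
            rank_contrasts([], "dprime")


def test_contrast_csv_round_trip(tmp_path):
    contrasts = [Contrast(9, 8, 8, label="hardest"), Contrast(9, 1, 9)]
    path = tmp_path / "contrasts.csv"
    write_contrasts_csv(contrasts, path)
    back = read_contrasts_csv(path)
    assert [(c.n_a, c.n_b, c.hidden) for c in back] == [(9, 8, 8), (9, 1, 9)]
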