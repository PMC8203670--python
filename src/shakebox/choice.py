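"""Forced-choice statistics: proportions, binomial CIs, tests vs. chance.

The forced-choice experiments yield one binary choice per child (did the
child open the box whose unheard alternative was easier to discriminate?).
This module computes the sample proportion with either the Bernoulli
normal-approximation CI used in the original write-ups (fixed z = 1.96,
bounds clipped to [0, 1]) or the exact Clopper-Pearson interval, plus a
two-sided exact binomial test against chance.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import math

import pandas as pd
from scipy.stats import binomtest

from .exceptions import ConfigurationError, DataError, InvalidParameterError

__all__ = [
    "ProportionResult",
    "proportion_with_ci",
    "proportion_from_choices",
    "binomial_test_vs_chance",
    "round_half_up",
    "format_interval",
]

# Fixed normal quantile, not re-derived: guarantees bit-reproducible
# normal-approximation intervals.
_Z95 = 1.96

CI_METHODS = ("normal_approx", "exact_binomial")


@dataclass(frozen=True)
class ProportionResult:
    """A sample proportion with a 95% binomial CI."""

    k: int
    n: int
    p_hat: float
    ci_low: float
    ci_high: float
    method: str
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.ci_high <= 1.0):
            raise ValueError(f"invalid CI [{self.ci_low}, {self.ci_high}]")


def proportion_with_ci(k: int, n: int, method: str = "normal_approx") -> ProportionResult:
    """95% CI for a binomial proportion k/n.

    ``normal_approx``: p +/- 1.96*sqrt(p(1-p)/n), clipped to [0, 1]; at
    p in {0, 1} the interval is zero-width and flagged degenerate.
    ``exact_binomial``: Clopper-Pearson, which needs no clipping.
    """
    if n < 1:
        raise DataError("n must be >= 1")
    if not (0 <= k <= n):
        raise DataError(f"k must be in [0, {n}], got {k}")
    if method not in CI_METHODS:
        raise ConfigurationError(
            f"unknown CI method {method!r}; available: {CI_METHODS}"
        )
    p = k / n
    if method == "normal_approx":
        se = math.sqrt(p * (1.0 - p) / n)
        lo = max(0.0, p - _Z95 * se)
        hi = min(1.0, p + _Z95 * se)
        return ProportionResult(
            k=k, n=n, p_hat=p, ci_low=lo, ci_high=hi,
            method=method, degenerate=(se == 0.0),
        )
    ci = binomtest(k, n).proportion_ci(confidence_level=0.95, method="exact")
    return ProportionResult(
        k=k, n=n, p_hat=p, ci_low=float(ci.low), ci_high=float(ci.high), method=method
    )


def proportion_from_choices(
    choices: pd.DataFrame, method: str = "normal_approx"
) -> ProportionResult:
    """Proportion of children choosing the discriminable box."""
    if len(choices) == 0:
        raise DataError("choice table is empty")
    if "chose_discriminable" not in choices.columns:
        raise DataError("choice table lacks column 'chose_discriminable'")
    col = choices["chose_discriminable"].astype(bool)
    return proportion_with_ci(int(col.sum()), int(len(col)), method=method)


def binomial_test_vs_chance(k: int, n: int, chance: float = 0.5) -> float:
    """Two-sided exact binomial p-value for k successes in n vs. chance.

    Uses the "minlike" two-sided convention: the sum of probabilities of
    all outcomes no more likely than the observed one.
    """
    if n < 1 or not (0 <= k <= n):
        raise DataError(f"invalid counts k={k}, n={n}")
    if not (0.0 < chance < 1.0):
        raise InvalidParameterError(f"chance must be in (0, 1), got {chance!r}")
    return float(binomtest(int(k), int(n), chance).pvalue)


def round_half_up(x: float, decimals: int = 2) -> float:
    """Display rounding with the round-half-up rule (0.925 -> 0.93)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def format_interval(result: ProportionResult, decimals: int = 2) -> str:
    """Render a CI the way the write-ups print them, e.g. '[0.58-0.92]'."""
    lo = round_half_up(result.ci_low, decimals)
    hi = round_half_up(result.ci_high, decimals)
    fmt = f"{{:.{decimals}f}}"
    return f"[{fmt.format(lo)}-{fmt.format(hi)}]"
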