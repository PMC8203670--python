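"""Exploration-time analyses: normalization, regressions, individual slopes.

The pipeline mirrors the free-exploration analyses: each child's playtimes
are converted to proportions of their own total play (times the number of
trials, so the per-child mean is exactly 1), then regressed on negative
discriminability, on the count actually hidden, on trial order, and on age;
accuracy is regressed logistically on d'; condition means are correlated
with the model; and each child contributes an individual playtime-on-
difficulty slope whose sign summarizes qualitative agreement with the
model.

The default estimator is trial-level OLS with cluster-robust (by child)
standard errors: the normalization already removes per-child intercepts,
so clustering is the minimal correction for within-child dependence.  A
per-child random-intercept mixed model is available as an option.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .choice import proportion_with_ci
from .difficulty import Contrast, DifficultyParams, dprime
from .exceptions import (
    ConfigurationError,
    DataError,
    DegenerateDesignError,
)

__all__ = [
    "FitResult",
    "SlopeSummary",
    "trial_dprime",
    "normalize_playtimes",
    "fit_playtime_regression",
    "fit_accuracy_regression",
    "condition_mean_correlation",
    "individual_slopes",
    "PLAYTIME_PREDICTORS",
]

logger = logging.getLogger(__name__)

PLAYTIME_PREDICTORS = ("neg_dprime", "hidden_count", "trial_order", "age")


@dataclass(frozen=True)
class FitResult:
    """A fitted coefficient with its 95% CI and fitting metadata."""

    predictor: str
    beta: float
    ci_low: float
    ci_high: float
    estimator: str
    clustering: str
    n_obs: int
    n_children: int
    converged: bool = True
    notes: str = ""

    def __post_init__(self) -> None:
        if self.converged and not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError(
                f"CI [{self.ci_low}, {self.ci_high}] does not bracket beta={self.beta}"
            )


@dataclass(frozen=True)
class SlopeSummary:
    """Per-child playtime-on-difficulty slopes and the positive-slope count."""

    per_child_slopes: tuple[tuple[str, float], ...]
    k_positive: int
    n: int
    proportion: float
    ci_low: float
    ci_high: float
    ci_method: str


def trial_dprime(trials: pd.DataFrame, params: DifficultyParams | None = None) -> np.ndarray:
    """Row-wise d' of the advertised pair (independent of which is hidden)."""
    params = params or DifficultyParams()
    a = trials["n_a"].to_numpy(float)
    b = trials["n_b"].to_numpy(float)
    return np.log(np.maximum(a, b) / np.minimum(a, b)) / params.sigma


def normalize_playtimes(trials: pd.DataFrame) -> pd.DataFrame:
    """Add ``normalized_playtime``: trial share of the child's total play.

    normalized = n_trials_for_child * playtime / child_total, so each
    child's normalized values average exactly 1.  Children whose total
    playtime is zero cannot be normalized and are excluded with a warning.
    """
    if "playtime_s" not in trials.columns:
        raise DataError("trial table lacks required column 'playtime_s'")
    play = trials["playtime_s"].to_numpy(float)
    if np.isnan(play).any():
        raise DataError("playtime_s contains missing values")
    if (play < 0).any():
        raise DataError("playtime_s contains negative values")
    out = trials.copy()
    totals = out.groupby("child_id")["playtime_s"].transform("sum")
    counts = out.groupby("child_id")["playtime_s"].transform("size")
    zero = totals == 0
    if zero.any():
        excluded = sorted(out.loc[zero, "child_id"].unique())
        msg = f"excluding {len(excluded)} child(ren) with zero total playtime: {excluded}"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
        out = out.loc[~zero].copy()
        totals = totals[~zero]
        counts = counts[~zero]
    out["normalized_playtime"] = counts * out["playtime_s"] / totals
    return out


def _response_column(norm_trials: pd.DataFrame, playtime_scale: str) -> np.ndarray:
    if playtime_scale == "normalized":
        if "normalized_playtime" not in norm_trials.columns:
            raise DataError(
                "table lacks 'normalized_playtime'; run normalize_playtimes first"
            )
        return norm_trials["normalized_playtime"].to_numpy(float)
    if playtime_scale == "log":
        play = norm_trials["playtime_s"].to_numpy(float)
        if (play <= 0).any():
            raise DataError("log playtime scale requires strictly positive playtimes")
        return np.log(play)
    raise ConfigurationError(
        f"playtime_scale must be 'normalized' or 'log', got {playtime_scale!r}"
    )


def _predictor_column(
    norm_trials: pd.DataFrame, predictor: str, params: DifficultyParams
) -> np.ndarray:
    if predictor == "neg_dprime":
        return -trial_dprime(norm_trials, params)
    if predictor == "hidden_count":
        return norm_trials["hidden"].to_numpy(float)
    if predictor == "trial_order":
        return norm_trials["trial_order"].to_numpy(float)
    if predictor == "age":
        if "age_years" not in norm_trials.columns:
            raise DataError("predictor 'age' requires column 'age_years'")
        return norm_trials["age_years"].to_numpy(float)
    raise ConfigurationError(
        f"unknown predictor {predictor!r}; available: {PLAYTIME_PREDICTORS}"
    )


def fit_playtime_regression(
    norm_trials: pd.DataFrame,
    predictor: str = "neg_dprime",
    params: DifficultyParams | None = None,
    estimator: str = "ols-cluster",
    playtime_scale: str = "normalized",
) -> FitResult:
    """Regress (normalized) playtime on one predictor.

    ``neg_dprime`` is -d' in natural-log units, unstandardized, so the
    slope is directly comparable to the headline exploration effect.
    """
    params = params or DifficultyParams()
    y = _response_column(norm_trials, playtime_scale)
    if np.isnan(y).any():
        raise DataError("playtime response contains missing values")
    x = _predictor_column(norm_trials, predictor, params)
    if np.unique(x).size < 2:
        raise DegenerateDesignError(f"predictor {predictor!r} is constant")
    groups = norm_trials["child_id"].to_numpy()
    n_children = np.unique(groups).size
    X = sm.add_constant(x)
    notes = ""
    if estimator == "ols-cluster":
        model = sm.OLS(y, X)
        if n_children < 2:
            # a single cluster cannot support clustered SEs: fall back to
            # conventional OLS and flag it
            res = model.fit()
            clustering = "none"
            notes = "single child: clustered SEs unavailable, conventional SEs used"
            warnings.warn(notes, stacklevel=2)
        else:
            res = model.fit(cov_type="cluster", cov_kwds={"groups": groups})
            clustering = "child"
        beta = float(res.params[1])
        lo, hi = (float(v) for v in res.conf_int()[1])
        converged = True
    elif estimator == "mixed":
        model = sm.MixedLM(y, X, groups=groups)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=True)
        beta = float(np.asarray(res.params)[1])
        se = float(np.asarray(res.bse)[1])
        lo, hi = beta - 1.96 * se, beta + 1.96 * se
        clustering = "child-random-intercept"
        converged = bool(res.converged)
    else:
        raise ConfigurationError(
            f"unknown estimator {estimator!r}; use 'ols-cluster' or 'mixed'"
        )
    return FitResult(
        predictor=predictor,
        beta=beta,
        ci_low=lo,
        ci_high=hi,
        estimator=estimator,
        clustering=clustering,
        n_obs=len(y),
        n_children=int(n_children),
        converged=converged,
        notes=notes,
    )


def fit_accuracy_regression(
    trials: pd.DataFrame, params: DifficultyParams | None = None
) -> FitResult:
    """Logistic regression of trial correctness on d' (child-clustered SEs).

    The slope is in log-odds of a correct report per unit d'.  Perfect
    separation (e.g. every response correct) is reported as a flagged
    non-converged fit rather than raised.
    """
    params = params or DifficultyParams()
    if "correct" not in trials.columns:
        raise DataError("trial table lacks required column 'correct'")
    y = trials["correct"].astype(bool).to_numpy().astype(float)
    d = trial_dprime(trials, params)
    if np.unique(d).size < 2:
        raise DegenerateDesignError("d' is constant across trials")
    groups = trials["child_id"].to_numpy()
    n_children = int(np.unique(groups).size)
    if y.min() == y.max():
        return FitResult(
            predictor="dprime",
            beta=float("nan"),
            ci_low=float("nan"),
            ci_high=float("nan"),
            estimator="logit-cluster",
            clustering="child",
            n_obs=len(y),
            n_children=n_children,
            converged=False,
            notes="perfect separation: a single outcome observed",
        )
    X = sm.add_constant(d)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(
                disp=0, cov_type="cluster", cov_kwds={"groups": groups}
            )
        converged = bool(res.mle_retvals.get("converged", True))
    except Exception as exc:  # separation or failure to converge
        return FitResult(
            predictor="dprime",
            beta=float("nan"),
            ci_low=float("nan"),
            ci_high=float("nan"),
            estimator="logit-cluster",
            clustering="child",
            n_obs=len(y),
            n_children=n_children,
            converged=False,
            notes=f"fit failed: {exc}",
        )
    beta = float(res.params[1])
    lo, hi = (float(v) for v in res.conf_int()[1])
    return FitResult(
        predictor="dprime",
        beta=beta,
        ci_low=lo,
        ci_high=hi,
        estimator="logit-cluster",
        clustering="child",
        n_obs=len(y),
        n_children=n_children,
        converged=converged,
        notes="" if converged else "did not converge",
    )


def condition_mean_correlation(
    norm_trials: pd.DataFrame, params: DifficultyParams | None = None
) -> FitResult:
    """Pearson r between per-contrast mean normalized playtime and -d'.

    Contrasts are pooled over experiments and identified by the unordered
    pair of counts.
    """
    params = params or DifficultyParams()
    if "normalized_playtime" not in norm_trials.columns:
        raise DataError("run normalize_playtimes first")
    df = norm_trials.copy()
    df["_hi"] = df[["n_a", "n_b"]].max(axis=1)
    df["_lo"] = df[["n_a", "n_b"]].min(axis=1)
    grouped = df.groupby(["experiment", "_hi", "_lo"])["normalized_playtime"].mean()
    if len(grouped) < 3:
        raise DataError("need at least 3 distinct contrasts")
    hi = grouped.index.get_level_values("_hi").to_numpy(float)
    lo = grouped.index.get_level_values("_lo").to_numpy(float)
    neg_d = -np.log(hi / lo) / params.sigma
    means = grouped.to_numpy(float)
    if np.allclose(means, means[0]) or np.allclose(neg_d, neg_d[0]):
        raise DegenerateDesignError("zero variance in condition means or predictor")
    res = stats.pearsonr(neg_d, means)
    try:
        ci = res.confidence_interval(0.95)
        lo_ci, hi_ci = float(ci.low), float(ci.high)
    except Exception:
        lo_ci = hi_ci = float("nan")
    return FitResult(
        predictor="neg_dprime_condition_means",
        beta=float(res.statistic),
        ci_low=lo_ci,
        ci_high=hi_ci,
        estimator="pearson",
        clustering="none",
        n_obs=len(means),
        n_children=int(norm_trials["child_id"].nunique()),
    )


def individual_slopes(
    norm_trials: pd.DataFrame,
    params: DifficultyParams | None = None,
    ci_method: str = "normal_approx",
) -> SlopeSummary:
    """Per-child OLS slope of normalized playtime on -d'.

    A positive slope means the child played longer on harder contrasts,
    i.e. qualitatively followed the discriminability model.  Children with
    constant d' across their trials cannot contribute a slope and are
    excluded with a warning.  The positive-slope proportion gets a
    binomial CI (normal approximation or exact Clopper-Pearson).
    """
    params = params or DifficultyParams()
    if "normalized_playtime" not in norm_trials.columns:
        raise DataError("run normalize_playtimes first")
    slopes: list[tuple[str, float]] = []
    excluded: list[str] = []
    for child, sub in norm_trials.groupby("child_id", sort=True):
        x = -trial_dprime(sub, params)
        y = sub["normalized_playtime"].to_numpy(float)
        if np.unique(x).size < 2:
            excluded.append(str(child))
            continue
        slope = float(np.polyfit(x, y, 1)[0])
        slopes.append((str(child), slope))
    if excluded:
        msg = f"excluding {len(excluded)} child(ren) with constant d': {excluded}"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    if not slopes:
        raise DataError("no child has at least 2 trials with distinct d'")
    k = sum(1 for _, s in slopes if s > 0)
    n = len(slopes)
    prop = proportion_with_ci(k, n, method=ci_method)
    return SlopeSummary(
        per_child_slopes=tuple(slopes),
        k_positive=k,
        n=n,
        proportion=prop.p_hat,
        ci_low=prop.ci_low,
        ci_high=prop.ci_high,
        ci_method=ci_method,
    )
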