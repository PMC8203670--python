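"""Compare the d' model against heuristic difficulty models.

Each registered model scores every contrast (larger = easier); the score is
negated so that the regression predictor increases with difficulty and all
fitted slopes are positive-signed and comparable.  For each model the table
reports the condition-mean Pearson correlation, the trial-level R^2 and
Gaussian AIC from OLS on the normalized playtime scale, and the Spearman
rank agreement of the model's contrast ordering with d-prime's.  d' and the
negative-ratio heuristic are monotone transforms of the same max/min ratio,
so their rank agreement is always 1; the absolute-difference heuristic can
genuinely reorder contrasts (e.g. it calls {9,5} harder than {2,1}).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .difficulty import Contrast, DifficultyParams, score
from .exceptions import ConfigurationError, DataError
from .difficulty import MODEL_NAMES

__all__ = ["compare_models", "COMPARISON_COLUMNS"]

COMPARISON_COLUMNS = [
    "model_name",
    "r_condition_means",
    "r2_trial_level",
    "aic_trial_level",
    "rank_agreement_with_dprime",
]


def _unique_contrasts(norm_trials: pd.DataFrame) -> pd.DataFrame:
    df = norm_trials.copy()
    df["_hi"] = df[["n_a", "n_b"]].max(axis=1)
    df["_lo"] = df[["n_a", "n_b"]].min(axis=1)
    return df


def compare_models(
    norm_trials: pd.DataFrame,
    models: tuple[str, ...] = MODEL_NAMES,
    params: DifficultyParams | None = None,
) -> pd.DataFrame:
    """One comparison row per difficulty model, on identical observations."""
    if len(models) < 2:
        raise ConfigurationError("need at least 2 models to compare")
    params = params or DifficultyParams()
    if "normalized_playtime" not in norm_trials.columns:
        raise DataError("run normalize_playtimes first")
    df = _unique_contrasts(norm_trials)
    if df[["_hi", "_lo"]].drop_duplicates().shape[0] < 3:
        raise DataError("need at least 3 distinct contrasts")
    # drop incomplete rows once so every model sees the same observations
    df = df.dropna(subset=["normalized_playtime", "n_a", "n_b"])
    y = df["normalized_playtime"].to_numpy(float)

    pair_scores: dict[str, dict[tuple[int, int], float]] = {}
    pairs = sorted({(int(h), int(l)) for h, l in zip(df["_hi"], df["_lo"])})
    for m in models:
        pair_scores[m] = {
            (h, l): score(Contrast(n_a=h, n_b=l, hidden=h), m, params).value
            for h, l in pairs
        }

    d_ref = [pair_scores.get("dprime", {}).get(p) for p in pairs]
    if "dprime" not in models:
        d_ref = [
            score(Contrast(n_a=h, n_b=l, hidden=h), "dprime", params).value
            for h, l in pairs
        ]

    rows = []
    for m in models:
        smap = pair_scores[m]
        # predictor oriented larger = harder
        x = -np.array([smap[(int(h), int(l))] for h, l in zip(df["_hi"], df["_lo"])])
        res = sm.OLS(y, sm.add_constant(x)).fit()
        cond = (
            df.assign(_x=x)
            .groupby(["experiment", "_hi", "_lo"])
            .agg(mean_play=("normalized_playtime", "mean"), x=("_x", "first"))
        )
        r = float(stats.pearsonr(cond["x"], cond["mean_play"]).statistic)
        rho = float(stats.spearmanr([smap[p] for p in pairs], d_ref).statistic)
        rows.append(
            {
                "model_name": m,
                "r_condition_means": r,
                "r2_trial_level": float(res.rsquared),
                "aic_trial_level": float(res.aic),
                "rank_agreement_with_dprime": rho,
            }
        )
    return pd.DataFrame(rows, columns=COMPARISON_COLUMNS)
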