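"""Synthetic trial generator for the box-shaking experiments.

Emulates the statistical structure of the free-exploration experiments
(four experiments x four numerosity contrasts x one shaking trial each,
24 children per experiment) and of the forced-choice experiments (one
binary box choice per child):

* per-child random baseline playtimes (lognormal multiplier on seconds);
* expected *normalized* playtime rising linearly in negative
  discriminability (slope ``playtime_slope_theta``, default 0.24, the
  headline exploration effect);
* a weak decline over the four trials (``trial_order_slope``, -0.051);
* no effect of the count actually hidden in the box (``content_slope`` 0);
* response accuracy increasing with d' through a logistic link
  (``accuracy_slope`` 1.12 log-odds per unit d');
* Bernoulli box choices in the forced-choice designs.

Trial order follows a Williams Latin square and the hidden alternative is
counterbalanced across children, except in the experiment that reproduces
the fixed-content design (contents held fixed at 8 and 3).  Everything is
deterministic given (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .difficulty import Contrast, DifficultyParams, dprime
from .exceptions import ConfigurationError, InvalidParameterError

__all__ = [
    "GeneratorConfig",
    "default_contrast_sets",
    "generate_exploration_trials",
    "generate_choice_trials",
    "TRIAL_COLUMNS",
    "CHOICE_COLUMNS",
]

TRIAL_COLUMNS = [
    "child_id",
    "experiment",
    "trial_order",
    "n_a",
    "n_b",
    "hidden",
    "playtime_s",
    "response_count",
    "correct",
    "age_years",
]
CHOICE_COLUMNS = ["child_id", "experiment", "chose_discriminable"]

# Williams design for 4 conditions: each condition appears once per row,
# once per column, and is balanced for first-order carryover.
_WILLIAMS_4 = ((0, 1, 3, 2), (1, 2, 0, 3), (2, 3, 1, 0), (3, 0, 2, 1))


def default_contrast_sets() -> dict[str, list[Contrast]]:
    """Default 16 contrasts, four per experiment, counts 1-9.

    The exact pairs used in the original designs are not fully public, so
    these defaults are a documented placeholder chosen to span the d'
    range of counts 1-9 (hardest 9-vs-8, easiest 9-vs-1) while keeping the
    four experiments statistically exchangeable: each experiment's four
    max/min ratios multiply to exactly 36, so every experiment has the
    same mean d' (ln 36 / 4), and the pairs were additionally chosen so
    that the hidden count is essentially uncorrelated with trial
    difficulty across the full design.  "exp6" mirrors the fixed-content
    design: every pair contains an 8 or a 3 and the stated count stays in
    the box for all children.
    """
    sets = {
        "exp4": [(2, 1), (4, 1), (3, 2), (6, 2)],
        "exp5": [(5, 1), (4, 2), (9, 3), (6, 5)],
        "exp6": [(3, 1), (8, 1), (4, 3), (9, 8)],
        "exp7": [(9, 1), (5, 3), (9, 5), (8, 6)],
    }
    hidden = {
        "exp6": (3, 8, 3, 8),  # contents held fixed at 8 and 3
    }
    out: dict[str, list[Contrast]] = {}
    for exp, pairs in sets.items():
        hid = hidden.get(exp, tuple(p[0] for p in pairs))
        out[exp] = [
            Contrast(n_a=a, n_b=b, hidden=h) for (a, b), h in zip(pairs, hid)
        ]
    return out


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of the synthetic cohort.

    Slope defaults are the study-calibrated effect sizes on the normalized
    playtime scale (playtime per unit predictor); ``child_sd`` is the SD
    of the per-child log baseline multiplier on raw seconds, ``noise_sd``
    the trial-level SD on the normalized scale, ``base_playtime_s`` the
    median raw playtime in seconds.  ``noise_scale`` selects additive
    Gaussian noise on the normalized scale (default) or multiplicative
    lognormal noise ("log").
    """

    n_children_per_experiment: int = 24
    contrast_sets: Mapping[str, Sequence[Contrast]] = field(
        default_factory=default_contrast_sets
    )
    fixed_content_experiments: tuple[str, ...] = ("exp6",)
    playtime_slope_theta: float = 0.24
    trial_order_slope: float = -0.051
    content_slope: float = 0.0
    accuracy_intercept: float = 0.0
    accuracy_slope: float = 1.12
    child_sd: float = 0.5
    noise_sd: float = 0.15
    base_playtime_s: float = 10.0
    noise_scale: str = "normalized"
    sigma: float = 1.0
    age_range: tuple[float, float] = (4.0, 9.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_children_per_experiment < 1:
            raise ConfigurationError("n_children_per_experiment must be >= 1")
        if not self.contrast_sets:
            raise ConfigurationError("contrast_sets must not be empty")
        for exp, contrasts in self.contrast_sets.items():
            if len(contrasts) != 4:
                raise ConfigurationError(
                    f"experiment {exp!r} must have exactly 4 contrasts, "
                    f"got {len(contrasts)}"
                )
        for name in ("child_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        if self.base_playtime_s <= 0:
            raise ConfigurationError("base_playtime_s must be positive")
        if self.noise_scale not in ("normalized", "log"):
            raise ConfigurationError(
                f"noise_scale must be 'normalized' or 'log', got {self.noise_scale!r}"
            )
        if self.sigma <= 0:
            raise ConfigurationError("sigma must be positive")

    @property
    def params(self) -> DifficultyParams:
        return DifficultyParams(sigma=self.sigma)

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=int(seed))


# Expected normalized playtime floor: keeps raw playtimes strictly positive
# even in the extreme noise tail.
_FLOOR = 0.05


def generate_exploration_trials(config: GeneratorConfig) -> pd.DataFrame:
    """Generate one shaking trial per child x contrast for every experiment.

    For child i on the trial with contrast c in position j (1-4), the
    expected normalized playtime is

        1 + theta * (-d'(c) - mean_k(-d'(c_k)))
          + trial_order_slope * (j - 2.5)
          + content_slope * (hidden - mean_k hidden_k)

    (all terms centered within the child's four trials, so each child's
    expected normalized playtimes sum to 4).  Raw seconds are
    ``base_playtime_s * exp(child effect) * max(0.05, expected + noise)``.
    Correctness is Bernoulli with logit(p) = accuracy_intercept +
    accuracy_slope * d'(c).
    """
    rng = np.random.default_rng(config.seed)
    params = config.params
    n = config.n_children_per_experiment
    frames = []
    child_offset = 0
    for exp, contrasts in config.contrast_sets.items():
        contrasts = list(contrasts)
        d = np.array([dprime(c, params).value for c in contrasts])
        neg_d_centered = (-d) - (-d).mean()
        fixed = exp in config.fixed_content_experiments

        child_eff = rng.normal(0.0, config.child_sd, size=n) if config.child_sd else np.zeros(n)
        ages = rng.uniform(config.age_range[0], config.age_range[1], size=n)
        noise = (
            rng.normal(0.0, config.noise_sd, size=(n, 4))
            if config.noise_sd
            else np.zeros((n, 4))
        )
        u_correct = rng.random(size=(n, 4))

        rows = []
        for i in range(n):
            order_row = _WILLIAMS_4[i % 4]
            # position (1-4) of contrast j for this child
            pos = np.empty(4, dtype=int)
            for t, j in enumerate(order_row):
                pos[j] = t + 1
            hidden = np.empty(4, dtype=int)
            for j, c in enumerate(contrasts):
                if fixed:
                    hidden[j] = c.hidden
                elif (i // 4 + j) % 2 == 0:
                    hidden[j] = max(c.n_a, c.n_b)
                else:
                    hidden[j] = min(c.n_a, c.n_b)
            expected = (
                1.0
                + config.playtime_slope_theta * neg_d_centered
                + config.trial_order_slope * (pos - 2.5)
                + config.content_slope * (hidden - hidden.mean())
            )
            if config.noise_scale == "normalized":
                shape = np.maximum(_FLOOR, expected + noise[i])
            else:
                shape = np.maximum(_FLOOR, expected * np.exp(noise[i]))
            playtime = config.base_playtime_s * math.exp(child_eff[i]) * shape
            p_correct = 1.0 / (
                1.0 + np.exp(-(config.accuracy_intercept + config.accuracy_slope * d))
            )
            correct = u_correct[i] < p_correct
            child_id = f"{exp}_c{child_offset + i:04d}"
            for j, c in enumerate(contrasts):
                other = c.n_a if hidden[j] == c.n_b else c.n_b
                rows.append(
                    (
                        child_id,
                        exp,
                        int(pos[j]),
                        c.n_a,
                        c.n_b,
                        int(hidden[j]),
                        float(playtime[j]),
                        int(hidden[j] if correct[j] else other),
                        bool(correct[j]),
                        float(ages[i]),
                    )
                )
        frame = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
        frame = frame.sort_values(["child_id", "trial_order"], kind="stable")
        frames.append(frame)
        child_offset += n
    out = pd.concat(frames, ignore_index=True)
    return out


def generate_choice_trials(
    n_children: int,
    p_correct: float,
    seed: int,
    experiment: str = "exp1",
) -> pd.DataFrame:
    """I.i.d. Bernoulli box choices: one row per child.

    ``chose_discriminable`` is True when the child picks the box whose
    unheard alternative would be easier to discriminate.
    """
    if n_children < 1:
        raise InvalidParameterError("n_children must be >= 1")
    if not (0.0 <= p_correct <= 1.0):
        raise InvalidParameterError(f"p_correct must be in [0, 1], got {p_correct!r}")
    rng = np.random.default_rng(seed)
    choices = rng.random(n_children) < p_correct
    return pd.DataFrame(
        {
            "child_id": [f"{experiment}_c{i:04d}" for i in range(n_children)],
            "experiment": experiment,
            "chose_discriminable": choices,
        }
    )
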