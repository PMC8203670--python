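"""Discriminability models for numerosity contrasts.

A *contrast* is a pair of candidate numerosities (marble counts), one of
which is actually hidden in the box.  The core model treats the internal
representation of an auditorily perceived numerosity ``n`` as a Gaussian on
a log scale with mean ``log n`` and a common standard deviation ``sigma``
(the approximate-number-system convention), so the discriminability of a
pair ``(l, m)`` is the classic signal-detection index

    d' = |log l - log m| / sigma

Two heuristic alternatives are provided for model comparison: the absolute
difference of the counts and the (negative) ratio of the smaller to the
larger count.  All three scores are oriented so that *larger means easier*;
an identical pair is the hardest possible case under every model.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from scipy.stats import norm

from .exceptions import ConfigurationError, InvalidParameterError

__all__ = [
    "Contrast",
    "DifficultyParams",
    "DifficultyScore",
    "MODEL_NAMES",
    "dprime",
    "abs_diff",
    "neg_ratio",
    "score",
    "accuracy_2afc",
    "rank_contrasts",
    "read_contrasts_csv",
    "write_contrasts_csv",
]


@dataclass(frozen=True)
class Contrast:
    """A pair of candidate numerosities plus which one is actually hidden.

    ``n_a`` and ``n_b`` are the two advertised counts (any positive
    integers; 1-9 in the experimental designs), ``hidden`` is the count
    actually placed in the box and must be one of the two.  An identical
    pair (``n_a == n_b``) is representable but has zero discriminability.
    """

    n_a: int
    n_b: int
    hidden: int
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("n_a", "n_b", "hidden"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 1:
                raise InvalidParameterError(
                    f"{name} must be a positive integer, got {v!r}"
                )
        if self.hidden not in (self.n_a, self.n_b):
            raise InvalidParameterError(
                f"hidden count {self.hidden} is neither n_a={self.n_a} "
                f"nor n_b={self.n_b}"
            )

    @property
    def alternative(self) -> int:
        """The advertised count that is *not* in the box."""
        return self.n_b if self.hidden == self.n_a else self.n_a

    @property
    def key(self) -> tuple[int, int]:
        """Order-free identity of the pair: (max, min)."""
        return (max(self.n_a, self.n_b), min(self.n_a, self.n_b))

    @property
    def name(self) -> str:
        return self.label or f"{self.key[0]}v{self.key[1]}"


@dataclass(frozen=True)
class DifficultyParams:
    """Parameters of the log-Gaussian representation.

    ``sigma`` is the common SD of the internal log-scale representation
    (dimensionless).  The default 1.0 reports d' in natural-log units;
    any log-base change is absorbed into sigma, so the natural log is
    fixed as the convention.
    """

    sigma: float = 1.0

    def __post_init__(self) -> None:
        if not (self.sigma > 0) or not math.isfinite(self.sigma):
            raise InvalidParameterError(f"sigma must be positive, got {self.sigma!r}")


@dataclass(frozen=True)
class DifficultyScore:
    """A difficulty score under a named model; larger = easier."""

    model_name: str
    value: float


def dprime(contrast: Contrast, params: DifficultyParams | None = None) -> DifficultyScore:
    """Signal-detection discriminability |log n_a - log n_b| / sigma.

    Symmetric in the pair, independent of which count is hidden, and
    scale-invariant (Weber's law): doubling both counts leaves it unchanged.
    """
    params = params or DifficultyParams()
    hi, lo = contrast.key
    # log of the exact ratio: contrasts with equal max/min ratios (e.g. 2:1
    # and 4:2) get bitwise-identical d', so rank ties are exact
    value = math.log(hi / lo) / params.sigma
    return DifficultyScore("dprime", value)


def abs_diff(contrast: Contrast, params: DifficultyParams | None = None) -> DifficultyScore:
    """Heuristic difficulty: absolute difference of the two counts (marbles)."""
    return DifficultyScore("abs_diff", float(abs(contrast.n_a - contrast.n_b)))


def neg_ratio(contrast: Contrast, params: DifficultyParams | None = None) -> DifficultyScore:
    """Heuristic difficulty: -min/max of the two counts.

    The identical pair scores -1 (hardest); the score increases toward 0
    as the ratio departs from 1, so easier contrasts score higher, the
    shared orientation of all difficulty models here.
    """
    lo = min(contrast.n_a, contrast.n_b)
    hi = max(contrast.n_a, contrast.n_b)
    return DifficultyScore("neg_ratio", -lo / hi)


_MODELS = {"dprime": dprime, "abs_diff": abs_diff, "neg_ratio": neg_ratio}
MODEL_NAMES: tuple[str, ...] = tuple(_MODELS)


def score(
    contrast: Contrast, model: str = "dprime", params: DifficultyParams | None = None
) -> DifficultyScore:
    """Score a contrast under a registered difficulty model."""
    try:
        fn = _MODELS[model]
    except KeyError:
        raise ConfigurationError(
            f"unknown difficulty model {model!r}; available: {sorted(_MODELS)}"
        ) from None
    return fn(contrast, params)


def accuracy_2afc(d: DifficultyScore | float) -> float:
    """Ideal-observer accuracy for 2AFC at discriminability d'.

    Returns Phi(d'/sqrt(2)), the equal-variance ideal observer: 0.5 at
    d'=0 (chance) rising strictly toward 1.
    """
    value = d.value if isinstance(d, DifficultyScore) else float(d)
    if not math.isfinite(value) and value > 0:
        return 1.0
    if value < 0 or not math.isfinite(value):
        raise InvalidParameterError(f"d' must be nonnegative, got {value!r}")
    return float(norm.cdf(value / math.sqrt(2.0)))


def rank_contrasts(
    contrasts: Sequence[Contrast],
    model: str = "dprime",
    params: DifficultyParams | None = None,
) -> list[Contrast]:
    """Sort contrasts easiest-first under the chosen model.

    Ties are broken deterministically by smaller max count, then smaller
    min count, so output order is reproducible.
    """
    if not contrasts:
        raise InvalidParameterError("contrast list must be nonempty")
    return sorted(
        contrasts,
        key=lambda c: (-score(c, model, params).value, c.key[0], c.key[1]),
    )


def read_contrasts_csv(path: str | Path) -> list[Contrast]:
    """Read a contrast list from CSV with columns label, n_a, n_b, hidden."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                Contrast(
                    n_a=int(row["n_a"]),
                    n_b=int(row["n_b"]),
                    hidden=int(row["hidden"]),
                    label=row.get("label", "") or "",
                )
            )
    return out


def write_contrasts_csv(contrasts: Iterable[Contrast], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "n_a", "n_b", "hidden"])
        for c in contrasts:
            w.writerow([c.name, c.n_a, c.n_b, c.hidden])
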