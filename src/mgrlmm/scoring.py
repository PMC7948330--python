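"""Diet-quality and lifestyle covariate scoring.

The overall diet quality index (DQI) summarises a short qualitative food
frequency questionnaire over seven food groups.  Each answered group is scored
0, 1 or 2 — higher meaning *lower* nutritional value — and the DQI is the mean
of the answered group scores, so it lives on [0, 2] with 0 the healthiest
diet.  Unhealthy groups (fast food, sweets, solid/animal fats, egg-dairy-meat)
score upward with weekly frequency; healthy groups (vegetables & fruit,
legumes-chicken-soy-fish, liquid vegetable oils) score downward.

Also provided: the coping-strategy percentage score (share of "often" among
"often"+"sometimes" answers) and per-wave tertile grouping used for physical
activity and coping covariates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "FOOD_GROUPS",
    "HEALTHY_GROUPS",
    "UNHEALTHY_GROUPS",
    "DqiThresholdConfig",
    "DqiResult",
    "TertileResult",
    "UnscorableRecordError",
    "score_dqi",
    "score_coping",
    "assign_tertiles",
]

#: The seven DQI food groups, in a fixed canonical order.
FOOD_GROUPS: tuple[str, ...] = (
    "fast_food",
    "veg_fruit",
    "legumes_chicken_soy_fish",
    "sweets",
    "unhealthy_fats",
    "egg_dairy_meat",
    "healthy_oils",
)

HEALTHY_GROUPS: frozenset[str] = frozenset(
    {"veg_fruit", "legumes_chicken_soy_fish", "healthy_oils"}
)
UNHEALTHY_GROUPS: frozenset[str] = frozenset(FOOD_GROUPS) - HEALTHY_GROUPS


class UnscorableRecordError(ValueError):
    """Raised when no food group in a record is answered."""


@dataclass(frozen=True)
class DqiThresholdConfig:
    """Per-group frequency bands mapping weekly frequency to a 0/1/2 score.

    ``cutpoints[group] = (lo, hi)`` splits the frequency axis into
    ``[0, lo)``, ``[lo, hi)`` and ``[hi, inf)``.  For unhealthy groups the
    bands score 0/1/2; for healthy groups the scoring is mirrored (2/1/0).
    The default bands apply the printed sweets rule (0: none or once weekly,
    1: two or three times, 2: four or more) to every group.
    """

    cutpoints: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {g: (2.0, 4.0) for g in FOOD_GROUPS}
    )

    def __post_init__(self) -> None:
        for group in FOOD_GROUPS:
            if group not in self.cutpoints:
                raise ValueError(f"missing cutpoints for food group {group!r}")
            lo, hi = self.cutpoints[group]
            if not lo < hi:
                raise ValueError(
                    f"cutpoints for {group!r} must be increasing, got ({lo}, {hi})"
                )

    def band(self, group: str, freq: float) -> int:
        """0-based band index of ``freq`` under this group's cutpoints."""
        lo, hi = self.cutpoints[group]
        if freq < lo:
            return 0
        if freq < hi:
            return 1
        return 2

    @classmethod
    def from_yaml(cls, path) -> "DqiThresholdConfig":
        """Load per-group cutpoints from a YAML mapping ``group: [lo, hi]``.

        Groups absent from the file keep the default (sweets-rule) bands.
        """
        import yaml

        raw = yaml.safe_load(open(path)) or {}
        cutpoints = {g: (2.0, 4.0) for g in FOOD_GROUPS}
        for group, pair in raw.items():
            if group not in FOOD_GROUPS:
                raise ValueError(f"unknown food group {group!r} in {path}")
            lo, hi = pair
            cutpoints[group] = (float(lo), float(hi))
        return cls(cutpoints=cutpoints)


@dataclass(frozen=True)
class DqiResult:
    """Component scores per answered group and the overall index."""

    component_scores: dict[str, int]
    n_answered: int
    dqi: float


def score_dqi(
    record: Mapping[str, float | None],
    config: DqiThresholdConfig | None = None,
) -> DqiResult:
    """Score one food-frequency record into the overall diet quality index.

    Parameters
    ----------
    record
        Weekly consumption frequency (times/week, ≥ 0) per food group;
        ``None`` or NaN marks an unanswered group.  Keys outside
        :data:`FOOD_GROUPS` are rejected.
    config
        Frequency bands; defaults to the sweets rule applied to all groups.

    Returns
    -------
    DqiResult
        Group scores in {0,1,2}, the number of answered groups and the DQI
        (mean of answered scores, in [0, 2]).  Unanswered groups are excluded
        from both numerator and denominator.
    """
    if config is None:
        config = DqiThresholdConfig()
    unknown = set(record) - set(FOOD_GROUPS)
    if unknown:
        raise ValueError(f"unknown food groups: {sorted(unknown)}")

    components: dict[str, int] = {}
    for group in FOOD_GROUPS:
        freq = record.get(group)
        if freq is None or (isinstance(freq, float) and math.isnan(freq)):
            continue
        if freq < 0:
            raise ValueError(f"negative frequency {freq} for group {group!r}")
        band = config.band(group, float(freq))
        components[group] = band if group in UNHEALTHY_GROUPS else 2 - band
    if not components:
        raise UnscorableRecordError("no food group answered; record not scorable")
    dqi = sum(components.values()) / len(components)
    return DqiResult(component_scores=components, n_answered=len(components), dqi=dqi)


def score_coping(n_often: int, n_sometimes: int, n_never: int) -> float:
    """Coping-strategy percentage score.

    Returns ``100 * n_often / (n_often + n_sometimes)`` — the share of
    strategies used "often" among those used at least sometimes.  Applied
    separately to the adaptive (20-item) and maladaptive (10-item) scales.
    When no item was answered "often" or "sometimes" the score is undefined
    and NaN is returned (a documented sentinel, not an error).
    """
    for name, n in (("n_often", n_often), ("n_sometimes", n_sometimes), ("n_never", n_never)):
        if n < 0:
            raise ValueError(f"{name} must be non-negative, got {n}")
    if n_often + n_sometimes + n_never == 0:
        raise ValueError("at least one item must be answered")
    denom = n_often + n_sometimes
    if denom == 0:
        return float("nan")
    return 100.0 * n_often / denom


@dataclass(frozen=True)
class TertileResult:
    """Tertile labels (1/2/3) with the wave's empirical cutpoints."""

    labels: np.ndarray
    cutpoints: tuple[float, float]
    degenerate: bool


def assign_tertiles(values: Sequence[float] | np.ndarray) -> TertileResult:
    """Assign within-wave tertile groups by empirical 1/3 and 2/3 quantiles.

    Labels follow half-open intervals ``[min, q1)``, ``[q1, q2)``,
    ``[q2, max]``: a value tied with a cutpoint goes to the upper group,
    keeping the rule deterministic and order-independent.  Missing (NaN)
    values receive label 0 and are excluded from the quantiles.  A constant
    vector yields all-1 labels with ``degenerate=True``.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("values must be one-dimensional")
    mask = ~np.isnan(arr)
    if mask.sum() < 3:
        raise ValueError("need at least 3 non-missing values to form tertiles")
    q1, q2 = np.quantile(arr[mask], [1.0 / 3.0, 2.0 / 3.0])
    degenerate = not (q1 < q2)
    labels = np.zeros(arr.shape, dtype=int)
    labels[mask] = 1
    if not degenerate:
        labels[mask & (arr >= q1)] = 2
        labels[mask & (arr >= q2)] = 3
    return TertileResult(labels=labels, cutpoints=(float(q1), float(q2)), degenerate=degenerate)
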