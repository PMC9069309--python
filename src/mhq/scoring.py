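"""Composite score: nonlinear life-impact transform onto [-100, 200].

The composite aggregates all 47 element ratings. Each element contributes
through a piecewise penalty curve that is linear in the benign region of the
scale (ratings 1-4 toward the healthy pole) and accelerates quadratically
toward the symptomatic pole, weighted by the element's seriousness class
(mild < moderate < severe). On top of the per-element sum, a deduction
proportional to the *count* of clinically significant symptoms couples the
score to the symptom thresholds used for clinical mapping, so that heavily
symptomatic profiles cannot land in the upper score range (with default
constants, any profile carrying 5 or more symptoms scores at most 100). The raw sum is affinely
mapped so the best possible answer set scores exactly +200 and the worst
exactly -100, the only two anchors the scale prints.

The transform is configuration-driven: curve constants, class weights,
symptom thresholds and the count-penalty coefficient can all be overridden.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np
import pandas as pd

from .instrument import ElementBank, ElementDefinition, RATING_MAX, RATING_MIN

SCORE_MIN = -100.0
SCORE_MAX = 200.0


class Category(str, Enum):
    DISTRESSED = "Distressed"
    STRUGGLING = "Struggling"
    ENDURING = "Enduring"
    MANAGING = "Managing"
    SUCCEEDING = "Succeeding"
    THRIVING = "Thriving"


@dataclass(frozen=True)
class ScoreTransformParams:
    """Constants of the composite transform.

    benign_slope: per-step penalty within the benign region (ratings 1-4
        from the healthy pole), before class weighting.
    acceleration: quadratic coefficient of the penalty beyond the benign
        region, i.e. penalty grows with (steps beyond 4)^2.
    class_weights: multiplier per seriousness class.
    symptom_penalty: score points deducted per clinically significant
        symptom, on top of the per-element curves.
    problem_symptom_threshold / spectrum_symptom_threshold: rating cutoffs
        defining a clinically significant symptom (>= 8 problem, <= 1
        spectrum by default), mirroring the clinical-mapping thresholds.
    """

    benign_slope: float = 0.8
    acceleration: float = 0.15
    class_weights: Mapping[str, float] = field(
        default_factory=lambda: {"mild": 1.0, "moderate": 2.0, "severe": 3.0}
    )
    symptom_penalty: float = 18.0
    problem_symptom_threshold: int = 8
    spectrum_symptom_threshold: int = 1

    def penalty_curve(self, definition: ElementDefinition) -> np.ndarray:
        """Penalty at ratings 1..9 for one element (index 0 unused).

        Defined on "steps from the healthy pole" d in 0..8: linear
        ``benign_slope * min(d, 3)`` plus ``acceleration * max(d - 3, 0)^2``,
        all scaled by the class weight. For problem elements the healthy pole
        is rating 1; for spectrum elements it is rating 9.
        """
        w = self.class_weights[definition.seriousness]
        ratings = np.arange(RATING_MIN, RATING_MAX + 1)
        d = (ratings - 1) if definition.format == "problem" else (9 - ratings)
        pen = self.benign_slope * np.minimum(d, 3) + self.acceleration * np.maximum(
            d - 3, 0
        ) ** 2
        table = np.full(RATING_MAX + 1, np.nan)
        table[RATING_MIN:] = w * pen
        return table

    def max_penalty(self, definition: ElementDefinition) -> float:
        return float(np.nanmax(self.penalty_curve(definition)))

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScoreTransformParams":
        return cls(**d)

    def to_dict(self) -> dict:
        return {
            "benign_slope": self.benign_slope,
            "acceleration": self.acceleration,
            "class_weights": dict(self.class_weights),
            "symptom_penalty": self.symptom_penalty,
            "problem_symptom_threshold": self.problem_symptom_threshold,
            "spectrum_symptom_threshold": self.spectrum_symptom_threshold,
        }


DEFAULT_PARAMS = ScoreTransformParams()


@dataclass(frozen=True)
class MHQResult:
    score: float
    category: Category


def element_contribution(
    definition: ElementDefinition,
    rating: int,
    params: ScoreTransformParams = DEFAULT_PARAMS,
) -> float:
    """Raw contribution of one rated element (higher well-being = larger).

    Expressed as the negated penalty, so the healthy pole contributes 0 and
    the symptomatic pole the most negative value for that element.
    """
    if not (RATING_MIN <= int(rating) <= RATING_MAX) or int(rating) != rating:
        raise ValueError(f"rating {rating!r} outside 1..9")
    return -float(params.penalty_curve(definition)[int(rating)])


def _is_symptom(
    definition: ElementDefinition, rating: int, params: ScoreTransformParams
) -> bool:
    if definition.format == "problem":
        return rating >= params.problem_symptom_threshold
    return rating <= params.spectrum_symptom_threshold


def compute_mhq(
    record: Mapping[str, int],
    bank: ElementBank,
    params: ScoreTransformParams = DEFAULT_PARAMS,
) -> MHQResult:
    """Score a single complete record."""
    ratings = record.get("ratings", record) if isinstance(record, Mapping) else record
    row = {eid: ratings[eid] for eid in bank.element_ids}
    df = pd.DataFrame([row])
    scores = compute_scores(df, bank, params)
    score = float(scores.iloc[0])
    return MHQResult(score=score, category=categorize(score))


def compute_scores(
    df: pd.DataFrame,
    bank: ElementBank,
    params: ScoreTransformParams = DEFAULT_PARAMS,
) -> pd.Series:
    """Vectorized scoring of a roster table (one column per element)."""
    values = df[bank.element_ids].to_numpy()
    if not np.isfinite(values.astype(float)).all():
        raise ValueError("incomplete record: scoring requires all 47 ratings")
    values = values.astype(int)
    if values.min(initial=RATING_MAX) < RATING_MIN or values.max(initial=RATING_MIN) > RATING_MAX:
        raise ValueError("rating outside 1..9")

    total_penalty = np.zeros(len(df))
    n_symptoms = np.zeros(len(df), dtype=int)
    max_penalty = 0.0
    for j, eid in enumerate(bank.element_ids):
        definition = bank[eid]
        curve = params.penalty_curve(definition)
        col = values[:, j]
        total_penalty += curve[col]
        max_penalty += params.max_penalty(definition)
        if definition.format == "problem":
            n_symptoms += col >= params.problem_symptom_threshold
        else:
            n_symptoms += col <= params.spectrum_symptom_threshold

    base = SCORE_MAX - (SCORE_MAX - SCORE_MIN) * total_penalty / max_penalty
    score = base - params.symptom_penalty * n_symptoms.astype(float)
    score = np.clip(score, SCORE_MIN, SCORE_MAX)
    return pd.Series(score, index=df.index, name="mhq_score")


#: Category bands: six 50-point bins. The lower bound of each band is
#: inclusive except that a score of exactly 100 is Managing (the upper two
#: bands are defined by score > 100).
_CATEGORY_BANDS = (
    (-100.0, -50.0, Category.DISTRESSED),
    (-50.0, 0.0, Category.STRUGGLING),
    (0.0, 50.0, Category.ENDURING),
    (50.0, 100.0, Category.MANAGING),
    (100.0, 150.0, Category.SUCCEEDING),
    (150.0, 200.0, Category.THRIVING),
)


def categorize(score: float) -> Category:
    """Map a score to its well-being category."""
    if not (SCORE_MIN <= score <= SCORE_MAX):
        raise ValueError(f"score {score} outside [{SCORE_MIN}, {SCORE_MAX}]")
    if score < -50:
        return Category.DISTRESSED
    if score < 0:
        return Category.STRUGGLING
    if score < 50:
        return Category.ENDURING
    if score <= 100:
        return Category.MANAGING
    if score <= 150:
        return Category.SUCCEEDING
    return Category.THRIVING


def categorize_series(scores: pd.Series) -> pd.Series:
    return scores.map(lambda s: categorize(float(s)).value).rename("category")


def score_roster(
    df: pd.DataFrame,
    bank: ElementBank,
    params: ScoreTransformParams = DEFAULT_PARAMS,
) -> pd.DataFrame:
    """Return a copy of ``df`` with ``mhq_score`` and ``category`` columns."""
    out = df.copy()
    out["mhq_score"] = compute_scores(df, bank, params)
    out["category"] = categorize_series(out["mhq_score"])
    return out


def save_params(params: ScoreTransformParams, path) -> None:
    with open(path, "w") as fh:
        json.dump(params.to_dict(), fh, indent=2)


def load_params(path) -> ScoreTransformParams:
    with open(path) as fh:
        return ScoreTransformParams.from_dict(json.load(fh))
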