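"""Construct validity of the life-impact scale against frequency and severity.

For one probed element, respondents who rated its life impact >= 5 also
reported how many days in the last week they experienced it (frequency,
0-7) and how strongly it impaired them (severity, 5 ordered levels).
Per-rating aggregates of these probes are fitted linearly against the
rating; the frequency x severity composite — the product of two linear
means — is fitted with a second-order polynomial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

PROBE_MIN_RATING = 5
PROBE_MAX_RATING = 9


@dataclass(frozen=True)
class RatingAggregate:
    """Per-rating probe table plus individual-level correlations."""

    table: pd.DataFrame  # rows: rating levels present; mean/SEM of freq & severity
    r_frequency: float  # Pearson r(life_impact, frequency) across individuals
    r_severity: float
    n: int


@dataclass(frozen=True)
class LineFit:
    slope: float
    intercept: float
    r_squared: float

    def extrapolate(self, rating: float) -> float:
        """Evaluate the fitted line, including outside the probed 5..9 range."""
        return self.intercept + self.slope * rating


@dataclass(frozen=True)
class QuadFit:
    coefficients: tuple[float, float, float]  # highest degree first
    r_squared: float

    def __call__(self, rating: float) -> float:
        return float(np.polyval(self.coefficients, rating))


def aggregate_probe(probes: pd.DataFrame) -> RatingAggregate:
    """Group probe answers by life-impact rating.

    ``probes`` needs columns ``life_impact`` (5..9), ``frequency`` (0..7) and
    ``severity`` (1..5). SEM is SD/sqrt(n) within each rating level.
    """
    if len(probes) == 0:
        raise ValueError("no probe responses")
    li = probes["life_impact"].to_numpy(dtype=int)
    if li.min() < PROBE_MIN_RATING or li.max() > PROBE_MAX_RATING:
        raise ValueError("life-impact ratings in probes must lie in 5..9")
    grouped = probes.groupby("life_impact")
    rows = {
        "n": grouped.size(),
        "freq_mean": grouped["frequency"].mean(),
        "freq_sem": grouped["frequency"].std(ddof=1) / np.sqrt(grouped.size()),
        "sev_mean": grouped["severity"].mean(),
        "sev_sem": grouped["severity"].std(ddof=1) / np.sqrt(grouped.size()),
        "product_mean": grouped.apply(
            lambda g: (g["frequency"] * g["severity"]).mean(), include_groups=False
        ),
    }
    table = pd.DataFrame(rows)
    table.index.name = "life_impact"

    def _corr(col: str) -> float:
        x = probes["life_impact"].to_numpy(dtype=float)
        y = probes[col].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            return float("nan")
        return float(stats.pearsonr(x, y).statistic)

    return RatingAggregate(
        table=table.reset_index(),
        r_frequency=_corr("frequency"),
        r_severity=_corr("severity"),
        n=len(probes),
    )


def fit_rating_line(aggregate: RatingAggregate, response: str) -> LineFit:
    """OLS of the per-rating mean (frequency or severity) on the rating.

    The returned fit extrapolates linearly outside 5..9, e.g. to ask what
    frequency a rating of 1 would correspond to.
    """
    col = {"frequency": "freq_mean", "severity": "sev_mean"}[response]
    t = aggregate.table
    if len(t) < 3:
        raise ValueError(f"need >= 3 rating levels, got {len(t)}")
    res = stats.linregress(t["life_impact"], t[col])
    yhat = res.intercept + res.slope * t["life_impact"]
    y = t[col].to_numpy()
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = float("nan") if ss_tot == 0 else 1 - float(np.sum((y - yhat) ** 2)) / ss_tot
    return LineFit(slope=float(res.slope), intercept=float(res.intercept), r_squared=r2)


def fit_product_curve(aggregate: RatingAggregate) -> QuadFit:
    """Quadratic least squares of mean frequency x severity on the rating.

    If frequency and severity are each linear in the rating, their product is
    exactly quadratic, so a second-order polynomial is the natural form.
    """
    t = aggregate.table
    if len(t) < 4:
        raise ValueError(f"need >= 4 rating levels, got {len(t)}")
    x = t["life_impact"].to_numpy(dtype=float)
    y = t["product_mean"].to_numpy(dtype=float)
    coeffs = np.polyfit(x, y, 2)
    yhat = np.polyval(coeffs, x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = float("nan") if ss_tot == 0 else 1 - float(np.sum((y - yhat) ** 2)) / ss_tot
    return QuadFit(coefficients=tuple(float(c) for c in coeffs), r_squared=r2)
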