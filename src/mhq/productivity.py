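"""Criterion validity against lost productivity.

Respondents report days in the past month they were fully unable to work
(absenteeism, M) and days with reduced productivity (presenteeism, R), both
0..31. Aggregated per 25-point score bin, mean M follows an exponential
decay in the score and mean R a straight line; total productivity loss is
the composite M + n*R with the fractional loss n on unproductive days
assumed to lie between 20% and 50%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .clinical import BIN_EDGES, assign_bins

DAYS_MIN = 0
DAYS_MAX = 31

#: Bins with fewer than this many respondents are excluded from curve fits
#: (their means are too unstable to constrain the fit).
MIN_BIN_N = 20


@dataclass(frozen=True)
class ProductivityFit:
    """Result of a trend fit to per-bin means."""

    model: str  # "exponential" | "linear"
    params: dict
    r_squared: float
    bin_table: pd.DataFrame = field(repr=False, default=None)
    degenerate: bool = False


def aggregate_by_bin(
    df: pd.DataFrame, employed_only: bool = False
) -> pd.DataFrame:
    """Mean/SD/SEM of days missed and reduced-productivity days per score bin.

    ``df`` needs ``mhq_score``, ``days_missed`` and ``reduced_days`` columns
    (plus ``employment_status`` when ``employed_only``).
    """
    work = df
    if employed_only:
        work = df[df["employment_status"] == "employed"]
    if len(work) == 0:
        table = _empty_table()
        table.attrs["empty"] = True
        return table
    bins = assign_bins(work["mhq_score"])
    out = _empty_table()
    grouped = work.assign(bin=bins).groupby("bin")
    out["n"] = grouped.size().reindex(out.index, fill_value=0)
    for col, prefix in (("days_missed", "m"), ("reduced_days", "r")):
        mean = grouped[col].mean().reindex(out.index)
        sd = grouped[col].std(ddof=1).reindex(out.index)
        out[f"{prefix}_mean"] = mean
        out[f"{prefix}_sd"] = sd
        out[f"{prefix}_sem"] = sd / np.sqrt(out["n"].where(out["n"] > 0))
    return out.reset_index()


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bin_low": BIN_EDGES[:-1],
            "bin_high": BIN_EDGES[1:],
            "bin_mid": (BIN_EDGES[:-1] + BIN_EDGES[1:]) / 2.0,
            "n": 0,
        },
        index=pd.RangeIndex(12, name="bin"),
    )


def _usable(bin_table: pd.DataFrame, col: str, min_bin_n: int) -> pd.DataFrame:
    t = bin_table[(bin_table["n"] >= min_bin_n) & bin_table[col].notna()]
    return t


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return float("nan")
    return 1.0 - ss_res / ss_tot


def fit_absenteeism(
    bin_table: pd.DataFrame, min_bin_n: int = MIN_BIN_N
) -> ProductivityFit:
    """Least-squares fit of mean days missed vs bin midpoint to a*exp(-b*s)+c.

    The additive floor c >= 0 absorbs the nonzero loss that persists in the
    top bins. Initialized from a log-linear regression on (mean - min).
    """
    t = _usable(bin_table, "m_mean", min_bin_n)
    if len(t) < 4:
        raise ValueError(f"need >= 4 usable bins, got {len(t)}")
    s = t["bin_mid"].to_numpy(dtype=float)
    y = t["m_mean"].to_numpy(dtype=float)

    if np.ptp(y) < 1e-12:
        return ProductivityFit(
            model="exponential",
            params={"a": 0.0, "b": 0.0, "c": float(y.mean())},
            r_squared=float("nan"),
            bin_table=t,
            degenerate=True,
        )

    # log-linear initializer on the floored means
    floor0 = max(y.min() - 1e-3, 0.0)
    positive = y - floor0 > 1e-8
    slope, intercept = np.polyfit(s[positive], np.log(y[positive] - floor0 + 1e-8), 1)
    p0 = (float(np.exp(intercept)), float(-slope), floor0)

    def model(sv, a, b, c):
        return a * np.exp(-b * sv) + c

    try:
        popt, _ = optimize.curve_fit(
            model, s, y, p0=p0, bounds=([0, 0, 0], [np.inf, 1.0, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as err:
        raise RuntimeError(
            f"exponential fit did not converge (initializer {p0})"
        ) from err
    a, b, c = (float(v) for v in popt)
    r2 = _r_squared(y, model(s, a, b, c))
    return ProductivityFit(
        model="exponential",
        params={"a": a, "b": b, "c": c},
        r_squared=r2,
        bin_table=t,
        degenerate=bool(b < 1e-8),
    )


def fit_presenteeism(
    bin_table: pd.DataFrame, min_bin_n: int = MIN_BIN_N
) -> ProductivityFit:
    """Ordinary least squares of mean reduced-productivity days vs bin midpoint."""
    t = _usable(bin_table, "r_mean", min_bin_n)
    if len(t) < 3:
        raise ValueError(f"need >= 3 usable bins, got {len(t)}")
    s = t["bin_mid"].to_numpy(dtype=float)
    y = t["r_mean"].to_numpy(dtype=float)
    res = stats.linregress(s, y)
    yhat = res.intercept + res.slope * s
    return ProductivityFit(
        model="linear",
        params={"slope": float(res.slope), "intercept": float(res.intercept)},
        r_squared=_r_squared(y, yhat),
        bin_table=t,
    )


def total_loss(days_missed: float, reduced_days: float, n: float) -> float:
    """Total productivity loss M + n*R for a fractional loss n in [0.2, 0.5]."""
    if not (0.2 <= n <= 0.5):
        raise ValueError(f"fractional loss n={n} outside the assumed band [0.2, 0.5]")
    return float(days_missed + n * reduced_days)


def total_loss_band(days_missed: float, reduced_days: float) -> tuple[float, float]:
    """Total loss evaluated at the two ends of the assumed band (n=0.2, n=0.5)."""
    return (
        total_loss(days_missed, reduced_days, 0.2),
        total_loss(days_missed, reduced_days, 0.5),
    )
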