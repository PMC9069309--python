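"""Sample reliability, internal consistency and test-retest statistics.

Three complementary checks that the instrument behaves like a stable
measurement device:

* *Sample reliability*: k demographically matched, nonoverlapping random
  samples drawn from one pooled cohort should be statistically
  indistinguishable — per-element one-way ANOVA plus pairwise correlation of
  the 47 per-element mean vectors.
* *Internal consistency*: semantically related item pairs (e.g. self-image
  and self-worth, or the two sleep questions) should correlate more strongly
  than unrelated pairs.
* *Test-retest*: respondents who retook the assessment at least 3 days later
  (same-day and next-day retakes are discarded as likely experimentation)
  should produce correlated scores and element ratings, reported overall and
  within gap strata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .instrument import ElementBank, SLEEP_SUFFICIENCY_RECODE, recode_series
from .scoring import ScoreTransformParams, DEFAULT_PARAMS, compute_scores

#: Retest gap strata in days (closed intervals), as reported in the
#: per-stratum retest table.
GAP_STRATA = ((3, 7), (8, 30), (31, 60), (61, 120), (121, 450))

MIN_RETEST_GAP_DAYS = 3

#: Default demographic matching cells: age band x gender x country.
DEFAULT_STRATA_COLUMNS = ("age_band", "gender", "country")

AGE_BAND_EDGES = (18, 25, 35, 45, 55, 65)


def age_band(ages: pd.Series) -> pd.Series:
    """Categorize age in years into the default matching bands (18-24 ... 65+)."""
    edges = list(AGE_BAND_EDGES) + [np.inf]
    labels = [
        f"{lo}-{hi - 1}" if np.isfinite(hi) else f"{lo}+"
        for lo, hi in zip(edges[:-1], edges[1:])
    ]
    return pd.cut(ages, bins=edges, labels=labels, right=False).astype(str)


@dataclass(frozen=True)
class MatchedSampleSet:
    """k pairwise-disjoint stratified samples (row indices into the cohort)."""

    samples: tuple[np.ndarray, ...]
    strata_columns: tuple[str, ...]
    allocation: pd.DataFrame  # per-cell target counts

    def frames(self, df: pd.DataFrame) -> list[pd.DataFrame]:
        return [df.loc[idx] for idx in self.samples]


def _largest_remainder(proportions: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` across cells, largest-remainder method."""
    quotas = proportions * total
    base = np.floor(quotas).astype(int)
    remainder = total - base.sum()
    if remainder > 0:
        order = np.argsort(-(quotas - base), kind="stable")
        base[order[:remainder]] += 1
    return base


def draw_matched_samples(
    df: pd.DataFrame,
    k: int = 4,
    size: int | None = None,
    strata_columns: Sequence[str] = DEFAULT_STRATA_COLUMNS,
    seed: int = 0,
) -> MatchedSampleSet:
    """Draw k nonoverlapping samples with matching demographic composition.

    Cell targets follow proportional allocation of the pooled cohort's strata
    frequencies, rounded by the largest-remainder method so each sample sums
    exactly to ``size``. Sampling is without replacement across all k
    samples, so cells must hold at least k times their target.
    """
    if size is None:
        size = len(df) // k
    if k < 2:
        raise ValueError("need k >= 2 samples")
    if k * size > len(df):
        raise ValueError(f"k*size = {k * size} exceeds cohort size {len(df)}")

    work = df.copy()
    if "age_band" in strata_columns and "age_band" not in work.columns:
        work["age_band"] = age_band(work["age"])
    cells = work.groupby(list(strata_columns), observed=True).groups
    cell_keys = list(cells)
    cell_sizes = np.array([len(cells[key]) for key in cell_keys])
    targets = _largest_remainder(cell_sizes / cell_sizes.sum(), size)

    deficient = [
        (key, int(t), int(n))
        for key, t, n in zip(cell_keys, targets, cell_sizes)
        if k * t > n
    ]
    if deficient:
        detail = "; ".join(f"{key}: need {k}*{t}, have {n}" for key, t, n in deficient)
        raise ValueError(f"infeasible cell allocation: {detail}")

    rng = np.random.default_rng(seed)
    samples: list[list] = [[] for _ in range(k)]
    for key, target in zip(cell_keys, targets):
        idx = np.asarray(cells[key])
        chosen = rng.choice(idx, size=k * target, replace=False)
        for i in range(k):
            samples[i].extend(chosen[i * target : (i + 1) * target])
    allocation = pd.DataFrame(
        {"cell": [str(key) for key in cell_keys], "available": cell_sizes,
         "target_per_sample": targets}
    )
    return MatchedSampleSet(
        samples=tuple(np.array(sorted(s)) for s in samples),
        strata_columns=tuple(strata_columns),
        allocation=allocation,
    )


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    degenerate: bool = False


def across_sample_anova(
    sample_frames: Sequence[pd.DataFrame], column: str
) -> AnovaResult:
    """One-way ANOVA of one value column with sample membership as the factor."""
    if len(sample_frames) < 2:
        raise ValueError("need >= 2 samples")
    groups = [frame[column].to_numpy(dtype=float) for frame in sample_frames]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each sample needs n >= 2")
    grand = np.concatenate(groups)
    if np.ptp(grand) == 0:
        return AnovaResult(f_statistic=0.0, p_value=1.0, degenerate=True)
    if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) > 1:
        # between-group variance with zero within-group variance
        return AnovaResult(f_statistic=float("inf"), p_value=0.0, degenerate=True)
    res = stats.f_oneway(*groups)
    return AnovaResult(f_statistic=float(res.statistic), p_value=float(res.pvalue))


def anova_battery(
    sample_frames: Sequence[pd.DataFrame], bank: ElementBank,
    score_column: str | None = "mhq_score",
) -> pd.DataFrame:
    """ANOVA per element rating (and the score when present) across samples."""
    rows = []
    columns = list(bank.element_ids)
    if score_column and all(score_column in f.columns for f in sample_frames):
        columns.append(score_column)
    for col in columns:
        res = across_sample_anova(sample_frames, col)
        rows.append({"column": col, "F": res.f_statistic, "p": res.p_value,
                     "degenerate": res.degenerate})
    return pd.DataFrame(rows)


def element_mean_correlation(
    sample_frames: Sequence[pd.DataFrame], bank: ElementBank
) -> pd.DataFrame:
    """Pearson r between the 47-element mean vectors of every sample pair."""
    if len(sample_frames) < 2:
        raise ValueError("need >= 2 samples")
    means = [f[bank.element_ids].mean().to_numpy() for f in sample_frames]
    k = len(means)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            if np.std(means[i]) == 0 or np.std(means[j]) == 0:
                r = float("nan")
            else:
                r = float(stats.pearsonr(means[i], means[j]).statistic)
            rows.append({"sample_a": i, "sample_b": j, "r": r})
    return pd.DataFrame(rows)


def gap_stratum(gap_days: int) -> str | None:
    """Label of the retest-interval stratum, or None outside all strata."""
    for lo, hi in GAP_STRATA:
        if lo <= gap_days <= hi:
            return f"{lo}-{hi}"
    return None


@dataclass(frozen=True)
class RetestPairs:
    """Aligned first/second attempts, one row per respondent with a retake."""

    first: pd.DataFrame
    second: pd.DataFrame
    gap_days: np.ndarray
    strata: tuple[str | None, ...]

    def __len__(self) -> int:
        return len(self.gap_days)


def pair_retests(df: pd.DataFrame) -> RetestPairs:
    """Pair each repeat respondent's first attempt with the earliest retake
    at least 3 days later.

    Respondents whose only retakes fall within 2 days of the first attempt
    are dropped (same-day and next-day retakes are treated as
    experimentation, and the inclusion rule requires a 3-day gap). Each
    respondent contributes at most one pair.
    """
    ordered = df.sort_values(["respondent_id", "attempt_day"], kind="stable")
    first_rows, second_rows, gaps, strata = [], [], [], []
    for _, group in ordered.groupby("respondent_id", sort=False):
        if len(group) < 2:
            continue
        first = group.iloc[0]
        later = group.iloc[1:]
        qualifying = later[later["attempt_day"] >= first["attempt_day"] + MIN_RETEST_GAP_DAYS]
        if len(qualifying) == 0:
            continue
        second = qualifying.iloc[0]
        gap = int(second["attempt_day"] - first["attempt_day"])
        first_rows.append(first)
        second_rows.append(second)
        gaps.append(gap)
        strata.append(gap_stratum(gap))
    if first_rows:
        first_df = pd.DataFrame(first_rows).reset_index(drop=True)
        second_df = pd.DataFrame(second_rows).reset_index(drop=True)
    else:
        first_df = df.iloc[0:0].copy()
        second_df = df.iloc[0:0].copy()
    return RetestPairs(
        first=first_df,
        second=second_df,
        gap_days=np.array(gaps, dtype=int),
        strata=tuple(strata),
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class RetestStats:
    score_r: float
    element_r: float  # pooled over all (pair, element) tuples
    n_pairs: int
    by_stratum: pd.DataFrame
    per_element_r: pd.Series = field(repr=False, default=None)


def test_retest_stats(
    pairs: RetestPairs,
    bank: ElementBank,
    params: ScoreTransformParams = DEFAULT_PARAMS,
) -> RetestStats:
    """Score and element correlations between first and second attempts.

    The element correlation pools every (pair, element) rating tuple into a
    single paired sequence — aggregate consistency across the whole item
    bank — with the 47 per-element correlations also emitted for
    diagnostics. Strata with fewer than 3 pairs are reported as absent.
    """
    if len(pairs) < 3:
        raise ValueError("need >= 3 retest pairs")
    s1 = compute_scores(pairs.first, bank, params).to_numpy()
    s2 = compute_scores(pairs.second, bank, params).to_numpy()
    r1 = pairs.first[bank.element_ids].to_numpy(dtype=float)
    r2 = pairs.second[bank.element_ids].to_numpy(dtype=float)

    rows = []
    strata = np.array([s if s is not None else "" for s in pairs.strata])
    for lo, hi in GAP_STRATA:
        label = f"{lo}-{hi}"
        mask = strata == label
        n = int(mask.sum())
        if n < 3:
            rows.append({"stratum": label, "n": n, "score_r": np.nan,
                         "element_r": np.nan})
            continue
        rows.append(
            {
                "stratum": label,
                "n": n,
                "score_r": _pearson(s1[mask], s2[mask]),
                "element_r": _pearson(r1[mask].ravel(), r2[mask].ravel()),
            }
        )
    per_element = pd.Series(
        [_pearson(r1[:, j], r2[:, j]) for j in range(len(bank.element_ids))],
        index=bank.element_ids,
        name="retest_r",
    )
    return RetestStats(
        score_r=_pearson(s1, s2),
        element_r=_pearson(r1.ravel(), r2.ravel()),
        n_pairs=len(pairs),
        by_stratum=pd.DataFrame(rows),
        per_element_r=per_element,
    )


test_retest_stats.__test__ = False  # library function, not a pytest case


@dataclass(frozen=True)
class ConsistencyPairSpec:
    """Two item accessors to correlate, with an optional recode for item B."""

    name: str
    item_a: str
    item_b: str
    recode_b: Mapping[str, int] | None = None
    related: bool = True


DEFAULT_CONSISTENCY_SPECS = (
    ConsistencyPairSpec("sleep", "sleep_quality", "sleep_sufficiency",
                        recode_b=SLEEP_SUFFICIENCY_RECODE),
    ConsistencyPairSpec("mood", "sadness", "current_mood"),
    ConsistencyPairSpec("self_regard", "self_image", "self_worth"),
    ConsistencyPairSpec("memory_intimacy", "memory", "physical_intimacy",
                        related=False),
    ConsistencyPairSpec("control_coordination", "emotional_control", "coordination",
                        related=False),
    ConsistencyPairSpec("memory_control", "memory", "emotional_control",
                        related=False),
)


def internal_consistency(
    df: pd.DataFrame,
    specs: Sequence[ConsistencyPairSpec] = DEFAULT_CONSISTENCY_SPECS,
) -> pd.DataFrame:
    """Pearson r per consistency pair, recoding categorical items first."""
    rows = []
    for spec in specs:
        a = df[spec.item_a].astype(float)
        b = df[spec.item_b]
        if spec.recode_b is not None:
            b = recode_series(b, spec.recode_b)
        b = b.astype(float)
        mask = a.notna() & b.notna()
        x, y = a[mask].to_numpy(), b[mask].to_numpy()
        degenerate = len(x) < 3 or np.std(x) == 0 or np.std(y) == 0
        rows.append(
            {
                "pair": spec.name,
                "item_a": spec.item_a,
                "item_b": spec.item_b,
                "related": spec.related,
                "n": int(mask.sum()),
                "r": float("nan") if degenerate else _pearson(x, y),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)
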