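"""Clinical symptom profiles, diagnostic rule engine and burden-by-bin tables.

A rating marks a clinically significant symptom when it signals a highly
negative life impact: >= 8 on problem elements, <= 1 on spectrum elements
(equivalent, on average, to experiencing the symptom about 5 days a week).
Boolean rules over these symptom flags — required elements plus k-of-set
clauses — map profiles onto 10 major disorders; burden is then aggregated
per 25-point score bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, field_validator

from .instrument import ElementBank

PROBLEM_SYMPTOM_THRESHOLD = 8
SPECTRUM_SYMPTOM_THRESHOLD = 1

#: 12 score bins of width 25 partitioning [-100, 200]; the top bin is closed.
BIN_EDGES = np.arange(-100, 201, 25)


class KOfSetClause(BaseModel):
    elements: list[str]
    min_count: int

    @field_validator("min_count")
    @classmethod
    def _positive(cls, v: int) -> int:
        if v < 1:
            raise ValueError("min_count must be >= 1")
        return v


class DisorderRule(BaseModel):
    disorder: str
    required: list[str] = []
    clauses: list[KOfSetClause] = []

    def referenced_elements(self) -> set[str]:
        out = set(self.required)
        for clause in self.clauses:
            out.update(clause.elements)
        return out


def load_rule_table(path: str | None = None, bank: ElementBank | None = None
                    ) -> list[DisorderRule]:
    """Load the disorder rule table (default: packaged 10-disorder table).

    When a bank is given, every referenced element id is checked against it.
    """
    if path is None:
        text = resources.files("mhq.data").joinpath("disorder_rules.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    rules = [DisorderRule(**row) for row in raw["rules"]]
    if bank is not None:
        for rule in rules:
            unknown = rule.referenced_elements() - set(bank.element_ids)
            if unknown:
                raise ValueError(
                    f"rule {rule.disorder!r} references unknown elements {sorted(unknown)}"
                )
    return rules


def symptom_profile(
    ratings: Mapping[str, int] | pd.Series, bank: ElementBank
) -> dict[str, bool]:
    """Symptom flags for a single record."""
    out = {}
    for eid in bank.element_ids:
        r = int(ratings[eid])
        if bank[eid].format == "problem":
            out[eid] = r >= PROBLEM_SYMPTOM_THRESHOLD
        else:
            out[eid] = r <= SPECTRUM_SYMPTOM_THRESHOLD
    return out


def symptom_profiles(df: pd.DataFrame, bank: ElementBank) -> pd.DataFrame:
    """Vectorized symptom flags, one boolean column per element."""
    flags = {}
    for eid in bank.element_ids:
        col = df[eid].to_numpy(dtype=int)
        if bank[eid].format == "problem":
            flags[eid] = col >= PROBLEM_SYMPTOM_THRESHOLD
        else:
            flags[eid] = col <= SPECTRUM_SYMPTOM_THRESHOLD
    return pd.DataFrame(flags, index=df.index)


def evaluate_disorder(profile: Mapping[str, bool], rule: DisorderRule) -> bool:
    """True iff all required elements are symptomatic and every clause holds."""
    for eid in rule.required:
        if eid not in profile:
            raise KeyError(f"rule {rule.disorder!r} references unknown element {eid!r}")
        if not profile[eid]:
            return False
    for clause in rule.clauses:
        count = 0
        for eid in clause.elements:
            if eid not in profile:
                raise KeyError(
                    f"rule {rule.disorder!r} references unknown element {eid!r}"
                )
            count += bool(profile[eid])
        if count < clause.min_count:
            return False
    return True


@dataclass(frozen=True)
class DiagnosisResult:
    flags: Mapping[str, bool]
    n_disorders: int
    any_disorder: bool


def diagnose_record(
    ratings: Mapping[str, int], bank: ElementBank, rules: Sequence[DisorderRule]
) -> DiagnosisResult:
    profile = symptom_profile(ratings, bank)
    flags = {rule.disorder: evaluate_disorder(profile, rule) for rule in rules}
    n = sum(flags.values())
    return DiagnosisResult(flags=flags, n_disorders=n, any_disorder=n >= 1)


def diagnose(
    df: pd.DataFrame, bank: ElementBank, rules: Sequence[DisorderRule]
) -> pd.DataFrame:
    """Per-disorder flags plus symptom/diagnosis counts for a roster table."""
    profiles = symptom_profiles(df, bank)
    out = pd.DataFrame(index=df.index)
    for rule in rules:
        mask = np.ones(len(df), dtype=bool)
        for eid in rule.required:
            mask &= profiles[eid].to_numpy()
        for clause in rule.clauses:
            counts = profiles[clause.elements].to_numpy().sum(axis=1)
            mask &= counts >= clause.min_count
        out[rule.disorder] = mask
    disorder_cols = [rule.disorder for rule in rules]
    out["n_symptoms"] = profiles.to_numpy().sum(axis=1)
    out["n_disorders"] = out[disorder_cols].to_numpy().sum(axis=1)
    out["any_disorder"] = out["n_disorders"] >= 1
    return out


def assign_bins(scores: pd.Series | np.ndarray) -> np.ndarray:
    """Index of the 25-point score bin (0..11); the top bin is closed at 200."""
    s = np.asarray(scores, dtype=float)
    if np.any(s < BIN_EDGES[0]) or np.any(s > BIN_EDGES[-1]):
        raise ValueError("score outside [-100, 200]")
    idx = np.floor((s - BIN_EDGES[0]) / 25).astype(int)
    return np.minimum(idx, len(BIN_EDGES) - 2)


def burden_by_bin(scored: pd.DataFrame, diagnosed: pd.DataFrame) -> pd.DataFrame:
    """Aggregate clinical burden per 25-point score bin.

    ``scored`` must carry ``mhq_score``; ``diagnosed`` is the output of
    :func:`diagnose` aligned on the same index. Empty bins appear with n = 0
    and NaN means.
    """
    if len(scored) == 0:
        raise ValueError("empty cohort")
    bins = assign_bins(scored["mhq_score"])
    work = pd.DataFrame(
        {
            "bin": bins,
            "n_symptoms": diagnosed["n_symptoms"].to_numpy(),
            "n_disorders": diagnosed["n_disorders"].to_numpy(),
            "any_disorder": diagnosed["any_disorder"].to_numpy(dtype=float),
        }
    )
    grouped = work.groupby("bin")
    table = pd.DataFrame(
        {
            "bin_low": BIN_EDGES[:-1],
            "bin_high": BIN_EDGES[1:],
            "bin_mid": (BIN_EDGES[:-1] + BIN_EDGES[1:]) / 2.0,
        },
        index=pd.RangeIndex(12, name="bin"),
    )
    table["n"] = grouped.size().reindex(table.index, fill_value=0)
    table["mean_symptoms"] = grouped["n_symptoms"].mean().reindex(table.index)
    table["mean_disorders"] = grouped["n_disorders"].mean().reindex(table.index)
    table["sd_disorders"] = grouped["n_disorders"].std(ddof=1).reindex(table.index)
    table["pct_any_disorder"] = 100.0 * grouped["any_disorder"].mean().reindex(table.index)
    return table.reset_index()
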