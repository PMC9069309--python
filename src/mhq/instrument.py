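"""Item bank, respondent records, validation, exclusion filtering and recoding.

The instrument is a 47-element questionnaire answered on a 9-point life-impact
scale. 27 *spectrum* elements describe mental functions that run from
positive to negative (9 = healthy pole); 20 *problem* elements describe pure
detractions from mental health (9 = constant, severe life impact). A roster
is one row per assessment attempt; respondent ids may repeat (retakes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

RATING_MIN = 1
RATING_MAX = 9

FORMATS = ("spectrum", "problem")
SERIOUSNESS_CLASSES = ("mild", "moderate", "severe")

EMPLOYMENT_STATUSES = (
    "employed",
    "homemaker",
    "unemployed",
    "retired",
    "studying",
    "not_able_to_work",
)

#: Answer options of the sleep-sufficiency question and their numeric recode,
#: used by the internal-consistency battery.
SLEEP_SUFFICIENCY_RECODE = {
    "all the time": 7,
    "most of the time": 5,
    "some of the time": 3,
    "hardly ever": 1,
}

#: Non-rating columns of the roster table, in canonical order.
METADATA_COLUMNS = (
    "respondent_id",
    "attempt_day",
    "age",
    "gender",
    "country",
    "employment_status",
    "easy_to_understand",
    "sleep_sufficiency",
    "current_mood",
)


@dataclass(frozen=True)
class ElementDefinition:
    """One questionnaire item."""

    element_id: str
    label: str
    format: str  # "spectrum" | "problem"
    seriousness: str  # "mild" | "moderate" | "severe"
    related_group: str | None = None

    def __post_init__(self) -> None:
        if self.format not in FORMATS:
            raise ValueError(f"unknown format {self.format!r}")
        if self.seriousness not in SERIOUSNESS_CLASSES:
            raise ValueError(f"unknown seriousness class {self.seriousness!r}")


class ElementBank:
    """Ordered collection of the 47 element definitions.

    The 27/20 spectrum/problem split is a hard invariant of the instrument;
    labels and seriousness classes are configuration.
    """

    def __init__(self, elements: Sequence[ElementDefinition], strict: bool = True):
        ids = [e.element_id for e in elements]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate element_id in bank")
        self._elements = tuple(elements)
        self._by_id = {e.element_id: e for e in elements}
        if strict:
            n_spec = sum(e.format == "spectrum" for e in elements)
            n_prob = sum(e.format == "problem" for e in elements)
            if (n_spec, n_prob) != (27, 20):
                raise ValueError(
                    f"bank must hold 27 spectrum + 20 problem elements, "
                    f"got {n_spec} + {n_prob}"
                )

    def __len__(self) -> int:
        return len(self._elements)

    def __iter__(self):
        return iter(self._elements)

    def __contains__(self, element_id: str) -> bool:
        return element_id in self._by_id

    def __getitem__(self, element_id: str) -> ElementDefinition:
        return self._by_id[element_id]

    @property
    def element_ids(self) -> list[str]:
        return [e.element_id for e in self._elements]

    @property
    def spectrum_ids(self) -> list[str]:
        return [e.element_id for e in self._elements if e.format == "spectrum"]

    @property
    def problem_ids(self) -> list[str]:
        return [e.element_id for e in self._elements if e.format == "problem"]

    def related_groups(self) -> dict[str, list[str]]:
        groups: dict[str, list[str]] = {}
        for e in self._elements:
            if e.related_group:
                groups.setdefault(e.related_group, []).append(e.element_id)
        return groups


def load_element_bank(path: str | None = None, strict: bool = True) -> ElementBank:
    """Load the element bank from YAML (default: the packaged bank)."""
    if path is None:
        text = resources.files("mhq.data").joinpath("elements.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    elements = [ElementDefinition(**row) for row in raw["elements"]]
    return ElementBank(elements, strict=strict)


@dataclass
class Roster:
    """One row per assessment attempt, plus provenance.

    ``data`` holds metadata columns (see :data:`METADATA_COLUMNS`) and one
    integer column per element_id. ``latent`` optionally carries the
    generator's per-person latent state (needed to simulate retakes); it is
    never written to the roster CSV.
    """

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    latent: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Roster":
        df = pd.read_csv(path)
        return cls(data=df, provenance={"source": str(path)})


@dataclass(frozen=True)
class ValidationResult:
    valid: bool
    reasons: tuple[str, ...] = ()


def validate_record(
    record: Mapping[str, object], bank: ElementBank
) -> ValidationResult:
    """Check one attempt for completeness and in-range ratings.

    A record is valid iff every element of the bank is rated exactly once and
    every rating lies in 1..9. Reasons are itemized: ``incomplete`` (missing
    rating), ``out-of-range`` (rating outside 1..9), ``schema mismatch``
    (rating key not in the bank, for mapping-style records).
    """
    reasons: list[str] = []
    ratings = record.get("ratings", record)
    if ratings is not record:  # nested mapping form: unknown keys detectable
        for key in ratings:
            if key not in bank:
                reasons.append(f"schema mismatch: unknown element {key!r}")
    for eid in bank.element_ids:
        value = ratings.get(eid) if isinstance(ratings, Mapping) else None
        if value is None or (isinstance(value, float) and np.isnan(value)):
            reasons.append(f"incomplete: missing rating for {eid!r}")
            continue
        try:
            v = int(value)
        except (TypeError, ValueError):
            reasons.append(f"out-of-range: non-integer rating for {eid!r}")
            continue
        if v != value or not (RATING_MIN <= v <= RATING_MAX):
            reasons.append(f"out-of-range: rating {value!r} for {eid!r}")
    return ValidationResult(valid=not reasons, reasons=tuple(reasons))


def validate_roster(df: pd.DataFrame, bank: ElementBank) -> pd.Series:
    """Vectorized validity mask: complete, integral, in-range ratings per row."""
    missing = [eid for eid in bank.element_ids if eid not in df.columns]
    if missing:
        raise KeyError(f"roster lacks rating columns: {missing}")
    block = df[bank.element_ids]
    values = block.to_numpy(dtype=float)
    ok = np.isfinite(values)
    ok &= values == np.floor(values)
    ok &= (values >= RATING_MIN) & (values <= RATING_MAX)
    return pd.Series(ok.all(axis=1), index=df.index, name="valid")


@dataclass(frozen=True)
class FilterCounts:
    input: int
    retained: int
    excluded: int


def apply_exclusion_filter(roster: Roster) -> tuple[Roster, FilterCounts]:
    """Keep only respondents who found the assessment easy to understand.

    Raises if the flag is missing anywhere: the rule cannot be applied to
    records that never answered the comprehension question.
    """
    df = roster.data
    if "easy_to_understand" not in df.columns:
        raise ValueError("cannot filter: easy_to_understand column missing")
    flag = df["easy_to_understand"]
    if flag.isna().any():
        raise ValueError("cannot filter: easy_to_understand missing for some records")
    mask = flag.astype(bool)
    kept = df[mask]
    latent = roster.latent.loc[kept.index] if roster.latent is not None else None
    counts = FilterCounts(input=len(df), retained=int(mask.sum()),
                          excluded=int((~mask).sum()))
    out = Roster(
        data=kept.reset_index(drop=True),
        provenance={**roster.provenance, "exclusion_filter": counts.__dict__},
        latent=latent.reset_index(drop=True) if latent is not None else None,
    )
    return out, counts


def recode_categorical(answer: str, mapping: Mapping[str, int]) -> int:
    """Map a categorical answer option to its numeric code."""
    try:
        return mapping[answer]
    except KeyError:
        raise KeyError(f"unknown category {answer!r}") from None


def recode_series(values: pd.Series, mapping: Mapping[str, int]) -> pd.Series:
    """Vectorized :func:`recode_categorical`; unmapped answers raise."""
    out = values.map(mapping)
    if out.isna().any() and not values.isna().all():
        bad = sorted(set(values[out.isna()].dropna()))
        if bad:
            raise KeyError(f"unknown categories {bad}")
    return out
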