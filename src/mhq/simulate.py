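"""Synthetic respondent cohorts with the statistical structure the
validation battery assumes.

The generative model is a one-factor ordered-categorical response model:
each respondent carries a latent well-being trait theta (a two-component
normal mixture, the smaller component representing the unwell tail seen in
population data). Each element's *healthy propensity* is

    h_e = loading * theta + group_loading_g * u_g + sigma_e * eps_e,

where u_g is an extra factor shared by semantically related elements
(self-image/self-worth, the sleep pair, the mood pair) and eps_e is
idiosyncratic, with sigma_e chosen so h_e has unit variance. Ratings
discretize the propensity linearly around a per-element baseline: spectrum
elements rate high when healthy, problem elements rate low. Retakes redraw
theta and the shared factors with stability rho; the idiosyncratic part
carries a small persistent person-by-item component (stable individual
quirks in how specific items are read) plus transient noise, which is what
lets single-item retest reliability exceed the between-item correlations.

Conditional submodels mirror the study's auxiliary measurements: probe
frequency is binomial over 7 days with mean linear in the life-impact
rating anchored at 5 days/week for a rating of 8; probe severity is a
shifted binomial over the 5 ordered levels, also linear in the rating;
absenteeism days decay exponentially in the composite score and
presenteeism days decay linearly, both with overdispersed count noise.

Defaults were frozen after a grid calibration of the loading, group
loadings, baseline spreads and retest stability against the package's
anchored reliability/validity statistics (see docs/methods.md).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .instrument import (
    ElementBank,
    EMPLOYMENT_STATUSES,
    Roster,
    load_element_bank,
)

# rng stream ids so each operation draws from an independent, reproducible stream
_STREAM_COHORT = 0
_STREAM_RETEST = 1
_STREAM_PROBE = 2
_STREAM_PRODUCTIVITY = 3


class TraitModel(BaseModel):
    """Normal-mixture shape of the latent well-being trait.

    The draw is standardized to zero mean and unit variance, so the mixture
    sets only the distribution's shape (the smaller, low-mean component is
    the unwell tail); loadings and baselines are calibrated against a
    unit-variance trait.
    """

    weights: list[float] = [0.78, 0.22]
    means: list[float] = [0.2, -2.2]
    sds: list[float] = [0.95, 1.15]

    def moments(self) -> tuple[float, float]:
        w = np.asarray(self.weights)
        mu = np.asarray(self.means)
        sd = np.asarray(self.sds)
        mean = float(w @ mu)
        var = float(w @ (sd**2 + mu**2) - mean**2)
        return mean, var

    @model_validator(mode="after")
    def _check(self) -> "TraitModel":
        if not (len(self.weights) == len(self.means) == len(self.sds)):
            raise ValueError("mixture component lists must share a length")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if any(w < 0 for w in self.weights) or any(s <= 0 for s in self.sds):
            raise ValueError("weights must be >= 0 and sds > 0")
        return self


class ResponseModel(BaseModel):
    """Ordered-categorical response model parameters."""

    loading: float = 0.60
    rating_scale: float = 2.0
    group_loadings: dict[str, float] = {
        "self_regard": 0.67,
        "sleep": 0.57,
        "mood": 0.54,
    }
    spectrum_baseline_range: tuple[float, float] = (5.2, 8.0)
    problem_baseline_range: tuple[float, float] = (1.6, 4.6)
    baseline_overrides: dict[str, float] = {"sadness": 3.6, "sleep_quality": 6.2}
    mood_question_baseline: float = 6.3
    sufficiency_thresholds: tuple[float, float, float] = (-1.2, -0.3, 0.9)

    @model_validator(mode="after")
    def _check(self) -> "ResponseModel":
        for g, gamma in self.group_loadings.items():
            if self.loading**2 + gamma**2 >= 1.0:
                raise ValueError(
                    f"loading^2 + group loading^2 must be < 1 (group {g!r})"
                )
        if not 0 < self.loading < 1:
            raise ValueError("loading must lie in (0, 1)")
        return self

    def baselines(self, bank: ElementBank) -> dict[str, float]:
        """Per-element rating baseline, evenly spread within each format."""
        out: dict[str, float] = {}
        for ids, (lo, hi) in (
            (bank.spectrum_ids, self.spectrum_baseline_range),
            (bank.problem_ids, self.problem_baseline_range),
        ):
            values = np.linspace(lo, hi, len(ids))
            out.update(dict(zip(ids, values)))
        out.update(self.baseline_overrides)
        return out


class RetestModel(BaseModel):
    """Retake model: latent stability plus a gap-day distribution.

    ``gap_probs`` deliberately includes mass below 3 days so the pairing
    rule's exclusion of same-day/next-day retakes is exercised.
    """

    fraction: float = 1.0
    stability: float = 0.91
    item_stability: float = 0.15
    gap_probs: dict[str, float] = {
        "0-2": 0.15,
        "3-7": 0.12,
        "8-30": 0.30,
        "31-60": 0.18,
        "61-120": 0.15,
        "121-450": 0.10,
    }

    @model_validator(mode="after")
    def _check(self) -> "RetestModel":
        if not 0 <= self.fraction <= 1:
            raise ValueError("fraction must lie in [0, 1]")
        if not 0 <= self.stability <= 1:
            raise ValueError("stability must lie in [0, 1]")
        if not 0 <= self.item_stability <= 1:
            raise ValueError("item_stability must lie in [0, 1]")
        if abs(sum(self.gap_probs.values()) - 1.0) > 1e-9:
            raise ValueError("gap_probs must sum to 1")
        for key in self.gap_probs:
            lo, hi = key.split("-")
            if int(lo) > int(hi):
                raise ValueError(f"bad gap stratum {key!r}")
        return self


class ProbeModel(BaseModel):
    """Frequency/severity probe conditional on the probed element's rating.

    Mean frequency is linear in the rating and anchored so a rating of 8
    corresponds to 5 days/week on average; extrapolated to a rating of 1 it
    stays below 1 day/week.
    """

    element_id: str = "sadness"
    min_rating: int = 5
    freq_slope: float = 0.65
    freq_intercept: float = -0.2
    severity_slope: float = 0.4
    severity_intercept: float = 0.4

    def freq_mean(self, rating: np.ndarray) -> np.ndarray:
        return self.freq_intercept + self.freq_slope * np.asarray(rating, dtype=float)

    def severity_mean(self, rating: np.ndarray) -> np.ndarray:
        return self.severity_intercept + self.severity_slope * np.asarray(
            rating, dtype=float
        )


class ProductivityModel(BaseModel):
    """Days-missed and reduced-productivity days conditional on the score.

    E[M | s] = a*exp(-b*s) + c; E[R | s] = intercept + slope*s; counts are
    drawn negative-binomial (variance mean + mean^2/dispersion) and clamped
    to the answer range 0..31.
    """

    absent_a: float = 2.43
    absent_b: float = 0.0207
    absent_c: float = 0.15
    reduced_intercept: float = 10.7
    reduced_slope: float = -0.04
    dispersion: float = 2.0
    max_days: int = 31

    def absent_mean(self, score: np.ndarray) -> np.ndarray:
        return self.absent_a * np.exp(-self.absent_b * np.asarray(score)) + self.absent_c

    def reduced_mean(self, score: np.ndarray) -> np.ndarray:
        return np.maximum(
            self.reduced_intercept + self.reduced_slope * np.asarray(score), 0.05
        )


class Demographics(BaseModel):
    age_range: tuple[int, int] = (18, 85)
    gender_probs: dict[str, float] = {"female": 0.58, "male": 0.40, "nonbinary": 0.02}
    country_probs: dict[str, float] = {
        "United States": 0.45,
        "India": 0.18,
        "United Kingdom": 0.12,
        "Canada": 0.06,
        "Australia": 0.06,
        "South Africa": 0.04,
        "New Zealand": 0.03,
        "Ireland": 0.02,
        "Singapore": 0.02,
        "Nigeria": 0.02,
    }
    employment_probs: dict[str, float] = {
        "employed": 0.55,
        "homemaker": 0.06,
        "unemployed": 0.12,
        "retired": 0.08,
        "studying": 0.15,
        "not_able_to_work": 0.04,
    }

    @model_validator(mode="after")
    def _check(self) -> "Demographics":
        for name, probs in (
            ("gender_probs", self.gender_probs),
            ("country_probs", self.country_probs),
            ("employment_probs", self.employment_probs),
        ):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if set(self.employment_probs) != set(EMPLOYMENT_STATUSES):
            raise ValueError("employment_probs must cover the answer options")
        return self


class GeneratorConfig(BaseModel):
    """Full parameterization of a synthetic cohort."""

    n: int = 10000
    seed: int = 0
    trait: TraitModel = Field(default_factory=TraitModel)
    response: ResponseModel = Field(default_factory=ResponseModel)
    retest: RetestModel = Field(default_factory=RetestModel)
    probe: ProbeModel = Field(default_factory=ProbeModel)
    productivity: ProductivityModel = Field(default_factory=ProductivityModel)
    demographics: Demographics = Field(default_factory=Demographics)
    easy_prob: float = 0.9742
    first_attempt_day_range: tuple[int, int] = (0, 180)

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if not 0 <= self.easy_prob <= 1:
            raise ValueError("easy_prob must lie in [0, 1]")
        return self


def default_config(**overrides) -> GeneratorConfig:
    return GeneratorConfig(**overrides)


def load_config(path) -> GeneratorConfig:
    """Read a generator configuration from YAML (validation errors are itemized)."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return GeneratorConfig(**raw)


def save_config(config: GeneratorConfig, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _draw_trait(trait: TraitModel, n: int, rng: np.random.Generator) -> np.ndarray:
    component = rng.choice(len(trait.weights), size=n, p=trait.weights)
    raw = rng.normal(np.take(trait.means, component), np.take(trait.sds, component))
    mean, var = trait.moments()
    return (raw - mean) / np.sqrt(var)


def _ratings_from_latents(
    bank: ElementBank,
    response: ResponseModel,
    theta: np.ndarray,
    group_factors: Mapping[str, np.ndarray],
    eps: np.ndarray,
) -> pd.DataFrame:
    """Discretize propensities into ratings; ``eps`` is the (n, 47)
    standard-normal idiosyncratic component, one column per bank element."""
    lam = response.loading
    c = response.rating_scale
    baselines = response.baselines(bank)
    cols: dict[str, np.ndarray] = {}
    for j, e in enumerate(bank):
        gamma = response.group_loadings.get(e.related_group, 0.0) if e.related_group else 0.0
        shared = gamma * group_factors[e.related_group] if gamma else 0.0
        sigma = np.sqrt(max(1.0 - lam**2 - gamma**2, 1e-12))
        h = lam * theta + shared + sigma * eps[:, j]
        mu = baselines[e.element_id]
        raw = mu + c * h if e.format == "spectrum" else mu - c * h
        cols[e.element_id] = np.clip(np.rint(raw), 1, 9).astype(int)
    return pd.DataFrame(cols)


def _sleep_sufficiency(
    response: ResponseModel,
    theta: np.ndarray,
    u_sleep: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    lam = response.loading
    gamma = response.group_loadings.get("sleep", 0.0)
    sigma = np.sqrt(max(1.0 - lam**2 - gamma**2, 1e-12))
    h = lam * theta + gamma * u_sleep + sigma * rng.normal(size=len(theta))
    t1, t2, t3 = response.sufficiency_thresholds
    labels = np.array(["hardly ever", "some of the time", "most of the time",
                       "all the time"])
    idx = np.searchsorted([t1, t2, t3], h, side="right")
    return labels[idx]


def _current_mood(
    response: ResponseModel,
    theta: np.ndarray,
    u_mood: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    lam = response.loading
    gamma = response.group_loadings.get("mood", 0.0)
    sigma = np.sqrt(max(1.0 - lam**2 - gamma**2, 1e-12))
    h = lam * theta + gamma * u_mood + sigma * rng.normal(size=len(theta))
    raw = response.mood_question_baseline + response.rating_scale * h
    return np.clip(np.rint(raw), 1, 9).astype(int)


def _choice(rng: np.random.Generator, probs: Mapping[str, float], n: int) -> np.ndarray:
    keys = list(probs)
    return rng.choice(keys, size=n, p=[probs[k] for k in keys])


def generate_cohort(config: GeneratorConfig, bank: ElementBank | None = None) -> Roster:
    """Generate a cohort of first attempts; latent state is kept on the roster."""
    bank = bank or load_element_bank()
    rng = _rng(config, _STREAM_COHORT)
    n = config.n

    theta = _draw_trait(config.trait, n, rng)
    groups = bank.related_groups()
    groups.setdefault("mood", [])  # the mood pair includes a non-bank question
    group_factors = {g: rng.normal(size=n) for g in sorted(groups)}
    eps = rng.normal(size=(n, len(bank)))

    ratings = _ratings_from_latents(bank, config.response, theta, group_factors, eps)

    lo, hi = config.demographics.age_range
    day_lo, day_hi = config.first_attempt_day_range
    meta = pd.DataFrame(
        {
            "respondent_id": [f"r{config.seed:04d}x{i:07d}" for i in range(n)],
            "attempt_day": rng.integers(day_lo, day_hi + 1, size=n),
            "age": rng.integers(lo, hi + 1, size=n),
            "gender": _choice(rng, config.demographics.gender_probs, n),
            "country": _choice(rng, config.demographics.country_probs, n),
            "employment_status": _choice(rng, config.demographics.employment_probs, n),
            "easy_to_understand": rng.random(n) < config.easy_prob,
            "sleep_sufficiency": _sleep_sufficiency(
                config.response, theta, group_factors["sleep"], rng
            ),
            "current_mood": _current_mood(
                config.response, theta, group_factors["mood"], rng
            ),
        }
    )
    data = pd.concat([meta, ratings], axis=1)
    latent = pd.DataFrame({"theta": theta})
    for g, u in group_factors.items():
        latent[f"u_{g}"] = u
    for j, eid in enumerate(bank.element_ids):
        latent[f"eps_{eid}"] = eps[:, j]
    return Roster(
        data=data,
        provenance={"generator": "mhq.simulate", "seed": config.seed, "n": n},
        latent=latent,
    )


def generate_retests(
    roster: Roster, config: GeneratorConfig, bank: ElementBank | None = None
) -> Roster:
    """Second attempts for a subset of the cohort.

    Person-level latents are redrawn with stability rho (theta' =
    rho*theta + sqrt(1-rho^2)*noise, likewise each shared factor). The
    idiosyncratic element component mixes the stored person-by-item draw
    (weight ``item_stability``) with transient noise, so element ratings are
    less stable than the aggregate score but more stable than the shared
    trait alone would make them. Gap days follow the configured stratum
    distribution, including gaps below 3 days that the pairing rule must
    exclude.
    """
    if roster.latent is None:
        raise ValueError("roster lacks stored latent state; regenerate the cohort")
    bank = bank or load_element_bank()
    rng = _rng(config, _STREAM_RETEST)
    n = len(roster)
    take = rng.random(n) < config.retest.fraction
    idx = np.flatnonzero(take)
    m = len(idx)

    rho = config.retest.stability
    fresh = np.sqrt(1.0 - rho**2)
    theta2 = rho * roster.latent["theta"].to_numpy()[idx] + fresh * rng.normal(size=m)
    group_factors = {}
    for col in roster.latent.columns:
        if col.startswith("u_"):
            g = col[2:]
            group_factors[g] = (
                rho * roster.latent[col].to_numpy()[idx] + fresh * rng.normal(size=m)
            )

    rho_item = config.retest.item_stability
    eps_cols = [f"eps_{eid}" for eid in bank.element_ids]
    eps1 = roster.latent[eps_cols].to_numpy()[idx]
    eps2 = rho_item * eps1 + np.sqrt(1.0 - rho_item**2) * rng.normal(
        size=(m, len(bank))
    )

    ratings = _ratings_from_latents(bank, config.response, theta2, group_factors, eps2)

    strata = list(config.retest.gap_probs)
    chosen = rng.choice(len(strata), size=m, p=list(config.retest.gap_probs.values()))
    gaps = np.empty(m, dtype=int)
    for i, key in enumerate(strata):
        lo, hi = (int(v) for v in key.split("-"))
        mask = chosen == i
        gaps[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))

    first = roster.data.iloc[idx].reset_index(drop=True)
    meta = first[
        ["respondent_id", "age", "gender", "country", "employment_status"]
    ].copy()
    meta.insert(1, "attempt_day", first["attempt_day"].to_numpy() + gaps)
    meta["easy_to_understand"] = rng.random(m) < config.easy_prob
    meta["sleep_sufficiency"] = _sleep_sufficiency(
        config.response, theta2, group_factors["sleep"], rng
    )
    meta["current_mood"] = _current_mood(
        config.response, theta2, group_factors["mood"], rng
    )
    data = pd.concat([meta.reset_index(drop=True), ratings], axis=1)
    latent = pd.DataFrame({"theta": theta2})
    for g, u in group_factors.items():
        latent[f"u_{g}"] = u
    for j, eid in enumerate(bank.element_ids):
        latent[f"eps_{eid}"] = eps2[:, j]
    return Roster(
        data=data,
        provenance={"generator": "mhq.simulate.retests", "seed": config.seed},
        latent=latent,
    )


def generate_probes(
    roster: Roster, config: GeneratorConfig
) -> pd.DataFrame:
    """Frequency/severity probe answers for respondents whose probed-element
    rating is >= 5. Frequency is Binomial(7, p) and severity 1 + Binomial(4, p),
    with p set so the conditional means are linear in the rating."""
    probe = config.probe
    rng = _rng(config, _STREAM_PROBE)
    ratings = roster.data[probe.element_id].to_numpy(dtype=int)
    mask = ratings >= probe.min_rating
    r = ratings[mask]
    m = len(r)

    p_freq = np.clip(probe.freq_mean(r) / 7.0, 0.0, 1.0)
    frequency = rng.binomial(7, p_freq, size=m)
    p_sev = np.clip((probe.severity_mean(r) - 1.0) / 4.0, 0.0, 1.0)
    severity = 1 + rng.binomial(4, p_sev, size=m)

    return pd.DataFrame(
        {
            "respondent_id": roster.data["respondent_id"].to_numpy()[mask],
            "life_impact": r,
            "frequency": frequency,
            "severity": severity,
        }
    )


def generate_productivity(
    scored: pd.DataFrame, config: GeneratorConfig
) -> pd.DataFrame:
    """Days-missed / reduced-productivity answers for a scored roster table.

    ``scored`` must carry ``mhq_score``. Counts are negative binomial with
    the configured mean functions, clamped to the 0..31 answer range.
    """
    model = config.productivity
    rng = _rng(config, _STREAM_PRODUCTIVITY)
    score = scored["mhq_score"].to_numpy(dtype=float)
    out = {}
    for col, mean in (
        ("days_missed", model.absent_mean(score)),
        ("reduced_days", model.reduced_mean(score)),
    ):
        k = model.dispersion
        p = k / (k + mean)
        draws = rng.negative_binomial(k, p)
        out[col] = np.minimum(draws, model.max_days)
    return pd.DataFrame(
        {"respondent_id": scored["respondent_id"].to_numpy(), **out},
        index=scored.index,
    )
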