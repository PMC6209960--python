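"""Synthetic survey generator with planted latent segments and risk factors.

The generator emulates the statistical structure the analysis pipeline
assumes: a metropolitan adult survey of ~4,749 respondents with ~9% diagnosed
type-2-diabetes prevalence, where

* every respondent belongs to one of three latent socioeconomic *segments*
  whose modal-category indicator profiles mirror the reference diabetic
  cluster profiles (private-insured working, retired publicly insured, and
  disadvantaged segments);
* segment membership shapes the 11 informative socioeconomic indicators
  (modal category drawn with probability ``adherence``, a background
  distribution otherwise) while 24 further candidate indicators are pure
  background noise;
* diabetes is assigned by a logistic model in the biometric risk factors
  (high blood pressure, age >= 45, body-mass index), so biological variables
  dominate prediction while socioeconomic profiles cluster the diagnosed —
  segments influence biometrics only through segment-specific age, blood
  pressure, and BMI distributions;
* respondents live in 28 areas with heterogeneous segment mixtures; a few
  areas are strongly enriched for a single segment, creating the planted
  "vulnerable neighborhood" signal;
* survey weights are lognormal and strictly positive.

The logistic intercept and the population segment mixture are calibrated by
a seeded pilot simulation so that the realized prevalence matches the target
and the realized segment shares *within the diabetic subpopulation* match the
configured shares (which are stated as shares of the diabetic population).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .data_model import (
    AGE_BINS,
    IndicatorSchema,
    PROFILE_INDICATORS,
    SurveyTable,
    _age_bin,
    candidate_indicators,
    default_schema,
)


class ConfigError(ValueError):
    """Raised for infeasible generator configurations."""


# modal profiles mirroring the three reference diabetic clusters
_SEGMENT_PROFILES: dict[str, dict[str, str]] = {
    "working-insured": {
        "health_insurance": "Private",
        "age_group": "55-64",
        "public_programs": "None",
        "employment": "Employed",
        "fpl_category": ">=400%",
        "difficulty_buying_food": "Never",
        "days_poor_health": "0",
        "race_ethnicity": "White NH",
        "general_health": "Good",
        "social_support": "Low",
        "physical_activity": "Active/highly active",
    },
    "retired-public": {
        "health_insurance": "Public",
        "age_group": "65+",
        "public_programs": "None",
        "employment": "Unemployed",
        "fpl_category": "200-399.9%",
        "difficulty_buying_food": "Never",
        "days_poor_health": "0",
        "race_ethnicity": "White NH",
        "general_health": "Good",
        "social_support": "Medium",
        "physical_activity": "Active/highly active",
    },
    "disadvantaged": {
        "health_insurance": "Public",
        "age_group": "65+",
        "public_programs": "1+",
        "employment": "Unemployed",
        "fpl_category": "<100%",
        "difficulty_buying_food": "Rarely/sometimes",
        "days_poor_health": "8+",
        "race_ethnicity": "Black NH",
        "general_health": "Fair/poor",
        "social_support": "Low",
        "physical_activity": "Somewhat active",
    },
}

_AGE_BIN_RANGES = {"20-44": (20, 44), "45-54": (45, 54), "55-64": (55, 64), "65+": (65, 90)}

#: young-skewed age-bin background so the non-modal 20% of segment draws
#: resemble a general adult population rather than the diabetic profile ages
_AGE_BACKGROUND = {"age_group": (0.55, 0.17, 0.15, 0.13)}


@dataclass(frozen=True)
class SegmentSpec:
    """A planted diabetic-population segment.

    ``share`` is the segment's share of the *diabetic* population.  With
    probability ``adherence`` a member draws its modal category on each
    informative indicator, otherwise a draw from ``background`` (uniform over
    the variable's categories when unspecified).  ``bmi_log_mean`` /
    ``bmi_log_sd`` parameterize the lognormal body-mass index and
    ``hbp_logit_shift`` shifts the age-driven blood-pressure propensity.
    """

    label: str
    share: float
    modal_profile: Mapping[str, str]
    adherence: float = 0.8
    background: Mapping[str, Sequence[float]] | None = None
    bmi_log_mean: float = np.log(28.0)
    bmi_log_sd: float = 0.17
    hbp_logit_shift: float = 0.0

    def __post_init__(self) -> None:
        if not 0.5 < self.adherence <= 1.0:
            raise ConfigError(
                f"segment {self.label!r}: adherence must lie in (0.5, 1], got {self.adherence}"
            )


@dataclass(frozen=True)
class RiskModel:
    """Logistic diabetes model: logit p = intercept + b_hbp·HBP + b_age45·1[age>=45] + b_bmi·BMI.

    ``intercept=None`` requests calibration to the prevalence target.
    """

    intercept: float | None = None
    beta_hbp: float = 1.7
    beta_age45: float = 1.1
    beta_bmi: float = 0.055


def default_segments() -> tuple[SegmentSpec, ...]:
    return (
        SegmentSpec("working-insured", 0.494, _SEGMENT_PROFILES["working-insured"],
                    background=_AGE_BACKGROUND, bmi_log_mean=np.log(28.5)),
        SegmentSpec("retired-public", 0.284, _SEGMENT_PROFILES["retired-public"],
                    background=_AGE_BACKGROUND, bmi_log_mean=np.log(27.0)),
        SegmentSpec("disadvantaged", 0.222, _SEGMENT_PROFILES["disadvantaged"],
                    background=_AGE_BACKGROUND, bmi_log_mean=np.log(30.0)),
    )


@dataclass(frozen=True)
class GeneratorConfig:
    n_respondents: int = 4749
    prevalence_target: float = 0.091
    segments: tuple[SegmentSpec, ...] = field(default_factory=default_segments)
    n_areas: int = 28
    #: Dirichlet concentration scaling for non-enriched per-area mixtures
    area_mixing: float = 25.0
    #: number of leading areas each strongly enriched for one segment (round-robin)
    n_enriched_areas: int = 3
    #: mixture weight placed on the enriched segment within an enriched area
    enrichment: float = 0.75
    #: Dirichlet concentration for heterogeneous area population sizes
    #: (enriched areas are pinned at the average size so both selection
    #: dimensions — share and concentration — respond to enrichment)
    area_size_spread: float = 6.0
    #: (log-mean, log-sd) of lognormal survey weights
    weight_distribution: tuple[float, float] = (6.2, 0.7)
    risk_model: RiskModel = field(default_factory=RiskModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prevalence_target < 1:
            raise ConfigError("prevalence_target must lie in (0, 1)")
        if len(self.segments) < 1:
            raise ConfigError("at least one segment required")
        total = sum(s.share for s in self.segments)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"segment shares must sum to 1, got {total}")
        if self.area_mixing <= 0 or self.enrichment <= 0:
            raise ConfigError("concentration parameters must be positive")
        if self.n_areas < 1 or self.n_respondents < 1:
            raise ConfigError("n_areas and n_respondents must be positive")


@dataclass
class Truth:
    """Hidden generation truth: per-respondent labels plus planted structure."""

    frame: pd.DataFrame  # respondent_id, segment, area, age, hbp, bmi, p_diabetes, diabetes
    intercept: float
    population_shares: dict[str, float]
    area_mixtures: pd.DataFrame  # area x segment mixture weights
    enriched_areas: dict[str, str]  # area code -> enriched segment label
    config: GeneratorConfig


def _area_codes(n: int) -> list[str]:
    return [f"A{i + 1:02d}" for i in range(n)]


def _background_probs(var_categories: Sequence[str], spec: SegmentSpec, name: str) -> np.ndarray:
    if spec.background and name in spec.background:
        p = np.asarray(spec.background[name], dtype=float)
        if p.size != len(var_categories) or p.min() < 0 or not np.isclose(p.sum(), 1.0):
            raise ConfigError(f"segment {spec.label!r}: bad background for {name!r}")
        return p
    return np.full(len(var_categories), 1.0 / len(var_categories))


def _draw_profile_value(rng: np.random.Generator, var, spec: SegmentSpec, n: int) -> np.ndarray:
    """Vector of category draws for one informative indicator, one segment."""
    cats = np.asarray(var.categories, dtype=object)
    modal = spec.modal_profile[var.name]
    if modal not in var.categories:
        raise ConfigError(f"segment {spec.label!r}: {modal!r} not a category of {var.name!r}")
    back = _background_probs(var.categories, spec, var.name)
    use_modal = rng.random(n) < spec.adherence
    draws = cats[rng.choice(len(cats), size=n, p=back)]
    draws[use_modal] = modal
    return draws


def _draw_ages(rng: np.random.Generator, bins: np.ndarray) -> np.ndarray:
    ages = np.empty(len(bins), dtype=int)
    for label, (lo, hi) in _AGE_BIN_RANGES.items():
        mask = bins == label
        if mask.any():
            ages[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))
    return ages


def _hbp_prob(age: np.ndarray, shift: float) -> np.ndarray:
    # age-driven propensity; roughly one third positive at the default mix
    base = 0.04 + 0.55 * expit((age - 62.0) / 10.0)
    logit = np.log(base / (1.0 - base)) + shift
    return expit(logit)


def _simulate_biometrics(
    rng: np.random.Generator, spec: SegmentSpec, schema: IndicatorSchema, n: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw (age_group, age, hbp, bmi) for n members of one segment."""
    age_var = schema["age_group"]
    bins = _draw_profile_value(rng, age_var, spec, n)
    ages = _draw_ages(rng, bins)
    hbp = rng.random(n) < _hbp_prob(ages, spec.hbp_logit_shift)
    bmi = np.exp(rng.normal(spec.bmi_log_mean, spec.bmi_log_sd, size=n))
    return bins, ages, hbp, bmi


def _linear_predictor(risk: RiskModel, hbp: np.ndarray, age: np.ndarray, bmi: np.ndarray) -> np.ndarray:
    return (
        risk.beta_hbp * hbp.astype(float)
        + risk.beta_age45 * (age >= 45).astype(float)
        + risk.beta_bmi * bmi
    )


def _calibrate(config: GeneratorConfig, rng: np.random.Generator, schema: IndicatorSchema,
               pilot_size: int = 1500) -> tuple[float, np.ndarray]:
    """Solve the logistic intercept and population segment shares.

    A pilot simulation per segment yields linear predictors eta; with
    population shares pi_s proportional to share_s / pbar_s(c), the realized
    diabetic-population shares equal the configured shares and overall
    prevalence equals 1 / sum_s share_s / pbar_s(c).  The intercept c is the
    root of that prevalence identity (unless supplied explicitly).
    """
    etas = []
    for spec in config.segments:
        _, ages, hbp, bmi = _simulate_biometrics(rng, spec, schema, pilot_size)
        etas.append(_linear_predictor(config.risk_model, hbp, ages, bmi))

    shares = np.array([s.share for s in config.segments])

    def pbar(c: float) -> np.ndarray:
        return np.array([float(expit(c + e).mean()) for e in etas])

    if config.risk_model.intercept is None:
        def f(c: float) -> float:
            return 1.0 / float((shares / pbar(c)).sum()) - config.prevalence_target

        intercept = float(brentq(f, -25.0, 10.0, xtol=1e-10))
    else:
        intercept = float(config.risk_model.intercept)
    p = pbar(intercept)
    pi = shares / p
    pi = pi / pi.sum()
    return intercept, pi


def _area_mixture_matrix(
    config: GeneratorConfig, rng: np.random.Generator, pi: np.ndarray
) -> tuple[np.ndarray, dict[str, str]]:
    codes = _area_codes(config.n_areas)
    S = len(config.segments)
    mix = np.empty((config.n_areas, S))
    enriched: dict[str, str] = {}
    n_enr = min(config.n_enriched_areas, config.n_areas)
    for a in range(config.n_areas):
        if a < n_enr and S > 1:
            s = a % S
            rest = pi.copy()
            rest[s] = 0.0
            rest = rest / rest.sum() * (1.0 - config.enrichment)
            mix[a] = rest
            mix[a, s] = config.enrichment
            enriched[codes[a]] = config.segments[s].label
        else:
            mix[a] = rng.dirichlet(config.area_mixing * pi)
    return mix, enriched


def generate(config: GeneratorConfig | None = None, *, seed: int | None = None) -> tuple[SurveyTable, Truth]:
    """Generate a synthetic survey table plus its hidden truth sidecar.

    Deterministic given ``config.seed`` (``seed`` overrides it).  The
    realized diabetes prevalence lands within about two percentage points of
    the target for n >= 2000.
    """
    config = config or GeneratorConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    schema = default_schema()
    ss = np.random.SeedSequence(config.seed)
    rng_pilot, rng_area, rng_pop, rng_outcome = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    intercept, pi = _calibrate(config, rng_pilot, schema)
    mix, enriched = _area_mixture_matrix(config, rng_area, pi)
    codes = _area_codes(config.n_areas)
    n = config.n_respondents
    S = len(config.segments)

    # heterogeneous area population sizes; enriched areas at the mean size
    n_enr = len(enriched)
    area_probs = np.full(config.n_areas, 1.0 / config.n_areas)
    if config.n_areas > n_enr:
        rest = rng_area.dirichlet(
            np.full(config.n_areas - n_enr, config.area_size_spread)
        )
        area_probs[n_enr:] = rest * (1.0 - n_enr / config.n_areas)
    area_idx = rng_pop.choice(config.n_areas, size=n, p=area_probs)
    # per-respondent segment from the area's mixture
    u = rng_pop.random(n)
    cum = np.cumsum(mix, axis=1)
    seg_idx = (u[:, None] > cum[area_idx]).sum(axis=1)

    data = pd.DataFrame(index=range(n))
    data["respondent_id"] = [f"R{i + 1:05d}" for i in range(n)]
    data["weight"] = np.exp(rng_pop.normal(*config.weight_distribution, size=n))
    data["area"] = np.asarray(codes, dtype=object)[area_idx]

    age_group = np.empty(n, dtype=object)
    age = np.empty(n, dtype=int)
    hbp = np.empty(n, dtype=bool)
    bmi = np.empty(n, dtype=float)
    informative = [v for v in PROFILE_INDICATORS if v != "age_group"]
    columns: dict[str, np.ndarray] = {v: np.empty(n, dtype=object) for v in informative}
    for s, spec in enumerate(config.segments):
        mask = seg_idx == s
        m = int(mask.sum())
        if m == 0:
            continue
        bins, ages, h, b = _simulate_biometrics(rng_pop, spec, schema, m)
        age_group[mask], age[mask], hbp[mask], bmi[mask] = bins, ages, h, b
        for v in informative:
            columns[v][mask] = _draw_profile_value(rng_pop, schema[v], spec, m)

    eta = intercept + _linear_predictor(config.risk_model, hbp, age, bmi)
    p_diab = expit(eta)
    diabetes = rng_outcome.random(n) < p_diab

    data["diabetes"] = diabetes
    for v in PROFILE_INDICATORS:
        data[v] = age_group if v == "age_group" else columns[v]
    # noise indicators: uniform background, independent of segments
    noise = [v for v in candidate_indicators(schema) if v not in PROFILE_INDICATORS]
    for v in noise:
        cats = np.asarray(schema[v].categories, dtype=object)
        data[v] = cats[rng_pop.integers(0, len(cats), size=n)]
    data["high_blood_pressure"] = np.where(hbp, "Yes", "No")
    data["bmi"] = np.round(bmi, 2)
    data["age"] = age.astype(float)

    order = ["respondent_id", "weight", "area", "diabetes"] + schema.names
    table = SurveyTable(schema, data[order])

    labels = np.asarray([s.label for s in config.segments], dtype=object)
    truth_frame = pd.DataFrame(
        {
            "respondent_id": data["respondent_id"],
            "segment": labels[seg_idx],
            "area": data["area"],
            "age": age,
            "hbp": hbp,
            "bmi": bmi,
            "p_diabetes": p_diab,
            "diabetes": diabetes,
        }
    )
    truth = Truth(
        frame=truth_frame,
        intercept=intercept,
        population_shares={s.label: float(pi[i]) for i, s in enumerate(config.segments)},
        area_mixtures=pd.DataFrame(mix, index=codes, columns=labels),
        enriched_areas=enriched,
        config=config,
    )
    return table, truth


def _odds_ratio(flag: np.ndarray, outcome: np.ndarray) -> float:
    """Unweighted odds ratio with a 0.5 continuity correction."""
    a = float(np.sum(flag & outcome)) + 0.5
    b = float(np.sum(flag & ~outcome)) + 0.5
    c = float(np.sum(~flag & outcome)) + 0.5
    d = float(np.sum(~flag & ~outcome)) + 0.5
    return (a * d) / (b * c)


def plant_truth_report(table: SurveyTable, truth: Truth) -> dict:
    """Tabulate the realized planted structure for recovery tests.

    Reports realized prevalence, diabetic-subpopulation segment shares,
    per-area segment enrichment (dominant segment and its realized share of
    area respondents), and unweighted risk-factor odds ratios.
    """
    df = table.data
    tf = truth.frame
    if not df["respondent_id"].equals(tf["respondent_id"]):
        raise ValueError("truth sidecar does not match the table")

    diab = tf.loc[tf["diabetes"]]
    shares = (diab["segment"].value_counts(normalize=True)).to_dict()
    seg_labels = [s.label for s in truth.config.segments]
    diabetic_shares = {s: float(shares.get(s, 0.0)) for s in seg_labels}

    area_tab = (
        tf.groupby("area")["segment"].value_counts(normalize=True).unstack(fill_value=0.0)
    )
    dominant = {
        a: {"segment": str(area_tab.loc[a].idxmax()), "share": float(area_tab.loc[a].max())}
        for a in area_tab.index
    }

    outcome = tf["diabetes"].to_numpy()
    report = {
        "n_respondents": int(len(df)),
        "realized_prevalence": float(outcome.mean()),
        "diabetic_segment_shares": diabetic_shares,
        "area_dominant_segment": dominant,
        "enriched_areas": dict(truth.enriched_areas),
        "odds_ratios": {
            "hbp": _odds_ratio(tf["hbp"].to_numpy(), outcome),
            "age45": _odds_ratio(tf["age"].to_numpy() >= 45, outcome),
            "high_bmi": _odds_ratio(tf["bmi"].to_numpy() > 26.93, outcome),
        },
    }
    return report
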