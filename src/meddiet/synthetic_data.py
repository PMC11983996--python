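"""Synthetic matched case-control cohorts for the diet-adherence pipeline.

No raw data accompany the study this pipeline models, so every stage is
exercised on generated cohorts that mimic its structure: 1:1 pairs matched
on sex, centre and age (+/- 5 years), FFQ-style item-level intakes in
g/day, and Table-1-style covariate marginals.

Two generation modes, deliberately distinct:

* ``marginal`` — case and control covariates are drawn independently from
  their respective configured marginals (status is fixed by design). This
  reproduces *realized* case/control contrasts and is used for plumbing
  and calibration checks; it encodes no causal diet effect.
* ``mechanistic`` — both pair members are drawn from one common population
  model; each member's adherence score is computed against the
  generator-known true sex-specific medians, and the case is assigned
  within the pair with the exact conditional probability
  exp(x1.b) / (exp(x1.b) + exp(x2.b)), where b places the configured true
  log-odds-ratios on the score-category indicators. The fitted
  conditional-logistic model is therefore correctly specified by
  construction, which is what parameter-recovery and type-I-error
  simulations require.

Intakes are log-normal per component and sex (right-skewed, non-negative
— the standard shape for dietary data). The intake medians and the
composition table shipped here are *synthetic defaults*, chosen to be
plausible for a North-African diet; they are not study values.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import md_score
from .food_composition import FOOD_COMPONENTS, SCORED_COMPONENTS

AGE_BOUNDS = (18.0, 95.0)
CENTRES = ("Rabat", "Casablanca", "Marrakech", "Oujda", "Fez")
SUBSITES = ("colon", "rectum", "other")

#: Synthetic food-composition table: ~30 items spanning every component
#: plus olive oil and other non-component fats. Densities are
#: literature-plausible per 100 g; ``weight`` splits a component's total
#: g/day across its member items. Non-authoritative.
DEFAULT_FCT: tuple[dict, ...] = (
    {"item_id": "CER01", "name": "wheat bread", "component": "cereals", "weight": 0.50, "energy": 265.0, "sfa": 0.40, "mufa": 0.30},
    {"item_id": "CER02", "name": "couscous (semolina)", "component": "cereals", "weight": 0.30, "energy": 112.0, "sfa": 0.05, "mufa": 0.02},
    {"item_id": "CER03", "name": "rice", "component": "cereals", "weight": 0.20, "energy": 130.0, "sfa": 0.08, "mufa": 0.09},
    {"item_id": "DAI01", "name": "milk", "component": "dairy", "weight": 0.50, "energy": 61.0, "sfa": 1.90, "mufa": 0.80},
    {"item_id": "DAI02", "name": "lben (buttermilk)", "component": "dairy", "weight": 0.20, "energy": 38.0, "sfa": 0.60, "mufa": 0.30},
    {"item_id": "DAI03", "name": "yogurt", "component": "dairy", "weight": 0.20, "energy": 61.0, "sfa": 2.10, "mufa": 0.90},
    {"item_id": "DAI04", "name": "cream", "component": "dairy", "weight": 0.10, "energy": 195.0, "sfa": 12.00, "mufa": 5.50},
    {"item_id": "LEG01", "name": "lentils", "component": "legumes", "weight": 0.40, "energy": 116.0, "sfa": 0.06, "mufa": 0.07},
    {"item_id": "LEG02", "name": "white beans", "component": "legumes", "weight": 0.40, "energy": 127.0, "sfa": 0.08, "mufa": 0.05},
    {"item_id": "LEG03", "name": "chickpeas", "component": "legumes", "weight": 0.20, "energy": 164.0, "sfa": 0.27, "mufa": 0.60},
    {"item_id": "FRU01", "name": "fresh fruit", "component": "fruits_nuts", "weight": 0.60, "energy": 52.0, "sfa": 0.05, "mufa": 0.01},
    {"item_id": "FRU02", "name": "dates", "component": "fruits_nuts", "weight": 0.20, "energy": 282.0, "sfa": 0.03, "mufa": 0.04},
    {"item_id": "FRU03", "name": "olives", "component": "fruits_nuts", "weight": 0.10, "energy": 115.0, "sfa": 1.80, "mufa": 7.90},
    {"item_id": "FRU04", "name": "nuts and almonds", "component": "fruits_nuts", "weight": 0.10, "energy": 607.0, "sfa": 4.50, "mufa": 32.00},
    {"item_id": "VEG01", "name": "tomatoes", "component": "vegetables", "weight": 0.30, "energy": 18.0, "sfa": 0.03, "mufa": 0.01},
    {"item_id": "VEG02", "name": "leafy greens", "component": "vegetables", "weight": 0.30, "energy": 23.0, "sfa": 0.04, "mufa": 0.01},
    {"item_id": "VEG03", "name": "other vegetables", "component": "vegetables", "weight": 0.40, "energy": 35.0, "sfa": 0.05, "mufa": 0.02},
    {"item_id": "FIS01", "name": "sardines", "component": "fish", "weight": 0.60, "energy": 208.0, "sfa": 1.50, "mufa": 3.90},
    {"item_id": "FIS02", "name": "white fish", "component": "fish", "weight": 0.40, "energy": 82.0, "sfa": 0.30, "mufa": 0.20},
    {"item_id": "POU01", "name": "chicken", "component": "poultry", "weight": 0.80, "energy": 165.0, "sfa": 1.00, "mufa": 1.20},
    {"item_id": "POU02", "name": "turkey", "component": "poultry", "weight": 0.20, "energy": 135.0, "sfa": 0.80, "mufa": 0.70},
    {"item_id": "RED01", "name": "beef and lamb", "component": "red_meat", "weight": 0.70, "energy": 250.0, "sfa": 6.00, "mufa": 6.50},
    {"item_id": "RED02", "name": "processed meat", "component": "red_meat", "weight": 0.30, "energy": 300.0, "sfa": 10.00, "mufa": 9.00},
    {"item_id": "ALC01", "name": "beer", "component": "alcohol", "weight": 0.70, "energy": 43.0, "sfa": 0.00, "mufa": 0.00},
    {"item_id": "ALC02", "name": "wine", "component": "alcohol", "weight": 0.30, "energy": 83.0, "sfa": 0.00, "mufa": 0.00},
    {"item_id": "OIL01", "name": "olive oil", "component": "none", "weight": 1.00, "energy": 884.0, "sfa": 13.80, "mufa": 73.00, "olive_oil": True},
    {"item_id": "OTH01", "name": "sugar", "component": "none", "weight": 1.00, "energy": 387.0, "sfa": 0.00, "mufa": 0.00},
    {"item_id": "OTH02", "name": "butter", "component": "none", "weight": 1.00, "energy": 717.0, "sfa": 51.40, "mufa": 21.00},
    {"item_id": "OTH03", "name": "mint tea", "component": "none", "weight": 1.00, "energy": 1.0, "sfa": 0.00, "mufa": 0.00},
    {"item_id": "OTH04", "name": "pastry and sweets", "component": "none", "weight": 1.00, "energy": 450.0, "sfa": 8.00, "mufa": 6.00},
)

#: Synthetic per-sex log-normal intake models, (median g/day, geometric SD).
#: Men consume more legumes, fruits/nuts, fish, red meat and dairy, per the
#: qualitative sex contrast the score's reference medians reflect.
DEFAULT_INTAKE = {
    "cereals": {"M": (350.0, 1.5), "F": (320.0, 1.5)},
    "dairy": {"M": (160.0, 1.8), "F": (130.0, 1.8)},
    "legumes": {"M": (60.0, 1.8), "F": (48.0, 1.8)},
    "fruits_nuts": {"M": (230.0, 1.7), "F": (200.0, 1.7)},
    "vegetables": {"M": (300.0, 1.5), "F": (300.0, 1.5)},
    "fish": {"M": (42.0, 2.0), "F": (33.0, 2.0)},
    "poultry": {"M": (55.0, 1.8), "F": (55.0, 1.8)},
    "red_meat": {"M": (65.0, 1.8), "F": (50.0, 1.8)},
    "alcohol": {"M": (2.0, 4.0), "F": (1.0, 4.0)},
}

#: Intake models for non-component items (item_id -> per-sex (median, GSD)).
DEFAULT_EXTRA_INTAKE = {
    "OIL01": {"M": (25.0, 1.8), "F": (22.0, 1.8)},
    "OTH01": {"M": (30.0, 1.6), "F": (28.0, 1.6)},
    "OTH02": {"M": (5.0, 2.5), "F": (5.0, 2.5)},
    "OTH03": {"M": (400.0, 1.5), "F": (400.0, 1.5)},
    "OTH04": {"M": (20.0, 2.2), "F": (22.0, 2.2)},
}

#: Case/control covariate marginals. Values marked (study) are the printed
#: in-text Table-1 contrasts; the rest are synthetic defaults completing
#: each distribution.
DEFAULT_MARGINALS = {
    "residence": {  # urban share: (study) 69.2 % cases v. 75.7 % controls
        "case": {"urban": 0.692, "rural": 0.308},
        "control": {"urban": 0.757, "rural": 0.243},
    },
    "education": {  # synthetic; controls better educated (study, direction only)
        "case": {"illiterate": 0.55, "primary": 0.25, "secondary": 0.13, "higher": 0.07},
        "control": {"illiterate": 0.48, "primary": 0.26, "secondary": 0.16, "higher": 0.10},
    },
    "income": {  # synthetic; modest incomes predominate (study, direction only)
        "case": {"low": 0.70, "medium": 0.24, "high": 0.06},
        "control": {"low": 0.68, "medium": 0.25, "high": 0.07},
    },
    "smoking": {  # never/current shares (study): 77.6/12.1 cases, 83.8/6.2 controls
        "case": {"never": 0.776, "ex": 0.103, "current": 0.121},
        "control": {"never": 0.838, "ex": 0.100, "current": 0.062},
    },
    "bmi_category": {  # obese share (study): 15.8 % cases v. 8.7 % controls
        "case": {"normal": 0.500, "underweight": 0.060, "overweight": 0.282, "obese": 0.158},
        "control": {"normal": 0.550, "underweight": 0.060, "overweight": 0.303, "obese": 0.087},
    },
    "activity": {  # high/low shares (study): 21.7/33.9 cases, 26.6/22.2 controls
        "case": {"low": 0.339, "moderate": 0.444, "high": 0.217},
        "control": {"low": 0.222, "moderate": 0.512, "high": 0.266},
    },
    "family_history": {  # synthetic
        "case": {"no": 0.92, "yes": 0.08},
        "control": {"no": 0.96, "yes": 0.04},
    },
    "nsaid": {  # synthetic
        "case": {"no": 0.90, "yes": 0.10},
        "control": {"no": 0.85, "yes": 0.15},
    },
}

#: Continuous value band sampled uniformly within each reported category.
BMI_BANDS = {"underweight": (16.0, 18.5), "normal": (18.5, 25.0),
             "overweight": (25.0, 30.0), "obese": (30.0, 40.0)}
MET_BANDS = {"low": (0.0, 600.0), "moderate": (600.0, 3000.0), "high": (3000.0, 6000.0)}


class ConfigError(ValueError):
    """Raised for an invalid generator configuration."""


@dataclass
class GeneratorConfig:
    """Full description of a synthetic cohort.

    ``age`` holds (mean, SD) of recruitment age per status; ``marginals``
    the per-status categorical distributions; ``intake`` the per-component,
    per-sex log-normal (median g/day, geometric SD); ``true_log_or`` the
    conditional log-odds-ratios on the medium/high score-category
    indicators used by mechanistic case assignment, with optional
    per-subsite overrides in ``subsite_log_or``.
    """

    n_pairs: int = 1516
    mode: str = "marginal"  # marginal | mechanistic
    sex_male_prob: float = 0.5
    age: dict = field(default_factory=lambda: {"case": (56.4, 13.9), "control": (55.5, 13.7)})
    age_caliper: float = 5.0
    marginals: dict = field(default_factory=lambda: _deepcopy(DEFAULT_MARGINALS))
    intake: dict = field(default_factory=lambda: _deepcopy(DEFAULT_INTAKE))
    extra_intake: dict = field(default_factory=lambda: _deepcopy(DEFAULT_EXTRA_INTAKE))
    true_log_or: dict = field(default_factory=lambda: {"medium": 0.0, "high": 0.0})
    subsite_log_or: dict = field(default_factory=dict)
    subsite_probs: dict = field(default_factory=lambda: {"colon": 0.4, "rectum": 0.5, "other": 0.1})

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ConfigError("n_pairs must be >= 1")
        if self.mode not in ("marginal", "mechanistic"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.age_caliper <= 0:
            raise ConfigError("age caliper must be positive")
        for var, per_status in self.marginals.items():
            for status, probs in per_status.items():
                total = sum(probs.values())
                if abs(total - 1.0) > 1e-9:
                    raise ConfigError(
                        f"marginal {var}/{status} sums to {total}, not 1"
                    )
                if any(p < 0 for p in probs.values()):
                    raise ConfigError(f"marginal {var}/{status} has a negative probability")
        for comp, per_sex in {**self.intake, **self.extra_intake}.items():
            for sex, (median, gsd) in per_sex.items():
                if median <= 0 or gsd <= 1.0:
                    raise ConfigError(
                        f"intake {comp}/{sex}: median must be > 0 and geometric SD > 1"
                    )
        if not abs(sum(self.subsite_probs.values()) - 1.0) < 1e-9:
            raise ConfigError("subsite probabilities must sum to 1")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "GeneratorConfig":
        raw = yaml.safe_load(text) or {}
        raw["age"] = {k: tuple(v) for k, v in raw.get("age", {}).items()} or None
        kwargs = {k: v for k, v in raw.items() if v is not None}
        for key in ("intake", "extra_intake"):
            if key in kwargs:
                kwargs[key] = {
                    comp: {sex: tuple(mv) for sex, mv in per_sex.items()}
                    for comp, per_sex in kwargs[key].items()
                }
        return cls(**kwargs)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _deepcopy(obj):
    import copy

    return copy.deepcopy(obj)


def default_config(**overrides) -> GeneratorConfig:
    """The default study-shaped configuration (1516 pairs, printed marginals)."""
    return GeneratorConfig(**overrides)


@dataclass
class SyntheticCohort:
    """A generated cohort in the pipeline's own input formats."""

    subjects: pd.DataFrame  # indexed by subject_id
    intake: pd.DataFrame  # subject x item, g/day
    fct: pd.DataFrame  # composition-table rows, loader dialect
    config: GeneratorConfig
    seed: int
    mode: str
    truth: dict | None = None  # mechanistic only: true medians + true scores


def fct_frame() -> pd.DataFrame:
    """The synthetic FCT as a loader-dialect DataFrame."""
    rows = [
        {
            "item_id": it["item_id"], "name": it["name"], "component": it["component"],
            "energy_kcal_per_100g": it["energy"], "sfa_g_per_100g": it["sfa"],
            "mufa_g_per_100g": it["mufa"], "is_olive_oil": int(it.get("olive_oil", False)),
        }
        for it in DEFAULT_FCT
    ]
    return pd.DataFrame(rows)


def _lognormal(rng: np.random.Generator, median: float, gsd: float, size: int) -> np.ndarray:
    return rng.lognormal(mean=np.log(median), sigma=np.log(gsd), size=size)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, size: int) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _draw_categorical(rng: np.random.Generator, probs: dict[str, float], size: int) -> np.ndarray:
    levels = list(probs)
    return rng.choice(levels, size=size, p=[probs[k] for k in levels])


def _component_intakes(rng: np.random.Generator, config: GeneratorConfig,
                       sex: np.ndarray) -> pd.DataFrame:
    """Draw per-subject component totals and non-component item intakes."""
    n = len(sex)
    out = {}
    for comp in FOOD_COMPONENTS:
        values = np.empty(n)
        for s in ("M", "F"):
            mask = sex == s
            median, gsd = config.intake[comp][s]
            values[mask] = _lognormal(rng, median, gsd, int(mask.sum()))
        out[comp] = values
    for item_id, per_sex in config.extra_intake.items():
        values = np.empty(n)
        for s in ("M", "F"):
            mask = sex == s
            median, gsd = per_sex[s]
            values[mask] = _lognormal(rng, median, gsd, int(mask.sum()))
        out[item_id] = values
    return pd.DataFrame(out)


def _intake_matrix(draws: pd.DataFrame, subject_ids: list[str]) -> pd.DataFrame:
    """Split component totals across member items by the fixed FCT weights."""
    cols = {}
    for it in DEFAULT_FCT:
        if it["component"] == "none":
            cols[it["item_id"]] = draws[it["item_id"]].to_numpy()
        else:
            cols[it["item_id"]] = it["weight"] * draws[it["component"]].to_numpy()
    matrix = pd.DataFrame(cols, index=pd.Index(subject_ids, name="subject_id"))
    return matrix


def _sfa_mufa_coefficients() -> tuple[dict[str, float], dict[str, float], dict[str, float]]:
    """Per-component SFA g/day per g of component, and per-item densities."""
    sfa_by_comp: dict[str, float] = {c: 0.0 for c in FOOD_COMPONENTS}
    sfa_items: dict[str, float] = {}
    mufa_oo: dict[str, float] = {}
    for it in DEFAULT_FCT:
        if it["component"] == "none":
            sfa_items[it["item_id"]] = it["sfa"] / 100.0
            if it.get("olive_oil"):
                mufa_oo[it["item_id"]] = it["mufa"] / 100.0
        else:
            sfa_by_comp[it["component"]] += it["weight"] * it["sfa"] / 100.0
    return sfa_by_comp, sfa_items, mufa_oo


def _ratio_from_draws(draws: pd.DataFrame) -> np.ndarray:
    sfa_by_comp, sfa_items, mufa_oo = _sfa_mufa_coefficients()
    sfa = sum(draws[c].to_numpy() * k for c, k in sfa_by_comp.items())
    sfa = sfa + sum(draws[i].to_numpy() * k for i, k in sfa_items.items())
    mufa = sum(draws[i].to_numpy() * k for i, k in mufa_oo.items())
    return mufa / sfa


_TRUE_MEDIAN_SEED = 987654321
_TRUE_MEDIAN_DRAWS = 200_000
_median_cache: dict[str, pd.DataFrame] = {}


def true_median_table(config: GeneratorConfig) -> pd.DataFrame:
    """Generator-known true sex-specific medians of the ten scored components.

    Food-component medians are the configured log-normal medians exactly;
    the MUFA/SFA-ratio median has no closed form under the item model and
    is estimated once by a large fixed-seed Monte-Carlo draw, so it is
    deterministic given the configuration.
    """
    key = yaml.safe_dump({"intake": config.intake, "extra": config.extra_intake},
                         sort_keys=True)
    if key in _median_cache:
        return _median_cache[key].copy()
    table = pd.DataFrame(index=list(SCORED_COMPONENTS), columns=["M", "F"], dtype=float)
    for comp in FOOD_COMPONENTS:
        for s in ("M", "F"):
            table.loc[comp, s] = config.intake[comp][s][0]
    rng = np.random.default_rng(_TRUE_MEDIAN_SEED)
    for s in ("M", "F"):
        draws = _component_intakes(rng, config, np.repeat(s, _TRUE_MEDIAN_DRAWS))
        table.loc["mufa_sfa_ratio", s] = float(np.median(_ratio_from_draws(draws)))
    _median_cache[key] = table.copy()
    return table


def _true_scores(draws: pd.DataFrame, sex: np.ndarray, subject_ids: list[str],
                 medians: pd.DataFrame) -> pd.DataFrame:
    comp = draws[list(FOOD_COMPONENTS)].copy()
    comp.index = pd.Index(subject_ids, name="subject_id")
    comp["mufa_sfa_ratio"] = _ratio_from_draws(draws)
    comp["ratio_defined"] = True
    subjects = pd.DataFrame({"sex": sex}, index=comp.index)
    return md_score.score_subjects(comp, subjects, medians)


def generate_cohort(config: GeneratorConfig | None = None, seed: int = 0) -> SyntheticCohort:
    """Generate one matched cohort; identical (config, seed) gives identical output."""
    config = config or default_config()
    rng = np.random.default_rng(seed)
    n_pairs = config.n_pairs
    n = 2 * n_pairs

    pair_ids = [f"P{i:05d}" for i in range(n_pairs)]
    sex_pair = np.where(rng.random(n_pairs) < config.sex_male_prob, "M", "F")
    centre_pair = rng.choice(CENTRES, size=n_pairs)
    sex = np.repeat(sex_pair, 2)

    lo, hi = AGE_BOUNDS
    if config.mode == "marginal":
        status = np.tile(["case", "control"], n_pairs)
        mean_c, sd_c = config.age["case"]
        case_age = _truncnorm(rng, mean_c, sd_c, lo, hi, n_pairs)
        mean_k, sd_k = config.age["control"]
        # control age from its own marginal, truncated to the pair caliper
        # (slightly shrunk so 2-decimal rounding cannot breach it)
        caliper = config.age_caliper - 0.01
        lo_k = np.maximum(lo, case_age - caliper)
        hi_k = np.minimum(hi, case_age + caliper)
        a = (lo_k - mean_k) / sd_k
        b = (hi_k - mean_k) / sd_k
        control_age = stats.truncnorm.rvs(a, b, loc=mean_k, scale=sd_k,
                                          size=n_pairs, random_state=rng)
        age = np.empty(n)
        age[0::2], age[1::2] = case_age, control_age
        covariates = _draw_status_covariates(rng, config, status)
        subsite_case = _draw_categorical(rng, config.subsite_probs, n_pairs)
        subsite = np.where(status == "case", np.repeat(subsite_case, 2), "")
        draws = _component_intakes(rng, config, sex)
        truth = None
    else:
        half = (config.age_caliper - 0.01) / 2.0
        mid = 0.5 * (config.age["case"][0] + config.age["control"][0])
        sd = 0.5 * (config.age["case"][1] + config.age["control"][1])
        base = _truncnorm(rng, mid, sd, lo + half, hi - half, n_pairs)
        age = np.repeat(base, 2) + rng.uniform(-half, half, size=n)
        covariates = _draw_status_covariates(
            rng, config, np.repeat("control", n)  # common population model
        )
        subsite_case = _draw_categorical(rng, config.subsite_probs, n_pairs)
        draws = _component_intakes(rng, config, sex)
        medians = true_median_table(config)
        provisional_ids = [f"S{i:05d}" for i in range(n)]
        scores = _true_scores(draws, sex, provisional_ids, medians)
        # within-pair case assignment: exact conditional probability
        beta = {"medium": float(config.true_log_or.get("medium", 0.0)),
                "high": float(config.true_log_or.get("high", 0.0))}
        eta = np.zeros(n)
        cats = scores["category"].to_numpy()
        for i_pair, sub in enumerate(subsite_case):
            b = config.subsite_log_or.get(sub, beta)
            for m in (2 * i_pair, 2 * i_pair + 1):
                eta[m] = float(b.get(cats[m], 0.0)) if isinstance(b, dict) else 0.0
        p_first = 1.0 / (1.0 + np.exp(eta[1::2] - eta[0::2]))
        first_is_case = rng.random(n_pairs) < p_first
        status = np.empty(n, dtype=object)
        status[0::2] = np.where(first_is_case, "case", "control")
        status[1::2] = np.where(first_is_case, "control", "case")
        subsite = np.where(status == "case", np.repeat(subsite_case, 2), "")
        truth = {"medians": medians, "scores": scores,
                 "log_or": beta, "subsite_log_or": config.subsite_log_or}

    subject_ids = [f"S{i:05d}" for i in range(n)]
    subjects = pd.DataFrame(
        {
            "pair_id": np.repeat(pair_ids, 2),
            "status": status,
            "sex": sex,
            "age": np.round(age, 2),
            "centre": np.repeat(centre_pair, 2),
            "subsite": subsite,
            "residence": covariates["residence"],
            "education": covariates["education"],
            "income": covariates["income"],
            "smoking": covariates["smoking"],
            "bmi": covariates["bmi"],
            "met_minutes": covariates["met_minutes"],
            "family_history": covariates["family_history"],
            "nsaid": covariates["nsaid"],
        },
        index=pd.Index(subject_ids, name="subject_id"),
    )
    intake = _intake_matrix(draws, subject_ids)
    if truth is not None:
        truth["scores"].index = subjects.index
    return SyntheticCohort(subjects=subjects, intake=intake, fct=fct_frame(),
                           config=config, seed=seed, mode=config.mode, truth=truth)


def _draw_status_covariates(rng: np.random.Generator, config: GeneratorConfig,
                            status: np.ndarray) -> dict[str, np.ndarray]:
    n = len(status)
    out: dict[str, np.ndarray] = {}
    drawn: dict[str, np.ndarray] = {}
    for var, per_status in config.marginals.items():
        values = np.empty(n, dtype=object)
        for st in ("case", "control"):
            mask = status == st
            if mask.any():
                values[mask] = _draw_categorical(rng, per_status[st], int(mask.sum()))
        drawn[var] = values
    out["residence"] = drawn["residence"]
    out["education"] = drawn["education"]
    out["income"] = drawn["income"]
    out["smoking"] = drawn["smoking"]
    out["family_history"] = (drawn["family_history"] == "yes").astype(int)
    out["nsaid"] = (drawn["nsaid"] == "yes").astype(int)
    # continuous BMI / MET values drawn uniformly within the sampled category band
    bmi = np.empty(n)
    for cat, (lo, hi) in BMI_BANDS.items():
        mask = drawn["bmi_category"] == cat
        bmi[mask] = rng.uniform(lo, hi - 1e-9, int(mask.sum()))
    out["bmi"] = np.round(bmi, 2)
    met = np.empty(n)
    for cat, (lo, hi) in MET_BANDS.items():
        mask = drawn["activity"] == cat
        met[mask] = rng.uniform(lo, hi - 1e-9, int(mask.sum()))
    out["met_minutes"] = np.round(met, 1)
    return out


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write subjects.csv, intake.csv and fct.csv in the loader dialects.

    Mechanistic cohorts additionally get generator-truth files
    (true_medians.tsv, true_scores.tsv) and every cohort a provenance
    block (provenance.yaml) holding config, seed and mode.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "subjects": out_dir / "subjects.csv",
        "intake": out_dir / "intake.csv",
        "fct": out_dir / "fct.csv",
        "provenance": out_dir / "provenance.yaml",
    }
    cohort.subjects.to_csv(paths["subjects"])
    cohort.intake.to_csv(paths["intake"])
    cohort.fct.to_csv(paths["fct"], index=False)
    prov = {"seed": cohort.seed, "mode": cohort.mode,
            "config_digest": cohort.config.digest(),
            "config": yaml.safe_load(cohort.config.to_yaml())}
    paths["provenance"].write_text(yaml.safe_dump(prov, sort_keys=True))
    if cohort.truth is not None:
        paths["true_medians"] = out_dir / "true_medians.tsv"
        cohort.truth["medians"].to_csv(paths["true_medians"], sep="\t")
        paths["true_scores"] = out_dir / "true_scores.tsv"
        cohort.truth["scores"].to_csv(paths["true_scores"], sep="\t")
    return paths
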