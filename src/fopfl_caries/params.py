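"""Model parameters: domain types, validation, config file I/O, and defaults.

The model is parameterised per population stratum (sex x age band: added-sugar
intake in g/day, annual caries incidence probability, 2017 reference
population size) plus global blocks for economics (restoration unit cost,
discount rate, GDP per capita, per-lesion DALY components), the labeling
intervention (fractional sugar reduction, sugar-caries dose-response slope),
and simulation controls (horizon, cohort size, seed, common random numbers).

Configs are plain YAML mappings with keys exactly matching the field names
here; unknown keys are rejected so typos surface as errors rather than
silently falling back to defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import yaml

__all__ = [
    "SEXES",
    "AGE_BANDS",
    "UNIT_COST_PRESETS",
    "PER_LESION_DALY",
    "ConfigError",
    "ValidationError",
    "DalyParams",
    "Stratum",
    "EconomicParams",
    "InterventionParams",
    "SimControls",
    "ModelConfig",
    "load_config",
    "write_config",
    "default_config",
]

SEXES = ("male", "female")
AGE_BANDS = ("15-18", "19-24", "25-34", "35-50", "51-64", "65-80")

#: Disease burden per restored lesion, implied by the headline German totals
#: (677.62 DALYs over 2,370,715 lesions).
PER_LESION_DALY = 677.62 / 2_370_715

#: Euro per 1-surface restoration. "base" is the conservative statutory fee;
#: "copayment" and "restoration_failure" are derived scenario unit costs
#: (published scenario totals divided by total lesions), for one-line
#: alternate-cost analyses.
UNIT_COST_PRESETS = {
    "base": 74.10,
    "copayment": 118.11,
    "restoration_failure": 148.73,
}

DEFAULT_GDP_PER_CAPITA = 40_332.0
DEFAULT_SLOPE = 0.002  # absolute annual incidence reduction per g/day sugar


class ConfigError(ValueError):
    """Config file cannot be parsed or has a malformed structure."""


class ValidationError(ValueError):
    """A parameter violates its documented bounds or invariants."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class DalyParams:
    """Components of the per-lesion DALY: DALY = p_symptomatic * duration * disability_weight."""

    p_symptomatic: float = PER_LESION_DALY / (0.010 * 0.1)
    duration: float = 0.1
    disability_weight: float = 0.010

    def __post_init__(self) -> None:
        _check(0.0 <= self.p_symptomatic <= 1.0, "p_symptomatic must be in [0,1]")
        _check(self.duration > 0.0, "duration must be > 0")
        _check(0.0 <= self.disability_weight <= 1.0, "disability_weight must be in [0,1]")
        # zero components are allowed (they switch DALY accounting off)
        _check(0.0 <= self.per_lesion < 1.0, "per-lesion DALY must be in [0,1)")

    @property
    def per_lesion(self) -> float:
        return self.p_symptomatic * self.duration * self.disability_weight


@dataclass(frozen=True)
class Stratum:
    """One sex x age-band population cell."""

    sex: str
    age_band: str
    sugar_intake: float  # grams added sugar per person per day
    incidence: float  # annual probability of >=1 new caries lesion
    population: int  # persons in the 2017 reference population

    def __post_init__(self) -> None:
        _check(self.sex in SEXES, f"sex must be one of {SEXES}")
        _check(self.age_band in AGE_BANDS, f"age_band must be one of {AGE_BANDS}")
        _check(self.sugar_intake > 0.0, "sugar_intake must be > 0")
        _check(0.0 <= self.incidence <= 1.0, "incidence must be in [0,1]")
        _check(int(self.population) == self.population and self.population >= 0,
               "population must be a non-negative integer")

    @property
    def label(self) -> str:
        return f"{self.sex} {self.age_band}"

    @property
    def order_key(self) -> tuple[int, int]:
        """Canonical (sex, age_band) position: males first, youngest first."""
        return (SEXES.index(self.sex), AGE_BANDS.index(self.age_band))


@dataclass(frozen=True)
class EconomicParams:
    unit_cost: float = UNIT_COST_PRESETS["base"]  # EUR per 1-surface restoration
    discount_rate: float = 0.03  # annual, applied to benefits and costs
    gdp_per_capita: float = DEFAULT_GDP_PER_CAPITA  # EUR per DALY (CMH approach)
    daly_per_lesion_params: DalyParams = field(default_factory=DalyParams)

    def __post_init__(self) -> None:
        _check(self.unit_cost > 0.0, "unit_cost must be > 0")
        _check(self.discount_rate >= 0.0, "discount_rate must be >= 0")
        _check(self.gdp_per_capita > 0.0, "gdp_per_capita must be > 0")


@dataclass(frozen=True)
class InterventionParams:
    effect_fraction: float = 0.066  # fractional reduction in added-sugar intake
    sugar_caries_slope: float = DEFAULT_SLOPE
    dose_response: str = "absolute"  # "absolute" or "relative" risk reduction

    def __post_init__(self) -> None:
        _check(0.0 <= self.effect_fraction <= 1.0, "effect_fraction must be in [0,1]")
        _check(self.sugar_caries_slope >= 0.0, "sugar_caries_slope must be >= 0")
        _check(self.dose_response in ("absolute", "relative"),
               "dose_response must be 'absolute' or 'relative'")


@dataclass(frozen=True)
class SimControls:
    horizon: int = 10  # years
    n_individuals: int = 500_000  # persons simulated per stratum
    seed: int = 2017
    common_random_numbers: bool = True

    def __post_init__(self) -> None:
        _check(int(self.horizon) == self.horizon and self.horizon >= 1, "horizon must be >= 1")
        _check(int(self.n_individuals) == self.n_individuals and self.n_individuals >= 1,
               "n_individuals must be >= 1")
        _check(int(self.seed) == self.seed and self.seed >= 0, "seed must be a non-negative integer")


@dataclass(frozen=True)
class ModelConfig:
    strata: tuple[Stratum, ...]
    economics: EconomicParams = field(default_factory=EconomicParams)
    intervention: InterventionParams = field(default_factory=InterventionParams)
    controls: SimControls = field(default_factory=SimControls)
    implementation_cost_range: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        strata = tuple(sorted(self.strata, key=lambda s: s.order_key))
        object.__setattr__(self, "strata", strata)
        _check(len(strata) == len(SEXES) * len(AGE_BANDS),
               f"expected {len(SEXES) * len(AGE_BANDS)} strata, got {len(strata)}")
        keys = {(s.sex, s.age_band) for s in strata}
        _check(len(keys) == len(strata), "duplicate (sex, age_band) stratum")
        if self.implementation_cost_range is not None:
            lo, hi = self.implementation_cost_range
            _check(0.0 <= lo <= hi, "implementation_cost_range must satisfy 0 <= low <= high")
            object.__setattr__(self, "implementation_cost_range", (float(lo), float(hi)))

    def stratum(self, sex: str, age_band: str) -> Stratum:
        for s in self.strata:
            if s.sex == sex and s.age_band == age_band:
                return s
        raise KeyError((sex, age_band))

    def with_effect(self, effect_fraction: float) -> "ModelConfig":
        return replace(self, intervention=replace(self.intervention,
                                                  effect_fraction=effect_fraction))


# --------------------------------------------------------------------------
# Config file I/O

def _expect_mapping(node, context: str) -> dict:
    if not isinstance(node, dict):
        raise ConfigError(f"{context}: expected a mapping, got {type(node).__name__}")
    return node


def _take(mapping: dict, known: Sequence[str], context: str) -> None:
    unknown = set(mapping) - set(known)
    if unknown:
        raise ConfigError(f"{context}: unknown key(s) {sorted(unknown)}")


def _build_stratum(node, i: int) -> Stratum:
    node = _expect_mapping(node, f"strata[{i}]")
    _take(node, ("sex", "age_band", "sugar_intake", "incidence", "population"), f"strata[{i}]")
    for key in ("sex", "age_band", "sugar_intake", "incidence", "population"):
        if key not in node:
            raise ConfigError(f"strata[{i}]: missing key '{key}'")
    return Stratum(
        sex=str(node["sex"]),
        age_band=str(node["age_band"]),
        sugar_intake=float(node["sugar_intake"]),
        incidence=float(node["incidence"]),
        population=int(node["population"]),
    )


def _build_economics(node) -> EconomicParams:
    node = _expect_mapping(node, "economics")
    _take(node, ("unit_cost", "discount_rate", "gdp_per_capita", "daly_per_lesion"), "economics")
    kwargs = {}
    for key in ("unit_cost", "discount_rate", "gdp_per_capita"):
        if key in node:
            kwargs[key] = float(node[key])
    if "daly_per_lesion" in node:
        dnode = _expect_mapping(node["daly_per_lesion"], "economics.daly_per_lesion")
        _take(dnode, ("p_symptomatic", "duration", "disability_weight"),
              "economics.daly_per_lesion")
        kwargs["daly_per_lesion_params"] = DalyParams(
            **{k: float(v) for k, v in dnode.items()})
    return EconomicParams(**kwargs)


def _build_intervention(node) -> InterventionParams:
    node = _expect_mapping(node, "intervention")
    _take(node, ("effect_fraction", "sugar_caries_slope", "dose_response"), "intervention")
    kwargs = {k: float(node[k]) for k in ("effect_fraction", "sugar_caries_slope") if k in node}
    if "dose_response" in node:
        kwargs["dose_response"] = str(node["dose_response"])
    return InterventionParams(**kwargs)


def _build_controls(node) -> SimControls:
    node = _expect_mapping(node, "controls")
    _take(node, ("horizon", "n_individuals", "seed", "common_random_numbers"), "controls")
    kwargs = {k: int(node[k]) for k in ("horizon", "n_individuals", "seed") if k in node}
    if "common_random_numbers" in node:
        kwargs["common_random_numbers"] = bool(node["common_random_numbers"])
    return SimControls(**kwargs)


def load_config(path) -> ModelConfig:
    """Read and validate a YAML model configuration.

    Missing optional blocks fall back to the documented defaults; the
    ``strata`` list is required and must contain exactly one entry per
    (sex, age band) combination. Raises :class:`ConfigError` for structural
    problems and :class:`ValidationError` for out-of-bounds values.
    """
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML: {exc}") from exc
    doc = _expect_mapping(doc, str(path))
    _take(doc, ("strata", "economics", "intervention", "controls",
                "implementation_cost_range"), str(path))
    if "strata" not in doc:
        raise ConfigError(f"{path}: missing required key 'strata'")
    if not isinstance(doc["strata"], list):
        raise ConfigError(f"{path}: 'strata' must be a list")
    strata = tuple(_build_stratum(s, i) for i, s in enumerate(doc["strata"]))
    kwargs = {}
    if "economics" in doc:
        kwargs["economics"] = _build_economics(doc["economics"])
    if "intervention" in doc:
        kwargs["intervention"] = _build_intervention(doc["intervention"])
    if "controls" in doc:
        kwargs["controls"] = _build_controls(doc["controls"])
    if "implementation_cost_range" in doc and doc["implementation_cost_range"] is not None:
        rng = doc["implementation_cost_range"]
        if not (isinstance(rng, (list, tuple)) and len(rng) == 2):
            raise ConfigError("implementation_cost_range must be [low, high]")
        kwargs["implementation_cost_range"] = (float(rng[0]), float(rng[1]))
    return ModelConfig(strata=strata, **kwargs)


def config_to_dict(config: ModelConfig) -> dict:
    """Plain-python representation matching the config file schema."""
    doc = {
        "strata": [
            {
                "sex": s.sex,
                "age_band": s.age_band,
                "sugar_intake": float(s.sugar_intake),
                "incidence": float(s.incidence),
                "population": int(s.population),
            }
            for s in config.strata
        ],
        "economics": {
            "unit_cost": float(config.economics.unit_cost),
            "discount_rate": float(config.economics.discount_rate),
            "gdp_per_capita": float(config.economics.gdp_per_capita),
            "daly_per_lesion": {
                "p_symptomatic": float(config.economics.daly_per_lesion_params.p_symptomatic),
                "duration": float(config.economics.daly_per_lesion_params.duration),
                "disability_weight": float(
                    config.economics.daly_per_lesion_params.disability_weight),
            },
        },
        "intervention": {
            "effect_fraction": float(config.intervention.effect_fraction),
            "sugar_caries_slope": float(config.intervention.sugar_caries_slope),
            "dose_response": config.intervention.dose_response,
        },
        "controls": {
            "horizon": int(config.controls.horizon),
            "n_individuals": int(config.controls.n_individuals),
            "seed": int(config.controls.seed),
            "common_random_numbers": bool(config.controls.common_random_numbers),
        },
    }
    if config.implementation_cost_range is not None:
        doc["implementation_cost_range"] = [float(x) for x in config.implementation_cost_range]
    return doc


def write_config(config: ModelConfig, path) -> None:
    """Write a config as YAML; ``load_config`` round-trips all fields exactly."""
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


def default_config(seed: int = 2017) -> ModelConfig:
    """The packaged German-like default parameter set.

    Economics, intervention, and control defaults are the documented
    base-case values; the 12 strata are synthetic German-like inputs drawn
    with a fixed seed (2017, the reference year) so the default model is
    fully reproducible without any external data.
    """
    from .synth import SyntheticSpec, generate_strata

    strata = generate_strata(SyntheticSpec(seed=seed))
    return ModelConfig(
        strata=tuple(strata),
        implementation_cost_range=(5.29e6, 9.56e6),
    )
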