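"""Synthetic German-like per-stratum inputs.

Real inputs for this model (national nutrition-survey sugar intakes, GBD-style
caries incidences, census population sizes) are not redistributable, so the
pipeline ships a generator producing parameter sets with the same qualitative
structure: 12 strata (2 sexes x 6 age bands), male intakes above female
intakes within every band, intake highest in the youngest band and declining
with age, with a slight terminal uptick so the lowest-consumption stratum is
women aged 51-64 — the pattern reported for Germany (highest: boys 15-18;
lowest: women 51-64).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import AGE_BANDS, SEXES, Stratum, ModelConfig, ValidationError

__all__ = ["SyntheticSpec", "generate_strata", "extreme_strata"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Controls for the synthetic input generator.

    ``age_gradient`` gives one multiplicative factor per age band applied to
    the youngest band's intake; the default declines through the 51-64 band
    and rises slightly for 65-80, mirroring the reported German intake
    profile. ``male_excess`` scales male intake above female within each band.
    """

    seed: int = 2017
    sugar_range: tuple[float, float] = (40.0, 100.0)  # g/day stratum means
    male_excess: float = 1.15
    age_gradient: tuple[float, ...] = (1.0, 0.95, 0.88, 0.80, 0.72, 0.74)
    incidence_range: tuple[float, float] = (0.15, 0.35)  # annual probability
    population_scale: float = 1_000_000  # persons per stratum

    def __post_init__(self) -> None:
        lo, hi = self.sugar_range
        if not (0 < lo < hi):
            raise ValidationError("sugar_range must satisfy 0 < min < max")
        ilo, ihi = self.incidence_range
        if not (0.0 <= ilo < ihi <= 1.0):
            raise ValidationError("incidence_range must be an ordered subset of [0,1]")
        if self.male_excess <= 1.0:
            raise ValidationError("male_excess must be > 1")
        if len(self.age_gradient) != len(AGE_BANDS):
            raise ValidationError(f"age_gradient must have {len(AGE_BANDS)} factors")
        if any(g <= 0 for g in self.age_gradient):
            raise ValidationError("age_gradient factors must be > 0")
        if self.age_gradient[0] < max(self.age_gradient):
            raise ValidationError("age_gradient must peak at the youngest band")
        if self.population_scale <= 0:
            raise ValidationError("population_scale must be > 0")
        if int(self.seed) != self.seed or self.seed < 0:
            raise ValidationError("seed must be a non-negative integer")


def generate_strata(spec: SyntheticSpec) -> list[Stratum]:
    """Draw a deterministic list of 12 strata from ``spec``.

    The youngest female band's intake is drawn uniformly so that after the
    male_excess scaling every value stays inside ``sugar_range``; the age
    gradient interpolates each band between the range floor and that base,
    which preserves the gradient's ordering exactly. Incidences are drawn
    independently per stratum within ``incidence_range``; populations are
    uniform within +/-20% of ``population_scale``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    lo, hi = spec.sugar_range
    # female base chosen so the male youngest band (base scaled by male_excess,
    # relative to the range floor) cannot exceed the range ceiling
    base_f = rng.uniform(lo + 0.6 * (hi - lo) / spec.male_excess,
                         lo + (hi - lo) / spec.male_excess)
    base = {"female": base_f, "male": lo + (base_f - lo) * spec.male_excess}
    strata = []
    for sex in SEXES:
        for band, g in zip(AGE_BANDS, spec.age_gradient):
            intake = lo + (base[sex] - lo) * g
            incidence = rng.uniform(*spec.incidence_range)
            population = int(round(spec.population_scale * rng.uniform(0.8, 1.2)))
            strata.append(Stratum(sex=sex, age_band=band, sugar_intake=float(intake),
                                  incidence=float(incidence), population=population))
    return strata


def extreme_strata(config: ModelConfig) -> tuple[Stratum, Stratum]:
    """The (highest, lowest) sugar-consumption strata of a config.

    Ties are broken by canonical (sex, age band) order — males before
    females, youngest first: the maximum takes the first tied stratum, the
    minimum the last. These are the two strata used for the probabilistic
    sensitivity analysis.
    """
    ordered = sorted(config.strata, key=lambda s: s.order_key)
    highest = max(ordered, key=lambda s: s.sugar_intake)  # first among ties
    lowest = min(reversed(ordered), key=lambda s: s.sugar_intake)  # last among ties
    return highest, lowest
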