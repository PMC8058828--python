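"""Valuation of lesion trajectories: costs, DALYs, productivity, scaling.

Four outcomes are derived from the per-year incremental lesion counts
(baseline minus intervention): lesions prevented, treatment costs avoided
(one 1-surface restoration per lesion), DALYs averted (lesions x proportion
symptomatic x symptomatic duration x disability weight), and productivity
losses avoided (DALYs x GDP per capita, the WHO Commission on Macroeconomics
and Health valuation).

Discounting uses the standard health-economic convention of an undiscounted
first year: factor (1 + r)^-(y - 1) for year y. The headline lesion count is
reported undiscounted, which preserves the exact identity
undiscounted costs = lesions prevented x unit cost; discounted variants of
every monetary/DALY outcome are carried alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import DalyParams, EconomicParams, Stratum, ValidationError
from .engine import ScenarioResult

__all__ = [
    "discount_factor",
    "treatment_costs",
    "dalys_averted",
    "productivity_loss_avoided",
    "scale_to_population",
    "IncrementalResult",
    "incremental",
    "aggregate",
]


def discount_factor(year: int, rate: float):
    """Present-value factor for 1-based ``year``; year 1 is undiscounted."""
    year = np.asarray(year)
    if np.any(year < 1):
        raise ValidationError("year must be >= 1")
    if rate < 0:
        raise ValidationError("rate must be >= 0")
    out = (1.0 + rate) ** -(year - 1)
    return float(out) if out.ndim == 0 else out


def _discounted_sum(lesions_by_year, per_lesion_value: float, rate: float) -> float:
    counts = np.asarray(lesions_by_year, dtype=float)
    years = np.arange(1, counts.size + 1)
    return float(np.sum(counts * per_lesion_value * discount_factor(years, rate)))


def treatment_costs(lesions_by_year, unit_cost: float, rate: float) -> float:
    """Discounted restoration costs (EUR) of a yearly lesion trajectory."""
    if unit_cost <= 0:
        raise ValidationError("unit_cost must be > 0")
    return _discounted_sum(lesions_by_year, unit_cost, rate)


def dalys_averted(lesions_by_year, daly_params: DalyParams, rate: float) -> float:
    """Discounted DALYs of a yearly lesion trajectory."""
    return _discounted_sum(lesions_by_year, daly_params.per_lesion, rate)


def productivity_loss_avoided(dalys: float, gdp_per_capita: float) -> float:
    """Monetised disease burden: DALYs x GDP per capita (EUR)."""
    if gdp_per_capita <= 0:
        raise ValidationError("gdp_per_capita must be > 0")
    return dalys * gdp_per_capita


def scale_to_population(per_simulated_total: float, n_individuals: int,
                        population: int) -> float:
    """Rescale a simulated-cohort total to the stratum's real population."""
    if n_individuals <= 0:
        raise ValidationError("n_individuals must be > 0")
    return per_simulated_total * population / n_individuals


@dataclass(frozen=True)
class IncrementalResult:
    """Population-scaled baseline-minus-intervention outcomes for one stratum.

    ``lesions_prevented`` is the undiscounted headline count; the monetary
    and DALY outcomes carry both discounted and undiscounted values.
    """

    stratum_label: str
    lesions_prevented: float
    costs_avoided: float
    dalys_averted: float
    productivity_avoided: float
    lesions_prevented_discounted: float
    costs_avoided_undiscounted: float
    dalys_averted_undiscounted: float
    productivity_avoided_undiscounted: float

    def __add__(self, other: "IncrementalResult") -> "IncrementalResult":
        return IncrementalResult(
            stratum_label="total",
            lesions_prevented=self.lesions_prevented + other.lesions_prevented,
            costs_avoided=self.costs_avoided + other.costs_avoided,
            dalys_averted=self.dalys_averted + other.dalys_averted,
            productivity_avoided=self.productivity_avoided + other.productivity_avoided,
            lesions_prevented_discounted=(self.lesions_prevented_discounted
                                          + other.lesions_prevented_discounted),
            costs_avoided_undiscounted=(self.costs_avoided_undiscounted
                                        + other.costs_avoided_undiscounted),
            dalys_averted_undiscounted=(self.dalys_averted_undiscounted
                                        + other.dalys_averted_undiscounted),
            productivity_avoided_undiscounted=(self.productivity_avoided_undiscounted
                                               + other.productivity_avoided_undiscounted),
        )


def incremental(baseline: ScenarioResult, intervention: ScenarioResult,
                stratum: Stratum, economics: EconomicParams) -> IncrementalResult:
    """Value the incremental lesion trajectory of one stratum.

    The undiscounted costs and DALYs are computed from the scaled headline
    lesion count so that ``costs_avoided_undiscounted == lesions_prevented *
    unit_cost`` holds to machine precision.
    """
    if baseline.stratum_label != intervention.stratum_label:
        raise ValidationError("scenario results are for different strata")
    if baseline.lesions_by_year.size != intervention.lesions_by_year.size:
        raise ValidationError("scenario horizons differ")
    if baseline.n_individuals != intervention.n_individuals:
        raise ValidationError("scenario cohort sizes differ")

    diff = baseline.lesions_by_year - intervention.lesions_by_year
    n = baseline.n_individuals
    rate = economics.discount_rate
    daly_p = economics.daly_per_lesion_params

    scale = lambda x: scale_to_population(x, n, stratum.population)

    lesions = scale(float(diff.sum()))
    lesions_disc = scale(_discounted_sum(diff, 1.0, rate))
    costs_disc = scale(treatment_costs(diff, economics.unit_cost, rate))
    dalys_disc = scale(dalys_averted(diff, daly_p, rate))

    dalys_undisc = lesions * daly_p.per_lesion
    return IncrementalResult(
        stratum_label=stratum.label,
        lesions_prevented=lesions,
        costs_avoided=costs_disc,
        dalys_averted=dalys_disc,
        productivity_avoided=productivity_loss_avoided(dalys_disc,
                                                       economics.gdp_per_capita),
        lesions_prevented_discounted=lesions_disc,
        costs_avoided_undiscounted=lesions * economics.unit_cost,
        dalys_averted_undiscounted=dalys_undisc,
        productivity_avoided_undiscounted=productivity_loss_avoided(
            dalys_undisc, economics.gdp_per_capita),
    )


def aggregate(results: list[IncrementalResult]) -> IncrementalResult:
    """Exact field-wise total over strata."""
    if not results:
        raise ValidationError("cannot aggregate an empty result list")
    total = results[0]
    for r in results[1:]:
        total = total + r
    return IncrementalResult(**{**total.__dict__, "stratum_label": "total"}) \
        if total.stratum_label != "total" else total
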