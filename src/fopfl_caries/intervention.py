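"""Dose-response linkage: labeling effect on sugar intake -> caries incidence.

The labeling intervention reduces each stratum's added-sugar intake by a
fixed fraction (default 6.6%, applied homogeneously across strata and held
constant over the horizon). The intake reduction is mapped to a lower annual
caries incidence through a linear dose-response: by default an absolute
reduction of the annual probability per g/day of sugar removed, clamped to
[0, baseline]; a relative-risk form is available for robustness checks.
Baseline incidence is taken to already correspond to baseline intake — only
the intervention scenario is adjusted.
"""

from __future__ import annotations

from .params import InterventionParams, Stratum, ValidationError

__all__ = ["sugar_reduction", "adjusted_incidence", "intervention_incidence"]


def sugar_reduction(sugar_intake: float, effect_fraction: float) -> float:
    """Grams/day of added sugar removed by the labeling effect."""
    if sugar_intake <= 0:
        raise ValidationError("sugar_intake must be > 0")
    if not 0.0 <= effect_fraction <= 1.0:
        raise ValidationError("effect_fraction must be in [0,1]")
    return sugar_intake * effect_fraction


def adjusted_incidence(baseline_incidence: float, delta_sugar: float, slope: float,
                       form: str = "absolute") -> float:
    """Annual incidence after removing ``delta_sugar`` g/day.

    ``form="absolute"``: clamp(p - slope * delta, 0, p), with slope in units
    of probability per g/day. ``form="relative"``: p * clamp(1 - slope *
    delta, 0, 1), with slope as a fractional risk reduction per g/day.
    Monotone non-increasing in both ``delta_sugar`` and ``slope``.
    """
    if not 0.0 <= baseline_incidence <= 1.0:
        raise ValidationError("baseline_incidence must be in [0,1]")
    if delta_sugar < 0:
        raise ValidationError("delta_sugar must be >= 0")
    if slope < 0:
        raise ValidationError("slope must be >= 0")
    if form == "absolute":
        return min(max(baseline_incidence - slope * delta_sugar, 0.0), baseline_incidence)
    if form == "relative":
        return baseline_incidence * min(max(1.0 - slope * delta_sugar, 0.0), 1.0)
    raise ValidationError("form must be 'absolute' or 'relative'")


def intervention_incidence(stratum: Stratum, params: InterventionParams) -> float:
    """Adjusted annual incidence for one stratum under the labeling scenario."""
    delta = sugar_reduction(stratum.sugar_intake, params.effect_fraction)
    return adjusted_incidence(stratum.incidence, delta, params.sugar_caries_slope,
                              form=params.dose_response)
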