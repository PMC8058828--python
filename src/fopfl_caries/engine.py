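"""Two-state microsimulation engine.

Each simulated individual starts caries-free and in every yearly cycle
develops at most one new lesion with the stratum's annual incidence
probability; the lesion is restored at the next visit within the cycle, so
the individual re-enters the no-caries state and cycles are independent
Bernoulli trials. There is no mortality, migration, or ageing between strata
over the horizon.

Randomness is organised as one named substream per (seed, stream key) via
``numpy.random.SeedSequence`` spawn keys, so every (stratum, scenario, PSA
run) triple is independent and bit-reproducible. Scenario pairs are simulated
with common random numbers by default: the same uniforms are thresholded
against both incidences, making per-year lesions(intervention) <=
lesions(baseline) hold in every realisation, not just in expectation.

``cohort_expectation`` is the closed-form cohort counterpart
(n * horizon * p) used as an analytic oracle for the stochastic engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import SimControls, Stratum, ValidationError

__all__ = [
    "ScenarioResult",
    "make_rng",
    "simulate_stratum",
    "simulate_pair",
    "cohort_expectation",
]

# scenario codes for stream keys
BASELINE, INTERVENTION = 0, 1

# chunk size for per-individual uniform draws (bounds peak memory)
_CHUNK = 1_000_000


@dataclass(frozen=True)
class ScenarioResult:
    """Yearly new-lesion counts among the simulated cohort of one stratum."""

    stratum_label: str
    lesions_by_year: np.ndarray  # int64, length = horizon
    n_individuals: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.lesions_by_year, dtype=np.int64)
        object.__setattr__(self, "lesions_by_year", counts)
        if counts.min(initial=0) < 0 or counts.max(initial=0) > self.n_individuals:
            raise ValidationError("yearly lesion counts must be in [0, n_individuals]")

    @property
    def total_lesions(self) -> int:
        return int(self.lesions_by_year.sum())


def make_rng(seed: int, *key: int) -> np.random.Generator:
    """Independent generator for substream ``key`` of master ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(key)))


def _count_below(rng: np.random.Generator, n: int, threshold: float) -> int:
    total = 0
    for start in range(0, n, _CHUNK):
        m = min(_CHUNK, n - start)
        total += int(np.count_nonzero(rng.random(m) < threshold))
    return total


def simulate_stratum(stratum: Stratum, incidence: float, controls: SimControls,
                     stream_id: int = 0) -> ScenarioResult:
    """Simulate one scenario for one stratum.

    Yearly counts are sums of per-individual Bernoulli indicators obtained by
    thresholding uniform draws, reproducible given (controls.seed, stream_id).
    """
    if not 0.0 <= incidence <= 1.0:
        raise ValidationError("incidence must be in [0,1]")
    rng = make_rng(controls.seed, stream_id)
    counts = np.array(
        [_count_below(rng, controls.n_individuals, incidence)
         for _ in range(controls.horizon)],
        dtype=np.int64,
    )
    return ScenarioResult(stratum.label, counts, controls.n_individuals)


def simulate_pair(stratum: Stratum, baseline_incidence: float,
                  intervention_incidence: float, controls: SimControls,
                  stream_id: int = 0) -> tuple[ScenarioResult, ScenarioResult]:
    """Simulate baseline and intervention scenarios for one stratum.

    With ``controls.common_random_numbers`` the two incidences are applied to
    identical uniform draws, so incremental lesion counts are non-negative in
    every year of every run; otherwise the scenarios use independent streams.
    """
    if not 0.0 <= intervention_incidence <= baseline_incidence <= 1.0:
        raise ValidationError("requires 0 <= intervention incidence <= baseline incidence <= 1")
    n, horizon = controls.n_individuals, controls.horizon
    if controls.common_random_numbers:
        rng = make_rng(controls.seed, stream_id, BASELINE)
        base = np.empty(horizon, dtype=np.int64)
        intv = np.empty(horizon, dtype=np.int64)
        for year in range(horizon):
            b = i = 0
            for start in range(0, n, _CHUNK):
                u = rng.random(min(_CHUNK, n - start))
                b += int(np.count_nonzero(u < baseline_incidence))
                i += int(np.count_nonzero(u < intervention_incidence))
            base[year], intv[year] = b, i
        return (ScenarioResult(stratum.label, base, n),
                ScenarioResult(stratum.label, intv, n))
    return (simulate_stratum(stratum, baseline_incidence, controls,
                             stream_id=stream_id * 2 + BASELINE),
            simulate_stratum(stratum, intervention_incidence, controls,
                             stream_id=stream_id * 2 + INTERVENTION))


def cohort_expectation(incidence: float, n_individuals: int, horizon: int) -> float:
    """Expected total lesions in a closed cohort: n * horizon * incidence.

    Exact because cycles are independent and carry at most one lesion each.
    """
    if not 0.0 <= incidence <= 1.0:
        raise ValidationError("incidence must be in [0,1]")
    if n_individuals < 0 or horizon < 0:
        raise ValidationError("n_individuals and horizon must be >= 0")
    return n_individuals * horizon * incidence
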