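"""Synthetic stand-ins for the survey and demographic inputs.

The projection consumes three external inputs: individual survey records
(age, diabetes status, years since diagnosis, survey weight, social-security
affiliation), a yearly adult-population projection, and a yearly diabetes
incidence-rate schedule.  None of the original microdata ship with this
package, so this module generates statistically matched substitutes:

* survey records drawn band-by-band at the configured prevalence, with
  durations sampled from the band's fitted duration law and weights whose
  band totals are proportional to the configured weight masses;
* a geometric population trajectory (default calibrated to 22% total growth
  over the 16-year horizon);
* a constant incidence schedule, with a calibration helper that root-finds
  the rate reproducing a target accumulated-cohort trajectory.

All generators are seeded and byte-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .duration_model import fit_from_quantiles
from .parameters_io import AgeGroupProfile

__all__ = [
    "SurveyRecord",
    "generate_survey",
    "as_records",
    "generate_population",
    "growth_rate_for_total",
    "generate_incidence",
    "calibrate_incidence_rate",
    "write_survey",
    "write_schedule",
    "read_schedule",
    "DEFAULT_SURVEY_N",
    "ADULT_ONSET_AGE",
]

#: Default synthetic survey size: tight enough moments for testing, seconds to build.
DEFAULT_SURVEY_N = 200_000

#: Youngest assumed age at type 2 diagnosis; durations never exceed age - 18.
ADULT_ONSET_AGE = 18

SURVEY_COLUMNS = [
    "age_years",
    "has_t2dm",
    "years_since_diagnosis",
    "survey_weight",
    "has_social_security",
]


@dataclass(frozen=True)
class SurveyRecord:
    """One synthetic survey respondent (row schema of the survey frame)."""

    age_years: int
    has_t2dm: bool
    years_since_diagnosis: float | None
    survey_weight: float
    has_social_security: bool


def generate_survey(
    profiles: list[AgeGroupProfile],
    n: int,
    seed: int,
    social_security_share: float = 0.5,
) -> pd.DataFrame:
    """Synthetic survey of ``n`` adults with the configured band structure.

    Records are allocated to age bands proportionally to each band's survey
    weight mass, ages drawn uniformly within the band, diabetes status at
    the band prevalence, and (for diabetic records) years since diagnosis
    from the band's quantile-fitted duration law, capped at age minus
    ``ADULT_ONSET_AGE``.  Survey weights are positive with band totals
    proportional to the configured weight masses in expectation.

    Returns a DataFrame with columns ``age_years, has_t2dm,
    years_since_diagnosis, survey_weight, has_social_security``;
    ``years_since_diagnosis`` is NaN for non-diabetic records.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not profiles:
        raise ValueError("need at least one age-group profile")
    rng = np.random.default_rng(seed)

    masses = np.array([p.weight_mass for p in profiles], dtype=float)
    shares = masses / masses.sum()
    band_idx = rng.choice(len(profiles), size=n, p=shares)

    ages = np.empty(n, dtype=np.int64)
    has_dm = np.zeros(n, dtype=bool)
    dur = np.full(n, np.nan)
    weight = np.empty(n)
    for i, prof in enumerate(profiles):
        mask = band_idx == i
        m = int(mask.sum())
        if m == 0:
            continue
        ages[mask] = rng.integers(prof.age_lo, prof.age_hi + 1, size=m)
        has_dm[mask] = rng.random(m) < prof.prevalence
        # mean weight per record chosen so the band's weight total tracks
        # its configured mass (up to the overall sampling scale)
        base = prof.weight_mass / (shares[i] * n)
        weight[mask] = base * rng.gamma(shape=25.0, scale=1.0 / 25.0, size=m)
        dm_mask = mask & has_dm
        k = int(dm_mask.sum())
        if k:
            law = fit_from_quantiles(prof.duration_median, prof.duration_iqr,
                                     age_band=prof.age_band)
            draws = np.asarray(law.sample(k, rng), dtype=float)
            cap = (ages[dm_mask] - ADULT_ONSET_AGE).astype(float)
            dur[dm_mask] = np.minimum(draws, cap)
    has_ss = rng.random(n) < social_security_share

    return pd.DataFrame(
        {
            "age_years": ages,
            "has_t2dm": has_dm,
            "years_since_diagnosis": dur,
            "survey_weight": weight,
            "has_social_security": has_ss,
        }
    )


def as_records(survey: pd.DataFrame) -> list[SurveyRecord]:
    """Materialise survey rows as typed records (small surveys only)."""
    return [
        SurveyRecord(
            age_years=int(r.age_years),
            has_t2dm=bool(r.has_t2dm),
            years_since_diagnosis=None if pd.isna(r.years_since_diagnosis)
            else float(r.years_since_diagnosis),
            survey_weight=float(r.survey_weight),
            has_social_security=bool(r.has_social_security),
        )
        for r in survey.itertuples()
    ]


def growth_rate_for_total(total_growth: float = 0.22, horizon: int = 16) -> float:
    """Annual growth rate g with (1+g)^horizon = 1 + total_growth."""
    return (1.0 + total_growth) ** (1.0 / horizon) - 1.0


def generate_population(
    base_2016: float,
    annual_growth: float,
    horizon: int,
    start_year: int = 2016,
) -> dict[int, float]:
    """Geometric adult-population trajectory over ``horizon`` years."""
    if base_2016 <= 0:
        raise ValueError(f"base population must be positive, got {base_2016}")
    if not (-0.05 < annual_growth < 0.05):
        raise ValueError(f"annual growth must lie in (-0.05, 0.05), got {annual_growth}")
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    return {
        start_year + t: base_2016 * (1.0 + annual_growth) ** t for t in range(horizon + 1)
    }


def generate_incidence(
    rate: float, horizon: int, start_year: int = 2016
) -> dict[int, float]:
    """Constant annual incidence schedule (rate strictly inside (0, 0.05)).

    Covers the ``horizon`` accrual years after the baseline year (new cases
    first accrue the year after baseline), so a 16-year horizon starting
    2016 yields 16 entries for 2017-2032.
    """
    if not (0.0 < rate < 0.05):
        raise ValueError(f"incidence rate must lie in (0, 0.05), got {rate}")
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    return {start_year + 1 + t: rate for t in range(horizon)}


def calibrate_incidence_rate(
    target_cohort: dict[int, float],
    population: dict[int, float],
) -> float:
    """Constant incidence rate whose accrued cohort matches a target series.

    Root-finds the rate at which prevalence-plus-cumulative-incidence accrual
    on ``population`` reproduces the target's final-year cohort exactly; with
    a geometric population the whole accrued series then tracks a target
    built the same way closely.
    """
    from .needs_pipeline import cohort_series  # local import; no cycle

    years = sorted(target_cohort)
    start, end = years[0], years[-1]
    prev0 = target_cohort[start]

    def gap(rate: float) -> float:
        sched = {y: rate for y in range(start + 1, end + 1)}
        series = cohort_series(prev0, sched, population)
        return series[end] - target_cohort[end]

    return float(optimize.brentq(gap, 1e-6, 0.049, xtol=1e-12))


def write_survey(survey: pd.DataFrame, path: str | Path) -> None:
    survey.to_csv(path, index=False)


def write_schedule(schedule: dict[int, float], path: str | Path,
                   value_name: str = "value") -> None:
    """Two-column CSV (year, value) for population or incidence schedules."""
    pd.DataFrame(
        {"year": sorted(schedule), value_name: [schedule[y] for y in sorted(schedule)]}
    ).to_csv(path, index=False)


def read_schedule(path: str | Path) -> dict[int, float]:
    df = pd.read_csv(path, comment="#")
    year_col, value_col = df.columns[0], df.columns[1]
    return {int(r[0]): float(r[1]) for r in df[[year_col, value_col]].itertuples(index=False)}
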