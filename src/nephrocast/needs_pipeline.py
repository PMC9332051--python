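"""End-to-end health-needs projection.

Orchestrates the full assessment: accrue yearly diabetic cohorts
(baseline prevalence plus cumulative incidence), initialise the prevalent
cohort from its years-since-diagnosis distribution per age band and
glycemic-control stratum, propagate everyone through the five-state annual
chain to the end of the horizon, and aggregate into a projection table of
per-year state counts and shares (deaths included in the denominator).

Controlled patients (HbA1c < 7, 18.7% by default) progress at the
lower-bound rates and uncontrolled patients at the upper-bound rates;
incident cases enter at normoalbuminuria on January 1 of their incidence
year and first transition at the end of that year.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .duration_model import DurationDistribution, fit_from_quantiles, integer_year_weights
from .markov_engine import (
    N_STATES,
    TransitionMatrix,
    build_matrix,
    required_n,
    SimulationResult,
)
from .parameters_io import (
    STATE_ORDER,
    AgeGroupProfile,
    HealthState,
    ScenarioConfig,
    TransitionTable,
    ValidationError,
    default_age_profiles,
    default_transition_table,
    provenance_lines,
)

__all__ = [
    "ProjectionTable",
    "cohort_series",
    "band_duration_models",
    "initial_state_mix",
    "run_assessment",
    "monte_carlo_assessment",
    "stage_distribution",
    "growth_summary",
    "write_projection",
    "read_projection",
]

_STATE_CODES = [s.code for s in STATE_ORDER]
_DEATH = HealthState.DEATH_CV.code


@dataclass(frozen=True)
class ProjectionTable:
    """Per-year cohort size and expected state counts (persons).

    ``frame`` is indexed by calendar year with columns ``cohort_size`` plus
    one count column per state code.  Deaths are cumulative and counted in
    the cohort denominator, so per year the five counts sum to the cohort
    size.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        f = self.frame
        missing = {"cohort_size", *_STATE_CODES} - set(f.columns)
        if missing:
            raise ValidationError(f"projection frame missing columns {sorted(missing)}")
        counts = f[_STATE_CODES].to_numpy()
        if np.any(counts < -1e-9):
            raise ValidationError("negative state counts in projection")
        rel = np.abs(counts.sum(axis=1) - f["cohort_size"].to_numpy()) / f[
            "cohort_size"
        ].to_numpy()
        if np.max(rel) > 0.005:
            raise ValidationError(
                f"state counts deviate from cohort size by up to {np.max(rel):.3%}"
            )
        deaths = f[_DEATH].to_numpy()
        if np.any(np.diff(deaths) < -1e-6):
            raise ValidationError("cumulative death counts must be non-decreasing")

    @property
    def years(self) -> list[int]:
        return [int(y) for y in self.frame.index]

    def counts(self, year: int) -> pd.Series:
        self._check_year(year)
        return self.frame.loc[year, _STATE_CODES]

    def cohort_size(self, year: int) -> float:
        self._check_year(year)
        return float(self.frame.loc[year, "cohort_size"])

    def shares_frame(self) -> pd.DataFrame:
        """Per-year stage distribution in percent (deaths included)."""
        return self.frame[_STATE_CODES].div(self.frame["cohort_size"], axis=0) * 100.0

    def _check_year(self, year: int) -> None:
        if year not in self.frame.index:
            raise ValueError(
                f"year {year} outside projection horizon "
                f"{self.years[0]}-{self.years[-1]}"
            )


def cohort_series(
    prev_2016: float,
    incidence: dict[int, float],
    population: dict[int, float],
) -> dict[int, float]:
    """Accrue yearly diabetic-cohort sizes from prevalence plus incidence.

    ``incidence`` maps each accrual year (baseline + 1 onwards) to its rate.
    The at-risk population each year is the total adult population minus the
    baseline prevalent cases; new cases are the incidence rate applied to it,
    and the cohort is baseline prevalence plus cumulative new cases.  The
    returned series starts at the baseline year (the year before the first
    accrual year) with the prevalent count.
    """
    years = sorted(incidence)
    missing = [y for y in years if y not in population]
    if missing:
        raise ValidationError(f"population projection missing years {missing}")
    if prev_2016 <= 0:
        raise ValidationError(f"baseline prevalent cases must be positive, got {prev_2016}")
    series: dict[int, float] = {years[0] - 1: float(prev_2016)}
    for y in years:
        at_risk = population[y] - prev_2016
        if at_risk < 0:
            raise ValidationError(
                f"negative at-risk population in {y}: {population[y]} < {prev_2016}"
            )
        series[y] = series[y - 1] + incidence[y] * at_risk
    return series


def band_duration_models(
    profiles: list[AgeGroupProfile],
) -> dict[tuple[int, int], DurationDistribution]:
    """Quantile-fitted duration law per age band (the default duration source)."""
    return {
        p.age_band: fit_from_quantiles(p.duration_median, p.duration_iqr, age_band=p.age_band)
        for p in profiles
    }


def initial_state_mix(
    profiles: list[AgeGroupProfile],
    matrix: TransitionMatrix,
    durations: dict[tuple[int, int], DurationDistribution],
    condition_on_survival: bool = False,
) -> np.ndarray:
    """Expected baseline state probabilities for the prevalent cohort.

    Each band contributes in proportion to its survey-weight mass; within a
    band the pure-NORMO entry vector is advanced k annual cycles with
    probability P(floor(duration) = k).  With ``condition_on_survival`` the
    accumulated pre-baseline death mass is renormalised away.
    """
    masses = np.array([p.weight_mass for p in profiles], dtype=float)
    shares = masses / masses.sum()
    e0 = np.zeros(N_STATES)
    e0[HealthState.NORMO.index] = 1.0
    mix = np.zeros(N_STATES)
    for share, prof in zip(shares, profiles):
        law = durations[prof.age_band]
        wk = integer_year_weights(law)
        band = np.zeros(N_STATES)
        v = e0.copy()
        for w in wk:
            if w > 0:
                band += w * v
            v = v @ matrix.entries
        mix += share * band
    if condition_on_survival:
        mix[HealthState.DEATH_CV.index] = 0.0
        mix /= mix.sum()
    return mix


def _strata(config: ScenarioConfig, table: TransitionTable):
    out = []
    for frac, policy in (
        (config.control_fraction, config.rate_policy_controlled),
        (1.0 - config.control_fraction, config.rate_policy_uncontrolled),
    ):
        if frac > 0:
            out.append((frac, build_matrix(table, policy)))
    return out


def _check_horizon(config: ScenarioConfig) -> list[int]:
    years = list(config.years)
    missing = [y for y in years if y not in config.cohort_sizes]
    if missing:
        raise ValidationError(
            f"cohort_sizes does not cover the scenario horizon; missing years {missing}"
        )
    return years


def run_assessment(
    config: ScenarioConfig,
    profiles: list[AgeGroupProfile] | None = None,
    table: TransitionTable | None = None,
    durations: dict[tuple[int, int], DurationDistribution] | None = None,
) -> ProjectionTable:
    """Full analytic-expectation projection over the scenario horizon."""
    profiles = default_age_profiles() if profiles is None else profiles
    table = default_transition_table() if table is None else table
    durations = band_duration_models(profiles) if durations is None else durations
    years = _check_horizon(config)
    condition = config.init_mode == "condition_on_survival"

    strata = []
    for frac, matrix in _strata(config, table):
        init = initial_state_mix(profiles, matrix, durations, condition_on_survival=condition)
        strata.append(
            {"frac": frac, "matrix": matrix, "v": frac * config.cohort_sizes[years[0]] * init}
        )

    rows = []
    for y in years:
        if y != years[0]:
            inc = config.cohort_sizes[y] - config.cohort_sizes[y - 1]
            for s in strata:
                s["v"] = s["v"] @ s["matrix"].entries
                s["v"][HealthState.NORMO.index] += s["frac"] * inc
                if s["v"][HealthState.NORMO.index] < 0:
                    raise ValidationError(
                        f"cohort shrinkage in {y} exceeds the normoalbuminuric stock"
                    )
        total = np.sum([s["v"] for s in strata], axis=0)
        rows.append([config.cohort_sizes[y], *total])

    frame = pd.DataFrame(rows, index=pd.Index(years, name="year"),
                         columns=["cohort_size", *_STATE_CODES])
    return ProjectionTable(frame)


def monte_carlo_assessment(
    config: ScenarioConfig,
    profiles: list[AgeGroupProfile] | None = None,
    table: TransitionTable | None = None,
    durations: dict[tuple[int, int], DurationDistribution] | None = None,
    n_sim: int | None = None,
    n_boot: int = 200,
) -> SimulationResult:
    """Individual-level microsimulation of the full assessment.

    Simulated individuals stand in for blocks of real persons: the total
    entrant mass (baseline prevalent cohort plus all incident increments) is
    spread over ``n_sim`` individuals, allocated across strata and entry
    years in proportion to person mass.  With ``n_sim='auto'`` in the
    scenario, the sample size follows the binomial error-bound rule on the
    baseline cohort.  Reported counts are person-scaled; ``expected`` is the
    analytic projection for the same scenario (the validation oracle).
    """
    profiles = default_age_profiles() if profiles is None else profiles
    table = default_transition_table() if table is None else table
    durations = band_duration_models(profiles) if durations is None else durations
    years = _check_horizon(config)
    n_years = len(years) - 1
    condition = config.init_mode == "condition_on_survival"

    if n_sim is None:
        n_sim = (
            required_n(config.error_bound, config.cohort_sizes[years[0]])
            if config.n_sim == "auto"
            else int(config.n_sim)
        )
    rng = np.random.default_rng(config.seed)

    increments = {
        y: config.cohort_sizes[y] - config.cohort_sizes[y - 1] for y in years[1:]
    }
    if any(v < 0 for v in increments.values()):
        raise ValidationError("microsimulation requires a non-shrinking cohort series")
    total_mass = config.cohort_sizes[years[0]] + sum(increments.values())

    counts = np.zeros((n_years + 1, N_STATES))
    entered = np.zeros(n_years + 1)  # simulated individuals present per year
    cum = {}
    for frac, matrix in _strata(config, table):
        cum_matrix = np.cumsum(matrix.entries, axis=1)
        init = initial_state_mix(profiles, matrix, durations, condition_on_survival=condition)
        groups = [(0, frac * config.cohort_sizes[years[0]], init)]
        groups += [
            (t, frac * increments[y], None) for t, y in enumerate(years[1:], start=1)
        ]
        for t0, mass, init_probs in groups:
            m = int(round(n_sim * mass / total_mass))
            if m == 0 or mass == 0:
                continue
            w = mass / m
            if init_probs is None:
                states = np.full(m, HealthState.NORMO.index, dtype=np.int64)
            else:
                states = rng.choice(N_STATES, size=m, p=init_probs)
            entered[t0:] += m
            for t in range(t0, n_years + 1):
                counts[t] += np.bincount(states, minlength=N_STATES) * w
                if t < n_years:
                    u = rng.random(m)
                    states = (u[:, None] > cum_matrix[states]).sum(axis=1)
        cum[frac] = cum_matrix

    analytic = run_assessment(config, profiles, table, durations)
    expected = analytic.frame[_STATE_CODES].to_numpy()

    mean = np.zeros_like(counts)
    var = np.zeros_like(counts)
    qs = {q: np.zeros_like(counts) for q in (0.025, 0.25, 0.50, 0.75, 0.975)}
    for t in range(n_years + 1):
        tot = counts[t].sum()
        p_hat = counts[t] / tot
        n_t = int(entered[t])
        scale = tot / n_t
        reps = rng.multinomial(n_t, p_hat, size=n_boot).astype(float) * scale
        mean[t] = reps.mean(axis=0)
        var[t] = reps.var(axis=0, ddof=1)
        qvals = np.quantile(reps, list(qs), axis=0)
        for qi, q in enumerate(qs):
            qs[q][t] = qvals[qi]

    return SimulationResult(
        years=np.array(years),
        counts=counts,
        expected=expected,
        mean=mean,
        variance=var,
        quantiles=qs,
        n_sim=n_sim,
        seed=config.seed,
    )


def stage_distribution(table: ProjectionTable, year: int) -> dict[str, float]:
    """Stage shares (percent of the accumulated cohort, deaths included)."""
    counts = table.counts(year)
    size = table.cohort_size(year)
    return {code: float(counts[code]) / size * 100.0 for code in _STATE_CODES}


def growth_summary(table: ProjectionTable, y0: int, y1: int) -> dict[str, float]:
    """Percent change of each state's count between two years.

    A zero baseline count makes the growth undefined and is reported as NaN.
    """
    if y0 >= y1:
        raise ValueError(f"need y0 < y1, got {y0} >= {y1}")
    c0, c1 = table.counts(y0), table.counts(y1)
    out = {}
    for code in _STATE_CODES:
        base = float(c0[code])
        out[code] = float("nan") if base == 0 else (float(c1[code]) - base) / base * 100.0
    return out


def write_projection(
    table: ProjectionTable,
    path: str | Path,
    seed: int | None = None,
    parameter_files: list[str | Path] = (),
) -> None:
    """Long-format CSV (year, state, count, share_pct, cohort_size).

    Counts are rounded to whole persons and shares to 0.01% at write time
    only; a provenance header records the seed and parameter-file hashes.
    """
    shares = table.shares_frame()
    rows = []
    for year in table.years:
        for code in _STATE_CODES:
            rows.append(
                (
                    year,
                    code,
                    int(round(table.frame.loc[year, code])),
                    round(float(shares.loc[year, code]), 2),
                    int(round(table.cohort_size(year))),
                )
            )
    df = pd.DataFrame(rows, columns=["year", "state", "count", "share_pct", "cohort_size"])
    header = "\n".join(provenance_lines(seed=seed, files=parameter_files))
    Path(path).write_text(header + "\n" + df.to_csv(index=False))


def read_projection(path: str | Path) -> ProjectionTable:
    df = pd.read_csv(path, comment="#")
    wide = df.pivot(index="year", columns="state", values="count")[_STATE_CODES]
    wide["cohort_size"] = df.groupby("year")["cohort_size"].first()
    return ProjectionTable(wide[["cohort_size", *_STATE_CODES]].astype(float))


def manifest(config: ScenarioConfig, n_sim: int | None = None) -> str:
    """JSON run manifest (scenario echo plus engine settings)."""
    payload = {
        "start_year": config.start_year,
        "horizon_years": config.horizon_years,
        "control_fraction": config.control_fraction,
        "rate_policy_controlled": config.rate_policy_controlled,
        "rate_policy_uncontrolled": config.rate_policy_uncontrolled,
        "init_mode": config.init_mode,
        "seed": config.seed,
        "n_sim": n_sim if n_sim is not None else config.n_sim,
        "error_bound": config.error_bound,
    }
    return json.dumps(payload, indent=2)
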