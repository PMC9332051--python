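"""Model parameters: health states, transition bounds, age-group profiles, scenarios.

The progression model runs on five albuminuria-based health states and seven
annual transition probabilities, each published as a (lower, upper) confidence
bound from the UKPDS nephropathy cohort.  This module loads, validates and
round-trips every parameter the pipeline consumes, and ships the national
2016 defaults (survey-derived age-group prevalence and years-since-diagnosis
summaries, the yearly diabetic-cohort sizes for the population without social
security, the 18.7% glycemic-control fraction) as plain CSV/YAML data files.

Percentages in the data files follow the published tables (e.g. ``1.9`` for
1.9%); conversion to fractions happens exactly once, at load time.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

__all__ = [
    "HealthState",
    "STATE_ORDER",
    "TransitionBound",
    "TransitionTable",
    "AgeGroupProfile",
    "ScenarioConfig",
    "ParameterError",
    "SchemaError",
    "ValidationError",
    "CompletenessError",
    "load_scenario",
    "load_transition_table",
    "load_age_profiles",
    "load_cohort_sizes",
    "write_scenario",
    "write_transition_table",
    "write_age_profiles",
    "default_scenario",
    "default_transition_table",
    "default_age_profiles",
    "default_cohort_sizes",
    "default_data_path",
    "provenance_lines",
]


class ParameterError(ValueError):
    """Base class for parameter loading/validation failures."""


class SchemaError(ParameterError):
    """A config file does not match the documented schema."""


class ValidationError(ParameterError):
    """A parsed value violates a model invariant."""


class CompletenessError(ParameterError):
    """A required record (e.g. one of the seven transition pairs) is missing."""


class HealthState(Enum):
    """One of the five albuminuria-defined progression stages.

    Ordering is the model's canonical state index (0..4); cardiovascular
    death is the single absorbing state, while end-stage renal disease still
    transitions to death.
    """

    NORMO = ("NORMO", "< 30 mg/g")
    MICRO = ("MICRO", "30-300 mg/24h")
    MACRO = ("MACRO", ">= 300 mg/g")
    ESRD = ("ESRD", "renal replacement")
    DEATH_CV = ("DEATH_CV", "cardiovascular death")

    def __init__(self, code: str, albuminuria_band: str):
        self.code = code
        self.albuminuria_band = albuminuria_band

    @property
    def index(self) -> int:
        return STATE_ORDER.index(self)

    @property
    def is_absorbing(self) -> bool:
        return self is HealthState.DEATH_CV

    @classmethod
    def parse(cls, name: str) -> "HealthState":
        key = str(name).strip().upper()
        aliases = {"DEATH": "DEATH_CV", "DEATH_CV": "DEATH_CV"}
        key = aliases.get(key, key)
        try:
            return cls[key]
        except KeyError:
            raise SchemaError(f"unknown health state name: {name!r}") from None


STATE_ORDER: tuple[HealthState, ...] = (
    HealthState.NORMO,
    HealthState.MICRO,
    HealthState.MACRO,
    HealthState.ESRD,
    HealthState.DEATH_CV,
)

#: The seven allowed (from, to) transition pairs; all other off-diagonal
#: moves (e.g. NORMO -> MACRO within one year) are impossible by construction.
ALLOWED_TRANSITIONS: tuple[tuple[HealthState, HealthState], ...] = (
    (HealthState.NORMO, HealthState.MICRO),
    (HealthState.MICRO, HealthState.MACRO),
    (HealthState.MACRO, HealthState.ESRD),
    (HealthState.NORMO, HealthState.DEATH_CV),
    (HealthState.MICRO, HealthState.DEATH_CV),
    (HealthState.MACRO, HealthState.DEATH_CV),
    (HealthState.ESRD, HealthState.DEATH_CV),
)

RATE_POLICIES = ("min", "max", "midpoint")


@dataclass(frozen=True)
class TransitionBound:
    """Annual transition probability interval for one (from, to) state pair."""

    from_state: HealthState
    to_state: HealthState
    p_min: float
    p_max: float

    def __post_init__(self):
        if (self.from_state, self.to_state) not in ALLOWED_TRANSITIONS:
            raise ValidationError(
                f"transition {self.from_state.code}->{self.to_state.code} "
                "is not one of the seven allowed pairs"
            )
        if not (0.0 <= self.p_min <= self.p_max <= 1.0):
            raise ValidationError(
                f"bounds for {self.from_state.code}->{self.to_state.code} must "
                f"satisfy 0 <= p_min <= p_max <= 1, got [{self.p_min}, {self.p_max}]"
            )

    def value(self, policy: str) -> float:
        if policy == "min":
            return self.p_min
        if policy == "max":
            return self.p_max
        if policy == "midpoint":
            return 0.5 * (self.p_min + self.p_max)
        raise ValidationError(f"unknown rate policy {policy!r}; expected one of {RATE_POLICIES}")


@dataclass(frozen=True)
class TransitionTable:
    """The complete set of seven annual transition-probability intervals."""

    bounds: tuple[TransitionBound, ...]

    def __post_init__(self):
        pairs = [(b.from_state, b.to_state) for b in self.bounds]
        if len(set(pairs)) != len(pairs):
            dup = [p for p in pairs if pairs.count(p) > 1][0]
            raise ValidationError(f"duplicate transition pair {dup[0].code}->{dup[1].code}")
        missing = [p for p in ALLOWED_TRANSITIONS if p not in pairs]
        if missing:
            names = ", ".join(f"{f.code}->{t.code}" for f, t in missing)
            raise CompletenessError(f"transition table is missing pairs: {names}")
        # Guard here so matrix construction can never yield a negative stay
        # probability under any policy.
        for state in STATE_ORDER:
            out = sum(b.p_max for b in self.bounds if b.from_state is state)
            if out >= 1.0:
                raise ValidationError(
                    f"outgoing upper bounds from {state.code} sum to {out} >= 1"
                )

    def bound(self, from_state: HealthState, to_state: HealthState) -> TransitionBound:
        for b in self.bounds:
            if b.from_state is from_state and b.to_state is to_state:
                return b
        raise KeyError(f"{from_state.code}->{to_state.code}")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "from_state": [b.from_state.code for b in self.bounds],
                "to_state": [b.to_state.code for b in self.bounds],
                "p_min_pct": [b.p_min * 100.0 for b in self.bounds],
                "p_max_pct": [b.p_max * 100.0 for b in self.bounds],
            }
        )


@dataclass(frozen=True)
class AgeGroupProfile:
    """One age band's diabetes prevalence and years-since-diagnosis summary.

    ``prevalence`` is the fraction of the age band with diabetes (diagnosed
    plus undiagnosed); ``weight_mass`` is the survey-weight total (persons)
    for diagnosed respondents without social security, used to apportion the
    prevalent cohort across bands; the duration summary is the median and
    interquartile range of years since diagnosis.
    """

    age_lo: int
    age_hi: int
    prevalence: float
    weight_mass: float
    duration_median: float
    duration_q25: float
    duration_q75: float

    def __post_init__(self):
        if self.age_lo >= self.age_hi:
            raise ValidationError(f"age band [{self.age_lo}, {self.age_hi}] is empty")
        if not (0.0 < self.prevalence < 1.0):
            raise ValidationError(
                f"prevalence must lie in (0, 1) as a fraction, got {self.prevalence}"
            )
        if self.weight_mass <= 0:
            raise ValidationError(f"weight_mass must be positive, got {self.weight_mass}")
        if not (0.0 <= self.duration_q25 <= self.duration_median <= self.duration_q75):
            raise ValidationError(
                f"band {self.age_lo}-{self.age_hi}: need 0 <= q25 <= median <= q75, "
                f"got median {self.duration_median}, IQR "
                f"[{self.duration_q25}, {self.duration_q75}]"
            )

    @property
    def age_band(self) -> tuple[int, int]:
        return (self.age_lo, self.age_hi)

    @property
    def prevalence_pct(self) -> float:
        return self.prevalence * 100.0

    @property
    def duration_iqr(self) -> tuple[float, float]:
        return (self.duration_q25, self.duration_q75)


def _validate_profiles(profiles: list[AgeGroupProfile]) -> list[AgeGroupProfile]:
    ordered = sorted(profiles, key=lambda p: p.age_lo)
    for a, b in zip(ordered, ordered[1:]):
        if b.age_lo <= a.age_hi:
            raise ValidationError(
                f"age bands {a.age_lo}-{a.age_hi} and {b.age_lo}-{b.age_hi} overlap"
            )
    return ordered


DEFAULT_SEED = 20160101  # documented default; any int below 2**31 is valid


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything that defines one projection run.

    ``control_fraction`` is the share of treated patients with glycemic
    control (HbA1c < 7); controlled patients progress at
    ``rate_policy_controlled`` rates and the remainder at
    ``rate_policy_uncontrolled`` rates.  ``cohort_sizes`` maps calendar year
    to the accumulated diabetic cohort (persons without social security);
    ``init_mode`` selects whether pre-baseline death mass is carried in the
    baseline-year state mix (``carry_deaths``) or renormalized away
    (``condition_on_survival``).
    """

    start_year: int = 2016
    horizon_years: int = 16
    control_fraction: float = 0.187
    rate_policy_controlled: str = "min"
    rate_policy_uncontrolled: str = "max"
    n_sim: int | str = "auto"
    error_bound: float = 10_000.0
    seed: int = DEFAULT_SEED
    init_mode: str = "carry_deaths"
    cohort_sizes: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.horizon_years < 1:
            raise ValidationError(f"horizon_years must be >= 1, got {self.horizon_years}")
        if not (0.0 <= self.control_fraction <= 1.0):
            raise ValidationError(
                f"control_fraction must lie in [0, 1], got {self.control_fraction}"
            )
        for name in ("rate_policy_controlled", "rate_policy_uncontrolled"):
            pol = getattr(self, name)
            if pol not in RATE_POLICIES:
                raise ValidationError(f"{name} must be one of {RATE_POLICIES}, got {pol!r}")
        if self.init_mode not in ("carry_deaths", "condition_on_survival"):
            raise ValidationError(
                f"init_mode must be 'carry_deaths' or 'condition_on_survival', "
                f"got {self.init_mode!r}"
            )
        if self.n_sim != "auto" and (not isinstance(self.n_sim, int) or self.n_sim < 1):
            raise ValidationError(f"n_sim must be 'auto' or a positive integer, got {self.n_sim!r}")
        if self.error_bound <= 0:
            raise ValidationError(f"error_bound must be positive, got {self.error_bound}")
        for year, size in self.cohort_sizes.items():
            if size <= 0:
                raise ValidationError(f"cohort size for {year} must be positive, got {size}")

    @property
    def end_year(self) -> int:
        return self.start_year + self.horizon_years

    @property
    def years(self) -> range:
        return range(self.start_year, self.end_year + 1)

    def with_overrides(self, **kwargs) -> "ScenarioConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# loading / writing


def default_data_path(name: str) -> Path:
    """Path to a shipped default data file (inside the installed package)."""
    return Path(resources.files("nephrocast").joinpath("data", name))


_SCENARIO_FIELDS = {
    "start_year": int,
    "horizon_years": int,
    "control_fraction": float,
    "rate_policy_controlled": str,
    "rate_policy_uncontrolled": str,
    "n_sim": None,
    "error_bound": float,
    "seed": int,
    "init_mode": str,
    "cohort_sizes": None,
}


def load_scenario(path: str | Path) -> ScenarioConfig:
    """Load a scenario config (YAML); missing fields take the shipped defaults."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise SchemaError(f"scenario file {path} must contain a mapping at top level")
    unknown = set(raw) - set(_SCENARIO_FIELDS)
    if unknown:
        raise SchemaError(f"unknown scenario field(s): {sorted(unknown)}")
    kwargs: dict = {}
    for name, caster in _SCENARIO_FIELDS.items():
        if name not in raw:
            continue
        value = raw[name]
        if value is None:
            raise SchemaError(f"scenario field {name!r} is present but null")
        if name == "cohort_sizes":
            if not isinstance(value, dict):
                raise SchemaError("cohort_sizes must map year -> persons")
            value = {int(k): float(v) for k, v in value.items()}
        elif name == "n_sim":
            if value != "auto":
                value = int(value)
        elif caster is not None:
            value = caster(value)
        kwargs[name] = value
    if "cohort_sizes" not in kwargs:
        kwargs["cohort_sizes"] = default_cohort_sizes()
    return ScenarioConfig(**kwargs)


def write_scenario(config: ScenarioConfig, path: str | Path) -> None:
    data = {
        "start_year": config.start_year,
        "horizon_years": config.horizon_years,
        "control_fraction": config.control_fraction,
        "rate_policy_controlled": config.rate_policy_controlled,
        "rate_policy_uncontrolled": config.rate_policy_uncontrolled,
        "n_sim": config.n_sim,
        "error_bound": config.error_bound,
        "seed": config.seed,
        "init_mode": config.init_mode,
        "cohort_sizes": {int(k): float(v) for k, v in config.cohort_sizes.items()},
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_transition_table(path: str | Path) -> TransitionTable:
    """Load the seven-pair transition table from CSV (percent units on file)."""
    df = pd.read_csv(path, comment="#")
    required = {"from_state", "to_state", "p_min_pct", "p_max_pct"}
    if not required.issubset(df.columns):
        raise SchemaError(
            f"transition table must have columns {sorted(required)}, got {list(df.columns)}"
        )
    bounds = tuple(
        TransitionBound(
            from_state=HealthState.parse(row.from_state),
            to_state=HealthState.parse(row.to_state),
            p_min=float(row.p_min_pct) / 100.0,
            p_max=float(row.p_max_pct) / 100.0,
        )
        for row in df.itertuples()
    )
    return TransitionTable(bounds)


def write_transition_table(table: TransitionTable, path: str | Path) -> None:
    table.as_frame().to_csv(path, index=False)


def load_age_profiles(path: str | Path) -> list[AgeGroupProfile]:
    """Load age-group profiles from CSV (prevalence in percent on file)."""
    df = pd.read_csv(path, comment="#")
    required = {
        "age_lo",
        "age_hi",
        "prevalence_pct",
        "weight_mass",
        "duration_median",
        "duration_q25",
        "duration_q75",
    }
    if not required.issubset(df.columns):
        raise SchemaError(
            f"age-profile table must have columns {sorted(required)}, got {list(df.columns)}"
        )
    profiles = [
        AgeGroupProfile(
            age_lo=int(row.age_lo),
            age_hi=int(row.age_hi),
            prevalence=float(row.prevalence_pct) / 100.0,
            weight_mass=float(row.weight_mass),
            duration_median=float(row.duration_median),
            duration_q25=float(row.duration_q25),
            duration_q75=float(row.duration_q75),
        )
        for row in df.itertuples()
    ]
    return _validate_profiles(profiles)


def write_age_profiles(profiles: Iterable[AgeGroupProfile], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "age_lo": [p.age_lo for p in profiles],
            "age_hi": [p.age_hi for p in profiles],
            "prevalence_pct": [p.prevalence_pct for p in profiles],
            "weight_mass": [p.weight_mass for p in profiles],
            "duration_median": [p.duration_median for p in profiles],
            "duration_q25": [p.duration_q25 for p in profiles],
            "duration_q75": [p.duration_q75 for p in profiles],
        }
    )
    df.to_csv(path, index=False)


def load_cohort_sizes(path: str | Path) -> dict[int, float]:
    df = pd.read_csv(path, comment="#")
    if not {"year", "persons"}.issubset(df.columns):
        raise SchemaError("cohort-size file must have columns year, persons")
    sizes = {int(r.year): float(r.persons) for r in df.itertuples()}
    for year, size in sizes.items():
        if size <= 0:
            raise ValidationError(f"cohort size for {year} must be positive, got {size}")
    return sizes


# default parameter set (shipped data files)


def default_transition_table() -> TransitionTable:
    return load_transition_table(default_data_path("transition_bounds.csv"))


def default_age_profiles() -> list[AgeGroupProfile]:
    return load_age_profiles(default_data_path("age_profiles.csv"))


def default_cohort_sizes() -> dict[int, float]:
    return load_cohort_sizes(default_data_path("cohort_sizes.csv"))


def default_scenario() -> ScenarioConfig:
    return load_scenario(default_data_path("scenario_default.yaml"))


def provenance_lines(seed: int | None = None, files: Iterable[str | Path] = ()) -> list[str]:
    """Comment lines recording parameter-file hashes (and seed) for outputs."""
    lines = ["# nephrocast provenance"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    for f in files:
        digest = hashlib.sha256(Path(f).read_bytes()).hexdigest()[:16]
        lines.append(f"# sha256[{Path(f).name}]={digest}")
    return lines
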