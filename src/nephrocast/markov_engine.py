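"""Five-state annual-cycle Markov machinery.

The chain has states NORMO -> MICRO -> MACRO -> ESRD -> DEATH_CV with
cardiovascular death reachable from every living state and absorbing.  The
published annual transition probabilities are consumed directly as one-cycle
probabilities (no hazard conversion): off-diagonal entries take the
policy-selected bound (``min``, ``max`` or ``midpoint``) and the stay
probability is the row complement, which the table-level guard keeps
strictly positive.

Two propagation routes are provided and cross-validated: exact expectation
propagation (matrix powering) and individual-level Monte-Carlo simulation
with bootstrap uncertainty, with the simulation sample size chosen so the
scaled binomial standard error stays below a persons-scale error bound.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .parameters_io import (
    STATE_ORDER,
    HealthState,
    TransitionTable,
    ValidationError,
)

__all__ = [
    "TransitionMatrix",
    "StateVector",
    "SimulationResult",
    "build_matrix",
    "propagate",
    "initialize_from_duration",
    "required_n",
    "simulate",
]

N_STATES = len(STATE_ORDER)
_QUANTILES = (0.025, 0.25, 0.50, 0.75, 0.975)


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic 5x5 annual transition matrix."""

    entries: np.ndarray
    policy_label: str

    def __post_init__(self):
        a = np.asarray(self.entries, dtype=float)
        if a.shape != (N_STATES, N_STATES):
            raise ValidationError(f"matrix must be {N_STATES}x{N_STATES}, got {a.shape}")
        if np.any(a < 0):
            raise ValidationError("matrix entries must be non-negative")
        rowsums = a.sum(axis=1)
        if np.max(np.abs(rowsums - 1.0)) > 1e-12:
            raise ValidationError(f"rows must sum to 1, got {rowsums}")
        death = HealthState.DEATH_CV.index
        if a[death, death] != 1.0:
            raise ValidationError("cardiovascular death must be absorbing")
        object.__setattr__(self, "entries", a)

    def __getitem__(self, key) -> float:
        f, t = key
        if isinstance(f, HealthState):
            f = f.index
        if isinstance(t, HealthState):
            t = t.index
        return float(self.entries[f, t])

    def power(self, k: int) -> np.ndarray:
        return np.linalg.matrix_power(self.entries, k)


@dataclass(frozen=True)
class StateVector:
    """Occupancy over the five states for one cohort-year.

    ``scale`` is ``probability`` (sums to 1) or ``persons`` (sums to the
    cohort size); mass is conserved under propagation because death is kept
    as a state.
    """

    values: np.ndarray
    scale: str = "probability"
    year: int | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_STATES,):
            raise ValidationError(f"state vector must have {N_STATES} entries, got {v.shape}")
        if np.any(v < -1e-12):
            raise ValidationError("state vector entries must be non-negative")
        if self.scale not in ("probability", "persons"):
            raise ValidationError(f"scale must be 'probability' or 'persons', got {self.scale!r}")
        if self.scale == "probability" and abs(v.sum() - 1.0) > 1e-9:
            raise ValidationError(f"probability vector must sum to 1, got {v.sum()!r}")
        object.__setattr__(self, "values", v)

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def get(self, state: HealthState) -> float:
        return float(self.values[state.index])

    def conditioned_on_survival(self) -> "StateVector":
        """Renormalise over living states (drop accumulated death mass)."""
        v = self.values.copy()
        v[HealthState.DEATH_CV.index] = 0.0
        if v.sum() <= 0:
            raise ValidationError("no surviving mass to condition on")
        if self.scale == "probability":
            v = v / v.sum()
        return StateVector(v, scale=self.scale, year=self.year)


def build_matrix(table: TransitionTable, policy: str) -> TransitionMatrix:
    """Annual matrix with the policy-selected bound on the seven allowed pairs."""
    a = np.zeros((N_STATES, N_STATES))
    for b in table.bounds:
        a[b.from_state.index, b.to_state.index] = b.value(policy)
    for i, state in enumerate(STATE_ORDER):
        out = a[i].sum()
        if out >= 1.0:
            raise ValidationError(
                f"outgoing probabilities from {state.code} sum to {out} >= 1 "
                f"under policy {policy!r}"
            )
        a[i, i] = 1.0 - out
    return TransitionMatrix(a, policy_label=policy)


def propagate(init: StateVector, matrix: TransitionMatrix, n_years: int) -> list[StateVector]:
    """Expected occupancy trajectory: ``init`` followed by ``n_years`` steps."""
    if n_years < 0:
        raise ValueError(f"n_years must be >= 0, got {n_years}")
    out = [init]
    v = init.values
    year = init.year
    for _ in range(n_years):
        v = v @ matrix.entries
        year = None if year is None else year + 1
        out.append(StateVector(v, scale=init.scale, year=year))
    return out


def initialize_from_duration(duration_years: float, matrix: TransitionMatrix) -> StateVector:
    """State mix of a patient diagnosed ``duration_years`` ago.

    A pure-NORMO probability vector is advanced floor(duration) annual
    cycles; accumulated death mass is retained (callers decide whether to
    condition on survival).
    """
    if duration_years < 0:
        raise ValueError(f"duration must be >= 0, got {duration_years}")
    k = int(math.floor(duration_years))
    e0 = np.zeros(N_STATES)
    e0[HealthState.NORMO.index] = 1.0
    return StateVector(e0 @ matrix.power(k), scale="probability")


def required_n(
    error_bound: float, cohort_size: float, worst_case_p: float = 0.5, round_to: int = 10_000
) -> int:
    """Smallest simulation size keeping the scaled binomial SE below the bound.

    Finds the least n with cohort_size * sqrt(p(1-p)/n) < error_bound at the
    worst-case occupancy probability, then rounds up to the next multiple of
    ``round_to`` (minimum one multiple).
    """
    if error_bound <= 0:
        raise ValueError(f"error_bound must be positive, got {error_bound}")
    if cohort_size <= 0:
        raise ValueError(f"cohort_size must be positive, got {cohort_size}")
    if error_bound >= cohort_size:
        raise ValueError(
            f"error_bound {error_bound} >= cohort_size {cohort_size}: bound is vacuous"
        )
    if not (0.0 <= worst_case_p <= 1.0):
        raise ValueError(f"worst_case_p must lie in [0, 1], got {worst_case_p}")
    var = worst_case_p * (1.0 - worst_case_p)
    if var == 0.0:
        n = 1
    else:
        # least integer n with n > cohort^2 var / bound^2
        n = int(math.floor((cohort_size / error_bound) ** 2 * var)) + 1
    return int(math.ceil(n / round_to) * round_to)


@dataclass
class SimulationResult:
    """Per-year state counts from microsimulation with bootstrap uncertainty.

    ``expected`` is the analytic expectation for the same initial counts
    (the validation oracle); ``counts`` are the realised per-year counts;
    ``mean``/``variance``/``quantiles`` summarise bootstrap resamples of the
    simulated individuals.
    """

    years: np.ndarray
    counts: np.ndarray  # (n_years+1, 5) realised
    expected: np.ndarray  # (n_years+1, 5) analytic
    mean: np.ndarray
    variance: np.ndarray
    quantiles: dict[float, np.ndarray] = field(default_factory=dict)
    n_sim: int = 0
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        """Long format: year, state, statistic, value."""
        rows = []
        stats_map = {"count": self.counts, "expected": self.expected,
                     "boot_mean": self.mean, "boot_variance": self.variance}
        for q, arr in self.quantiles.items():
            stats_map[f"q{q:g}"] = arr
        for name, arr in stats_map.items():
            for yi, year in enumerate(self.years):
                for si, state in enumerate(STATE_ORDER):
                    rows.append((int(year), state.code, name, float(arr[yi, si])))
        return pd.DataFrame(rows, columns=["year", "state", "statistic", "value"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_sim": self.n_sim,
            "seed": self.seed,
            "years": [int(y) for y in self.years],
            "states": [s.code for s in STATE_ORDER],
            "counts": self.counts.tolist(),
            "expected": self.expected.tolist(),
            "boot_mean": self.mean.tolist(),
            "boot_variance": self.variance.tolist(),
            "quantiles": {str(q): a.tolist() for q, a in self.quantiles.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def simulate(
    init_states: list[HealthState] | np.ndarray,
    matrix: TransitionMatrix,
    n_years: int,
    seed: int,
    n_boot: int = 200,
    start_year: int | None = None,
) -> SimulationResult:
    """Individual-level Monte-Carlo simulation of the annual-cycle chain.

    Random numbers are consumed year by year, one uniform per individual per
    year in individual order (vectorised), so a fixed seed reproduces the
    same trajectories.  Bootstrap resampling of individuals provides the
    per-year mean/variance/quantile summaries.
    """
    if isinstance(init_states, np.ndarray) and init_states.dtype != object:
        states = init_states.astype(np.int64)
    else:
        states = np.array(
            [s.index if isinstance(s, HealthState) else int(s) for s in init_states],
            dtype=np.int64,
        )
    n = states.size
    if n < 1:
        raise ValueError("need at least one individual to simulate")
    if np.any((states < 0) | (states >= N_STATES)):
        raise ValueError("initial states out of range")
    rng = np.random.default_rng(seed)
    cum = np.cumsum(matrix.entries, axis=1)

    counts = np.zeros((n_years + 1, N_STATES))
    counts[0] = np.bincount(states, minlength=N_STATES)
    for t in range(1, n_years + 1):
        u = rng.random(n)
        states = (u[:, None] > cum[states]).sum(axis=1)
        counts[t] = np.bincount(states, minlength=N_STATES)

    # analytic oracle for the same initial counts
    expected = np.zeros_like(counts)
    expected[0] = counts[0]
    v = counts[0].astype(float)
    for t in range(1, n_years + 1):
        v = v @ matrix.entries
        expected[t] = v

    # per-year bootstrap: resampling n trajectories and counting one year's
    # states is distributionally a multinomial draw on that year's empirical
    # occupancy, so the marginal summaries can be drawn directly
    mean = np.zeros_like(counts)
    var = np.zeros_like(counts)
    qs = {q: np.zeros_like(counts) for q in _QUANTILES}
    for t in range(n_years + 1):
        p_hat = counts[t] / n
        reps = rng.multinomial(n, p_hat, size=n_boot).astype(float)
        mean[t] = reps.mean(axis=0)
        var[t] = reps.var(axis=0, ddof=1)
        qvals = np.quantile(reps, _QUANTILES, axis=0)
        for qi, q in enumerate(_QUANTILES):
            qs[q][t] = qvals[qi]

    years = np.arange(n_years + 1) + (start_year if start_year is not None else 0)
    return SimulationResult(
        years=years,
        counts=counts,
        expected=expected,
        mean=mean,
        variance=var,
        quantiles=qs,
        n_sim=n,
        seed=seed,
    )
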