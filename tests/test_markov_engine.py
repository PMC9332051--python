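"""Matrix construction, propagation, sample-size rule and microsimulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nephrocast.markov_engine import (
    StateVector,
    build_matrix,
    initialize_from_duration,
    propagate,
    required_n,
    simulate,
)
from nephrocast.parameters_io import (
    ALLOWED_TRANSITIONS,
    STATE_ORDER,
    HealthState,
    TransitionBound,
    TransitionTable,
    ValidationError,
)

N, M, C, E, D = (s.index for s in STATE_ORDER)


def make_table(values: dict[tuple[str, str], tuple[float, float]]) -> TransitionTable:
    return TransitionTable(
        tuple(
            TransitionBound(HealthState[f], HealthState[t], lo, hi)
            for (f, t), (lo, hi) in values.items()
        )
    )


ZERO_TABLE = make_table({(f.name, t.name): (0.0, 0.0) for f, t in ALLOWED_TRANSITIONS})


@st.composite
def random_tables(draw):
    vals = {}
    for f, t in ALLOWED_TRANSITIONS:
        hi = draw(st.floats(0.0, 0.2))
        lo = draw(st.floats(0.0, 1.0)) * hi
        vals[(f.name, t.name)] = (lo, hi)
    return make_table(vals)


class TestBuildMatrix:
    def test_max_policy_normoalbuminuria_row(self, table):
        m = build_matrix(table, "max")
        assert m.entries[N].tolist() == pytest.approx([0.963, 0.022, 0, 0, 0.015], abs=1e-12)

    def test_max_policy_esrd_row(self, table):
        m = build_matrix(table, "max")
        assert m.entries[E].tolist() == pytest.approx([0, 0, 0, 0.756, 0.244], abs=1e-12)

    def test_min_policy_micro_stay_probability(self, table):
        m = build_matrix(table, "min")
        assert m[M, M] == pytest.approx(1 - 0.025 - 0.026, abs=1e-12)

    def test_midpoint_policy_between_bounds(self, table):
        m = build_matrix(table, "midpoint")
        assert m[N, M] == pytest.approx((0.019 + 0.022) / 2)

    def test_death_row_is_absorbing(self, table):
        for policy in ("min", "max", "midpoint"):
            m = build_matrix(table, policy)
            assert m.entries[D].tolist() == [0, 0, 0, 0, 1.0]

    def test_overloaded_row_rejected_naming_the_state(self):
        # the load-time guard fires before any matrix can be built, so an
        # overloaded row can never reach construction
        with pytest.raises(ValidationError, match="MACRO"):
            make_table(
                {
                    (f.name, s.name): (0.5, 0.6) if f is HealthState.MACRO else (0.01, 0.02)
                    for f, s in ALLOWED_TRANSITIONS
                }
            )

    @given(random_tables(), st.sampled_from(["min", "max", "midpoint"]))
    @settings(max_examples=40, deadline=None)
    def test_rows_stochastic_and_sparsity_structure(self, t, policy):
        m = build_matrix(t, policy)
        a = m.entries
        assert np.all(a >= 0)
        assert np.allclose(a.sum(axis=1), 1.0, atol=1e-12)
        allowed = {(f.index, t_.index) for f, t_ in ALLOWED_TRANSITIONS}
        for i in range(5):
            for j in range(5):
                if i != j and (i, j) not in allowed:
                    assert a[i, j] == 0.0


class TestPropagate:
    def test_identity_chain_leaves_any_vector_unchanged(self, table):
        m = build_matrix(ZERO_TABLE, "max")
        init = StateVector(np.array([0.4, 0.3, 0.2, 0.05, 0.05]))
        traj = propagate(init, m, 5)
        for v in traj:
            assert v.values.tolist() == pytest.approx(init.values.tolist())

    def test_single_step_from_pure_normoalbuminuria(self, table):
        m = build_matrix(table, "max")
        init = StateVector(np.eye(5)[N])
        one = propagate(init, m, 1)[1]
        assert one.values.tolist() == pytest.approx([0.963, 0.022, 0, 0, 0.015])

    def test_ten_year_normoalbuminuric_share_decays_geometrically(self, table):
        m = build_matrix(table, "max")
        traj = propagate(StateVector(np.eye(5)[N]), m, 10)
        assert traj[10].values[N] == pytest.approx(0.963**10, rel=1e-12)

    def test_negative_years_rejected(self, table):
        with pytest.raises(ValueError):
            propagate(StateVector(np.eye(5)[N]), build_matrix(table, "max"), -1)

    @given(random_tables(), st.lists(st.floats(0.0, 1e6), min_size=5, max_size=5))
    @settings(max_examples=40, deadline=None)
    def test_mass_conserved_at_every_step(self, t, counts):
        total = sum(counts)
        if total == 0:
            counts = [1.0] * 5
            total = 5.0
        m = build_matrix(t, "max")
        traj = propagate(StateVector(np.array(counts), scale="persons"), m, 10)
        for v in traj:
            assert v.total == pytest.approx(total, rel=1e-9)

    def test_death_mass_non_decreasing_and_max_dominates_min(self, table):
        init = StateVector(np.eye(5)[N])
        tmax = [v.values[D] for v in propagate(init, build_matrix(table, "max"), 50)]
        tmin = [v.values[D] for v in propagate(init, build_matrix(table, "min"), 50)]
        assert np.all(np.diff(tmax) >= 0) and np.all(np.diff(tmin) >= 0)
        assert np.all(np.array(tmax) >= np.array(tmin))

    def test_all_mass_eventually_absorbed_in_death(self, table):
        m = build_matrix(table, "min")
        final = propagate(StateVector(np.eye(5)[N]), m, 500)[-1]
        assert final.values[D] == pytest.approx(1.0, abs=1e-6)


class TestInitializeFromDuration:
    def test_zero_duration_is_pure_normoalbuminuria(self, table):
        v = initialize_from_duration(0.0, build_matrix(table, "max"))
        assert v.values.tolist() == [1.0, 0, 0, 0, 0]

    def test_one_completed_year_equals_one_step(self, table):
        v = initialize_from_duration(1.0, build_matrix(table, "max"))
        assert v.values.tolist() == pytest.approx([0.963, 0.022, 0, 0, 0.015])

    def test_fifteen_years_matches_closed_form_stay_probability(self, table):
        v = initialize_from_duration(15.9, build_matrix(table, "max"))
        assert v.values[N] == pytest.approx(0.963**15, rel=1e-12)

    def test_negative_duration_rejected(self, table):
        with pytest.raises(ValueError):
            initialize_from_duration(-0.1, build_matrix(table, "max"))

    def test_survival_conditioning_drops_death_mass(self, table):
        v = initialize_from_duration(10, build_matrix(table, "max"))
        s = v.conditioned_on_survival()
        assert s.values[D] == 0.0
        assert s.total == pytest.approx(1.0)


class TestRequiredN:
    def test_published_cohort_and_bound_gives_80000(self):
        # ceil((5,449,204 * 0.5 / 10,000)^2) = 74,236 -> next 10,000 = 80,000
        assert required_n(10_000, 5_449_204) == 80_000

    def test_loose_bound_floors_at_one_rounding_block(self):
        assert required_n(5_449_204 / 2, 5_449_204) == 10_000

    def test_zero_variance_case_is_minimal(self):
        assert required_n(10_000, 5_449_204, worst_case_p=0.0) == 10_000

    def test_vacuous_bound_rejected(self):
        with pytest.raises(ValueError):
            required_n(6_000_000, 5_449_204)

    def test_resulting_sample_size_achieves_the_error_bound(self):
        # realized SE of the scaled occupancy estimate stays below the bound
        cohort, bound = 5_449_204, 10_000
        n = required_n(bound, cohort)
        assert cohort * np.sqrt(0.25 / n) < bound
        rng = np.random.default_rng(0)
        means = rng.binomial(n, 0.5, size=400) / n * cohort
        assert means.std(ddof=1) < bound

    @given(st.floats(1e3, 1e5), st.floats(1e6, 1e7))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_the_error_bound(self, bound, cohort):
        assert required_n(bound, cohort) >= required_n(bound * 2, cohort)


class TestSimulate:
    def test_identity_matrix_freezes_everyone(self, table):
        m = build_matrix(ZERO_TABLE, "max")
        init = [HealthState.MICRO] * 500
        res = simulate(init, m, 5, seed=1)
        assert np.all(res.counts[:, M] == 500)

    def test_one_step_micro_count_within_binomial_error(self, table):
        m = build_matrix(table, "max")
        res = simulate([HealthState.NORMO] * 100_000, m, 1, seed=2)
        sd = np.sqrt(100_000 * 0.022 * 0.978)
        assert abs(res.counts[1, M] - 2_200) < 4 * sd

    def test_monte_carlo_means_match_analytic_expectation(self, table):
        # the engine's own validation: simulated counts vs matrix propagation
        m = build_matrix(table, "max")
        n = 200_000
        res = simulate([HealthState.NORMO] * n, m, 16, seed=3)
        p = res.expected / n
        se = np.sqrt(np.clip(p * (1 - p), 1e-12, None) * n)
        dev = np.abs(res.counts - res.expected)
        assert np.all(dev[1:] <= 5 * se[1:] + 1e-9)

    def test_fixed_seed_reproduces_counts(self, table):
        m = build_matrix(table, "min")
        a = simulate([HealthState.NORMO] * 1000, m, 8, seed=11)
        b = simulate([HealthState.NORMO] * 1000, m, 8, seed=11)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.mean, b.mean)

    def test_bootstrap_quantiles_ordered_and_bracket_counts(self, table):
        m = build_matrix(table, "max")
        res = simulate([HealthState.NORMO] * 20_000, m, 10, seed=4)
        q = res.quantiles
        assert np.all(q[0.025] <= q[0.25]) and np.all(q[0.25] <= q[0.50])
        assert np.all(q[0.50] <= q[0.75]) and np.all(q[0.75] <= q[0.975])

    def test_empty_cohort_rejected(self, table):
        with pytest.raises(ValueError):
            simulate([], build_matrix(table, "max"), 1, seed=0)

    @pytest.mark.parametrize("start", [HealthState.NORMO, HealthState.MICRO,
                                       HealthState.MACRO, HealthState.ESRD])
    def test_one_step_frequencies_recover_matrix_row(self, table, start):
        # 250,000 simulated person-years per row; each entry within its
        # 99% binomial interval
        m = build_matrix(table, "max")
        n = 250_000
        res = simulate([start] * n, m, 1, seed=start.index)
        p_hat = res.counts[1] / n
        for j in range(5):
            p = m.entries[start.index, j]
            half = 2.576 * np.sqrt(max(p * (1 - p), 1e-12) / n)
            assert abs(p_hat[j] - p) <= half + 1e-9

    def test_esrd_sojourn_matches_geometric_closed_form(self, table):
        # single exit rate p -> expected completed-year sojourn 1/p
        m = build_matrix(table, "max")
        n, horizon = 50_000, 200
        res = simulate([HealthState.ESRD] * n, m, horizon, seed=5)
        sojourn = res.counts[:, E].sum() / n
        assert sojourn == pytest.approx(1 / 0.244, abs=0.05)

    def test_long_format_export_round_trips_counts(self, table, tmp_path):
        m = build_matrix(table, "max")
        res = simulate([HealthState.NORMO] * 100, m, 3, seed=6)
        df = res.to_frame()
        got = df[(df.statistic == "count") & (df.state == "NORMO") & (df.year == 0)]
        assert got.value.iloc[0] == 100
        res.to_json(tmp_path / "sim.json")
        assert (tmp_path / "sim.json").stat().st_size > 0
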