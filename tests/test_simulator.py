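"""Solvers: closed forms, SSA statistics, events, chaining, sweeps, queries."""

import math

import numpy as np
import pytest

from metareact import (Model, Simulation, SimulationError, SweepResults, Zero,
                       u)


def exp_model(k_per_h=1.05, x0=1):
    m = Model()
    A = m.base_species("A")
    A >> 2 * A [k_per_h / u.h]
    A(x0)
    return m, A


class TestOde:
    def test_exponential_growth_matches_closed_form(self):
        m, A = exp_model()
        s = Simulation(A)
        s.duration = 3 * u.h
        s.rtol, s.atol = 1e-10, 1e-12
        res = s.run()
        t = res.trajectories[0].time / 3600.0
        series = res[A][0]
        expected = np.exp(1.05 * t)
        assert np.max(np.abs(series - expected) / expected) < 1e-6

    def test_exponential_decay_matches_closed_form(self):
        m = Model()
        X = m.base_species("X")
        X >> Zero [0.7 / u.h]
        X(500)
        s = Simulation(X)
        s.duration = 5 * u.h
        s.rtol, s.atol = 1e-10, 1e-12
        res = s.run()
        t = res.trajectories[0].time / 3600.0
        series = res[X][0]
        expected = 500 * np.exp(-0.7 * t)
        assert np.max(np.abs(series - expected) / expected) < 1e-6

    def test_zero_reaction_model_stays_constant(self):
        m = Model()
        A = m.base_species("A")
        A(42)
        s = Simulation(A)
        s.duration = 1 * u.h
        res = s.run()
        assert np.all(res[A][0] == 42)

    def test_reversible_pair_conserves_total(self):
        m = Model()
        A, B = m.base_species("A", "B")
        A >> B [1 / u.h]
        B >> A [0.5 / u.h]
        A(100)
        s = Simulation(A | B)
        s.duration = 10 * u.h
        res = s.run()
        total = res[A][0] + res[B][0]
        assert np.max(np.abs(total - 100)) < 1e-4


class TestSsa:
    def test_pure_death_mean_within_three_standard_errors(self):
        m = Model()
        X = m.base_species("X")
        X >> Zero [1 / u.h]
        X(100)
        s = Simulation(X)
        s.duration = 2 * u.h
        s.method = "stochastic"
        s.runs = 200
        res = s.run(seed=11)
        p = math.exp(-2.0)
        mean = np.mean(res.final(X))
        se = math.sqrt(100 * p * (1 - p) / 200)
        assert abs(mean - 100 * p) < 3 * se

    def test_identical_seeds_are_bit_identical(self):
        m = Model()
        X = m.base_species("X")
        X >> 2 * X [1 / u.h]
        X >> Zero [0.5 / u.h]
        X(50)
        s = Simulation(X)
        s.duration = 3 * u.h
        s.method = "stochastic"
        s.runs = 5
        r1 = s.run(seed=3)
        r2 = s.run(seed=3)
        for t1, t2 in zip(r1.trajectories, r2.trajectories):
            assert np.array_equal(t1.time, t2.time)
            assert all(np.array_equal(t1.amounts[n], t2.amounts[n])
                       for n in t1.amounts)

    def test_conservation_is_exact(self):
        m = Model()
        A, B = m.base_species("A", "B")
        A >> B [1 / u.h]
        B >> A [1 / u.h]
        A(200)
        s = Simulation(A | B)
        s.duration = 2 * u.h
        s.method = "stochastic"
        res = s.run(seed=1)
        total = res[A][0] + res[B][0]
        assert np.all(total == 200)

    def test_zero_propensity_trajectory_is_flat(self):
        m = Model()
        A, B = m.base_species("A", "B")
        A + B >> Zero [1 / u.h]
        A(10)  # B stays 0, so nothing ever fires
        s = Simulation(A | B)
        s.duration = 1 * u.h
        s.method = "stochastic"
        res = s.run(seed=0)
        assert np.all(res[A][0] == 10)

    def test_scaled_ssa_converges_to_ode(self):
        # deterministic surrogate: amounts x1000, same per-capita rates
        n = 1000
        m = Model()
        X = m.base_species("X")
        X >> Zero [1 / u.h]
        X(n)
        s = Simulation(X)
        s.duration = 1 * u.h
        s.method = "stochastic"
        s.runs = 20
        res = s.run(seed=9)
        mean = np.mean(res.final(X)) / n
        ode = math.exp(-1.0)
        assert abs(mean - ode) / ode < 0.05


class TestEvents:
    def test_time_event_sets_species(self):
        m = Model()
        A = m.base_species("A")
        A >> Zero [1 / u.h]
        A(100)
        s = Simulation(A)
        s.duration = 2 * u.h
        s.event_time(1 * u.h, {A: 500})
        res = s.run()
        tr = res.trajectories[0]
        after = res[A][0][np.searchsorted(tr.time, 3600.0 + 30)]
        assert 400 < after <= 500
        assert res[A][0][-1] == pytest.approx(500 * math.exp(-1.0), rel=1e-3)

    def test_event_beyond_duration_never_fires(self):
        m = Model()
        A = m.base_species("A")
        A(10)
        s = Simulation(A)
        s.duration = 1 * u.h
        s.event_time(2 * u.h, {A: 99})
        res = s.run()
        assert np.all(res[A][0] == 10)

    def test_condition_event_fires_once_on_rising_edge(self):
        m = Model()
        A, B = m.base_species("A", "B")
        A >> 2 * A [1 / u.h]
        A(10)
        s = Simulation(A | B)
        s.duration = 4 * u.h
        s.event_condition(A >= 100, {B: 7})
        res = s.run()
        b = res[B][0]
        assert b[0] == 0 and b[-1] == 7
        # fires near t = ln(10)/1 h
        t_fire = res.trajectories[0].time[np.argmax(b > 0)] / 3600
        assert abs(t_fire - math.log(10)) < 0.05

    def test_condition_event_in_stochastic_run(self):
        m = Model()
        A, B = m.base_species("A", "B")
        A >> 2 * A [1 / u.h]
        A(20)
        s = Simulation(A | B)
        s.duration = 6 * u.h
        s.method = "stochastic"
        s.event_condition(A >= 200, {B: 1})
        res = s.run(seed=4)
        assert res[B][0][-1] == 1

    def test_detector_style_protocol_sequence(self):
        # three timed assignments applied in order
        m = Model()
        T = m.base_species("T")
        s = Simulation(T)
        s.duration = 100 * u.h
        s.event_time(25 * u.h, {T: 100})
        s.event_time(60 * u.h, {T: 0})
        s.event_time(80 * u.h, {T: 55})
        res = s.run()
        tr = res.trajectories[0]
        series = res[T][0]

        def value_at(hour):
            return series[np.searchsorted(tr.time, hour * 3600.0 + 1)]
        assert value_at(10) == 0 and value_at(40) == 100
        assert value_at(70) == 0 and value_at(90) == 55


class TestDurationCondition:
    def test_ode_stops_at_first_crossing(self):
        m = Model()
        X = m.base_species("X")
        X >> Zero [1 / u.h]
        X(100)
        s = Simulation(X)
        s.duration = X <= 50
        s.condition_cap = 10 * u.h
        s.rtol, s.atol = 1e-10, 1e-12
        res = s.run()
        t_stop = res.trajectories[0].end_time / 3600
        assert abs(t_stop - math.log(2)) < 1e-6
        assert res[X][0][-1] == pytest.approx(50, rel=1e-6)

    def test_condition_true_at_start_stops_immediately(self):
        m = Model()
        X = m.base_species("X")
        X(0)
        s = Simulation(X)
        s.duration = X <= 0
        res = s.run()
        assert res.trajectories[0].end_time == 0.0


class TestChaining:
    def test_state_hands_off_between_phases(self):
        m = Model()
        A = m.base_species("A")
        A >> 2 * A [1 / u.h]
        A(1)
        s1 = Simulation(A)
        s1.duration = 1 * u.h
        s2 = Simulation(A)
        s2.duration = 1 * u.h
        res = (s1 + s2).run()
        assert res[A][0][-1] == pytest.approx(math.exp(2.0), rel=1e-4)
        assert res.trajectories[0].boundaries == pytest.approx(
            [0.0, 3600.0, 7200.0])

    def test_single_phase_chain_equals_phase_alone(self):
        m = Model()
        A = m.base_species("A")
        A >> Zero [1 / u.h]
        A(50)
        s = Simulation(A)
        s.duration = 1 * u.h
        alone = s.run()[A][0]
        from metareact import ChainedSimulation
        chained = ChainedSimulation([s]).run()[A][0]
        assert np.array_equal(alone, chained)

    def test_phase_only_species_starts_at_declared_initial(self):
        m = Model()
        A, B = m.base_species("A", "B")
        A(10)
        s1 = Simulation(A)
        s1.duration = 1 * u.h
        B(33)
        s2 = Simulation(A | B)
        s2.duration = 1 * u.h
        res = (s1 + s2).run()
        assert res[B][0][-1] == 33

    def test_mixed_methods_deterministic_then_stochastic(self):
        m = Model()
        A = m.base_species("A")
        A >> 2 * A [1 / u.h]
        A(1)
        s1 = Simulation(A)
        s1.duration = 3 * u.h
        A >> Zero [2 / u.h]
        s2 = Simulation(A)
        s2.duration = (A <= 0)
        s2.method = "stochastic"
        s2.condition_cap = 200 * u.h
        res = (s1 + s2).run(seed=6)
        assert res[A][0][-1] == 0.0


class TestSweep:
    def _sweep_model(self, values_a, values_b):
        m = Model()
        A = m.base_species("A")
        ka = m.parameter("ka", values_a)
        kb = m.parameter("kb", values_b)
        Zero >> A [lambda: ka * (1 / u.h)]
        A >> Zero [lambda: kb * (1 / u.h)]
        s = Simulation(A)
        s.duration = 50 * u.h
        return m, A, s

    def test_full_factorial_cell_count(self):
        m, A, s = self._sweep_model([1, 2, 3], [1, 2, 3, 4])
        res = s.run(seed=0)
        assert isinstance(res, SweepResults) and len(res) == 12

    def test_single_valued_parameters_run_one_cell(self):
        m, A, s = self._sweep_model([2], [1])
        res = s.run(seed=0)
        assert not isinstance(res, SweepResults)
        assert res[A][0][-1] == pytest.approx(2.0, rel=1e-3)

    def test_cell_results_keyed_by_assignment(self):
        m, A, s = self._sweep_model([1.0, 4.0], [1.0, 2.0])
        res = s.run(seed=0)
        # steady state ka/kb
        cell = res[{"ka": 4.0, "kb": 2.0}]
        assert cell[A][0][-1] == pytest.approx(2.0, rel=1e-3)
        cell = res[{"ka": 1.0, "kb": 1.0}]
        assert cell[A][0][-1] == pytest.approx(1.0, rel=1e-3)


class TestQueryAccess:
    def test_query_sums_matching_series(self):
        m = Model()
        Age, Mortal = m.base_species("Age", "Mortal")
        Age.young, Age.old
        Tree = m.species("Tree", Age * Mortal)
        Tree(10)
        Tree.old(4)
        s = Simulation(Tree)
        s.duration = 1 * u.h
        res = s.run()
        assert res[Tree.young][0][0] == 10
        assert res[Tree][0][0] == 14

    def test_query_on_unsimulated_meta_species_is_an_error(self):
        m = Model()
        A, B = m.base_species("A", "B")
        A(5)
        s = Simulation(A)
        s.duration = 1 * u.h
        res = s.run()
        with pytest.raises(SimulationError):
            res[B]

    def test_mean_and_sd_shapes(self):
        m = Model()
        X = m.base_species("X")
        X >> Zero [1 / u.h]
        X(50)
        s = Simulation(X)
        s.duration = 1 * u.h
        s.method = "stochastic"
        s.runs = 10
        res = s.run(seed=2)
        t, mean = res.mean(X)
        _, sd = res.sd(X)
        assert len(t) == len(mean) == len(sd)
        assert mean[0] == 50 and sd[0] == 0
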