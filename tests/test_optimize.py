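"""N-LRTO ladder growth, offset rebalancing and the convergence rule."""

import math

import numpy as np
import pytest

from edsflow.metrics import SamplingReport
from edsflow.optimize import (
    IterationRecord,
    OptimizationSchedule,
    OptimizationState,
    RebalanceConfig,
    check_convergence,
    correction_for_fold_reduction,
    detect_bottlenecks,
    nlrto_step,
    rebalance_offsets,
    rebalancing_correction_cap,
    run_optimization,
)
from edsflow.sampling import ExchangeRecord, RoundTripStats, SDistribution
from edsflow.toys import analytic_free_energy_matrix


def _report(f_mc):
    f_mc = np.asarray(f_mc, dtype=float)
    return SamplingReport(f_mc=f_mc, f_occur=None, undersampling_fraction=None, n_frames=100)


def _records(specs):
    """specs: list of (pair_upper, accepted, mc_i, mc_j)."""
    return [
        ExchangeRecord(step=k, pair=(p, p + 1), probability=0.5, accepted=acc,
                       mc_states=(mi, mj))
        for k, (p, acc, mi, mj) in enumerate(specs)
    ]


class TestDetectBottlenecks:
    def test_all_accepted_zero_severity(self):
        ladder = SDistribution((1.0, 0.5, 0.1))
        recs = _records([(0, True, 0, 0), (1, True, 0, 0)] * 5)
        bn = detect_bottlenecks(recs, n_states=1, s_distribution=ladder)
        assert all(sev == 0.0 for _, sev in bn[0])

    def test_zero_attempt_pair_ranked_first(self):
        ladder = SDistribution((1.0, 0.5, 0.1))
        # pair (1,2) never attempted for state 0 -> severity 1, ranked first
        recs = _records([(0, True, 0, 0)] * 4)
        bn = detect_bottlenecks(recs, n_states=1, s_distribution=ladder)
        assert bn[0][0][0] == 1 and bn[0][0][1] == 1.0

    def test_per_state_recount_matches_brute_force(self, rng):
        ladder = SDistribution((1.0, 0.4, 0.2, 0.05))
        n_states, n_int = 3, 3
        specs = []
        for _ in range(300):
            p = int(rng.integers(0, n_int))
            specs.append((p, bool(rng.random() < 0.5),
                          int(rng.integers(0, n_states)), int(rng.integers(0, n_states))))
        recs = _records(specs)
        bn = detect_bottlenecks(recs, n_states=n_states, s_distribution=ladder)
        for state in range(n_states):
            att = np.zeros(n_int)
            acc = np.zeros(n_int)
            for p, a, mi, mj in specs:
                if state in {mi, mj}:
                    att[p] += 1
                    acc[p] += a
            sev = np.where(
                att > 0, 1 - np.divide(acc, att, out=np.zeros_like(acc), where=att > 0), 1.0
            )
            got = dict(bn[state])
            for k in range(n_int):
                assert got[k] == pytest.approx(sev[k])

    def test_tie_break_prefers_larger_gap(self):
        ladder = SDistribution((1.0, 0.6, 0.5))  # gaps 0.4 then 0.1
        recs = _records([(0, False, 0, 0), (1, False, 0, 0)])
        bn = detect_bottlenecks(recs, n_states=1, s_distribution=ladder)
        assert bn[0][0][0] == 0


class TestNlrtoStep:
    def test_midpoint_insertion(self):
        ladder = SDistribution((1.0, 0.1, 0.01))
        bn = [[(1, 1.0), (0, 0.0)]]
        new = nlrto_step(ladder, bn, n_insert=1)
        assert 0.055 in [round(v, 10) for v in new.values]

    def test_equal_spacing_for_multiple_insertions(self):
        ladder = SDistribution((1.0, 0.5, 0.004))
        bn = [[(0, 1.0), (1, 0.0)]]
        new = nlrto_step(ladder, bn, n_insert=4)
        inserted = sorted(set(new.values) - set(ladder.values), reverse=True)
        np.testing.assert_allclose(inserted, [0.9, 0.8, 0.7, 0.6], rtol=1e-12)

    def test_prior_ladder_retained(self, rng):
        ladder = SDistribution(tuple(np.logspace(0, -3, 7)))
        bn = [[(int(rng.integers(0, 6)), 1.0)] for _ in range(3)]
        new = nlrto_step(ladder, bn, n_insert=4)
        assert set(ladder.values) <= set(new.values)

    def test_round_robin_across_states(self):
        ladder = SDistribution((1.0, 0.5, 0.1))
        bn = [[(0, 0.9)], [(1, 0.8)]]
        new = nlrto_step(ladder, bn, n_insert=2)
        # one insertion per state's top interval
        inserted = set(new.values) - set(ladder.values)
        assert len(inserted) == 2
        assert any(0.5 < v < 1.0 for v in inserted) and any(0.1 < v < 0.5 for v in inserted)

    def test_duplicates_coalesced(self):
        ladder = SDistribution((1.0, 0.5))
        bn = [[(0, 1.0)], [(0, 1.0)]]
        new = nlrto_step(ladder, bn, n_insert=2)
        vals = new.as_array()
        assert len(vals) == len(set(vals))


class TestRebalance:
    def test_ideal_sampling_fixed_point(self, thermo):
        cfg = RebalanceConfig(thermo=thermo)
        offsets = np.array([0.0, -3.0, 12.0, 5.0])
        new = rebalance_offsets(_report([0.25] * 4), offsets, cfg)
        np.testing.assert_array_equal(new, offsets)

    def test_zero_sampling_correction_is_literal_maximum(self, thermo):
        # f = 0, x = 30: dE = (1/beta) ln(31); at 300 K this is 8.566 kJ/mol,
        # distinct from the 8.43 quoted as kB*T*ln(30) at 298.15 K
        cfg = RebalanceConfig(intensity_factor=30.0, thermo=thermo)
        new = rebalance_offsets(_report([0.0, 1.0]), np.zeros(2), cfg)
        literal = thermo.kT * math.log(31.0)
        assert new[0] == pytest.approx(literal, rel=1e-12)
        assert literal == pytest.approx(8.5655, abs=5e-4)
        assert rebalancing_correction_cap(thermo, 30.0) == pytest.approx(literal, rel=1e-12)
        from edsflow.potentials import ThermoContext

        assert correction_for_fold_reduction(
            ThermoContext(temperature=298.15), 30.0
        ) == pytest.approx(8.43, abs=5e-3)

    def test_oversampled_state_gets_negative_correction(self, thermo):
        cfg = RebalanceConfig(thermo=thermo)
        new = rebalance_offsets(_report([0.7, 0.1, 0.1, 0.1]), np.zeros(4), cfg)
        assert new[0] < 0
        assert np.all(new[1:] > 0)

    def test_correction_magnitude_cap(self, thermo, rng):
        cfg = RebalanceConfig(intensity_factor=30.0, thermo=thermo)
        cap = rebalancing_correction_cap(thermo, 30.0)
        for _ in range(50):
            raw = rng.random(5)
            f = raw / raw.sum()
            new = rebalance_offsets(_report(f), np.zeros(5), cfg)
            assert np.all(np.abs(new) <= cap + 1e-12)

    def test_intensity_factor_must_be_positive(self, thermo):
        with pytest.raises(ValueError):
            RebalanceConfig(intensity_factor=0.0, thermo=thermo)


def _iteration(f_mc, n_rt, tau, n_steps=5000, n_levels=5):
    return IterationRecord(
        kind="s_opt",
        s_distribution=SDistribution(tuple(np.logspace(0, -2, n_levels))),
        offsets=np.zeros(len(f_mc)),
        round_trips=RoundTripStats(
            n_round_trips=n_rt,
            mean_round_trip_time=tau,
            round_trip_times=np.full(n_rt, tau if tau else 0.0),
            per_walker_counts=np.zeros(n_levels, dtype=int),
        ),
        report=_report(f_mc),
        n_steps=n_steps,
    )


class TestCheckConvergence:
    def test_unsampled_state_blocks_convergence(self):
        ok, reasons = check_convergence(_iteration([0.5, 0.5, 0.0], 10, 100.0))
        assert not ok
        assert any("state sampling" in r for r in reasons)

    def test_zero_round_trips_blocks_convergence(self):
        ok, reasons = check_convergence(_iteration([0.4, 0.3, 0.3], 0, None))
        assert not ok
        assert any("round trips" in r for r in reasons)

    def test_slow_round_trips_block_convergence(self):
        # tau/nRT = (1e6 steps / 5e5 per ns) / 1 = 2 ns >= 0.5 ns
        ok, reasons = check_convergence(_iteration([0.4, 0.3, 0.3], 1, 1.0e6))
        assert not ok
        assert any("tau_bar/nRT" in r for r in reasons)

    def test_all_clauses_pass(self):
        ok, reasons = check_convergence(_iteration([0.4, 0.3, 0.3], 20, 500.0))
        assert ok and reasons == []


class TestRunOptimization:
    def test_zero_caps_return_input_unchanged(self, thermo, benchmark_states):
        ladder = SDistribution((1.0, 0.1))
        init = OptimizationState(
            s_distribution=ladder, offsets=np.zeros(5), configurations=np.zeros((2, 1))
        )
        sched = OptimizationSchedule(max_s_iterations=0, max_rebalance_iterations=0)
        out = run_optimization(
            benchmark_states, thermo, init, sched, np.random.default_rng(0)
        )
        assert not out.converged
        assert out.s_distribution.values == ladder.values
        np.testing.assert_array_equal(out.offsets, np.zeros(5))
        assert out.history == []

    def test_ideal_start_converges_quickly(self, thermo, benchmark_states):
        # analytic offsets and a dense ladder: one s-iteration, few rebalances
        offsets = analytic_free_energy_matrix(benchmark_states, thermo)[:, 0]
        ladder = SDistribution(tuple(np.logspace(0, -3, 14)))
        mins = np.array([st.minimum for st in benchmark_states])
        init = OptimizationState(
            s_distribution=ladder,
            offsets=offsets,
            configurations=mins[np.arange(14) % 5],
        )
        sched = OptimizationSchedule(
            s_iteration_steps=(6000,), max_s_iterations=3,
            rebalance_steps=4000, max_rebalance_iterations=3,
            exchange_interval=10,
        )
        out = run_optimization(
            benchmark_states, thermo, init, sched, np.random.default_rng(8)
        )
        s_iters = [r for r in out.history if r.kind == "s_opt"]
        rebal = [r for r in out.history if r.kind == "rebalance"]
        assert len(s_iters) == 1
        assert len(rebal) <= 3
        assert out.converged

    def test_history_preserves_ladder_growth(self, thermo, benchmark_states):
        offsets = analytic_free_energy_matrix(benchmark_states, thermo)[:, 0]
        ladder = SDistribution(tuple(np.logspace(0, -3, 5)))
        mins = np.array([st.minimum for st in benchmark_states])
        init = OptimizationState(
            s_distribution=ladder, offsets=offsets,
            configurations=mins[np.arange(5) % 5],
        )
        sched = OptimizationSchedule(
            s_iteration_steps=(1500,), max_s_iterations=3,
            rebalance_steps=0, max_rebalance_iterations=0,
            rt_time_limit_ns=1e-9,  # unreachable: force all three s-iterations
        )
        out = run_optimization(
            benchmark_states, thermo, init, sched, np.random.default_rng(9)
        )
        ladders = [set(r.s_distribution.values) for r in out.history]
        for prev, nxt in zip(ladders, ladders[1:]):
            assert prev <= nxt
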