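"""Replica-ladder optimisation (N-LRTO) and energy-offset rebalancing.

N-LRTO (multistate local round-trip-time optimisation) inserts new
replicas by linear interpolation into the s-intervals with the worst
exchange acceptance, judged *per end state*: an attempt counts towards a
state's statistics when that state was the maximal contributor on either
side of the attempted swap.  Replica positions from earlier iterations are
always retained.

Offset rebalancing drives the maximal-contributor fractions ``f_mc`` at
s = 1 towards the ideal ``1/N`` by the iterative correction

    dE_i = -(1/beta) * ln((f_i^mc + c) / (1/N + c)),   c = (1/N) / x

with pseudo-count intensity factor ``x`` (default 30).  The pseudo count
keeps the correction finite at ``f_i = 0``, where it attains its literal
maximum ``(1/beta) * ln(x + 1)``.  The commonly quoted cap for an x-fold
under-sampled state without the pseudo count is ``kB*T*ln(x)``; both
quantities are exposed because they differ (8.57 vs 8.43 kJ/mol at
x = 30 and 300 vs 298.15 K) and the workflow log prints both.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .metrics import SamplingReport, sampling_report
from .potentials import ThermoContext, pin_offsets
from .sampling import (
    STEPS_PER_NS,
    ExchangeRecord,
    ReplicaEnsemble,
    RoundTripStats,
    SDistribution,
    run_reeds,
)

__all__ = [
    "RebalanceConfig",
    "OptimizationSchedule",
    "OptimizationState",
    "IterationRecord",
    "detect_bottlenecks",
    "nlrto_step",
    "rebalance_offsets",
    "rebalancing_correction_cap",
    "correction_for_fold_reduction",
    "check_convergence",
    "run_optimization",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RebalanceConfig:
    """Pseudo-count intensity factor x > 0 (default 30) and thermo context."""

    intensity_factor: float = 30.0
    thermo: ThermoContext = field(default_factory=ThermoContext)

    def __post_init__(self) -> None:
        if not self.intensity_factor > 0:
            raise ValueError("intensity_factor must be positive")


def rebalancing_correction_cap(thermo: ThermoContext, intensity_factor: float = 30.0) -> float:
    """Literal maximum of the rebalancing correction, attained at f_mc = 0.

    Equals ``(1/beta) * ln(x + 1)`` independently of N; 8.57 kJ/mol at
    x = 30 and T = 300 K.
    """
    return thermo.kT * math.log(intensity_factor + 1.0)


def correction_for_fold_reduction(thermo: ThermoContext, fold: float = 30.0) -> float:
    """``kB*T*ln(fold)``: correction for a ``fold``-times under-sampled state
    relative to ideal, ignoring the pseudo count.  At fold = 30 and
    T = 298.15 K this is the familiar 8.43 kJ/mol figure."""
    return thermo.kT * math.log(fold)


def rebalance_offsets(
    report: SamplingReport, offsets: np.ndarray, config: RebalanceConfig
) -> np.ndarray:
    """One rebalancing step applied to the offsets, from an s = 1 report.

    Exact fixed point at f_mc = 1/N for all states.  The returned vector is
    absolute; use :func:`edsflow.potentials.pin_offsets` for reporting
    relative to state 1.
    """
    offsets = np.asarray(offsets, dtype=float)
    f = np.asarray(report.f_mc, dtype=float)
    ideal = report.ideal_fraction
    c = ideal / config.intensity_factor
    correction = -config.thermo.kT * np.log((f + c) / (ideal + c))
    return offsets + correction


def detect_bottlenecks(
    exchange_records: Sequence[ExchangeRecord],
    n_states: int,
    s_distribution: SDistribution,
) -> list[list[tuple[int, float]]]:
    """Per-state ranking of ladder intervals by exchange bottleneck severity.

    For each end state i, only attempts where i was the maximal contributor
    on either side of the swap count; severity = 1 - acceptance rate.  An
    interval with zero attempts for a state is treated as a full bottleneck
    (severity 1) with a logged warning.  Ties break towards the larger
    s-gap, then the lower interval index.  Interval k spans
    (s_k, s_{k+1}).
    """
    s = s_distribution.as_array()
    n_int = len(s) - 1
    if n_int < 1:
        return [[] for _ in range(n_states)]
    attempts = np.zeros((n_states, n_int), dtype=int)
    accepted = np.zeros((n_states, n_int), dtype=int)
    for rec in exchange_records:
        k = rec.pair[0]
        if not (0 <= k < n_int and rec.pair[1] == k + 1):
            raise ValueError(f"exchange record pair {rec.pair} is not a neighbour pair")
        for st in set(rec.mc_states):
            if 0 <= st < n_states:
                attempts[st, k] += 1
                if rec.accepted:
                    accepted[st, k] += 1
    gaps = s[:-1] - s[1:]
    out: list[list[tuple[int, float]]] = []
    for i in range(n_states):
        sev = np.ones(n_int)
        has = attempts[i] > 0
        sev[has] = 1.0 - accepted[i, has] / attempts[i, has]
        if not has.all():
            logger.warning(
                "state %d: %d interval(s) with zero exchange attempts treated as full bottlenecks",
                i + 1,
                int((~has).sum()),
            )
        order = sorted(range(n_int), key=lambda k: (-sev[k], -gaps[k], k))
        out.append([(k, float(sev[k])) for k in order])
    return out


def nlrto_step(
    s_distribution: SDistribution,
    bottlenecks: list[list[tuple[int, float]]],
    n_insert: int = 4,
) -> SDistribution:
    """Insert ``n_insert`` replicas at the per-state worst bottlenecks.

    Insertions are allocated round-robin over the states' top-severity
    intervals; within an interval the new s-values are linearly
    interpolated with equal spacing between the endpoints.  All previous
    s-values are retained; near-duplicates (within 1e-12 relative) are
    coalesced.
    """
    if n_insert < 1:
        raise ValueError("n_insert must be >= 1")
    s = s_distribution.as_array()
    n_states = len(bottlenecks)
    counts: dict[int, int] = {}
    for a in range(n_insert):
        ranking = bottlenecks[a % n_states]
        if not ranking:
            continue
        k = ranking[0][0]
        counts[k] = counts.get(k, 0) + 1
    new_values: list[float] = list(s)
    for k, m in counts.items():
        pts = np.linspace(s[k], s[k + 1], m + 2)[1:-1]
        new_values.extend(float(p) for p in pts)
    new_values.sort(reverse=True)
    merged: list[float] = []
    for v in new_values:
        if merged and abs(merged[-1] - v) <= 1e-12 * max(abs(v), abs(merged[-1])):
            continue
        merged.append(v)
    return SDistribution(tuple(merged))


@dataclass
class IterationRecord:
    """History entry for one optimisation iteration."""

    kind: str  # "s_opt" or "rebalance"
    s_distribution: SDistribution
    offsets: np.ndarray
    round_trips: RoundTripStats
    report: SamplingReport  # at s = 1
    n_steps: int


@dataclass
class OptimizationState:
    """Current ladder, offsets and configurations, plus the full history."""

    s_distribution: SDistribution
    offsets: np.ndarray
    configurations: np.ndarray  # (R, d)
    iteration: int = 0
    history: list[IterationRecord] = field(default_factory=list)
    converged: bool = False
    status_reasons: list[str] = field(default_factory=list)


@dataclass
class OptimizationSchedule:
    """Iteration lengths and caps for the optimisation stage.

    Lengths are in MC steps; the s-iteration ramp mirrors the canonical
    short-to-longer schedule (each entry reused once exhausted).  The
    ns-denominated round-trip criterion is mapped through
    ``steps_per_ns``.
    """

    s_iteration_steps: tuple[int, ...] = (3000, 6000, 9000)
    max_s_iterations: int = 6
    n_insert: int = 4
    rebalance_steps: int = 5000
    max_rebalance_iterations: int = 20
    f_mc_tolerance: float = 0.12
    exchange_interval: int = 20
    record_interval: int = 2
    steps_per_ns: float = STEPS_PER_NS
    rt_time_limit_ns: float = 0.5
    step_size: float | None = None


def check_convergence(
    record: IterationRecord,
    steps_per_ns: float = STEPS_PER_NS,
    rt_time_limit_ns: float = 0.5,
) -> tuple[bool, list[str]]:
    """Convergence rule for the optimisation stage.

    Converged iff (a) every end state has f_mc > 0 at s = 1, (b) round
    trips per ns exceed zero, and (c) tau_bar / nRT < 0.5 ns.  The ratio in
    (c) is the literal mean round-trip time divided by the round-trip
    count; both quantities are logged since the criterion is also read as
    "improvement of tau_bar per iteration" in some workflows.
    """
    reasons: list[str] = []
    if np.any(record.report.f_mc <= 0.0):
        missing = [str(i + 1) for i, f in enumerate(record.report.f_mc) if f <= 0]
        reasons.append(f"state sampling: f_mc = 0 for state(s) {', '.join(missing)}")
    rt = record.round_trips
    sim_ns = record.n_steps / steps_per_ns
    if rt.n_round_trips == 0 or sim_ns <= 0 or rt.n_round_trips / sim_ns <= 0:
        reasons.append("round trips: none completed")
    else:
        tau_ns = (rt.mean_round_trip_time or 0.0) / steps_per_ns
        ratio = tau_ns / rt.n_round_trips
        logger.info(
            "round-trip criterion: tau_bar = %.4g ns, nRT = %d, tau_bar/nRT = %.4g ns",
            tau_ns,
            rt.n_round_trips,
            ratio,
        )
        if not ratio < rt_time_limit_ns:
            reasons.append(
                f"round-trip time: tau_bar/nRT = {ratio:.3g} ns >= {rt_time_limit_ns} ns"
            )
    return (len(reasons) == 0), reasons


def _reseed_configurations(
    configs: np.ndarray, old_s: SDistribution, new_s: SDistribution
) -> np.ndarray:
    """Seed configurations for a grown ladder from the nearest old level (in log s)."""
    old = np.log(old_s.as_array())
    new = np.log(new_s.as_array())
    idx = np.argmin(np.abs(new[:, None] - old[None, :]), axis=1)
    return configs[idx].copy()


def run_optimization(
    end_states: Sequence,
    thermo: ThermoContext,
    initial: OptimizationState,
    schedule: OptimizationSchedule,
    rng: np.random.Generator,
    rebalance_config: RebalanceConfig | None = None,
) -> OptimizationState:
    """Alternate N-LRTO s-iterations, then offset-rebalancing iterations.

    s-iterations run until the round-trip part of the convergence rule
    passes or the cap is reached; rebalancing iterations (which add no
    replicas) run until ``max |f_mc - 1/N| <= f_mc_tolerance`` or their
    cap.  With both caps zero the input state is returned unchanged,
    flagged non-converged.  The full iteration history is retained.
    """
    rebalance_config = rebalance_config or RebalanceConfig(thermo=thermo)
    state = OptimizationState(
        s_distribution=initial.s_distribution,
        offsets=np.asarray(initial.offsets, float).copy(),
        configurations=np.asarray(initial.configurations, float).copy(),
        iteration=initial.iteration,
        history=list(initial.history),
    )
    n_states = len(end_states)

    def simulate(n_steps: int):
        ens = ReplicaEnsemble(
            end_states,
            s_distribution=state.s_distribution,
            offsets=state.offsets,
            thermo=thermo,
            configurations=state.configurations,
        )
        return run_reeds(
            ens,
            n_steps,
            exchange_interval=schedule.exchange_interval,
            record_interval=schedule.record_interval,
            step_size=schedule.step_size,
            rng=rng,
        )

    last_record: IterationRecord | None = None
    rt_ok = False
    for it in range(schedule.max_s_iterations):
        steps = schedule.s_iteration_steps[min(it, len(schedule.s_iteration_steps) - 1)]
        res = simulate(steps)
        report = sampling_report(res.trajectory.at_s(1.0), state.offsets)
        last_record = IterationRecord(
            kind="s_opt",
            s_distribution=state.s_distribution,
            offsets=state.offsets.copy(),
            round_trips=res.round_trips,
            report=report,
            n_steps=steps,
        )
        state.history.append(last_record)
        state.iteration += 1
        state.configurations = res.final_configurations
        ok, reasons = check_convergence(
            last_record, schedule.steps_per_ns, schedule.rt_time_limit_ns
        )
        rt_reasons = [r for r in reasons if r.startswith("round")]
        if not rt_reasons:
            rt_ok = True
            break
        bottlenecks = detect_bottlenecks(res.exchanges, n_states, state.s_distribution)
        new_s = nlrto_step(state.s_distribution, bottlenecks, schedule.n_insert)
        state.configurations = _reseed_configurations(
            state.configurations, state.s_distribution, new_s
        )
        state.s_distribution = new_s

    rebal_ok = False
    for it in range(schedule.max_rebalance_iterations):
        res = simulate(schedule.rebalance_steps)
        report = sampling_report(res.trajectory.at_s(1.0), state.offsets)
        last_record = IterationRecord(
            kind="rebalance",
            s_distribution=state.s_distribution,
            offsets=state.offsets.copy(),
            round_trips=res.round_trips,
            report=report,
            n_steps=schedule.rebalance_steps,
        )
        state.history.append(last_record)
        state.iteration += 1
        state.configurations = res.final_configurations
        if np.max(np.abs(report.f_mc - report.ideal_fraction)) <= schedule.f_mc_tolerance:
            rebal_ok = True
            break
        state.offsets = rebalance_offsets(report, state.offsets, rebalance_config)
        logger.info(
            "rebalance iteration %d: offsets (rel. to state 1) %s",
            it + 1,
            np.array2string(pin_offsets(state.offsets), precision=3),
        )

    if last_record is None:
        state.converged = False
        state.status_reasons = ["no iterations executed (caps are zero)"]
        return state
    converged, reasons = check_convergence(
        last_record, schedule.steps_per_ns, schedule.rt_time_limit_ns
    )
    if not rebal_ok:
        reasons.append("rebalancing: f_mc tolerance not reached within the iteration cap")
    state.converged = converged and rt_ok and rebal_ok
    state.status_reasons = reasons
    return state
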