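"""Parameter exploration: lower s-bound, per-state coordinates, PEOE offsets.

The exploration stage turns a bare system definition into a usable
replica-exchange setup in three substeps:

1. *Lower bound* — a short run over a wide log-spaced ladder (default 21
   values from 1 down to 1e-5).  Undersampling thresholds ``T_us`` come
   from the lowest-s replica; a replica counts as undersampling when every
   state's occurrence fraction against ``T_us`` is at least 0.75.  The
   lower bound is set conservatively two ladder levels below the highest-s
   undersampling replica.
2. *State coordinates* — for each end state an s = 1 EDS run biased with
   a +500 kJ/mol offset on that state (-500 on all others); the final
   configuration is accepted only if the state is the maximal contributor
   throughout the last 30% of the run.
3. *PEOE* — parallel energy-offset estimation: for every replica in deep
   undersampling (occurrence >= 0.9 against ``T_us``) a fresh offset vector

       E_i(new) = -(1/beta) * ln < exp(-beta (V_i - V_R)) >

   is extracted and the per-replica vectors are averaged.  At s = 1 the
   optimal offsets equal the state free energies, so on the analytic toys
   PEOE offset differences can be checked against exact dG values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

from .metrics import (
    ThresholdSet,
    estimate_undersampling_thresholds,
    max_contributing_states,
    occurrence_fractions_us,
)
from .potentials import ReferenceState, ThermoContext
from .sampling import (
    EnergyTrajectory,
    ReplicaEnsemble,
    SDistribution,
    propagate,
    run_reeds,
)

__all__ = [
    "ExplorationConfig",
    "ExplorationResult",
    "PeoeResult",
    "StateOptimizationError",
    "find_lower_bound",
    "optimize_state_coordinates",
    "peoe_undersampling_flags",
    "peoe_estimate",
    "run_exploration",
]


@dataclass
class ExplorationConfig:
    """Knobs of the exploration stage; defaults are the canonical ones.

    The occurrence fractions (0.75 for the lower-bound criterion, 0.9 for
    PEOE membership), the two-levels-below rule, the +/-500 kJ/mol biasing
    offsets and the last-30% state-optimisation criterion are the standard
    workflow settings.  Run lengths are in MC steps, sized for the analytic
    toy systems.
    """

    n_initial_s: int = 21
    s_min: float = 1e-5
    undersampling_occurrence_min: float = 0.75
    levels_below: int = 2
    bias_offset_magnitude: float = 500.0
    state_opt_tail_fraction: float = 0.30
    peoe_undersampling_min: float = 0.9
    threshold_quantile: float = 0.95
    equilibration_discard: float = 0.25
    lower_bound_steps: int = 4000
    state_opt_steps: int = 4000
    peoe_steps: int = 8000
    peoe_n_replicas: int = 12
    exchange_interval: int = 20
    record_interval: int = 2

    def initial_ladder(self) -> SDistribution:
        return SDistribution.log_spaced(self.n_initial_s, self.s_min)


class StateOptimizationError(RuntimeError):
    """A state could not be driven to dominate its own biased simulation."""


def find_lower_bound(
    trajs_by_level: Sequence[EnergyTrajectory],
    thresholds: ThresholdSet,
    config: ExplorationConfig | None = None,
) -> tuple[float, np.ndarray]:
    """Determine the lower s-bound from a descending ladder of trajectories.

    A level is undersampling when every state's occurrence fraction against
    ``T_us`` (on V_i - E_i) is at least ``undersampling_occurrence_min``.
    Returns the s-value ``levels_below`` positions below the highest-s
    undersampling level, clamped to the last ladder entry, plus the
    per-level flags.  Raises if no level is undersampling.
    """
    config = config or ExplorationConfig()
    if not trajs_by_level:
        raise ValueError("no trajectories supplied")
    s_of = []
    flags = np.zeros(len(trajs_by_level), dtype=bool)
    for k, traj in enumerate(trajs_by_level):
        if traj.offsets_used is None:
            raise ValueError("trajectories must carry offsets_used")
        s_of.append(float(traj.frames["s"].iloc[0]))
        occ = occurrence_fractions_us(traj, thresholds, traj.offsets_used)
        flags[k] = bool(np.all(occ >= config.undersampling_occurrence_min))
    if np.any(np.diff(s_of) >= 0):
        raise ValueError("trajectories must be ordered by strictly decreasing s")
    if not flags.any():
        raise ValueError(
            "no undersampling replica found; extend the ladder to smaller s-values"
        )
    highest = int(np.argmax(flags))  # first True in descending-s order
    idx = min(highest + config.levels_below, len(trajs_by_level) - 1)
    return s_of[idx], flags


def split_by_level(traj: EnergyTrajectory) -> list[EnergyTrajectory]:
    """Split a multi-level trajectory into per-level trajectories, descending s."""
    return [traj.at_s(s) for s in traj.s_levels()]


def optimize_state_coordinates(
    states: Sequence,
    thermo: ThermoContext,
    config: ExplorationConfig,
    rng: np.random.Generator,
    start_configuration: np.ndarray | None = None,
) -> tuple[np.ndarray, list[EnergyTrajectory]]:
    """Produce one low-energy configuration per end state via biased EDS runs.

    For state i the biasing offsets are +bias_offset_magnitude on i and
    -bias_offset_magnitude elsewhere, simulated at s = 1.  The result is
    accepted when state i is the maximal contributor in *every* frame of
    the last ``state_opt_tail_fraction`` of the run; one retry with doubled
    length is attempted before giving up.
    """
    n = len(states)
    if n < 2:
        raise ValueError("need at least two end states")
    d = states[0].dimension
    x0 = (
        np.zeros(d)
        if start_configuration is None
        else np.atleast_1d(np.asarray(start_configuration, float))
    )
    mag = config.bias_offset_magnitude
    configs = np.empty((n, d))
    trajs: list[EnergyTrajectory] = []
    for i in range(n):
        offsets = np.full(n, -mag)
        offsets[i] = mag
        ref = ReferenceState(states, s=1.0, offsets=offsets, thermo=thermo)
        n_steps = config.state_opt_steps
        for attempt in range(2):
            result = propagate(ref, x0, n_steps, rng, record_interval=1)
            traj = result.trajectory
            tail = traj.discard(1.0 - config.state_opt_tail_fraction)
            mc = max_contributing_states(tail, offsets)
            if np.all(mc == i):
                configs[i] = result.configuration
                trajs.append(traj)
                break
            n_steps *= 2
        else:
            raise StateOptimizationError(
                f"state {getattr(states[i], 'identifier', i + 1)!r} failed to dominate "
                f"the last {config.state_opt_tail_fraction:.0%} of its biased run"
            )
    return configs, trajs


@dataclass
class PeoeResult:
    """Averaged PEOE offsets plus the per-replica estimates and their spread."""

    offsets: np.ndarray
    per_replica_offsets: np.ndarray  # (n_included, N)
    spread: np.ndarray  # per-state std over included replicas
    included_levels: np.ndarray  # s-values of the included replicas


def peoe_undersampling_flags(
    trajs_by_level: Sequence[EnergyTrajectory],
    thresholds: ThresholdSet,
    offsets: np.ndarray,
    min_occurrence: float = 0.9,
) -> np.ndarray:
    """Replica inclusion flags for PEOE: all-state occurrence >= 0.9 vs T_us."""
    flags = np.zeros(len(trajs_by_level), dtype=bool)
    for k, traj in enumerate(trajs_by_level):
        occ = occurrence_fractions_us(traj, thresholds, offsets)
        flags[k] = bool(np.all(occ >= min_occurrence))
    return flags


def _log_mean_exp(a: np.ndarray, axis: int = 0) -> np.ndarray:
    return logsumexp(a, axis=axis) - np.log(a.shape[axis])


def peoe_estimate(
    trajs_by_level: Sequence[EnergyTrajectory],
    undersampling_flags: np.ndarray,
    old_offsets: np.ndarray,
    thermo: ThermoContext,
    config: ExplorationConfig | None = None,
) -> PeoeResult:
    """Parallel energy-offset estimation over the undersampling replicas.

    For each included replica the per-state exponential average of
    ``V_i - V_R`` is evaluated in log space; the per-replica offset vectors
    are then averaged unweighted.  The spread is the per-state standard
    deviation over the included replicas.
    """
    undersampling_flags = np.asarray(undersampling_flags, dtype=bool)
    if len(trajs_by_level) != undersampling_flags.size:
        raise ValueError("one flag per replica trajectory is required")
    included = [t for t, f in zip(trajs_by_level, undersampling_flags) if f]
    if not included:
        raise ValueError("no undersampling replica available for PEOE")
    beta = thermo.beta
    rows = []
    s_vals = []
    for traj in included:
        v = traj.state_energy_matrix()
        vr = traj.v_ref()
        log_avg = _log_mean_exp(-beta * (v - vr[:, None]), axis=0)
        rows.append(-log_avg / beta)
        s_vals.append(float(traj.frames["s"].iloc[0]))
    per_replica = np.vstack(rows)
    offsets = per_replica.mean(axis=0)
    spread = per_replica.std(axis=0, ddof=1) if len(rows) > 1 else np.zeros_like(offsets)
    return PeoeResult(
        offsets=offsets,
        per_replica_offsets=per_replica,
        spread=spread,
        included_levels=np.asarray(s_vals),
    )


@dataclass
class ExplorationResult:
    """Everything the optimisation stage needs, produced by exploration."""

    lower_bound_s: float
    undersampling_flags: np.ndarray
    thresholds: ThresholdSet
    peoe: PeoeResult
    state_configurations: np.ndarray  # (N, d)
    peoe_ladder: SDistribution
    final_configurations: np.ndarray  # (R, d) end of the PEOE run
    offsets: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.offsets = self.peoe.offsets.copy()


def run_exploration(
    end_states: Sequence,
    thermo: ThermoContext,
    config: ExplorationConfig,
    rng: np.random.Generator,
    start_configuration: np.ndarray | None = None,
    start_mode: str = "SSM",
) -> ExplorationResult:
    """Run the full exploration stage on a system of end states.

    ``start_mode`` selects how the PEOE replicas are seeded: ``"SSM"``
    assigns replica r the optimised coordinates of state (r mod N) + 1
    (starting-state mixing), ``"1SS"`` starts every replica from the final
    configuration of the lower-bound run.
    """
    if start_mode not in ("SSM", "1SS"):
        raise ValueError("start_mode must be 'SSM' or '1SS'")
    n = len(end_states)
    d = end_states[0].dimension
    x0 = (
        np.zeros(d)
        if start_configuration is None
        else np.atleast_1d(np.asarray(start_configuration, float))
    )

    # substep (i): wide ladder, zero offsets, lower bound from T_us
    ladder0 = config.initial_ladder()
    ens0 = ReplicaEnsemble(
        end_states,
        s_distribution=ladder0,
        offsets=np.zeros(n),
        thermo=thermo,
        configurations=np.tile(x0, (len(ladder0), 1)),
    )
    res0 = run_reeds(
        ens0,
        config.lower_bound_steps,
        exchange_interval=config.exchange_interval,
        record_interval=config.record_interval,
        rng=rng,
    )
    levels0 = split_by_level(res0.trajectory)
    t_us = estimate_undersampling_thresholds(levels0[-1], config.threshold_quantile)
    provisional = ThresholdSet(physical=np.full(n, np.inf), undersampling=t_us)
    lower_s, flags = find_lower_bound(levels0, provisional, config)

    # substep (ii): per-state biased coordinate optimisation + T_phys
    state_configs, state_trajs = optimize_state_coordinates(
        end_states, thermo, config, rng, start_configuration=x0
    )
    from .metrics import estimate_physical_thresholds

    t_phys = estimate_physical_thresholds(state_trajs, config.threshold_quantile)
    thresholds = ThresholdSet(physical=t_phys, undersampling=t_us)

    # substep (iii): PEOE on a log ladder down to the lower bound
    peoe_ladder = SDistribution(
        tuple(np.logspace(0.0, np.log10(lower_s), config.peoe_n_replicas))
    )
    if start_mode == "SSM":
        seeds = state_configs[np.arange(len(peoe_ladder)) % n]
    else:
        seeds = np.tile(res0.final_configurations[0], (len(peoe_ladder), 1))
    ens1 = ReplicaEnsemble(
        end_states,
        s_distribution=peoe_ladder,
        offsets=np.zeros(n),
        thermo=thermo,
        configurations=seeds,
    )
    res1 = run_reeds(
        ens1,
        config.peoe_steps,
        exchange_interval=config.exchange_interval,
        record_interval=config.record_interval,
        rng=rng,
    )
    levels1 = [t.discard(config.equilibration_discard) for t in split_by_level(res1.trajectory)]
    peoe_flags = peoe_undersampling_flags(
        levels1, thresholds, np.zeros(n), min_occurrence=config.peoe_undersampling_min
    )
    if not peoe_flags.any():
        # short runs can leave every replica marginally below the strict 0.9
        # occurrence criterion; the lowest-s replica is by construction the
        # deepest into undersampling, so fall back to it rather than abort
        logger.warning(
            "no replica met the %.2f occurrence criterion for PEOE; "
            "falling back to the lowest-s replica (s = %g)",
            config.peoe_undersampling_min,
            peoe_ladder[len(peoe_ladder) - 1],
        )
        peoe_flags[-1] = True
    peoe = peoe_estimate(levels1, peoe_flags, np.zeros(n), thermo, config)

    return ExplorationResult(
        lower_bound_s=lower_s,
        undersampling_flags=flags,
        thresholds=thresholds,
        peoe=peoe,
        state_configurations=state_configs,
        peoe_ladder=peoe_ladder,
        final_configurations=res1.final_configurations,
    )
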