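"""Canonical sampling of EDS reference states and replica exchange in s-space.

The propagator is Metropolis Monte Carlo with isotropic Gaussian step
proposals.  It samples the canonical ensemble of ``eds_energy`` exactly (no
discretisation bias), which keeps the replica-exchange acceptance statistics
clean.  Replica exchange runs a ladder of smoothing parameters
``s_1 = 1 > s_2 > ... > s_R``; neighbouring replicas attempt configuration
swaps with the Metropolis-Hastings criterion

    p_{k,l} = min(1, exp(-beta * [ (H_R(r_k; s_l) + H_R(r_l; s_k))
                                  - (H_R(r_l; s_l) + H_R(r_k; s_k)) ]))

Configurations are swapped between s-levels; each configuration carries a
persistent walker identity so that round trips (top -> bottom -> top ladder
traversals) can be counted per walker.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .potentials import (
    EndStatePotential,
    HarmonicPotential,
    PotentialEvaluationError,
    ReferenceState,
    ThermoContext,
    eds_energy_from_matrix,
    eds_forces,
    state_energies,
)

__all__ = [
    "SDistribution",
    "ReplicaEnsemble",
    "ExchangeRecord",
    "RoundTripStats",
    "EnergyTrajectory",
    "PropagationResult",
    "REEDSResult",
    "propagate",
    "propagate_langevin",
    "exchange_probability",
    "run_reeds",
    "count_round_trips",
    "STEPS_PER_NS",
]

#: Default mapping of Monte Carlo steps to nanosecond-denominated criteria
#: (2 fs per step, i.e. 5e5 steps per ns).  Configurable wherever used.
STEPS_PER_NS = 5.0e5


@dataclass(frozen=True)
class SDistribution:
    """Descending ladder of smoothing parameters; the top level is s = 1."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("s-distribution must be a non-empty 1D sequence")
        if abs(v[0] - 1.0) > 1e-12:
            raise ValueError("the first (top) s-value must be 1.0")
        if np.any(v <= 0) or np.any(v > 1.0):
            raise ValueError("s-values must lie in (0, 1]")
        if np.any(np.diff(v) >= 0):
            raise ValueError("s-values must be strictly decreasing")
        object.__setattr__(self, "values", tuple(float(x) for x in v))

    @classmethod
    def log_spaced(cls, n: int = 21, s_min: float = 1e-5) -> "SDistribution":
        """``n`` logarithmically spaced values from 1 down to ``s_min``."""
        if n < 1:
            raise ValueError("n must be >= 1")
        return cls(tuple(np.logspace(0.0, math.log10(s_min), n)))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, i: int) -> float:
        return self.values[i]


@dataclass
class ReplicaEnsemble:
    """A replica-exchange ensemble: one configuration per s-level.

    All replicas share a single offset vector; they differ only in ``s``.
    """

    end_states: Sequence[EndStatePotential]
    s_distribution: SDistribution
    offsets: np.ndarray
    thermo: ThermoContext = field(default_factory=ThermoContext)
    configurations: np.ndarray | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.end_states = list(self.end_states)
        n = len(self.end_states)
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.offsets.shape != (n,):
            raise ValueError("offsets must have one entry per end state")
        d = self.end_states[0].dimension
        r = len(self.s_distribution)
        if self.configurations is None:
            self.configurations = np.zeros((r, d))
        else:
            self.configurations = np.array(self.configurations, dtype=float)
            if self.configurations.shape == (d,):
                self.configurations = np.tile(self.configurations, (r, 1))
            if self.configurations.shape != (r, d):
                raise ValueError(
                    f"configurations must have shape ({r}, {d}), got {self.configurations.shape}"
                )

    @property
    def n_replicas(self) -> int:
        return len(self.s_distribution)

    def reference_state(self, level: int) -> ReferenceState:
        return ReferenceState(
            self.end_states,
            s=self.s_distribution[level],
            offsets=self.offsets.copy(),
            thermo=self.thermo,
        )


@dataclass(frozen=True)
class ExchangeRecord:
    """One neighbour-exchange attempt between ladder levels ``pair``."""

    step: int
    pair: tuple[int, int]
    probability: float
    accepted: bool
    #: maximally contributing end state of the configuration at each level
    #: at the moment of the attempt (upper level first).
    mc_states: tuple[int, int] = (-1, -1)

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError("exchange probability must lie in [0, 1]")


def exchange_table(records: Sequence[ExchangeRecord]) -> pd.DataFrame:
    """Exchange log as a DataFrame: step, i, j, p, accepted, mc_i, mc_j."""
    return pd.DataFrame(
        {
            "step": [r.step for r in records],
            "i": [r.pair[0] for r in records],
            "j": [r.pair[1] for r in records],
            "p": [r.probability for r in records],
            "accepted": [int(r.accepted) for r in records],
            "mc_i": [r.mc_states[0] for r in records],
            "mc_j": [r.mc_states[1] for r in records],
        }
    )


@dataclass
class RoundTripStats:
    """Round-trip bookkeeping over all walkers.

    A round trip is one walker touching the top (s = 1) level, then the
    bottom level, then the top again.  ``mean_round_trip_time`` is ``None``
    when no round trip completed.
    """

    n_round_trips: int
    mean_round_trip_time: float | None
    round_trip_times: np.ndarray
    per_walker_counts: np.ndarray

    @property
    def tau_mean(self) -> float | None:
        return self.mean_round_trip_time


class EnergyTrajectory:
    """Per-frame record of all end-state energies plus V_R, replica id and s.

    The universal currency between workflow stages.  Backed by a pandas
    DataFrame with columns ``time, replica, s, V_R, V_1 ... V_N``.
    """

    def __init__(self, frames: pd.DataFrame, offsets_used: np.ndarray | None = None):
        required = ["time", "replica", "s", "V_R"]
        for col in required:
            if col not in frames.columns:
                raise ValueError(f"trajectory frame table is missing column {col!r}")
        self.frames = frames.reset_index(drop=True)
        self._state_cols = [c for c in frames.columns if c.startswith("V_") and c != "V_R"]
        if not self._state_cols:
            raise ValueError("trajectory has no end-state energy columns")
        self.offsets_used = (
            None if offsets_used is None else np.asarray(offsets_used, dtype=float)
        )
        if self.offsets_used is not None and self.offsets_used.shape != (self.n_states,):
            raise ValueError("offsets_used length must match the number of state columns")

    @classmethod
    def from_arrays(
        cls,
        times: np.ndarray,
        replica_ids: np.ndarray,
        s_values: np.ndarray,
        v_ref: np.ndarray,
        state_energies_matrix: np.ndarray,
        offsets_used: np.ndarray | None = None,
    ) -> "EnergyTrajectory":
        n_states = state_energies_matrix.shape[1]
        data = {
            "time": np.asarray(times, dtype=float),
            "replica": np.asarray(replica_ids, dtype=int),
            "s": np.asarray(s_values, dtype=float),
            "V_R": np.asarray(v_ref, dtype=float),
        }
        for i in range(n_states):
            data[f"V_{i + 1}"] = np.asarray(state_energies_matrix[:, i], dtype=float)
        return cls(pd.DataFrame(data), offsets_used=offsets_used)

    @property
    def n_states(self) -> int:
        return len(self._state_cols)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def state_energy_matrix(self) -> np.ndarray:
        """End-state energies, shape (n_frames, N)."""
        return self.frames[self._state_cols].to_numpy(dtype=float)

    def v_ref(self) -> np.ndarray:
        return self.frames["V_R"].to_numpy(dtype=float)

    def times(self) -> np.ndarray:
        return self.frames["time"].to_numpy(dtype=float)

    def s_levels(self) -> np.ndarray:
        """Distinct s-values present, descending."""
        return np.sort(self.frames["s"].unique())[::-1]

    def at_s(self, s: float, rtol: float = 1e-9) -> "EnergyTrajectory":
        """Sub-trajectory of the frames recorded at ladder level ``s``."""
        mask = np.isclose(self.frames["s"].to_numpy(), s, rtol=rtol, atol=0.0)
        return EnergyTrajectory(self.frames[mask], offsets_used=self.offsets_used)

    def discard(self, fraction: float) -> "EnergyTrajectory":
        """Drop the first ``fraction`` of frames (equilibration)."""
        if not 0.0 <= fraction < 1.0:
            raise ValueError("discard fraction must be in [0, 1)")
        k = int(len(self.frames) * fraction)
        return EnergyTrajectory(self.frames.iloc[k:], offsets_used=self.offsets_used)

    def check_consistency(self, thermo: ThermoContext, atol: float = 1e-8) -> float:
        """Max |V_R(stored) - V_R(recomputed from V_i, s, offsets)| in kJ/mol."""
        if self.offsets_used is None:
            raise ValueError("offsets_used is required to recompute V_R")
        v = self.state_energy_matrix()
        s = self.frames["s"].to_numpy(dtype=float)
        err = 0.0
        for sv in self.s_levels():
            m = np.isclose(s, sv, rtol=1e-12, atol=0.0)
            vr = eds_energy_from_matrix(v[m], self.offsets_used, float(sv), thermo.beta)
            err = max(err, float(np.max(np.abs(vr - self.v_ref()[m]), initial=0.0)))
        if err > atol:
            raise AssertionError(f"trajectory V_R inconsistent with Eq. recomputation: {err}")
        return err


@dataclass
class PropagationResult:
    configuration: np.ndarray
    trajectory: EnergyTrajectory
    acceptance_rate: float
    positions: np.ndarray | None = None  # (n_records, d) when requested


def _state_energy_evaluator(end_states: Sequence[EndStatePotential]):
    """Batched end-state energy evaluator: x (..., d) -> (..., N).

    Separable harmonic systems get a closed-form broadcast evaluation (one
    numpy expression for all states); anything else falls back to a per-state
    loop.  Non-finite energies raise naming the state.
    """
    if all(isinstance(st, HarmonicPotential) for st in end_states):
        k = np.stack([st.force_constants for st in end_states])  # (N, d)
        x0 = np.stack([st.minimum for st in end_states])
        sh = np.array([st.shift for st in end_states])

        def ev(x: np.ndarray) -> np.ndarray:
            diff = x[..., None, :] - x0
            return sh + 0.5 * np.einsum("...nd,...nd->...n", k * diff, diff)

        return ev

    def ev_generic(x: np.ndarray) -> np.ndarray:
        cols = []
        for st in end_states:
            vv = np.asarray(st.energy(x), dtype=float)
            if not np.all(np.isfinite(vv)):
                raise PotentialEvaluationError(
                    f"end state {st.identifier!r} produced a non-finite energy"
                )
            cols.append(vv)
        return np.stack(cols, axis=-1)

    return ev_generic


def _default_step_size(end_states: Sequence[EndStatePotential], thermo: ThermoContext) -> float:
    """Proposal scale heuristic: ~1.5x the narrowest well width, floor 0.02 nm."""
    sigmas = []
    for st in end_states:
        boltz = getattr(st, "boltzmann_sigma", None)
        if callable(boltz):
            sigmas.append(float(np.min(boltz(thermo))))
    if not sigmas:
        return 0.08
    return max(0.02, 1.5 * min(sigmas))


def propagate(
    ref: ReferenceState,
    conf: np.ndarray,
    n_steps: int,
    rng: np.random.Generator,
    step_size: float | None = None,
    record_interval: int = 1,
    store_positions: bool = False,
) -> PropagationResult:
    """Metropolis Monte Carlo sampling of the reference-state canonical ensemble.

    Gaussian step proposals of scale ``step_size``; exact detailed balance
    with respect to ``exp(-beta * V_R)``.  ``n_steps = 0`` returns the input
    configuration unchanged with an empty trajectory.  Deterministic under
    the supplied ``rng``.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    x = np.atleast_1d(np.asarray(conf, dtype=float)).copy()
    beta = ref.thermo.beta
    if step_size is None:
        step_size = _default_step_size(ref.end_states, ref.thermo)

    evaluate = _state_energy_evaluator(ref.end_states)
    offsets = ref.offsets
    bs = beta * ref.s

    def v_ref_of(v: np.ndarray) -> float:
        h = -bs * (v - offsets)
        m = h.max()
        return float(-(m + math.log(np.exp(h - m).sum())) / bs)

    v = state_energies(ref, x)
    vr = v_ref_of(v)

    n_rec = n_steps // record_interval
    rec_t = np.empty(n_rec)
    rec_v = np.empty((n_rec, ref.n_states))
    rec_vr = np.empty(n_rec)
    rec_x = np.empty((n_rec, x.size)) if store_positions else None
    n_acc = 0
    i_rec = 0

    proposals = rng.normal(scale=step_size, size=(n_steps, x.size))
    log_u = np.log(rng.random(n_steps))
    for t in range(n_steps):
        x_new = x + proposals[t]
        try:
            v_new = evaluate(x_new)
        except PotentialEvaluationError as exc:
            raise PotentialEvaluationError(f"at step {t + 1}: {exc}") from exc
        vr_new = v_ref_of(v_new)
        if not np.isfinite(vr_new):
            raise PotentialEvaluationError(f"reference energy diverged at step {t + 1}")
        if log_u[t] < -beta * (vr_new - vr):
            x, v, vr = x_new, v_new, vr_new
            n_acc += 1
        if (t + 1) % record_interval == 0:
            rec_t[i_rec] = t + 1
            rec_v[i_rec] = v
            rec_vr[i_rec] = vr
            if rec_x is not None:
                rec_x[i_rec] = x
            i_rec += 1

    traj = EnergyTrajectory.from_arrays(
        rec_t[:i_rec],
        np.zeros(i_rec, dtype=int),
        np.full(i_rec, ref.s),
        rec_vr[:i_rec],
        rec_v[:i_rec],
        offsets_used=ref.offsets.copy(),
    )
    rate = n_acc / n_steps if n_steps else 0.0
    return PropagationResult(
        configuration=x,
        trajectory=traj,
        acceptance_rate=rate,
        positions=None if rec_x is None else rec_x[:i_rec],
    )


def propagate_langevin(
    ref: ReferenceState,
    conf: np.ndarray,
    n_steps: int,
    rng: np.random.Generator,
    time_step: float = 2e-4,
    diffusion: float = 1.0,
    record_interval: int = 1,
    store_positions: bool = False,
) -> PropagationResult:
    """Overdamped Langevin (Euler-Maruyama) integration of the reference state.

    dx = -D*beta*grad(V_R)*dt + sqrt(2*D*dt)*xi.  Unlike the Metropolis
    propagator this carries an O(dt) discretisation bias, but it moves with
    the reference-state forces and is the MD-like alternative.  Stability
    requires ``time_step`` well below 2/(D*beta*k_max) for the stiffest
    well of curvature k_max.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    x = np.atleast_1d(np.asarray(conf, dtype=float)).copy()
    beta = ref.thermo.beta
    evaluate = _state_energy_evaluator(ref.end_states)
    noise_scale = math.sqrt(2.0 * diffusion * time_step)
    drift = diffusion * beta * time_step

    n_rec = n_steps // record_interval
    rec_t = np.empty(n_rec)
    rec_v = np.empty((n_rec, ref.n_states))
    rec_vr = np.empty(n_rec)
    rec_x = np.empty((n_rec, x.size)) if store_positions else None
    i_rec = 0
    bs = beta * ref.s
    offsets = ref.offsets
    noise = rng.normal(scale=noise_scale, size=(n_steps, x.size))
    for t in range(n_steps):
        f = eds_forces(ref, x)
        x = x + drift * f + noise[t]
        if not np.all(np.isfinite(x)):
            raise PotentialEvaluationError(f"Langevin integration diverged at step {t + 1}")
        if (t + 1) % record_interval == 0:
            v = evaluate(x)
            h = -bs * (v - offsets)
            m = h.max()
            rec_t[i_rec] = t + 1
            rec_v[i_rec] = v
            rec_vr[i_rec] = -(m + math.log(np.exp(h - m).sum())) / bs
            if rec_x is not None:
                rec_x[i_rec] = x
            i_rec += 1
    traj = EnergyTrajectory.from_arrays(
        rec_t[:i_rec],
        np.zeros(i_rec, dtype=int),
        np.full(i_rec, ref.s),
        rec_vr[:i_rec],
        rec_v[:i_rec],
        offsets_used=ref.offsets.copy(),
    )
    return PropagationResult(
        configuration=x,
        trajectory=traj,
        acceptance_rate=1.0,
        positions=None if rec_x is None else rec_x[:i_rec],
    )


def exchange_probability(
    ref_k: ReferenceState,
    ref_l: ReferenceState,
    conf_k: np.ndarray,
    conf_l: np.ndarray,
) -> float:
    """Metropolis-Hastings swap probability for two replicas differing only in s."""
    if ref_k.end_states is not ref_l.end_states and [
        st.identifier for st in ref_k.end_states
    ] != [st.identifier for st in ref_l.end_states]:
        raise ValueError("replicas must share the same end states")
    if not np.allclose(ref_k.offsets, ref_l.offsets):
        raise ValueError("replicas must share the same energy offsets")
    beta = ref_k.thermo.beta
    v_k = state_energies(ref_k, np.atleast_1d(np.asarray(conf_k, float)))
    v_l = state_energies(ref_l, np.atleast_1d(np.asarray(conf_l, float)))
    e = ref_k.offsets
    h_kk = eds_energy_from_matrix(v_k, e, ref_k.s, beta)
    h_ll = eds_energy_from_matrix(v_l, e, ref_l.s, beta)
    h_kl = eds_energy_from_matrix(v_k, e, ref_l.s, beta)
    h_lk = eds_energy_from_matrix(v_l, e, ref_k.s, beta)
    delta = -beta * ((h_kl + h_lk) - (h_ll + h_kk))
    return 1.0 if delta >= 0 else float(np.exp(delta))


@dataclass
class REEDSResult:
    """Outcome of a replica-exchange EDS run."""

    trajectory: EnergyTrajectory
    exchanges: list[ExchangeRecord]
    round_trips: RoundTripStats
    final_configurations: np.ndarray
    walker_positions: np.ndarray  # (n_records, n_walkers) ladder level per walker
    position_times: np.ndarray
    acceptance_rate: float  # MC move acceptance, averaged over replicas
    configuration_trace: np.ndarray | None = None  # (n_records, R, d) when requested


def run_reeds(
    ensemble: ReplicaEnsemble,
    n_steps: int,
    exchange_interval: int = 20,
    step_size: float | None = None,
    record_interval: int = 1,
    rng: np.random.Generator | None = None,
    store_configurations: bool = False,
) -> REEDSResult:
    """Run replica-exchange EDS: alternate MC propagation and neighbour swaps.

    All replicas are propagated in lockstep (vectorised over the ladder).
    Every ``exchange_interval`` steps a sweep of neighbour exchanges is
    attempted, alternating between even and odd pairs.  On acceptance the
    two configurations swap s-levels; walker identities move with the
    configurations so round trips can be counted.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    if exchange_interval < 1:
        raise ValueError("exchange_interval must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(ensemble.rng_seed)
    thermo = ensemble.thermo
    beta = thermo.beta
    s_arr = ensemble.s_distribution.as_array()
    n_rep = ensemble.n_replicas
    offsets = ensemble.offsets
    n_states = len(ensemble.end_states)
    if step_size is None:
        step_size = _default_step_size(ensemble.end_states, thermo)

    x = ensemble.configurations.copy()  # (R, d)
    d = x.shape[1]

    energy_matrix = _state_energy_evaluator(ensemble.end_states)

    def scalar_ref_energy(v_row: np.ndarray, s: float) -> float:
        h = -beta * s * (v_row - offsets)
        m = h.max()
        return float(-(m + math.log(np.exp(h - m).sum())) / (beta * s))

    def ref_energy(v: np.ndarray, s: np.ndarray) -> np.ndarray:
        # per-row s: shifted log-sum-exp
        h = -beta * s[:, None] * (v - offsets[None, :])
        m = np.max(h, axis=1)
        lse = m + np.log(np.sum(np.exp(h - m[:, None]), axis=1))
        return -lse / (beta * s)

    v = energy_matrix(x)  # (R, N)
    vr = ref_energy(v, s_arr)

    walker_at_level = np.arange(n_rep)  # walker id occupying each level

    n_rec = n_steps // record_interval
    rec_t = np.empty(n_rec)
    rec_v = np.empty((n_rec, n_rep, n_states))
    rec_vr = np.empty((n_rec, n_rep))
    rec_walker = np.empty((n_rec, n_rep), dtype=int)
    rec_x = np.empty((n_rec, n_rep, d)) if store_configurations else None
    i_rec = 0

    pos_t = np.empty(n_steps // exchange_interval + 1)
    pos = np.empty((n_steps // exchange_interval + 1, n_rep), dtype=np.int32)
    i_pos = 0

    def record_positions(t: float) -> None:
        nonlocal i_pos
        level_of_walker = np.empty(n_rep, dtype=np.int32)
        level_of_walker[walker_at_level] = np.arange(n_rep, dtype=np.int32)
        pos[i_pos] = level_of_walker
        pos_t[i_pos] = t
        i_pos += 1

    record_positions(0.0)
    exchanges: list[ExchangeRecord] = []
    attempt_parity = 0
    n_acc_moves = 0

    for t in range(n_steps):
        x_new = x + rng.normal(scale=step_size, size=(n_rep, d))
        v_new = energy_matrix(x_new)
        vr_new = ref_energy(v_new, s_arr)
        acc = np.log(rng.random(n_rep)) < -beta * (vr_new - vr)
        x[acc] = x_new[acc]
        v[acc] = v_new[acc]
        vr[acc] = vr_new[acc]
        n_acc_moves += int(np.sum(acc))

        if (t + 1) % record_interval == 0:
            rec_t[i_rec] = t + 1
            rec_v[i_rec] = v
            rec_vr[i_rec] = vr
            rec_walker[i_rec] = walker_at_level
            if rec_x is not None:
                rec_x[i_rec] = x
            i_rec += 1

        if (t + 1) % exchange_interval == 0 and n_rep > 1:
            start = attempt_parity % 2
            attempt_parity += 1
            mc = np.argmin(v - offsets[None, :], axis=1)
            for p in range(start, n_rep - 1, 2):
                q = p + 1
                h_pq = scalar_ref_energy(v[p], s_arr[q])
                h_qp = scalar_ref_energy(v[q], s_arr[p])
                delta = -beta * ((h_pq + h_qp) - (vr[q] + vr[p]))
                prob = 1.0 if delta >= 0 else float(np.exp(delta))
                accepted = rng.random() < prob
                exchanges.append(
                    ExchangeRecord(
                        step=t + 1,
                        pair=(p, q),
                        probability=prob,
                        accepted=bool(accepted),
                        mc_states=(int(mc[p]), int(mc[q])),
                    )
                )
                if accepted:
                    x[[p, q]] = x[[q, p]]
                    v[[p, q]] = v[[q, p]]
                    vr[p], vr[q] = h_qp, h_pq
                    walker_at_level[[p, q]] = walker_at_level[[q, p]]
            record_positions(float(t + 1))

    # flatten records: one row per (frame, level)
    levels = np.arange(n_rep)
    times = np.repeat(rec_t[:i_rec], n_rep)
    s_col = np.tile(s_arr[levels], i_rec)
    walker_col = rec_walker[:i_rec].reshape(-1)
    vr_col = rec_vr[:i_rec].reshape(-1)
    v_col = rec_v[:i_rec].reshape(-1, n_states)
    traj = EnergyTrajectory.from_arrays(
        times, walker_col, s_col, vr_col, v_col, offsets_used=offsets.copy()
    )
    stats = count_round_trips(pos[:i_pos], n_levels=n_rep, times=pos_t[:i_pos])
    rate = n_acc_moves / (n_steps * n_rep) if n_steps else 0.0
    return REEDSResult(
        trajectory=traj,
        exchanges=exchanges,
        round_trips=stats,
        final_configurations=x,
        walker_positions=pos[:i_pos],
        position_times=pos_t[:i_pos],
        acceptance_rate=rate,
        configuration_trace=None if rec_x is None else rec_x[:i_rec],
    )


def count_round_trips(
    positions: np.ndarray,
    n_levels: int,
    times: np.ndarray | None = None,
) -> RoundTripStats:
    """Count completed round trips (top -> bottom -> top) per walker.

    ``positions`` has shape (T, n_walkers) with ladder level indices
    (0 = top).  The round-trip clock starts at the *last* top visit before
    the walker heads down, and stops at the first top visit after touching
    the bottom.  A single level is a degenerate ladder with no round trips.
    """
    positions = np.asarray(positions)
    if positions.ndim != 2:
        raise ValueError("positions must have shape (T, n_walkers)")
    if positions.size and (positions.min() < 0 or positions.max() >= n_levels):
        raise ValueError("ladder indices out of bounds")
    t_axis = (
        np.arange(positions.shape[0], dtype=float) if times is None else np.asarray(times, float)
    )
    n_walkers = positions.shape[1]
    rt_times: list[float] = []
    per_walker = np.zeros(n_walkers, dtype=int)
    if n_levels > 1:
        bottom = n_levels - 1
        for w in range(n_walkers):
            p = positions[:, w]
            events = np.nonzero((p == 0) | (p == bottom))[0]
            state = 0  # 0: waiting for first top, 1: seeking bottom, 2: seeking top
            start = 0.0
            for idx in events:
                at_top = p[idx] == 0
                if at_top:
                    if state == 2:
                        rt_times.append(float(t_axis[idx] - start))
                        per_walker[w] += 1
                    state = 1
                    start = float(t_axis[idx])
                elif state == 1:
                    state = 2
    arr = np.asarray(rt_times, dtype=float)
    mean_t = float(arr.mean()) if arr.size else None
    return RoundTripStats(
        n_round_trips=int(arr.size),
        mean_round_trip_time=mean_t,
        round_trip_times=arr,
        per_walker_counts=per_walker,
    )
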