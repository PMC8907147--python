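"""Sampling diagnostics for EDS trajectories.

Three per-state metrics quantify how well a reference-state simulation
covers its end states:

* ``f_mc`` — fraction of frames in which a state is the *maximally
  contributing* one, i.e. has the lowest ``V_i - E_i``.  Ideal sampling is
  ``f_mc = 1/N`` for every state.
* ``f_occur`` — fraction of frames in which a state's raw potential energy
  falls below its physical threshold ``T_phys``; several states can occur
  simultaneously when their phase spaces overlap.
* undersampling — a frame counts as undersampling when *every* state
  satisfies ``V_i - E_i <= T_us``, the signature of the flattened
  small-s regime.

Thresholds are estimated as empirical quantiles (default 0.95) of the
relevant energy distributions; the quantile is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .sampling import EnergyTrajectory

__all__ = [
    "ThresholdSet",
    "SamplingReport",
    "max_contributing_fractions",
    "max_contributing_states",
    "occurrence_fractions",
    "undersampling_frames",
    "estimate_thresholds",
    "estimate_physical_thresholds",
    "estimate_undersampling_thresholds",
    "occurrence_fractions_us",
    "sampling_report",
]


@dataclass(frozen=True)
class ThresholdSet:
    """Per-state energy thresholds (kJ/mol).

    ``physical`` applies to raw end-state energies V_i (occurrence metric);
    ``undersampling`` applies to offset-shifted energies V_i - E_i.
    """

    physical: np.ndarray
    undersampling: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "physical", np.asarray(self.physical, dtype=float))
        object.__setattr__(self, "undersampling", np.asarray(self.undersampling, dtype=float))
        if self.physical.shape != self.undersampling.shape or self.physical.ndim != 1:
            raise ValueError("physical and undersampling thresholds must be 1D, same length")

    @property
    def n_states(self) -> int:
        return self.physical.size


@dataclass(frozen=True)
class SamplingReport:
    """Per-state sampling fractions for one trajectory (usually one s-level)."""

    f_mc: np.ndarray
    f_occur: np.ndarray | None
    undersampling_fraction: float | None
    n_frames: int

    @property
    def ideal_fraction(self) -> float:
        return 1.0 / len(self.f_mc)

    def to_frame(self) -> pd.DataFrame:
        data = {"state": np.arange(1, len(self.f_mc) + 1), "f_mc": self.f_mc}
        if self.f_occur is not None:
            data["f_occur"] = self.f_occur
        return pd.DataFrame(data)


def _require_frames(traj: EnergyTrajectory) -> np.ndarray:
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    return traj.state_energy_matrix()


def max_contributing_states(traj: EnergyTrajectory, offsets: np.ndarray) -> np.ndarray:
    """Per-frame index of the maximally contributing state (argmin V_i - E_i).

    Ties go to the lowest state index (numpy argmin convention), which only
    matters on measure-zero coincidences but keeps tests deterministic.
    """
    v = _require_frames(traj)
    return np.argmin(v - np.asarray(offsets, float)[None, :], axis=1)


def max_contributing_fractions(traj: EnergyTrajectory, offsets: np.ndarray) -> np.ndarray:
    """f_mc per state; sums to 1 exactly (each frame has one maximal contributor)."""
    mc = max_contributing_states(traj, offsets)
    return np.bincount(mc, minlength=traj.n_states) / traj.n_frames


def occurrence_fractions(traj: EnergyTrajectory, thresholds: ThresholdSet) -> np.ndarray:
    """f_occur per state: fraction of frames with V_i <= T_phys_i."""
    v = _require_frames(traj)
    if thresholds.n_states != traj.n_states:
        raise ValueError("threshold count does not match trajectory state count")
    return np.mean(v <= thresholds.physical[None, :], axis=0)


def undersampling_frames(
    traj: EnergyTrajectory, thresholds: ThresholdSet, offsets: np.ndarray
) -> tuple[float, np.ndarray]:
    """Undersampling fraction plus per-frame flags.

    A frame is undersampling when every state satisfies V_i - E_i <= T_us_i.
    """
    v = _require_frames(traj)
    if thresholds.n_states != traj.n_states:
        raise ValueError("threshold count does not match trajectory state count")
    shifted = v - np.asarray(offsets, float)[None, :]
    flags = np.all(shifted <= thresholds.undersampling[None, :], axis=1)
    return float(np.mean(flags)), flags


def occurrence_fractions_us(
    traj: EnergyTrajectory, thresholds: ThresholdSet, offsets: np.ndarray
) -> np.ndarray:
    """Per-state occurrence against the undersampling thresholds (on V_i - E_i)."""
    v = _require_frames(traj)
    shifted = v - np.asarray(offsets, float)[None, :]
    return np.mean(shifted <= thresholds.undersampling[None, :], axis=0)


def estimate_physical_thresholds(
    per_state_trajs: Sequence[EnergyTrajectory], quantile: float = 0.95
) -> np.ndarray:
    """T_phys_i: quantile of V_i over frames of state i's biased run where
    state i is the maximal contributor (under that run's biasing offsets).

    A state that is never maximal in its own biased run signals a failed
    state optimisation and raises.
    """
    if not 0.0 < quantile <= 1.0:
        raise ValueError("quantile must be in (0, 1]")
    n = len(per_state_trajs)
    t_phys = np.empty(n)
    for i, traj in enumerate(per_state_trajs):
        if traj.offsets_used is None:
            raise ValueError("biased trajectories must carry offsets_used")
        mc = max_contributing_states(traj, traj.offsets_used)
        sel = traj.state_energy_matrix()[mc == i, i]
        if sel.size == 0:
            raise ValueError(
                f"state {i + 1} is never the maximal contributor in its own biased run"
            )
        t_phys[i] = np.quantile(sel, quantile)
    return t_phys


def estimate_undersampling_thresholds(
    lowest_s_traj: EnergyTrajectory, quantile: float = 0.95
) -> np.ndarray:
    """T_us_i: quantile of V_i - E_i over the lowest-s trajectory's frames."""
    if not 0.0 < quantile <= 1.0:
        raise ValueError("quantile must be in (0, 1]")
    if lowest_s_traj.offsets_used is None:
        raise ValueError("lowest-s trajectory must carry offsets_used")
    shifted = lowest_s_traj.state_energy_matrix() - lowest_s_traj.offsets_used[None, :]
    return np.quantile(shifted, quantile, axis=0)


def estimate_thresholds(
    per_state_trajs: Sequence[EnergyTrajectory],
    lowest_s_traj: EnergyTrajectory,
    quantile: float = 0.95,
) -> ThresholdSet:
    """Estimate T_phys and T_us from exploration-stage trajectories.

    See :func:`estimate_physical_thresholds` and
    :func:`estimate_undersampling_thresholds`; the quantile (default 0.95)
    applies to both.
    """
    if len(per_state_trajs) != lowest_s_traj.n_states:
        raise ValueError("need one biased trajectory per end state")
    return ThresholdSet(
        physical=estimate_physical_thresholds(per_state_trajs, quantile),
        undersampling=estimate_undersampling_thresholds(lowest_s_traj, quantile),
    )


def sampling_report(
    traj: EnergyTrajectory,
    offsets: np.ndarray,
    thresholds: ThresholdSet | None = None,
) -> SamplingReport:
    """Bundle f_mc (always) and threshold-based metrics (when available)."""
    f_mc = max_contributing_fractions(traj, offsets)
    f_occur = None
    us_frac = None
    if thresholds is not None:
        f_occur = occurrence_fractions(traj, thresholds)
        us_frac, _ = undersampling_frames(traj, thresholds, offsets)
    return SamplingReport(
        f_mc=f_mc, f_occur=f_occur, undersampling_fraction=us_frac, n_frames=traj.n_frames
    )
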