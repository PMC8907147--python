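"""Plain-text serialisation of energy trajectories and exchange logs.

Energy-trajectory TSV dialect: an optional ``# offsets:`` comment line
carrying the offset vector used during the run, then a tab-separated
header ``time  replica  s  V_R  V_1 ... V_N`` and one row per stored
frame.  Energies are in kJ/mol and numbers are written with 10 significant
digits, so write -> read -> write is byte-identical.

Exchange-log TSV: ``step  i  j  p  accepted`` (+ the maximally
contributing state on each side of the attempt).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from .sampling import EnergyTrajectory, ExchangeRecord

__all__ = [
    "TrajectoryFormatError",
    "write_energy_trajectory",
    "read_energy_trajectory",
    "write_exchange_log",
]

_FMT = "%.10g"


class TrajectoryFormatError(ValueError):
    """Malformed trajectory file; the message carries the line number."""


def write_energy_trajectory(traj: EnergyTrajectory, path: str | Path) -> None:
    path = Path(path)
    n_states = traj.n_states
    header = ["time", "replica", "s", "V_R"] + [f"V_{i + 1}" for i in range(n_states)]
    lines: list[str] = []
    if traj.offsets_used is not None:
        lines.append("# offsets:\t" + "\t".join(_FMT % v for v in traj.offsets_used))
    lines.append("\t".join(header))
    times = traj.times()
    reps = traj.frames["replica"].to_numpy(dtype=int)
    s = traj.frames["s"].to_numpy(dtype=float)
    vr = traj.v_ref()
    v = traj.state_energy_matrix()
    for f in range(traj.n_frames):
        row = [_FMT % times[f], str(reps[f]), _FMT % s[f], _FMT % vr[f]]
        row.extend(_FMT % v[f, i] for i in range(n_states))
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")


def read_energy_trajectory(path: str | Path) -> EnergyTrajectory:
    path = Path(path)
    offsets = None
    header: list[str] | None = None
    times: list[float] = []
    reps: list[int] = []
    s: list[float] = []
    vr: list[float] = []
    v: list[list[float]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("offsets:"):
                    offsets = np.array(
                        [float(t) for t in body[len("offsets:"):].split()], dtype=float
                    )
                continue
            tokens = line.split("\t")
            if header is None:
                if tokens[:4] != ["time", "replica", "s", "V_R"] or len(tokens) < 5:
                    raise TrajectoryFormatError(
                        f"{path}:{lineno}: bad header; expected "
                        "'time\\treplica\\ts\\tV_R\\tV_1...'"
                    )
                header = tokens
                continue
            if len(tokens) != len(header):
                raise TrajectoryFormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, found {len(tokens)}"
                )
            try:
                times.append(float(tokens[0]))
                reps.append(int(tokens[1]))
                s.append(float(tokens[2]))
                vr.append(float(tokens[3]))
                v.append([float(t) for t in tokens[4:]])
            except ValueError as exc:
                raise TrajectoryFormatError(f"{path}:{lineno}: {exc}") from None
    if header is None:
        raise TrajectoryFormatError(f"{path}:1: empty file (missing header)")
    n_states = len(header) - 4
    matrix = np.asarray(v, dtype=float).reshape(len(times), n_states)
    return EnergyTrajectory.from_arrays(
        np.asarray(times),
        np.asarray(reps, dtype=int),
        np.asarray(s),
        np.asarray(vr),
        matrix,
        offsets_used=offsets,
    )


def write_exchange_log(records: Sequence[ExchangeRecord], path: str | Path) -> None:
    path = Path(path)
    lines = ["step\ti\tj\tp\taccepted\tmc_i\tmc_j"]
    for r in records:
        lines.append(
            "\t".join(
                [
                    str(r.step),
                    str(r.pair[0]),
                    str(r.pair[1]),
                    _FMT % r.probability,
                    str(int(r.accepted)),
                    str(r.mc_states[0]),
                    str(r.mc_states[1]),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
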