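"""Run-directory orchestration of the four workflow stages.

``run_workflow`` executes exploration -> optimization -> production ->
analysis in a run directory, writing plain-text artefacts per stage plus a
JSON ledger with checksums, seeds, wall-clock times and per-stage status.
Each stage persists its state to disk, so a rerun in the same directory
resumes after the last completed stage; identical config + seed reproduce
byte-identical TSV outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import RunConfig
from .explore import run_exploration
from .free_energy import zwanzig_multistate
from .metrics import sampling_report
from .optimize import (
    OptimizationState,
    RebalanceConfig,
    correction_for_fold_reduction,
    rebalancing_correction_cap,
    run_optimization,
)
from .potentials import pin_offsets
from .sampling import ReplicaEnsemble, SDistribution, run_reeds
from .toys import analytic_free_energy_matrix
from .trajio import read_energy_trajectory, write_energy_trajectory, write_exchange_log

__all__ = ["StageStatus", "RunLedger", "Workflow", "run_workflow", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("explore", "optimize", "produce", "analyze")


@dataclass
class StageStatus:
    name: str
    status: str = "pending"  # completed | failed | skipped | resumed
    wall_clock_s: float = 0.0
    files: dict[str, str] = field(default_factory=dict)  # relpath -> sha256
    reason: str | None = None


@dataclass
class RunLedger:
    seed: int
    stages: dict[str, StageStatus] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "stages": {
                k: {
                    "status": v.status,
                    "wall_clock_s": round(v.wall_clock_s, 3),
                    "files": v.files,
                    "reason": v.reason,
                }
                for k, v in self.stages.items()
            },
        }

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _dump_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


class Workflow:
    """Stage runner bound to a config, a run directory and a master seed.

    Per-stage RNGs are spawned from one seed sequence, so resuming a run
    midway yields the same results as running straight through.
    """

    def __init__(self, config: RunConfig, out_dir: str | Path, seed: int | None = None):
        config.validate()
        self.config = config
        self.out_dir = Path(out_dir)
        self.out_dir.mkdir(parents=True, exist_ok=True)
        self.seed = config.seed if seed is None else seed
        children = np.random.SeedSequence(self.seed).spawn(len(STAGES))
        self._rngs = {name: np.random.default_rng(ss) for name, ss in zip(STAGES, children)}
        self.end_states = config.system.build()
        self.ledger = RunLedger(seed=self.seed)
        self._log_audit()

    def _log_audit(self) -> None:
        c = self.config
        logger.info(
            "workflow parameters: %d initial s-values in [1, %g]; undersampling "
            "occurrence >= %.2f (lower bound, %d levels below) and >= %.2f (PEOE); "
            "state-opt offsets +/-%g kJ/mol, tail fraction %.2f; rebalancing x = %g "
            "(literal cap %.3f kJ/mol at T = %g K; %.3f kJ/mol as kB*T*ln(x) at 298.15 K); "
            "%d replicas inserted per N-LRTO iteration; s-iteration schedule %s steps; "
            "round-trip criterion tau_bar/nRT < %g ns at %g steps/ns",
            c.exploration.n_initial_s,
            c.exploration.s_min,
            c.exploration.undersampling_occurrence_min,
            c.exploration.levels_below,
            c.exploration.peoe_undersampling_min,
            c.exploration.bias_offset_magnitude,
            c.exploration.state_opt_tail_fraction,
            c.rebalance_intensity_factor,
            rebalancing_correction_cap(c.thermo, c.rebalance_intensity_factor),
            c.thermo.temperature,
            correction_for_fold_reduction(
                type(c.thermo)(temperature=298.15), c.rebalance_intensity_factor
            ),
            c.optimization.n_insert,
            list(c.optimization.s_iteration_steps),
            c.optimization.rt_time_limit_ns,
            c.optimization.steps_per_ns,
        )

    # -- stage helpers ---------------------------------------------------

    def _stage_dir(self, name: str) -> Path:
        d = self.out_dir / name
        d.mkdir(exist_ok=True)
        return d

    def _finish(self, name: str, t0: float, files: list[Path], status: str = "completed") -> None:
        rel = {str(p.relative_to(self.out_dir)): _sha256(p) for p in files}
        self.ledger.stages[name] = StageStatus(
            name=name, status=status, wall_clock_s=time.perf_counter() - t0, files=rel
        )
        self.ledger.save(self.out_dir / "ledger.json")

    def _fail(self, name: str, t0: float, reason: str) -> None:
        self.ledger.stages[name] = StageStatus(
            name=name, status="failed", wall_clock_s=time.perf_counter() - t0, reason=reason
        )
        self.ledger.save(self.out_dir / "ledger.json")

    def _done(self, name: str) -> bool:
        return (self._stage_dir(name) / "state.json").exists()

    # -- stages ----------------------------------------------------------

    def explore(self) -> dict:
        name = "explore"
        d = self._stage_dir(name)
        state_file = d / "state.json"
        if state_file.exists():
            self.ledger.stages.setdefault(name, StageStatus(name=name, status="resumed"))
            return json.loads(state_file.read_text())
        t0 = time.perf_counter()
        cfg = self.config
        res = run_exploration(
            self.end_states,
            cfg.thermo,
            cfg.exploration,
            self._rngs[name],
            start_mode=cfg.start_mode,
        )
        (d / "lower_bound.txt").write_text(f"{res.lower_bound_s:.10g}\n")
        offsets_tsv = d / "offsets_peoe.tsv"
        pinned = pin_offsets(res.peoe.offsets)
        lines = ["state\toffset\tspread"]
        for i in range(len(pinned)):
            lines.append(f"{i + 1}\t{pinned[i]:.10g}\t{res.peoe.spread[i]:.10g}")
        offsets_tsv.write_text("\n".join(lines) + "\n")
        coords = d / "state_coordinates.txt"
        np.savetxt(coords, res.state_configurations, fmt="%.10g")
        state = {
            "lower_bound_s": res.lower_bound_s,
            "t_phys": res.thresholds.physical.tolist(),
            "t_us": res.thresholds.undersampling.tolist(),
            "offsets": res.peoe.offsets.tolist(),
            "offset_spread": res.peoe.spread.tolist(),
            "state_configurations": res.state_configurations.tolist(),
            "peoe_ladder": list(res.peoe_ladder.values),
            "final_configurations": res.final_configurations.tolist(),
        }
        _dump_json(state_file, state)
        self._finish(name, t0, [d / "lower_bound.txt", offsets_tsv, coords, state_file])
        return state

    def optimize(self) -> dict:
        name = "optimize"
        d = self._stage_dir(name)
        state_file = d / "state.json"
        if state_file.exists():
            self.ledger.stages.setdefault(name, StageStatus(name=name, status="resumed"))
            return json.loads(state_file.read_text())
        upstream = self.explore()
        t0 = time.perf_counter()
        cfg = self.config
        ladder = SDistribution(tuple(upstream["peoe_ladder"]))
        offsets = np.asarray(upstream["offsets"], float)
        if cfg.start_mode == "SSM":
            state_configs = np.asarray(upstream["state_configurations"], float)
            configs = state_configs[np.arange(len(ladder)) % len(self.end_states)]
        else:
            configs = np.asarray(upstream["final_configurations"], float)
        initial = OptimizationState(
            s_distribution=ladder, offsets=offsets, configurations=configs
        )
        result = run_optimization(
            self.end_states,
            cfg.thermo,
            initial,
            cfg.optimization,
            self._rngs[name],
            rebalance_config=RebalanceConfig(
                intensity_factor=cfg.rebalance_intensity_factor, thermo=cfg.thermo
            ),
        )
        iters = d / "iterations.tsv"
        n = len(self.end_states)
        head = ["iteration", "kind", "n_replicas", "nRT", "tau_mean"] + [
            f"f_mc_{i + 1}" for i in range(n)
        ]
        rows = ["\t".join(head)]
        for k, rec in enumerate(result.history, start=1):
            tau = rec.round_trips.mean_round_trip_time
            rows.append(
                "\t".join(
                    [
                        str(k),
                        rec.kind,
                        str(len(rec.s_distribution)),
                        str(rec.round_trips.n_round_trips),
                        "nan" if tau is None else f"{tau:.10g}",
                    ]
                    + [f"{f:.10g}" for f in rec.report.f_mc]
                )
            )
        iters.write_text("\n".join(rows) + "\n")
        s_tsv = d / "s_distribution.tsv"
        s_tsv.write_text("\n".join(f"{v:.10g}" for v in result.s_distribution.values) + "\n")
        off_tsv = d / "offsets_final.tsv"
        pinned = pin_offsets(result.offsets)
        off_tsv.write_text(
            "state\toffset\n"
            + "\n".join(f"{i + 1}\t{v:.10g}" for i, v in enumerate(pinned))
            + "\n"
        )
        state = {
            "s_values": list(result.s_distribution.values),
            "offsets": result.offsets.tolist(),
            "configurations": result.configurations.tolist(),
            "converged": bool(result.converged),
            "status_reasons": result.status_reasons,
            "n_iterations": result.iteration,
        }
        _dump_json(state_file, state)
        self._finish(name, t0, [iters, s_tsv, off_tsv, state_file])
        return state

    def produce(self) -> dict:
        name = "produce"
        d = self._stage_dir(name)
        state_file = d / "state.json"
        if state_file.exists():
            self.ledger.stages.setdefault(name, StageStatus(name=name, status="resumed"))
            return json.loads(state_file.read_text())
        upstream = self.optimize()
        t0 = time.perf_counter()
        cfg = self.config
        ens = ReplicaEnsemble(
            self.end_states,
            s_distribution=SDistribution(tuple(upstream["s_values"])),
            offsets=np.asarray(upstream["offsets"], float),
            thermo=cfg.thermo,
            configurations=np.asarray(upstream["configurations"], float),
        )
        res = run_reeds(
            ens,
            cfg.production.n_steps,
            exchange_interval=cfg.production.exchange_interval,
            record_interval=cfg.production.record_interval,
            rng=self._rngs[name],
        )
        traj_path = d / "energies.tsv"
        write_energy_trajectory(res.trajectory, traj_path)
        exch_path = d / "exchanges.tsv"
        write_exchange_log(res.exchanges, exch_path)
        state = {
            "trajectory": str(traj_path.relative_to(self.out_dir)),
            "n_round_trips": res.round_trips.n_round_trips,
            "tau_mean": res.round_trips.mean_round_trip_time,
            "acceptance_rate": res.acceptance_rate,
        }
        _dump_json(state_file, state)
        self._finish(name, t0, [traj_path, exch_path, state_file])
        return state

    def analyze(self) -> dict:
        name = "analyze"
        d = self._stage_dir(name)
        state_file = d / "state.json"
        if state_file.exists():
            self.ledger.stages.setdefault(name, StageStatus(name=name, status="resumed"))
            return json.loads(state_file.read_text())
        upstream = self.produce()
        t0 = time.perf_counter()
        cfg = self.config
        traj = read_energy_trajectory(self.out_dir / upstream["trajectory"])
        top = traj.at_s(1.0)
        fe = zwanzig_multistate(
            top,
            cfg.thermo,
            discard_fraction=cfg.production.discard_fraction,
            environment_label=cfg.system.preset,
        )
        analytic = analytic_free_energy_matrix(self.end_states, cfg.thermo)
        fe_tsv = d / "free_energies.tsv"
        rows = ["j\ti\tdG\tsigma\tanalytic\terror"]
        n = fe.n_states
        for j in range(n):
            for i in range(n):
                if i == j:
                    continue
                rows.append(
                    f"{j + 1}\t{i + 1}\t{fe.pairwise_dG[j, i]:.10g}\t"
                    f"{fe.uncertainties[j, i]:.10g}\t{analytic[j, i]:.10g}\t"
                    f"{fe.pairwise_dG[j, i] - analytic[j, i]:.10g}"
                )
        fe_tsv.write_text("\n".join(rows) + "\n")
        offsets = traj.offsets_used if traj.offsets_used is not None else np.zeros(n)
        report = sampling_report(top, offsets)
        rep_tsv = d / "sampling.tsv"
        rep_tsv.write_text(report.to_frame().to_csv(sep="\t", index=False))
        err = np.abs(fe.pairwise_dG - analytic)
        state = {
            "max_abs_error": float(np.max(err)),
            "n_frames_used": fe.n_frames_used,
            "f_mc": report.f_mc.tolist(),
            "pairwise_dG": fe.pairwise_dG.tolist(),
            "uncertainties": fe.uncertainties.tolist(),
            "analytic": analytic.tolist(),
        }
        _dump_json(state_file, state)
        self._finish(name, t0, [fe_tsv, rep_tsv, state_file])
        return state

    def run_all(self) -> RunLedger:
        for stage in STAGES:
            method = getattr(self, stage)
            try:
                method()
            except Exception as exc:  # noqa: BLE001 - recorded in the ledger
                self._fail(stage, time.perf_counter(), f"{type(exc).__name__}: {exc}")
                logger.error("stage %s failed: %s; downstream stages skipped", stage, exc)
                for later in STAGES[STAGES.index(stage) + 1 :]:
                    self.ledger.stages[later] = StageStatus(
                        name=later, status="skipped", reason=f"upstream stage {stage} failed"
                    )
                self.ledger.save(self.out_dir / "ledger.json")
                break
        return self.ledger


def run_workflow(config: RunConfig, out_dir: str | Path, seed: int | None = None) -> RunLedger:
    """Execute all four stages in ``out_dir``; returns the run ledger."""
    return Workflow(config, out_dir, seed=seed).run_all()
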