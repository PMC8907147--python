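"""Multistate free-energy estimation from the s = 1 replica.

The Zwanzig (exponential-averaging) formula is applied twice through the
reference state: for every end state

    L_i = ln < exp(-beta * (V_i - V_R)) >_R

is accumulated in one pass over the production frames, and any pairwise
difference follows as

    dG_ji = -(1/beta) * (L_j - L_i).

Because every pair derives from the single vector L, cycle closure
(dG_ca = dG_cb + dG_ba) holds to machine precision by construction.  All
exponential averages are evaluated in log space; ``V_i - V_R`` spans
hundreds of kJ/mol when dummy states are present.

Uncertainties use a first-order (Gaussian) propagation of the standard
error of the exponential averages, with autocorrelation absorbed by a
blocked standard error (10 blocks by default).  Pairwise uncertainties are
computed from the per-block estimates of the *difference* L_j - L_i rather
than by adding the two per-state variances in quadrature: the per-frame
weights of different states are correlated (for two states exactly
anticorrelated), and the blocked difference captures that covariance.
Estimates are cross-checkable against a nonparametric bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import spearmanr

from .potentials import ThermoContext
from .sampling import EnergyTrajectory

__all__ = [
    "FreeEnergyResult",
    "RelativeBindingResult",
    "zwanzig_multistate",
    "gaussian_uncertainty",
    "combine_environments",
    "anchored_absolute",
]


@dataclass
class FreeEnergyResult:
    """Pairwise free-energy differences for one environment.

    ``pairwise_dG[j, i]`` is dG_ji = G_j - G_i in kJ/mol; the matrix is
    exactly antisymmetric with a zero diagonal.
    """

    pairwise_dG: np.ndarray
    uncertainties: np.ndarray
    n_frames_used: int
    environment_label: str = ""
    state_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.pairwise_dG = np.asarray(self.pairwise_dG, dtype=float)
        self.uncertainties = np.asarray(self.uncertainties, dtype=float)
        n = self.pairwise_dG.shape[0]
        if self.pairwise_dG.shape != (n, n):
            raise ValueError("pairwise_dG must be square")
        if not self.state_labels:
            self.state_labels = tuple(f"L{i + 1}" for i in range(n))

    @property
    def n_states(self) -> int:
        return self.pairwise_dG.shape[0]

    def dG(self, j: int, i: int) -> float:
        return float(self.pairwise_dG[j, i])


def _log_weights(traj: EnergyTrajectory, beta: float) -> np.ndarray:
    """Per-frame log Zwanzig weights -beta*(V_i - V_R), shape (F, N)."""
    v = traj.state_energy_matrix()
    vr = traj.v_ref()
    return -beta * (v - vr[:, None])


def _select_s1(traj: EnergyTrajectory) -> EnergyTrajectory:
    levels = traj.s_levels()
    if levels.size > 1:
        if not np.isclose(levels[0], 1.0):
            raise ValueError("trajectory contains no s = 1.0 frames")
        traj = traj.at_s(1.0)
    return traj


def _block_log_means(logw: np.ndarray, n_blocks: int = 10) -> np.ndarray:
    """Per-block L = ln(mean w) for a (F, N) log-weight matrix -> (n_blocks, N).

    With fewer frames than blocks every frame becomes its own block (the
    plain i.i.d. limit); callers warn in that case.
    """
    n = logw.shape[0]
    nb = min(n_blocks, n)
    out = np.empty((nb, logw.shape[1]))
    for j, block in enumerate(np.array_split(logw, nb, axis=0)):
        out[j] = logsumexp(block, axis=0) - np.log(block.shape[0])
    return out


def _blocked_pair_sigma(logw: np.ndarray, n_blocks: int = 10) -> np.ndarray:
    """Covariance-aware pairwise sigma of (L_j - L_i), shape (N, N).

    The per-block difference series carries the full correlation between
    the two weight columns (exact anticorrelation for N = 2), which a
    quadrature sum of per-state variances would miss.
    """
    n, n_states = logw.shape
    if n < n_blocks:
        warnings.warn(
            "fewer frames than blocks; falling back to a single-frame (i.i.d.) blocking",
            stacklevel=3,
        )
    lb = _block_log_means(logw, n_blocks)
    nb = lb.shape[0]
    sig = np.zeros((n_states, n_states))
    for j in range(n_states):
        for i in range(j):
            d = lb[:, j] - lb[:, i]
            if not np.all(np.isfinite(d)):
                s = np.inf
            else:
                s = float(np.std(d, ddof=1)) / np.sqrt(nb) if nb > 1 else np.inf
            sig[j, i] = sig[i, j] = s
    return sig


def zwanzig_multistate(
    traj: EnergyTrajectory,
    thermo: ThermoContext,
    discard_fraction: float = 0.0,
    n_blocks: int = 10,
    environment_label: str = "",
) -> FreeEnergyResult:
    """All pairwise dG_ji from one pass over an s = 1 trajectory.

    ``discard_fraction`` drops initial frames as equilibration (default 0:
    the parameter stages already equilibrate the production start point).
    States whose weights all underflow get infinite uncertainty and a
    warning rather than an error.
    """
    traj = _select_s1(traj).discard(discard_fraction)
    if traj.n_frames < 2:
        raise ValueError("need at least two retained frames")
    beta = thermo.beta
    logw = _log_weights(traj, beta)
    n_frames, n_states = logw.shape
    log_avg = logsumexp(logw, axis=0) - np.log(n_frames)
    g = -log_avg / beta  # per-state -1/beta * L_i (relative free energies)
    if np.any(~np.isfinite(g)):
        bad = [str(i + 1) for i in range(n_states) if not np.isfinite(g[i])]
        warnings.warn(
            f"all Zwanzig weights underflowed for state(s) {', '.join(bad)}; "
            "their free energies and uncertainties are unreliable",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):  # inf - inf on a vanished state's diagonal
        dg = g[:, None] - g[None, :]  # [j, i] = dG_ji
    np.fill_diagonal(dg, 0.0)
    unc = _blocked_pair_sigma(logw, n_blocks) / beta
    np.fill_diagonal(unc, 0.0)
    return FreeEnergyResult(
        pairwise_dG=dg,
        uncertainties=unc,
        n_frames_used=n_frames,
        environment_label=environment_label,
    )


def gaussian_uncertainty(
    traj: EnergyTrajectory,
    pair: tuple[int, int],
    thermo: ThermoContext,
    n_blocks: int = 10,
) -> float:
    """Gaussian-approximation standard error of dG_ji for one state pair.

    Blocked standard error of the per-block difference L_j - L_i, divided
    by beta.  ``pair`` is (j, i) with 0-based state indices.
    """
    traj = _select_s1(traj)
    beta = thermo.beta
    logw = _log_weights(traj, beta)
    j, i = pair
    return float(_blocked_pair_sigma(logw[:, [i, j]], n_blocks)[1, 0] / beta)


@dataclass
class RelativeBindingResult:
    """ddG matrix (complex minus water) with optional reference statistics."""

    ddG: np.ndarray
    uncertainties: np.ndarray
    state_labels: tuple[str, ...] = ()
    rmse: float | None = None
    rmse_uncertainty: float | None = None
    mae: float | None = None
    mae_spread: float | None = None
    spearman: float | None = None

    @property
    def n_states(self) -> int:
        return self.ddG.shape[0]


def _offdiag(mat: np.ndarray) -> np.ndarray:
    n = mat.shape[0]
    mask = ~np.eye(n, dtype=bool)
    return mat[mask]


def combine_environments(
    water: FreeEnergyResult,
    complex_: FreeEnergyResult,
    reference_ddG: np.ndarray | None = None,
    n_bootstrap: int = 100,
    rng: np.random.Generator | None = None,
) -> RelativeBindingResult:
    """Relative binding free energies ddG_ji = dG_ji(complex) - dG_ji(water).

    If a reference matrix (e.g. experimental ddG) is given, RMSE, MAE
    (with the spread of absolute errors) and the Spearman rank coefficient
    are computed over all N(N-1) ordered pairs, and the RMSE uncertainty by
    an ``n_bootstrap``-fold bootstrap over those pairs.
    """
    if water.state_labels != complex_.state_labels:
        raise ValueError(
            f"state labels differ between environments: "
            f"{water.state_labels} vs {complex_.state_labels}"
        )
    ddg = complex_.pairwise_dG - water.pairwise_dG
    unc = np.sqrt(complex_.uncertainties**2 + water.uncertainties**2)
    result = RelativeBindingResult(ddG=ddg, uncertainties=unc, state_labels=water.state_labels)
    if reference_ddG is not None:
        ref = np.asarray(reference_ddG, dtype=float)
        if ref.shape != ddg.shape:
            raise ValueError("reference ddG matrix has the wrong shape")
        pred = _offdiag(ddg)
        obs = _offdiag(ref)
        err = pred - obs
        result.rmse = float(np.sqrt(np.mean(err**2)))
        result.mae = float(np.mean(np.abs(err)))
        result.mae_spread = float(np.std(np.abs(err)))
        result.spearman = float(spearmanr(pred, obs).statistic)
        rng = rng if rng is not None else np.random.default_rng(0)
        boot = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            idx = rng.integers(0, err.size, size=err.size)
            boot[b] = np.sqrt(np.mean(err[idx] ** 2))
        result.rmse_uncertainty = float(np.std(boot, ddof=1))
    return result


def anchored_absolute(
    ddG: np.ndarray,
    experimental_anchors: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Absolute binding free energies by anchoring on experimental values.

    For every state ``a`` with a finite anchor value G_a, each state's
    absolute value is reconstructed as ``G_i(a) = anchor_a + ddG[i, a]``;
    the function returns the per-state mean and standard deviation over all
    anchor choices (population std: the anchor set is exhaustive, not a
    sample).  A single anchor gives a deterministic shift with zero sd.
    """
    ddG = np.asarray(ddG, dtype=float)
    anchors = np.asarray(experimental_anchors, dtype=float)
    n = ddG.shape[0]
    if anchors.shape != (n,):
        raise ValueError("need one (possibly NaN) anchor entry per state")
    valid = np.where(np.isfinite(anchors))[0]
    if valid.size == 0:
        raise ValueError("at least one finite anchor value is required")
    estimates = np.stack([anchors[a] + ddG[:, a] for a in valid], axis=1)  # (N, n_anchors)
    return estimates.mean(axis=1), estimates.std(axis=1)
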